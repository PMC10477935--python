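"""Ortholog-anchored cross-training of two network autoencoders.

The two per-species embeddings are pushed into one joint latent space by a
translation-style objective over ortholog anchor pairs (theta, theta'):
species A's encoder places theta in latent space, and species B's decoder
must reconstruct theta's ortholog's NetMF row from there (and vice versa):

    L_cross = phi * sum_{(i,i') in anchors}
        BCE(sigmoid(De_B(En_A(m_i))), m'_i') +
        BCE(sigmoid(De_A(En_B(m'_i'))), m_i)

Alignment epochs update only the encoders — the alignment should happen in
latent space, not reconstruction space. One *training block* is one
embedding epoch per species followed by one alignment epoch; iterating
blocks lets each species' embedding absorb information from the other.

Bidirectionality is exact here: all computation runs in a canonical network
order keyed by content hashes, so ``fit_joint(A, B)`` and ``fit_joint(B, A)``
execute identical arithmetic and the two score matrices are bit-exact
transposes of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .graph_io import Network, OrthologAnchors
from .netmf import NetMFMatrix, netmf_matrix
from .model import (
    AdamState,
    AutoencoderParams,
    LossWeights,
    _stable_bce,
    _lrelu,
    _dlrelu,
    ENCODER_KEYS,
    DIVERGENCE_THRESHOLD,
    encode,
    init_autoencoder,
    train_embed_epoch,
)
from .seeds import derive_seed

__all__ = [
    "FitConfig",
    "JointEmbedding",
    "ScoreMatrix",
    "loss_cross",
    "cross_loss_and_grad",
    "train_align_epoch",
    "fit_joint",
    "score_matrix",
]


@dataclass
class FitConfig:
    """Architecture / optimization knobs for a joint fit.

    ``adjacency_input`` swaps the NetMF matrix for raw adjacency rows (the
    ablation baseline); ``no_cross_training`` drops the alignment epochs so
    phi is ignored.
    """

    hidden: int = 1024
    latent: int = 128
    window: int = 10       # NetMF T
    negative: float = 1.0  # NetMF b
    lr: float = 2e-3
    batch_size: int = 16
    grad_clip: float = 0.0  # 0 disables gradient-norm clipping
    adjacency_input: bool = False
    no_cross_training: bool = False


@dataclass
class JointEmbedding:
    """Result of :func:`fit_joint`, in the caller's (A, B) orientation."""

    Z_A: np.ndarray
    Z_B: np.ndarray
    params_A: AutoencoderParams
    params_B: AutoencoderParams
    ids_A: list[str]
    ids_B: list[str]
    input_A: np.ndarray
    input_B: np.ndarray
    log: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    # canonical bookkeeping for exact bidirectionality
    swapped: bool = False


@dataclass
class ScoreMatrix:
    """Cross-species cosine-similarity matrix (rows species A, cols B)."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.col_ids) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# cross loss


def _forward_cross(enc: AutoencoderParams, dec: AutoencoderParams, X: np.ndarray):
    """Encode with one species' encoder, decode with the other's decoder."""
    te, td = enc.tensors, dec.tensors
    s = enc.slope
    H1p = X @ te["enc_W1"] + te["enc_b1"]
    H1 = _lrelu(H1p, s)
    Z = H1 @ te["enc_W2"] + te["enc_b2"]  # linear latent
    H2p = Z @ td["dec_W1"] + td["dec_b1"]
    H2 = _lrelu(H2p, s)
    logits = H2 @ td["dec_W2"] + td["dec_b2"]
    return H1p, H1, Z, H2p, H2, logits


def _direction_loss_and_grad(
    enc: AutoencoderParams,
    dec: AutoencoderParams,
    X: np.ndarray,
    Y: np.ndarray,
    g_enc: dict[str, np.ndarray],
    g_dec: dict[str, np.ndarray],
) -> float:
    """One translation direction; per-anchor BCE is mean-per-entry, summed."""
    te, td = enc.tensors, dec.tensors
    s = enc.slope
    H1p, H1, Z, H2p, H2, logits = _forward_cross(enc, dec, X)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite cross-reconstruction logits")
    width = Y.shape[1]
    loss = float(_stable_bce(logits, Y).sum() / width)

    dlogits = (1.0 / (1.0 + np.exp(-logits)) - Y) / width
    g_dec["dec_W2"] += H2.T @ dlogits
    g_dec["dec_b2"] += dlogits.sum(axis=0)
    dH2 = (dlogits @ td["dec_W2"].T) * _dlrelu(H2p, s)
    g_dec["dec_W1"] += Z.T @ dH2
    g_dec["dec_b1"] += dH2.sum(axis=0)
    dZ = dH2 @ td["dec_W1"].T
    dZp = dZ  # linear latent
    g_enc["enc_W2"] += H1.T @ dZp
    g_enc["enc_b2"] += dZp.sum(axis=0)
    dH1 = (dZp @ te["enc_W2"].T) * _dlrelu(H1p, s)
    g_enc["enc_W1"] += X.T @ dH1
    g_enc["enc_b1"] += dH1.sum(axis=0)
    return loss


def cross_loss_and_grad(
    params_A: AutoencoderParams,
    params_B: AutoencoderParams,
    X_A: np.ndarray,
    X_B: np.ndarray,
    targets_A: np.ndarray,
    targets_B: np.ndarray,
    pairs: np.ndarray,
    phi: float,
):
    """Cross-training loss over anchor ``pairs`` plus gradients.

    Returns ``(loss, grads_A, grads_B)``; gradient dicts cover both encoder
    and decoder tensors (callers freezing decoders simply ignore those keys).
    """
    if len(pairs) == 0:
        raise ValueError("empty anchor set")
    pairs = np.asarray(pairs)
    ia, ib = pairs[:, 0], pairs[:, 1]
    gA = {k: np.zeros_like(v) for k, v in params_A.tensors.items()}
    gB = {k: np.zeros_like(v) for k, v in params_B.tensors.items()}
    loss = _direction_loss_and_grad(
        params_A, params_B, X_A[ia], targets_B[ib], gA, gB
    )
    loss += _direction_loss_and_grad(
        params_B, params_A, X_B[ib], targets_A[ia], gB, gA
    )
    for g in (gA, gB):
        for k in g:
            g[k] *= phi
    return phi * loss, gA, gB


def loss_cross(
    params_A: AutoencoderParams,
    params_B: AutoencoderParams,
    M_A: NetMFMatrix | np.ndarray,
    M_B: NetMFMatrix | np.ndarray,
    anchors: OrthologAnchors | np.ndarray,
    phi: float,
) -> float:
    """Evaluate the cross-training objective (no gradients)."""
    X_A = M_A.values if isinstance(M_A, NetMFMatrix) else M_A
    X_B = M_B.values if isinstance(M_B, NetMFMatrix) else M_B
    T_A = M_A.scaled01() if isinstance(M_A, NetMFMatrix) else M_A
    T_B = M_B.scaled01() if isinstance(M_B, NetMFMatrix) else M_B
    pairs = np.asarray(anchors.pairs if isinstance(anchors, OrthologAnchors) else anchors)
    if len(pairs) == 0:
        raise ValueError("empty anchor set")
    if phi == 0:
        return 0.0
    ia, ib = pairs[:, 0], pairs[:, 1]
    *_, logits_ab = _forward_cross(params_A, params_B, X_A[ia])
    *_, logits_ba = _forward_cross(params_B, params_A, X_B[ib])
    loss = float(_stable_bce(logits_ab, T_B[ib]).sum() / T_B.shape[1])
    loss += float(_stable_bce(logits_ba, T_A[ia]).sum() / T_A.shape[1])
    return phi * loss


def train_align_epoch(
    params_A: AutoencoderParams,
    params_B: AutoencoderParams,
    X_A: np.ndarray,
    X_B: np.ndarray,
    targets_A: np.ndarray,
    targets_B: np.ndarray,
    pairs: np.ndarray,
    phi: float,
    opt_A: AdamState,
    opt_B: AdamState,
    seed: int,
    batch_size: int = 16,
    divergence_threshold: float = DIVERGENCE_THRESHOLD,
) -> float:
    """One pass over anchors in seeded mini-batches; encoders only.

    Decoder tensors are bitwise unchanged on return. Returns the summed
    cross loss of the epoch's batches.
    """
    rng = np.random.default_rng(seed)
    pairs = np.asarray(pairs)
    order = rng.permutation(len(pairs))
    total = 0.0
    for start in range(0, len(pairs), batch_size):
        batch = pairs[order[start : start + batch_size]]
        loss, gA, gB = cross_loss_and_grad(
            params_A, params_B, X_A, X_B, targets_A, targets_B, batch, phi
        )
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite cross loss")
        if loss > divergence_threshold:
            raise FloatingPointError(f"cross loss diverged ({loss:.3g})")
        opt_A.step(params_A, gA, only=ENCODER_KEYS)
        opt_B.step(params_B, gB, only=ENCODER_KEYS)
        total += loss
    return total


# ---------------------------------------------------------------------------
# joint fitting


def _input_matrices(net: Network, cfg: FitConfig):
    """Autoencoder input rows and scaled BCE targets for one species."""
    if cfg.adjacency_input:
        X = net.adjacency.toarray()
        return X, X
    M = netmf_matrix(net, window=cfg.window, negative=cfg.negative)
    return M.values, M.scaled01()


def fit_joint(
    netA: Network,
    netB: Network,
    anchors: OrthologAnchors,
    weights: LossWeights | tuple[LossWeights, LossWeights] | None = None,
    blocks: int = 10,
    config: FitConfig | None = None,
    seed: int = 0,
) -> JointEmbedding:
    """Train the two autoencoders and align them over the anchors.

    ``weights`` may be a single :class:`LossWeights` (shared) or one per
    species ``(w_A, w_B)``; ``phi`` is read from the canonically-first
    species' weights so it cannot depend on argument order.
    Results are independent of argument order: internally the two networks
    are processed in a canonical order keyed by their content hashes.
    """
    if config is None:
        config = FitConfig()
    if weights is None:
        weights = LossWeights()
    if isinstance(weights, LossWeights):
        wA = wB = weights
    else:
        wA, wB = weights
    if len(anchors) == 0:
        raise ValueError("anchors must be nonempty")
    if blocks < 0:
        raise ValueError("blocks must be >= 0")

    hashA, hashB = netA.content_hash(), netB.content_hash()
    swapped = hashB < hashA
    if swapped:
        net1, net2 = netB, netA
        w1, w2 = wB, wA
        pairs12 = np.asarray([(b, a) for a, b in anchors.pairs])
        h1, h2 = hashB, hashA
    else:
        net1, net2 = netA, netB
        w1, w2 = wA, wB
        pairs12 = np.asarray(anchors.pairs)
        h1, h2 = hashA, hashB
    # phi belongs to the canonically-first species so argument order is moot
    phi = w1.phi

    X1, T1 = _input_matrices(net1, config)
    X2, T2 = _input_matrices(net2, config)

    p1 = init_autoencoder(net1.n, config.hidden, config.latent,
                          seed=derive_seed(seed, "init", h1))
    p2 = init_autoencoder(net2.n, config.hidden, config.latent,
                          seed=derive_seed(seed, "init", h2))
    # one optimizer per species per phase: the cross gradients are on a very
    # different scale from the embedding gradients, and sharing Adam moment
    # estimates across the two phases measurably degrades both
    opt1 = AdamState(lr=config.lr, clip=config.grad_clip)
    opt2 = AdamState(lr=config.lr, clip=config.grad_clip)
    opt1_align = AdamState(lr=config.lr, clip=config.grad_clip)
    opt2_align = AdamState(lr=config.lr, clip=config.grad_clip)

    log: list[dict] = []
    for block in range(blocks):
        e1 = train_embed_epoch(
            p1, X1, T1, net1, w1, opt1,
            seed=derive_seed(seed, "embed", h1, str(block)),
            batch_size=config.batch_size,
        )
        e2 = train_embed_epoch(
            p2, X2, T2, net2, w2, opt2,
            seed=derive_seed(seed, "embed", h2, str(block)),
            batch_size=config.batch_size,
        )
        entry = {"block": block, "embed_1": e1, "embed_2": e2}
        if not config.no_cross_training and phi > 0:
            entry["cross"] = train_align_epoch(
                p1, p2, X1, X2, T1, T2, pairs12, phi, opt1_align, opt2_align,
                seed=derive_seed(seed, "align", h1, h2, str(block)),
                batch_size=config.batch_size,
            )
        log.append(entry)

    Z1 = encode(p1, X1)
    Z2 = encode(p2, X2)

    cfg_snapshot = dict(asdict(config), blocks=blocks, seed=int(seed),
                        phi=phi, swapped=swapped)
    if swapped:
        return JointEmbedding(
            Z_A=Z2, Z_B=Z1, params_A=p2, params_B=p1,
            ids_A=list(net2.vertex_ids), ids_B=list(net1.vertex_ids),
            input_A=X2, input_B=X1, log=log, config=cfg_snapshot, swapped=True,
        )
    return JointEmbedding(
        Z_A=Z1, Z_B=Z2, params_A=p1, params_B=p2,
        ids_A=list(net1.vertex_ids), ids_B=list(net2.vertex_ids),
        input_A=X1, input_B=X2, log=log, config=cfg_snapshot, swapped=False,
    )


def _normalize_rows(Z: np.ndarray, ids: list[str]) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"zero-norm embedding row for vertex {ids[zero[0]]!r}")
    return Z / norms[:, None]


def score_matrix(joint: JointEmbedding) -> ScoreMatrix:
    """All-pairs cross-species cosine similarities (rows A, columns B).

    Computed in the canonical network order so that the matrices from
    ``fit_joint(A, B)`` and ``fit_joint(B, A)`` are exact transposes.
    """
    if joint.swapped:
        Zn1 = _normalize_rows(joint.Z_B, joint.ids_B)
        Zn2 = _normalize_rows(joint.Z_A, joint.ids_A)
        return ScoreMatrix((Zn1 @ Zn2.T).T, list(joint.ids_A), list(joint.ids_B))
    Zn1 = _normalize_rows(joint.Z_A, joint.ids_A)
    Zn2 = _normalize_rows(joint.Z_B, joint.ids_B)
    return ScoreMatrix(Zn1 @ Zn2.T, list(joint.ids_A), list(joint.ids_B))


def cosine_scores(Z_A: np.ndarray, Z_B: np.ndarray,
                  ids_A: list[str] | None = None,
                  ids_B: list[str] | None = None) -> ScoreMatrix:
    """Cosine score matrix for two arbitrary embedding matrices."""
    ids_A = ids_A if ids_A is not None else [str(i) for i in range(len(Z_A))]
    ids_B = ids_B if ids_B is not None else [str(i) for i in range(len(Z_B))]
    Zn1 = _normalize_rows(np.asarray(Z_A, dtype=float), ids_A)
    Zn2 = _normalize_rows(np.asarray(Z_B, dtype=float), ids_B)
    return ScoreMatrix(Zn1 @ Zn2.T, ids_A, ids_B)


def random_weight_search(n_draws: int, seed: int = 0) -> list[LossWeights]:
    """Seeded log-uniform draws over the recommended search ranges.

    alpha in [1e0, 1e3]; gamma, lam, omega, phi in [1e-1, 1e2]. A plain
    hook for manual exploration; the shipped defaults are not tuned by it.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_draws):
        out.append(
            LossWeights(
                alpha=10 ** rng.uniform(0, 3),
                gamma=10 ** rng.uniform(-1, 2),
                lam=10 ** rng.uniform(-1, 2),
                omega=10 ** rng.uniform(-1, 2),
                phi=10 ** rng.uniform(-1, 2),
            )
        )
    return out
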