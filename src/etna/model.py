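"""Per-species graph autoencoder: architecture, losses and training.

Each species' network is embedded by an autoencoder that takes the rows of
the NetMF matrix as input: encoder ``n -> 1024 -> 128`` and an independent
decoder ``128 -> 1024 -> n``, leaky-rectifier activations (negative slope
0.1) after every layer except the decoder output, which stays in logit space.

The embedding objective combines four terms,

    L_embed = alpha * L_high + gamma * L_1st + lambda * L2 + omega * L_norm

* ``L_high``  — binary cross-entropy between the sigmoid of the decoder
  logits and the (min-max scaled) NetMF rows: reconstruction of multi-hop
  neighborhood structure.
* ``L_1st``   — ``-(1/2|E|) sum_{ij} A_ij log cos(z_i, z_j)``: adjacent
  vertices are pulled together in latent space; only reported edges
  contribute (missing edges in PPI data are unreliable negatives).
* ``L2``      — squared weight-matrix entries (biases excluded).
* ``L_norm``  — ``sum_i ||z_i||^2`` against exploding latent norms.

Everything here is plain numpy with hand-written backpropagation; the
gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph_io import Network
from .netmf import NetMFMatrix

__all__ = [
    "LossWeights",
    "AutoencoderParams",
    "AdamState",
    "init_autoencoder",
    "encode",
    "decode",
    "loss_first_order",
    "loss_high",
    "l2_penalty",
    "loss_norm",
    "loss_embed",
    "embed_loss_and_grad",
    "train_embed_epoch",
]

COS_EPS = 1e-8

WEIGHT_KEYS = ("enc_W1", "enc_W2", "dec_W1", "dec_W2")
ENCODER_KEYS = ("enc_W1", "enc_b1", "enc_W2", "enc_b2")


@dataclass
class LossWeights:
    """Weights of the loss terms; defaults are the recommended starting set."""

    alpha: float = 100.0  # L_high
    gamma: float = 5.0    # L_1st
    lam: float = 1.0      # L2 on weights
    omega: float = 1.0    # latent norm penalty
    phi: float = 50.0     # cross-training loss

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "lam", "omega", "phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be >= 0")


@dataclass
class AutoencoderParams:
    """Encoder/decoder tensors plus activation slope.

    ``tensors`` maps names (enc_W1, enc_b1, enc_W2, enc_b2, dec_W1, dec_b1,
    dec_W2, dec_b2) to arrays; encoder maps n -> hidden -> latent, decoder
    latent -> hidden -> n with independent weights.
    """

    tensors: dict[str, np.ndarray]
    slope: float = 0.1
    seed: int = 0

    @property
    def n(self) -> int:
        return self.tensors["enc_W1"].shape[0]

    @property
    def hidden(self) -> int:
        return self.tensors["enc_W1"].shape[1]

    @property
    def latent(self) -> int:
        return self.tensors["enc_W2"].shape[1]

    def copy(self) -> "AutoencoderParams":
        return AutoencoderParams(
            {k: v.copy() for k, v in self.tensors.items()},
            slope=self.slope,
            seed=self.seed,
        )


def init_autoencoder(
    n: int, hidden: int = 1024, latent: int = 128, seed: int = 0
) -> AutoencoderParams:
    """Seeded fan-in-scaled uniform initialization (U(-1/sqrt(f), 1/sqrt(f)))."""
    if n <= 0 or hidden <= 0 or latent <= 0:
        raise ValueError("layer sizes must be positive")
    if latent > n:
        import warnings

        warnings.warn("latent dimension exceeds input dimension", stacklevel=2)
    rng = np.random.default_rng(seed)

    def layer(fan_in: int, fan_out: int) -> tuple[np.ndarray, np.ndarray]:
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = rng.uniform(-bound, bound, size=fan_out)
        return W, b

    t: dict[str, np.ndarray] = {}
    t["enc_W1"], t["enc_b1"] = layer(n, hidden)
    t["enc_W2"], t["enc_b2"] = layer(hidden, latent)
    t["dec_W1"], t["dec_b1"] = layer(latent, hidden)
    t["dec_W2"], t["dec_b2"] = layer(hidden, n)
    return AutoencoderParams(t, seed=int(seed))


def _lrelu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _dlrelu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def encode(params: AutoencoderParams, X: np.ndarray | NetMFMatrix) -> np.ndarray:
    """Map input rows to latent rows Z.

    The hidden layer is leaky-rectified; the embedding layer itself is
    linear. A rectified latent would push all coordinates positive and
    collapse the cosine-similarity score distribution into a narrow cone,
    so the latent must carry both signs.
    """
    if isinstance(X, NetMFMatrix):
        X = X.values
    t, s = params.tensors, params.slope
    if X.shape[1] != params.n:
        raise ValueError(f"input width {X.shape[1]} != encoder width {params.n}")
    H1 = _lrelu(X @ t["enc_W1"] + t["enc_b1"], s)
    return H1 @ t["enc_W2"] + t["enc_b2"]


def decode(params: AutoencoderParams, Z: np.ndarray) -> np.ndarray:
    """Map latent rows back to reconstruction logits (pre-sigmoid)."""
    t, s = params.tensors, params.slope
    if Z.shape[1] != params.latent:
        raise ValueError(f"latent width {Z.shape[1]} != decoder width {params.latent}")
    H2 = _lrelu(Z @ t["dec_W1"] + t["dec_b1"], s)
    return H2 @ t["dec_W2"] + t["dec_b2"]


# ---------------------------------------------------------------------------
# loss terms


def _cosine_rows(Z: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding row")
    num = np.einsum("ij,ij->i", Z[idx_i], Z[idx_j])
    return num / (norms[idx_i] * norms[idx_j])


def loss_first_order(Z: np.ndarray, net: Network) -> float:
    """First-order proximity loss over reported edges (nonnegative).

    ``-(1/(2|E|)) * sum_{i,j} A_ij log(clamp(cos(z_i, z_j), eps, 1))`` with
    the ordered-pair sum counting each undirected edge twice.
    """
    if net.n_edges < 1:
        raise ValueError("network has no edges")
    coo = net.adjacency.tocoo()
    deg = net.degrees
    norms = np.linalg.norm(Z, axis=1)
    bad = np.where((norms == 0) & (deg > 0))[0]
    if bad.size:
        raise ValueError(f"zero-norm embedding row for vertex index {bad[0]}")
    cos = _cosine_rows(Z, coo.row, coo.col)
    cl = np.clip(cos, COS_EPS, 1.0)
    return float(-np.log(cl).sum() / (2.0 * net.n_edges))


def _stable_bce(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy in the numerically stable logit form."""
    return (
        np.maximum(logits, 0.0)
        - logits * targets
        + np.log1p(np.exp(-np.abs(logits)))
    )


def loss_high(
    logits: np.ndarray,
    targets: np.ndarray | NetMFMatrix,
    normalization: str = "row",
) -> float:
    """Binary cross-entropy between sigmoid(logits) and the scaled M.

    ``normalization="row"`` (default) divides the summed cross-entropy by
    the number of rows only — each vertex contributes the *sum* over its
    n reconstruction entries. This is the scale on which the recommended
    loss weights balance: with a per-entry mean the reconstruction term
    would be ~n times smaller than the weight penalty at alpha=100,
    lambda=1 and the latent provably collapses to zero.
    ``normalization="entry"`` gives the per-entry mean form instead.
    """
    if isinstance(targets, NetMFMatrix):
        targets = targets.scaled01()
    if logits.shape != targets.shape:
        raise ValueError("logits / target shape mismatch")
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    total = float(_stable_bce(logits, targets).sum())
    if normalization == "row":
        return total / logits.shape[0]
    if normalization == "entry":
        return total / logits.size
    raise ValueError("normalization must be 'row' or 'entry'")


def l2_penalty(params: AutoencoderParams) -> float:
    """Sum of squared weight entries; biases excluded."""
    return float(sum(np.sum(params.tensors[k] ** 2) for k in WEIGHT_KEYS))


def loss_norm(Z: np.ndarray) -> float:
    """sum_i ||z_i||^2 — keeps latent norms bounded."""
    return float(np.sum(Z * Z))


def loss_embed(
    Z: np.ndarray,
    logits: np.ndarray,
    net: Network,
    targets: np.ndarray | NetMFMatrix,
    params: AutoencoderParams,
    w: LossWeights,
    normalization: str = "row",
) -> float:
    """The combined embedding objective (see module docstring)."""
    return (
        w.alpha * loss_high(logits, targets, normalization=normalization)
        + w.gamma * loss_first_order(Z, net)
        + w.lam * l2_penalty(params)
        + w.omega * loss_norm(Z)
    )


# ---------------------------------------------------------------------------
# gradients

_ZERO = object()


def embed_loss_and_grad(
    params: AutoencoderParams,
    X: np.ndarray,
    targets: np.ndarray,
    net: Network,
    w: LossWeights,
    rows: np.ndarray | None = None,
):
    """Loss and exact gradient of the (optionally row-restricted) objective.

    With ``rows=None`` this is exactly ``loss_embed`` on the full input. With
    a row subset B the objective restricts L_high and L_norm to rows in B,
    L_1st to ordered pairs whose first element is in B, and scales the L2
    term by |B|/n so a full shuffled pass matches the full objective in
    expectation. All rows are still encoded, because neighbors of batch rows
    receive first-order gradients.
    """
    t, s = params.tensors, params.slope
    n = params.n
    if rows is None:
        rows = np.arange(n)
    rows = np.asarray(rows)
    sf = rows.size / n

    # forward
    H1p = X @ t["enc_W1"] + t["enc_b1"]
    H1 = _lrelu(H1p, s)
    Z = H1 @ t["enc_W2"] + t["enc_b2"]  # linear latent
    H2p = Z[rows] @ t["dec_W1"] + t["dec_b1"]
    H2 = _lrelu(H2p, s)
    logits = H2 @ t["dec_W2"] + t["dec_b2"]
    Yb = targets[rows]

    # L_high, row-normalized: each vertex contributes its summed row BCE
    n_rows = logits.shape[0]
    loss = w.alpha * float(_stable_bce(logits, Yb).sum() / n_rows)
    dlogits = w.alpha * (1.0 / (1.0 + np.exp(-logits)) - Yb) / n_rows

    g = {k: np.zeros_like(v) for k, v in t.items()}
    g["dec_W2"] += H2.T @ dlogits
    g["dec_b2"] += dlogits.sum(axis=0)
    dH2 = (dlogits @ t["dec_W2"].T) * _dlrelu(H2p, s)
    g["dec_W1"] += Z[rows].T @ dH2
    g["dec_b1"] += dH2.sum(axis=0)
    dZ = np.zeros_like(Z)
    np.add.at(dZ, rows, dH2 @ t["dec_W1"].T)

    # L_norm
    loss += w.omega * float(np.sum(Z[rows] ** 2))
    dZ[rows] += w.omega * 2.0 * Z[rows]

    # L_1st over ordered pairs (i, j) with i in batch
    m = net.n_edges
    if m >= 1 and w.gamma > 0:
        sub = net.adjacency[rows].tocoo()
        idx_i = rows[sub.row]
        idx_j = sub.col
        norms = np.linalg.norm(Z, axis=1)
        if np.any(norms[np.unique(np.concatenate([idx_i, idx_j]))] == 0):
            raise ValueError("zero-norm embedding row on an edge endpoint")
        cos = np.einsum("ij,ij->i", Z[idx_i], Z[idx_j]) / (norms[idx_i] * norms[idx_j])
        cl = np.clip(cos, COS_EPS, 1.0)
        loss += w.gamma * float(-np.log(cl).sum() / (2.0 * m))
        active = (cos > COS_EPS) & (cos < 1.0)
        dcos = np.zeros_like(cos)
        dcos[active] = w.gamma * (-1.0 / cl[active]) / (2.0 * m)
        # d cos / d z_i and d cos / d z_j
        inv_ni = 1.0 / norms[idx_i]
        inv_nj = 1.0 / norms[idx_j]
        gi = (Z[idx_j] * inv_nj[:, None] - cos[:, None] * Z[idx_i] * inv_ni[:, None]) * inv_ni[:, None]
        gj = (Z[idx_i] * inv_ni[:, None] - cos[:, None] * Z[idx_j] * inv_nj[:, None]) * inv_nj[:, None]
        np.add.at(dZ, idx_i, dcos[:, None] * gi)
        np.add.at(dZ, idx_j, dcos[:, None] * gj)

    # encoder backward (latent is linear)
    dZp = dZ
    g["enc_W2"] += H1.T @ dZp
    g["enc_b2"] += dZp.sum(axis=0)
    dH1 = (dZp @ t["enc_W2"].T) * _dlrelu(H1p, s)
    g["enc_W1"] += X.T @ dH1
    g["enc_b1"] += dH1.sum(axis=0)

    # L2 (scaled so a full epoch of batches applies it once in expectation)
    if w.lam > 0:
        l2 = sum(np.sum(t[k] ** 2) for k in WEIGHT_KEYS)
        loss += sf * w.lam * float(l2)
        for k in WEIGHT_KEYS:
            g[k] += sf * w.lam * 2.0 * t[k]

    return loss, g


# ---------------------------------------------------------------------------
# optimizer and epochs


@dataclass
class AdamState:
    """Adaptive-moment optimizer state over a named tensor dict."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    clip: float = 0.0  # 0 disables; norm clipping interacts badly with Adam here
    t: int = 0
    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def step(self, params: AutoencoderParams, grads: dict[str, np.ndarray],
             only: tuple[str, ...] | None = None) -> None:
        keys = tuple(grads) if only is None else only
        if self.clip and self.clip > 0:
            gn = np.sqrt(sum(float(np.sum(grads[k] ** 2)) for k in keys))
            if gn > self.clip:
                scale = self.clip / gn
                grads = {k: grads[k] * scale for k in keys}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in keys:
            gk = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(gk)
                self.v[k] = np.zeros_like(gk)
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params.tensors[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


DIVERGENCE_THRESHOLD = 1e6


def train_embed_epoch(
    params: AutoencoderParams,
    X: np.ndarray,
    targets: np.ndarray,
    net: Network,
    w: LossWeights,
    opt: AdamState,
    seed: int,
    batch_size: int = 16,
    divergence_threshold: float = DIVERGENCE_THRESHOLD,
) -> float:
    """One pass over all vertex rows in seeded shuffled mini-batches.

    Returns the mean per-batch loss. Raises on non-finite or diverging loss.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(params.n)
    losses = []
    for start in range(0, params.n, batch_size):
        batch = order[start : start + batch_size]
        loss, grads = embed_loss_and_grad(params, X, targets, net, w, rows=batch)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite embedding loss")
        if loss > divergence_threshold:
            raise FloatingPointError(f"embedding loss diverged ({loss:.3g})")
        opt.step(params, grads)
        losses.append(loss)
    return float(np.mean(losses))
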