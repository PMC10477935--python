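"""Evaluation stack for cross-species joint embeddings.

Implements the functional-similarity gold standard (co-annotation to a slim
term set), ranking metrics (AUPRC over random, top-k Jaccard), cross-species
gene-set matching with a degree-matched null, gene-stratified
cross-validation with leakage guards, synthetic-lethality transfer with an
RBF-kernel SVM, and the top-percentile cross-species score graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.svm import SVC

from .align import ScoreMatrix
from .graph_io import AnnotationTable, Network, OrthologAnchors

__all__ = [
    "PairStandard",
    "FoldAssignment",
    "GeneSetMatch",
    "select_slim",
    "build_pair_standard",
    "auprc_over_random",
    "jaccard_index",
    "jaccard_topk",
    "gene_set_match_z",
    "gene_stratified_folds",
    "sl_predict_eval",
    "top_percent_graph",
]


@dataclass
class PairStandard:
    """Labeled cross-species gene pairs and the positive prior."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    slim: set[str]

    @property
    def prior(self) -> float:
        return float(self.labels.mean())

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FoldAssignment:
    """Gene -> fold maps for both species; anchored orthologs share folds."""

    fold_of_A: dict[str, int]
    fold_of_B: dict[str, int]
    k: int
    excluded_pairs: int = 0


@dataclass
class GeneSetMatch:
    """Connectivity of one matched cross-species gene set vs a null."""

    term: str
    observed: float
    t_score: float
    null_mean: float
    null_sd: float
    z_score: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# slim selection and pair standard


def select_slim(
    annA: AnnotationTable,
    annB: AnnotationTable,
    min_genes: int = 10,
    max_genes: int = 100,
    curated: set[str] | None = None,
) -> set[str]:
    """Terms annotated to [min, max] genes in each species separately.

    A curated term list, restricted to terms annotated in both species, is
    unioned in regardless of the size filter.
    """
    t2gA, t2gB = annA.term_to_genes, annB.term_to_genes
    slim = {
        t
        for t in set(t2gA) & set(t2gB)
        if min_genes <= len(t2gA[t]) <= max_genes
        and min_genes <= len(t2gB[t]) <= max_genes
    }
    if curated:
        slim |= {t for t in curated if t in t2gA and t in t2gB}
    if not slim:
        raise ValueError("empty slim term set")
    return slim


def build_pair_standard(
    annA: AnnotationTable,
    annB: AnnotationTable,
    slim: set[str],
    genesA,
    genesB,
) -> PairStandard:
    """Label every cross-species pair of annotated genes.

    Positive iff the two genes share at least one slim term; genes without
    any annotation are excluded entirely (not counted as negatives).
    """
    if not slim:
        raise ValueError("slim term set is empty")
    gA = [g for g in genesA if annA.terms_of(g)]
    gB = [g for g in genesB if annB.terms_of(g)]
    pairs: list[tuple[str, str]] = []
    labels: list[int] = []
    slimA = {g: annA.terms_of(g) & slim for g in gA}
    slimB = {g: annB.terms_of(g) & slim for g in gB}
    for a in gA:
        sa = slimA[a]
        for b in gB:
            pairs.append((a, b))
            labels.append(1 if sa & slimB[b] else 0)
    labels_arr = np.asarray(labels, dtype=np.int8)
    if labels_arr.sum() == 0 or labels_arr.sum() == len(labels_arr):
        raise ValueError("pair standard needs both positives and negatives")
    return PairStandard(pairs=pairs, labels=labels_arr, slim=set(slim))


# ---------------------------------------------------------------------------
# ranking metrics


def auprc_over_random(scores, labels) -> tuple[float, float]:
    """AUPRC and its log2 enrichment over the positive prior.

    0 means random performance, 1 a two-fold improvement over random; the
    AUPRC is step-interpolated average precision.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to compute AUPRC")
    auprc = float(average_precision_score(labels, scores))
    prior = float(labels.mean())
    return auprc, float(np.log2(auprc / prior))


def jaccard_index(termsA: set, termsB: set) -> float:
    """|intersection| / |union|; 0 when both sets are empty."""
    union = len(termsA | termsB)
    if union == 0:
        return 0.0
    return len(termsA & termsB) / union


def _ranked_pairs(S: ScoreMatrix, mask: np.ndarray | None = None):
    """Indices of matrix entries sorted by score desc, then id pair lex."""
    n, m = S.shape
    flat = S.values.ravel()
    idx = np.arange(flat.size)
    if mask is not None:
        idx = idx[mask.ravel()]
    ids = [(S.row_ids[i // m], S.col_ids[i % m]) for i in idx]
    order = sorted(range(len(idx)), key=lambda r: (-flat[idx[r]], ids[r]))
    return [idx[r] for r in order]


def jaccard_topk(
    S: ScoreMatrix,
    annA: AnnotationTable,
    annB: AnnotationTable,
    k: int,
    exclude_anchors: bool = False,
    anchors: OrthologAnchors | None = None,
) -> list[float]:
    """Jaccard indices of the k highest-scoring annotated cross pairs.

    Pairs are ranked score-descending with a deterministic lexicographic
    tie-break; with ``exclude_anchors`` the anchor id pairs are removed from
    the ranking first (the "novel pairs" view).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n, m = S.shape
    maskA = np.array([bool(annA.terms_of(g)) for g in S.row_ids])
    maskB = np.array([bool(annB.terms_of(g)) for g in S.col_ids])
    mask = maskA[:, None] & maskB[None, :]
    if exclude_anchors and anchors is not None:
        anchor_ids = set(anchors.source_ids)
        for i, a in enumerate(S.row_ids):
            if not maskA[i]:
                continue
            for j, b in enumerate(S.col_ids):
                if (a, b) in anchor_ids:
                    mask[i, j] = False
    ranked = _ranked_pairs(S, mask)
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds {len(ranked)} annotated cross pairs")
    out = []
    for flat in ranked[:k]:
        a, b = S.row_ids[flat // m], S.col_ids[flat % m]
        out.append(jaccard_index(annA.terms_of(a), annB.terms_of(b)))
    return out


# ---------------------------------------------------------------------------
# gene-set matching with a degree-matched null


def _degree_bins(net: Network, n_bins: int = 10) -> dict[str, np.ndarray]:
    """Vertex indices grouped into degree-quantile bins."""
    deg = net.degrees
    quantiles = np.quantile(deg, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_of = np.searchsorted(quantiles, deg, side="right")
    return {b: np.where(bin_of == b)[0] for b in np.unique(bin_of)}, bin_of


def _matched_sample(idx: np.ndarray, bins, bin_of, rng) -> np.ndarray:
    """Random vertex set matching the degree-bin profile of ``idx``."""
    out = np.empty(len(idx), dtype=int)
    for r, i in enumerate(idx):
        pool = bins[bin_of[i]]
        out[r] = pool[rng.integers(len(pool))]
    return out


def _block_t(S: np.ndarray, rows: np.ndarray, cols: np.ndarray,
             global_mean: float) -> tuple[float, float]:
    block = S[np.ix_(rows, cols)]
    obs = float(block.mean())
    sd = float(block.std(ddof=1))
    if sd == 0:
        return obs, np.nan
    return obs, (obs - global_mean) / (sd / np.sqrt(block.size))


def gene_set_match_z(
    S: ScoreMatrix,
    setA,
    setB,
    netA: Network,
    netB: Network,
    n_null: int = 100,
    seed: int = 0,
    n_bins: int = 10,
    term: str = "",
) -> GeneSetMatch:
    """Connectivity z-score of a matched cross-species gene set.

    The observed statistic is the mean score over setA x setB, standardized
    into a t-score against the global matrix mean; the z-score compares that
    t against ``n_null`` replicates drawn with the same set sizes from
    degree-quantile-matched vertices of each species.
    """
    rng = np.random.default_rng(seed)
    rowsA = np.array([S.row_ids.index(g) if isinstance(g, str) else g for g in setA])
    colsB = np.array([S.col_ids.index(g) if isinstance(g, str) else g for g in setB])
    if rowsA.size == 0 or colsB.size == 0:
        raise ValueError("gene sets must be nonempty")
    binsA, bin_of_A = _degree_bins(netA, n_bins)
    binsB, bin_of_B = _degree_bins(netB, n_bins)
    gmean = float(S.values.mean())

    obs, t_obs = _block_t(S.values, rowsA, colsB, gmean)
    null_t = np.empty(n_null)
    for r in range(n_null):
        ra = _matched_sample(rowsA, binsA, bin_of_A, rng)
        rb = _matched_sample(colsB, binsB, bin_of_B, rng)
        _, null_t[r] = _block_t(S.values, ra, rb, gmean)

    degenerate = bool(np.isnan(t_obs) or np.isnan(null_t).any())
    valid = null_t[~np.isnan(null_t)]
    if valid.size < 2:
        null_mean, null_sd, z = np.nan, np.nan, np.nan
        degenerate = True
    else:
        null_mean = float(valid.mean())
        null_sd = float(valid.std(ddof=1))
        if null_sd == 0 or np.isnan(null_sd):
            degenerate = True
            z = np.nan
        else:
            z = float((t_obs - null_mean) / null_sd)
    return GeneSetMatch(
        term=term, observed=obs, t_score=float(t_obs), null_mean=null_mean,
        null_sd=null_sd, z_score=z, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# gene-stratified cross-validation


def gene_stratified_folds(
    genesA,
    genesB,
    anchors: OrthologAnchors | list[tuple[str, str]] | None,
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Assign genes of both species to k folds, keeping orthologs together.

    Genes are grouped into connected components over anchor edges (so an
    anchored pair can never span folds); components are dealt to folds
    greedily by size from a seeded shuffle. Pairs whose genes land in
    different folds are meant to be excluded by the caller.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    genesA, genesB = list(genesA), list(genesB)
    nodes = [("A", g) for g in genesA] + [("B", g) for g in genesB]
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(u, v):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv

    if anchors is not None:
        src = anchors.source_ids if isinstance(anchors, OrthologAnchors) else anchors
        for a, b in src:
            if ("A", a) in parent and ("B", b) in parent:
                union(("A", a), ("B", b))

    comps: dict = {}
    for v in nodes:
        comps.setdefault(find(v), []).append(v)
    components = list(comps.values())
    if len(components) < k:
        raise ValueError(f"only {len(components)} gene components for k={k} folds")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(components))
    # largest-first greedy balance over the shuffled deterministic tie order
    order = sorted(order, key=lambda i: (-len(components[i]), i))
    sizes = np.zeros(k, dtype=int)
    fold_of_A: dict[str, int] = {}
    fold_of_B: dict[str, int] = {}
    for ci in order:
        f = int(np.argmin(sizes))
        for sp, g in components[ci]:
            (fold_of_A if sp == "A" else fold_of_B)[g] = f
        sizes[f] += len(components[ci])
    return FoldAssignment(fold_of_A=fold_of_A, fold_of_B=fold_of_B, k=k)


def count_excluded_pairs(folds: FoldAssignment, pairs) -> int:
    """Number of (geneA, geneB) pairs whose genes sit in different folds."""
    return sum(
        1
        for a, b in pairs
        if folds.fold_of_A.get(a) != folds.fold_of_B.get(b)
    )


# ---------------------------------------------------------------------------
# synthetic-lethality transfer


class LeakageError(RuntimeError):
    """A test-fold gene appeared in the training pairs."""


def _median_heuristic_gamma(X: np.ndarray, rng) -> float:
    sub = X if len(X) <= 500 else X[rng.choice(len(X), 500, replace=False)]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices(len(sub), k=1)])
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med)


def _pair_features(Z: np.ndarray, index: dict[str, int], pairs) -> np.ndarray:
    """Order-invariant features: the sum of the two embedding rows."""
    return np.array([Z[index[a]] + Z[index[b]] for a, b in pairs])


def _balanced_standard(positives, genes, rng):
    """Positives plus an equal number of sampled non-positive pairs.

    Negatives are drawn among genes that occur in at least one positive
    pair (the SL-participating genes), excluding reported positives.
    """
    pos = {tuple(sorted(p)) for p in positives}
    genes = sorted(genes)
    negs: set[tuple[str, str]] = set()
    max_tries = 100 * len(pos) + 1000
    tries = 0
    while len(negs) < len(pos) and tries < max_tries:
        tries += 1
        a, b = rng.choice(len(genes), 2, replace=False)
        pair = tuple(sorted((genes[a], genes[b])))
        if pair in pos or pair in negs:
            continue
        negs.add(pair)
    if len(negs) < len(pos):
        raise ValueError("could not sample enough negative pairs")
    pairs = sorted(pos) + sorted(negs)
    labels = np.array([1] * len(pos) + [0] * len(negs))
    return pairs, labels


def sl_predict_eval(
    Z_by_species: dict[str, tuple[np.ndarray, list[str]]],
    positives_by_species: dict[str, list[tuple[str, str]]],
    mode: str = "within",
    train_species: str | None = None,
    test_species: str | None = None,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[float, float]:
    """Genetic-interaction prediction from embedding-sum features.

    ``within`` mode does k-fold gene-split cross-validation inside one
    species (pairs spanning folds are excluded); ``cross`` mode trains an
    RBF-kernel SVM on one species' pairs and evaluates on the other's, both
    expressed in the joint latent space. A leakage audit raises if any test
    gene occurs among the training genes. Returns (AUPRC, AUROC), averaged
    over evaluable folds — per-fold decision scores are not pooled because
    separately-fitted SVMs are not on a common scale.
    """
    rng = np.random.default_rng(seed)
    if mode not in ("within", "cross"):
        raise ValueError("mode must be 'within' or 'cross'")

    def standard_for(species):
        Z, ids = Z_by_species[species]
        index = {g: i for i, g in enumerate(ids)}
        pos = [p for p in positives_by_species[species]
               if p[0] in index and p[1] in index]
        if not pos:
            raise ValueError(f"no usable positive pairs for {species}")
        sl_genes = {g for p in pos for g in p}
        pairs, labels = _balanced_standard(pos, sl_genes, rng)
        return Z, index, pairs, labels

    fold_metrics: list[tuple[float, float]] = []
    if mode == "within":
        species = train_species or next(iter(positives_by_species))
        Z, index, pairs, labels = standard_for(species)
        genes = sorted({g for p in pairs for g in p})
        fold_of = {g: int(f) for g, f in zip(
            genes, rng.permutation(len(genes)) % k
        )}
        for f in range(k):
            train_idx = [i for i, (a, b) in enumerate(pairs)
                         if fold_of[a] != f and fold_of[b] != f]
            test_idx = [i for i, (a, b) in enumerate(pairs)
                        if fold_of[a] == f and fold_of[b] == f]
            if not train_idx or not test_idx:
                continue
            train_genes = {g for i in train_idx for g in pairs[i]}
            test_genes = {g for i in test_idx for g in pairs[i]}
            if train_genes & test_genes:
                raise LeakageError("test gene found in training folds")
            ytr = labels[train_idx]
            yte = labels[test_idx]
            if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
                continue
            Xtr = _pair_features(Z, index, [pairs[i] for i in train_idx])
            Xte = _pair_features(Z, index, [pairs[i] for i in test_idx])
            gamma = _median_heuristic_gamma(Xtr, rng)
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            clf.fit(Xtr, ytr)
            sc = clf.decision_function(Xte)
            fold_metrics.append(
                (float(average_precision_score(yte, sc)),
                 float(roc_auc_score(yte, sc)))
            )
    else:
        if train_species is None or test_species is None:
            raise ValueError("cross mode needs train_species and test_species")
        Ztr, itr, ptr, ytr = standard_for(train_species)
        Zte, ite, pte, yte = standard_for(test_species)
        # distinct species -> distinct gene universes; audit anyway
        if ({g for p in ptr for g in p} & {g for p in pte for g in p}
                and train_species == test_species):
            raise LeakageError("test gene found in training pairs")
        Xtr = _pair_features(Ztr, itr, ptr)
        Xte = _pair_features(Zte, ite, pte)
        gamma = _median_heuristic_gamma(Xtr, rng)
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(Xtr, ytr)
        sc = clf.decision_function(Xte)
        fold_metrics.append(
            (float(average_precision_score(yte, sc)),
             float(roc_auc_score(yte, sc)))
        )

    if not fold_metrics:
        raise ValueError("no evaluable folds")
    auprc = float(np.mean([m[0] for m in fold_metrics]))
    auroc = float(np.mean([m[1] for m in fold_metrics]))
    return auprc, auroc


# ---------------------------------------------------------------------------
# top-percentile score graph


def top_percent_graph(
    S: ScoreMatrix, percent: float = 1.0, min_degree: int = 0
) -> list[tuple[str, str]]:
    """Bipartite edge list of the top percent of cross-species scores.

    Takes the floor(percent/100 * n * n') highest entries with the standard
    deterministic tie-break; vertices with degree below ``min_degree`` are
    pruned from the returned edge list afterwards (display convention).
    """
    if not (0 < percent <= 100):
        raise ValueError("percent must be in (0, 100]")
    n, m = S.shape
    n_top = int(np.floor(percent / 100.0 * n * m))
    if n_top == 0:
        raise ValueError("zero pairs selected at this percentile")
    ranked = _ranked_pairs(S)[:n_top]
    edges = [(S.row_ids[f // m], S.col_ids[f % m]) for f in ranked]
    if min_degree > 0:
        from collections import Counter

        deg = Counter()
        for a, b in edges:
            deg[("A", a)] += 1
            deg[("B", b)] += 1
        edges = [
            (a, b)
            for a, b in edges
            if deg[("A", a)] >= min_degree and deg[("B", b)] >= min_degree
        ]
    return edges
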