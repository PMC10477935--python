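"""Network, anchor and annotation I/O plus topology preprocessing.

The canonical in-memory containers are:

* :class:`Network` — an undirected, unweighted simple graph with an ordered
  vertex index and a sparse symmetric adjacency matrix.
* :class:`OrthologAnchors` — cross-network index pairs tying two networks.
* :class:`AnnotationTable` — gene -> functional-term sets (e.g. GO biological
  process), with ancestor propagation over ``is_a`` / ``part_of`` relations.

Preprocessing removes self-loops, degree-0 vertices and — recursively —
duplicate-neighborhood vertices: with only topology as input, two vertices
with identical neighbor sets are indistinguishable to the embedding model, so
one seeded-random representative per duplicate group is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Network",
    "PreprocessReport",
    "OrthologAnchors",
    "AnnotationTable",
    "read_edge_list",
    "network_from_edges",
    "write_edge_list",
    "preprocess_network",
    "replay_report",
    "read_anchor_pairs",
    "write_anchor_pairs",
    "read_gaf",
    "read_ontology_table",
    "read_obo",
    "propagate_annotations",
]


class GraphIOError(ValueError):
    """Malformed input file or empty result."""


@dataclass
class Network:
    """Undirected simple graph with an ordered vertex index.

    Attributes
    ----------
    vertex_ids : list of str
        Gene identifiers in index order (opaque strings).
    adjacency : scipy.sparse.csr_matrix
        Symmetric binary n x n matrix with zero diagonal.
    """

    vertex_ids: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency, dtype=np.float64)
        self._index = {v: i for i, v in enumerate(self.vertex_ids)}

    @property
    def n(self) -> int:
        return len(self.vertex_ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def volume(self) -> int:
        """vol(G): the sum of vertex degrees (twice the edge count)."""
        return int(self.degrees.sum())

    @property
    def n_edges(self) -> int:
        return self.volume // 2

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edge_set(self) -> set[tuple[str, str]]:
        """Undirected edges as sorted id pairs."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        out = set()
        for i, j in zip(coo.row, coo.col):
            a, b = self.vertex_ids[i], self.vertex_ids[j]
            out.add((a, b) if a <= b else (b, a))
        return out

    def content_hash(self) -> str:
        """Stable hash of the vertex-labelled edge structure."""
        import hashlib

        h = hashlib.sha256()
        for a, b in sorted(self.edge_set()):
            h.update(a.encode())
            h.update(b"\t")
            h.update(b.encode())
            h.update(b"\n")
        for v in sorted(set(self.vertex_ids) - {g for e in self.edge_set() for g in e}):
            h.update(b"|")
            h.update(v.encode())
        return h.hexdigest()

    def validate(self) -> None:
        A = self.adjacency
        if A.shape != (self.n, self.n):
            raise GraphIOError("adjacency shape does not match vertex count")
        if A.diagonal().any():
            raise GraphIOError("adjacency has nonzero diagonal (self-loop)")
        if (A != A.T).nnz != 0:
            raise GraphIOError("adjacency is not symmetric")
        if A.nnz and not np.all(np.isin(A.data, [1.0])):
            raise GraphIOError("adjacency entries must be in {0, 1}")


@dataclass
class PreprocessReport:
    """Replayable log of what :func:`preprocess_network` removed.

    ``collapsed_duplicates`` lists, per recursion round, groups as
    ``(kept_id, [removed_ids])``.
    """

    removed_self_loops: int = 0
    removed_isolated: list[str] = field(default_factory=list)
    collapsed_duplicates: list[list[tuple[str, list[str]]]] = field(default_factory=list)
    seed: int = 0

    def removed_vertices(self) -> list[str]:
        out = list(self.removed_isolated)
        for round_groups in self.collapsed_duplicates:
            for _, removed in round_groups:
                out.extend(removed)
        return out

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed\t{self.seed}\n")
            fh.write(f"# removed_self_loops\t{self.removed_self_loops}\n")
            for v in self.removed_isolated:
                fh.write(f"isolated\t{v}\n")
            for r, groups in enumerate(self.collapsed_duplicates):
                for kept, removed in groups:
                    fh.write(f"duplicate\t{r}\t{kept}\t{','.join(removed)}\n")


@dataclass
class OrthologAnchors:
    """Cross-network anchor pairs, as indices into two :class:`Network` s."""

    pairs: list[tuple[int, int]]
    source_ids: list[tuple[str, str]]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def mirrored(self) -> "OrthologAnchors":
        return OrthologAnchors(
            pairs=[(b, a) for a, b in self.pairs],
            source_ids=[(y, x) for x, y in self.source_ids],
            dropped=[(y, x) for x, y in self.dropped],
        )


@dataclass
class AnnotationTable:
    """gene id -> set of term ids, with the inverse map kept in sync."""

    gene_to_terms: dict[str, set[str]]
    propagated: bool = False

    @property
    def term_to_genes(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                inv.setdefault(t, set()).add(g)
        return inv

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())

    @property
    def genes(self) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if ts}

    def restricted(self, genes) -> "AnnotationTable":
        keep = set(genes)
        return AnnotationTable(
            {g: set(ts) for g, ts in self.gene_to_terms.items() if g in keep},
            propagated=self.propagated,
        )


# ---------------------------------------------------------------------------
# edge lists


def network_from_edges(edges, vertex_order=None) -> Network:
    """Build a :class:`Network` from an iterable of id pairs.

    Self-loops are dropped; duplicate undirected edges are collapsed. When
    ``vertex_order`` is None, vertices are indexed in first-appearance order.
    """
    seen_edges: set[tuple[str, str]] = set()
    order: list[str] = []
    index: dict[str, int] = {}

    def intern(g: str) -> int:
        if g not in index:
            index[g] = len(order)
            order.append(g)
        return index[g]

    if vertex_order is not None:
        for g in vertex_order:
            intern(g)

    n_self = 0
    rows, cols = [], []
    for a, b in edges:
        a, b = str(a), str(b)
        ia, ib = intern(a), intern(b)
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen_edges:
            continue
        seen_edges.add(key)
        rows += [ia, ib]
        cols += [ib, ia]

    n = len(order)
    if n == 0:
        raise GraphIOError("empty edge set")
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    return Network(order, A)


def read_edge_list(path: str, delimiter: str = "\t") -> Network:
    """Read an undirected unweighted network from a two-column edge list.

    Lines starting with ``#`` are ignored; self-loops are removed and
    duplicate undirected edges deduplicated. Vertex order is first appearance.
    """
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise GraphIOError(f"{path}: malformed line {lineno}: {line!r}")
            edges.append((parts[0].strip(), parts[1].strip()))
    if not edges:
        raise GraphIOError(f"{path}: empty edge set")
    return network_from_edges(edges)


def write_edge_list(net: Network, path: str, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edge_set()):
            fh.write(f"{a}{delimiter}{b}\n")


# ---------------------------------------------------------------------------
# preprocessing


def _neighbor_groups(net: Network) -> list[list[int]]:
    """Group vertex indices by identical neighbor sets (self excluded)."""
    A = net.adjacency.tocsr()
    groups: dict[tuple, list[int]] = {}
    for i in range(net.n):
        nbrs = tuple(A.indices[A.indptr[i] : A.indptr[i + 1]])
        groups.setdefault(nbrs, []).append(i)
    return [g for g in groups.values() if len(g) > 1]


def preprocess_network(net: Network, seed: int = 0) -> tuple[Network, PreprocessReport]:
    """Remove degree-0 vertices and collapse duplicate-neighborhood vertices.

    Runs to fixpoint: each round removes isolated vertices, then keeps one
    uniformly random representative (seeded) per group of vertices sharing an
    identical neighbor set. Returns the reduced network and a replayable
    report.
    """
    rng = np.random.default_rng(seed)
    report = PreprocessReport(seed=int(seed))
    cur = Network(list(net.vertex_ids), net.adjacency.copy())
    cur.adjacency.setdiag(0)
    cur.adjacency.eliminate_zeros()

    while True:
        deg = cur.degrees
        isolated = np.where(deg == 0)[0]
        changed = False
        if isolated.size:
            report.removed_isolated.extend(cur.vertex_ids[i] for i in isolated)
            keep = np.where(deg > 0)[0]
            if keep.size == 0:
                raise GraphIOError("network fully collapsed during preprocessing")
            cur = Network(
                [cur.vertex_ids[i] for i in keep],
                cur.adjacency[np.ix_(keep, keep)].tocsr(),
            )
            changed = True

        groups = _neighbor_groups(cur)
        if groups:
            round_log: list[tuple[str, list[str]]] = []
            drop: set[int] = set()
            for g in groups:
                kept = g[int(rng.integers(len(g)))]
                removed = [i for i in g if i != kept]
                drop.update(removed)
                round_log.append(
                    (cur.vertex_ids[kept], [cur.vertex_ids[i] for i in removed])
                )
            report.collapsed_duplicates.append(round_log)
            keep = np.array([i for i in range(cur.n) if i not in drop])
            if keep.size == 0:
                raise GraphIOError("network fully collapsed during preprocessing")
            cur = Network(
                [cur.vertex_ids[i] for i in keep],
                cur.adjacency[np.ix_(keep, keep)].tocsr(),
            )
            changed = True

        if not changed:
            break

    if cur.n == 0:
        raise GraphIOError("network fully collapsed during preprocessing")
    return cur, report


def replay_report(raw: Network, report: PreprocessReport) -> Network:
    """Reapply a :class:`PreprocessReport` to the raw network.

    Removes exactly the vertices the report names (after zeroing self-loops)
    and returns the induced subgraph; used to audit reproducibility.
    """
    removed = set(report.removed_vertices())
    keep = [i for i, v in enumerate(raw.vertex_ids) if v not in removed]
    A = raw.adjacency.tolil(copy=True)
    A.setdiag(0)
    A = A.tocsr()
    A.eliminate_zeros()
    return Network([raw.vertex_ids[i] for i in keep], A[np.ix_(keep, keep)].tocsr())


# ---------------------------------------------------------------------------
# anchors


def read_anchor_pairs(path: str, netA: Network, netB: Network) -> OrthologAnchors:
    """Read two-column ortholog pairs and map them onto network indices.

    Pairs with either gene absent from the (preprocessed) networks are
    dropped and logged; duplicates are collapsed.
    """
    pairs_raw = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GraphIOError(f"{path}: malformed line {lineno}: {line!r}")
            pairs_raw.append((parts[0].strip(), parts[1].strip()))
    return anchors_from_pairs(pairs_raw, netA, netB)


def anchors_from_pairs(pairs_raw, netA: Network, netB: Network) -> OrthologAnchors:
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[int, int]] = []
    source: list[tuple[str, str]] = []
    dropped: list[tuple[str, str]] = []
    for a, b in pairs_raw:
        if (a, b) in seen:
            continue
        seen.add((a, b))
        if a in netA and b in netB:
            pairs.append((netA.index_of(a), netB.index_of(b)))
            source.append((a, b))
        else:
            dropped.append((a, b))
    if not pairs:
        raise GraphIOError("no anchors available for alignment")
    return OrthologAnchors(pairs=pairs, source_ids=source, dropped=dropped)


def write_anchor_pairs(anchors: OrthologAnchors, path: str) -> None:
    with open(path, "w") as fh:
        for a, b in anchors.source_ids:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# annotations (GAF 2.x) and ontology relations

DEFAULT_EVIDENCE_ALLOW = frozenset({"EXP", "IDA", "IMP", "IGI", "IEP"})
DEFAULT_EVIDENCE_DENY = frozenset({"IPI"})


def read_gaf(
    path: str,
    aspect: str = "P",
    evidence_allow=DEFAULT_EVIDENCE_ALLOW,
    evidence_deny=DEFAULT_EVIDENCE_DENY,
) -> AnnotationTable:
    """Read a GAF 2.x annotation file into an :class:`AnnotationTable`.

    Keeps the (DB object id, GO id) columns, filtered to the given ontology
    aspect (default biological process, ``P``) and to the experimental,
    low-throughput evidence codes; ``IPI`` is excluded by default so physical
    interactions cannot leak into PPI-based evaluations. ``NOT`` qualifiers
    are skipped.
    """
    gene_to_terms: dict[str, set[str]] = {}
    allow = set(evidence_allow) if evidence_allow else None
    deny = set(evidence_deny or ())
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            gene, qualifier, term, evidence, asp = (
                cols[1],
                cols[3],
                cols[4],
                cols[6],
                cols[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            if aspect and asp != aspect:
                continue
            if allow is not None and evidence not in allow:
                continue
            if evidence in deny:
                continue
            gene_to_terms.setdefault(gene, set()).add(term)
    return AnnotationTable(gene_to_terms, propagated=False)


def write_gaf(ann: AnnotationTable, path: str, db: str = "SYN", evidence: str = "EXP",
              aspect: str = "P") -> None:
    """Write an annotation table as a minimal valid GAF 2.2 file."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(ann.gene_to_terms):
            for term in sorted(ann.gene_to_terms[gene]):
                fields = [
                    db, gene, gene, "involved_in", term, "REF:0", evidence,
                    "", aspect, "", "", "protein", "taxon:0", "20200716", db,
                ]
                fh.write("\t".join(fields) + "\n")


PROPAGATION_RELATIONS = frozenset({"is_a", "part_of"})


def read_ontology_table(path: str) -> list[tuple[str, str, str]]:
    """Read a (term, parent, relation) tab-delimited table."""
    rels = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GraphIOError(f"{path}: malformed line {lineno}: {line!r}")
            rels.append((parts[0], parts[1], parts[2]))
    return rels


def read_obo(path: str) -> list[tuple[str, str, str]]:
    """Extract (term, parent, relation) triples from an OBO file.

    Only ``is_a`` and ``relationship: part_of`` lines of ``[Term]`` stanzas
    are collected; obsolete terms are skipped.
    """
    rels = []
    term = None
    in_term = False
    obsolete = False
    pending: list[tuple[str, str]] = []

    def flush():
        if term and not obsolete:
            rels.extend((term, parent, rel) for parent, rel in pending)

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                term, obsolete, pending = None, False, []
            elif in_term:
                if line.startswith("id:"):
                    term = line[3:].strip()
                elif line.startswith("is_a:"):
                    pending.append((line[5:].split("!")[0].strip(), "is_a"))
                elif line.startswith("relationship:"):
                    parts = line[len("relationship:") :].split("!")[0].split()
                    if len(parts) >= 2 and parts[0] == "part_of":
                        pending.append((parts[1], "part_of"))
                elif line == "is_obsolete: true":
                    obsolete = True
    flush()
    return rels


def _ancestor_closure(relations) -> dict[str, set[str]]:
    """Map each term to the set of its ancestors; raises on cycles."""
    parents: dict[str, set[str]] = {}
    for child, parent, rel in relations:
        if rel in PROPAGATION_RELATIONS:
            parents.setdefault(child, set()).add(parent)

    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    ancestors: dict[str, set[str]] = {}

    def visit(t: str, stack: list[str]) -> set[str]:
        state = color.get(t, WHITE)
        if state == BLACK:
            return ancestors[t]
        if state == GRAY:
            cyc = stack[stack.index(t) :] + [t]
            raise GraphIOError(f"ontology relation cycle: {' -> '.join(cyc)}")
        color[t] = GRAY
        stack.append(t)
        anc: set[str] = set()
        for p in parents.get(t, ()):
            anc.add(p)
            anc |= visit(p, stack)
        stack.pop()
        color[t] = BLACK
        ancestors[t] = anc
        return anc

    for t in list(parents):
        visit(t, [])
    return ancestors


def propagate_annotations(ann: AnnotationTable, ontology) -> AnnotationTable:
    """Close every gene's term set under is_a / part_of ancestor traversal."""
    ancestors = _ancestor_closure(ontology)
    out: dict[str, set[str]] = {}
    for gene, terms in ann.gene_to_terms.items():
        closed = set(terms)
        for t in terms:
            closed |= ancestors.get(t, set())
        out[gene] = closed
    return AnnotationTable(out, propagated=True)
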