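"""Metrics, gold standards, folds, gene-set matching and SL transfer."""

import numpy as np
import pytest

from etna.align import ScoreMatrix, cosine_scores
from etna.graph_io import AnnotationTable, network_from_edges
from etna.evaluation import (
    LeakageError,
    auprc_over_random,
    build_pair_standard,
    count_excluded_pairs,
    gene_set_match_z,
    gene_stratified_folds,
    jaccard_index,
    jaccard_topk,
    select_slim,
    sl_predict_eval,
    top_percent_graph,
)


def make_ann(d):
    return AnnotationTable({g: set(t) for g, t in d.items()}, propagated=True)


class TestSlim:
    def test_size_bounds_per_species(self):
        # t1: 5 genes in A (below min); t2: 200 genes in B (above max);
        # t3 passes in both species
        annA = make_ann({f"a{i}": ["t1"] for i in range(5)}
                        | {f"b{i}": ["t2"] for i in range(50)}
                        | {f"c{i}": ["t3"] for i in range(30)})
        annB = make_ann({f"x{i}": ["t1"] for i in range(20)}
                        | {f"y{i}": ["t2"] for i in range(200)}
                        | {f"z{i}": ["t3"] for i in range(40)})
        assert select_slim(annA, annB, min_genes=10, max_genes=100) == {"t3"}
        with pytest.raises(ValueError, match="empty slim"):
            select_slim(annA, annB, min_genes=60, max_genes=80)

    def test_filter_comprehension_oracle(self, rng):
        terms = [f"t{i}" for i in range(20)]
        annA = make_ann({
            f"a{i}": rng.choice(terms, 3, replace=False) for i in range(60)
        })
        annB = make_ann({
            f"b{i}": rng.choice(terms, 3, replace=False) for i in range(60)
        })
        slim = select_slim(annA, annB, min_genes=5, max_genes=15)
        tA, tB = annA.term_to_genes, annB.term_to_genes
        oracle = {
            t for t in terms
            if 5 <= len(tA.get(t, ())) <= 15 and 5 <= len(tB.get(t, ())) <= 15
        }
        assert slim == oracle

    def test_curated_union_restricted_to_shared(self):
        annA = make_ann({"a1": ["t1", "t9"], "a2": ["t1"]})
        annB = make_ann({"b1": ["t1"]})
        slim = select_slim(annA, annB, min_genes=1, max_genes=5,
                           curated={"t9", "t_missing"})
        assert "t1" in slim
        assert "t9" not in slim  # t9 unannotated in B
        assert "t_missing" not in slim


class TestPairStandard:
    def test_shared_term_positive(self):
        annA = make_ann({"gA": ["t1"], "gC": ["t3"]})
        annB = make_ann({"gB": ["t1"], "gD": ["t2"]})
        std = build_pair_standard(annA, annB, {"t1", "t2", "t3"},
                                  ["gA", "gC"], ["gB", "gD"])
        labels = dict(zip(std.pairs, std.labels))
        assert labels[("gA", "gB")] == 1
        assert labels[("gA", "gD")] == 0
        assert labels[("gC", "gB")] == 0

    def test_prior_matches_exhaustive_pair_oracle(self, rng):
        terms = [f"t{i}" for i in range(6)]
        annA = make_ann({f"a{i}": rng.choice(terms, 2, replace=False)
                         for i in range(10)})
        annB = make_ann({f"b{i}": rng.choice(terms, 2, replace=False)
                         for i in range(10)})
        slim = set(terms)
        std = build_pair_standard(annA, annB, slim, sorted(annA.genes),
                                  sorted(annB.genes))
        oracle = np.mean([
            1 if annA.terms_of(a) & annB.terms_of(b) else 0
            for a in sorted(annA.genes) for b in sorted(annB.genes)
        ])
        assert std.prior == pytest.approx(float(oracle))

    def test_symmetry_under_species_swap(self, rng):
        terms = [f"t{i}" for i in range(5)]
        annA = make_ann({f"a{i}": rng.choice(terms, 2, replace=False)
                         for i in range(6)})
        annB = make_ann({f"b{i}": rng.choice(terms, 2, replace=False)
                         for i in range(6)})
        fwd = build_pair_standard(annA, annB, set(terms),
                                  sorted(annA.genes), sorted(annB.genes))
        rev = build_pair_standard(annB, annA, set(terms),
                                  sorted(annB.genes), sorted(annA.genes))
        fl = dict(zip(fwd.pairs, fwd.labels))
        rl = dict(zip(rev.pairs, rev.labels))
        assert all(fl[(a, b)] == rl[(b, a)] for a, b in fl)

    def test_one_class_raises(self):
        annA = make_ann({"a": ["t1"]})
        annB = make_ann({"b": ["t1"]})
        with pytest.raises(ValueError):
            build_pair_standard(annA, annB, {"t1"}, ["a"], ["b"])


class TestAUPRC:
    def test_footnote_semantics(self):
        # hand-built score lists realizing auprc == prior and == 2 * prior
        labels = [1, 0, 1, 0, 0, 1, 0, 0, 0, 0]
        const = np.ones(len(labels))  # constant scores: AP equals the prior
        auprc, over = auprc_over_random(const, labels)
        assert auprc == pytest.approx(0.3)
        assert over == pytest.approx(0.0, abs=1e-12)

    def test_perfect_ranking_toy(self):
        labels = [1, 1, 1] + [0] * 7
        scores = list(range(10, 0, -1))
        auprc, over = auprc_over_random(scores, labels)
        assert auprc == pytest.approx(1.0)
        assert over == pytest.approx(np.log2(1 / 0.3), rel=1e-12)

    def test_doubling_gives_one(self):
        # construct a ranking whose AP is exactly 2 * prior, then check log2
        labels = np.array([1, 0, 0, 0])
        scores = np.array([4.0, 3.0, 2.0, 1.0])
        auprc, over = auprc_over_random(scores, labels)
        assert auprc == pytest.approx(1.0)  # single positive ranked first
        labels2 = np.array([1, 0, 1, 0, 0, 0, 0, 0])
        scores2 = np.array([8, 7, 6, 5, 4, 3, 2, 1.0])
        auprc2, over2 = auprc_over_random(scores2, labels2)
        # AP = (1 + 2/3)/2 = 5/6; prior = 1/4
        assert auprc2 == pytest.approx(5 / 6)
        assert over2 == pytest.approx(np.log2((5 / 6) / 0.25), rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        scores = rng.normal(size=50)
        a1 = auprc_over_random(scores, labels)
        a2 = auprc_over_random(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            auprc_over_random([1.0, 2.0], [1, 1])


class TestJaccard:
    def test_basic_values(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_index({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard_index({"a"}, {"b"}) == 0.0
        assert jaccard_index(set(), set()) == 0.0

    def test_topk_matches_sort_oracle(self):
        V = np.array([[0.9, 0.1], [0.5, 0.8]])
        S = ScoreMatrix(V, ["a1", "a2"], ["b1", "b2"])
        annA = make_ann({"a1": ["t1"], "a2": ["t2"]})
        annB = make_ann({"b1": ["t1", "t2"], "b2": ["t2"]})
        vals = jaccard_topk(S, annA, annB, k=2)
        # ranking: (a1,b1)=0.9 then (a2,b2)=0.8
        assert vals == [
            pytest.approx(1 / 2),  # {t1} vs {t1,t2}
            pytest.approx(1.0),    # {t2} vs {t2}
        ]

    def test_tie_break_lexicographic(self):
        V = np.array([[0.5, 0.5], [0.5, 0.5]])
        S = ScoreMatrix(V, ["a2", "a1"], ["b1", "b2"])
        annA = make_ann({"a1": ["t1"], "a2": ["t1"]})
        annB = make_ann({"b1": ["t1"], "b2": ["t2"]})
        vals = jaccard_topk(S, annA, annB, k=1)
        # all scores tie; lexicographically first pair is (a1, b1)
        assert vals[0] == pytest.approx(1.0)

    def test_exclude_anchor_pairs(self):
        from etna.graph_io import OrthologAnchors
        V = np.array([[0.9, 0.1]])
        S = ScoreMatrix(V, ["a1"], ["b1", "b2"])
        annA = make_ann({"a1": ["t1"]})
        annB = make_ann({"b1": ["t1"], "b2": ["t1"]})
        anchors = OrthologAnchors(pairs=[(0, 0)], source_ids=[("a1", "b1")])
        vals = jaccard_topk(S, annA, annB, k=1, exclude_anchors=True,
                            anchors=anchors)
        assert len(vals) == 1  # only (a1, b2) remains

    def test_k_validation(self):
        S = ScoreMatrix(np.array([[1.0]]), ["a"], ["b"])
        ann = make_ann({"a": ["t"], "b": ["t"]})
        with pytest.raises(ValueError):
            jaccard_topk(S, ann, ann, k=0)
        with pytest.raises(ValueError):
            jaccard_topk(S, ann, ann, k=5)


def chain_net(ids):
    return network_from_edges(list(zip(ids[:-1], ids[1:])))


class TestGeneSetMatch:
    def test_constant_matrix_flagged_degenerate(self):
        ids_a = [f"a{i}" for i in range(12)]
        ids_b = [f"b{i}" for i in range(12)]
        netA, netB = chain_net(ids_a), chain_net(ids_b)
        S = ScoreMatrix(np.full((12, 12), 0.5), ids_a, ids_b)
        res = gene_set_match_z(S, ids_a[:4], ids_b[:4], netA, netB, seed=0)
        assert res.degenerate

    def test_planted_block_high_z(self, rng):
        n = 60
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in range(n)]
        netA, netB = chain_net(ids_a), chain_net(ids_b)
        V = rng.normal(size=(n, n))
        V[:10, :10] += 1.5  # planted high-similarity block
        S = ScoreMatrix(V, ids_a, ids_b)
        res = gene_set_match_z(S, ids_a[:10], ids_b[:10], netA, netB, seed=1)
        assert res.z_score > 3

    def test_observed_statistic_is_hand_mean(self):
        ids_a = ["a0", "a1", "a2"]
        ids_b = ["b0", "b1", "b2"]
        V = np.arange(9, dtype=float).reshape(3, 3)
        S = ScoreMatrix(V, ids_a, ids_b)
        netA, netB = chain_net(ids_a), chain_net(ids_b)
        res = gene_set_match_z(S, ["a0", "a1"], ["b1", "b2"], netA, netB,
                               n_null=5, seed=0)
        assert res.observed == pytest.approx(np.mean([1, 2, 4, 5]))

    def test_null_reproducible_with_seed(self, rng):
        n = 40
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in range(n)]
        netA, netB = chain_net(ids_a), chain_net(ids_b)
        S = ScoreMatrix(rng.normal(size=(n, n)), ids_a, ids_b)
        r1 = gene_set_match_z(S, ids_a[:8], ids_b[:8], netA, netB, seed=9)
        r2 = gene_set_match_z(S, ids_a[:8], ids_b[:8], netA, netB, seed=9)
        assert r1.z_score == r2.z_score


class TestFolds:
    def test_anchored_pair_shares_fold(self):
        genesA = [f"a{i}" for i in range(10)]
        genesB = [f"b{i}" for i in range(10)]
        anchors = [("a0", "b0"), ("a3", "b7")]
        folds = gene_stratified_folds(genesA, genesB, anchors, k=3, seed=0)
        assert folds.fold_of_A["a0"] == folds.fold_of_B["b0"]
        assert folds.fold_of_A["a3"] == folds.fold_of_B["b7"]

    def test_every_gene_exactly_one_fold(self):
        genesA = [f"a{i}" for i in range(9)]
        genesB = [f"b{i}" for i in range(7)]
        folds = gene_stratified_folds(genesA, genesB, None, k=4, seed=1)
        assert set(folds.fold_of_A) == set(genesA)
        assert set(folds.fold_of_B) == set(genesB)
        assert set(folds.fold_of_A.values()) <= set(range(4))

    def test_excluded_pairs_match_exhaustive_scan(self):
        genesA = [f"a{i}" for i in range(6)]
        genesB = [f"b{i}" for i in range(6)]
        anchors = [("a0", "b0"), ("a1", "b1"), ("a2", "b2")]
        folds = gene_stratified_folds(genesA, genesB, anchors, k=3, seed=2)
        pairs = [(a, b) for a in genesA for b in genesB]
        oracle = sum(
            1 for a, b in pairs
            if folds.fold_of_A[a] != folds.fold_of_B[b]
        )
        assert count_excluded_pairs(folds, pairs) == oracle

    def test_too_few_components_raises(self):
        with pytest.raises(ValueError, match="components"):
            gene_stratified_folds(["a0"], ["b0"], [("a0", "b0")], k=2, seed=0)


def planted_embedding(rng, n_genes=60, modules=3, dim=8, spread=0.25):
    """Genes in the same module share a latent direction."""
    centers = rng.normal(size=(modules, dim)) * 3
    ids, Z, module_of = [], [], {}
    for i in range(n_genes):
        m = i % modules
        ids.append(f"g{i:03d}")
        module_of[ids[-1]] = m
        Z.append(centers[m] + rng.normal(size=dim) * spread)
    return np.array(Z), ids, module_of


class TestSLPredict:
    def _standard(self, rng, module_of, n_pos=None):
        """All (or a sample of) within-module pairs as SL positives.

        With all within-module pairs positive, the internally sampled
        negatives are necessarily cross-module, so the task is separable
        by construction.
        """
        genes = sorted(module_of)
        by_mod = {}
        for g in genes:
            by_mod.setdefault(module_of[g], []).append(g)
        within = [(a, b) for gs in by_mod.values()
                  for i, a in enumerate(gs) for b in gs[i + 1:]]
        if n_pos is None:
            return within
        idx = rng.choice(len(within), n_pos, replace=False)
        return [within[i] for i in idx]

    def test_features_order_invariant(self, rng):
        Z, ids, _ = planted_embedding(rng)
        from etna.evaluation import _pair_features
        index = {g: i for i, g in enumerate(ids)}
        f1 = _pair_features(Z, index, [(ids[0], ids[5])])
        f2 = _pair_features(Z, index, [(ids[5], ids[0])])
        assert np.array_equal(f1, f2)

    def test_separable_construction_high_auroc(self, rng):
        Z, ids, module_of = planted_embedding(rng)
        pos = self._standard(rng, module_of)
        auprc, auroc = sl_predict_eval(
            {"A": (Z, ids)}, {"A": pos}, mode="within", k=4, seed=0
        )
        assert auroc >= 0.9

    def test_cross_species_transfer(self, rng):
        Z, ids, module_of = planted_embedding(rng)
        # species B lives in the same latent space with its own ids
        idsB = [g.replace("g", "h") for g in ids]
        module_of_B = {h: module_of[g] for g, h in zip(ids, idsB)}
        posA = self._standard(rng, module_of)
        posB = [(a.replace("g", "h"), b.replace("g", "h"))
                for a, b in self._standard(rng, module_of_B
                                           if False else module_of)]
        auprc, auroc = sl_predict_eval(
            {"A": (Z, ids), "B": (Z, idsB)},
            {"A": posA, "B": posB},
            mode="cross", train_species="A", test_species="B", seed=1,
        )
        assert auroc >= 0.8

    def test_shuffled_labels_near_chance(self, rng):
        """Random pair labels on a structureless embedding: mean AUROC over
        10 seeds sits at chance within [0.4, 0.6]."""
        ids = [f"g{i:03d}" for i in range(120)]
        Z = rng.normal(size=(120, 8))
        aurocs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            pos, seen = [], set()
            while len(pos) < 150:
                a, b = r.choice(len(ids), 2, replace=False)
                p = tuple(sorted((ids[a], ids[b])))
                if p not in seen:
                    seen.add(p)
                    pos.append(p)
            _, auroc = sl_predict_eval(
                {"A": (Z, ids)}, {"A": pos}, mode="within", k=3, seed=seed
            )
            aurocs.append(auroc)
        assert 0.4 <= float(np.mean(aurocs)) <= 0.6

    def test_leakage_audit_by_construction(self, rng, monkeypatch):
        # corrupt the fold map builder so train and test folds overlap and
        # check the guard trips
        Z, ids, module_of = planted_embedding(rng)
        pos = self._standard(rng, module_of)
        import etna.evaluation as ev

        class EvilRng:
            def __init__(self, real):
                self.real = real

            def permutation(self, n):
                return np.zeros(n, dtype=int)  # everyone in fold 0

            def __getattr__(self, name):
                return getattr(self.real, name)

        real_rng = np.random.default_rng(0)
        monkeypatch.setattr(ev.np.random, "default_rng",
                            lambda *a, **k: EvilRng(real_rng))
        # all genes land in fold 0 -> for f=0 every pair is both train
        # candidate and test candidate; the audit must catch it or produce
        # no evaluable folds
        with pytest.raises((LeakageError, ValueError)):
            sl_predict_eval({"A": (Z, ids)}, {"A": pos}, mode="within",
                            k=4, seed=0)


class TestTopPercentGraph:
    def test_percent_100_complete_bipartite(self, rng):
        V = rng.normal(size=(3, 4))
        S = ScoreMatrix(V, ["a0", "a1", "a2"], ["b0", "b1", "b2", "b3"])
        edges = top_percent_graph(S, percent=100)
        assert len(edges) == 12
        assert set(edges) == {(a, b) for a in S.row_ids for b in S.col_ids}

    def test_toy_selects_two_largest(self):
        V = np.array([
            [0.1, 0.2, 0.3, 0.4, 0.5],
            [0.6, 0.7, 0.8, 0.95, 0.05],
            [0.15, 0.25, 0.35, 0.45, 0.55],
            [0.65, 0.75, 0.9, 0.85, 0.12],
        ])
        S = ScoreMatrix(V, [f"a{i}" for i in range(4)],
                        [f"b{j}" for j in range(5)])
        edges = top_percent_graph(S, percent=10)  # floor(0.1*20) = 2
        assert edges == [("a1", "b3"), ("a3", "b2")]

    def test_min_degree_pruning_can_empty(self, rng):
        V = rng.normal(size=(4, 4))
        S = ScoreMatrix(V, [f"a{i}" for i in range(4)],
                        [f"b{j}" for j in range(4)])
        edges = top_percent_graph(S, percent=25, min_degree=10)
        assert edges == []

    def test_zero_selected_raises(self):
        S = ScoreMatrix(np.array([[1.0]]), ["a"], ["b"])
        with pytest.raises(ValueError):
            top_percent_graph(S, percent=0.0001)
        with pytest.raises(ValueError):
            top_percent_graph(S, percent=0)
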