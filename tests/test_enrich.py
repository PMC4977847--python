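"""Hypergeometric enrichment, BH adjustment, slim mapping, similarity, tiers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirx.enrich import (GOAnnotation, Ontology, TISSUES, UNCLASSIFIED,
                         bh_adjust, classify_tissue_levels, enrich_module,
                         functional_similarity, hypergeom_enrich, map_to_slim)


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by explicit combinatorial summation."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(n, K) + 1)) / total


def tiny_ontology():
    terms = {t: {"name": t, "namespace": "biological_process"}
             for t in ["root1", "root2", "mid1", "mid2", "leafA", "leafB",
                       "leafC"]}
    parents = {"mid1": ["root1"], "mid2": ["root1", "root2"],
               "leafA": ["mid1"], "leafB": ["mid2"], "leafC": ["root2"]}
    return Ontology(terms, parents)


@pytest.fixture(scope="module")
def onto():
    return tiny_ontology()


class TestHypergeom:
    def test_matches_combinatorial_oracle(self, onto):
        background = [f"g{i}" for i in range(100)]
        ann = GOAnnotation({g: {"leafA"} for g in background[:10]}, onto)
        module = background[:5] + background[50:55]  # k=5 of K=10, n=10
        res = hypergeom_enrich(module, "leafA", ann, background)
        assert (res.k, res.K, res.n, res.N_bg) == (5, 10, 10, 100)
        assert res.p_raw == pytest.approx(
            hypergeom_tail_oracle(100, 10, 10, 5), abs=1e-12)

    def test_grid_against_oracle(self, onto):
        for N, K, n in [(20, 5, 8), (57, 12, 20), (200, 40, 30)]:
            background = [f"g{i}" for i in range(N)]
            ann = GOAnnotation({g: {"leafB"} for g in background[:K]}, onto)
            for k in (0, 1, min(n, K) // 2, min(n, K)):
                module = background[:k] + background[K:K + (n - k)]
                res = hypergeom_enrich(module, "leafB", ann, background)
                assert res.p_raw == pytest.approx(
                    hypergeom_tail_oracle(N, K, n, k), abs=1e-10)

    def test_term_annotating_everything_gives_one(self, onto):
        background = [f"g{i}" for i in range(30)]
        ann = GOAnnotation({g: {"leafC"} for g in background}, onto)
        res = hypergeom_enrich(background[:6], "leafC", ann, background)
        assert res.p_raw == 1.0

    def test_zero_overlap_gives_one(self, onto):
        background = [f"g{i}" for i in range(30)]
        ann = GOAnnotation({g: {"leafC"} for g in background[20:]}, onto)
        res = hypergeom_enrich(background[:5], "leafC", ann, background)
        assert res.p_raw == 1.0

    def test_module_outside_background_rejected(self, onto):
        ann = GOAnnotation({}, onto)
        with pytest.raises(ValueError):
            hypergeom_enrich(["x"], "leafA", ann, ["a", "b"])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    def test_bounds_and_monotone_dominance(self, ps):
        adj = bh_adjust(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(a <= 1.0 + 1e-12 for a in adj)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ps = rng.uniform(size=15).tolist()
        adj = bh_adjust(ps)
        perm = rng.permutation(15)
        adj_perm = bh_adjust([ps[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrichModule:
    def test_planted_term_detected(self, onto):
        background = [f"g{i}" for i in range(100)]
        g2t = {g: {"leafC"} for g in background[:5]}
        for g in background[:8]:
            g2t.setdefault(g, set()).add("leafA")  # planted in the module
        ann = GOAnnotation(g2t, onto)
        results = enrich_module(background[:10], ann, background, alpha=0.1)
        assert any(r.term_id == "leafA" and r.p_adj < 0.1 for r in results)
        # propagation reaches ancestors of the planted term
        assert any(r.term_id == "mid1" for r in results)

    def test_unannotated_module_yields_nothing(self, onto):
        background = [f"g{i}" for i in range(40)]
        ann = GOAnnotation({g: {"leafA"} for g in background[20:]}, onto)
        assert enrich_module(background[:10], ann, background) == []

    def test_empty_module(self, onto):
        ann = GOAnnotation({}, onto)
        assert enrich_module([], ann, ["a"]) == []

    def test_results_sorted_and_thresholded(self, onto):
        background = [f"g{i}" for i in range(80)]
        g2t = {}
        for g in background[:9]:
            g2t[g] = {"leafA"}
        for g in background[:6]:
            g2t[g].add("leafC")
        ann = GOAnnotation(g2t, onto)
        results = enrich_module(background[:10], ann, background, alpha=0.1)
        adjs = [r.p_adj for r in results]
        assert adjs == sorted(adjs)
        assert all(a < 0.1 for a in adjs)


class TestSlimMapping:
    def test_slim_term_maps_to_itself(self, onto):
        m = map_to_slim(["mid1"], ["mid1"], onto)
        assert m.mapping["mid1"] == {"mid1"}

    def test_transitive_chain(self, onto):
        m = map_to_slim(["leafA"], ["root1"], onto)
        assert m.mapping["leafA"] == {"root1"}

    def test_unreachable_term_goes_to_unclassified(self, onto):
        m = map_to_slim(["leafA"], ["root2"], onto)
        assert m.mapping["leafA"] == {UNCLASSIFIED}

    def test_idempotent_on_slim_categories(self, onto):
        slim = ["root1", "root2"]
        m = map_to_slim(["leafA", "leafB", "leafC"], slim, onto)
        cats = sorted(set(m.categories()))
        again = map_to_slim(cats, slim, onto)
        assert all(again.mapping[c] == {c} for c in cats)

    def test_random_dag_matches_reachability_oracle(self):
        rng = np.random.default_rng(5)
        n = 50
        names = [f"t{i}" for i in range(n)]
        parents = {names[i]: [names[j] for j in range(i)
                              if rng.random() < 0.08] for i in range(n)}
        onto = Ontology({t: {"name": t} for t in names}, parents)
        slim = [names[i] for i in range(0, n, 7)]

        def reach(t):  # DFS over explicit parent lists
            out, stack = set(), [t]
            while stack:
                u = stack.pop()
                for p in parents.get(u, []):
                    if p not in out:
                        out.add(p)
                        stack.append(p)
            return out

        m = map_to_slim(names, slim, onto)
        for t in names:
            expected = ({t} | reach(t)) & set(slim)
            assert m.mapping[t] == (expected or {UNCLASSIFIED})

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            Ontology({"a": {}, "b": {}}, {"a": ["b"], "b": ["a"]})

    def test_unknown_slim_rejected(self, onto):
        with pytest.raises(ValueError):
            map_to_slim(["leafA"], ["nope"], onto)


class TestFunctionalSimilarity:
    def test_identical_sets(self):
        sim = functional_similarity(["a", "b"], ["b", "a"])
        assert sim["jaccard"] == 1.0
        assert sim["overlap_coef"] == 1.0

    def test_disjoint_sets(self):
        sim = functional_similarity(["a"], ["b"])
        assert sim["jaccard"] == 0.0
        assert sim["shared"] == set()

    def test_partial_overlap(self):
        a = ["ion transport", "stress response", "growth"]
        b = ["ion transport", "stress response", "photosynthesis"]
        sim = functional_similarity(a, b)
        assert sim["jaccard"] == pytest.approx(0.5)
        assert sim["shared"] == {"ion transport", "stress response"}
        assert sim["overlap_coef"] == pytest.approx(2 / 3)

    def test_both_empty_warns(self):
        with pytest.warns(UserWarning):
            sim = functional_similarity([], [])
        assert sim["jaccard"] == 0.0


class TestTissueLevels:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=list(TISSUES))

    def test_all_tissues_is_ubiquitous(self):
        lv = classify_tissue_levels(self.frame([[5.0] * 8]))
        assert lv["level"].tolist() == ["ubiquitous"]

    def test_single_tissue_is_specific(self):
        row = [0.0] * 8
        row[3] = 9.0
        lv = classify_tissue_levels(self.frame([row]))
        assert lv["level"].tolist() == ["specific"]
        assert lv["tissues"].tolist() == [TISSUES[3]]

    def test_all_zero_not_expressed(self):
        lv = classify_tissue_levels(self.frame([[0.0] * 8]))
        assert lv["level"].tolist() == ["not_expressed"]

    def test_peaked_profile_is_high(self):
        row = [0.0] * 8
        row[0], row[1], row[2] = 10.0, 3.0, 3.0
        lv = classify_tissue_levels(self.frame([row]))
        assert lv["level"].tolist() == ["high"]

    def test_flat_mid_breadth_is_unclassified(self):
        row = [0.0] * 8
        for t in range(5):
            row[t] = 5.0
        lv = classify_tissue_levels(self.frame([row]))
        assert lv["level"].tolist() == ["unclassified"]

    def test_single_tissue_matrix_rejected(self):
        with pytest.raises(ValueError):
            classify_tissue_levels(pd.DataFrame({"brain": [1.0]}))

    def test_negative_values_rejected(self):
        bad = self.frame([[1.0] * 8])
        bad.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            classify_tissue_levels(bad)
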