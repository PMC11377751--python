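"""Co-expression: correlation, module detection, pair mining, signatures."""

import numpy as np
import pandas as pd
import pytest

from gmdomains.coexpr import (cross_tissue_filter, detect_modules,
                              filter_coexpr_pairs, module_pairs,
                              pearson_matrix, rank_coexpressed)
from gmdomains.ontology import DNA_REPAIR
from gmdomains.synthetic import ExpressionSpec, generate_expression


def frame(data, genes):
    return pd.DataFrame(data, index=genes,
                        columns=[f"s{i}" for i in range(np.shape(data)[1])])


class TestPearson:
    def test_affine_relation_is_perfectly_correlated(self):
        x = np.arange(10.0)
        df = frame([x, 2 * x + 1, -x], ["x", "y", "z"])
        r = pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self, rng):
        data = rng.normal(size=(5, 10))
        r = pearson_matrix(frame(data, list("abcde"))).to_numpy()
        # independent textbook two-pass oracle
        mu = data.mean(axis=1, keepdims=True)
        xc = data - mu
        cov = xc @ xc.T / (data.shape[1] - 1)
        sd = np.sqrt(np.diag(cov))
        oracle = cov / np.outer(sd, sd)
        assert np.allclose(r, oracle, atol=1e-12)

    def test_zero_variance_gene_dropped(self):
        df = frame([np.arange(5.0), np.ones(5)], ["ok", "flat"])
        r = pearson_matrix(df)
        assert list(r.index) == ["ok"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(frame(np.ones((2, 2)), ["a", "b"]))


class TestDetectModules:
    def planted(self, seed=11):
        genes = tuple(f"mod{i}" for i in range(10))
        spec = ExpressionSpec(n_tissues=1, n_samples_per_tissue=200,
                              module_defs=(("M1", genes, 0.9),),
                              n_background_genes=200, seed=seed)
        mats, truth = generate_expression(spec)
        return mats["tissue01"], set(genes)

    def test_planted_module_recovered_without_background(self):
        expr, planted = self.planted()
        mods = detect_modules(expr, tissue="t1", r_min=0.6)
        assert len(mods) == 1
        got = set(mods[0].genes)
        assert len(got & planted) >= 9
        assert not any(g.startswith("BG") for g in got)

    def test_background_only_yields_no_modules(self):
        spec = ExpressionSpec(1, 200, (), 150, seed=3)
        mats, _ = generate_expression(spec)
        assert detect_modules(mats["tissue01"], r_min=0.6) == []

    def test_threshold_above_one_yields_empty(self):
        expr, _ = self.planted()
        assert detect_modules(expr, r_min=1.01) == []

    def test_custom_detector_plugs_in(self):
        expr, planted = self.planted()
        mods = detect_modules(expr, tissue="t",
                              detector=lambda c: [set(list(c.index)[:6])])
        assert len(mods) == 1 and len(mods[0].genes) == 6


class TestPairs:
    def test_triangle_count(self):
        from gmdomains.coexpr import CoexpressionModule
        mods = [CoexpressionModule("t1", "M1", frozenset("abc"))]
        assert len(module_pairs(mods)) == 3

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_combinatorial_count(self, k):
        from gmdomains.coexpr import CoexpressionModule
        genes = frozenset(f"g{i}" for i in range(k))
        mods = [CoexpressionModule("t", "M", genes)]
        assert len(module_pairs(mods)) == k * (k - 1) // 2

    def test_no_cross_module_pairs(self):
        from gmdomains.coexpr import CoexpressionModule
        mods = [CoexpressionModule("t", "M1", frozenset("ab")),
                CoexpressionModule("t", "M2", frozenset("cd"))]
        pairs = {p for p, _ in module_pairs(mods)}
        assert pairs == {("a", "b"), ("c", "d")}


class TestCrossTissue:
    def test_single_tissue_pair_excluded(self):
        assert cross_tissue_filter({(("a", "b"), "t1")}) == set()

    def test_two_of_three_tissues_included(self):
        pairs = {(("a", "b"), "t1"), (("a", "b"), "t2"), (("c", "d"), "t3")}
        assert cross_tissue_filter(pairs) == {("a", "b")}

    def test_matches_brute_force_count(self, rng):
        tissues = ["t1", "t2", "t3", "t4"]
        genes = [f"g{i}" for i in range(12)]
        tagged = set()
        for t in tissues:
            for _ in range(40):
                a, b = rng.choice(12, 2, replace=False)
                pair = tuple(sorted((genes[a], genes[b])))
                tagged.add((pair, t))
        got = cross_tissue_filter(tagged, min_tissues=2)
        from collections import Counter
        counts = Counter(p for p, _ in tagged)
        assert got == {p for p, c in counts.items() if c >= 2}

    def test_min_tissues_one_is_identity_on_union(self):
        tagged = {(("a", "b"), "t1"), (("c", "d"), "t2")}
        assert cross_tissue_filter(tagged, min_tissues=1) == {("a", "b"),
                                                              ("c", "d")}


class TestFilterPairs:
    def test_two_ddr_genes_dropped(self):
        annots = {"a": {DNA_REPAIR}, "b": {DNA_REPAIR}}
        cands, _ = filter_coexpr_pairs({("a", "b")}, annots, [], [])
        assert cands == []

    def test_housekeeping_partner_dropped(self):
        annots = {"a": {DNA_REPAIR}, "hk": set()}
        cands, _ = filter_coexpr_pairs({("a", "hk")}, annots, ["hk"], [])
        assert cands == []

    def test_matches_brute_force(self, rng):
        genes = [f"g{i}" for i in range(30)]
        annots = {g: ({DNA_REPAIR} if rng.random() < 0.4 else set())
                  for g in genes}
        hk = set(rng.choice(genes, 4, replace=False))
        pairs = set()
        for _ in range(200):
            a, b = rng.choice(30, 2, replace=False)
            pairs.add(tuple(sorted((genes[a], genes[b]))))
        cands, _ = filter_coexpr_pairs(pairs, annots, hk, [])
        brute = sorted({cand for a, b in pairs
                        for anchor, cand in ((a, b), (b, a))
                        if DNA_REPAIR in annots[anchor]
                        and not annots[cand] and cand not in hk})
        assert cands == brute


class TestRankCoexpressed:
    def test_planted_mate_outranks_background(self):
        genes = tuple(f"m{i}" for i in range(5))
        spec = ExpressionSpec(1, 200, (("M", genes, 0.9),), 100, seed=8)
        mats, _ = generate_expression(spec)
        ranked = rank_coexpressed(mats, "m0", top_k=10)
        assert set(g for g, _ in ranked[:4]) == set(genes) - {"m0"}

    def test_top_k_zero_empty(self):
        df = frame(np.random.default_rng(0).normal(size=(4, 20)), list("abcd"))
        assert rank_coexpressed({"t": df}, "a", top_k=0) == []

    def test_unknown_query_raises(self):
        df = frame(np.random.default_rng(0).normal(size=(3, 10)), list("abc"))
        with pytest.raises(KeyError):
            rank_coexpressed({"t": df}, "zzz")

    def test_duplicate_gene_rows_collapsed(self):
        data = np.random.default_rng(1).normal(size=(4, 30))
        df = pd.DataFrame(data, index=["a", "b", "b", "c"],
                          columns=[f"s{i}" for i in range(30)])
        ranked = rank_coexpressed({"t": df}, "a")
        names = [g for g, _ in ranked]
        assert names.count("b") == 1
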