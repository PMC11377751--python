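"""Generators: planted families, proteins, expression, interactions, GO."""

import numpy as np
import pytest

from gmdomains.alphabet import AMINO_ACIDS
from gmdomains.synthetic import (EvidenceModel, ExpressionSpec, FamilySpec,
                                 FeatureSpec, generate_expression,
                                 generate_family, generate_go,
                                 generate_ppi_table, plant_proteins)

HYDROPHOBIC = set("LIVMF")


class TestGenerateFamily:
    def test_identity_one_no_indels_gives_identical_members(self):
        fam = generate_family(FamilySpec("f", 50, 5, 1.0, 0.0, seed=1))
        assert all(seq == fam.ancestor for seq in fam.members.values())
        assert all("-" not in row for row in fam.msa.rows)

    def test_mean_identity_matches_binomial_expectation(self):
        # direct column-count oracle over 30 draws at target 0.4:
        # expected realized identity 0.4 + 0.6/20 = 0.43
        fam = generate_family(FamilySpec("f", 100, 30, 0.4, 0.0, seed=2))
        mean_id = fam.mean_member_ancestor_identity()
        assert 0.34 <= mean_id <= 0.46

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.8])
    def test_identity_control_within_band(self, target):
        fam = generate_family(FamilySpec("f", 150, 20, target, 0.0, seed=3))
        expected = target + (1 - target) * 0.05
        assert abs(fam.mean_member_ancestor_identity() - expected) <= 0.06

    def test_different_seeds_differ_same_seed_identical(self):
        a = generate_family(FamilySpec("f", 60, 4, 0.5, 0.01, seed=10))
        b = generate_family(FamilySpec("f", 60, 4, 0.5, 0.01, seed=11))
        c = generate_family(FamilySpec("f", 60, 4, 0.5, 0.01, seed=10))
        assert a.members != b.members
        assert a.members == c.members and a.msa.rows == c.msa.rows

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec("f", 100, 30, 0.0, 0.0, seed=1)  # zero identity
        with pytest.raises(ValueError):
            FamilySpec("f", 5, 30, 0.5, 0.0, seed=1)    # too short
        with pytest.raises(ValueError):
            FamilySpec("f", 100, 1, 0.5, 0.0, seed=1)   # one member

    def test_msa_records_homologous_columns(self):
        fam = generate_family(FamilySpec("f", 80, 10, 0.6, 0.05, seed=4))
        widths = {len(r) for r in fam.msa.rows}
        assert len(widths) == 1
        for mid, seq in fam.members.items():
            row = fam.msa.rows[fam.msa.ids.index(mid)]
            assert row.replace("-", "") == seq


class TestPlantProteins:
    def test_linker_arithmetic(self):
        member = ("m1", "A" * 50)
        prots = plant_proteins([("fam", [member])],
                               linker_length_distribution=25, seed=0)
        (p,) = prots
        assert len(p.sequence) == 100
        assert p.truth_intervals == [("fam", 26, 75)]
        assert p.sequence[25:75] == "A" * 50

    def test_decoys_have_no_truth_intervals(self):
        prots = plant_proteins([], n_decoys=100, seed=1)
        assert len(prots) == 100
        assert all(p.truth_intervals == [] for p in prots)
        assert all(set(p.sequence) <= set(AMINO_ACIDS) for p in prots)

    def test_planted_coiled_coil_heptads_are_hydrophobic_at_a_and_d(self):
        prots = plant_proteins([], n_decoys=5,
                               feature_specs=[FeatureSpec("coiled_coil", 70, 3)],
                               seed=2)
        feats = [(p, f) for p in prots for f in p.planted_features]
        assert len(feats) == 3
        for p, (kind, s, e) in feats:
            assert kind == "coiled_coil"
            segment = p.sequence[s - 1:e]
            for i, ch in enumerate(segment):
                if i % 7 in (0, 3):
                    assert ch in HYDROPHOBIC

    def test_low_complexity_feature_uses_few_residue_types(self):
        prots = plant_proteins([], n_decoys=5,
                               feature_specs=[FeatureSpec("low_complexity", 30, 4)],
                               seed=3)
        for p in prots:
            for kind, s, e in p.planted_features:
                assert len(set(p.sequence[s - 1:e])) <= 3

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            plant_proteins([], n_decoys=0, seed=0)

    def test_negative_linker_support_rejected(self):
        with pytest.raises(ValueError):
            plant_proteins([("f", [("m", "AAAA" * 5)])],
                           linker_length_distribution=(-5, 10), seed=0)


class TestGenerateExpression:
    def test_within_module_correlation_matches_latent_factor(self):
        # oracle: E[r] = rho under x = sqrt(rho) z + sqrt(1-rho) eps
        spec = ExpressionSpec(n_tissues=1, n_samples_per_tissue=200,
                              module_defs=(("M1", tuple(f"g{i}" for i in range(10)), 0.9),),
                              n_background_genes=0, seed=5)
        mats, truth = generate_expression(spec)
        df = mats["tissue01"]
        r = np.corrcoef(df.to_numpy())
        off = r[np.triu_indices(10, 1)]
        assert 0.85 <= off.mean() <= 0.95

    def test_background_null_correlation_tail(self):
        spec = ExpressionSpec(n_tissues=1, n_samples_per_tissue=200,
                              module_defs=(), n_background_genes=150, seed=6)
        mats, _ = generate_expression(spec)
        r = np.corrcoef(mats["tissue01"].to_numpy())
        off = np.abs(r[np.triu_indices(150, 1)])
        assert (off >= 0.8).mean() <= 0.001

    def test_seed_contract_membership_fixed_values_differ(self):
        defs = (("M1", ("a", "b", "c", "d", "e"), 0.8),)
        m1, t1 = generate_expression(ExpressionSpec(2, 50, defs, 10, seed=1))
        m2, t2 = generate_expression(ExpressionSpec(2, 50, defs, 10, seed=2))
        assert t1 == t2
        assert not np.allclose(m1["tissue01"], m2["tissue01"])

    def test_validation(self):
        with pytest.raises(ValueError):
            ExpressionSpec(1, 2, (), 5, seed=0)  # <3 samples
        with pytest.raises(ValueError):
            ExpressionSpec(1, 10, (("M", ("a",), 1.5),), 5, seed=0)
        with pytest.raises(ValueError):
            ExpressionSpec(1, 10, (("M", ("a", "b"), 0.5),
                                   ("N", ("b", "c"), 0.5)), 5, seed=0)


class TestGeneratePPITable:
    def test_forced_evidence_passes_downstream_filter(self):
        def forced(rng):
            return frozenset({"experimental"}), 2
        recs, truth = generate_ppi_table(["p1", "p2"], [("p1", "p2")], forced,
                                         seed=0)
        (rec,) = recs
        assert "experimental" in rec.evidence_types
        assert rec.n_publications_experimental >= 2

    def test_contaminant_records_draw_from_list(self):
        recs, truth = generate_ppi_table(
            ["p1", "p2", "p3"], [], EvidenceModel(), contaminant_ids=["c1", "c2"],
            seed=1, n_contaminant_records=10)
        assert len(recs) == 10
        assert all(r.protein_b in {"c1", "c2"} for r in recs)
        assert truth["origins"] == ["contaminant"] * 10

    def test_unknown_ids_rejected(self):
        with pytest.raises(KeyError):
            generate_ppi_table(["p1"], [("p1", "nope")], EvidenceModel(), seed=0)


class TestGenerateGO:
    def test_acyclic_for_any_seed(self):
        import networkx as nx
        for seed in range(5):
            dag, _ = generate_go(3, ["p1"], seed=seed)
            g = nx.DiGraph((c, p) for c, ps in dag.parents.items() for p in ps)
            assert nx.is_directed_acyclic_graph(g)

    def test_child_rule_annotates_descendant_not_term(self):
        from gmdomains.ontology import DNA_REPAIR, descendants
        dag, annots = generate_go(3, ["p1"],
                                  {"p1": ("child", DNA_REPAIR)}, seed=2)
        (term,) = annots["p1"]
        assert term != DNA_REPAIR
        assert term in descendants(dag, DNA_REPAIR)

    def test_depth_one_leaves_terms_childless(self):
        from gmdomains.ontology import DEFAULT_TERMS_OF_INTEREST, descendants
        dag, _ = generate_go(1, [], seed=0)
        for t in DEFAULT_TERMS_OF_INTEREST:
            assert descendants(dag, t) == set()
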