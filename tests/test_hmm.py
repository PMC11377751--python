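"""Profile-HMM engine: construction, scoring oracles, E-value machinery."""

import itertools

import numpy as np
import pytest

from gmdomains.hmm import (EVDParams, ProfileHMM, background_decoy_sampler,
                           calibrate_evd, coemission_scores, fit_gumbel,
                           forward_score, hmm_from_msa, hmm_hmm_align,
                           hmm_hmm_score, read_profile, search,
                           single_sequence_hmm, viterbi_align, write_profile)
from gmdomains.msa import MSA


# ---------------------------------------------------------------------------
# Brute-force path enumeration oracle (independent of the DP kernels)
# ---------------------------------------------------------------------------

def enumerate_path_odds(hmm: ProfileHMM, codes):
    """Odds of every legal local path, in probability space."""
    M = hmm.n_match
    L = len(codes)
    odds = hmm.match_emit / hmm.background
    K = hmm.n_letters
    out = []

    def em(k, i):
        c = codes[i]
        return odds[k, c] if c < K else 1.0

    def extend(kind, k, i, w):
        if kind == "M":
            out.append(w * hmm.t_me[k])
            if k < M - 1:
                if i + 1 < L:
                    extend("M", k + 1, i + 1, w * hmm.t_mm[k] * em(k + 1, i + 1))
                    extend("I", k, i + 1, w * hmm.t_mi[k])
                extend("D", k + 1, i, w * hmm.t_md[k])
        elif kind == "I":
            if i + 1 < L:
                extend("I", k, i + 1, w * hmm.t_ii[k])
                extend("M", k + 1, i + 1, w * hmm.t_im[k] * em(k + 1, i + 1))
        else:
            if k < M - 1:
                extend("D", k + 1, i, w * hmm.t_dd[k])
                if i + 1 < L:
                    extend("M", k + 1, i + 1, w * hmm.t_dm[k] * em(k + 1, i + 1))

    for i0 in range(L):
        for k0 in range(M):
            extend("M", k0, i0, em(k0, i0) / (M * L))
    return out


def random_hmm(rng, M, alphabet="ACGT", eta=0.1):
    K = len(alphabet)
    emit = rng.dirichlet(np.ones(K), size=M)
    t = dict(t_mm=np.zeros(M), t_mi=np.zeros(M), t_md=np.zeros(M),
             t_im=np.zeros(M), t_ii=np.zeros(M), t_dm=np.zeros(M),
             t_dd=np.zeros(M), t_me=np.zeros(M))
    t["t_me"][M - 1] = 1.0
    for k in range(M - 1):
        if k == M - 2:
            p = rng.dirichlet(np.ones(2))
            t["t_mm"][k], t["t_mi"][k] = (1 - eta) * p
            t["t_dm"][k] = 1.0
        else:
            p = rng.dirichlet(np.ones(3))
            t["t_mm"][k], t["t_mi"][k], t["t_md"][k] = (1 - eta) * p
            q = rng.dirichlet(np.ones(2))
            t["t_dm"][k], t["t_dd"][k] = q
        t["t_me"][k] = eta
        q = rng.dirichlet(np.ones(2))
        t["t_im"][k], t["t_ii"][k] = q
    h = ProfileHMM(name="rand", match_emit=emit,
                   background=np.full(K, 1.0 / K), alphabet=alphabet, **t)
    h.validate()
    return h


def point_mass_hmm(residue="A"):
    emit = np.zeros((1, 20))
    emit[0, "ACDEFGHIKLMNPQRSTVWY".index(residue)] = 1.0
    return ProfileHMM(name="one", match_emit=emit,
                      background=np.full(20, 0.05),
                      t_mm=np.zeros(1), t_mi=np.zeros(1), t_md=np.zeros(1),
                      t_im=np.zeros(1), t_ii=np.zeros(1), t_dm=np.zeros(1),
                      t_dd=np.zeros(1), t_me=np.ones(1))


class TestConstruction:
    def test_two_identical_rows_closed_form(self):
        msa = MSA(ids=["a", "b"], rows=["ACD", "ACD"], master_index=0)
        hmm = hmm_from_msa(msa, alpha=1.0)
        assert hmm.n_match == 3
        f_a = hmm.background[0]
        assert hmm.match_emit[0, 0] == pytest.approx((1 + 1.0 * f_a) / 2.0)

    def test_sixty_percent_gap_column_not_match_state(self):
        rows = ["A-", "A-", "AC", "AC", "A-"]  # col 2: 60% gaps
        msa = MSA(ids=list("abcde"), rows=rows, master_index=2)
        hmm = hmm_from_msa(msa)
        assert hmm.n_match == 1

    def test_boundary_exactly_half_gaps_not_match(self):
        # gap fraction must be strictly below the threshold
        rows = ["A-", "AC", "A-", "AC"]
        msa = MSA(ids=list("abcd"), rows=rows, master_index=1)
        assert hmm_from_msa(msa, match_gap_fraction=0.5).n_match == 1
        rows = ["A-", "AC", "AC", "AC"]  # 25% gaps -> match
        msa = MSA(ids=list("abcd"), rows=rows, master_index=1)
        assert hmm_from_msa(msa, match_gap_fraction=0.5).n_match == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_random_msa_rows_normalized(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY-"), 50))
                for _ in range(20)]
        rows[0] = rows[0].replace("-", "A")
        msa = MSA(ids=[f"s{i}" for i in range(20)], rows=rows, master_index=0)
        hmm = hmm_from_msa(msa)
        hmm.validate(tol=1e-9)  # emission + transition sums

    def test_row_order_invariance(self, small_family):
        msa = small_family.msa
        perm = np.random.default_rng(5).permutation(msa.n_rows)
        shuffled = MSA(ids=[msa.ids[i] for i in perm],
                       rows=[msa.rows[i] for i in perm],
                       master_index=int(np.where(perm == 0)[0][0]))
        a = hmm_from_msa(msa)
        b = hmm_from_msa(shuffled)
        assert np.allclose(a.match_emit, b.match_emit, atol=1e-12)
        assert np.allclose(a.t_mm, b.t_mm, atol=1e-12)

    def test_all_gap_master_region_errors(self):
        msa = MSA(ids=["a", "b"], rows=["--", "--"], master_index=0)
        with pytest.raises(ValueError):
            hmm_from_msa(msa)


class TestScoringOracle:
    def test_single_path_closed_form(self):
        hmm = point_mass_hmm("A")
        expect = np.log2(1.0 / 0.05)
        assert forward_score(hmm, "A") == pytest.approx(expect, abs=1e-9)
        score, trace = viterbi_align(hmm, "A")
        assert score == pytest.approx(expect, abs=1e-9)
        assert trace == [(1, 1)]

    def test_background_emissions_never_positive(self, rng):
        msa = MSA(ids=["a", "b"], rows=["ACDEF", "ACDEF"], master_index=0)
        ref = hmm_from_msa(msa)
        bg = ProfileHMM(name="bg", match_emit=np.tile(ref.background, (5, 1)),
                        background=ref.background, t_mm=ref.t_mm,
                        t_mi=ref.t_mi, t_md=ref.t_md, t_im=ref.t_im,
                        t_ii=ref.t_ii, t_dm=ref.t_dm, t_dd=ref.t_dd,
                        t_me=ref.t_me)
        for L in (1, 5, 40):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L))
            assert forward_score(bg, seq) <= 1e-9

    def test_forward_viterbi_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for M in (1, 2, 3):
            hmm = random_hmm(rng, M)
            for L in (1, 2, 3, 4):
                for seq in itertools.product("ACGT", repeat=L):
                    s = "".join(seq)
                    paths = enumerate_path_odds(hmm, hmm.encode(s))
                    f_expect = np.log2(sum(paths))
                    v_expect = np.log2(max(paths))
                    assert forward_score(hmm, s) == pytest.approx(
                        f_expect, abs=1e-6)
                    v, _ = viterbi_align(hmm, s)
                    assert v == pytest.approx(v_expect, abs=1e-6)

    def test_viterbi_never_exceeds_forward(self, rng, family_hmm):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     int(rng.integers(5, 120))))
            v, _ = viterbi_align(family_hmm, seq)
            assert v <= forward_score(family_hmm, seq) + 1e-9

    def test_long_sequence_scores_finite(self, family_hmm, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 10000))
        assert np.isfinite(forward_score(family_hmm, seq))
        v, _ = viterbi_align(family_hmm, seq)
        assert np.isfinite(v)

    def test_non_canonical_residues_scored_as_background(self, family_hmm):
        clean, _ = viterbi_align(family_hmm, "ACDEFGHIKLMNPQRSTVWY" * 3)
        noisy, _ = viterbi_align(family_hmm, "ACDEFGHIKLMNPQRSTVWY" * 3 + "XXBZU")
        assert np.isfinite(noisy)
        assert noisy <= clean + 1e-9

    def test_empty_sequence_rejected(self, family_hmm):
        with pytest.raises(ValueError):
            forward_score(family_hmm, "")


class TestProfileProfile:
    def test_point_mass_column_closed_form(self):
        a = point_mass_hmm("A")
        score, pairs = hmm_hmm_align(a, a)
        assert score == pytest.approx(np.log2(1 / 0.05), abs=1e-9)
        assert pairs == [(1, 1)]

    def test_background_column_scores_zero(self):
        a = point_mass_hmm("A")
        bg = ProfileHMM(name="bg", match_emit=np.full((1, 20), 0.05),
                        background=np.full(20, 0.05),
                        t_mm=np.zeros(1), t_mi=np.zeros(1), t_md=np.zeros(1),
                        t_im=np.zeros(1), t_ii=np.zeros(1), t_dm=np.zeros(1),
                        t_dd=np.zeros(1), t_me=np.ones(1))
        S = coemission_scores(a, bg)
        assert S[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_with_symmetric_gap_costs(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            msa1 = MSA(ids=["a", "b"],
                       rows=["".join(r.choice(list("ACDEFGHIKL"), 30))] * 2,
                       master_index=0)
            msa2 = MSA(ids=["c", "d"],
                       rows=["".join(r.choice(list("ACDEFGHIKL"), 25))] * 2,
                       master_index=0)
            h1, h2 = hmm_from_msa(msa1), hmm_from_msa(msa2)
            assert hmm_hmm_score(h1, h2) == pytest.approx(
                hmm_hmm_score(h2, h1), abs=1e-9)

    def test_score_only_equals_full_alignment(self, small_family, family_hmm):
        other = single_sequence_hmm("ACDEFGHIKLMNPQRSTVWY" * 4)
        s1, _ = hmm_hmm_align(family_hmm, other)
        assert hmm_hmm_score(family_hmm, other) == pytest.approx(s1, abs=1e-9)


class TestEVD:
    def test_gumbel_fit_recovery(self):
        rng = np.random.default_rng(5)
        scores = rng.gumbel(loc=5.0, scale=1 / 0.7, size=5000)
        lam, mu = fit_gumbel(scores)
        assert 0.63 <= lam <= 0.77
        assert 4.8 <= mu <= 5.2

    def test_evalue_monotone_in_score(self):
        evd = EVDParams(lam=0.7, mu=5.0, n_db=100)
        s = np.linspace(-5, 30, 200)
        e = evd.evalue(s)
        assert (np.diff(e) <= 0).all()
        assert (e >= 0).all()

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel(np.ones(100))

    def test_calibration_deterministic_under_seed(self, family_hmm):
        sampler = background_decoy_sampler([100, 150, 200])
        a = calibrate_evd(family_hmm, sampler, n_decoys=200, seed=11)
        b = calibrate_evd(family_hmm, sampler, n_decoys=200, seed=11)
        c = calibrate_evd(family_hmm, sampler, n_decoys=200, seed=12)
        assert (a.lam, a.mu) == (b.lam, b.mu)
        assert (a.lam, a.mu) != (c.lam, c.mu)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EVDParams(lam=-1.0, mu=0.0)
        with pytest.raises(ValueError):
            EVDParams(lam=1.0, mu=0.0, n_db=0)


class TestSearch:
    def test_planted_member_found_decoys_not(self, small_family, family_hmm):
        rng = np.random.default_rng(2)
        member = list(small_family.members.values())[5]
        targets = [("true", member)]
        targets += [(f"d{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                                 100))) for i in range(50)]
        sampler = background_decoy_sampler([100])
        evd = calibrate_evd(family_hmm, sampler, n_decoys=500, seed=3,
                            n_db=len(targets))
        hits = search(family_hmm, targets, evd, e_max=0.01)
        assert hits and hits[0].target_id == "true"
        assert all(h.target_id == "true" for h in hits)

    def test_e_max_zero_empty(self, small_family, family_hmm):
        member = list(small_family.members.values())[0]
        evd = EVDParams(lam=0.7, mu=0.0, n_db=1)
        assert search(family_hmm, [("t", member)], evd, e_max=0.0) == []

    def test_empty_target_set(self, family_hmm):
        evd = EVDParams(lam=0.7, mu=0.0, n_db=1)
        assert search(family_hmm, [], evd) == []

    def test_hits_sorted_by_evalue_then_id(self, small_family, family_hmm):
        members = list(small_family.members.values())[:6]
        targets = [(f"m{i}", s) for i, s in enumerate(members)]
        sampler = background_decoy_sampler([100])
        evd = calibrate_evd(family_hmm, sampler, n_decoys=300, seed=4,
                            n_db=6)
        hits = search(family_hmm, targets, evd, e_max=1.0)
        keys = [(h.evalue, h.target_id) for h in hits]
        assert keys == sorted(keys)


class TestSerialization:
    def test_profile_round_trip(self, family_hmm, tmp_path):
        p = tmp_path / "fam.hmm"
        write_profile(family_hmm, p)
        back = read_profile(p)
        assert back.n_match == family_hmm.n_match
        assert np.allclose(back.match_emit, family_hmm.match_emit, atol=1e-7)
        assert np.allclose(back.t_mm, family_hmm.t_mm, atol=1e-7)
        s = "ACDEFGHIKLMNPQRSTVWY" * 3
        assert forward_score(back, s) == pytest.approx(
            forward_score(family_hmm, s), abs=1e-5)
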