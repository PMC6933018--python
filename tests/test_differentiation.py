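"""Weir-Cockerham theta (oracle equivalence, limits, invariances), bootstrap
CIs, and AMOVA variance partitioning with permutation calibration."""

import numpy as np
import pandas as pd
import pytest

import radpop as rp
from radpop import MISSING
from radpop.experiments import fixed_difference_panel
from radpop.sim import simulate_panel, two_pop_scenario

from conftest import make_panel
from oracles import wc_theta_reference


def _random_two_pop_panel(rng, n_max=12, l_max=30):
    n1, n2 = rng.integers(3, n_max, size=2)
    L = int(rng.integers(5, l_max))
    geno = rng.integers(0, 3, size=(n1 + n2, L)).astype(np.int8)
    miss = rng.random((n1 + n2, L)) < 0.1
    geno[miss] = MISSING
    return make_panel(geno, "A" * n1 + "B" * n2)


class TestWcTheta:
    def test_matches_independent_transcription_on_random_panels(self):
        """100 random small panels agree with the literal general-r
        transcription of the published estimator to 1e-10."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            panel = _random_two_pop_panel(rng)
            rows = panel.pop_indices()
            try:
                expected = wc_theta_reference(
                    [panel.genotypes[rows["A"]], panel.genotypes[rows["B"]]]
                )
                got, _ = rp.wc_theta_pair(panel, "A", "B")
            except (ValueError, rp.differentiation.DifferentiationError):
                continue
            assert got == pytest.approx(expected, abs=1e-10)
            checked += 1
        assert checked >= 90

    def test_single_locus_hand_case(self):
        """n1=n2=10, p1=0.9, p2=0.1, h1=h2=0.2 vs the loop transcription."""
        # pop A: 8 hom-alt, 2 het -> p=0.9, h=0.2; pop B mirrored
        a = [2] * 8 + [1] * 2
        b = [0] * 8 + [1] * 2
        panel = make_panel([[g] for g in a + b], "A" * 10 + "B" * 10)
        got, comp = rp.wc_theta_pair(panel, "A", "B")
        expected = wc_theta_reference(
            [np.array(a, dtype=np.int8)[:, None], np.array(b, dtype=np.int8)[:, None]]
        )
        assert got == pytest.approx(expected, abs=1e-10)
        assert list(comp.columns) == ["a", "b", "c"]

    def test_fixed_difference_gives_theta_one(self):
        panel = fixed_difference_panel(n_per_pop=20, n_loci=30)
        theta, _ = rp.wc_theta_pair(panel, "A", "B")
        assert theta == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.8, size=200)
        block = rng.binomial(2, p, size=(50, 200)).astype(np.int8)  # HWE draws
        panel = make_panel(np.vstack([block, block]), "A" * 50 + "B" * 50)
        theta, _ = rp.wc_theta_pair(panel, "A", "B")
        assert abs(theta) < 0.02

    def test_invariance_to_within_pop_permutation_and_allele_swap(self):
        rng = np.random.default_rng(9)
        panel = _random_two_pop_panel(rng, n_max=15, l_max=40)
        theta, _ = rp.wc_theta_pair(panel, "A", "B")
        rows = panel.pop_indices()
        order = np.concatenate(
            [rng.permutation(rows["A"]), rng.permutation(rows["B"])]
        )
        shuffled = panel.subset_samples(order)
        theta_perm, _ = rp.wc_theta_pair(shuffled, "A", "B")
        swapped = panel.subset_loci(np.arange(panel.n_loci))
        g = swapped.genotypes
        g[g >= 0] = 2 - g[g >= 0]
        theta_swap, _ = rp.wc_theta_pair(swapped, "A", "B")
        assert theta_perm == pytest.approx(theta, abs=1e-12)
        assert theta_swap == pytest.approx(theta, abs=1e-12)

    def test_no_shared_loci_raises(self):
        geno = np.array([[0, MISSING], [1, MISSING], [MISSING, 1], [MISSING, 2]],
                        dtype=np.int8)
        panel = make_panel(geno, "AABB")
        with pytest.raises(rp.differentiation.DifferentiationError, match="share"):
            rp.wc_theta_pair(panel, "A", "B")


class TestFstMatrix:
    def test_ci_brackets_point_estimate_and_p_small_when_differentiated(self):
        panel, _ = simulate_panel(two_pop_scenario(F=0.2, n_per_pop=30,
                                                   n_loci=800, seed=5))
        res = rp.fst_matrix(panel, n_boot=500, seed=8)
        th = res.theta.loc["A", "B"]
        assert res.ci_low.loc["A", "B"] <= th <= res.ci_high.loc["A", "B"]
        assert res.p_value.loc["A", "B"] == 0.0
        assert "<0.002" in res.to_frame()["p"].iloc[0]

    def test_panmictic_split_not_significant(self):
        panel, _ = simulate_panel(two_pop_scenario(F=0.0, n_per_pop=30,
                                                   n_loci=500, seed=6))
        res = rp.fst_matrix(panel, n_boot=500, seed=9)
        assert res.p_value.loc["A", "B"] > 0.05

    def test_matrix_symmetry_and_empty_diagonal(self, study_filtered):
        panel, _ = study_filtered
        sub = panel.select_populations(["Victoria", "FETA", "TAFIRI"])
        res = rp.fst_matrix(sub, n_boot=50, seed=1)
        m = res.theta.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.isnan(np.diag(m)).all()

    def test_rejects_bad_n_boot(self, toy_panel):
        with pytest.raises(rp.differentiation.DifferentiationError):
            rp.fst_matrix(toy_panel, n_boot=0)


class TestAmova:
    def test_fixed_difference_phi_is_one(self):
        panel = fixed_difference_panel(n_per_pop=10, n_loci=40)
        res = rp.amova(panel, n_perm=50, seed=2)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_percentages_sum_to_100_and_p_in_range(self, study_filtered):
        panel, _ = study_filtered
        res = rp.amova(panel, n_perm=50, seed=3)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)
        assert 1 / 51 <= res.p_value <= 1.0
        assert res.phi_st == pytest.approx(
            res.sigma2_among / (res.sigma2_among + res.sigma2_within)
        )

    def test_panmictic_split_phi_near_zero(self):
        panel, _ = simulate_panel(two_pop_scenario(F=0.0, n_per_pop=25,
                                                   n_loci=400, seed=13))
        res = rp.amova(panel, n_perm=100, seed=14)
        assert abs(res.phi_st) < 0.02
        assert res.p_value > 0.05

    def test_degenerate_identical_genotypes_flagged(self):
        panel = make_panel(np.ones((8, 5), dtype=np.int8) * 2, "AAAABBBB")
        res = rp.amova(panel, n_perm=10, seed=1)
        assert res.degenerate and np.isnan(res.phi_st)

    def test_missing_data_rescaling_modes_agree_without_missingness(self):
        panel = fixed_difference_panel(n_per_pop=6, n_loci=20)
        a = rp.amova(panel, n_perm=10, seed=4, rescale_missing=True)
        b = rp.amova(panel, n_perm=10, seed=4, rescale_missing=False)
        assert a.phi_st == pytest.approx(b.phi_st)
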