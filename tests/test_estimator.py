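"""Estimator module: mixture, LOD scan, corrections, jackknife, warnings."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ldcontam.counts import PairObservations, SiteCounts
from ldcontam.estimator import (ContaminationEstimator, damage_corrected_estimate,
                                estimate, external_corrected_estimate,
                                floor_counter, jackknife_se, lod_scan,
                                mixture_distribution, pair_loglik,
                                very_high_warning, weighted_jackknife)
from ldcontam.panel import HaplotypePanel, background_freqs

from oracle_utils import (expected_pair_observations, mixture_T,
                          random_consistent_panel)


# ---------------------------------------------------------------------------
# mixture distribution
# ---------------------------------------------------------------------------

class TestMixture:
    q = np.array([0.4, 0.1, 0.1, 0.4])
    hbg = background_freqs(0.5, 0.5)

    def test_alpha_zero_is_q(self):
        assert mixture_distribution(self.q, self.hbg, 0.0) == pytest.approx(self.q)

    def test_alpha_half_mixes_quarter(self):
        # q = h/2 + h~/2  =>  T(1/2) = 0.25 h + 0.75 h~
        h = 2 * self.q - self.hbg
        T = mixture_distribution(self.q, self.hbg, 0.5)
        assert T == pytest.approx(0.25 * h + 0.75 * self.hbg)

    def test_symmetry_alpha_one_minus_alpha(self):
        for a in (0.2, 0.35, 0.45):
            assert mixture_distribution(self.q, self.hbg, a) == \
                pytest.approx(mixture_distribution(self.q, self.hbg, 1 - a))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-0.1, 0.5))
    def test_valid_distribution_on_scan_range(self, alpha):
        rng = np.random.default_rng(2)
        h = rng.dirichlet((1, 1, 1, 1))
        hbg = background_freqs(h[2] + h[3], h[1] + h[3])
        T = mixture_distribution(0.5 * h + 0.5 * hbg, hbg, alpha)
        assert np.all(T >= -1e-12)
        assert T.sum() == pytest.approx(1.0)

    def test_inadmissible_alpha_errors(self):
        with pytest.raises(ValueError, match="admissible"):
            mixture_distribution(self.q, self.hbg, -0.5)

    def test_matches_printed_equation(self):
        for a in (-0.1, 0.0, 0.07, 0.5):
            assert mixture_distribution(self.q, self.hbg, a) == \
                pytest.approx(mixture_T(self.q, self.hbg, a))


# ---------------------------------------------------------------------------
# pair log-likelihood
# ---------------------------------------------------------------------------

class TestPairLoglik:
    def test_single_observation(self):
        assert pair_loglik([1, 0, 0, 0], [0.5, 0.25, 0.125, 0.125]) == \
            pytest.approx(math.log(0.5))

    def test_zero_observations(self):
        assert pair_loglik([0, 0, 0, 0], [0.25] * 4) == 0.0

    def test_random_against_direct_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs = rng.integers(0, 10, 4)
            T = rng.dirichlet((1, 1, 1, 1))
            direct = sum(o * math.log(t) for o, t in zip(obs, T) if o)
            assert pair_loglik(obs, T) == pytest.approx(direct)

    def test_floor_counter_on_zero_probability(self):
        floor_counter.reset()
        val = pair_loglik([1, 1, 0, 0], [1.0, 0.0, 0.0, 0.0])
        assert floor_counter.count == 1
        assert val < -600  # log(1e-300)


# ---------------------------------------------------------------------------
# LOD scan
# ---------------------------------------------------------------------------

class TestLodScan:
    @pytest.mark.parametrize("alpha_star", [0.0, 0.05, 0.1, 0.2, 0.333, 0.4])
    def test_noise_free_recovery(self, synthetic_panel, alpha_star):
        obs = expected_pair_observations(synthetic_panel, alpha_star)
        curve, alpha_hat = lod_scan(obs, synthetic_panel)
        assert abs(alpha_hat - alpha_star) <= 1e-4 + 1e-12

    def test_lod_zero_at_null(self, synthetic_panel):
        obs = expected_pair_observations(synthetic_panel, 0.07)
        curve, _ = lod_scan(obs, synthetic_panel)
        i0 = int(np.argmin(np.abs(curve.grid)))
        assert curve.grid[i0] == 0.0
        assert curve.lod[i0] == 0.0

    def test_permutation_invariance(self, synthetic_panel):
        obs = expected_pair_observations(synthetic_panel, 0.1)
        curve, _ = lod_scan(obs, synthetic_panel)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(obs.pair_index))
        shuffled = PairObservations(
            pair_index=obs.pair_index[perm], chrom=obs.chrom[perm],
            uu=obs.uu[perm], du=obs.du[perm], dd=obs.dd[perm])
        curve2, _ = lod_scan(shuffled, synthetic_panel)
        assert np.allclose(curve.lod, curve2.lod)

    def test_empty_observations_error(self, synthetic_panel):
        empty = PairObservations(pair_index=np.arange(2), chrom=np.array([1, 2]),
                                 uu=np.zeros((2, 4)), du=np.zeros((2, 4)),
                                 dd=np.zeros((2, 4)))
        with pytest.raises(ValueError, match="no pair observations"):
            lod_scan(empty, synthetic_panel)


# ---------------------------------------------------------------------------
# damage-corrected joint estimate
# ---------------------------------------------------------------------------

class TestDamageCorrection:
    @pytest.mark.parametrize("alpha_star", [0.0, 0.02, 0.05, 0.10])
    @pytest.mark.parametrize("k_star", [-0.02, 0.0, 0.03])
    def test_noise_free_joint_recovery(self, synthetic_panel, alpha_star, k_star):
        obs = expected_pair_observations(
            synthetic_panel, alpha_uu=alpha_star + k_star,
            alpha_du=alpha_star / 2 + k_star, alpha_dd=k_star,
            n_per_pair=2000.0)
        with pytest.warns(RuntimeWarning):  # DD below the reliability floor
            alpha, k, alpha_all = damage_corrected_estimate(
                obs, synthetic_panel, d=0.0, min_dd_obs=10 ** 9)
        assert abs(alpha - alpha_star) <= 1e-4 + 1e-12
        assert abs(k - k_star) <= 1e-4 + 1e-12
        assert alpha_all == pytest.approx(alpha)

    def test_spec_example_and_rescaling(self, synthetic_panel):
        # classes at alpha=0.04, k=0.02; then the (1 - d) rescale
        obs = expected_pair_observations(synthetic_panel, 0.06, 0.04, 0.02,
                                         n_per_pair=2000.0)
        alpha, k, alpha_all = damage_corrected_estimate(obs, synthetic_panel,
                                                        d=0.2, min_dd_obs=0)
        assert alpha == pytest.approx(0.04, abs=1e-4)
        assert k == pytest.approx(0.02, abs=1e-4)
        assert alpha_all == pytest.approx(alpha * 0.8)

    def test_agreeing_classes_mean_zero_alpha(self, synthetic_panel):
        obs = expected_pair_observations(synthetic_panel, 0.02, 0.02, 0.02,
                                         n_per_pair=2000.0)
        alpha, k, _ = damage_corrected_estimate(obs, synthetic_panel, d=0.0,
                                                min_dd_obs=0)
        assert alpha == pytest.approx(0.0, abs=1e-4)
        assert k == pytest.approx(0.02, abs=1e-4)

    def test_insufficient_dd_warns(self, synthetic_panel):
        obs = expected_pair_observations(synthetic_panel, 0.05, 0.05, 0.05,
                                         n_per_pair=10.0)
        with pytest.warns(RuntimeWarning, match="insufficient damaged data"):
            damage_corrected_estimate(obs, synthetic_panel, d=0.0,
                                      min_dd_obs=10 ** 6)


# ---------------------------------------------------------------------------
# external correction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw,bench,expected", [
    (0.07, 0.02, 0.05),
    (0.02, 0.02, 0.0),
    (0.01, 0.02, -0.01),  # negative allowed; reporting floors at 0 separately
])
def test_external_correction(raw, bench, expected):
    assert external_corrected_estimate(raw, bench) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

class TestJackknife:
    def test_identical_deletions_zero_se(self):
        assert weighted_jackknife(0.05, [0.05] * 5, [1, 2, 3, 4, 5]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_equal_blocks_closed_form(self):
        a, b = 0.03, 0.07
        se = weighted_jackknife(0.05, [a, b], [10, 10])
        assert se == pytest.approx(abs(a - b) / 2)

    def test_equal_weights_match_unweighted_formula(self):
        rng = np.random.default_rng(12)
        theta = rng.normal(0.05, 0.01, 22)
        full = 0.05
        se = weighted_jackknife(full, theta, np.full(22, 7.0))
        g = 22
        unweighted = math.sqrt((g - 1) / g * np.sum((theta - theta.mean()) ** 2))
        assert se == pytest.approx(unweighted)

    def test_requires_two_blocks(self):
        with pytest.raises(ValueError, match=">=2 blocks"):
            weighted_jackknife(0.05, [0.05], [1.0])

    def test_jackknife_se_op_single_chromosome_errors(self, synthetic_panel):
        obs = expected_pair_observations(synthetic_panel, 0.05)
        one = obs.chrom == 1
        single = PairObservations(pair_index=obs.pair_index[one],
                                  chrom=obs.chrom[one], uu=obs.uu[one],
                                  du=obs.du[one], dd=obs.dd[one])
        with pytest.raises(ValueError, match=">=2 chromosomes"):
            jackknife_se(single, synthetic_panel, {"mode": "none"})

    def test_jackknife_se_op_none_mode(self, synthetic_panel):
        obs = expected_pair_observations(synthetic_panel, 0.05)
        se, per_chrom = jackknife_se(obs, synthetic_panel, {"mode": "none"})
        # noise-free expected counts: every delete-one estimate is 0.05
        assert se == pytest.approx(0.0, abs=1e-9)
        assert set(per_chrom) == set(range(1, 23))


# ---------------------------------------------------------------------------
# warnings and orchestration
# ---------------------------------------------------------------------------

class TestWarningRule:
    def test_threshold(self):
        assert very_high_warning(0.151) == "Very_High_Contamination"
        assert very_high_warning(0.149) == ""
        assert very_high_warning(0.15) == ""

    @pytest.mark.parametrize("alpha_star,expect_flag", [(0.151, True), (0.149, False)])
    def test_raw_scan_triggers_flag(self, synthetic_panel, alpha_star, expect_flag):
        obs = expected_pair_observations(synthetic_panel, alpha_star)
        _, alpha_hat = lod_scan(obs, synthetic_panel)
        assert alpha_hat == pytest.approx(alpha_star, abs=1e-4)
        assert bool(very_high_warning(alpha_hat)) is expect_flag


@pytest.fixture(scope="module")
def fitted(recovery_world):
    from conftest import sample_from_world
    counts = sample_from_world(recovery_world, alpha=0.05, rep=13)
    est = ContaminationEstimator(panel=recovery_world[1], correction="damage")
    est.fit(counts)
    return est


class TestEstimateOrchestration:
    def test_fitted_attributes(self, fitted):
        assert fitted.se_ > 0
        assert 0 <= fitted.damage_rate_ <= 1
        assert fitted.n_pair_obs_ > 0
        assert fitted.warning_ == ""
        assert fitted.diagnostics_["n_chromosomes"] == 22
        assert len(fitted.per_chrom_) == 22

    def test_parameter_recovery_within_ci(self, fitted):
        # true contamination 0.05 spiked into undamaged sequences at d=0.1
        assert abs(fitted.alpha_corrected_ - 0.05) <= 1.96 * fitted.se_

    def test_report_frame(self, fitted):
        df = fitted.report_().to_frame(sample="s1")
        expect = {"sample", "alpha_raw", "k_hat", "damage_rate", "alpha_corrected",
                  "alpha_corrected_floor0", "se", "ci95_lo", "ci95_hi",
                  "n_pair_obs", "warning"}
        assert set(df.columns) == expect
        assert df["alpha_corrected_floor0"].iloc[0] >= 0

    def test_external_mode_requires_benchmark(self, recovery_world):
        est = ContaminationEstimator(panel=recovery_world[1], correction="external")
        with pytest.raises(ValueError, match="benchmark"):
            est.fit(SiteCounts(pd.DataFrame(
                columns=["chrom", "pos", "ref", "alt", "nref_und", "nalt_und",
                         "nref_dam", "nalt_dam"])))

    def test_external_mode_shifts_raw(self, recovery_world):
        from conftest import sample_from_world
        counts = sample_from_world(recovery_world, alpha=0.05, rep=14)
        res = estimate(counts, recovery_world[1], mode="external", benchmark=0.01)
        assert res.alpha_corrected == pytest.approx(res.alpha_raw - 0.01)

    def test_sklearn_clone_roundtrip(self, recovery_world):
        from sklearn.base import clone
        est = ContaminationEstimator(panel=recovery_world[1], correction="none",
                                     min_dd_obs=500)
        c = clone(est)
        assert c.get_params()["min_dd_obs"] == 500
        assert c.get_params()["correction"] == "none"

    def test_floor0_negative_estimates(self, fitted):
        rec = fitted.report_()
        rec.alpha_corrected = -0.01
        assert rec.alpha_corrected_floor0 == 0.0
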