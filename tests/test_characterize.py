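import math

import numpy as np
import pytest
from scipy import stats as sps

import squigglesim as sq
from squigglesim.errors import ConfigError

GEV_LSF_MEAN = 2194 + 217 * (math.gamma(1.1) - 1) / (-0.10)  # mu + sigma*(Gamma(1-k)-1)/k


def _length_ensemble(lengths, rng):
    return sq.Ensemble(
        squiggles=[
            sq.Squiggle(id=f"s{i}", events=rng.normal(size=n)) for i, n in enumerate(lengths)
        ]
    )


class TestLsf:
    def test_known_ratio(self):
        rng = np.random.default_rng(0)
        _, gold = sq.make_fixture(1, 1314, 5)
        ens = _length_ensemble([2227], rng)
        assert sq.compute_lsf(ens, gold)[0] == pytest.approx(1.70, abs=0.005)

    def test_equal_length_is_one(self, small_fixture):
        _, gold = small_fixture
        ens = _length_ensemble([400], np.random.default_rng(1))
        assert sq.compute_lsf(ens, gold)[0] == 1.0

    def test_gev_sample_mean(self):
        # closed-form GEV mean over gold length 1310 is ~1.755
        draws = sps.genextreme.rvs(
            c=0.10, loc=2194, scale=217, size=5000, random_state=np.random.default_rng(2)
        )
        assert np.mean(draws) / 1310 == pytest.approx(GEV_LSF_MEAN / 1310, rel=0.01)


class TestEmpiricalModel:
    def test_step_cdf(self):
        model = sq.empirical_length_model([1.0, 2.0, 3.0])
        assert model.cdf(2.0) == pytest.approx(2 / 3)
        assert model.cdf(1.0 - 1e-9) == 0.0
        assert model.cdf(3.0) == 1.0

    def test_ks_against_fresh_sample(self):
        gen = sps.genextreme(c=0.10, loc=2194, scale=217)
        a = gen.rvs(size=2000, random_state=np.random.default_rng(3)) / 1310
        b = gen.rvs(size=2000, random_state=np.random.default_rng(4)) / 1310
        model = sq.empirical_length_model(a)
        ks = sps.ks_2samp(a, b).statistic
        assert ks < 0.05
        # model CDF agrees with its own sample's empirical CDF by construction
        assert model.cdf(np.median(a)) == pytest.approx(0.5, abs=0.01)

    def test_interpolated_inverse(self):
        model = sq.empirical_length_model([1.5, 1.7, 1.9])
        assert model.ppf(0.5) == pytest.approx(1.7)


class TestRateCurves:
    def test_reference_zero_insertion_at_lsf_17(self):
        assert sq.eval_rate(sq.REFERENCE_RATE_CURVE, 0, 1.7) == pytest.approx(67.10, abs=0.01)

    def test_lsf_one_returns_intercept(self):
        assert sq.eval_rate(sq.REFERENCE_RATE_CURVE, 0, 1.0) == pytest.approx(90.2)

    def test_negative_rate_clamped(self):
        # A=-0.7, B=6.2 at lsf 1.05 evaluates to -0.405 raw
        assert sq.eval_rate(sq.REFERENCE_RATE_CURVE, 4, 1.05) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sq.eval_rate(sq.REFERENCE_RATE_CURVE, 0, 0.9)

    def test_monotone_in_lsf(self):
        grid = np.linspace(1.01, 3.5, 40)
        vals = [sq.eval_rate(sq.REFERENCE_RATE_CURVE, 1, x) for x in grid]  # B > 0
        assert np.all(np.diff(vals) >= 0)
        vals0 = [sq.eval_rate(sq.REFERENCE_RATE_CURVE, 0, x) for x in grid]  # B < 0
        assert np.all(np.diff(vals0) <= 0)


class TestTail:
    def test_five_insertions_at_lsf_17(self):
        assert sq.tail_prob(sq.REFERENCE_TAIL, 5, 1.7) == pytest.approx(1.963, abs=0.001)

    def test_zero_at_lsf_one(self):
        for count in (5, 7, 12):
            assert sq.tail_prob(sq.REFERENCE_TAIL, count, 1.0) == 0.0

    def test_heavier_decay_shrinks_tail(self):
        heavy = sq.TailModel(b4=6.2, decay=2.0)
        assert sq.tail_prob(heavy, 6, 1.7) < sq.tail_prob(sq.REFERENCE_TAIL, 6, 1.7)

    def test_count_below_five_rejected(self):
        with pytest.raises(ValueError):
            sq.tail_prob(sq.REFERENCE_TAIL, 4, 1.7)

    def test_categorical_normalized_over_lsf_grid(self):
        for lsf in np.linspace(1.0, 3.5, 26):
            pmf = sq.insertion_pmf(sq.REFERENCE_RATE_CURVE, sq.REFERENCE_TAIL, lsf)
            assert pmf.sum() == pytest.approx(1.0)
            assert np.all(pmf >= 0)


class TestDistributionFits:
    def test_lognormal_sigma_recovered(self):
        x = np.exp(np.random.default_rng(7).normal(7.73, 0.106, size=2000))
        fit = sq.fit_long_tailed(x, "lognormal")
        assert fit.converged
        lo, hi = fit.ci95["sigma"]
        assert lo <= 0.106 <= hi

    def test_loglogistic_mu_recovered(self):
        x = sps.fisk.rvs(c=1 / 0.061, scale=np.exp(7.73), size=2000,
                         random_state=np.random.default_rng(8))
        fit = sq.fit_long_tailed(x, "loglogistic")
        assert fit.converged
        lo, hi = fit.ci95["mu"]
        assert lo <= 7.73 <= hi

    def test_constant_data_flagged(self):
        fit = sq.fit_long_tailed(np.full(50, 1310.0), "gev")
        assert not fit.converged

    def test_cis_bracket_estimates(self):
        x = sps.genextreme.rvs(c=0.10, loc=2194, scale=217, size=500,
                               random_state=np.random.default_rng(9))
        fit = sq.fit_long_tailed(x, "gev")
        assert fit.converged
        for name, val in fit.params.items():
            lo, hi = fit.ci95[name]
            assert lo < val < hi


class TestSnr:
    def _noisy_ensemble(self, gold, n, noise_std, seed):
        cfg = sq.SimConfig(
            model_kind="chan_geometric", n_squiggles=n, seed=seed, i0=0.0,
            snr_target=1.0 / noise_std,
        )
        ens, _ = sq.simulate_ensemble(gold, cfg)
        return ens

    def test_round_trip_at_noise_025(self, small_fixture):
        _, gold = small_fixture
        ens = self._noisy_ensemble(gold, 20, 0.25, seed=31)
        est = sq.estimate_snr(ens, gold_length=400, K=1)
        assert est.snr_mean == pytest.approx(4.0, rel=0.10)

    def test_round_trip_at_noise_010(self, small_fixture):
        _, gold = small_fixture
        ens = self._noisy_ensemble(gold, 20, 0.10, seed=32)
        est = sq.estimate_snr(ens, gold_length=400, K=1)
        assert est.snr_mean == pytest.approx(10.0, rel=0.10)

    def test_warping_bias_bounded_at_noise_050(self, small_fixture):
        # at SNR 2 the optimal warp visibly absorbs noise; the estimate is
        # biased high but stays within ~25% of the target
        _, gold = small_fixture
        ens = self._noisy_ensemble(gold, 20, 0.50, seed=33)
        est = sq.estimate_snr(ens, gold_length=400, K=1)
        assert 2.0 <= est.snr_mean <= 2.5

    def test_k_scales_linearly(self, small_fixture):
        _, gold = small_fixture
        ens = self._noisy_ensemble(gold, 10, 0.25, seed=34)
        e1 = sq.estimate_snr(ens, gold_length=400, K=1)
        e2 = sq.estimate_snr(ens, gold_length=400, K=1.25)
        assert e2.snr_mean == pytest.approx(1.25 * e1.snr_mean)

    def test_identical_pairs_skipped(self, small_fixture):
        _, gold = small_fixture
        gz = sq.ensure_normalized(gold.squiggle)
        copies = [sq.Squiggle(id=f"c{i}", events=gz.events.copy(), normalized=True) for i in range(3)]
        noisy = sq.Squiggle(
            id="n", events=gz.events + np.random.default_rng(0).normal(0, 0.2, 400),
            normalized=True,
        )
        ens = sq.Ensemble(squiggles=copies + [noisy])
        with pytest.warns(UserWarning):
            est = sq.estimate_snr(ens, gold_length=400, K=1)
        assert est.n_pairs == 3  # only pairs involving the noisy member inform

    def test_range_snr(self):
        assert sq.range_snr([0.0, 10.0], noise_std=0.2) == pytest.approx(50.0)


class TestFitRateCurves:
    def test_single_lsf_unidentifiable(self, small_fixture):
        _, gold = small_fixture
        gz = sq.ensure_normalized(gold.squiggle)
        ens = sq.Ensemble(
            squiggles=[sq.Squiggle(id=f"c{i}", events=gz.events.copy(), normalized=True) for i in range(6)]
        )
        with pytest.raises(ConfigError):
            sq.fit_rate_curves(ens, gold, bin_width=50)
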