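"""Neutral indel model estimators: geometric fitting, NIM1 excess
summation, NIM2 mixture likelihood, aggregation and subset estimation."""

import math
from collections import Counter

import numpy as np
import pytest

from selindel.alignio import IGSHistogram, extract_igs
from selindel.nim import (
    ConstraintEstimate,
    NeutralIndelModel,
    NotGeometricError,
    Z95,
    _wls_line,
    alpha_genome,
    alpha_nim1,
    alpha_nim2,
    alpha_subset,
    fit_neutral_geometric,
)


def geometric_hist(theta=0.02, n=1_000_000, xmax=1500, exact=True, rng=None,
                   total_bp=None):
    """Histogram of a pure geometric IGS law; exact expected counts or a
    Poisson sample of them."""
    x = np.arange(1, xmax + 1)
    lam = n * theta * (1 - theta) ** (x - 1)
    counts = lam if exact else rng.poisson(lam)
    c = Counter({int(k): float(v) for k, v in zip(x, counts) if v > 0})
    total = total_bp if total_bp is not None else int((x * counts).sum())
    return IGSHistogram("1", c, total_aligned_bp=total)


class TestGeometricFit:
    def test_exact_counts_invert_to_machine_precision(self):
        # c(x) = 1000 * 0.98^x over [30, 130]
        counts = Counter({x: 1000 * 0.98**x for x in range(30, 131)})
        hist = IGSHistogram("1", counts, total_aligned_bp=10**7)
        fit = fit_neutral_geometric(hist, fit_range=(30, 130))
        assert fit.theta == pytest.approx(0.02, abs=1e-12)
        assert fit.K == pytest.approx(49.0, abs=1e-9)
        assert fit.T == 130

    def test_matches_statsmodels_wls(self):
        # the closed-form weighted regression equals the library fit
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        hist = geometric_hist(0.03, n=200_000, exact=False, rng=rng)
        xs, cs = hist.lengths_counts()
        m = (xs >= 20) & (xs <= 120)
        x, c = xs[m].astype(float), cs[m]
        params, cov, _ = _wls_line(x, np.log(c), c)
        res = sm.WLS(np.log(c), sm.add_constant(x), weights=c).fit()
        assert np.allclose(params, res.params, rtol=1e-10)
        assert np.allclose(cov, res.cov_params(), rtol=1e-8)

    def test_single_length_is_error(self):
        hist = IGSHistogram("1", Counter({50: 1000}))
        with pytest.raises(ValueError):
            fit_neutral_geometric(hist)

    def test_increasing_counts_not_geometric(self):
        counts = Counter({x: float(x) for x in range(10, 200)})
        hist = IGSHistogram("1", counts)
        with pytest.raises((NotGeometricError, ValueError)):
            fit_neutral_geometric(hist, fit_range=(10, 199))

    def test_theta_coverage_under_poisson_sampling(self):
        """The fitted slope's own CI covers the generating theta at roughly
        nominal rate over seeded Poisson replicates."""
        theta = 0.02
        hit = 0
        reps = 60
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            hist = geometric_hist(theta, n=300_000, exact=False, rng=rng)
            fit = fit_neutral_geometric(hist, fit_range=(20, 140))
            se = math.sqrt(fit.covariance[1, 1])
            lo, hi = fit.slope - Z95 * se, fit.slope + Z95 * se
            if lo <= math.log(1 - theta) <= hi:
                hit += 1
        assert hit / reps >= 0.85


class TestAlphaNIM1:
    def test_pure_geometric_histogram_gives_zero(self):
        hist = geometric_hist(0.02, exact=True)
        fit = fit_neutral_geometric(hist, fit_range=(30, 130))
        est = alpha_nim1(hist, fit, n_boot=100, rng=0)
        assert est.alpha_bp == pytest.approx(0.0, abs=1.0)

    def test_excess_spike_contributes_x_minus_2k(self):
        counts = Counter({x: 1000 * 0.98**x for x in range(1, 1200)})
        counts[500] += 100
        hist = IGSHistogram("1", counts, total_aligned_bp=10**8)
        fit = fit_neutral_geometric(hist, fit_range=(30, 130))
        est = alpha_nim1(hist, fit, n_boot=200, rng=0)
        assert est.alpha_bp == pytest.approx(100 * (500 - 2 * fit.K), rel=1e-3)
        assert est.ci95[0] <= est.alpha_bp <= est.ci95[1]

    def test_empty_tail_degenerate(self):
        counts = Counter({x: 1000 * 0.98**x for x in range(30, 131)})
        hist = IGSHistogram("1", counts, total_aligned_bp=10**6)
        fit = fit_neutral_geometric(hist, fit_range=(30, 130))
        est = alpha_nim1(hist, fit, n_boot=10, rng=0)
        assert est.alpha_bp == 0.0 and est.ci95 == (0.0, 0.0)

    def test_threshold_below_fit_range_is_error(self):
        hist = geometric_hist(0.02)
        fit = fit_neutral_geometric(hist, fit_range=(30, 130))
        fit.T = 100
        with pytest.raises(ValueError, match="[Tt]hreshold"):
            alpha_nim1(hist, fit)


def mixture_sample(rng, theta=0.02, pi=0.05, mu=300.0, n=20_000):
    neutral = rng.geometric(theta, size=n)
    is_c = rng.random(n) < pi
    core = rng.geometric(1.0 / mu, size=n)
    ov = rng.geometric(theta, size=(2, n)) - 1
    x = np.where(is_c, core + ov[0] + ov[1], neutral)
    c = Counter({int(k): int(v) for k, v in zip(*np.unique(x, return_counts=True))})
    return IGSHistogram("1", c, total_aligned_bp=int(x.sum())), is_c, core


class TestAlphaNIM2:
    def test_pure_geometric_gives_near_zero_pi(self):
        hist = geometric_hist(0.02, n=200_000, exact=True, xmax=1200)
        est = alpha_nim2(hist, ci=False)
        # alpha is a negligible fraction of the aligned bases
        assert est.alpha_fraction < 2e-3

    def test_recovers_mixture_truth_within_10pct(self):
        ok = 0
        reps = 12
        for i in range(reps):
            rng = np.random.default_rng(300 + i)
            hist, is_c, core = mixture_sample(rng)
            truth = core[is_c].sum()
            est = alpha_nim2(hist, ci=False)
            if abs(est.alpha_bp - truth) / truth <= 0.10:
                ok += 1
        assert ok >= reps - 2

    def test_profile_ci_brackets_estimate_and_truth(self):
        rng = np.random.default_rng(42)
        hist, is_c, core = mixture_sample(rng, n=30_000)
        est = alpha_nim2(hist, ci=True, ci_method="profile")
        assert est.ci95[0] <= est.alpha_bp <= est.ci95[1]
        truth = core[is_c].sum()
        assert est.ci95[0] <= truth * 1.1 and est.ci95[1] >= truth * 0.9


class TestAggregation:
    def _estimate(self, alpha, half):
        return ConstraintEstimate(alpha, 0.0, (alpha - half, alpha + half), "NIM1", ["1"])

    def test_two_bins_sum(self):
        h1 = geometric_hist(0.02, n=300_000, exact=True)
        counts = Counter({x: 300_000 * 0.02 * 0.98 ** (x - 1) for x in range(1, 1500)})
        counts[600] += 50
        h2 = IGSHistogram("2", counts, total_aligned_bp=h1.total_aligned_bp)
        tot = alpha_genome([h1, h2], method="NIM1", n_boot=100, rng=0)
        e2 = alpha_nim1(h2, n_boot=100, rng=0)
        assert tot.alpha_bp == pytest.approx(e2.alpha_bp, rel=1e-6)

    def test_identical_bins_ci_scales_sqrt2(self):
        rng = np.random.default_rng(9)
        hist, _, _ = mixture_sample(rng, n=40_000)
        one = alpha_nim1(hist, n_boot=400, rng=1)
        two = alpha_genome([hist, hist], method="NIM1", n_boot=400, rng=1)
        w1 = one.ci95[1] - one.ci95[0]
        w2 = two.ci95[1] - two.ci95[0]
        assert w2 == pytest.approx(math.sqrt(2) * w1, rel=0.25)
        assert two.alpha_bp == pytest.approx(2 * one.alpha_bp, rel=0.05)

    def test_failing_bin_skipped_with_warning(self):
        good = geometric_hist(0.02, n=200_000, exact=True)
        bad = IGSHistogram("bad", Counter({40: 10}))
        with pytest.warns(UserWarning, match="skipped"):
            est = alpha_genome([good, bad], method="NIM1", n_boot=50, rng=0)
        assert est.diagnostics["skipped"] == ["bad"]


class TestSubset:
    def test_empty_subset_gives_zero(self, constrained_sim):
        blocks, _ = constrained_sim
        est = alpha_subset(blocks, {}, method="NIM1", n_bins=1)
        assert est.alpha_bp == 0.0

    def test_subset_containing_all_elements_absorbs_alpha(self, constrained_sim):
        """Excising every constrained element leaves G\\S with ~no signal, so
        alpha(S) recovers most of alpha(G)."""
        blocks, truth = constrained_sim
        subset = {"chr1": truth.elements_ref.copy()}
        est = alpha_subset(
            blocks, subset, buffer=50, method="NIM1", n_bins=1, n_boot=100, rng=3
        )
        g = est.diagnostics["G"]
        gs = est.diagnostics["G_minus_S"]
        assert gs.alpha_bp < 0.15 * g.alpha_bp
        assert est.alpha_bp > 0.7 * g.alpha_bp
        assert est.alpha_bp <= 1.1 * truth.mutual_bp

    def test_subset_covering_everything_is_error(self, constrained_sim):
        blocks, _ = constrained_sim
        whole = {"chr1": np.array([[0, 10**9]])}
        with pytest.raises(ValueError, match="99"):
            alpha_subset(blocks, whole, method="NIM1", n_bins=1)


class TestModelFrontEnd:
    def test_from_blocks_fit_and_summary(self, constrained_sim):
        blocks, truth = constrained_sim
        model = NeutralIndelModel.from_blocks(blocks, n_bins=2)
        res = model.fit(method="nim1", n_boot=100, seed=5)
        assert 0 < res.alpha_fraction < 0.2
        lo, hi = res.conf_int()
        assert lo <= res.alpha_bp <= hi
        text = res.summary()
        assert "NIM1" in text and "alpha_selIndel" in text
        assert len(res.per_bin) == 2

    def test_fit_is_deterministic_given_seed(self, constrained_sim):
        blocks, _ = constrained_sim
        model = NeutralIndelModel.from_blocks(blocks, n_bins=2)
        a = model.fit(method="nim1", n_boot=100, seed=5)
        b = model.fit(method="nim1", n_boot=100, seed=5)
        assert a.alpha_bp == b.alpha_bp and a.conf_int() == b.conf_int()
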