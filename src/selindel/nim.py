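"""Neutral indel model estimators of indel-constrained sequence.

In neutrally evolving sequence the distance between neighbouring indel
events is geometrically distributed, so the log-counts of inter-gap segment
(IGS) lengths fall on a straight line.  Sequence under purifying selection
with respect to indels interrupts this: long IGSs are over-represented
relative to the geometric expectation.  Two estimators quantify the
constrained fraction alpha_selIndel:

* **NIM1** (regression): fit the geometric law over a window of medium IGS
  lengths, then sum ``x - 2K`` over the long IGSs in excess of the neutral
  expectation, where ``K = (1-theta)/theta`` is the neutral overhang (the
  expected spacing from a constrained segment's edge to the nearest indel).
  Each excess segment contributes its length minus two overhangs; this is a
  deliberate lower bound.
* **NIM2** (likelihood): maximum likelihood under a two-component mixture in
  which an IGS is neutral-geometric with probability ``1 - pi``, or contains
  a geometric constrained core (mean ``mu_c``) flanked by two independent
  neutral overhangs with probability ``pi``.

Estimation is stratified (G+C bins, X chromosome apart) and aggregated
across strata; constraint within an annotation subset S is obtained by
difference between estimates on G and on G with S excised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, signal

from .alignio import (
    AlignmentBlock,
    IGSHistogram,
    IGSRecord,
    assign_gc_bins,
    excise_intervals,
    extract_igs,
)

__all__ = [
    "GeometricFit",
    "ConstraintEstimate",
    "NotGeometricError",
    "fit_neutral_geometric",
    "alpha_nim1",
    "alpha_nim2",
    "alpha_genome",
    "alpha_subset",
    "NeutralIndelModel",
    "NIMResults",
]

Z95 = 1.959963984540054

# Text-S1-style corrections, at contract level:
# (A) thresholding/censoring biases overhang expectations -> censored
#     segments are excluded outright and the unconditional K is used;
# (B) neutral segments are depleted from the background by the presence of
#     constrained segments -> the expected neutral count is rescaled by the
#     neutral fraction (1 - alpha) and the estimate iterated to a fixed
#     point.
DEPLETION_TOL = 1e-4
DEPLETION_MAX_ITER = 20
# The two corrections have equal-but-opposite effects on the estimate, so
# the default estimator applies neither beyond censored-exclusion and keeps
# the plain netted lower bound; the depletion fixed point can be switched on
# for sensitivity analysis (it raises estimates by ~alpha * neutral-tail).
DEPLETION_DEFAULT = False


class NotGeometricError(ValueError):
    """Histogram shows no geometric-like decay over the fit range."""


@dataclass
class GeometricFit:
    """Fitted neutral geometric law for one stratum.

    theta is the per-base probability that a neutral IGS ends at the next
    base; ln(counts) regress on length with slope ln(1 - theta).  K is the
    neutral overhang (1-theta)/theta and T the threshold above which excess
    is summed (defaults to the top of the fit range).
    """

    theta: float
    log_intercept: float
    fit_range: tuple[int, int]
    T: int
    K: float
    covariance: np.ndarray  # 2x2, order (log_intercept, slope)
    rsquared: float = float("nan")
    n_segments: int = 0

    @property
    def slope(self) -> float:
        return math.log1p(-self.theta)

    def expected(self, x: np.ndarray) -> np.ndarray:
        """Expected neutral count at length(s) x."""
        return np.exp(self.log_intercept + self.slope * np.asarray(x, dtype=float))


@dataclass
class ConstraintEstimate:
    """alpha_selIndel for a stratum, a genome, or an annotation subset."""

    alpha_bp: float
    alpha_fraction: float
    ci95: tuple[float, float]
    method: str
    bins: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def sigma(self) -> float:
        """Normal-approximation standard error from the 95% CI width."""
        return (self.ci95[1] - self.ci95[0]) / (2 * Z95)


# ---------------------------------------------------------------------------
# weighted regression on log-counts


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form 2-parameter weighted least squares of y on [1, x].

    Returns (params, cov, r2) with params = (intercept, slope) and the
    covariance scaled by the weighted residual variance (n - 2 dof).
    """
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    if sxx <= 0:
        raise ValueError("degenerate regression support")
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    wrss = (w * resid**2).sum()
    wtss = (w * (y - ym) ** 2).sum()
    dof = max(len(x) - 2, 1)
    s2 = wrss / dof
    cov = s2 * np.array(
        [[1.0 / W + xm**2 / sxx, -xm / sxx], [-xm / sxx, 1.0 / sxx]]
    )
    r2 = 1.0 - wrss / wtss if wtss > 0 else float("nan")
    return np.array([intercept, slope]), cov, r2


# Margin (bp) added above 2K when choosing the excess threshold T: segments
# shorter than 2K + T_MARGIN can each contribute at most T_MARGIN bases
# after overhang subtraction and their excess counts sit where neutral-fit
# uncertainty dominates, so they are left out of the excess sum.  A fixed
# absolute margin keeps the detection floor comparable across divergences.
T_MARGIN = 40


def _auto_range(xs: np.ndarray, cs: np.ndarray) -> tuple[int, int]:
    """Scale-aware fit window [L_lo, L_hi].

    Two passes: a provisional decay rate theta0 from the mean IGS length
    anchors a medium-length window [0.5/theta, 2K]; the window is
    re-anchored once on the refitted theta.  The window deliberately stops
    at ~2K: segments containing a constrained core start appearing just
    above two neutral overhangs, and letting them into the window flattens
    the fitted slope and inflates the extrapolated neutral tail.  Windows
    in absolute units are unusable here because the IGS length scale varies
    by a factor of several across divergences.
    """
    total = float(cs.sum())
    mean_x = float((xs * cs).sum() / total)
    theta = 1.0 / max(mean_x, 2.0)
    lo, hi = 2, int(xs.max())
    for _ in range(2):
        k2 = 2.0 * (1.0 - theta) / theta
        lo = max(10, int(round(0.25 / theta)))
        hi = int(round(k2))
        hi = max(hi, lo + 20)
        # extend upward until the window holds enough populated lengths
        while ((xs >= lo) & (xs <= hi)).sum() < 10 and hi < int(xs.max()):
            hi = min(hi * 2, int(xs.max()))
        m = (xs >= lo) & (xs <= hi)
        if m.sum() < 10:
            break
        params, _, _ = _wls_line(
            xs[m].astype(float), np.log(cs[m].astype(float)), cs[m].astype(float)
        )
        if params[1] < 0:
            theta = 1.0 - math.exp(params[1])
    return lo, hi


def fit_neutral_geometric(
    hist: IGSHistogram, fit_range: tuple[int, int] | None = None
) -> GeometricFit:
    """Fit the neutral geometric IGS law to one histogram by weighted
    regression of ln(count) on length (weights = counts; zero-count lengths
    skipped).

    When ``fit_range`` is not given, candidate windows are scanned and the
    one maximising the weighted R^2 is used (see :func:`_auto_windows`).
    """
    xs, cs = hist.lengths_counts()
    if len(xs) == 0:
        raise ValueError(f"bin {hist.bin_label}: empty histogram")

    def _fit(lo: int, hi: int):
        m = (xs >= lo) & (xs <= hi)
        if m.sum() < 10:
            return None
        x = xs[m].astype(float)
        c = cs[m].astype(float)
        params, cov, r2 = _wls_line(x, np.log(c), c)
        return params, cov, r2, (lo, hi)

    if fit_range is not None:
        got = _fit(int(fit_range[0]), int(fit_range[1]))
        if got is None:
            raise ValueError(
                f"bin {hist.bin_label}: fewer than 10 populated lengths in "
                f"fit range {fit_range}"
            )
    else:
        got = _fit(*_auto_range(xs, cs))
        if got is None:
            raise ValueError(
                f"bin {hist.bin_label}: no viable fit window (insufficient "
                "support); use fewer bins or supply fit_range"
            )

    params, cov, r2, rng = got
    intercept, slope = params
    if slope >= 0:
        raise NotGeometricError(
            f"bin {hist.bin_label}: non-negative slope {slope:.3g}; "
            "histogram not geometric-like"
        )
    theta = 1.0 - math.exp(slope)
    if fit_range is not None:
        # classic closed-form overhang; threshold at the top of the window
        K = (1.0 - theta) / theta
        T = rng[1]
    else:
        # The overhang K is anchored on the memoryless moment estimator
        # E[x - L_lo | x >= L_lo], which equals (1-theta)/theta under the
        # geometric law but uses the whole upper histogram and is an order
        # of magnitude less variable than the regression slope; any
        # contamination by constrained segments only enlarges K, making the
        # x - 2K lower bound more conservative.  The regression parameters
        # are kept for extrapolating the expected neutral counts.  The
        # excess threshold sits a fixed margin above two overhangs
        # (segments below 2K have zero net contribution anyway).
        m_up = xs >= rng[0]
        K = float(((xs[m_up] - rng[0]) * cs[m_up]).sum() / cs[m_up].sum())
        K = max(K, 1.0)
        T = max(rng[1], int(round(2.0 * K)) + T_MARGIN)
    return GeometricFit(
        theta=theta,
        log_intercept=float(intercept),
        fit_range=rng,
        T=T,
        K=K,
        covariance=cov,
        rsquared=r2,
        n_segments=int(cs.sum()),
    )


# ---------------------------------------------------------------------------
# NIM1: excess summation


def _excess_alpha(
    tail_x: np.ndarray,
    tail_c: np.ndarray,
    intercept: float,
    slope: float,
    k2: float,
    total_bp: float,
    depletion: bool = DEPLETION_DEFAULT,
) -> float:
    """Excess constrained bases: sum over the tail of
    (count - expected) * max(x - 2K, 0), iterated with the neutral-depletion
    rescaling of the expectation.

    Signed deviations are netted across tail lengths (zero-count lengths
    included, with the analytic geometric remainder beyond the last observed
    length) so that sampling noise cancels in expectation; only the total is
    floored at zero.  Per-length flooring would accumulate half-normal noise
    into a positive bias of order sqrt(N) that violates both null
    calibration and conservativeness on simulated data.
    """
    if slope >= 0 or len(tail_x) == 0:
        return 0.0
    theta = 1.0 - math.exp(slope)
    # full integer tail grid so zero-count lengths contribute -e_hat
    x_lo = int(tail_x.min())
    x_hi = int(tail_x.max())
    grid = np.arange(x_lo, x_hi + 1, dtype=float)
    counts = np.zeros(grid.size)
    counts[(tail_x - x_lo).astype(int)] = tail_c
    contrib_len = np.maximum(grid - k2, 0.0)
    e_hat = np.exp(intercept + slope * grid)
    # analytic remainder of sum_{x > x_hi} e_hat(x) * (x - k2):
    # with r = 1 - theta, sum_{x>=M} A r^x = A r^M / (1 - r) and
    # sum_{x>=M} A x r^x = A r^M (M + r/(1-r)) / (1 - r)
    r = 1.0 - theta
    A = math.exp(intercept)
    M = x_hi + 1
    rm = A * r**M / (1.0 - r)
    remainder = rm * ((M + r / (1.0 - r)) - k2) if M > k2 else 0.0
    obs_term = float((counts * contrib_len).sum())
    exp_term = float((e_hat * contrib_len).sum()) + max(remainder, 0.0)
    scale = 1.0
    frac = 0.0
    alpha_bp = 0.0
    for _ in range(DEPLETION_MAX_ITER if depletion else 1):
        alpha_bp = max(obs_term - scale * exp_term, 0.0)
        new_frac = alpha_bp / total_bp if total_bp > 0 else 0.0
        if abs(new_frac - frac) < DEPLETION_TOL:
            frac = new_frac
            break
        frac = new_frac
        scale = max(1.0 - frac, 0.0)
    return alpha_bp


def alpha_nim1(
    hist: IGSHistogram,
    fit: GeometricFit | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    depletion: bool = DEPLETION_DEFAULT,
) -> ConstraintEstimate:
    """NIM1 estimate for one stratum.

    Excess over the (depletion-rescaled) neutral expectation at lengths
    x > T contributes ``x - 2K`` constrained bases per segment, floored at
    zero.  The 95% CI is a parametric bootstrap over the regression
    parameters (intercept, slope) drawn from their fitted covariance.
    """
    if fit is None:
        fit = fit_neutral_geometric(hist)
    if fit.T < fit.fit_range[1]:
        raise ValueError("threshold T below the top of the fit range")
    rng = np.random.default_rng(rng)
    xs, cs = hist.lengths_counts()
    m = xs > fit.T
    tail_x = xs[m].astype(float)
    tail_c = cs[m].astype(float)
    total_bp = float(hist.total_aligned_bp)
    if len(tail_x) == 0:
        return ConstraintEstimate(
            0.0, 0.0, (0.0, 0.0), "NIM1", [hist.bin_label],
            {"fit": fit, "note": "empty tail"},
        )
    k2 = 2.0 * fit.K
    point = _excess_alpha(
        tail_x, tail_c, fit.log_intercept, fit.slope, k2, total_bp, depletion
    )
    draws = rng.multivariate_normal(
        [fit.log_intercept, fit.slope], fit.covariance, size=n_boot
    )
    boots = np.array(
        [
            _excess_alpha(tail_x, tail_c, b0, sl, k2, total_bp, depletion)
            for b0, sl in draws
        ]
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    ci = (min(float(lo), point), max(float(hi), point))
    return ConstraintEstimate(
        alpha_bp=point,
        alpha_fraction=point / total_bp if total_bp > 0 else 0.0,
        ci95=ci,
        method="NIM1",
        bins=[hist.bin_label],
        diagnostics={"fit": fit, "n_boot": n_boot},
    )


# ---------------------------------------------------------------------------
# NIM2: mixture likelihood


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def _mixture_pmf(theta: float, pi: float, mu: float, xmax: int) -> np.ndarray:
    """P(X = x) for x = 1..xmax under the two-component IGS mixture."""
    x0 = np.arange(xmax, dtype=float)  # 0-based
    log1mt = math.log1p(-theta)
    g = theta * np.exp(log1mt * x0)  # geometric on 1.. : index x-1
    q = 1.0 / mu
    core = q * np.exp(math.log1p(-q) * x0)  # core length c at index c-1
    ov = theta * np.exp(log1mt * x0)  # overhang o >= 0 at index o
    h = signal.fftconvolve(core, ov)[:xmax]
    h = signal.fftconvolve(h, ov)[:xmax]
    h = np.clip(h, 0.0, None)
    return (1.0 - pi) * g + pi * h


def alpha_nim2(
    hist: IGSHistogram,
    init: tuple[float, float, float] | None = None,
    ci: bool = True,
    ci_method: str = "profile",
) -> ConstraintEstimate:
    """NIM2 likelihood estimate for one stratum.

    An IGS is neutral-geometric(theta) with probability 1 - pi, or, with
    probability pi, the sum of a geometric constrained core (mean mu_c) and
    two independent neutral overhangs (geometric, same theta).  (theta, pi,
    mu_c) maximise the multinomial likelihood of the internal-IGS histogram;
    alpha_bp = pi * N * mu_c.  The 95% CI comes from the profile likelihood
    of psi = pi * mu_c (or a Wald approximation with ``ci_method='wald'``).
    """
    xs, cs = hist.lengths_counts()
    if len(xs) < 10:
        raise ValueError(f"bin {hist.bin_label}: insufficient support for NIM2")
    n_igs = float(cs.sum())
    xmax = int(xs.max())
    idx = xs - 1
    csf = cs.astype(float)

    def nll(v: np.ndarray) -> float:
        theta = _expit(float(np.clip(v[0], -12, 12)))
        pi = _expit(float(np.clip(v[1], -16, 12)))
        mu = 1.0 + math.exp(float(np.clip(v[2], -10, 12)))
        p = _mixture_pmf(theta, pi, mu, xmax)[idx]
        if np.any(p <= 0):
            return 1e12
        return -float((csf * np.log(p)).sum())

    if init is None:
        try:
            theta0 = fit_neutral_geometric(hist).theta
        except ValueError:
            theta0 = 1.0 / max(float((xs * cs).sum() / n_igs), 1.5)
        init = (theta0, 0.01, 200.0)
    v0 = np.array([_logit(init[0]), _logit(init[1]), math.log(max(init[2] - 1, 0.5))])
    res = optimize.minimize(
        nll, v0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-7},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"NIM2 optimiser failed: {res.message}")
    theta = _expit(float(res.x[0]))
    pi = _expit(float(res.x[1]))
    mu = 1.0 + math.exp(float(res.x[2]))
    psi_hat = pi * mu
    alpha_bp = psi_hat * n_igs
    total_bp = float(hist.total_aligned_bp)
    nll_hat = float(res.fun)

    ci95 = (alpha_bp, alpha_bp)
    if ci and ci_method == "profile":
        lo, hi = _profile_psi_ci(nll, res.x, psi_hat, nll_hat)
        ci95 = (lo * n_igs, hi * n_igs)
    elif ci and ci_method == "wald":
        se = _wald_psi_se(nll, res.x, theta, pi, mu)
        ci95 = (max(alpha_bp - Z95 * se * n_igs, 0.0), alpha_bp + Z95 * se * n_igs)
    ci95 = (min(ci95[0], alpha_bp), max(ci95[1], alpha_bp))
    return ConstraintEstimate(
        alpha_bp=alpha_bp,
        alpha_fraction=alpha_bp / total_bp if total_bp > 0 else 0.0,
        ci95=ci95,
        method="NIM2",
        bins=[hist.bin_label],
        diagnostics={
            "theta": theta, "pi": pi, "mu_c": mu, "n_igs": n_igs,
            "loglike": -nll_hat, "converged": bool(res.success),
        },
    )


def _profile_nll_at_psi(nll3, psi: float, v_hat: np.ndarray) -> float:
    """Minimise the NIM2 negative log-likelihood at fixed psi = pi * mu_c."""
    if psi <= 0:
        # pi -> 0 boundary: neutral-only model; mu unidentified
        def nll0(u):
            return nll3(np.array([u[0], -30.0, 0.0]))
        r = optimize.minimize_scalar(lambda t: nll0([t]), bracket=(-6, -2))
        return float(r.fun)

    def nll2(u: np.ndarray) -> float:
        mu = 1.0 + math.exp(float(np.clip(u[1], -10, 12)))
        pi = psi / mu
        if pi >= 1.0:
            return 1e12
        return nll3(np.array([u[0], _logit(max(pi, 1e-300)), u[1]]))

    r = optimize.minimize(
        nll2, v_hat[[0, 2]], method="Nelder-Mead",
        options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-6},
    )
    return float(r.fun)


def _profile_psi_ci(
    nll3, v_hat: np.ndarray, psi_hat: float, nll_hat: float, crit: float = 1.9207
) -> tuple[float, float]:
    def deficit(psi: float) -> float:
        return _profile_nll_at_psi(nll3, psi, v_hat) - nll_hat - crit

    # lower bound
    if psi_hat <= 1e-9 or deficit(0.0) <= 0:
        lo = 0.0
    else:
        lo = optimize.brentq(deficit, 0.0, psi_hat, xtol=max(psi_hat * 1e-3, 1e-6))
    # upper bound
    hi = max(psi_hat, 1e-3)
    step = max(psi_hat, 1.0)
    for _ in range(40):
        if deficit(hi + step) > 0:
            hi = optimize.brentq(
                deficit, hi, hi + step, xtol=max(psi_hat * 1e-3, 1e-6)
            )
            break
        hi += step
        step *= 1.6
    return lo, hi


def _wald_psi_se(nll3, v_hat: np.ndarray, theta: float, pi: float, mu: float) -> float:
    """Delta-method SE of psi = pi*mu_c from a finite-difference Hessian in
    the transformed coordinates."""
    h = 1e-4
    k = len(v_hat)
    H = np.zeros((k, k))
    f0 = nll3(v_hat)
    for i in range(k):
        for j in range(i, k):
            vpp = v_hat.copy(); vpp[i] += h; vpp[j] += h
            vpm = v_hat.copy(); vpm[i] += h; vpm[j] -= h
            vmp = v_hat.copy(); vmp[i] -= h; vmp[j] += h
            vmm = v_hat.copy(); vmm[i] -= h; vmm[j] -= h
            H[i, j] = H[j, i] = (nll3(vpp) - nll3(vpm) - nll3(vmp) + nll3(vmm)) / (
                4 * h * h
            )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float("nan")
    # psi = expit(v1) * (1 + exp(v2)); gradient in transformed coords
    g = np.array([0.0, pi * (1 - pi) * mu, pi * (mu - 1.0)])
    var = float(g @ cov @ g)
    _ = f0
    return math.sqrt(var) if var > 0 else float("nan")


# ---------------------------------------------------------------------------
# aggregation


def alpha_genome(
    histograms: Sequence[IGSHistogram],
    method: str = "NIM1",
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> ConstraintEstimate:
    """Aggregate per-stratum estimates: alpha_bp sums; the CI combines
    per-bin variances assuming independence across strata."""
    rng = np.random.default_rng(rng)
    ci_method = kwargs.pop("ci_method", "wald")
    per_bin: list[ConstraintEstimate] = []
    skipped: list[str] = []
    total_bp = 0.0
    for hist in histograms:
        total_bp += hist.total_aligned_bp
        try:
            if method.upper() == "NIM1":
                est = alpha_nim1(hist, n_boot=n_boot, rng=rng, **kwargs)
            elif method.upper() == "NIM2":
                est = alpha_nim2(hist, ci_method=ci_method, **kwargs)
            else:
                raise ValueError(f"unknown method {method!r}")
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"bin {hist.bin_label} skipped: {exc}")
            skipped.append(hist.bin_label)
            continue
        per_bin.append(est)
    if not per_bin:
        raise ValueError("no stratum could be fitted")
    alpha_bp = sum(e.alpha_bp for e in per_bin)
    var = sum(e.sigma**2 for e in per_bin)
    half = Z95 * math.sqrt(var)
    return ConstraintEstimate(
        alpha_bp=alpha_bp,
        alpha_fraction=alpha_bp / total_bp if total_bp > 0 else 0.0,
        ci95=(max(alpha_bp - half, 0.0), alpha_bp + half),
        method=method.upper(),
        bins=[e.bins[0] for e in per_bin],
        diagnostics={"per_bin": per_bin, "skipped": skipped, "total_aligned_bp": total_bp},
    )


def alpha_subset(
    blocks: Sequence[AlignmentBlock],
    subset: dict[str, np.ndarray],
    buffer: int = 0,
    method: str = "NIM1",
    n_bins: int = 20,
    **kwargs,
) -> ConstraintEstimate:
    """Constraint within an annotation subset S, by difference: alpha(S) =
    alpha(G) - alpha(G\\S), with the CI combined in quadrature."""
    if not subset or all(len(v) == 0 for v in subset.values()):
        return ConstraintEstimate(0.0, 0.0, (0.0, 0.0), f"{method}-subset", [],
                                  {"note": "empty subset"})
    recs_g = _records_from_blocks(blocks)
    est_g = alpha_genome(assign_gc_bins(recs_g, n_bins), method, **kwargs)
    blocks_gs = excise_intervals(blocks, subset, buffer=buffer)
    recs_gs = _records_from_blocks(blocks_gs)
    bp_g = sum(r.x for r in recs_g)
    bp_gs = sum(r.x for r in recs_gs)
    if bp_gs < 0.01 * bp_g:
        raise ValueError("subset covers >= 99% of aligned bases; G\\S unusable")
    est_gs = alpha_genome(assign_gc_bins(recs_gs, n_bins), method, **kwargs)
    diff = est_g.alpha_bp - est_gs.alpha_bp
    half = Z95 * math.sqrt(est_g.sigma**2 + est_gs.sigma**2)
    denom = bp_g - bp_gs
    return ConstraintEstimate(
        alpha_bp=diff,
        alpha_fraction=diff / denom if denom > 0 else 0.0,
        ci95=(diff - half, diff + half),
        method=f"{method}-subset",
        bins=est_g.bins,
        diagnostics={"G": est_g, "G_minus_S": est_gs, "subset_aligned_bp": denom},
    )


def _records_from_blocks(blocks: Iterable[AlignmentBlock]) -> list[IGSRecord]:
    records: list[IGSRecord] = []
    for b in blocks:
        records.extend(extract_igs(b))
    return records


# ---------------------------------------------------------------------------
# model / results front end


class NeutralIndelModel:
    """Neutral indel model of an alignment's IGS length distribution.

    Construct from stratified histograms, IGS records, or alignment blocks;
    ``fit`` returns a :class:`NIMResults` carrying the aggregate estimate,
    per-stratum estimates, and diagnostics.

    Examples
    --------
    >>> model = NeutralIndelModel.from_blocks(blocks, n_bins=20)
    >>> res = model.fit(method="nim1", seed=1)
    >>> res.alpha_fraction, res.conf_int()
    """

    def __init__(self, histograms: Sequence[IGSHistogram]):
        if not histograms:
            raise ValueError("no histograms")
        self.histograms = list(histograms)

    @classmethod
    def from_records(cls, records: Sequence[IGSRecord], n_bins: int = 20):
        return cls(assign_gc_bins(records, n_bins))

    @classmethod
    def from_blocks(cls, blocks: Iterable[AlignmentBlock], n_bins: int = 20):
        return cls.from_records(_records_from_blocks(blocks), n_bins)

    def fit(
        self,
        method: str = "nim1",
        n_boot: int = 1000,
        seed: np.random.Generator | int | None = None,
        **kwargs,
    ) -> "NIMResults":
        est = alpha_genome(self.histograms, method=method, n_boot=n_boot, rng=seed, **kwargs)
        return NIMResults(self, est)


class NIMResults:
    """Fitted constraint estimate with per-stratum detail."""

    def __init__(self, model: NeutralIndelModel, estimate: ConstraintEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def alpha_bp(self) -> float:
        return self.estimate.alpha_bp

    @property
    def alpha_fraction(self) -> float:
        return self.estimate.alpha_fraction

    @property
    def per_bin(self) -> list[ConstraintEstimate]:
        return self.estimate.diagnostics.get("per_bin", [])

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci95

    def summary(self) -> str:
        e = self.estimate
        lines = [
            f"Neutral indel model ({e.method}) constraint estimate",
            "=" * 52,
            f"alpha_selIndel      {e.alpha_bp:14.1f} bp"
            f"  ({e.alpha_fraction * 100:.3f}% of aligned)",
            f"95% CI              [{e.ci95[0]:.1f}, {e.ci95[1]:.1f}] bp",
            f"strata              {len(e.bins)} fitted"
            + (f", {len(e.diagnostics.get('skipped', []))} skipped" if e.diagnostics.get("skipped") else ""),
            "-" * 52,
            f"{'bin':>5} {'alpha_bp':>12} {'theta':>9} {'K':>8} {'T':>6}",
        ]
        for b in self.per_bin:
            fit = b.diagnostics.get("fit")
            if fit is not None:
                lines.append(
                    f"{b.bins[0]:>5} {b.alpha_bp:12.1f} {fit.theta:9.5f} "
                    f"{fit.K:8.1f} {fit.T:6d}"
                )
            else:
                d = b.diagnostics
                lines.append(
                    f"{b.bins[0]:>5} {b.alpha_bp:12.1f} {d.get('theta', float('nan')):9.5f} "
                    f"{'':8} {'':6}"
                )
        return "\n".join(lines)
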