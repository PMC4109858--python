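"""Time-homogeneous model of functional-sequence turnover.

For a class of functional elements, assume the total constrained amount
``a`` and the per-nucleotide turnover rate ``b`` (events per neutral
substitution) are constant in time.  The amount still mutually constrained
between two genomes at divergence ``d`` (substitutions per neutral site,
summed over both branches) then decays as

    amount(d) = a * exp(-b * d)

The model is fitted by weighted linear regression of ln(amount) on d
(slope = -b, intercept = ln a), under independent normal errors.  The
turnover half-life is d_half = ln(2)/b, converted to years with a per-year
substitution rate (default 2.2e-9/site/yr, appropriate to the human
lineage; rodent lineages run faster and the rate is overridable).
Observation weights are inverse variances of the amount on the natural
scale (by default derived from each observation's 95% CI), moved to the log
scale by the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SUBSTITUTION_RATE_PER_YEAR",
    "TurnoverObservation",
    "TurnoverModel",
    "TurnoverResults",
    "fit_turnover",
    "half_life",
    "divergence_to_years",
    "retained_fraction",
    "extrapolate_present",
    "compare_rates",
    "proportion_of",
    "read_observations_csv",
]

#: neutral substitution rate per site per year (human lineage)
SUBSTITUTION_RATE_PER_YEAR = 2.2e-9

Z95 = 1.959963984540054


@dataclass
class TurnoverObservation:
    """One (divergence, constrained amount) point.

    ``weight`` is the inverse variance of ``amount`` on the natural scale;
    when omitted it is derived from ``ci`` as (1.96 / halfwidth)^2, or set
    to None (unit log-scale weight) if no CI is available.
    """

    label: str
    d: float
    amount: float
    weight: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.d <= 0 or self.amount <= 0:
            raise ValueError("d and amount must be positive")
        if self.weight is None and self.ci is not None:
            half = (self.ci[1] - self.ci[0]) / 2.0
            if half > 0:
                self.weight = (Z95 / half) ** 2

    @property
    def log_weight(self) -> float:
        """Inverse variance of ln(amount) (delta method)."""
        if self.weight is None:
            return 1.0
        return self.weight * self.amount**2


def _design(obs: Sequence[TurnoverObservation]):
    d = np.array([o.d for o in obs], dtype=float)
    y = np.log([o.amount for o in obs])
    w = np.array([o.log_weight for o in obs], dtype=float)
    return d, y, w


class TurnoverModel:
    """Exponential-decay turnover model for one element class."""

    def __init__(self, observations: Sequence[TurnoverObservation], label: str = ""):
        if len(observations) < 3:
            raise ValueError("need >= 3 observations")
        if len({o.d for o in observations}) < 2:
            raise ValueError("all divergences identical; b unidentifiable")
        self.observations = list(observations)
        self.label = label or (observations[0].label if observations else "")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = ""):
        obs = []
        for _, row in df.iterrows():
            ci = None
            if "ci_low" in row and "ci_high" in row and np.isfinite(row.get("ci_low", np.nan)):
                ci = (float(row["ci_low"]), float(row["ci_high"]))
            obs.append(
                TurnoverObservation(
                    label=str(row.get("label", label)), d=float(row["d"]),
                    amount=float(row["amount"]), ci=ci,
                    weight=float(row["weight"]) if "weight" in row and np.isfinite(row.get("weight", np.nan)) else None,
                )
            )
        return cls(obs, label=label)

    def fit(self, r: float = SUBSTITUTION_RATE_PER_YEAR) -> "TurnoverResults":
        d, y, w = _design(self.observations)
        X = sm.add_constant(d)
        res = sm.WLS(y, X, weights=w).fit()
        intercept, slope = res.params
        ci = res.conf_int(alpha=0.05)
        b = -slope
        if abs(b) < 1e-12:  # numerically flat decay
            b = 0.0
        floored = False
        if b < 0:
            warnings.warn(f"{self.label or 'turnover fit'}: positive slope; b floored at 0")
            b = 0.0
            floored = True
        ci_b = (max(-ci[1][1], 0.0), max(-ci[1][0], 0.0))
        ci_a = (math.exp(ci[0][0]), math.exp(ci[0][1]))
        return TurnoverResults(
            model=self,
            a=math.exp(intercept),
            b=b,
            ci_a=ci_a,
            ci_b=ci_b,
            covariance=np.asarray(res.cov_params()),
            r=r,
            b_floored=floored,
            wls_results=res,
        )


@dataclass
class TurnoverResults:
    """Fitted turnover parameters with conversions to half-lives and years."""

    model: TurnoverModel
    a: float
    b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    covariance: np.ndarray
    r: float = SUBSTITUTION_RATE_PER_YEAR
    b_floored: bool = False
    wls_results: object = None

    @property
    def d_half(self) -> float:
        return half_life(self.b)

    @property
    def ci_d_half(self) -> tuple[float, float]:
        # monotone transform of the b interval; a <=0.01 rounding mismatch
        # with intervals derived by other routes is expected
        return (half_life(self.ci_b[1]), half_life(self.ci_b[0]))

    def half_life_years(self, as_ancestor_age: bool = False) -> float:
        return divergence_to_years(self.d_half, self.r, as_ancestor_age)

    def retained_fraction(self, d: float) -> float:
        return retained_fraction(self.b, d)

    def amount_at(self, d: float) -> float:
        return self.a * retained_fraction(self.b, d)

    def summary(self) -> str:
        hy = self.half_life_years() / 1e6 if self.b > 0 else float("inf")
        lines = [
            f"Turnover model fit{' (' + self.model.label + ')' if self.model.label else ''}",
            "=" * 52,
            f"n observations        {len(self.model.observations)}",
            f"a (present amount)    {self.a:.4g}  [{self.ci_a[0]:.4g}, {self.ci_a[1]:.4g}]",
            f"b (events/subst)      {self.b:.4g}  [{self.ci_b[0]:.4g}, {self.ci_b[1]:.4g}]"
            + ("  (floored at 0)" if self.b_floored else ""),
            f"d_half (divergence)   {self.d_half:.4g}"
            f"  [{self.ci_d_half[0]:.4g}, {self.ci_d_half[1]:.4g}]",
            f"half-life (My)        {hy:.4g}   at r = {self.r:.3g}/site/yr",
        ]
        return "\n".join(lines)


def fit_turnover(
    obs: Sequence[TurnoverObservation], r: float = SUBSTITUTION_RATE_PER_YEAR
) -> TurnoverResults:
    """Fit a * exp(-b d) to observations by weighted log-linear regression."""
    return TurnoverModel(obs).fit(r=r)


def half_life(b: float) -> float:
    """Turnover half-life in divergence units: ln(2)/b (inf when b = 0)."""
    if b < 0:
        raise ValueError("b must be >= 0")
    if b == 0:
        warnings.warn("b = 0: no turnover, half-life infinite")
        return float("inf")
    return math.log(2.0) / b


def divergence_to_years(
    d: float, r: float = SUBSTITUTION_RATE_PER_YEAR, as_ancestor_age: bool = False
) -> float:
    """Convert a divergence (substitutions/site, both branches) to years.

    With ``as_ancestor_age`` the result is halved: the age of the most
    recent common ancestor, since d accumulates along two branches."""
    if d < 0 or r <= 0:
        raise ValueError("need d >= 0 and r > 0")
    years = d / r
    return years / 2.0 if as_ancestor_age else years


def retained_fraction(b: float, d: float) -> float:
    """Fraction of presently functional sequence still mutually constrained
    at divergence d: exp(-b d)."""
    if d < 0:
        raise ValueError("d must be >= 0")
    return math.exp(-b * d)


def extrapolate_present(fits: Sequence[TurnoverResults]) -> dict:
    """Total present-day constrained amount across mutually exclusive
    annotation classes: sum of per-class a, CI by quadrature under the
    stated independence assumption."""
    labels = [f.model.label for f in fits]
    if len(set(labels)) < len(labels):
        warnings.warn("duplicate class labels; classes must be mutually exclusive")
    total = sum(f.a for f in fits)
    var = sum(((f.ci_a[1] - f.ci_a[0]) / (2 * Z95)) ** 2 for f in fits)
    half = Z95 * math.sqrt(var)
    return {
        "total_a": total,
        "ci95": (total - half, total + half),
        "classes": labels,
        "assumption": "independent class estimates (CI by quadrature)",
    }


def _wrss(d, y, w, X) -> float:
    beta, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)
    resid = y - X @ beta
    return float((w * resid**2).sum())


def compare_rates(
    obs_a: Sequence[TurnoverObservation], obs_b: Sequence[TurnoverObservation]
) -> tuple[float, float]:
    """Likelihood-ratio test of equal turnover rates between two classes.

    Fits a shared-b model (common slope, separate intercepts) against an
    independent-b model by weighted least squares.  Weights are taken as
    exact inverse variances, so the LR statistic is the drop in weighted
    RSS, referred to chi-square(1).  Returns (LR, p).
    """
    for obs in (obs_a, obs_b):
        if len(obs) < 3 or len({o.d for o in obs}) < 2:
            raise ValueError("each observation set needs >= 3 points at >= 2 divergences")
    da, ya, wa = _design(obs_a)
    db, yb, wb = _design(obs_b)
    d = np.concatenate([da, db])
    y = np.concatenate([ya, yb])
    w = np.concatenate([wa, wb])
    ind_a = np.concatenate([np.ones_like(da), np.zeros_like(db)])
    ind_b = 1.0 - ind_a
    X_shared = np.column_stack([ind_a, ind_b, d])
    X_free = np.column_stack([ind_a, ind_b, d * ind_a, d * ind_b])
    lr = _wrss(d, y, w, X_shared) - _wrss(d, y, w, X_free)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return lr, p


def proportion_of(part: float, whole: float, percent: bool = True) -> float:
    """Share of an amount within a larger amount (reported as % by default).

    Used for statements like "13.3 Mb of the 43.5 Mb constrained TFBS
    sequence (30.6%) is constrained in both species"."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    frac = part / whole
    return 100.0 * frac if percent else frac


def read_observations_csv(path: str | Path, label: str = "") -> TurnoverModel:
    """Observations CSV with columns label,d,amount[,ci_low,ci_high[,weight]]."""
    return TurnoverModel.from_dataframe(pd.read_csv(path), label=label)
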