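"""Dose--response statistics for insecticide bioassays.

Implements the classical topical-application analysis: control-mortality
(Abbott) correction, maximum-likelihood probit regression on log10 dose,
LD50 with a Fieller confidence interval, Pearson goodness of fit, and the
resistance ratio (LD50 resistant / LD50 susceptible) with a Fieller interval
between two independently fitted strains.

Model: for dose d, observed dead ~ Binomial(n, p) with
``p = Phi(alpha + beta * log10 d)`` after Abbott adjustment, where Phi is the
standard normal CDF. LD50 = 10 ** (-alpha / beta).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DoseGroup",
    "ProbitFit",
    "FiellerInterval",
    "ResistanceRatioResult",
    "abbott_correct",
    "fit_probit",
    "ld50_with_ci",
    "resistance_ratio",
    "summarize_pair",
]


@dataclass(frozen=True)
class DoseGroup:
    """Mortality observed in one dose group (dose in µg/individual)."""

    dose: float
    n: int
    dead: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.is_control:
            if self.dose != 0:
                raise ValueError("control group must have dose 0")
        elif self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not (0 <= self.dead <= self.n):
            raise ValueError(f"dead ({self.dead}) must lie in 0..n ({self.n})")

    @property
    def mortality(self) -> float:
        return self.dead / self.n


@dataclass
class ProbitFit:
    """Fitted probit dose--response model on log10 dose."""

    alpha: float
    beta: float
    cov: np.ndarray  # 2x2 covariance of (alpha, beta)
    chi2: float
    df: int
    p_value: float
    converged: bool
    n_groups: int
    n_subjects: int

    @property
    def ld50(self) -> float:
        return 10.0 ** (-self.alpha / self.beta)

    @property
    def log10_ld50(self) -> float:
        return -self.alpha / self.beta

    @property
    def se_slope(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    def log10_ld50_variance(self) -> float:
        """Delta-method variance of log10 LD50 = -alpha/beta."""
        grad = np.array([-1.0 / self.beta, self.alpha / self.beta**2])
        return float(grad @ self.cov @ grad)

    def ld50_variance(self) -> float:
        """Delta-method variance of LD50 on the dose scale."""
        return (self.ld50 * math.log(10.0)) ** 2 * self.log10_ld50_variance()


@dataclass(frozen=True)
class FiellerInterval:
    """Ratio estimate with Fieller confidence bounds.

    ``g`` is the Fieller statistic z^2 * var(denominator) / denominator^2;
    when g >= 1 the denominator is not significantly nonzero and the
    confidence set is unbounded (``valid=False``, infinite bounds).
    """

    estimate: float
    lower: float
    upper: float
    g: float
    valid: bool
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.valid and not (self.lower <= self.estimate <= self.upper):
            raise ValueError("valid Fieller interval must contain the estimate")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class ResistanceRatioResult:
    """Resistance ratio (LD50_R / LD50_S) with its 95% Fieller interval."""

    rr: float
    ci: FiellerInterval

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("resistance ratio must be positive")


def abbott_correct(
    groups: Sequence[DoseGroup], control: Optional[DoseGroup] = None
) -> np.ndarray:
    """Control-corrected mortality fractions p' = (p - c) / (1 - c), floored at 0.

    With no control row (or zero control mortality) fractions pass through
    unchanged. Control mortality of 1 is a hard error.
    """
    p = np.array([g.mortality for g in groups], dtype=float)
    if control is None:
        return p
    c = control.mortality
    if c >= 1.0:
        raise ValueError("control mortality is 1: no treatment effect is estimable")
    if c == 0.0:
        return p
    return np.maximum((p - c) / (1.0 - c), 0.0)


class SeparationError(ValueError):
    """All-dead or all-alive data: the probit model is not identifiable."""


def fit_probit(
    groups: Sequence[DoseGroup],
    control: Optional[DoseGroup] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ProbitFit:
    """Maximum-likelihood probit fit of mortality on log10 dose.

    Abbott-adjusted mortality fractions are fitted by iteratively reweighted
    least squares (Fisher scoring) with binomial weights; the covariance is
    the inverse Fisher information. The Pearson statistic
    ``chi2 = sum (dead_i - n_i p_i)^2 / (n_i p_i (1 - p_i))`` on
    ``df = n_groups - 2`` measures goodness of fit.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 dose groups (2 parameters + residual df)")
    n = np.array([g.n for g in groups], dtype=float)
    padj = abbott_correct(groups, control)
    if np.all(padj == 0.0) or np.all(padj == 1.0):
        raise SeparationError("separation: adjusted mortality is constant at 0 or 1")

    x = np.log10([g.dose for g in groups])
    X = sm.add_constant(x)
    model = sm.GLM(padj, X, family=sm.families.Binomial(sm.families.links.Probit()),
                   var_weights=n)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=max_iter, tol=tol)
            converged = bool(res.converged)
        except Exception:
            # fall back to a few heavily damped iterations before giving up
            res = model.fit(maxiter=max_iter, tol=1e-4, method="IRLS")
            converged = False

    alpha, beta = float(res.params[0]), float(res.params[1])
    cov = np.asarray(res.cov_params(), dtype=float)

    phat = stats.norm.cdf(alpha + beta * x)
    eps = 1e-12
    phat = np.clip(phat, eps, 1 - eps)
    dead_adj = padj * n
    chi2 = float(np.sum((dead_adj - n * phat) ** 2 / (n * phat * (1 - phat))))
    df = len(groups) - 2
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")

    return ProbitFit(
        alpha=alpha,
        beta=beta,
        cov=cov,
        chi2=chi2,
        df=df,
        p_value=p_value,
        converged=converged,
        n_groups=len(groups),
        n_subjects=int(n.sum()),
    )


def _fieller_quadratic(num: float, den: float, v_num: float, v_den: float,
                       cov_nd: float, z: float) -> tuple[float, float, float, bool]:
    """Solve the Fieller quadratic for the ratio num/den of jointly normal
    estimates: set of t with (num - t*den)^2 <= z^2 (v_num - 2t cov + t^2 v_den).

    Returns (lower, upper, g, valid)."""
    z2 = z * z
    g = z2 * v_den / den**2
    A = den**2 - z2 * v_den
    B = -2.0 * (num * den - z2 * cov_nd)
    C = num**2 - z2 * v_num
    if A <= 0:
        return -math.inf, math.inf, g, False
    disc = B * B - 4 * A * C
    if disc < 0:
        # numerically degenerate (interval collapses to the point estimate)
        t = num / den
        return t, t, g, True
    root = math.sqrt(disc)
    lo = (-B - root) / (2 * A)
    hi = (-B + root) / (2 * A)
    return min(lo, hi), max(lo, hi), g, True


def ld50_with_ci(fit: ProbitFit, level: float = 0.95) -> FiellerInterval:
    """Fieller confidence interval for the LD50 of one fitted strain.

    Fieller is applied to m = -alpha/beta on the log10-dose scale using the
    full (alpha, beta) covariance, then mapped to the dose scale as 10**m.
    """
    if not fit.converged:
        raise ValueError("cannot form a confidence interval from a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    v_a, v_b = fit.cov[0, 0], fit.cov[1, 1]
    c_ab = fit.cov[0, 1]
    # m solves alpha + beta*m = 0, so apply Fieller to (-alpha)/beta
    lo, hi, g, valid = _fieller_quadratic(
        num=-fit.alpha, den=fit.beta, v_num=v_a, v_den=v_b, cov_nd=-c_ab, z=z
    )
    if not valid:
        return FiellerInterval(
            estimate=fit.ld50, lower=0.0, upper=math.inf, g=g, valid=False, level=level
        )
    return FiellerInterval(
        estimate=fit.ld50, lower=10.0**lo, upper=10.0**hi, g=g, valid=True, level=level
    )


def resistance_ratio(
    fit_resistant: ProbitFit,
    fit_susceptible: ProbitFit,
    level: float = 0.95,
) -> ResistanceRatioResult:
    """Resistance ratio LD50_R / LD50_S with a Fieller confidence interval.

    Fieller is applied directly to the ratio of LD50 estimates on the dose
    scale with delta-method variances; the two fits are independent (zero
    cross-covariance). The interval is valid iff the susceptible LD50 is
    significantly nonzero at the chosen level.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    L_r, L_s = fit_resistant.ld50, fit_susceptible.ld50
    v_r, v_s = fit_resistant.ld50_variance(), fit_susceptible.ld50_variance()
    lo, hi, g, valid = _fieller_quadratic(
        num=L_r, den=L_s, v_num=v_r, v_den=v_s, cov_nd=0.0, z=z
    )
    rr = L_r / L_s
    if not valid:
        ci = FiellerInterval(estimate=rr, lower=0.0, upper=math.inf, g=g,
                             valid=False, level=level)
    else:
        ci = FiellerInterval(estimate=rr, lower=max(lo, 0.0), upper=hi, g=g,
                             valid=True, level=level)
    return ResistanceRatioResult(rr=rr, ci=ci)


def summarize_pair(
    fit_susceptible: ProbitFit,
    fit_resistant: ProbitFit,
    level: float = 0.95,
) -> dict:
    """Flat summary of two strain fits in the layout of a bioassay results
    table: n, slope ± SE, LD50 and CI, df, p, RR and CI."""
    rows = {}
    for label, fit in (("susceptible", fit_susceptible), ("resistant", fit_resistant)):
        ci = ld50_with_ci(fit, level)
        rows[label] = {
            "n": fit.n_subjects,
            "slope": fit.beta,
            "slope_se": fit.se_slope,
            "ld50": fit.ld50,
            "ld50_ci_lower": ci.lower,
            "ld50_ci_upper": ci.upper,
            "df": fit.df,
            "chi2": fit.chi2,
            "p_value": fit.p_value,
        }
    rr = resistance_ratio(fit_resistant, fit_susceptible, level)
    rows["resistance_ratio"] = {
        "rr": rr.rr,
        "rr_ci_lower": rr.ci.lower,
        "rr_ci_upper": rr.ci.upper,
        "valid": rr.ci.valid,
    }
    return rows
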