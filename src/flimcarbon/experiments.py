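"""End-to-end solution analyses and group statistics.

Three workflows sit here:

* single-enzyme titrations — whole-solution decays fitted with the free
  NADH lifetime fixed at 0.45 ns, tabulating the bound fraction alpha_2 and
  bound lifetime tau_2 against enzyme concentration;
* two-enzyme mixture unmixing — three-component fits with all lifetimes
  fixed (0.45 / 1.2 / 1.6 ns for free NADH, NADH-MDH and NADH-LDH), the
  measured LDH share of the bound signal regressed through the origin on
  the true concentration fraction (slope, uncentered R^2, 95% CI, p);
* the study's two significance tests — Welch's unequal-variance t-test and
  the ratio-paired t-test (one-sample t on log ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decay_model import IRF, DecayHistogram
from .fitting import FitConfig, FitResult, fit_decay

__all__ = [
    "FREE_NADH_TAU_NS",
    "MDH_BOUND_TAU_NS",
    "LDH_BOUND_TAU_NS",
    "UNMIX_LIFETIMES_NS",
    "OriginRegression",
    "GroupComparison",
    "regression_through_origin",
    "titration_analysis",
    "unmix_mixtures",
    "welch_t_test",
    "ratio_paired_t_test",
]

#: Lifetime of free NADH in solution (ns), fixed in solution fits.
FREE_NADH_TAU_NS = 0.45
#: Lifetime of NADH bound to malate dehydrogenase (ns).
MDH_BOUND_TAU_NS = 1.2
#: Lifetime of NADH bound to lactate dehydrogenase (ns).
LDH_BOUND_TAU_NS = 1.6
#: Fixed lifetime triple for three-component mixture unmixing.
UNMIX_LIFETIMES_NS = (FREE_NADH_TAU_NS, MDH_BOUND_TAU_NS, LDH_BOUND_TAU_NS)


@dataclass
class OriginRegression:
    """Least-squares line through the origin, y = m*x.

    ``r_squared`` is the uncentered coefficient of determination
    1 - SS_res / sum(y^2), the convention used when the intercept is forced
    to zero (a centered R^2 would differ).  ``p_value`` tests m = 0;
    ``p_value_correlation`` is the ordinary Pearson-correlation p for
    reference.
    """

    slope: float
    slope_se: float
    r_squared: float
    ci95_halfwidth: float
    p_value: float
    p_value_correlation: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float)

    def ci95_band(self, x) -> np.ndarray:
        """Half-width of the 95% confidence band for the fitted line at x."""
        return self.ci95_halfwidth * np.abs(np.asarray(x, dtype=float))


@dataclass
class GroupComparison:
    """Result of a two-group significance test at the 0.05 level."""

    test: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.p_value < 0.05)


def regression_through_origin(x, y) -> OriginRegression:
    """Fit y = m*x by least squares with the intercept forced to zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct x values for regression")
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(y**2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    dof = len(x) - 1  # one parameter estimated
    sigma2 = ss_res / dof if dof > 0 else np.nan
    slope_se = float(np.sqrt(sigma2 / sxx))
    t_crit = stats.t.ppf(0.975, dof)
    if slope_se > 0:
        t_stat = slope / slope_se
        p_value = float(2 * stats.t.sf(abs(t_stat), dof))
    else:
        p_value = 0.0 if slope != 0 else 1.0
    if len(x) > 2 and np.std(x) > 0 and np.std(y) > 0:
        _, p_corr = stats.pearsonr(x, y)
    else:
        p_corr = np.nan
    return OriginRegression(
        slope=slope,
        slope_se=slope_se,
        r_squared=r_squared,
        ci95_halfwidth=float(t_crit * slope_se),
        p_value=p_value,
        p_value_correlation=float(p_corr),
        n=len(x),
    )


def titration_analysis(
    decays: list[tuple[float, DecayHistogram]],
    irf: IRF,
    fixed_tau1: float = FREE_NADH_TAU_NS,
) -> pd.DataFrame:
    """Fit whole-solution decays across an enzyme titration.

    Each decay is labeled with its enzyme concentration (uM) and fitted to
    the two-component model with the free-NADH lifetime fixed.  Returns a
    table of (enzyme_um, alpha2, tau2_ns, reduced_chi_squared, converged);
    fit failures are recorded per row rather than raised.
    """
    config = FitConfig(n_components=2, fixed_taus=(fixed_tau1, None))
    rows = []
    for conc, hist in decays:
        row = {"enzyme_um": conc}
        try:
            res = fit_decay(hist, irf, config)
            row.update(
                alpha2=res.model.components[1].alpha,
                tau2_ns=res.model.components[1].tau,
                reduced_chi_squared=res.reduced_chi_squared,
                converged=res.converged,
            )
        except ValueError as exc:
            row.update(
                alpha2=np.nan, tau2_ns=np.nan, reduced_chi_squared=np.nan,
                converged=False, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("enzyme_um").reset_index(drop=True)


def unmix_mixtures(
    decays: list[tuple[float, DecayHistogram]],
    irf: IRF,
    fixed_lifetimes: tuple[float, float, float] = UNMIX_LIFETIMES_NS,
) -> tuple[pd.DataFrame, OriginRegression]:
    """Unmix NADH bound to two enzymes by fixed-lifetime three-component fits.

    Each decay is labeled with its true [LDH]/([LDH]+[MDH]) fraction.  The
    fit holds all three lifetimes fixed (free, MDH-bound, LDH-bound) so only
    the amplitude fractions are estimated; the measured LDH share
    alpha_LDH/(alpha_LDH + alpha_MDH) is then regressed through the origin
    on the true fraction.

    Returns the per-decay table and the origin regression (slope m,
    uncentered R^2, 95% CI, p-values).
    """
    config = FitConfig(n_components=3, fixed_taus=tuple(fixed_lifetimes))
    rows = []
    for true_fraction, hist in decays:
        res = fit_decay(hist, irf, config)
        a_free, a_mdh, a_ldh = (c.alpha for c in res.model.components)
        bound = a_mdh + a_ldh
        rows.append(
            {
                "true_ldh_fraction": true_fraction,
                "alpha_free": a_free,
                "alpha_mdh": a_mdh,
                "alpha_ldh": a_ldh,
                "measured_ldh_fraction": a_ldh / bound if bound > 0 else np.nan,
                "reduced_chi_squared": res.reduced_chi_squared,
            }
        )
    table = pd.DataFrame(rows)
    ok = table["measured_ldh_fraction"].notna()
    reg = regression_through_origin(
        table.loc[ok, "true_ldh_fraction"], table.loc[ok, "measured_ldh_fraction"]
    )
    return table, reg


def welch_t_test(a, b) -> GroupComparison:
    """Unpaired t-test with Welch's correction for unequal variances.

    Two-sided, Satterthwaite degrees of freedom.  Two identical
    zero-variance groups return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        dof = len(a) + len(b) - 2.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        sea, seb = va / len(a), vb / len(b)
        dof = (sea + seb) ** 2 / (
            sea**2 / (len(a) - 1) + seb**2 / (len(b) - 1)
        )
    return GroupComparison(
        test="welch_t",
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        t_statistic=float(t_stat), degrees_of_freedom=float(dof),
        p_value=float(p),
    )


def ratio_paired_t_test(before, after) -> GroupComparison:
    """Ratio-paired t-test: one-sample t on log(after/before) against zero.

    Appropriate when paired measurements differ by a multiplicative factor
    (e.g. dish-level redox ratios before/after treatment).  All values must
    be positive.  A constant nonunit ratio (zero variance of the logs) gives
    p = 0 by convention; a constant ratio of exactly 1 gives p = 1.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired groups must have equal length")
    if len(before) < 2:
        raise ValueError("need >= 2 pairs")
    if np.any(before <= 0) or np.any(after <= 0):
        raise ValueError("ratio-paired test requires positive values")
    logs = np.log(after / before)
    dof = len(logs) - 1.0
    if logs.var(ddof=1) == 0:
        t_stat, p = (0.0, 1.0) if logs.mean() == 0 else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_1samp(logs, 0.0)
    return GroupComparison(
        test="ratio_paired_t",
        mean_a=float(before.mean()), mean_b=float(after.mean()),
        sd_a=float(before.std(ddof=1)), sd_b=float(after.std(ddof=1)),
        t_statistic=float(t_stat), degrees_of_freedom=dof,
        p_value=float(p),
    )
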