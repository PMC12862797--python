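"""Statistical layer: ANOVA across salt concentrations, per-residue slopes,
moving averages, retardation factors and concentration trends.

Significance follows a one-way ANOVA, p = 1 - F_CDF(F_obs; df_between,
df_within), with df_between = k - 1 groups and df_within = N - k (the
total-minus-groups count; reported in JSON under the key ``df_total`` for
continuity with the source protocol's naming). Per-residue diffusion
slopes are ordinary least squares of D on concentration over all
replicate points, with the slope t-test as the primary p-value and a
companion concentration-group ANOVA p alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import DiffusionResult
from .trajectory import domain_of_residue


@dataclass
class AnovaResult:
    F_obs: float
    df_between: int
    df_within: int       # N - k; the source protocol calls this df_total
    p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"F_obs": self.F_obs, "df_between": self.df_between,
                "df_total": self.df_within, "p": self.p,
                "degenerate": self.degenerate}


@dataclass
class SlopeResult:
    residue_index: int   # 1-based
    slope: float         # m² s⁻¹ M⁻¹
    p_value: float       # slope t-test
    anova_p: float       # companion concentration-group ANOVA
    stderr: float
    domain: str


@dataclass
class TrendSummary:
    retardation_factor: float
    retardation_sd: float
    tau_slope: Optional[float] = None
    tau_slope_p: Optional[float] = None
    moving_average: Optional[np.ndarray] = None


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over replicate groups.

    F is MS_between / MS_within; p = 1 - F_CDF(F; k-1, N-k). Zero
    within-group variance with unequal means yields p = 0 with the
    degenerate flag set.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need ≥2 groups with ≥2 values each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df_between, df_within = k - 1, n_total - k
    means = np.array([g.mean() for g in groups])
    within_ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if within_ss == 0.0:
        if np.allclose(means, means[0]):
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(np.inf, df_between, df_within, 0.0,
                           degenerate=True)
    F, p = sps.f_oneway(*groups)
    if np.isnan(F):  # identical values everywhere
        return AnovaResult(0.0, df_between, df_within, 1.0)
    return AnovaResult(float(F), df_between, df_within, float(p))


def residue_slope(d_table: pd.DataFrame,
                  bh_correction: bool = False) -> pd.DataFrame:
    """Per-residue OLS slope of diffusion coefficient on concentration.

    ``d_table`` is long-format with columns ``residue`` (1-based),
    ``concentration`` (M) and ``value`` (D, m²/s); replicates are simply
    extra rows. Returns one row per residue with the slope, its t-test
    p-value, the companion concentration-group ANOVA p, and the domain
    label. ``bh_correction`` adds a Benjamini–Hochberg adjusted column.
    """
    required = {"residue", "concentration", "value"}
    if not required.issubset(d_table.columns):
        raise ValueError(f"d_table needs columns {sorted(required)}")
    rows = []
    for res, sub in d_table.groupby("residue"):
        concs = np.unique(sub["concentration"])
        if len(concs) < 2:
            raise ValueError(
                f"residue {res}: need ≥2 distinct concentrations")
        fit = sps.linregress(sub["concentration"], sub["value"])
        groups = [sub.loc[sub["concentration"] == c, "value"].to_numpy()
                  for c in concs]
        try:
            anova_p = one_way_anova(groups).p
        except ValueError:
            anova_p = np.nan
        try:
            domain = domain_of_residue(int(res))
        except ValueError:
            domain = "unknown"
        rows.append(SlopeResult(int(res), float(fit.slope),
                                float(fit.pvalue), float(anova_p),
                                float(fit.stderr), domain))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def moving_average(values, period: int):
    """Trailing moving average.

    Returns (smoothed, partial): position i is the mean of the trailing
    window ending at i; the first period-1 positions are partial-window
    means and are flagged True in ``partial``.
    """
    values = np.asarray(values, float)
    if period < 1 or period > len(values):
        raise ValueError("period must be in [1, len(values)]")
    out = np.empty(len(values))
    partial = np.zeros(len(values), bool)
    for i in range(len(values)):
        lo = max(0, i - period + 1)
        out[i] = values[lo:i + 1].mean()
        partial[i] = (i + 1 - lo) < period
    return out, partial


def retardation_factor(bulk: DiffusionResult | tuple,
                       shell: DiffusionResult | tuple) -> tuple[float, float]:
    """Bulk/shell diffusion ratio with first-order error propagation.

    Accepts DiffusionResult objects or plain (mean, sd) pairs.
    """
    b_mean, b_sd = ((bulk.mean, bulk.sd)
                    if isinstance(bulk, DiffusionResult) else bulk)
    s_mean, s_sd = ((shell.mean, shell.sd)
                    if isinstance(shell, DiffusionResult) else shell)
    if s_mean <= 0:
        raise ValueError("shell diffusion mean must be positive")
    ratio = b_mean / s_mean
    sd = abs(ratio) * np.sqrt((b_sd / b_mean) ** 2 + (s_sd / s_mean) ** 2) \
        if b_mean != 0 else np.nan
    return float(ratio), float(sd)


def concentration_trend(levels, means, sds=None) -> tuple[float, float]:
    """Slope of a scalar versus concentration, with its p-value.

    Weighted least squares with weights 1/sd² when all sds are positive,
    plain OLS otherwise. Needs ≥3 concentration levels.
    """
    import statsmodels.api as sm

    levels = np.asarray(levels, float)
    means = np.asarray(means, float)
    if len(levels) < 3:
        raise ValueError("need at least 3 concentration levels")
    X = sm.add_constant(levels)
    if sds is not None:
        sds = np.asarray(sds, float)
        if np.all(sds > 0):
            model = sm.WLS(means, X, weights=1.0 / sds ** 2)
        else:
            model = sm.OLS(means, X)
    else:
        model = sm.OLS(means, X)
    fit = model.fit()
    return float(fit.params[1]), float(fit.pvalues[1])
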