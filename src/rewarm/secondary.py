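"""Secondary analyses: interobserver differences, room-temperature
adjustment, and the finger-position (edge-effect) trend model.

The study design does not support an interobserver ICC (that would require
patients traveling between sites or all observers re-reading a large image
subset), so between-observer reliability is summarized as the paired mean
difference — patient-level averages over both visits, central observer
minus local observer — with a t-based 95% CI.

Room temperature is examined by adding the visit's mean room temperature
as a fixed covariate to the reliability model and recomputing the ICC.

Laser speckle images showed lower flux toward the image periphery (less
incident laser light at the edges), which would artificially depress
little-finger values relative to index fingers; thermography has no such
optical artifact.  The trend of finger-level measures across finger
position (index = 1 to little = 4, both hands pooled) is estimated on
standardized measurements with a linear mixed model including per-patient
random intercepts and slopes, so the standardized slopes of the two
modalities are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reliability import IccResult, estimate_icc


@dataclass
class ObserverComparison:
    measure: str
    modality: str
    mean_diff: float          # central minus local, patient-level averages
    ci_low: float
    ci_high: float
    n_patients: int


@dataclass
class TrendResult:
    modality: str
    measure: str
    slope_std: float          # standardized units per finger-position step
    ci_low: float
    ci_high: float
    random_slope_var: float
    converged: bool


@dataclass
class RoomTempResult:
    adjusted: IccResult | None
    unadjusted: IccResult
    temp_coefficient: float | None
    temp_ci: tuple[float, float] | None
    skipped: bool = False


def interobserver_difference(local: pd.DataFrame, central: pd.DataFrame,
                             measure: str, modality: str
                             ) -> ObserverComparison:
    """Paired mean difference between central and local observers.

    Each patient's values are first averaged over both visits within each
    observer's table; the difference vector (central - local) over patients
    common to both tables gets a t-based 95% CI.
    """
    def per_patient(df):
        sub = df[df["modality"] == modality]
        vals = sub[measure].astype(float)
        sub = sub[np.isfinite(vals)]
        return sub.groupby("patient_id")[measure].mean()

    a = per_patient(central)
    b = per_patient(local)
    joined = pd.concat({"central": a, "local": b}, axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} paired patients; need at least 3")
    d = (joined["central"] - joined["local"]).to_numpy()
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    tcrit = stats.t.ppf(0.975, n - 1)
    return ObserverComparison(measure=measure, modality=modality,
                              mean_diff=mean, ci_low=mean - tcrit * se,
                              ci_high=mean + tcrit * se, n_patients=n)


def room_temperature_adjustment(summaries: pd.DataFrame, measure: str,
                                modality: str, n_boot: int = 0,
                                seed: int | None = 0) -> RoomTempResult:
    """Refit the reliability model with room temperature as a covariate.

    Returns adjusted and unadjusted ICCs plus the temperature coefficient
    with a normal-approximation 95% CI.  A constant room temperature makes
    the coefficient inestimable; the adjustment is then skipped with a
    warning.
    """
    unadj = estimate_icc(summaries, measure, modality, n_boot=n_boot,
                         seed=seed)
    sub = summaries[summaries["modality"] == modality]
    if sub["room_temp_c"].nunique() <= 1:
        warnings.warn("room temperature is constant; adjustment skipped",
                      UserWarning, stacklevel=2)
        return RoomTempResult(adjusted=None, unadjusted=unadj,
                              temp_coefficient=None, temp_ci=None,
                              skipped=True)
    adj = estimate_icc(summaries, measure, modality, n_boot=n_boot,
                       seed=seed, covariates=["room_temp_c"])
    vc = adj.components
    i = list(vc.beta.index).index("room_temp_c")
    coef = float(vc.beta.iloc[i])
    se = float(np.sqrt(vc.cov_beta[i, i]))
    return RoomTempResult(adjusted=adj, unadjusted=unadj,
                          temp_coefficient=coef,
                          temp_ci=(coef - 1.96 * se, coef + 1.96 * se))


def edge_effect_trend(finger_summaries: pd.DataFrame, measure: str,
                      modality: str,
                      position_col: str = "finger_position") -> TrendResult:
    """Standardized linear trend of a finger-level measure across fingers.

    The measure is z-scored within modality, then regressed on finger
    position with per-patient random intercept and slope (REML, via
    statsmodels MixedLM).  The fixed slope and its normal-approximation
    95% CI are returned in standardized units per finger step.
    """
    import statsmodels.api as sm

    sub = finger_summaries[finger_summaries["modality"] == modality].copy()
    if position_col not in sub.columns:
        raise ValueError(f"missing finger numbering column {position_col!r}")
    vals = sub[measure].to_numpy(dtype=float)
    sub = sub[np.isfinite(vals)]
    if sub.empty:
        raise ValueError(f"no usable rows for {measure!r}/{modality!r}")
    z = sub[measure].to_numpy(dtype=float)
    sd = z.std(ddof=0)
    if sd == 0:
        raise ValueError("measure is constant; cannot standardize")
    z = (z - z.mean()) / sd
    pos = sub[position_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(z)), pos - pos.mean()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(z, X, groups=sub["patient_id"].to_numpy(), exog_re=X)
        res = md.fit(reml=True, method="lbfgs", maxiter=400)
    slope = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    return TrendResult(
        modality=modality, measure=measure, slope_std=slope,
        ci_low=slope - 1.96 * se, ci_high=slope + 1.96 * se,
        random_slope_var=float(np.asarray(res.cov_re)[1, 1]),
        converged=bool(res.converged))
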