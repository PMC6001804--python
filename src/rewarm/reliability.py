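"""Test-retest reliability as intraclass correlation coefficients.

Each summary measure (per modality) is modeled with a linear mixed model:
the measure is the dependent variable, center enters as a fixed effect
(reference-coded against the largest center), each patient contributes a
random intercept, and the two visits are treated as exchangeable repeats.
The ICC is the variance-component ratio

    ICC = sigma2_patient / (sigma2_patient + sigma2_resid)

— center variation is excluded because center is fixed.  Confidence
intervals come from a parametric bootstrap (resimulate from the fitted
model, refit, take percentiles), which respects the [0, 1] boundary better
than a Wald interval.  The ICC difference between two modalities is
bootstrapped nonparametrically over patients, preserving the within-patient
pairing across modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .lmm import RandomInterceptREML, UnivariateFit

ICC_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass
class VarianceComponents:
    """REML variance components for one measure/modality."""

    sigma2_patient: float
    sigma2_resid: float
    beta: pd.Series
    cov_beta: np.ndarray
    loglik_reml: float
    converged: bool
    boundary: str | None
    n_obs: int
    n_patients: int


@dataclass
class IccResult:
    measure: str
    modality: str
    icc: float
    ci_low: float | None
    ci_high: float | None
    n_patients: int
    n_visits: int
    classification: str
    components: VarianceComponents | None = None


def _design_matrix(df: pd.DataFrame, covariates: list[str] | None = None,
                   visit_effect: bool = False):
    """Fixed-effect design: intercept + center dummies (largest center is
    the reference) + optional covariates (+ optional visit-2 indicator)."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    sizes = df.groupby("center_id")["patient_id"].nunique()
    ref = sizes.sort_values(ascending=False).index[0]
    for c in sorted(sizes.index):
        if c == ref:
            continue
        cols.append((df["center_id"] == c).to_numpy(dtype=float))
        names.append(f"center[{c}]")
    if visit_effect:
        cols.append((df["visit"] > 1).to_numpy(dtype=float))
        names.append("visit2")
    for cov in covariates or []:
        vals = df[cov].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            raise ValueError(f"covariate {cov!r} is constant")
        cols.append(vals - vals.mean())
        names.append(cov)
    return np.column_stack(cols), names


def _build_model(summaries: pd.DataFrame, measure: str, modality: str,
                 covariates: list[str] | None = None,
                 visit_effect: bool = False) -> RandomInterceptREML:
    sub = summaries[summaries["modality"] == modality]
    sub = sub[np.isfinite(sub[measure].to_numpy(dtype=float))]
    if sub.empty:
        raise ValueError(
            f"no usable rows for measure {measure!r}, modality {modality!r}")
    reps = sub.groupby("patient_id").size()
    if (reps >= 2).sum() < 2:
        raise ValueError("need at least 2 patients with repeat visits")
    X, names = _design_matrix(sub, covariates, visit_effect)
    groups = sub["patient_id"].to_numpy()
    return RandomInterceptREML(X, sub[measure].to_numpy(dtype=float),
                               groups, xnames=names)


def _components(fit: UnivariateFit) -> VarianceComponents:
    return VarianceComponents(
        sigma2_patient=fit.sigma2_patient, sigma2_resid=fit.sigma2_resid,
        beta=pd.Series(fit.beta, index=fit.xnames),
        cov_beta=fit.cov_beta, loglik_reml=fit.loglik,
        converged=fit.converged, boundary=fit.boundary,
        n_obs=fit.n_obs, n_patients=fit.n_groups)


def fit_lmm(summaries: pd.DataFrame, measure: str, modality: str,
            covariates: list[str] | None = None,
            visit_effect: bool = False) -> VarianceComponents:
    """REML fit of measure ~ center (+ covariates) + (1 | patient)."""
    model = _build_model(summaries, measure, modality, covariates,
                         visit_effect)
    fit = model.fit()
    if fit.boundary is not None:
        warnings.warn(
            f"variance component at boundary ({fit.boundary}) for "
            f"{measure}/{modality}", UserWarning, stacklevel=2)
    return _components(fit)


def icc_from_components(vc: VarianceComponents) -> float:
    """ICC = sigma2_patient / (sigma2_patient + sigma2_resid)."""
    tot = vc.sigma2_patient + vc.sigma2_resid
    if tot <= 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return vc.sigma2_patient / tot


def bootstrap_icc_ci(summaries: pd.DataFrame, measure: str, modality: str,
                     n_boot: int = 2000, seed: int | None = 0,
                     covariates: list[str] | None = None
                     ) -> tuple[float, float]:
    """Percentile 95% CI for the ICC via parametric bootstrap."""
    model = _build_model(summaries, measure, modality, covariates)
    fit0 = model.fit()
    rng = np.random.default_rng(seed)
    iccs = np.empty(n_boot)
    n_fail = 0
    for b in range(n_boot):
        ystar = model.simulate(fit0, rng)
        try:
            iccs[b] = model.refit(ystar).icc
        except np.linalg.LinAlgError:
            iccs[b] = np.nan
            n_fail += 1
    if n_fail > 0.1 * n_boot:
        warnings.warn(f"{n_fail}/{n_boot} bootstrap refits failed",
                      UserWarning, stacklevel=2)
    lo, hi = np.nanpercentile(iccs, [2.5, 97.5])
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def icc_difference(summaries: pd.DataFrame, measure: str, modality_a: str,
                   modality_b: str, n_boot: int = 2000,
                   seed: int | None = 0) -> tuple[float, tuple[float, float]]:
    """ICC_a - ICC_b with a patient-resampling percentile 95% CI.

    Only patients measured by both modalities contribute; bootstrap
    replicates resample patients with replacement, keeping each patient's
    rows in both modalities together so the pairing is preserved.
    """
    pats = None
    for mod in (modality_a, modality_b):
        sub = summaries[(summaries["modality"] == mod)
                        & np.isfinite(summaries[measure].astype(float))]
        p = set(sub["patient_id"])
        pats = p if pats is None else pats & p
    if not pats:
        raise ValueError("no overlapping patients between the two modalities")
    common = summaries[summaries["patient_id"].isin(pats)]
    models = {mod: _build_model(common, measure, mod)
              for mod in (modality_a, modality_b)}
    # align patient coding across the two models
    labels = models[modality_a].group_labels
    if not np.array_equal(labels, models[modality_b].group_labels):
        raise ValueError("patient sets differ after filtering; cannot pair")
    point = (models[modality_a].fit().icc - models[modality_b].fit().icc)
    rng = np.random.default_rng(seed)
    G = len(labels)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        counts = np.bincount(rng.integers(0, G, G), minlength=G).astype(float)
        diffs[b] = (models[modality_a].fit(counts).icc
                    - models[modality_b].fit(counts).icc)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return float(point), (float(lo), float(hi))


def classify_icc(icc: float) -> str:
    """Qualitative reliability band for an ICC in [0, 1].

    Values are rounded to 2 decimals first, then banded with upper edges
    0.20 (slight), 0.40 (fair), 0.60 (moderate), 0.80 (substantial),
    1.00 (almost perfect); a boundary value belongs to the lower band.
    """
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"ICC {icc} outside [0, 1]")
    r = float(Decimal(repr(float(icc))).quantize(Decimal("0.01"),
                                                 rounding=ROUND_HALF_UP))
    for edge, label in ICC_BANDS:
        if r <= edge + 1e-12:
            return label
    return ICC_BANDS[-1][1]  # pragma: no cover


def estimate_icc(summaries: pd.DataFrame, measure: str, modality: str,
                 n_boot: int = 2000, seed: int | None = 0,
                 covariates: list[str] | None = None) -> IccResult:
    """Point estimate, bootstrap CI and classification in one call."""
    vc = fit_lmm(summaries, measure, modality, covariates)
    icc = icc_from_components(vc)
    lo = hi = None
    if n_boot > 0:
        lo, hi = bootstrap_icc_ci(summaries, measure, modality, n_boot, seed,
                                  covariates)
        lo, hi = min(lo, icc), max(hi, icc)   # bounds bracket the estimate
    sub = summaries[(summaries["modality"] == modality)
                    & np.isfinite(summaries[measure].astype(float))]
    return IccResult(
        measure=measure, modality=modality, icc=float(icc),
        ci_low=lo, ci_high=hi,
        n_patients=vc.n_patients,
        n_visits=int(sub["visit"].nunique()),
        classification=classify_icc(icc), components=vc)
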