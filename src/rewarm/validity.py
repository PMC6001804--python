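"""Convergent validity via bivariate linear mixed models.

Two modalities measuring the same construct (digital blood flow returning
after a cold challenge) are modeled jointly: each observation is

    value(patient, visit, modality) = center fixed effects (per modality)
        + patient random intercept for that modality + residual

with the two patient intercepts bivariate normal with covariance G and
modality-specific residual variances.  The latent correlation

    rho = G12 / sqrt(G11 * G22)

is 1 when the modalities measure the same patient-level construct.  G is
parameterized through its Cholesky factor, so positive semi-definiteness
is enforced by construction, and the restricted likelihood is maximized
from several deterministic starts.  Because modalities keep separate fixed
effects, residual variances and intercept variances, rho is invariant to
separate affine rescaling of each modality — which is what licenses
comparing degrees Celsius with arbitrary perfusion units.

The post hoc association between the summary measures and the Raynaud's
condition score (RCS) reported on each study day is also estimated here,
as the RCS fixed-effect slope in the univariate mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import BivariateFitResult, BivariateREML
from .reliability import _build_model

MIN_OVERLAP_PATIENTS = 10


@dataclass
class LatentCorrResult:
    modality_pair: tuple[str, str]
    measure: str
    rho: float | None
    ci_low: float | None
    ci_high: float | None
    n_patients: int
    converged: bool
    boundary: bool


def _stack_pair(summaries: pd.DataFrame, measure: str,
                modality_pair: tuple[str, str]):
    """Stacked design for the bivariate model.

    Fixed effects are modality-specific: an intercept and center dummies
    (largest center as reference) for each member of the pair.  Each
    modality's values are standardized to unit variance before fitting so
    the optimization is insensitive to the (arbitrary) measurement units;
    :func:`_unscale_fit` maps the estimates back.  The latent correlation
    itself is invariant to this rescaling.
    """
    mod_a, mod_b = modality_pair
    sub = summaries[summaries["modality"].isin(modality_pair)].copy()
    vals = sub[measure].to_numpy(dtype=float)
    sub = sub[np.isfinite(vals)]
    if sub.empty:
        raise ValueError(f"no usable rows for {measure!r} in {modality_pair}")
    by_mod = {m: set(sub.loc[sub["modality"] == m, "patient_id"])
              for m in modality_pair}
    overlap = by_mod[mod_a] & by_mod[mod_b]
    if len(overlap) < MIN_OVERLAP_PATIENTS:
        raise ValueError(
            f"only {len(overlap)} patients measured by both modalities; "
            f"need at least {MIN_OVERLAP_PATIENTS}")
    sizes = sub.groupby("center_id")["patient_id"].nunique()
    ref = sizes.sort_values(ascending=False).index[0]
    centers = sorted(c for c in sizes.index if c != ref)
    variate = (sub["modality"] == mod_b).to_numpy(dtype=int)
    y = sub[measure].to_numpy(dtype=float)
    sd = np.ones(2)
    nv = np.zeros(2)
    for v in (0, 1):
        s = float(np.std(y[variate == v]))
        sd[v] = s if s > 0 else 1.0
        nv[v] = int((variate == v).sum())
    cols, names, col_variate = [], [], []
    for vcode, mod in ((0, mod_a), (1, mod_b)):
        sel = (variate == vcode).astype(float)
        cols.append(sel)
        names.append(f"{mod}:intercept")
        col_variate.append(vcode)
        for c in centers:
            cols.append(sel * (sub["center_id"] == c).to_numpy(dtype=float))
            names.append(f"{mod}:center[{c}]")
            col_variate.append(vcode)
    X = np.column_stack(cols)
    keep = X.sum(axis=0) > 0          # a center can be absent for a modality
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    col_variate = np.array([cv for cv, k in zip(col_variate, keep) if k])
    model = BivariateREML(X, y / sd[variate],
                          sub["patient_id"].to_numpy(), variate,
                          xnames=names)
    meta = {"n_overlap": len(overlap), "sd": sd, "n_per_variate": nv,
            "col_variate": col_variate}
    return model, meta


def _unscale_fit(fit: BivariateFitResult, meta: dict) -> BivariateFitResult:
    """Map a fit on standardized data back to the original units."""
    sd, nv = meta["sd"], meta["n_per_variate"]
    S = np.diag(sd)
    # REML is the likelihood of N_v - p_v error contrasts per variate, so
    # the change-of-variables term subtracts (N_v - p_v) * log sd_v
    pv = np.array([(meta["col_variate"] == v).sum() for v in (0, 1)])
    return BivariateFitResult(
        G=S @ fit.G @ S, resid_var=fit.resid_var * sd ** 2,
        beta=fit.beta * sd[meta["col_variate"]],
        loglik=fit.loglik - float((nv - pv) @ np.log(sd)),
        converged=fit.converged, boundary=fit.boundary, theta=fit.theta,
        modalities=fit.modalities, xnames=fit.xnames)


def fit_bivariate_lmm(summaries: pd.DataFrame, measure: str,
                      modality_pair: tuple[str, str],
                      free_cov: bool = True) -> BivariateFitResult:
    """REML fit of the bivariate patient-intercept model for one pair."""
    model, meta = _stack_pair(summaries, measure, modality_pair)
    fit = model.fit(free_cov=free_cov)
    fit.modalities = tuple(modality_pair)
    if not fit.converged:
        warnings.warn(
            f"bivariate fit did not report convergence for {measure!r} "
            f"{modality_pair}", UserWarning, stacklevel=2)
    return _unscale_fit(fit, meta)


def latent_correlation(fit: BivariateFitResult,
                       measure: str = "") -> LatentCorrResult:
    """Latent correlation from a fitted bivariate model.

    If either patient-level variance collapsed to the zero boundary the
    correlation is undefined and flagged (``rho`` is None), never silently
    reported as 0.
    """
    return LatentCorrResult(
        modality_pair=fit.modalities or ("", ""), measure=measure,
        rho=fit.rho, ci_low=None, ci_high=None,
        n_patients=0, converged=fit.converged, boundary=fit.boundary)


def bootstrap_rho_ci(summaries: pd.DataFrame, measure: str,
                     modality_pair: tuple[str, str], n_boot: int = 2000,
                     seed: int | None = 0) -> tuple[float, float]:
    """Percentile 95% CI for rho via parametric bootstrap, clipped to [-1, 1]."""
    model, _ = _stack_pair(summaries, measure, modality_pair)
    fit0 = model.fit()
    if fit0.boundary or fit0.rho is None:
        raise ValueError("point fit is at a variance boundary; no CI")
    rng = np.random.default_rng(seed)
    rhos = np.full(n_boot, np.nan)
    n_bad = 0
    for b in range(n_boot):
        sims = model.simulate(fit0, rng)
        refit = model.refit(sims, start=fit0.theta)
        if refit.rho is None:
            n_bad += 1
        else:
            rhos[b] = refit.rho
    if n_bad > 0.1 * n_boot:
        warnings.warn(
            f"{n_bad}/{n_boot} bootstrap refits hit a variance boundary",
            UserWarning, stacklevel=2)
    lo, hi = np.nanpercentile(rhos, [2.5, 97.5])
    return float(np.clip(lo, -1.0, 1.0)), float(np.clip(hi, -1.0, 1.0))


def estimate_latent_correlation(summaries: pd.DataFrame, measure: str,
                                modality_pair: tuple[str, str],
                                n_boot: int = 2000,
                                seed: int | None = 0) -> LatentCorrResult:
    """Point estimate plus bootstrap CI for one measure/pair."""
    model, meta = _stack_pair(summaries, measure, modality_pair)
    fit = model.fit()
    fit.modalities = tuple(modality_pair)
    res = latent_correlation(fit, measure)
    res.n_patients = meta["n_overlap"]
    if n_boot > 0 and res.rho is not None:
        lo, hi = bootstrap_rho_ci(
            summaries, measure, modality_pair, n_boot, seed)
        res.ci_low, res.ci_high = min(lo, res.rho), max(hi, res.rho)
    return res


def rcs_association(summaries: pd.DataFrame, measure: str,
                    modality: str) -> tuple[float, float]:
    """Fixed-effect slope (and SE) of a measure on the day's RCS.

    Model: measure ~ center + RCS (fixed) + (1 | patient).  The RCS varies
    between visits, so the slope is identified from both between- and
    within-patient contrasts.
    """
    model = _build_model(summaries, measure, modality,
                         covariates=["rcs_on_day"])
    fit = model.fit()
    i = fit.xnames.index("rcs_on_day")
    return float(fit.beta[i]), float(np.sqrt(fit.cov_beta[i, i]))
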