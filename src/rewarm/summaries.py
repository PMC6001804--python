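"""Summary measures of the rewarming/reperfusion response.

Each patient x visit x modality group of ROI time series is reduced to four
finger-averaged measures:

DDD
    distal dorsal difference — dorsum minus finger on the baseline
    (pre-challenge) image, positive when fingertips are cooler / less
    perfused than the dorsum; averaged over the available fingers.
AUC
    trapezoidal area under the post-challenge curve over [0, 900] s (the
    one extra frame acquired beyond 15 min is excluded).
MAX
    maximum sampled value in [0, 900] s.
GRAD
    slope of the response over the first 2 minutes post-challenge
    (ordinary least squares by default; a two-point difference is offered
    as an alternative).

AUC and MAX are additionally reported on the natural-log scale, matching
the scale on which reliability and validity are analyzed.  Mobile
thermography contributes only DDD and an AUC approximated from its two
post-challenge images (which coincides with the trapezoid through those
points); its MAX and GRAD are not applicable and are left missing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import (DORSUM_ROIS, FINGER_ROIS, HAND_OF_FINGER,
                       POST_WINDOW_S)

GRAD_WINDOW_S = 120.0

SUMMARY_COLUMNS = ["patient_id", "center_id", "observer_id", "visit",
                   "modality", "n_fingers", "ddd", "auc", "max_value", "grad",
                   "auc_log", "max_log", "room_temp_c", "rcs_on_day"]


def _window(times, values, lo, hi):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    keep = (times >= lo) & (times <= hi)
    return times[keep], values[keep]


def compute_auc(times_s, values, window_s: float = POST_WINDOW_S) -> float:
    """Trapezoidal area under the curve over [0, window_s] seconds."""
    t, v = _window(times_s, values, 0.0, window_s)
    if len(t) < 2:
        raise ValueError("need at least 2 samples within the AUC window")
    return float(np.trapezoid(v, t))


def compute_max(times_s, values, window_s: float = POST_WINDOW_S) -> float:
    """Maximum sampled value over [0, window_s] seconds."""
    t, v = _window(times_s, values, 0.0, window_s)
    if len(t) == 0:
        raise ValueError("no samples within the MAX window")
    return float(np.max(v))


def compute_grad(times_s, values, window_s: float = GRAD_WINDOW_S,
                 method: str = "ols") -> float:
    """Initial rewarming gradient over [0, window_s] seconds (units/s)."""
    t, v = _window(times_s, values, 0.0, window_s)
    if len(t) < 2:
        raise ValueError("need at least 2 samples within the gradient window")
    if method == "ols":
        tc = t - t.mean()
        return float(np.dot(tc, v) / np.dot(tc, tc))
    if method == "two_point":
        return float((v[-1] - v[0]) / (t[-1] - t[0]))
    raise ValueError(f"unknown gradient method: {method!r}")


def compute_ddd(baseline_finger: float, baseline_dorsum: float) -> float:
    """Distal dorsal difference: dorsum minus finger at baseline."""
    if not (np.isfinite(baseline_finger) and np.isfinite(baseline_dorsum)):
        raise ValueError("baseline values must be finite")
    return float(baseline_dorsum - baseline_finger)


def average_fingers(per_finger_values) -> tuple[float, int]:
    """Missing-aware mean over up to 8 finger values.

    Returns ``(mean, n_contributing)``; all-missing yields ``(nan, 0)``.
    """
    vals = np.asarray(per_finger_values, dtype=float)
    if vals.size > 8:
        raise ValueError("at most 8 finger values expected")
    ok = np.isfinite(vals)
    if not ok.any():
        return float("nan"), 0
    return float(vals[ok].mean()), int(ok.sum())


def mobile_auc_approx(value_0min: float, value_15min: float) -> float:
    """AUC from the two mobile post-challenge images.

    The mean of the two values is scaled by the 900 s window so the result
    is on the same units*s scale as :func:`compute_auc`; this equals the
    trapezoid through the two points (exact for linear rewarming).
    """
    if not (np.isfinite(value_0min) and np.isfinite(value_15min)):
        return float("nan")
    return POST_WINDOW_S * (value_0min + value_15min) / 2.0


def add_log_transforms(df: pd.DataFrame) -> pd.DataFrame:
    """Attach natural-log AUC and MAX columns; non-positive values are
    flagged missing (excluded from log-scale analyses) with a warning."""
    out = df.copy()
    for raw, logged in (("auc", "auc_log"), ("max_value", "max_log")):
        vals = out[raw].to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals <= 0)
        if bad.any():
            warnings.warn(
                f"{bad.sum()} non-positive {raw} value(s); excluded from "
                "log-scale analyses", UserWarning, stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[logged] = np.where(np.isfinite(vals) & (vals > 0),
                                   np.log(np.where(vals > 0, vals, 1.0)),
                                   np.nan)
    return out


_GROUP = ["patient_id", "center_id", "observer_id", "visit", "modality"]


def _finger_number(roi: pd.Series) -> pd.Series:
    return roi.str.removeprefix("finger_").astype(int)


def summarize_fingers(frames: pd.DataFrame,
                      grad_window_s: float = GRAD_WINDOW_S,
                      grad_method: str = "ols") -> pd.DataFrame:
    """Finger-level summary measures (one row per finger ROI per group).

    This is the input for the edge-effect trend analysis; the usual
    finger-averaged table is built on top of it by
    :func:`summarize_dataset`.  Vectorized: the trapezoid, max and OLS
    slope are accumulated per group with grouped reductions.
    """
    post = frames[(frames["phase"] == "post_challenge")
                  & frames["roi"].isin(FINGER_ROIS)].copy()
    if post.empty:
        raise ValueError("no post-challenge finger rows in input")
    keys = _GROUP + ["roi"]
    post = post.sort_values(keys + ["time_s"], kind="stable")
    gid, uniq = pd.factorize(pd.MultiIndex.from_frame(post[keys]), sort=False)
    t = post["time_s"].to_numpy(dtype=float)
    v = post["value"].to_numpy(dtype=float)
    in_win = (t >= 0.0) & (t <= POST_WINDOW_S)
    n_groups = len(uniq)

    # trapezoid over consecutive in-window rows of the same group
    same = np.r_[gid[1:] == gid[:-1], False]
    pair = same & in_win & np.r_[in_win[1:], False]
    dt = np.r_[t[1:] - t[:-1], 0.0]
    contrib = np.where(pair, 0.5 * (v + np.r_[v[1:], 0.0]) * dt, 0.0)
    auc = np.bincount(gid, weights=contrib, minlength=n_groups)
    n_in = np.bincount(gid, weights=in_win.astype(float), minlength=n_groups)
    auc = np.where(n_in >= 2, auc, np.nan)

    # max over in-window rows
    vmax = np.full(n_groups, -np.inf)
    np.maximum.at(vmax, gid[in_win], v[in_win])
    vmax = np.where(np.isfinite(vmax), vmax, np.nan)

    # OLS slope over [0, grad_window_s]
    gw = (t >= 0.0) & (t <= grad_window_s)
    n_g = np.bincount(gid, weights=gw.astype(float), minlength=n_groups)
    St = np.bincount(gid[gw], weights=t[gw], minlength=n_groups)
    Sv = np.bincount(gid[gw], weights=v[gw], minlength=n_groups)
    Stt = np.bincount(gid[gw], weights=t[gw] ** 2, minlength=n_groups)
    Stv = np.bincount(gid[gw], weights=t[gw] * v[gw], minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = Stt - St ** 2 / np.where(n_g > 0, n_g, 1)
        sxv = Stv - St * Sv / np.where(n_g > 0, n_g, 1)
        grad = np.where((n_g >= 2) & (sxx > 0), sxv / np.where(sxx > 0, sxx, 1),
                        np.nan)
    if grad_method == "two_point":
        first = np.full(n_groups, np.nan)
        last = np.full(n_groups, np.nan)
        tfirst = np.full(n_groups, np.nan)
        tlast = np.full(n_groups, np.nan)
        idx = np.flatnonzero(gw)
        # first/last in-window row per group (rows are time-sorted)
        for arr_v, arr_t, take in ((first, tfirst, idx),
                                   (last, tlast, idx[::-1])):
            seen = np.zeros(n_groups, dtype=bool)
            for i in take:
                g = gid[i]
                if not seen[g]:
                    arr_v[g] = v[i]
                    arr_t[g] = t[i]
                    seen[g] = True
        with np.errstate(invalid="ignore", divide="ignore"):
            grad = np.where(n_g >= 2, (last - first) / (tlast - tfirst),
                            np.nan)
    elif grad_method != "ols":
        raise ValueError(f"unknown gradient method: {grad_method!r}")

    out = uniq.to_frame(index=False)
    out.columns = keys
    out["auc"] = auc
    out["max_value"] = vmax
    out["grad"] = grad
    # MAX and GRAD are not defined for the two-frame mobile acquisition
    mob = out["modality"] == "mobile"
    out.loc[mob, ["max_value", "grad"]] = np.nan
    out["finger_number"] = _finger_number(out["roi"])
    out["hand"] = out["finger_number"].map(HAND_OF_FINGER)
    # within-hand finger position 1..4 (index -> little)
    out["finger_position"] = np.where(out["finger_number"] <= 4,
                                      out["finger_number"],
                                      out["finger_number"] - 4)

    # baseline DDD per finger, against the same-hand dorsum
    base = frames[frames["phase"] == "baseline"]
    if not base.empty:
        dors = base[base["roi"].isin(DORSUM_ROIS)]
        dmean = (dors.groupby(_GROUP + ["roi"], sort=False)["value"].mean()
                 .unstack("roi"))
        fing = base[base["roi"].isin(FINGER_ROIS)]
        fmean = fing.groupby(_GROUP + ["roi"], sort=False)["value"].mean()
        fmean = fmean.reset_index()
        fmean["hand"] = _finger_number(fmean["roi"]).map(HAND_OF_FINGER)
        fmean = fmean.merge(dmean.reset_index(), on=_GROUP, how="left")
        dcol = np.where(fmean["hand"] == "left",
                        fmean.get("dorsum_left", np.nan),
                        fmean.get("dorsum_right", np.nan))
        fmean["ddd"] = dcol - fmean["value"].to_numpy()
        out = out.merge(fmean[_GROUP + ["roi", "ddd"]], on=_GROUP + ["roi"],
                        how="left")
    else:
        out["ddd"] = np.nan
    return out


def summarize_dataset(frames: pd.DataFrame,
                      grad_window_s: float = GRAD_WINDOW_S,
                      grad_method: str = "ols") -> pd.DataFrame:
    """Finger-averaged summary table: one row per patient x visit x modality.

    Missing fingers are dropped from the averages (``n_fingers`` records how
    many contributed); log transforms of AUC and MAX are attached.  Room
    temperature and the Raynaud's condition score for the visit are carried
    through from the frame table.
    """
    fl = summarize_fingers(frames, grad_window_s, grad_method)
    agg = (fl.groupby(_GROUP, sort=False)
             .agg(ddd=("ddd", "mean"), auc=("auc", "mean"),
                  max_value=("max_value", "mean"), grad=("grad", "mean"),
                  n_fingers=("auc", lambda s: int(s.notna().sum())))
             .reset_index())
    covars = (frames.groupby(_GROUP, sort=False)[["room_temp_c", "rcs_on_day"]]
              .first().reset_index())
    out = agg.merge(covars, on=_GROUP, how="left")
    out = add_log_transforms(out)
    return out[SUMMARY_COLUMNS]
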