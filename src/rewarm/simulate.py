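"""Synthetic multicenter cold-challenge data.

The generator emulates a study in which patients with systemic
sclerosis–related Raynaud's phenomenon attend a tertiary-care center on two
consecutive days, immerse both hands for one minute in 15 °C water, and are
then imaged for 15 minutes while the hands rewarm/reperfuse:

* laser speckle contrast imaging (LSCI) at 15 frames/min — 225 post-challenge
  frames plus one extra frame beyond the 15-minute window;
* standard infrared thermography at 4 frames/min — 61 frames (including the
  t = 0 image) plus one extra;
* mobile-phone thermography — three single images (baseline, 0 min, 15 min).

Each image yields means over 10 regions of interest: the 8 distal phalanges
(index–little of both hands; thumbs are not analyzed) and the 2 dorsa.

Two layers of generator are provided:

* :func:`generate_study` produces frame-level ROI time series.  Rewarming is
  mono-exponential (:func:`rewarming_curve`); patient-to-patient and
  visit-to-visit variation enter as vertical shifts of the curve plateau, a
  shared latent "vasoreactivity" factor links LSCI and thermography patient
  effects, and mobile thermography is the thermography truth sampled at the
  three mobile time points plus sensor noise.

* :func:`simulate_summary_measures` / :func:`simulate_finger_measures` draw
  finger-averaged (or finger-level) summary measures directly from the
  hierarchical model that the downstream mixed models assume, with exactly
  prescribed variance components and latent correlations.  These are the
  instruments for parameter-recovery experiments, where the generating truth
  must be controlled on the scale of the analyzed measure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("lsci", "thermo", "mobile")
MEASURES = ("ddd", "auc_log", "max_log", "grad")
FINGER_ROIS = tuple(f"finger_{i}" for i in range(1, 9))
DORSUM_ROIS = ("dorsum_left", "dorsum_right")
ROI_LABELS = FINGER_ROIS + DORSUM_ROIS

#: hand assignment of the finger ROIs (fingers 1–4 left hand, 5–8 right)
HAND_OF_FINGER = {i: ("left" if i <= 4 else "right") for i in range(1, 9)}

FRAME_COLUMNS = ["patient_id", "center_id", "observer_id", "visit", "modality",
                 "roi", "phase", "time_s", "value", "room_temp_c", "rcs_on_day"]

_BASELINE_TIME_S = -60.0
POST_WINDOW_S = 900.0


def _pair(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class StudyDesign:
    """Multicenter two-visit cold-challenge design.

    Defaults reproduce the study conditions: 6 centers, 159 patients (60 at
    the central site, 16–20 at the others), 2 visits on consecutive days,
    all three modalities, 15 °C water and a 23 °C target room temperature.
    """

    n_centers: int = 6
    patients_per_center: tuple[int, ...] = (60, 20, 20, 20, 20, 19)
    n_visits: int = 2
    modalities: tuple[str, ...] = MODALITIES
    frames_per_minute: dict = field(
        default_factory=lambda: {"lsci": 15, "thermo": 4})
    duration_min: float = 15.0
    water_temp_c: float = 15.0
    room_temp_mean_c: float = 23.0
    room_temp_sd_c: float = 1.0

    def __post_init__(self):
        if len(self.patients_per_center) != self.n_centers:
            raise ValueError("patients_per_center must have length n_centers")
        if any(n < 1 for n in self.patients_per_center):
            raise ValueError("every center needs at least one patient")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if any(r <= 0 for r in self.frames_per_minute.values()):
            raise ValueError("frame rates must be positive")
        bad = set(self.modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")

    @property
    def n_patients(self) -> int:
        return sum(self.patients_per_center)

    def center_ids(self) -> list[str]:
        return [f"C{i+1}" for i in range(self.n_centers)]

    def patient_table(self) -> pd.DataFrame:
        """One row per patient with ids and center assignment."""
        centers = np.repeat(self.center_ids(), self.patients_per_center)
        pid = [f"P{i+1:04d}" for i in range(self.n_patients)]
        return pd.DataFrame({"patient_id": pid, "center_id": centers,
                             "observer_id": [f"obs_{c}" for c in centers]})

    def post_challenge_times(self, modality: str) -> tuple[np.ndarray, float]:
        """Regular post-challenge frame times (s) and the one extra frame.

        Thermography starts its grid at t = 0 (61 frames with defaults);
        LSCI's first frame completes one frame interval after the challenge
        (225 frames with defaults).  Both acquire one extra frame beyond the
        window so the end-of-run gradient could be formed.
        """
        if modality == "mobile":
            return np.array([0.0, self.duration_min * 60.0]), math.nan
        step = 60.0 / self.frames_per_minute[modality]
        n = int(round(self.frames_per_minute[modality] * self.duration_min))
        if modality == "thermo":
            times = step * np.arange(0, n + 1)
        else:
            times = step * np.arange(1, n + 1)
        return times, times[-1] + step


@dataclass
class GeneratorParams:
    """Generating truth for the synthetic study.

    Variance maps are keyed by ``(modality, measure)``; the frame-level
    generator consumes the ``"max"`` (curve plateau shift, °C or perfusion
    units) and ``"ddd"`` entries, while the summary-level generators accept
    whatever scale the experiment prescribes.  ``rho_latent`` is keyed by a
    sorted modality pair and gives the correlation of patient-level effects.
    """

    sigma2_patient: dict = field(default_factory=lambda: {
        ("lsci", "max"): 1225.0, ("thermo", "max"): 2.25,
        ("lsci", "ddd"): 400.0, ("thermo", "ddd"): 1.2,
        # mobile entries are patient-level reading offsets added on top of
        # the thermography truth it is downsampled from
        ("mobile", "max"): 0.09, ("mobile", "ddd"): 0.28,
    })
    sigma2_visit: dict = field(default_factory=lambda: {
        ("lsci", "max"): 625.0, ("thermo", "max"): 1.0,
        ("lsci", "ddd"): 200.0, ("thermo", "ddd"): 0.8,
        ("mobile", "max"): 1.0, ("mobile", "ddd"): 0.8,
    })
    rho_latent: dict = field(default_factory=lambda: {
        _pair("lsci", "thermo"): 0.95})
    rho_ddd: float = 0.65        # patient-level DDD correlation across modalities
    rho_rate: float = 0.5        # patient-level log rewarm-rate correlation
    rate_sd_patient: float = 0.25  # sd of patient log rewarm-rate
    rate_sd_visit: float = 0.25    # sd of visit-to-visit log rewarm-rate
    center_effects: dict | None = None
    edge_slope: dict = field(default_factory=lambda: {
        "lsci": -6.0, "thermo": 0.15})
    rewarm_rate_mean: float = 0.35          # 1/min
    plateau_mean: dict = field(default_factory=lambda: {
        "lsci": 200.0, "thermo": 31.0})
    drop_mean: dict = field(default_factory=lambda: {
        "lsci": 120.0, "thermo": 7.0})
    ddd_mean: dict = field(default_factory=lambda: {
        "lsci": 60.0, "thermo": 3.0})
    noise_sd_frame: dict = field(default_factory=lambda: {
        "lsci": 6.0, "thermo": 0.15, "mobile": 0.3})
    sigma2_finger: dict = field(default_factory=lambda: {
        "lsci": 100.0, "thermo": 0.16})
    rcs_effect: float = -0.15               # change in DDD per RCS point
    room_temp_effect: float = 0.0           # per-°C shift of the plateau
    missing_rate: dict = field(default_factory=dict)  # modality -> fraction

    def validate(self, design: StudyDesign) -> None:
        for name in ("sigma2_patient", "sigma2_visit", "sigma2_finger"):
            for key, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}[{key!r}] is negative")
        for key, r in self.rho_latent.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(
                    f"rho_latent[{key!r}] = {r} outside [-1, 1] "
                    f"(offending modality pair: {key[0]}-{key[1]})")
        mods = sorted({m for k in self.rho_latent for m in k})
        if mods:
            check_psd_correlation(
                correlation_matrix(mods, self.rho_latent), mods)
        for mod, rate in self.missing_rate.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missing_rate[{mod!r}] outside [0, 1)")


def params_to_mapping(design: StudyDesign, params: GeneratorParams) -> dict:
    """Serializable echo of the design and generating truth (tuple keys
    flattened to ``a:b`` strings), for the sidecar config written next to
    simulated datasets."""
    def flat(d):
        return {":".join(map(str, k)) if isinstance(k, tuple) else k: v
                for k, v in d.items()}

    out = {"design": {
        "n_centers": design.n_centers,
        "patients_per_center": list(design.patients_per_center),
        "n_visits": design.n_visits,
        "modalities": list(design.modalities),
        "frames_per_minute": dict(design.frames_per_minute),
        "duration_min": design.duration_min,
        "water_temp_c": design.water_temp_c,
        "room_temp_mean_c": design.room_temp_mean_c,
        "room_temp_sd_c": design.room_temp_sd_c,
    }, "params": {}}
    for name, val in vars(params).items():
        out["params"][name] = flat(val) if isinstance(val, dict) else val
    return out


def correlation_matrix(modalities: list[str], rho: dict | float) -> np.ndarray:
    """Assemble a correlation matrix from pairwise entries (default 0)."""
    m = len(modalities)
    R = np.eye(m)
    for i, j in itertools.combinations(range(m), 2):
        if isinstance(rho, dict):
            r = rho.get(_pair(modalities[i], modalities[j]), 0.0)
        else:
            r = float(rho)
        R[i, j] = R[j, i] = r
    return R


def check_psd_correlation(R: np.ndarray, modalities: list[str]) -> None:
    """Reject a non-PSD implied patient-effect correlation matrix."""
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        # name the pair carrying the largest off-diagonal correlation, the
        # usual culprit when three pairwise values are jointly infeasible
        off = np.abs(R - np.diag(np.diag(R)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            "implied patient-level correlation matrix is not positive "
            f"semi-definite (min eigenvalue {eig.min():.3g}); offending "
            f"modality pair: {modalities[i]}-{modalities[j]}")


def rewarming_curve(t, plateau: float, drop: float, rate: float):
    """Mono-exponential rewarming value(t) = plateau - drop*exp(-rate*t/60).

    ``t`` is in seconds, ``rate`` in 1/min.  value(0) = plateau - drop and
    the curve approaches ``plateau`` monotonically; ``rate = 0`` degenerates
    to the constant ``plateau - drop``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time in rewarming_curve")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if drop < 0:
        raise ValueError("drop must be non-negative")
    return plateau - drop * np.exp(-rate * t / 60.0)


def _default_center_effects(design: StudyDesign) -> dict:
    """Small deterministic center shifts (image analysis is local per site)."""
    pattern = [0.0, 0.4, -0.3, 0.25, -0.2, 0.3, -0.15, 0.2]
    scale = {"lsci": 15.0, "thermo": 1.0, "mobile": 1.0}
    out = {}
    for ci, cid in enumerate(design.center_ids()):
        for mod in MODALITIES:
            out[(cid, mod)] = pattern[ci % len(pattern)] * scale[mod]
    return out


def _seed_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def generate_study(design: StudyDesign | None = None,
                   params: GeneratorParams | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full multicenter study at frame level.

    Returns ``(frames, truth)``: a long table with one row per frame per ROI
    (columns :data:`FRAME_COLUMNS`) and a patient-level table of the latent
    generating state for recovery tests.  Deterministic given ``seed``.
    """
    design = design or StudyDesign()
    params = params or GeneratorParams()
    params.validate(design)
    center_effects = params.center_effects
    if center_effects is None:
        center_effects = _default_center_effects(design)

    rng_lat, rng_visit, rng_frame, rng_day, rng_miss = _seed_streams(seed, 5)
    pats = design.patient_table()
    P, V = design.n_patients, design.n_visits
    centers = pats["center_id"].to_numpy()

    # latent patient state -------------------------------------------------
    u = rng_lat.standard_normal(P)                 # vasoreactivity construct
    w_ddd = rng_lat.standard_normal(P)             # shared DDD factor
    g_shared = rng_lat.standard_normal(P)          # shared rewarm-rate factor
    rho_lt = params.rho_latent.get(_pair("lsci", "thermo"), 0.0)
    load = math.sqrt(abs(rho_lt))
    sign_t = 1.0 if rho_lt >= 0 else -1.0
    resid_load = math.sqrt(max(1.0 - load ** 2, 0.0))
    r_d = math.sqrt(min(max(params.rho_ddd, 0.0), 1.0))
    r_g = math.sqrt(min(max(params.rho_rate, 0.0), 1.0))
    a_plateau, a_ddd, log_rate_p = {}, {}, {}
    for mod, s in (("lsci", 1.0), ("thermo", sign_t)):
        xi = rng_lat.standard_normal(P)
        sd = math.sqrt(params.sigma2_patient.get((mod, "max"), 0.0))
        a_plateau[mod] = sd * (s * load * u + resid_load * xi)
        xi2 = rng_lat.standard_normal(P)
        sd2 = math.sqrt(params.sigma2_patient.get((mod, "ddd"), 0.0))
        a_ddd[mod] = sd2 * (r_d * w_ddd + math.sqrt(1.0 - r_d ** 2) * xi2)
        # slower rewarming for more vasoreactive (severe) patients; LSCI
        # reperfusion and thermographic rewarming rates are only partially
        # shared (temperature lags perfusion)
        eta = rng_lat.standard_normal(P)
        g = -0.6 * u + 0.8 * (r_g * g_shared
                              + math.sqrt(1.0 - r_g ** 2) * eta)
        log_rate_p[mod] = params.rate_sd_patient * g

    # visit-level state ----------------------------------------------------
    room_temp = rng_day.normal(design.room_temp_mean_c,
                               design.room_temp_sd_c, (P, V))
    rcs = np.clip(np.round(5.0 + 1.8 * u[:, None]
                           + rng_day.normal(0, 0.8, (P, V))), 0, 10)
    e_plateau = {mod: rng_visit.normal(
        0.0, math.sqrt(params.sigma2_visit.get((mod, "max"), 0.0)), (P, V))
        for mod in ("lsci", "thermo")}
    e_ddd = {mod: rng_visit.normal(
        0.0, math.sqrt(params.sigma2_visit.get((mod, "ddd"), 0.0)), (P, V))
        for mod in ("lsci", "thermo")}
    rate_pv = {mod: params.rewarm_rate_mean * np.exp(
        log_rate_p[mod][:, None]
        + rng_visit.normal(0.0, params.rate_sd_visit, (P, V)))
        for mod in ("lsci", "thermo")}

    need_thermo_truth = bool({"thermo", "mobile"} & set(design.modalities))
    blocks: list[pd.DataFrame] = []
    truth_cols = {"patient_id": pats["patient_id"], "center_id": centers,
                  "vasoreactivity": u}

    # fingers are numbered 1..4 within each hand (index -> little)
    finger_pos = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
    pos_centered = finger_pos - finger_pos.mean()

    curves = {}       # modality -> dict with finger/dorsum arrays
    for mod in ("lsci", "thermo"):
        if mod not in design.modalities and not (
                mod == "thermo" and need_thermo_truth):
            continue
        ce = np.array([center_effects.get((c, mod), 0.0) for c in centers])
        base = (params.plateau_mean[mod] + ce[:, None] + a_plateau[mod][:, None]
                + e_plateau[mod]
                + params.room_temp_effect * (room_temp
                                             - design.room_temp_mean_c))
        fing_noise = rng_visit.normal(
            0.0, math.sqrt(params.sigma2_finger.get(mod, 0.0)), (P, V, 8))
        edge = params.edge_slope.get(mod, 0.0) * pos_centered
        plateau_f = base[:, :, None] + edge[None, None, :] + fing_noise
        # DDD truth per finger; scale the RCS effect to the modality units
        rcs_scale = (math.sqrt(params.sigma2_patient.get((mod, "ddd"), 1.0))
                     / math.sqrt(params.sigma2_patient.get(("thermo", "ddd"), 1.0) or 1.0))
        ddd_f = (params.ddd_mean[mod] + a_ddd[mod][:, None, None]
                 + e_ddd[mod][:, :, None]
                 + params.rcs_effect * rcs_scale * (rcs[:, :, None] - 5.0)
                 + rng_visit.normal(0.0, 0.3 * math.sqrt(
                     params.sigma2_visit.get((mod, "ddd"), 0.0) or 1e-12),
                     (P, V, 8)))
        curves[mod] = {"plateau_f": plateau_f, "dorsum": base, "ddd_f": ddd_f}
        truth_cols[f"patient_effect_{mod}"] = a_plateau[mod]
        truth_cols[f"patient_effect_ddd_{mod}"] = a_ddd[mod]
        truth_cols[f"rewarm_rate_{mod}"] = (
            params.rewarm_rate_mean * np.exp(log_rate_p[mod]))

    def frame_block(mod, roi, phase, times, values, keep=None):
        """Long-format rows for one ROI across patients/visits.

        ``values`` has shape (P, V, T); ``keep`` is a patient mask."""
        T = len(times)
        pidx = np.repeat(np.arange(P), V * T)
        vidx = np.tile(np.repeat(np.arange(V), T), P)
        df = pd.DataFrame({
            "patient_id": pats["patient_id"].to_numpy()[pidx],
            "center_id": centers[pidx],
            "observer_id": pats["observer_id"].to_numpy()[pidx],
            "visit": vidx + 1,
            "modality": mod,
            "roi": roi,
            "phase": phase,
            "time_s": np.tile(times, P * V),
            "value": values.reshape(-1),
            "room_temp_c": room_temp[pidx, vidx],
            "rcs_on_day": rcs[pidx, vidx].astype(int),
        })
        if keep is not None:
            df = df[keep[pidx]]
        return df

    drop_mask = {}
    for mod in design.modalities:
        rate_m = params.missing_rate.get(mod, 0.0)
        drop_mask[mod] = (rng_miss.random(P) >= rate_m) if rate_m > 0 else None

    for mod in design.modalities:
        if mod == "mobile":
            continue
        cv = curves[mod]
        times, extra = design.post_challenge_times(mod)
        all_t = np.r_[times, extra]
        decay = np.exp(-rate_pv[mod][:, :, None] * all_t / 60.0)  # (P, V, T)
        noise_sd = params.noise_sd_frame.get(mod, 0.0)
        keep = drop_mask[mod]
        for fi, roi in enumerate(FINGER_ROIS):
            vals = (cv["plateau_f"][:, :, fi][:, :, None]
                    - params.drop_mean[mod] * decay
                    + rng_frame.normal(0.0, noise_sd, (P, V, len(all_t))))
            blocks.append(frame_block(mod, roi, "post_challenge", all_t,
                                      vals, keep))
            hand = HAND_OF_FINGER[fi + 1]
            base_v = (cv["dorsum"][:, :, None] - cv["ddd_f"][:, :, fi][:, :, None]
                      + rng_frame.normal(0.0, noise_sd, (P, V, 1)))
            blocks.append(frame_block(mod, roi, "baseline",
                                      np.array([_BASELINE_TIME_S]),
                                      base_v, keep))
        for roi in DORSUM_ROIS:
            vals = (cv["dorsum"][:, :, None]
                    + rng_frame.normal(0.0, noise_sd, (P, V, len(all_t))))
            blocks.append(frame_block(mod, roi, "post_challenge", all_t,
                                      vals, keep))
            base_v = (cv["dorsum"][:, :, None]
                      + rng_frame.normal(0.0, noise_sd, (P, V, 1)))
            blocks.append(frame_block(mod, roi, "baseline",
                                      np.array([_BASELINE_TIME_S]),
                                      base_v, keep))

    if "mobile" in design.modalities:
        cv = curves["thermo"]
        times, _ = design.post_challenge_times("mobile")
        decay = np.exp(-rate_pv["thermo"][:, :, None] * times / 60.0)
        noise_sd = params.noise_sd_frame.get("mobile", 0.0)
        keep = drop_mask["mobile"]
        # mobile-specific reading offsets: the cheaper sensor and manual ROI
        # placement make mobile not a perfect copy of the thermography truth.
        # Mobile also gets its own visit-level deviations (replacing the
        # thermography ones) — visit effects are modality-specific for all
        # three modalities, matching the independent-residual structure the
        # validity model assumes
        mob_ap = rng_lat.normal(0.0, math.sqrt(
            params.sigma2_patient.get(("mobile", "max"), 0.0)), P)
        mob_ad = rng_lat.normal(0.0, math.sqrt(
            params.sigma2_patient.get(("mobile", "ddd"), 0.0)), P)
        mob_ep = rng_visit.normal(0.0, math.sqrt(
            params.sigma2_visit.get(("mobile", "max"), 0.0)), (P, V))
        mob_ed = rng_visit.normal(0.0, math.sqrt(
            params.sigma2_visit.get(("mobile", "ddd"), 0.0)), (P, V))
        plat_off = (mob_ap[:, None] + mob_ep - e_plateau["thermo"])[:, :, None]
        ddd_off = (mob_ad[:, None] + mob_ed - e_ddd["thermo"])[:, :, None]
        truth_cols["patient_effect_mobile"] = mob_ap
        truth_cols["patient_effect_ddd_mobile"] = mob_ad
        for fi, roi in enumerate(FINGER_ROIS):
            vals = (cv["plateau_f"][:, :, fi][:, :, None] + plat_off
                    - params.drop_mean["thermo"] * decay
                    + rng_frame.normal(0.0, noise_sd, (P, V, len(times))))
            blocks.append(frame_block("mobile", roi, "post_challenge",
                                      times, vals, keep))
            base_v = (cv["dorsum"][:, :, None] + plat_off
                      - cv["ddd_f"][:, :, fi][:, :, None] - ddd_off
                      + rng_frame.normal(0.0, noise_sd, (P, V, 1)))
            blocks.append(frame_block("mobile", roi, "baseline",
                                      np.array([_BASELINE_TIME_S]),
                                      base_v, keep))
        for roi in DORSUM_ROIS:
            vals = (cv["dorsum"][:, :, None] + plat_off
                    + rng_frame.normal(0.0, noise_sd, (P, V, len(times))))
            blocks.append(frame_block("mobile", roi, "post_challenge",
                                      times, vals, keep))
            base_v = (cv["dorsum"][:, :, None] + plat_off
                      + rng_frame.normal(0.0, noise_sd, (P, V, 1)))
            blocks.append(frame_block("mobile", roi, "baseline",
                                      np.array([_BASELINE_TIME_S]),
                                      base_v, keep))

    frames = pd.concat(blocks, ignore_index=True)
    frames = frames.sort_values(
        ["patient_id", "visit", "modality", "roi", "phase", "time_s"],
        kind="stable", ignore_index=True)
    truth = pd.DataFrame(truth_cols)
    return frames, truth


def downsample_mobile(series: pd.DataFrame) -> pd.DataFrame:
    """Reduce a full ROI series to the three mobile-thermography images.

    ``series`` is a frame-level table for a single ROI series containing a
    baseline row and post-challenge rows covering [0, 900] s.  The result
    keeps the baseline value and the post-challenge values at the frames
    nearest 0 s and 900 s, relabeled as the ``mobile`` modality.
    """
    base = series[series["phase"] == "baseline"]
    post = series[series["phase"] == "post_challenge"].sort_values("time_s")
    if base.empty or post.empty:
        raise ValueError("series must contain baseline and post-challenge rows")
    tmax = post["time_s"].max()
    if tmax < POST_WINDOW_S:
        raise ValueError(
            f"post-challenge series ends at {tmax} s; must cover 900 s")
    picks = []
    for target in (0.0, POST_WINDOW_S):
        i = (post["time_s"] - target).abs().idxmin()
        picks.append(post.loc[[i]])
    out = pd.concat([base.iloc[[0]]] + picks, ignore_index=True)
    out["modality"] = "mobile"
    return out


def simulate_reanalysis(summaries: pd.DataFrame, bias: float = 0.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        columns: tuple[str, ...] = ("ddd", "auc", "max_value",
                                                    "grad")) -> pd.DataFrame:
    """Emulate a second observer re-analyzing the same saved images.

    Adds ``bias`` plus independent N(0, noise_sd) reading noise to the
    summary columns (log columns are recomputed downstream if needed).
    """
    rng = np.random.default_rng(seed)
    out = summaries.copy()
    out["observer_id"] = "obs_central"
    for col in columns:
        if col in out.columns:
            vals = out[col].to_numpy(dtype=float, copy=True)
            ok = np.isfinite(vals)
            vals[ok] = vals[ok] + bias + rng.normal(0.0, noise_sd, ok.sum())
            out[col] = vals
    for raw, logged in (("auc", "auc_log"), ("max_value", "max_log")):
        if raw in out.columns and logged in out.columns:
            with np.errstate(invalid="ignore", divide="ignore"):
                out[logged] = np.where(out[raw] > 0, np.log(out[raw]), np.nan)
    return out


# ---------------------------------------------------------------------------
# summary-level generators (exact variance components)
# ---------------------------------------------------------------------------

def simulate_summary_measures(design: StudyDesign | None = None, *,
                              measure: str = "auc_log",
                              modalities: tuple[str, ...] = ("lsci", "thermo"),
                              sigma2_patient=1.0, sigma2_visit=1.0,
                              rho=0.0, mu=None, center_effects=None,
                              rcs_effect: float = 0.0,
                              room_temp_effect: float = 0.0,
                              seed: int = 0) -> pd.DataFrame:
    """Draw finger-averaged summary measures straight from the latent model.

    value[p, v, m] = mu_m + center[c(p), m] + a[p, m] + beta_T*(T[p,v]-23)
                     + beta_RCS*(RCS[p,v]-5) + e[p, v, m]

    with ``a`` multivariate normal across modalities (variances
    ``sigma2_patient``, correlations ``rho``) and independent visit residuals
    ``e``.  Scalars are broadcast across modalities.  Returns a table shaped
    like the output of the summary pipeline, with the measure in a column
    named after it.
    """
    design = design or StudyDesign()
    mods = list(modalities)
    m = len(mods)

    def as_map(x):
        return {mod: float(x[mod] if isinstance(x, dict) else x)
                for mod in mods}

    s2p, s2v = as_map(sigma2_patient), as_map(sigma2_visit)
    mu = as_map(mu if mu is not None else 0.0)
    R = correlation_matrix(mods, rho)
    check_psd_correlation(R, mods)
    sd = np.sqrt([s2p[mod] for mod in mods])
    cov = R * np.outer(sd, sd)
    rng_lat, rng_visit, rng_day = _seed_streams(seed, 3)
    pats = design.patient_table()
    P, V = design.n_patients, design.n_visits
    centers = pats["center_id"].to_numpy()
    # patient effects with exact target covariance structure
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
    a = rng_lat.standard_normal((P, m)) @ L.T
    room = rng_day.normal(design.room_temp_mean_c, design.room_temp_sd_c,
                          (P, V))
    # RCS independent of the patient effects: the injected rcs_effect path
    # is then the only association, so recovery experiments are well-posed
    rcs = np.clip(np.round(5.0 + rng_day.normal(0, 1.8, (P, V))), 0, 10)
    rows = []
    for j, mod in enumerate(mods):
        ce = np.zeros(P)
        if center_effects:
            ce = np.array([center_effects.get((c, mod), 0.0) for c in centers])
        e = rng_visit.normal(0.0, math.sqrt(s2v[mod]), (P, V))
        val = (mu[mod] + ce[:, None] + a[:, j][:, None]
               + room_temp_effect * (room - design.room_temp_mean_c)
               + rcs_effect * (rcs - 5.0) + e)
        pidx = np.repeat(np.arange(P), V)
        vidx = np.tile(np.arange(V), P)
        rows.append(pd.DataFrame({
            "patient_id": pats["patient_id"].to_numpy()[pidx],
            "center_id": centers[pidx],
            "observer_id": pats["observer_id"].to_numpy()[pidx],
            "visit": vidx + 1,
            "modality": mod,
            measure: val[pidx, vidx],
            "room_temp_c": room[pidx, vidx],
            "rcs_on_day": rcs[pidx, vidx].astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_finger_measures(design: StudyDesign | None = None, *,
                             modalities: tuple[str, ...] = ("lsci", "thermo"),
                             edge_slope=0.0, sigma2_patient: float = 0.5,
                             sigma2_slope: float = 0.02,
                             sigma2_visit: float = 0.3,
                             n_fingers: int = 4, mu: float = 0.0,
                             seed: int = 0) -> pd.DataFrame:
    """Finger-level summary measures with a linear finger-position trend.

    value = mu + a_p + (edge_slope_m + s_p) * (finger - center) + e, with
    per-patient random intercept ``a_p`` and random slope ``s_p``; both
    hands contribute as replicate runs of fingers 1..n_fingers.
    """
    design = design or StudyDesign()
    mods = list(modalities)
    slope = {mod: float(edge_slope[mod] if isinstance(edge_slope, dict)
                        else edge_slope) for mod in mods}
    rng_lat, rng_visit = _seed_streams(seed, 2)
    pats = design.patient_table()
    P, V = design.n_patients, design.n_visits
    fingers = np.arange(1, n_fingers + 1, dtype=float)
    fc = fingers - fingers.mean()
    rows = []
    for mod in mods:
        a = rng_lat.normal(0.0, math.sqrt(sigma2_patient), P)
        s = rng_lat.normal(0.0, math.sqrt(sigma2_slope), P)
        for hand in ("left", "right"):
            e = rng_visit.normal(0.0, math.sqrt(sigma2_visit),
                                 (P, V, n_fingers))
            val = (mu + a[:, None, None]
                   + (slope[mod] + s[:, None, None]) * fc[None, None, :] + e)
            pidx = np.repeat(np.arange(P), V * n_fingers)
            vidx = np.tile(np.repeat(np.arange(V), n_fingers), P)
            fidx = np.tile(np.arange(n_fingers), P * V)
            rows.append(pd.DataFrame({
                "patient_id": pats["patient_id"].to_numpy()[pidx],
                "center_id": pats["center_id"].to_numpy()[pidx],
                "visit": vidx + 1,
                "modality": mod,
                "hand": hand,
                "finger_number": fingers[fidx].astype(int),
                "value": val[pidx, vidx, fidx],
            }))
    return pd.concat(rows, ignore_index=True)
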