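"""End-to-end orchestration: simulate -> summarize -> reliability ->
validity -> secondary analyses, with a serialized config, a run manifest
and report tables shaped like the study's main results table (rows = DDD,
AUC_log, MAX_log, GRAD; reliability columns per modality plus the
LSCI-thermography ICC difference; validity columns per modality pair, with
not-applicable cells marked NA).

All randomness flows from one top-level seed split into named substreams
(simulation, reliability bootstrap, validity bootstrap, observer
re-analysis), so component results are individually reproducible and a
rerun with the same config and seed writes byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_roi_timeseries, write_roi_timeseries, write_summary
from .reliability import estimate_icc, icc_difference
from .secondary import (edge_effect_trend, interobserver_difference,
                        room_temperature_adjustment)
from .simulate import (GeneratorParams, StudyDesign, generate_study,
                       simulate_reanalysis)
from .summaries import summarize_dataset, summarize_fingers
from .validity import estimate_latent_correlation, rcs_association

log = logging.getLogger("rewarm")

#: (measure, modality) combinations that the acquisition cannot support
NOT_APPLICABLE = {("max_log", "mobile"), ("grad", "mobile")}

DEFAULT_MEASURES = ("ddd", "auc_log", "max_log", "grad")
DEFAULT_PAIRS = (("lsci", "thermo"), ("thermo", "mobile"), ("lsci", "mobile"))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (serialized into the output)."""

    out_dir: str = "rewarm_run"
    seed: int = 0
    input_csv: str | None = None        # if None, simulate a study
    modalities: tuple[str, ...] = ("lsci", "thermo", "mobile")
    measures: tuple[str, ...] = DEFAULT_MEASURES
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    n_boot_reliability: int = 500
    n_boot_validity: int = 200
    grad_window_s: float = 120.0
    grad_method: str = "ols"
    room_temp_adjustment: bool = True
    edge_effects: bool = True
    observer_comparison: bool = True
    observer_noise_sd: float = 0.05     # re-analysis reading noise (z-ish)
    write_frames: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.pairs = tuple(tuple(p) for p in cfg.pairs)
        cfg.measures = tuple(cfg.measures)
        cfg.modalities = tuple(cfg.modalities)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.canonical(), fh, sort_keys=True)

    def canonical(self) -> dict:
        d = asdict(self)
        d["pairs"] = [list(p) for p in self.pairs]
        d["measures"] = list(self.measures)
        d["modalities"] = list(self.modalities)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()).hexdigest()


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", na_rep="NA")


def _measure_available(summaries, measure, modality) -> bool:
    if (measure, modality) in NOT_APPLICABLE:
        return False
    sub = summaries[summaries["modality"] == modality]
    if sub.empty:
        return False
    return int(np.isfinite(sub[measure].astype(float)).sum()) >= 4


def run_full_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the whole pipeline; returns the result tables and writes them
    (plus config + manifest) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    seed_sim, seed_rel, seed_val, seed_obs = _seeds(config.seed, 4)

    if config.input_csv:
        log.info("reading frames from %s", config.input_csv)
        frames = read_roi_timeseries(config.input_csv)
    else:
        log.info("simulating default study (seed %d)", seed_sim)
        design = StudyDesign(modalities=tuple(config.modalities))
        frames, truth = generate_study(design, GeneratorParams(),
                                       seed=seed_sim)
        _fmt(truth, out / "truth.csv")
        if config.write_frames:
            write_roi_timeseries(frames, out / "frames.csv")

    summaries = summarize_dataset(frames, config.grad_window_s,
                                  config.grad_method)
    write_summary(summaries, out / "summaries.csv")
    modalities = [m for m in config.modalities
                  if m in set(summaries["modality"])]
    results: dict[str, pd.DataFrame] = {"summaries": summaries}

    # reliability ----------------------------------------------------------
    rel_rows = []
    for i, measure in enumerate(config.measures):
        for j, mod in enumerate(modalities):
            if not _measure_available(summaries, measure, mod):
                rel_rows.append({"measure": measure, "modality": mod,
                                 "icc": np.nan, "ci_low": np.nan,
                                 "ci_high": np.nan, "n_patients": np.nan,
                                 "classification": "NA"})
                continue
            r = estimate_icc(summaries, measure, mod,
                             n_boot=config.n_boot_reliability,
                             seed=seed_rel + 97 * i + j)
            rel_rows.append({"measure": measure, "modality": mod,
                             "icc": r.icc, "ci_low": r.ci_low,
                             "ci_high": r.ci_high,
                             "n_patients": r.n_patients,
                             "classification": r.classification})
    reliability = pd.DataFrame(rel_rows)
    results["reliability"] = reliability

    diff_rows = []
    if {"lsci", "thermo"} <= set(modalities):
        for i, measure in enumerate(config.measures):
            if not (_measure_available(summaries, measure, "lsci")
                    and _measure_available(summaries, measure, "thermo")):
                continue
            d, (lo, hi) = icc_difference(
                summaries, measure, "lsci", "thermo",
                n_boot=config.n_boot_reliability, seed=seed_rel + 7919 + i)
            diff_rows.append({"measure": measure,
                              "modality_a": "lsci", "modality_b": "thermo",
                              "icc_diff": d, "ci_low": lo, "ci_high": hi})
    results["icc_differences"] = pd.DataFrame(diff_rows)

    # validity -------------------------------------------------------------
    val_rows = []
    for i, pair in enumerate(config.pairs):
        if not set(pair) <= set(modalities):
            continue
        for j, measure in enumerate(config.measures):
            if not all(_measure_available(summaries, measure, m)
                       for m in pair):
                val_rows.append({"measure": measure, "pair": "_".join(pair),
                                 "rho": np.nan, "ci_low": np.nan,
                                 "ci_high": np.nan, "n_patients": np.nan})
                continue
            r = estimate_latent_correlation(
                summaries, measure, tuple(pair),
                n_boot=config.n_boot_validity, seed=seed_val + 97 * i + j)
            val_rows.append({"measure": measure, "pair": "_".join(pair),
                             "rho": (np.nan if r.rho is None else r.rho),
                             "ci_low": r.ci_low, "ci_high": r.ci_high,
                             "n_patients": r.n_patients})
    validity = pd.DataFrame(val_rows)
    results["validity"] = validity

    # RCS association --------------------------------------------------------
    rcs_rows = []
    for measure in config.measures:
        for mod in modalities:
            if not _measure_available(summaries, measure, mod):
                continue
            try:
                slope, se = rcs_association(summaries, measure, mod)
            except ValueError:
                continue
            rcs_rows.append({"measure": measure, "modality": mod,
                             "slope": slope, "se": se})
    results["rcs_association"] = pd.DataFrame(rcs_rows)

    # secondary --------------------------------------------------------------
    if config.observer_comparison:
        central = simulate_reanalysis(summaries, bias=0.0,
                                      noise_sd=config.observer_noise_sd,
                                      seed=seed_obs)
        obs_rows = []
        for measure in config.measures:
            for mod in modalities:
                if not _measure_available(summaries, measure, mod):
                    continue
                oc = interobserver_difference(summaries, central, measure, mod)
                obs_rows.append({"measure": measure, "modality": mod,
                                 "mean_diff": oc.mean_diff,
                                 "ci_low": oc.ci_low, "ci_high": oc.ci_high,
                                 "n_patients": oc.n_patients})
        results["observer_comparison"] = pd.DataFrame(obs_rows)

    if config.room_temp_adjustment:
        rt_rows = []
        for measure in config.measures:
            for mod in modalities:
                if not _measure_available(summaries, measure, mod):
                    continue
                rt = room_temperature_adjustment(summaries, measure, mod)
                rt_rows.append({
                    "measure": measure, "modality": mod,
                    "icc_unadjusted": rt.unadjusted.icc,
                    "icc_adjusted": (np.nan if rt.adjusted is None
                                     else rt.adjusted.icc),
                    "temp_coefficient": rt.temp_coefficient,
                    "skipped": rt.skipped})
        results["room_temperature"] = pd.DataFrame(rt_rows)

    if config.edge_effects:
        fingers = summarize_fingers(frames, config.grad_window_s,
                                    config.grad_method)
        tr_rows = []
        for mod in modalities:
            if mod == "mobile":
                continue
            for measure in ("auc", "max_value", "grad"):
                sub = fingers[fingers["modality"] == mod]
                if not np.isfinite(sub[measure].astype(float)).any():
                    continue
                tr = edge_effect_trend(fingers, measure, mod)
                tr_rows.append({"modality": mod, "measure": measure,
                                "slope_std": tr.slope_std,
                                "ci_low": tr.ci_low, "ci_high": tr.ci_high,
                                "random_slope_var": tr.random_slope_var})
        results["edge_trends"] = pd.DataFrame(tr_rows)

    # write ------------------------------------------------------------------
    for name in ("reliability", "icc_differences", "validity",
                 "rcs_association", "observer_comparison",
                 "room_temperature", "edge_trends"):
        if name in results:
            _fmt(results[name], out / f"{name}.csv")
    config.to_yaml(out / "config.yaml")
    manifest = {"seed": config.seed, "config_sha256": config.digest(),
                "rewarm_version": __version__,
                "n_summary_rows": int(len(summaries)),
                "tables": sorted(results.keys())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return results
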