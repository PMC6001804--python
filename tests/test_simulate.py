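"""Tests for the synthetic multicenter study generator."""

import math

import numpy as np
import pandas as pd
import pytest

from rewarm.simulate import (FINGER_ROIS, GeneratorParams, ROI_LABELS,
                             StudyDesign, downsample_mobile, generate_study,
                             rewarming_curve, simulate_finger_measures,
                             simulate_summary_measures)
from rewarm.summaries import summarize_dataset, summarize_fingers


class TestStudyDesign:
    def test_default_frame_counts(self, paper_design):
        lsci, lsci_extra = paper_design.post_challenge_times("lsci")
        thermo, thermo_extra = paper_design.post_challenge_times("thermo")
        mobile, _ = paper_design.post_challenge_times("mobile")
        assert len(lsci) == 225 and lsci[0] == 4.0 and lsci[-1] == 900.0
        assert lsci_extra == 904.0
        assert len(thermo) == 61 and thermo[0] == 0.0 and thermo[-1] == 900.0
        assert thermo_extra == 915.0
        assert list(mobile) == [0.0, 900.0]

    def test_patient_allocation(self, paper_design):
        assert paper_design.n_patients == 159
        tab = paper_design.patient_table()
        assert tab.groupby("center_id").size()["C1"] == 60

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(n_centers=2, patients_per_center=(5,))
        with pytest.raises(ValueError):
            StudyDesign(duration_min=0.0)
        with pytest.raises(ValueError):
            StudyDesign(patients_per_center=(0,) + (20,) * 5)


class TestRewarmingCurve:
    def test_value_at_zero(self):
        assert rewarming_curve(0.0, 32.0, 8.0, 1.7) == pytest.approx(24.0)

    def test_zero_rate_constant(self):
        t = np.linspace(0, 900, 61)
        assert np.allclose(rewarming_curve(t, 32.0, 8.0, 0.0), 24.0)

    def test_closed_form_one_minute(self):
        # independent evaluation of the exponential at t = 60 s
        expected = 32.0 - 8.0 * math.exp(-1.0)
        assert rewarming_curve(60.0, 32.0, 8.0, 1.0) == pytest.approx(
            expected, rel=1e-14)

    def test_monotone_nondecreasing(self):
        t = np.linspace(0, 900, 200)
        v = rewarming_curve(t, 31.0, 7.0, 0.4)
        assert np.all(np.diff(v) >= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rewarming_curve(-1.0, 31.0, 7.0, 0.4)


class TestGenerateStudy:
    def test_deterministic_given_seed(self, small_design):
        f1, t1 = generate_study(small_design, GeneratorParams(), seed=7)
        f2, t2 = generate_study(small_design, GeneratorParams(), seed=7)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_every_group_has_all_rois(self, small_study, small_design):
        frames, _ = small_study
        counts = frames.groupby(["patient_id", "visit", "modality"])["roi"] \
                       .nunique()
        assert (counts == 10).all()
        assert set(frames["roi"].unique()) == set(ROI_LABELS)
        n_groups = (small_design.n_patients * small_design.n_visits
                    * len(small_design.modalities))
        assert len(counts) == n_groups

    def test_zero_visit_noise_gives_identical_visits(self, small_design):
        params = GeneratorParams()
        params.sigma2_visit = {k: 0.0 for k in params.sigma2_visit}
        params.noise_sd_frame = {k: 0.0 for k in params.noise_sd_frame}
        params.sigma2_finger = {k: 0.0 for k in params.sigma2_finger}
        params.rate_sd_visit = 0.0
        frames, _ = generate_study(small_design, params, seed=3)
        # everything that varies between visits (visit effects, per-finger
        # scatter, frame noise, rate wobble) is off: visits must agree
        summ = summarize_dataset(frames)
        v1 = summ[summ.visit == 1].set_index(["patient_id", "modality"])
        v2 = summ[summ.visit == 2].set_index(["patient_id", "modality"])
        for col in ("auc", "max_value", "grad"):
            a, b = v1[col].sort_index(), v2[col].sort_index()
            ok = np.isfinite(a)
            assert np.allclose(a[ok], b[ok], rtol=1e-12)

    def test_negative_variance_rejected(self, small_design):
        params = GeneratorParams()
        params.sigma2_patient[("lsci", "max")] = -1.0
        with pytest.raises(ValueError, match="negative"):
            generate_study(small_design, params, seed=0)

    def test_bad_rho_names_offending_pair(self, small_design):
        params = GeneratorParams()
        params.rho_latent[("lsci", "thermo")] = 1.5
        with pytest.raises(ValueError, match="lsci-thermo"):
            generate_study(small_design, params, seed=0)

    def test_missingness_drops_whole_patient_datasets(self, small_design):
        params = GeneratorParams(missing_rate={"mobile": 0.5})
        frames, _ = generate_study(small_design, params, seed=5)
        by_mod = frames.groupby("modality")["patient_id"].nunique()
        assert by_mod["mobile"] < by_mod["thermo"]
        # remaining mobile patients still have complete ROI sets
        mob = frames[frames["modality"] == "mobile"]
        assert (mob.groupby(["patient_id", "visit"])["roi"].nunique() == 10).all()

    def test_edge_effect_sign_on_noise_free_data(self):
        design = StudyDesign(n_centers=1, patients_per_center=(40,),
                             modalities=("lsci", "thermo"))
        params = GeneratorParams()
        params.noise_sd_frame = {k: 0.0 for k in params.noise_sd_frame}
        params.sigma2_finger = {k: 0.0 for k in params.sigma2_finger}
        frames, _ = generate_study(design, params, seed=9)
        fingers = summarize_fingers(frames)
        mean_auc = fingers.groupby(["modality", "finger_position"])["auc"] \
                          .mean().unstack("finger_position")
        # per-finger mean AUC monotone decreasing in position for LSCI
        # (negative edge slope), increasing for thermography (positive)
        assert np.all(np.diff(mean_auc.loc["lsci"]) < 0)
        assert np.all(np.diff(mean_auc.loc["thermo"]) > 0)


class TestVarianceStructure:
    """Empirical checks that the generator injects the prescribed components."""

    @staticmethod
    def _noise_free_params():
        params = GeneratorParams()
        params.noise_sd_frame = {k: 0.0 for k in params.noise_sd_frame}
        params.sigma2_finger = {k: 0.0 for k in params.sigma2_finger}
        params.edge_slope = {}
        params.rate_sd_patient = 0.0
        params.rate_sd_visit = 0.0
        return params

    def test_max_variance_decomposition(self):
        # MAX inherits the plateau-shift components 1:1; the sample variance
        # of a variance needs a large cohort to sit well inside 10%
        design = StudyDesign(n_centers=1, patients_per_center=(1200,),
                             modalities=("thermo",))
        params = self._noise_free_params()
        frames, _ = generate_study(design, params, seed=21)
        summ = summarize_dataset(frames)
        wide = summ.pivot(index="patient_id", columns="visit",
                          values="max_value")
        between = wide.mean(axis=1).var(ddof=1)
        within = ((wide[1] - wide[2]) ** 2 / 2.0).mean()
        s2p = params.sigma2_patient[("thermo", "max")]
        s2v = params.sigma2_visit[("thermo", "max")]
        assert within == pytest.approx(s2v, rel=0.10)
        assert between - within / 2 == pytest.approx(s2p, rel=0.10)

    def test_auc_inherits_scaled_components(self):
        # a vertical plateau shift of delta moves the AUC by 900*delta
        design = StudyDesign(n_centers=1, patients_per_center=(800,),
                             modalities=("thermo",))
        params = self._noise_free_params()
        frames, _ = generate_study(design, params, seed=22)
        summ = summarize_dataset(frames)
        wide = summ.pivot(index="patient_id", columns="visit", values="auc")
        within = ((wide[1] - wide[2]) ** 2 / 2.0).mean()
        s2v = params.sigma2_visit[("thermo", "max")] * 900.0 ** 2
        assert within == pytest.approx(s2v, rel=0.15)

    def test_latent_correlation_matches_rho(self):
        design = StudyDesign(n_centers=1, patients_per_center=(600,),
                             modalities=("lsci", "thermo"))
        params = self._noise_free_params()
        frames, _ = generate_study(design, params, seed=21)
        summ = summarize_dataset(frames)
        wide = summ.pivot_table(index="patient_id", columns="modality",
                                values="max_value")
        r = np.corrcoef(wide["lsci"], wide["thermo"])[0, 1]
        rho = params.rho_latent[("lsci", "thermo")]
        # patient means include visit noise, attenuating r slightly
        s2p = params.sigma2_patient[("thermo", "max")]
        atten = math.sqrt(
            s2p / (s2p + params.sigma2_visit[("thermo", "max")] / 2)) * \
            math.sqrt(1225.0 / (1225.0 + 625.0 / 2))
        assert r == pytest.approx(rho * atten, abs=0.05)


class TestDownsampleMobile:
    def _series(self, values=None):
        t = np.arange(0.0, 916.0, 15.0)
        v = values if values is not None else np.full(len(t), 30.0)
        post = pd.DataFrame({"patient_id": "P1", "visit": 1,
                             "modality": "thermo", "roi": "finger_1",
                             "phase": "post_challenge", "time_s": t,
                             "value": v})
        base = pd.DataFrame({"patient_id": ["P1"], "visit": [1],
                             "modality": ["thermo"], "roi": ["finger_1"],
                             "phase": ["baseline"], "time_s": [-60.0],
                             "value": [25.0]})
        return pd.concat([base, post], ignore_index=True)

    def test_grid_contains_targets(self):
        out = downsample_mobile(self._series())
        post = out[out["phase"] == "post_challenge"]
        assert sorted(post["time_s"]) == [0.0, 900.0]
        assert (out["modality"] == "mobile").all()

    def test_constant_series_preserved(self):
        out = downsample_mobile(self._series())
        assert set(out[out.phase == "post_challenge"]["value"]) == {30.0}

    def test_linear_series_values(self):
        t = np.arange(0.0, 916.0, 15.0)
        out = downsample_mobile(self._series(values=t.copy()))
        post = out[out["phase"] == "post_challenge"].sort_values("time_s")
        assert post["value"].tolist() == [0.0, 900.0]

    def test_short_series_rejected(self):
        s = self._series()
        s = s[s["time_s"] < 500.0]
        with pytest.raises(ValueError, match="900"):
            downsample_mobile(s)


class TestSummaryLevelGenerators:
    def test_exact_components_at_scale(self):
        design = StudyDesign(n_centers=1, patients_per_center=(800,))
        df = simulate_summary_measures(
            design, measure="auc_log", modalities=("lsci", "thermo"),
            sigma2_patient=0.67, sigma2_visit=0.33, rho=0.94, seed=5)
        for mod in ("lsci", "thermo"):
            wide = df[df.modality == mod].pivot(
                index="patient_id", columns="visit", values="auc_log")
            within = ((wide[1] - wide[2]) ** 2 / 2.0).mean()
            between = wide.mean(axis=1).var(ddof=1) - within / 2
            assert within == pytest.approx(0.33, rel=0.1)
            assert between == pytest.approx(0.67, rel=0.1)

    def test_rho_one_duplicates_construct(self):
        design = StudyDesign(n_centers=1, patients_per_center=(500,))
        df = simulate_summary_measures(
            design, measure="auc_log", modalities=("lsci", "thermo"),
            sigma2_patient=1.0, sigma2_visit=0.0, rho=1.0, seed=6)
        wide = df.pivot_table(index="patient_id", columns="modality",
                              values="auc_log")
        r = np.corrcoef(wide["lsci"], wide["thermo"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_pairwise_rhos_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_summary_measures(
                StudyDesign(), measure="auc_log",
                modalities=("lsci", "thermo", "mobile"),
                rho={("lsci", "thermo"): 0.95, ("mobile", "thermo"): 0.95,
                     ("lsci", "mobile"): -0.9}, seed=0)

    def test_finger_measures_shape_and_trend(self):
        df = simulate_finger_measures(
            StudyDesign(n_centers=1, patients_per_center=(300,)),
            modalities=("lsci",), edge_slope=-0.3, sigma2_visit=0.01,
            sigma2_slope=0.0, seed=4)
        by_finger = df.groupby("finger_number")["value"].mean()
        slopes = np.diff(by_finger.to_numpy())
        assert np.all(slopes < 0)
        assert by_finger.index.tolist() == [1, 2, 3, 4]
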