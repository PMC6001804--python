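"""Shared fixtures: small simulated studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from rewarm.simulate import (GeneratorParams, StudyDesign, generate_study,
                             simulate_summary_measures)


@pytest.fixture(scope="session")
def small_design():
    """Two centers, a handful of patients, all modalities; fast to simulate."""
    return StudyDesign(n_centers=2, patients_per_center=(6, 5))


@pytest.fixture(scope="session")
def small_study(small_design):
    frames, truth = generate_study(small_design, GeneratorParams(), seed=11)
    return frames, truth


@pytest.fixture(scope="session")
def paper_design():
    """The full multicenter design: 159 patients over 6 centers."""
    return StudyDesign()


@pytest.fixture(scope="session")
def summary_pair():
    """Summary-level bivariate dataset with known generating truth."""
    truth = {"rho": 0.8, "s2p": {"lsci": 2.0, "thermo": 1.0},
             "s2v": {"lsci": 1.0, "thermo": 0.5}}
    df = simulate_summary_measures(
        StudyDesign(), measure="auc_log", modalities=("lsci", "thermo"),
        sigma2_patient=truth["s2p"], sigma2_visit=truth["s2v"],
        rho=truth["rho"],
        center_effects={("C2", "lsci"): 0.5, ("C3", "thermo"): -0.4},
        seed=202)
    return df, truth


def linear_series(m=0.01, b=20.0, step=15.0, t_end=900.0):
    t = np.arange(0.0, t_end + step / 2, step)
    return t, m * t + b
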