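"""Shared fixtures: small synthetic cohorts and extracted feature tables.

Heavy cohorts are session-scoped so the cost of generation and feature
extraction is paid once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import mentalload as ml

#: compact protocol for unit tests: long enough for spectral features
#: (>= 2 LF cycles per analysis window) but far shorter than the defaults
SHORT_DURATIONS = {"BL": 120.0, "Forward": 60.0, "Backward": 60.0,
                   "ImmR": 60.0, "DelR": 60.0, "Rec": 60.0}


def short_config(**kwargs) -> ml.SynthConfig:
    kwargs.setdefault("phase_durations", dict(SHORT_DURATIONS))
    kwargs.setdefault("n_subjects", 6)
    kwargs.setdefault("seed", 0)
    return ml.SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, shortened phases, default effect structure."""
    return ml.generate_cohort(short_config())


@pytest.fixture(scope="session")
def default_cohort():
    """One full default cohort: 26 subjects, default durations/effects."""
    return ml.generate_cohort(ml.SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return ml.extract_features(default_cohort)


@pytest.fixture(scope="session")
def dst_ir_table(default_features):
    return ml.assemble(default_features, "DST", "ir")


@pytest.fixture(scope="session")
def dst_table(default_features):
    return ml.assemble(default_features, "DST", "multimodal")


@pytest.fixture(scope="session")
def ravlt_table(default_features):
    return ml.assemble(default_features, "RAVLT", "multimodal")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
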