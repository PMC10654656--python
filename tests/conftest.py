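"""Shared fixtures: small calibrations, bead maps and synthetic lanes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from digiwest.calibration import fit_calibration
from digiwest.model import N_FRACTIONS, BeadMap, FractionProfile


@pytest.fixture
def simple_cal():
    """Two-anchor log-linear calibration spanning the whole lane."""
    return fit_calibration([(0, 250.0), (95, 10.0)])


@pytest.fixture
def identity_beadmap():
    """Color id ``c{k}`` maps to fraction k."""
    return BeadMap({f"c{k}": k for k in range(N_FRACTIONS)})


@pytest.fixture
def reversed_beadmap():
    return BeadMap({f"c{k}": N_FRACTIONS - 1 - k for k in range(N_FRACTIONS)})


def make_lane_rows(values, sample_id="s1", antibody_id="ab1", prefix="c"):
    """Readout rows for one lane under the identity bead map."""
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "antibody_id": antibody_id,
            "color_id": [f"{prefix}{k}" for k in range(len(values))],
            "mfi": np.asarray(values, dtype=float),
        }
    )


def gaussian_lane(center_frac, amplitude, width, baseline=0.0):
    """Noiseless lane: baseline plus one Gaussian peak in fraction space."""
    x = np.arange(N_FRACTIONS, dtype=float)
    return baseline + amplitude * np.exp(-0.5 * ((x - center_frac) / width) ** 2)


@pytest.fixture
def flat_profile():
    def _make(value, sample_id="s1", antibody_id="ab1"):
        return FractionProfile(
            sample_id, antibody_id, np.full(N_FRACTIONS, float(value))
        )

    return _make
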