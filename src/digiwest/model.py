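"""Core data types for DigiWest lane quantification.

A DigiWest run digitises one Western-blot lane into 96 molecular-weight
(MW) fractions, each coupled to a distinct color-coded bead set and read
out as a median fluorescence intensity (MFI).  The types here carry the
raw readout, the bead-color-to-fraction map, reconstructed lane profiles,
antibody panel definitions, detected peaks and per-marker calls.

Conventions fixed across the package:

* fraction indices are 0-based; index 0 is the top of the gel (highest
  MW), index 95 the bottom (lowest MW);
* all fluorescence values are in arbitrary units (AU) and non-negative;
* the reserved antibody ids ``EMPTY_BEAD`` and ``SECONDARY_ONLY`` mark
  control incubations carried inside the readout table, keyed either by
  a sample id or by the wildcard sample ``*`` (one control set per run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

N_FRACTIONS = 96

#: reserved antibody ids marking control incubations inside a readout
EMPTY_BEAD = "EMPTY_BEAD"
SECONDARY_ONLY = "SECONDARY_ONLY"
CONTROL_ANTIBODIES = (EMPTY_BEAD, SECONDARY_ONLY)

#: wildcard sample id for run-level (rather than per-sample) controls
WILDCARD_SAMPLE = "*"


class DigiWestError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class BeadMap:
    """Bijective map from bead color id to MW fraction index (0-95)."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        indices = sorted(self.entries.values())
        if indices != list(range(N_FRACTIONS)):
            raise DigiWestError(
                f"bead map must be bijective over exactly {N_FRACTIONS} fractions "
                f"(0-{N_FRACTIONS - 1}); got {len(self.entries)} entries covering "
                f"{len(set(indices))} distinct indices"
            )

    def fraction_of(self, color_id: str) -> int:
        try:
            return self.entries[color_id]
        except KeyError:
            raise DigiWestError(f"unknown color_id {color_id!r} in bead map") from None

    def inverse(self) -> dict[int, str]:
        """fraction index -> color id."""
        return {v: k for k, v in self.entries.items()}


@dataclass
class FractionProfile:
    """One virtual lane: 96 ordered fluorescence values for sample x antibody."""

    sample_id: str
    antibody_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FRACTIONS,):
            raise DigiWestError(
                f"profile for ({self.sample_id}, {self.antibody_id}) must have "
                f"exactly {N_FRACTIONS} values, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DigiWestError(
                f"profile for ({self.sample_id}, {self.antibody_id}) contains "
                "non-finite values"
            )
        if np.any(self.values < 0):
            raise DigiWestError(
                f"profile for ({self.sample_id}, {self.antibody_id}) contains "
                "negative values"
            )


@dataclass(frozen=True)
class AntibodySpec:
    """Panel entry: one antibody, its marker, expected MW band(s), species."""

    antibody_id: str
    marker: str
    expected_mw_kda: tuple[float, ...]
    valid_species: tuple[str, ...] = ()  # empty = valid for every species

    def __post_init__(self) -> None:
        mws = tuple(sorted(float(m) for m in self.expected_mw_kda))
        if not mws:
            raise DigiWestError(
                f"antibody {self.antibody_id!r}: expected_mw_kda must be non-empty"
            )
        if any(m <= 0 for m in mws):
            raise DigiWestError(
                f"antibody {self.antibody_id!r}: expected MWs must be > 0 kDa"
            )
        if len(set(mws)) != len(mws):
            raise DigiWestError(
                f"antibody {self.antibody_id!r}: expected MWs must be distinct"
            )
        object.__setattr__(self, "expected_mw_kda", mws)
        object.__setattr__(self, "valid_species", tuple(self.valid_species))

    def valid_for(self, species: str) -> bool:
        return not self.valid_species or species in self.valid_species


@dataclass(frozen=True)
class SampleMeta:
    """Sample annotation: species, source (milk, MSC, NC, SEC pool, ...)."""

    sample_id: str
    species: str
    source: str = ""
    protein_input_ug: float | None = None


@dataclass
class Baseline:
    """Control-derived background, aligned to the 96 fractions."""

    values: np.ndarray
    provenance: tuple[str, ...]  # which control lanes were used

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FRACTIONS,):
            raise DigiWestError(
                f"baseline must have {N_FRACTIONS} values, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise DigiWestError("baseline values must be >= 0")


@dataclass
class Peak:
    """A detected antibody-specific signal on one lane.

    ``afi`` (accumulated fluorescence intensity) is the sum of the
    baseline-subtracted values over the inclusive boundary window
    ``[left, right]``; ``height`` is the net apex value.
    """

    sample_id: str
    antibody_id: str
    apex_fraction: int
    apex_mw_kda: float
    height: float
    left: int
    right: int
    afi: float
    matched_expected_mw_kda: float | None = None
    mw_shift_kda: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.left <= self.apex_fraction <= self.right < N_FRACTIONS):
            raise DigiWestError(
                f"peak ({self.sample_id}, {self.antibody_id}): boundaries must "
                f"satisfy 0 <= left <= apex <= right < {N_FRACTIONS}; got "
                f"left={self.left} apex={self.apex_fraction} right={self.right}"
            )
        if self.height < 0:
            raise DigiWestError("peak height must be >= 0")


# machine-readable failure reasons for marker calls
REASON_NO_PEAK = "no_peak"
REASON_BELOW_MIN_HEIGHT = "below_min_height"
REASON_BELOW_MIN_AFI = "below_min_afi"
REASON_NO_MW_MATCH = "no_mw_match"
REASON_INCONSISTENT_SHIFT = "inconsistent_shift"

ALL_REASONS = (
    REASON_NO_PEAK,
    REASON_BELOW_MIN_HEIGHT,
    REASON_BELOW_MIN_AFI,
    REASON_NO_MW_MATCH,
    REASON_INCONSISTENT_SHIFT,
)

# detection states in a DetectionMatrix cell
DETECTED = "detected"
NOT_DETECTED = "not_detected"
NOT_APPLICABLE = "na"  # antibody not validated for this sample's species


@dataclass
class MarkerCall:
    """Pass/fail decision for one sample x marker, with failure reasons."""

    sample_id: str
    marker: str
    antibody_id: str
    status: str  # DETECTED | NOT_DETECTED | NOT_APPLICABLE
    reasons: tuple[str, ...] = ()
    peak: Peak | None = None

    def __post_init__(self) -> None:
        if self.status not in (DETECTED, NOT_DETECTED, NOT_APPLICABLE):
            raise DigiWestError(f"unknown call status {self.status!r}")
        if self.status == DETECTED and self.reasons:
            raise DigiWestError("a detected call must carry no failure reasons")
        if self.status == NOT_DETECTED and not self.reasons:
            raise DigiWestError("a not-detected call must carry >= 1 reason")
        unknown = set(self.reasons) - set(ALL_REASONS)
        if unknown:
            raise DigiWestError(f"unknown call reasons: {sorted(unknown)}")

    @property
    def detected(self) -> bool:
        return self.status == DETECTED


@dataclass
class DetectionMatrix:
    """Complete markers x samples grid of MarkerCalls plus sample metadata."""

    samples: tuple[SampleMeta, ...]
    markers: tuple[str, ...]
    calls: dict[tuple[str, str], MarkerCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.markers = tuple(self.markers)
        expected = {(s.sample_id, m) for s in self.samples for m in self.markers}
        if set(self.calls) != expected:
            missing = expected - set(self.calls)
            extra = set(self.calls) - expected
            raise DigiWestError(
                f"detection matrix must hold exactly one call per cell; "
                f"missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}..."
                if missing or extra
                else "inconsistent detection matrix"
            )

    def call(self, sample_id: str, marker: str) -> MarkerCall:
        return self.calls[(sample_id, marker)]

    def detected_markers(self, sample_id: str) -> set[str]:
        return {
            m for m in self.markers if self.calls[(sample_id, m)].status == DETECTED
        }

    def to_frame(self):
        """Markers x samples grid of status strings as a DataFrame."""
        import pandas as pd

        data = {
            s.sample_id: [self.calls[(s.sample_id, m)].status for m in self.markers]
            for s in self.samples
        }
        return pd.DataFrame(data, index=list(self.markers)).rename_axis("marker")


def sorted_profile_key(p: FractionProfile) -> tuple[str, str]:
    return (p.sample_id, p.antibody_id)
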