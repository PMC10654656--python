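"""Marker-acceptance criteria and the detection matrix.

A detected peak only counts as evidence for its marker when it clears
the signal-acceptance rules used for DigiWest EV panels: a minimal peak
height of 50 AU, a minimal AFI of 100 AU (both inclusive), an apex MW
within 10 kDa of an expected band of the antibody, and — when a MW shift
is observed — consistency of that shift across all samples in the run.
Antibodies not validated for a sample's species yield not-applicable
cells rather than not-detected ones.
"""

from __future__ import annotations

from typing import Sequence

from .model import (
    DETECTED,
    NOT_APPLICABLE,
    NOT_DETECTED,
    REASON_BELOW_MIN_AFI,
    REASON_BELOW_MIN_HEIGHT,
    REASON_INCONSISTENT_SHIFT,
    REASON_NO_MW_MATCH,
    REASON_NO_PEAK,
    AntibodySpec,
    DetectionMatrix,
    DigiWestError,
    MarkerCall,
    Peak,
    SampleMeta,
)
from .quantify import match_mw

DEFAULT_MIN_HEIGHT = 50.0
DEFAULT_MIN_AFI = 100.0
DEFAULT_MW_TOL_KDA = 10.0
DEFAULT_SPREAD_KDA = 5.0


def apply_thresholds(
    peak: Peak,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_afi: float = DEFAULT_MIN_AFI,
) -> tuple[bool, tuple[str, ...]]:
    """Signal thresholds: height >= 50 AND AFI >= 100, both inclusive."""
    reasons = []
    if peak.height < min_height:
        reasons.append(REASON_BELOW_MIN_HEIGHT)
    if peak.afi < min_afi:
        reasons.append(REASON_BELOW_MIN_AFI)
    return not reasons, tuple(reasons)


def check_consistency(
    passing_peaks: Sequence[Peak],
    spec: AntibodySpec,
    tol_kda: float = DEFAULT_MW_TOL_KDA,
    spread_kda: float = DEFAULT_SPREAD_KDA,
) -> bool:
    """Cross-sample consistency of the observed MW shift for one antibody.

    Consistent iff every thresholds-passing peak matches an expected MW
    within ``tol_kda`` and the spread of the signed shifts (max - min)
    is at most ``spread_kda``.  Zero passing peaks are vacuously
    consistent (there is nothing to detect anyway).
    """
    shifts = []
    for peak in passing_peaks:
        matched, shift = match_mw(peak.apex_mw_kda, spec, tol_kda=tol_kda)
        if matched is None:
            return False
        shifts.append(shift)
    if not shifts:
        return True
    return max(shifts) - min(shifts) <= spread_kda


def _best_peak(peaks: Sequence[Peak]) -> Peak:
    """Deterministic representative: max AFI, ties to lower apex fraction."""
    return max(peaks, key=lambda p: (p.afi, -p.apex_fraction))


def call_markers(
    peaks: Sequence[Peak],
    panel: Sequence[AntibodySpec],
    samples: Sequence[SampleMeta],
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_afi: float = DEFAULT_MIN_AFI,
    mw_tol_kda: float = DEFAULT_MW_TOL_KDA,
    spread_kda: float = DEFAULT_SPREAD_KDA,
) -> DetectionMatrix:
    """Apply the full acceptance ruleset and assemble the detection matrix.

    A (sample, marker) cell is detected iff the lane holds a peak that
    passes both thresholds, matches an expected MW within tolerance, and
    belongs to an antibody whose shift is consistent across the run's
    samples.  Every not-detected cell carries machine-readable reasons.
    """
    by_ab = {spec.antibody_id: spec for spec in panel}
    unknown = {p.antibody_id for p in peaks} - set(by_ab)
    if unknown:
        raise DigiWestError(
            f"peak table references antibodies missing from the panel: "
            f"{sorted(unknown)}"
        )

    species_of = {s.sample_id: s.species for s in samples}
    peaks_by_cell: dict[tuple[str, str], list[Peak]] = {}
    for p in peaks:
        if p.sample_id not in species_of:
            raise DigiWestError(
                f"peak table references unknown sample {p.sample_id!r}"
            )
        peaks_by_cell.setdefault((p.sample_id, p.antibody_id), []).append(p)

    # per-antibody cross-sample consistency over thresholds-passing peaks
    # from species-valid samples
    consistent: dict[str, bool] = {}
    for ab_id, spec in by_ab.items():
        passing = [
            p
            for p in peaks
            if p.antibody_id == ab_id
            and spec.valid_for(species_of[p.sample_id])
            and apply_thresholds(p, min_height, min_afi)[0]
        ]
        consistent[ab_id] = check_consistency(
            passing, spec, tol_kda=mw_tol_kda, spread_kda=spread_kda
        )

    calls: dict[tuple[str, str], MarkerCall] = {}
    for sample in samples:
        for spec in panel:
            key = (sample.sample_id, spec.marker)
            if not spec.valid_for(sample.species):
                calls[key] = MarkerCall(
                    sample.sample_id, spec.marker, spec.antibody_id, NOT_APPLICABLE
                )
                continue
            cell_peaks = peaks_by_cell.get(
                (sample.sample_id, spec.antibody_id), []
            )
            calls[key] = _call_cell(
                sample.sample_id,
                spec,
                cell_peaks,
                consistent[spec.antibody_id],
                min_height,
                min_afi,
                mw_tol_kda,
            )
    markers = tuple(spec.marker for spec in panel)
    return DetectionMatrix(tuple(samples), markers, calls)


def _call_cell(
    sample_id: str,
    spec: AntibodySpec,
    cell_peaks: Sequence[Peak],
    antibody_consistent: bool,
    min_height: float,
    min_afi: float,
    mw_tol_kda: float,
) -> MarkerCall:
    if not cell_peaks:
        return MarkerCall(
            sample_id, spec.marker, spec.antibody_id, NOT_DETECTED, (REASON_NO_PEAK,)
        )
    # qualifying peaks pass thresholds and match an expected MW
    qualifying = [
        p
        for p in cell_peaks
        if apply_thresholds(p, min_height, min_afi)[0]
        and match_mw(p.apex_mw_kda, spec, tol_kda=mw_tol_kda)[0] is not None
    ]
    if qualifying and antibody_consistent:
        return MarkerCall(
            sample_id,
            spec.marker,
            spec.antibody_id,
            DETECTED,
            peak=_best_peak(qualifying),
        )
    if qualifying:  # blocked only by cross-sample inconsistency
        return MarkerCall(
            sample_id,
            spec.marker,
            spec.antibody_id,
            NOT_DETECTED,
            (REASON_INCONSISTENT_SHIFT,),
            peak=_best_peak(qualifying),
        )
    # explain why the strongest peak fails
    best = _best_peak(cell_peaks)
    _, reasons = apply_thresholds(best, min_height, min_afi)
    if match_mw(best.apex_mw_kda, spec, tol_kda=mw_tol_kda)[0] is None:
        reasons = (*reasons, REASON_NO_MW_MATCH)
    if not antibody_consistent:
        reasons = (*reasons, REASON_INCONSISTENT_SHIFT)
    if not reasons:  # pragma: no cover - defensive; cannot happen
        reasons = (REASON_NO_PEAK,)
    return MarkerCall(
        sample_id, spec.marker, spec.antibody_id, NOT_DETECTED, reasons, peak=best
    )
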