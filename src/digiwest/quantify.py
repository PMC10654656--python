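"""Lane reconstruction, baseline subtraction, peak detection and AFI.

This is the computational heart of the pipeline.  For each sample x
antibody incubation the 96 per-bead-set MFI values are reassigned to
their MW fractions (reconstructing the virtual gel lane), a background
baseline derived from the empty-bead and secondary-antibody-only control
lanes is subtracted, and antibody-specific peaks are searched around
each expected MW of the antibody.  A detected peak is integrated over
its boundary window into the accumulated fluorescence intensity (AFI),
the assay's quantitative readout.

Peak-detection rules (all deterministic):

* for each expected MW ``m`` the search window is every fraction whose
  calibrated MW lies within ``m +/- mw_window_kda`` (default 10 kDa, the
  same tolerance used for MW matching downstream);
* the apex is the local maximum (>= both neighbours; one-sided at the
  lane edges) with the largest net value in the window — ties go to the
  fraction whose MW is closest to ``m``, then to the lower index;
* boundaries extend outward from the apex while the net signal stays
  above ``tau = max(0.05 * height, 10 AU)``, plus one shoulder fraction
  at or below tau when it still carries signal (keeping the peak tails
  in the integral); a local minimum below 50% of the apex height stops
  the extension, so isoform doublets separated by such a valley yield
  two peaks (the valley fraction goes to the taller peak);
* overlapping windows of two expected MWs yield two peaks only when a
  50%-valley separates their apexes, otherwise the single underlying
  band is reported once, matched to the nearer expected MW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import MWCalibration
from .model import (
    EMPTY_BEAD,
    N_FRACTIONS,
    SECONDARY_ONLY,
    WILDCARD_SAMPLE,
    AntibodySpec,
    Baseline,
    BeadMap,
    DigiWestError,
    FractionProfile,
    Peak,
)

logger = logging.getLogger(__name__)

#: boundary-extension floor in AU and as a fraction of apex height
TAU_ABS_AU = 10.0
TAU_REL = 0.05
#: a local minimum below this fraction of apex height splits peaks
VALLEY_SPLIT_REL = 0.5
DEFAULT_MW_WINDOW_KDA = 10.0


def reconstruct_lane(rows: pd.DataFrame, beadmap: BeadMap) -> FractionProfile:
    """Reorder one incubation's bead MFIs into a virtual gel lane.

    ``rows`` must hold exactly the 96 readout rows of one sample x
    antibody; after mapping color ids to fraction indices every fraction
    must occur exactly once.  The operation is a pure permutation: the
    multiset of MFI values is preserved.
    """
    samples = rows["sample_id"].unique()
    antibodies = rows["antibody_id"].unique()
    if len(samples) != 1 or len(antibodies) != 1:
        raise DigiWestError(
            "reconstruct_lane expects rows of exactly one sample x antibody; "
            f"got samples {list(samples)} x antibodies {list(antibodies)}"
        )
    indices = np.array([beadmap.fraction_of(c) for c in rows["color_id"]])
    counts = np.bincount(indices, minlength=N_FRACTIONS)
    if not np.all(counts == 1):
        missing = np.where(counts == 0)[0].tolist()
        duplicated = np.where(counts > 1)[0].tolist()
        raise DigiWestError(
            f"lane ({samples[0]}, {antibodies[0]}): fractions must be covered "
            f"exactly once after bead mapping; missing {missing}, "
            f"duplicated {duplicated}"
        )
    values = np.empty(N_FRACTIONS)
    values[indices] = rows["mfi"].to_numpy(dtype=float)
    return FractionProfile(str(samples[0]), str(antibodies[0]), values)


def _median_smooth3(values: np.ndarray) -> np.ndarray:
    """Window-3 running median; the window shrinks at the lane edges."""
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        out[i] = np.median(values[max(0, i - 1) : i + 2])
    return out


def estimate_baseline(
    empty_bead: FractionProfile | None,
    secondary_only: FractionProfile | None = None,
) -> Baseline:
    """Combine the control lanes into a per-fraction background estimate.

    The bead background (empty beads) and the secondary-antibody-only
    signal both contribute; where both are present the element-wise
    maximum is taken (conservative and order-independent), then the
    result is median-smoothed with window 3 to suppress single-bead
    spikes.
    """
    provenance = []
    parts = []
    if empty_bead is not None:
        parts.append(empty_bead.values)
        provenance.append(EMPTY_BEAD)
    if secondary_only is not None:
        parts.append(secondary_only.values)
        provenance.append(SECONDARY_ONLY)
    if not parts:
        raise DigiWestError("no control lanes: need empty-bead and/or secondary-only")
    combined = parts[0] if len(parts) == 1 else np.maximum(parts[0], parts[1])
    return Baseline(_median_smooth3(combined), tuple(provenance))


def subtract_background(
    profile: FractionProfile, baseline: Baseline
) -> FractionProfile:
    """Net signal ``max(0, profile - baseline)`` per fraction.

    Fractions falling below the baseline are clipped to zero (AFI is an
    accumulated intensity and must stay non-negative); the clip count is
    logged.
    """
    if len(profile.values) != len(baseline.values):
        raise DigiWestError("profile/baseline length mismatch")
    raw = profile.values - baseline.values
    n_clipped = int(np.sum(raw < 0))
    if n_clipped:
        logger.debug(
            "lane (%s, %s): clipped %d negative net fractions to zero",
            profile.sample_id,
            profile.antibody_id,
            n_clipped,
        )
    return FractionProfile(
        profile.sample_id, profile.antibody_id, np.maximum(raw, 0.0)
    )


def _is_local_max(net: np.ndarray, i: int) -> bool:
    left_ok = i == 0 or net[i] >= net[i - 1]
    right_ok = i == len(net) - 1 or net[i] >= net[i + 1]
    return left_ok and right_ok


def _walk_boundary(net: np.ndarray, apex: int, step: int) -> int:
    """Extend a boundary outward from the apex (step = -1 left, +1 right)."""
    height = net[apex]
    tau = max(TAU_REL * height, TAU_ABS_AU)
    valley_floor = VALLEY_SPLIT_REL * height
    j = apex
    while 0 <= j + step < N_FRACTIONS:
        nxt = net[j + step]
        if nxt <= tau:
            # include the first at-or-below-tau shoulder fraction (when it
            # still carries signal) so the integral keeps the peak tails
            if nxt > 0:
                j += step
            break
        # rising again past a sub-50% valley: another peak starts there
        if nxt > net[j] and net[j] < valley_floor:
            break
        j += step
    return j


def integrate_peak(net: FractionProfile | np.ndarray, left: int, right: int) -> float:
    """AFI: sum of net values over the inclusive window [left, right]."""
    values = net.values if isinstance(net, FractionProfile) else np.asarray(net)
    if left > right:
        raise DigiWestError(f"inverted peak boundaries: left={left} > right={right}")
    if left < 0 or right >= len(values):
        raise DigiWestError(
            f"peak boundaries [{left}, {right}] outside 0-{len(values) - 1}"
        )
    # plain sequential accumulation: the reported AFI is bit-identical to
    # a brute-force sum over the window
    total = 0.0
    for v in values[left : right + 1]:
        total += float(v)
    return total


def match_mw(
    apex_mw_kda: float, spec: AntibodySpec, tol_kda: float = DEFAULT_MW_WINDOW_KDA
) -> tuple[float | None, float | None]:
    """Match an apex MW against the antibody's expected band MWs.

    Returns ``(matched_expected_mw, signed_shift)`` where the match is
    the expected MW minimising the absolute distance; it succeeds iff
    that distance is <= ``tol_kda`` (inclusive, per the <=10 kDa rule).
    Equal distances break toward the lower expected MW (the list is
    stored sorted ascending, so the first minimum wins).
    """
    best = min(spec.expected_mw_kda, key=lambda m: abs(apex_mw_kda - m))
    shift = apex_mw_kda - best
    if abs(shift) <= tol_kda:
        return best, shift
    return None, None


@dataclass
class _Candidate:
    apex: int
    height: float
    expected_mw: float


def detect_peaks(
    net: FractionProfile,
    spec: AntibodySpec,
    cal: MWCalibration,
    mw_window_kda: float = DEFAULT_MW_WINDOW_KDA,
) -> list[Peak]:
    """Find antibody-specific peaks near each expected MW of the spec.

    Returns at most one peak per expected MW; an all-zero window yields
    none.  Each returned peak carries its AFI and, when within the
    window tolerance, the matched expected MW and signed shift.
    """
    values = net.values
    frac_mw = np.asarray(cal.fraction_to_mw(np.arange(N_FRACTIONS)))

    candidates: list[_Candidate] = []
    for m in spec.expected_mw_kda:
        window = np.where(np.abs(frac_mw - m) <= mw_window_kda)[0]
        if window.size == 0:
            continue
        best: int | None = None
        for i in window:
            if values[i] <= 0 or not _is_local_max(values, i):
                continue
            if best is None:
                best = i
                continue
            if values[i] > values[best]:
                best = i
            elif values[i] == values[best]:
                d_i = abs(frac_mw[i] - m)
                d_b = abs(frac_mw[best] - m)
                if d_i < d_b or (d_i == d_b and i < best):
                    best = i
        if best is not None:
            candidates.append(_Candidate(int(best), float(values[best]), m))

    # collapse candidates not separated by a sub-50% valley: one band
    # must not be reported once per overlapping expected-MW window
    candidates.sort(key=lambda c: c.apex)
    kept: list[_Candidate] = []
    for cand in candidates:
        if not kept:
            kept.append(cand)
            continue
        prev = kept[-1]
        if cand.apex == prev.apex or not _split_between(values, prev, cand):
            # same underlying band: keep the taller apex (ties: lower index)
            if cand.height > prev.height:
                kept[-1] = cand
        else:
            kept.append(cand)

    peaks: list[Peak] = []
    boundaries: list[tuple[int, int]] = []
    for cand in kept:
        left = _walk_boundary(values, cand.apex, -1)
        right = _walk_boundary(values, cand.apex, +1)
        boundaries.append((left, right))

    # a shared valley fraction between adjacent peaks belongs to the taller
    for k in range(len(kept) - 1):
        l_next = boundaries[k + 1][0]
        r_this = boundaries[k][1]
        if r_this >= l_next:
            if kept[k].height >= kept[k + 1].height:
                boundaries[k + 1] = (r_this + 1, max(boundaries[k + 1][1], r_this + 1))
            else:
                boundaries[k] = (boundaries[k][0], l_next - 1)

    for cand, (left, right) in zip(kept, boundaries):
        apex_mw = float(frac_mw[cand.apex])
        matched, shift = match_mw(apex_mw, spec, tol_kda=mw_window_kda)
        peaks.append(
            Peak(
                sample_id=net.sample_id,
                antibody_id=net.antibody_id,
                apex_fraction=cand.apex,
                apex_mw_kda=apex_mw,
                height=cand.height,
                left=left,
                right=right,
                afi=integrate_peak(values, left, right),
                matched_expected_mw_kda=matched,
                mw_shift_kda=shift,
            )
        )
    return peaks


def _split_between(values: np.ndarray, a: _Candidate, b: _Candidate) -> bool:
    """True when a sub-50% local minimum separates the two apexes."""
    lo, hi = sorted((a.apex, b.apex))
    if hi - lo < 2:
        return False
    valley = float(values[lo + 1 : hi].min())
    return valley < VALLEY_SPLIT_REL * min(a.height, b.height)


# ---------------------------------------------------------------------------
# run-level composition


@dataclass
class LaneResult:
    """Per-lane quantification record kept for reporting."""

    net: FractionProfile
    peaks: list[Peak] = field(default_factory=list)


def _control_profile(
    readout: pd.DataFrame, beadmap: BeadMap, sample_id: str, antibody_id: str
) -> FractionProfile | None:
    """Fetch a control lane for a sample, falling back to the wildcard."""
    for sid in (sample_id, WILDCARD_SAMPLE):
        rows = readout[
            (readout["sample_id"] == sid) & (readout["antibody_id"] == antibody_id)
        ]
        if len(rows):
            return reconstruct_lane(rows, beadmap)
    return None


def quantify_lane(
    readout: pd.DataFrame,
    beadmap: BeadMap,
    sample_id: str,
    panel: Sequence[AntibodySpec],
    cal: MWCalibration,
    mw_window_kda: float = DEFAULT_MW_WINDOW_KDA,
) -> dict[str, LaneResult]:
    """Quantify every antibody incubation of one sample.

    Composes lane reconstruction, baseline estimation from the sample's
    (or the run-wide) control lanes, background subtraction, peak
    detection and integration.  Returns one :class:`LaneResult` per
    antibody id.
    """
    empty = _control_profile(readout, beadmap, sample_id, EMPTY_BEAD)
    secondary = _control_profile(readout, beadmap, sample_id, SECONDARY_ONLY)
    try:
        baseline = estimate_baseline(empty, secondary)
    except DigiWestError as exc:
        raise DigiWestError(f"sample {sample_id!r}: {exc}") from exc

    results: dict[str, LaneResult] = {}
    for spec in panel:
        rows = readout[
            (readout["sample_id"] == sample_id)
            & (readout["antibody_id"] == spec.antibody_id)
        ]
        if not len(rows):
            continue
        try:
            profile = reconstruct_lane(rows, beadmap)
            net = subtract_background(profile, baseline)
            peaks = detect_peaks(net, spec, cal, mw_window_kda=mw_window_kda)
        except DigiWestError as exc:
            raise DigiWestError(
                f"sample {sample_id!r}, antibody {spec.antibody_id!r}: {exc}"
            ) from exc
        results[spec.antibody_id] = LaneResult(net=net, peaks=peaks)
    return results


def quantify_readout(
    readout: pd.DataFrame,
    beadmap: BeadMap,
    panel: Sequence[AntibodySpec],
    cal: MWCalibration,
    mw_window_kda: float = DEFAULT_MW_WINDOW_KDA,
) -> tuple[list[Peak], dict[tuple[str, str], LaneResult]]:
    """Quantify every sample x antibody lane of a readout table.

    Returns the flat peak list (ordered by sample, then panel order)
    and the per-lane results keyed by ``(sample_id, antibody_id)``.
    """
    sample_ids = [
        s
        for s in readout["sample_id"].drop_duplicates()
        if s != WILDCARD_SAMPLE
    ]
    all_peaks: list[Peak] = []
    lanes: dict[tuple[str, str], LaneResult] = {}
    for sid in sample_ids:
        per_ab = quantify_lane(
            readout, beadmap, sid, panel, cal, mw_window_kda=mw_window_kda
        )
        for ab_id, result in per_ab.items():
            lanes[(sid, ab_id)] = result
            all_peaks.extend(result.peaks)
        logger.info(
            "quantified sample %s: %d lanes, %d peaks",
            sid,
            len(per_ab),
            sum(len(r.peaks) for r in per_ab.values()),
        )
    return all_peaks, lanes
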