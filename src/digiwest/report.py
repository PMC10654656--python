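"""Western-blot mimics, SEC heat maps, and concordance tables.

The blot mimic re-renders quantified lane profiles as a grayscale image
resembling a traditional Western blot: one vertical band column per
sample x antibody lane, dark bands on a light background, MW axis from
the ladder calibration.  By default each lane is normalized on its own
(band intensities are not comparable across samples or experiments, so
the mimic only conveys band position); a per-figure mode normalizes
over the shared maximum instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .calibration import MWCalibration
from .model import (
    DETECTED,
    N_FRACTIONS,
    DetectionMatrix,
    DigiWestError,
    FractionProfile,
    MarkerCall,
    Peak,
)

#: sentinel for "signal too low for peak detection" heat-map cells (the
#: X-mark state); distinct from a true AFI of zero
BELOW_DETECTION = float("nan")

LANE_WIDTH_PX = 32
LANE_GAP_PX = 8
SCALE = 4  # vertical pixels per fraction (nearest-neighbour upsampling)


@dataclass(frozen=True)
class MimicSpec:
    """Layout of a Western-blot mimic figure."""

    lanes: tuple[tuple[str, str], ...]  # ordered (sample_id, antibody_id)
    normalization: str = "per-lane"  # or "per-figure"
    mw_ticks_kda: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lanes", tuple(tuple(l) for l in self.lanes))
        object.__setattr__(self, "mw_ticks_kda", tuple(self.mw_ticks_kda))
        if not self.lanes:
            raise DigiWestError("mimic needs >= 1 lane")
        if self.normalization not in ("per-lane", "per-figure"):
            raise DigiWestError(
                f"unknown normalization mode {self.normalization!r}"
            )


def mimic_array(
    profiles: Mapping[tuple[str, str], FractionProfile],
    spec: MimicSpec,
    blur_fractions: float = 0.0,
) -> np.ndarray:
    """Pre-layout mimic intensities: one row per fraction, one column per lane.

    Returns a float array of shape (96, n_lanes) with values in [0, 1]
    (1 = darkest band).  This is the testable geometric core; the image
    renderer only upsamples and quantises it.
    """
    cols = []
    for key in spec.lanes:
        if key not in profiles:
            raise DigiWestError(f"mimic lane {key} has no quantified profile")
        cols.append(profiles[key].values.astype(float))
    grid = np.stack(cols, axis=1)
    if blur_fractions > 0:
        grid = ndimage.gaussian_filter1d(grid, blur_fractions, axis=0)
    if spec.normalization == "per-lane":
        maxima = grid.max(axis=0)
        maxima[maxima == 0] = 1.0
        grid = grid / maxima
    else:
        peak = grid.max()
        grid = grid / peak if peak > 0 else grid
    return grid


def render_mimic(
    profiles: Mapping[tuple[str, str], FractionProfile],
    cal: MWCalibration,
    spec: MimicSpec,
    blur_fractions: float = 0.0,
) -> Image.Image:
    """Render a deterministic grayscale blot-mimic image.

    Fraction ``f`` of lane ``k`` maps to pixel rows ``[4f, 4f+4)`` of
    band column ``k``; intensity is ``255 * (1 - normalized value)``
    (white background, dark bands).  MW ticks are drawn as short black
    marks in a left margin at the rows given by the calibration.
    """
    grid = mimic_array(profiles, spec, blur_fractions=blur_fractions)
    n_lanes = grid.shape[1]
    margin = 12 if spec.mw_ticks_kda else 0
    height = N_FRACTIONS * SCALE
    width = margin + n_lanes * (LANE_WIDTH_PX + LANE_GAP_PX) - LANE_GAP_PX

    img = np.full((height, width), 255, dtype=np.uint8)
    gray = np.round(255.0 * (1.0 - grid)).astype(np.uint8)
    gray = np.repeat(gray, SCALE, axis=0)  # nearest-neighbour upsampling
    for k in range(n_lanes):
        x0 = margin + k * (LANE_WIDTH_PX + LANE_GAP_PX)
        img[:, x0 : x0 + LANE_WIDTH_PX] = gray[:, k : k + 1]

    for mw in spec.mw_ticks_kda:
        frac = float(cal.mw_to_fraction(mw))
        row = int(round(frac * SCALE + SCALE / 2))
        if 0 <= row < height:
            img[row, 0 : max(margin - 4, 4)] = 0

    return Image.fromarray(img, mode="L")


def darkest_row_mw(grid: np.ndarray, cal: MWCalibration, lane: int = 0) -> float:
    """MW at the darkest fraction of one mimic lane (geometry helper)."""
    grid = np.asarray(grid)
    frac = int(np.argmax(grid[:, lane]))
    return float(cal.fraction_to_mw(frac))


# ---------------------------------------------------------------------------
# SEC heat map


def heatmap_afi(
    calls: Sequence[MarkerCall],
    markers: Sequence[str],
    sample_order: Sequence[str],
) -> pd.DataFrame:
    """AFI matrix: one row per marker, one column per (SEC pool) sample.

    A cell holds the accepted peak's AFI; samples where the marker fell
    below detection hold NaN (the X-mark state of the published heat
    maps), which is distinct from a genuine AFI of zero.
    """
    by_cell = {(c.sample_id, c.marker): c for c in calls}
    data = np.full((len(markers), len(sample_order)), BELOW_DETECTION)
    for i, marker in enumerate(markers):
        for j, sid in enumerate(sample_order):
            call = by_cell.get((sid, marker))
            if call is not None and call.status == DETECTED and call.peak is not None:
                data[i, j] = call.peak.afi
    return pd.DataFrame(data, index=list(markers), columns=list(sample_order))


def render_heatmap(matrix: pd.DataFrame, path, title: str = "AFI per pooled SEC fraction set"):
    """Render the AFI heat map as a PNG; NaN cells carry an X mark."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.5 * matrix.shape[0])
    )
    values = matrix.to_numpy()
    masked = np.ma.masked_invalid(values)
    im = ax.imshow(masked, aspect="auto", cmap="viridis")
    for (i, j), v in np.ndenumerate(values):
        if np.isnan(v):
            ax.text(j, i, "X", ha="center", va="center", fontsize=9)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="AFI (AU)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_heatmap_matrix(matrix: pd.DataFrame, path) -> None:
    """Export the heat-map matrix as TSV; X-mark cells serialise as 'X'."""
    out = matrix.copy()
    out = out.astype(object)
    for col in out.columns:
        out[col] = [
            "X" if isinstance(v, float) and np.isnan(v) else repr(float(v))
            for v in out[col]
        ]
    out.rename_axis("marker").reset_index().to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_heatmap_matrix(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str).set_index("marker")
    return raw.apply(
        lambda col: [BELOW_DETECTION if v == "X" else float(v) for v in col]
    ).astype(float)


# ---------------------------------------------------------------------------
# concordance with an orthogonal reference (e.g. mass spectrometry)


@dataclass
class Concordance:
    """Set comparison of detected markers against a reference list."""

    group: str
    both: tuple[str, ...]
    digiwest_only: tuple[str, ...]
    reference_only: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "digiwest_only": len(self.digiwest_only),
            "reference_only": len(self.reference_only),
        }


def concordance_table(
    matrix: DetectionMatrix,
    reference: Mapping[str, Sequence[str]],
) -> list[Concordance]:
    """Partition markers per sample into {both, digiwest_only, reference_only}.

    ``reference`` maps sample ids to the marker list an orthogonal method
    (e.g. mass spectrometry) reported.  Reference markers outside the
    panel vocabulary are kept in ``reference_only`` (with a warning).
    """
    import logging

    logger = logging.getLogger(__name__)
    known = set(matrix.markers)
    out = []
    for sample_id, ref_markers in reference.items():
        if sample_id not in {s.sample_id for s in matrix.samples}:
            raise DigiWestError(
                f"concordance reference names unknown sample {sample_id!r}"
            )
        ref = set(ref_markers)
        unknown = ref - known
        if unknown:
            logger.warning(
                "reference for %s names markers outside the panel: %s",
                sample_id,
                sorted(unknown),
            )
        detected = matrix.detected_markers(sample_id)
        out.append(
            Concordance(
                group=sample_id,
                both=tuple(sorted(detected & ref)),
                digiwest_only=tuple(sorted(detected - ref)),
                reference_only=tuple(sorted(ref - detected)),
            )
        )
    return out


def export_tables(
    peaks,
    calls,
    matrix: DetectionMatrix,
    out_dir,
    heatmap: pd.DataFrame | None = None,
    concordance: Sequence["Concordance"] | None = None,
) -> dict[str, object]:
    """Write all result tables (TSV, deterministic column order) to a
    directory: peaks.tsv, calls.tsv, matrix.tsv and, when given,
    heatmap.tsv and concordance.tsv.  Empty inputs yield header-only
    files."""
    from pathlib import Path

    from . import io as dio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    dio.write_peaks(peaks, out / "peaks.tsv")
    paths["peaks"] = out / "peaks.tsv"
    dio.write_calls(calls, out / "calls.tsv")
    paths["calls"] = out / "calls.tsv"
    dio.write_matrix(matrix, out / "matrix.tsv")
    paths["matrix"] = out / "matrix.tsv"
    if heatmap is not None:
        write_heatmap_matrix(heatmap, out / "heatmap.tsv")
        paths["heatmap"] = out / "heatmap.tsv"
    if concordance is not None:
        write_concordance(concordance, out / "concordance.tsv")
        paths["concordance"] = out / "concordance.tsv"
    return paths


def write_concordance(rows: Sequence[Concordance], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "group": r.group,
                "n_both": len(r.both),
                "n_digiwest_only": len(r.digiwest_only),
                "n_reference_only": len(r.reference_only),
                "both": ";".join(r.both),
                "digiwest_only": ";".join(r.digiwest_only),
                "reference_only": ";".join(r.reference_only),
            }
            for r in rows
        ]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
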