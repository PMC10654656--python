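"""End-to-end pipeline: quantify -> call -> report from input files.

Each stage is also runnable standalone from the previous stage's files
via the CLI; this module chains them with structured logging and
all-or-nothing output handling (partial outputs are removed when a
stage fails).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as dio
from . import qc, quantify, report
from .calibration import fit_calibration
from .model import DigiWestError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    readout: Path
    beadmap: Path
    ladder: Path
    panel: Path
    samples: Path
    out_dir: Path
    min_height: float = qc.DEFAULT_MIN_HEIGHT
    min_afi: float = qc.DEFAULT_MIN_AFI
    mw_tol_kda: float = qc.DEFAULT_MW_TOL_KDA
    spread_kda: float = qc.DEFAULT_SPREAD_KDA
    mw_window_kda: float = quantify.DEFAULT_MW_WINDOW_KDA
    render_mimic: bool = True

    def __post_init__(self) -> None:
        for name in ("readout", "beadmap", "ladder", "panel", "samples", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        for name in ("min_height", "min_afi", "mw_tol_kda", "spread_kda"):
            if getattr(self, name) <= 0:
                raise DigiWestError(f"threshold {name} must be > 0")


class StageError(DigiWestError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run quantify -> call -> report, writing all artifact files.

    Returns the mapping of artifact names to paths.  On any stage
    failure the partially written outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, path: Path, writer) -> Path:
        writer(path)
        written.append(path)
        return path

    artifacts: dict[str, Path] = {}
    try:
        # ---- quantify ------------------------------------------------
        try:
            readout = dio.read_readout(config.readout)
            beadmap = dio.read_beadmap(config.beadmap)
            ladder = dio.read_ladder(config.ladder)
            panel = dio.read_panel(config.panel)
            samples = dio.read_samples(config.samples)
            cal = fit_calibration(ladder)
            peaks, lanes = quantify.quantify_readout(
                readout, beadmap, panel, cal, mw_window_kda=config.mw_window_kda
            )
        except Exception as exc:
            raise StageError("quantify", exc) from exc
        logger.info(
            "quantify: %d readout rows -> %d lanes, %d peaks",
            len(readout),
            len(lanes),
            len(peaks),
        )
        artifacts["peaks"] = _emit(
            "peaks", out / "peaks.tsv", lambda p: dio.write_peaks(peaks, p)
        )

        # ---- call ----------------------------------------------------
        try:
            matrix = qc.call_markers(
                peaks,
                panel,
                samples,
                min_height=config.min_height,
                min_afi=config.min_afi,
                mw_tol_kda=config.mw_tol_kda,
                spread_kda=config.spread_kda,
            )
            calls = [matrix.calls[k] for k in sorted(matrix.calls)]
        except Exception as exc:
            raise StageError("call", exc) from exc
        n_detected = sum(c.detected for c in calls)
        logger.info("call: %d cells, %d detected", len(calls), n_detected)
        artifacts["calls"] = _emit(
            "calls", out / "calls.tsv", lambda p: dio.write_calls(calls, p)
        )
        artifacts["matrix"] = _emit(
            "matrix", out / "matrix.tsv", lambda p: dio.write_matrix(matrix, p)
        )

        # ---- report --------------------------------------------------
        if config.render_mimic and lanes:
            try:
                spec = report.MimicSpec(
                    lanes=tuple(sorted(lanes)),
                    mw_ticks_kda=(250.0, 130.0, 70.0, 55.0, 35.0, 25.0, 15.0),
                )
                profiles = {k: r.net for k, r in lanes.items()}
                img = report.render_mimic(profiles, cal, spec)
            except Exception as exc:
                raise StageError("report", exc) from exc
            artifacts["mimic"] = _emit(
                "mimic", out / "mimic.png", lambda p: img.save(p, format="PNG")
            )
            logger.info("report: mimic with %d lanes", len(lanes))
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return artifacts
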