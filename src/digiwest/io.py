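"""Readers and writers for the DigiWest file dialects.

All tabular text formats are UTF-8 with LF line endings and a required
header row; readouts/bead maps/ladders are comma-separated, result
tables tab-separated; the decimal separator is ``.``.  Every reader
enforces the invariants of its target type at load time and reports
malformed rows with their line number; every writer's output re-reads
equal (floats are serialised with ``repr``, which round-trips exactly).
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    CONTROL_ANTIBODIES,
    N_FRACTIONS,
    AntibodySpec,
    BeadMap,
    DetectionMatrix,
    DigiWestError,
    MarkerCall,
    Peak,
    SampleMeta,
)

READOUT_COLUMNS = ["sample_id", "antibody_id", "color_id", "mfi"]
PEAK_COLUMNS = [
    "sample_id",
    "antibody_id",
    "apex_fraction",
    "apex_mw_kda",
    "height",
    "left",
    "right",
    "afi",
    "matched_expected_mw_kda",
    "mw_shift_kda",
]
CALL_COLUMNS = ["sample_id", "marker", "antibody_id", "status", "reasons"]


class ParseError(DigiWestError):
    """A file violated its dialect or a type invariant."""


def _fmt(value) -> str:
    """Serialise a cell; floats use repr for lossless round trips."""
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def _write_table(path, header: Sequence[str], rows: Iterable[Sequence], sep=","):
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(sep.join(header) + "\n")
            for row in rows:
                fh.write(sep.join(_fmt(v) for v in row) + "\n")
    except OSError as exc:
        raise DigiWestError(f"cannot write {path}: {exc}") from exc


def _read_rows(path, required: Sequence[str], sep=","):
    """Yield (line_number, dict) per data row; validates the header."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise ParseError(f"{path}: missing required column(s) {missing}")
        rows = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or (len(raw) == 1 and raw[0] == ""):
                continue
            if len(raw) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(raw)}"
                )
            rows.append((lineno, dict(zip(header, raw))))
    return header, rows


def _parse_float(text: str, path, lineno: int, column: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: column {column!r}: not a number: {text!r}"
        ) from None
    if not math.isfinite(value):
        raise ParseError(f"{path}: line {lineno}: column {column!r}: non-finite value")
    return value


def _parse_int(text: str, path, lineno: int, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: column {column!r}: not an integer: {text!r}"
        ) from None


# ---------------------------------------------------------------------------
# readout.csv


def read_readout(path) -> pd.DataFrame:
    """Load a bead readout table (sample_id, antibody_id, color_id, mfi).

    Enforces: finite MFI >= 0 and a unique (sample, antibody, color) key.
    Control incubations live in the same table under the reserved
    antibody ids.
    """
    _, rows = _read_rows(path, READOUT_COLUMNS)
    records = []
    seen: dict[tuple[str, str, str], int] = {}
    for lineno, row in rows:
        key = (row["sample_id"], row["antibody_id"], row["color_id"])
        if key in seen:
            raise ParseError(
                f"{path}: line {lineno}: duplicate (sample_id, antibody_id, "
                f"color_id) key {key} (first seen on line {seen[key]})"
            )
        seen[key] = lineno
        mfi = _parse_float(row["mfi"], path, lineno, "mfi")
        if mfi < 0:
            raise ParseError(f"{path}: line {lineno}: column 'mfi': negative MFI {mfi}")
        records.append((*key, mfi))
    return pd.DataFrame(records, columns=READOUT_COLUMNS)


def write_readout(readout: pd.DataFrame, path) -> None:
    missing = [c for c in READOUT_COLUMNS if c not in readout.columns]
    if missing:
        raise DigiWestError(f"readout table missing column(s) {missing}")
    _write_table(
        path,
        READOUT_COLUMNS,
        readout[READOUT_COLUMNS].itertuples(index=False),
    )


# ---------------------------------------------------------------------------
# beadmap.csv


def read_beadmap(path) -> BeadMap:
    _, rows = _read_rows(path, ["color_id", "fraction_index"])
    entries: dict[str, int] = {}
    for lineno, row in rows:
        cid = row["color_id"]
        if cid in entries:
            raise ParseError(f"{path}: line {lineno}: duplicate color_id {cid!r}")
        idx = _parse_int(row["fraction_index"], path, lineno, "fraction_index")
        entries[cid] = idx
    if sorted(entries.values()) != list(range(N_FRACTIONS)):
        raise ParseError(
            f"{path}: bead map must cover expected {N_FRACTIONS} fractions "
            f"bijectively; got {len(entries)} entries"
        )
    return BeadMap(entries)


def write_beadmap(beadmap: BeadMap, path) -> None:
    rows = sorted(beadmap.entries.items(), key=lambda kv: kv[1])
    _write_table(path, ["color_id", "fraction_index"], rows)


# ---------------------------------------------------------------------------
# ladder.csv


def read_ladder(path) -> list[tuple[float, float]]:
    """Ladder anchors (fraction_index, mw_kda), strictly MW-decreasing."""
    _, rows = _read_rows(path, ["fraction_index", "mw_kda"])
    anchors = []
    for lineno, row in rows:
        idx = _parse_float(row["fraction_index"], path, lineno, "fraction_index")
        mw = _parse_float(row["mw_kda"], path, lineno, "mw_kda")
        if mw <= 0:
            raise ParseError(f"{path}: line {lineno}: column 'mw_kda': must be > 0")
        anchors.append((idx, mw))
    anchors.sort(key=lambda a: a[0])
    for (i0, m0), (i1, m1) in zip(anchors, anchors[1:]):
        if i1 <= i0 or m1 >= m0:
            raise ParseError(
                f"{path}: ladder anchors must be strictly MW-decreasing with "
                f"increasing fraction index (violated between index {i0} and {i1})"
            )
    return anchors


def write_ladder(anchors, path) -> None:
    rows = [(float(i), float(m)) for i, m in anchors]
    _write_table(path, ["fraction_index", "mw_kda"], rows)


# ---------------------------------------------------------------------------
# panel.json


def read_panel(path) -> list[AntibodySpec]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise ParseError(f"{path}: panel must be a JSON list of antibody entries")
    panel = []
    seen = set()
    for i, entry in enumerate(raw):
        for key in ("antibody_id", "marker", "expected_mw_kda"):
            if key not in entry:
                raise ParseError(f"{path}: entry {i}: missing field {key!r}")
        if entry["antibody_id"] in seen:
            raise ParseError(
                f"{path}: duplicate antibody_id {entry['antibody_id']!r}"
            )
        seen.add(entry["antibody_id"])
        try:
            panel.append(
                AntibodySpec(
                    antibody_id=entry["antibody_id"],
                    marker=entry["marker"],
                    expected_mw_kda=tuple(entry["expected_mw_kda"]),
                    valid_species=tuple(entry.get("valid_species", ())),
                )
            )
        except DigiWestError as exc:
            raise ParseError(f"{path}: entry {i}: {exc}") from exc
    return panel


def write_panel(panel: Sequence[AntibodySpec], path) -> None:
    data = [
        {
            "antibody_id": s.antibody_id,
            "marker": s.marker,
            "expected_mw_kda": list(s.expected_mw_kda),
            "valid_species": list(s.valid_species),
        }
        for s in panel
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# samples.csv


def read_samples(path) -> list[SampleMeta]:
    _, rows = _read_rows(path, ["sample_id", "species", "source"])
    samples = []
    seen = set()
    for lineno, row in rows:
        sid = row["sample_id"]
        if sid in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        protein = row.get("protein_input_ug", "")
        samples.append(
            SampleMeta(
                sample_id=sid,
                species=row["species"],
                source=row["source"],
                protein_input_ug=(
                    _parse_float(protein, path, lineno, "protein_input_ug")
                    if protein
                    else None
                ),
            )
        )
    return samples


def write_samples(samples: Sequence[SampleMeta], path) -> None:
    rows = [
        (s.sample_id, s.species, s.source, s.protein_input_ug) for s in samples
    ]
    _write_table(path, ["sample_id", "species", "source", "protein_input_ug"], rows)


# ---------------------------------------------------------------------------
# result tables (tab-separated)


def write_peaks(peaks: Sequence[Peak], path) -> None:
    rows = [
        (
            p.sample_id,
            p.antibody_id,
            p.apex_fraction,
            p.apex_mw_kda,
            p.height,
            p.left,
            p.right,
            p.afi,
            p.matched_expected_mw_kda,
            p.mw_shift_kda,
        )
        for p in peaks
    ]
    _write_table(path, PEAK_COLUMNS, rows, sep="\t")


def read_peaks(path) -> list[Peak]:
    _, rows = _read_rows(path, PEAK_COLUMNS, sep="\t")
    peaks = []
    for lineno, row in rows:
        matched = row["matched_expected_mw_kda"]
        shift = row["mw_shift_kda"]
        peaks.append(
            Peak(
                sample_id=row["sample_id"],
                antibody_id=row["antibody_id"],
                apex_fraction=_parse_int(row["apex_fraction"], path, lineno, "apex_fraction"),
                apex_mw_kda=_parse_float(row["apex_mw_kda"], path, lineno, "apex_mw_kda"),
                height=_parse_float(row["height"], path, lineno, "height"),
                left=_parse_int(row["left"], path, lineno, "left"),
                right=_parse_int(row["right"], path, lineno, "right"),
                afi=_parse_float(row["afi"], path, lineno, "afi"),
                matched_expected_mw_kda=(
                    _parse_float(matched, path, lineno, "matched_expected_mw_kda")
                    if matched
                    else None
                ),
                mw_shift_kda=(
                    _parse_float(shift, path, lineno, "mw_shift_kda") if shift else None
                ),
            )
        )
    return peaks


def write_calls(calls: Sequence[MarkerCall], path) -> None:
    rows = [
        (c.sample_id, c.marker, c.antibody_id, c.status, ";".join(c.reasons))
        for c in calls
    ]
    _write_table(path, CALL_COLUMNS, rows, sep="\t")


def read_calls(path) -> list[MarkerCall]:
    _, rows = _read_rows(path, CALL_COLUMNS, sep="\t")
    calls = []
    for lineno, row in rows:
        reasons = tuple(r for r in row["reasons"].split(";") if r)
        try:
            calls.append(
                MarkerCall(
                    sample_id=row["sample_id"],
                    marker=row["marker"],
                    antibody_id=row["antibody_id"],
                    status=row["status"],
                    reasons=reasons,
                )
            )
        except DigiWestError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return calls


def write_matrix(matrix: DetectionMatrix, path) -> None:
    frame = matrix.to_frame()
    rows = [(marker, *frame.loc[marker]) for marker in frame.index]
    _write_table(path, ["marker", *frame.columns], rows, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    header, rows = _read_rows(path, ["marker"], sep="\t")
    data = [[row[c] for c in header] for _, row in rows]
    return pd.DataFrame(data, columns=header).set_index("marker")


def is_control_antibody(antibody_id: str) -> bool:
    return antibody_id in CONTROL_ANTIBODIES
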