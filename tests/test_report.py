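"""Blot-mimic geometry, SEC heat maps, and concordance set algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digiwest.model import (
    AntibodySpec,
    DetectionMatrix,
    DigiWestError,
    FractionProfile,
    MarkerCall,
    Peak,
    SampleMeta,
)
from digiwest.qc import call_markers
from digiwest.quantify import quantify_readout
from digiwest.report import (
    BELOW_DETECTION,
    Concordance,
    MimicSpec,
    concordance_table,
    darkest_row_mw,
    heatmap_afi,
    mimic_array,
    read_heatmap_matrix,
    render_mimic,
    write_heatmap_matrix,
)
from digiwest.simulate import (
    DEFAULT_SEC_WEIGHTS,
    default_sec_config,
    simulate_sec_series,
)
from tests.conftest import gaussian_lane


def profile(values, sample="s1", ab="ab1"):
    return FractionProfile(sample, ab, np.asarray(values, dtype=float))


class TestMimic:
    def test_all_zero_profile_uniform_background(self, simple_cal):
        profiles = {("s1", "ab1"): profile(np.zeros(96))}
        spec = MimicSpec(lanes=(("s1", "ab1"),))
        img = render_mimic(profiles, simple_cal, spec)
        assert set(np.asarray(img).flatten()) == {255}

    def test_band_row_maps_to_band_mw(self, simple_cal):
        center = float(simple_cal.mw_to_fraction(46.0))
        profiles = {("s1", "ab1"): profile(gaussian_lane(center, 500.0, 2.0))}
        spec = MimicSpec(lanes=(("s1", "ab1"),))
        grid = mimic_array(profiles, spec)
        mw = darkest_row_mw(grid, simple_cal)
        span = simple_cal.fraction_span_kda(int(round(center)))
        assert abs(mw - 46.0) <= span

    def test_per_lane_normalization_saturates_each_lane(self, simple_cal):
        profiles = {
            ("s1", "ab1"): profile(gaussian_lane(30, 100.0, 2.0)),
            ("s2", "ab1"): profile(gaussian_lane(30, 10000.0, 2.0)),
        }
        spec = MimicSpec(lanes=(("s1", "ab1"), ("s2", "ab1")))
        grid = mimic_array(profiles, spec)
        assert grid[:, 0].max() == pytest.approx(1.0)
        assert grid[:, 1].max() == pytest.approx(1.0)
        per_fig = mimic_array(
            profiles, MimicSpec(spec.lanes, normalization="per-figure")
        )
        assert per_fig[:, 0].max() == pytest.approx(0.01)

    def test_deterministic_bytes(self, simple_cal, tmp_path):
        center = float(simple_cal.mw_to_fraction(70.0))
        profiles = {("s1", "ab1"): profile(gaussian_lane(center, 300.0, 2.0))}
        spec = MimicSpec(lanes=(("s1", "ab1"),), mw_ticks_kda=(70.0, 25.0))
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_mimic(profiles, simple_cal, spec).save(p1, format="PNG")
        render_mimic(profiles, simple_cal, spec).save(p2, format="PNG")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_lane_list_rejected(self):
        with pytest.raises(DigiWestError, match="lane"):
            MimicSpec(lanes=())


@pytest.fixture(scope="module")
def sec_results():
    ds = simulate_sec_series(default_sec_config(seed=4), DEFAULT_SEC_WEIGHTS)
    peaks, _ = quantify_readout(ds.readout, ds.beadmap, ds.panel, ds.calibration)
    matrix = call_markers(peaks, ds.panel, ds.samples)
    return ds, peaks, matrix


class TestHeatmap:
    def test_enrichment_argmax_in_8_10(self, sec_results):
        """The pooled set holding the simulated EV enrichment peak
        ('8-10') is the argmax column for every enriched marker."""
        ds, _, matrix = sec_results
        afi = heatmap_afi(
            list(matrix.calls.values()),
            [s.marker for s in ds.panel],
            [s.sample_id for s in ds.samples],
        )
        for marker in afi.index:
            assert afi.loc[marker].idxmax() == "pool_8-10"

    def test_below_detection_is_sentinel_not_zero(self, sec_results):
        ds, _, matrix = sec_results
        afi = heatmap_afi(
            list(matrix.calls.values()),
            [s.marker for s in ds.panel],
            [s.sample_id for s in ds.samples],
        )
        # weight-zero pools are below detection: NaN sentinel, never 0.0
        assert np.isnan(afi["pool_23-25"]).all()
        assert not (afi.fillna(-1) == 0.0).any().any()

    def test_heatmap_values_equal_peak_afis(self, sec_results):
        ds, peaks, matrix = sec_results
        afi = heatmap_afi(
            list(matrix.calls.values()),
            [s.marker for s in ds.panel],
            [s.sample_id for s in ds.samples],
        )
        by_cell = {(p.sample_id, p.antibody_id): p.afi for p in peaks}
        for spec in ds.panel:
            for sample in ds.samples:
                value = afi.loc[spec.marker, sample.sample_id]
                if not np.isnan(value):
                    assert value == by_cell[(sample.sample_id, spec.antibody_id)]

    def test_matrix_tsv_round_trip(self, sec_results, tmp_path):
        ds, _, matrix = sec_results
        afi = heatmap_afi(
            list(matrix.calls.values()),
            [s.marker for s in ds.panel],
            [s.sample_id for s in ds.samples],
        )
        path = tmp_path / "heatmap.tsv"
        write_heatmap_matrix(afi, path)
        back = read_heatmap_matrix(path)
        assert np.allclose(back.to_numpy(), afi.to_numpy(), equal_nan=True)
        assert "X" in path.read_text()


class TestExportTables:
    def test_full_export_matrix_cell_count(self, sec_results, tmp_path):
        from digiwest.report import export_tables

        ds, peaks, matrix = sec_results
        calls = [matrix.calls[k] for k in sorted(matrix.calls)]
        paths = export_tables(peaks, calls, matrix, tmp_path)
        lines = paths["matrix"].read_text().strip().splitlines()
        assert len(lines) - 1 == len(matrix.markers)
        assert len(lines[1].split("\t")) - 1 == len(matrix.samples)

    def test_empty_results_header_only(self, tmp_path):
        from digiwest.model import DetectionMatrix
        from digiwest.report import export_tables

        empty = DetectionMatrix((), (), {})
        paths = export_tables([], [], empty, tmp_path)
        assert paths["peaks"].read_text().count("\n") == 1
        assert paths["calls"].read_text().count("\n") == 1


def _matrix_from_sets(detected: dict[str, set], markers):
    samples = tuple(SampleMeta(s, "human", "x") for s in detected)
    calls = {}
    for s in detected:
        for m in markers:
            if m in detected[s]:
                calls[(s, m)] = MarkerCall(
                    s, m, f"ab_{m}", "detected",
                    peak=Peak(s, f"ab_{m}", 40, 46.0, 200.0, 38, 42, 900.0),
                )
            else:
                calls[(s, m)] = MarkerCall(
                    s, m, f"ab_{m}", "not_detected", ("no_peak",)
                )
    return DetectionMatrix(samples, tuple(markers), calls)


class TestConcordance:
    def test_basic_partition(self):
        matrix = _matrix_from_sets({"g": {"A", "B", "C"}}, ["A", "B", "C", "D"])
        (row,) = concordance_table(matrix, {"g": ["A", "B"]})
        assert row.both == ("A", "B")
        assert row.digiwest_only == ("C",)
        assert row.reference_only == ()

    def test_nothing_detected(self):
        matrix = _matrix_from_sets({"g": set()}, ["A", "B"])
        (row,) = concordance_table(matrix, {"g": ["A", "B"]})
        assert row.both == ()
        assert row.reference_only == ("A", "B")

    def test_unknown_reference_marker_kept_in_reference_only(self, caplog):
        matrix = _matrix_from_sets({"g": {"A"}}, ["A"])
        (row,) = concordance_table(matrix, {"g": ["A", "mystery"]})
        assert "mystery" in row.reference_only

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        detected=st.sets(st.sampled_from("ABCDEFGH")),
        reference=st.sets(st.sampled_from("ABCDEFGH")),
    )
    def test_partition_property(self, detected, reference):
        """both/digiwest_only/reference_only is a true partition of the
        union: disjoint, covering, sizes summing to |union|."""
        markers = sorted(set("ABCDEFGH"))
        matrix = _matrix_from_sets({"g": set(detected)}, markers)
        (row,) = concordance_table(matrix, {"g": sorted(reference)})
        parts = [set(row.both), set(row.digiwest_only), set(row.reference_only)]
        assert parts[0] | parts[1] | parts[2] == set(detected) | set(reference)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert sum(len(p) for p in parts) == len(set(detected) | set(reference))
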