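"""Synthetic DigiWest datasets with known ground truth.

The generator emulates a multi-species extracellular-vesicle (EV)
characterisation run: for each sample x antibody incubation it builds a
96-fraction virtual lane as

    baseline + secondary bump + Gaussian marker peaks + noise,

clipped at zero, together with the bead map, ladder anchors, control
lanes (empty-bead and secondary-antibody-only), the antibody panel
definition, and a :class:`SyntheticTruth` record set carrying the exact
peak parameters (center MW, amplitude, width and the analytic AFI
``A * sigma * sqrt(2*pi)``) for recovery tests.

Peaks are Gaussian in fraction space with their centers placed via the
ladder calibration; the bead map is a seeded random permutation of the
96 color ids, so lane reconstruction is genuinely exercised.  Identical
(config, seed) pairs reproduce byte-identical outputs.

Default fluorescence scales: marker amplitudes of a few hundred AU over
a baseline of ~40 AU with additive noise of ~15 AU.  These emulate an
optimized low-protein-input EV run in which the 50 AU height / 100 AU
AFI acceptance thresholds sit several noise standard deviations above
background; the real instrument's noise magnitude is not published, so
these are order-of-magnitude choices (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .calibration import MWCalibration, default_ladder, fit_calibration
from .model import (
    EMPTY_BEAD,
    N_FRACTIONS,
    SECONDARY_ONLY,
    WILDCARD_SAMPLE,
    AntibodySpec,
    BeadMap,
    DigiWestError,
    SampleMeta,
)

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: pooled SEC fraction sets analysed in the dilution-series experiment
SEC_SET_LABELS = ("2-4", "5-7", "8-10", "11-13", "14-16", "17-19", "20-22", "23-25")


@dataclass(frozen=True)
class MarkerSim:
    """Simulation parameters for one antibody/marker.

    ``presence`` maps sample_id -> band specification: ``True`` places a
    band at every expected MW, a number places a single band at that MW
    (in kDa), and a missing/False entry means the marker is absent from
    that sample's lane.
    """

    antibody_id: str
    marker: str
    expected_mw_kda: tuple[float, ...]
    amplitude: float
    width_fractions: float
    presence: Mapping[str, object] = field(default_factory=dict)
    valid_species: tuple[str, ...] = ()
    mw_shift_kda: Mapping[str, float] = field(default_factory=dict)
    amplitude_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise DigiWestError(
                f"marker {self.marker!r}: amplitude must be >= 0"
            )
        if self.width_fractions <= 0:
            raise DigiWestError(
                f"marker {self.marker!r}: width_fractions must be > 0"
            )
        if any(s < 0 for s in self.amplitude_scale.values()):
            raise DigiWestError(
                f"marker {self.marker!r}: amplitude scales must be >= 0"
            )

    def band_centers(self, sample_id: str) -> tuple[float, ...]:
        """Band center MW(s) in kDa for this sample, () when absent."""
        spec = self.presence.get(sample_id, False)
        if spec is False or spec is None:
            return ()
        if spec is True:
            centers = self.expected_mw_kda
        elif isinstance(spec, (int, float)):
            centers = (float(spec),)
        else:
            centers = tuple(float(m) for m in spec)
        shift = float(self.mw_shift_kda.get(sample_id, 0.0))
        return tuple(m + shift for m in centers)

    def to_spec(self) -> AntibodySpec:
        return AntibodySpec(
            antibody_id=self.antibody_id,
            marker=self.marker,
            expected_mw_kda=self.expected_mw_kda,
            valid_species=self.valid_species,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic DigiWest run."""

    samples: tuple[SampleMeta, ...]
    markers: tuple[MarkerSim, ...]
    ladder: tuple[tuple[float, float], ...] = tuple(default_ladder())
    baseline_level: float = 40.0
    secondary_bump: tuple[float, float, float] | None = (88.0, 25.0, 6.0)
    noise_sd: float = 15.0
    multiplicative_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(
            self, "ladder", tuple((float(i), float(m)) for i, m in self.ladder)
        )
        if len(self.samples) < 1:
            raise DigiWestError("simulation needs >= 1 sample")
        if self.noise_sd < 0:
            raise DigiWestError("noise_sd must be >= 0")
        if self.baseline_level < 0:
            raise DigiWestError("baseline_level must be >= 0")
        if self.secondary_bump is not None and self.secondary_bump[1] < 0:
            raise DigiWestError("secondary bump amplitude must be >= 0")
        cal = fit_calibration(self.ladder)
        lo, hi = cal.mw_range
        for marker in self.markers:
            for mw in marker.expected_mw_kda:
                if not (lo <= mw <= hi):
                    raise DigiWestError(
                        f"marker {marker.marker!r}: expected MW {mw} kDa outside "
                        f"the calibration range [{lo:g}, {hi:g}] kDa"
                    )

    @property
    def species_labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s.species for s in self.samples))


@dataclass(frozen=True)
class TruthBand:
    """Ground truth for one simulated band (sample x marker x isoform)."""

    sample_id: str
    antibody_id: str
    marker: str
    center_mw_kda: float
    amplitude: float
    width_fractions: float
    afi: float  # analytic integral A * sigma * sqrt(2 pi)


@dataclass
class SyntheticTruth:
    """Ground-truth peak parameters emitted alongside a simulated dataset."""

    bands: tuple[TruthBand, ...]

    def for_cell(self, sample_id: str, marker: str) -> tuple[TruthBand, ...]:
        return tuple(
            b for b in self.bands if b.sample_id == sample_id and b.marker == marker
        )

    def present(self, sample_id: str, marker: str) -> bool:
        return bool(self.for_cell(sample_id, marker))

    def presence_grid(
        self, samples: Sequence[SampleMeta], markers: Sequence[str]
    ) -> dict[tuple[str, str], bool]:
        return {
            (s.sample_id, m): self.present(s.sample_id, m)
            for s in samples
            for m in markers
        }


@dataclass
class Dataset:
    """Everything a DigiWest analysis run consumes, plus the truth."""

    readout: pd.DataFrame
    beadmap: BeadMap
    ladder: tuple[tuple[float, float], ...]
    panel: list[AntibodySpec]
    samples: list[SampleMeta]
    truth: SyntheticTruth
    config: SimulationConfig | None = None

    @property
    def calibration(self) -> MWCalibration:
        return fit_calibration(self.ladder)


def _gaussian(x: np.ndarray, center: float, amplitude: float, width: float):
    return amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)


def _bump_profile(config: SimulationConfig, x: np.ndarray) -> np.ndarray:
    if config.secondary_bump is None:
        return np.zeros_like(x)
    center, amp, width = config.secondary_bump
    return _gaussian(x, center, amp, width)


def _apply_noise(
    values: np.ndarray, rng: np.random.Generator, config: SimulationConfig
) -> np.ndarray:
    # one draw per fraction regardless of noise level, so the stream of
    # random numbers (and hence everything downstream) is structurally
    # identical across noise settings
    eps = rng.normal(0.0, 1.0, size=values.shape)
    if config.multiplicative_noise:
        noisy = values * (1.0 + config.noise_sd * eps)
    else:
        noisy = values + config.noise_sd * eps
    return np.maximum(noisy, 0.0)


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Generate a complete, self-consistent dataset from a config.

    The emitted readout table contains one row per sample x antibody x
    bead color (96 per lane) plus the two control lanes under the
    wildcard sample ``*``.  Rerunning with the same config (which
    includes the seed) reproduces the output exactly.
    """
    rng = np.random.default_rng(config.seed)
    cal = fit_calibration(config.ladder)

    # seeded random bead-color permutation; color ids mimic bead region ids
    perm = rng.permutation(N_FRACTIONS)
    beadmap = BeadMap(
        {f"bead_{k + 1:03d}": int(perm[k]) for k in range(N_FRACTIONS)}
    )
    color_of = beadmap.inverse()

    x = np.arange(N_FRACTIONS, dtype=float)
    bump = _bump_profile(config, x)

    lanes: list[tuple[str, str, np.ndarray]] = []
    # control lanes first (fixed draw order)
    empty = np.full(N_FRACTIONS, config.baseline_level)
    lanes.append((WILDCARD_SAMPLE, EMPTY_BEAD, _apply_noise(empty, rng, config)))
    lanes.append(
        (WILDCARD_SAMPLE, SECONDARY_ONLY, _apply_noise(empty + bump, rng, config))
    )

    truth_bands: list[TruthBand] = []
    lo_mw, hi_mw = cal.mw_range
    for sample in config.samples:
        for marker in config.markers:
            signal = empty + bump
            amp = marker.amplitude * float(
                marker.amplitude_scale.get(sample.sample_id, 1.0)
            )
            for center_mw in marker.band_centers(sample.sample_id):
                if not (lo_mw <= center_mw <= hi_mw):
                    raise DigiWestError(
                        f"marker {marker.marker!r}, sample "
                        f"{sample.sample_id!r}: band MW {center_mw:g} kDa "
                        f"outside the calibration range [{lo_mw:g}, {hi_mw:g}]"
                    )
                if amp <= 0:
                    continue
                center_frac = float(cal.mw_to_fraction(center_mw))
                signal = signal + _gaussian(
                    x, center_frac, amp, marker.width_fractions
                )
                truth_bands.append(
                    TruthBand(
                        sample_id=sample.sample_id,
                        antibody_id=marker.antibody_id,
                        marker=marker.marker,
                        center_mw_kda=center_mw,
                        amplitude=amp,
                        width_fractions=marker.width_fractions,
                        afi=amp * marker.width_fractions * SQRT_2PI,
                    )
                )
            lanes.append(
                (
                    sample.sample_id,
                    marker.antibody_id,
                    _apply_noise(signal, rng, config),
                )
            )

    rows = []
    for sample_id, antibody_id, values in lanes:
        for f in range(N_FRACTIONS):
            rows.append((sample_id, antibody_id, color_of[f], float(values[f])))
    readout = pd.DataFrame(rows, columns=dio.READOUT_COLUMNS)

    return Dataset(
        readout=readout,
        beadmap=beadmap,
        ladder=config.ladder,
        panel=[m.to_spec() for m in config.markers],
        samples=list(config.samples),
        truth=SyntheticTruth(tuple(truth_bands)),
        config=config,
    )


def simulate_sec_series(
    base_config: SimulationConfig,
    enrichment_weights: Mapping[str, float] | Sequence[float],
    species: str | None = None,
) -> Dataset:
    """Simulate a pooled-SEC-fraction dilution series.

    One lane set ("sample") is generated per pooled fraction set; every
    marker of the base config is present in each set with its amplitude
    scaled by the set's enrichment weight (weight 0 = absent).  The
    returned truth carries the per-set analytic AFI, so enrichment
    localisation (which pooled set holds the most EVs) can be checked
    against construction.
    """
    if isinstance(enrichment_weights, Mapping):
        labels = tuple(enrichment_weights)
        weights = [float(enrichment_weights[k]) for k in labels]
    else:
        weights = [float(w) for w in enrichment_weights]
        if len(weights) > len(SEC_SET_LABELS):
            raise DigiWestError(
                f"at most {len(SEC_SET_LABELS)} pooled fraction sets supported"
            )
        labels = SEC_SET_LABELS[: len(weights)]
    if not weights:
        raise DigiWestError("enrichment weights must be non-empty")
    if any(w < 0 for w in weights):
        raise DigiWestError("enrichment weights must be >= 0")
    if not any(w > 0 for w in weights):
        raise DigiWestError("at least one enrichment weight must be > 0")

    if species is None:
        species = base_config.samples[0].species if base_config.samples else "pig"

    pools = tuple(
        SampleMeta(
            sample_id=f"pool_{label}",
            species=species,
            source=f"SEC fractions {label}",
        )
        for label in labels
    )
    markers = []
    for m in base_config.markers:
        center = m.expected_mw_kda[0]
        presence = {
            p.sample_id: center if w > 0 else False
            for p, w in zip(pools, weights)
        }
        scale = {p.sample_id: w for p, w in zip(pools, weights)}
        markers.append(
            replace(m, presence=presence, amplitude_scale=scale, mw_shift_kda={})
        )
    config = replace(base_config, samples=pools, markers=tuple(markers))
    return simulate_dataset(config)


# ---------------------------------------------------------------------------
# default configurations emulating the published experiments


def default_panel_config(
    seed: int = 0,
    noise_sd: float = 15.0,
) -> SimulationConfig:
    """A 3-species, 15-antibody EV characterisation run.

    Four EV preparations (human milk, human MSC, pig NC, dog NC) probed
    with a 15-antibody panel: nine general EV markers present across all
    samples, CD9 with a consistent downward MW shift and absent from
    MSC-EVs, caveolin-1 as a 21/24 kDa isoform pair (24 kDa only in
    milk), SHH restricted to notochordal-cell samples, ITGB1 in two
    species, and three coisolated-contaminant markers (keratins, S6
    ribosomal protein) absent from every EV lane.  The default noise of
    15 AU is one-twentieth of the weakest marker amplitude.
    """
    samples = (
        SampleMeta("human_milk", "human", "milk", 10.0),
        SampleMeta("human_MSC", "human", "MSC", 2.4),
        SampleMeta("pig_NC", "pig", "NC", 0.9),
        SampleMeta("dog_NC", "dog", "NC", 1.6),
    )
    everywhere = {s.sample_id: True for s in samples}

    def only(*ids):
        return {sid: True for sid in ids}

    markers = (
        MarkerSim("ab_FLOT1", "flotillin-1", (48.0,), 700.0, 2.0, everywhere),
        MarkerSim("ab_TSG101", "TSG101", (46.0,), 650.0, 2.0, everywhere),
        MarkerSim(
            "ab_CAV1",
            "caveolin-1",
            (21.0, 24.0),
            500.0,
            1.8,
            {
                "human_milk": 24.0,
                "human_MSC": 21.0,
                "pig_NC": 21.0,
                "dog_NC": 21.0,
            },
        ),
        MarkerSim("ab_HSP70", "HSP70", (70.0,), 800.0, 2.2, everywhere),
        MarkerSim("ab_HSPA8", "HSPA8", (73.0,), 600.0, 2.2, everywhere),
        MarkerSim("ab_ANXA2", "annexin II", (38.0,), 550.0, 1.9, everywhere),
        MarkerSim("ab_GAPDH", "GAPDH", (36.0,), 750.0, 1.8, everywhere),
        MarkerSim("ab_FN1", "fibronectin", (240.0,), 400.0, 2.4, everywhere),
        MarkerSim("ab_ENO1", "enolase-1", (47.0,), 500.0, 1.9, everywhere),
        # consistent -8 kDa shift, absent from MSC-EVs
        MarkerSim(
            "ab_CD9",
            "CD9",
            (25.0,),
            450.0,
            1.7,
            only("human_milk", "pig_NC", "dog_NC"),
            mw_shift_kda={
                "human_milk": -8.0,
                "pig_NC": -8.0,
                "dog_NC": -8.0,
            },
        ),
        MarkerSim(
            "ab_SHH",
            "SHH",
            (45.0,),
            350.0,
            1.8,
            only("pig_NC", "dog_NC"),
            valid_species=("pig", "dog"),
        ),
        MarkerSim(
            "ab_ITGB1", "ITGB1", (130.0,), 300.0, 2.3, only("human_milk", "dog_NC")
        ),
        # coisolated contaminants: absent from every EV preparation
        MarkerSim("ab_KRT8", "keratin 8", (54.0,), 400.0, 1.8, {}),
        MarkerSim("ab_KRT18", "keratin 18", (48.0,), 400.0, 1.8, {}),
        MarkerSim("ab_RPS6", "S6 ribosomal protein", (32.0,), 400.0, 1.6, {}),
    )
    return SimulationConfig(
        samples=samples, markers=markers, noise_sd=noise_sd, seed=seed
    )


def default_sec_config(seed: int = 0, noise_sd: float = 15.0) -> SimulationConfig:
    """Base config for the pooled-SEC-fraction series (pig NC-CM markers)."""
    sample = (SampleMeta("pig_NC_CM", "pig", "NC-CM", 0.9),)
    markers = (
        MarkerSim("ab_CD9", "CD9", (25.0,), 600.0, 1.7),
        MarkerSim("ab_TSG101", "TSG101", (46.0,), 650.0, 2.0),
        MarkerSim("ab_FLOT1", "flotillin-1", (48.0,), 700.0, 2.0),
        MarkerSim("ab_CAV1", "caveolin-1", (21.0,), 500.0, 1.8),
        MarkerSim("ab_GAPDH", "GAPDH", (36.0,), 750.0, 1.8),
    )
    return SimulationConfig(
        samples=sample, markers=markers, noise_sd=noise_sd, seed=seed
    )


#: default SEC enrichment profile: EVs elute in pooled sets 8-10 and 11-13
DEFAULT_SEC_WEIGHTS = {
    "2-4": 0.0,
    "5-7": 0.1,
    "8-10": 1.0,
    "11-13": 0.8,
    "14-16": 0.15,
    "17-19": 0.05,
    "20-22": 0.0,
    "23-25": 0.0,
}


# ---------------------------------------------------------------------------
# fixture files


def write_fixture_files(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write a dataset as the pipeline's input file set (plus truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "readout": out / "readout.csv",
        "beadmap": out / "beadmap.csv",
        "ladder": out / "ladder.csv",
        "panel": out / "panel.json",
        "samples": out / "samples.csv",
        "truth": out / "truth.json",
    }
    dio.write_readout(dataset.readout, paths["readout"])
    dio.write_beadmap(dataset.beadmap, paths["beadmap"])
    dio.write_ladder(dataset.ladder, paths["ladder"])
    dio.write_panel(dataset.panel, paths["panel"])
    dio.write_samples(dataset.samples, paths["samples"])
    truth_json = [
        {
            "sample_id": b.sample_id,
            "antibody_id": b.antibody_id,
            "marker": b.marker,
            "center_mw_kda": b.center_mw_kda,
            "amplitude": b.amplitude,
            "width_fractions": b.width_fractions,
            "afi": b.afi,
        }
        for b in dataset.truth.bands
    ]
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth_json, fh, indent=2)
        fh.write("\n")
    return paths


def read_fixture_files(in_dir) -> Dataset:
    """Read a fixture directory back into a Dataset (inverse of write)."""
    d = Path(in_dir)
    truth_path = d / "truth.json"
    bands: tuple[TruthBand, ...] = ()
    if truth_path.exists():
        with open(truth_path, encoding="utf-8") as fh:
            bands = tuple(TruthBand(**rec) for rec in json.load(fh))
    return Dataset(
        readout=dio.read_readout(d / "readout.csv"),
        beadmap=dio.read_beadmap(d / "beadmap.csv"),
        ladder=tuple(dio.read_ladder(d / "ladder.csv")),
        panel=dio.read_panel(d / "panel.json"),
        samples=dio.read_samples(d / "samples.csv"),
        truth=SyntheticTruth(bands),
    )
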