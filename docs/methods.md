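# Methods

## The measurement being modelled

DigiWest is a bead-based multiplex Western blot. A blotted gel lane is
cut into 96 strips of 0.5 mm, each strip's proteins are coupled to a
distinct color-coded magnetic bead set, and the pooled beads are probed
with antibodies and read on a flow-based fluorescence instrument, which
reports one median fluorescence intensity (MFI) per bead set. Because
each bead color corresponds to one molecular-weight (MW) slice of the
original lane, reassigning color ids to their MW fractions reconstructs
a digital version of the lane: 96 ordered fluorescence values. An
antibody-specific protein band appears in this coordinate as a peak of
fluorescence; its background-subtracted integral, the accumulated
fluorescence intensity (AFI), is the assay's quantitative readout.

This package implements the computational half of that assay: lane
reconstruction, MW calibration, baseline subtraction, peak detection
and integration, the marker-acceptance ruleset used for extracellular
vesicle (EV) panels, and the standard visualisations (Western-blot
mimics, SEC-fraction heat maps, concordance tables). A synthetic-data
generator with analytic ground truth stands in for the instrument.

## Lane coordinate and MW calibration

Fraction indices are 0-based with index 0 at the top of the gel
(highest MW). Migration in SDS-PAGE is approximately linear in
log10(MW), so `fit_calibration` interpolates log10(MW) piecewise
linearly against fraction index through the ladder anchors, extends the
edge segments linearly beyond the outermost anchors, and clamps the
result to [1, 500] kDa. The forward and inverse maps are exact
piecewise-linear inverses of each other inside the anchor span (round
trips reproduce the index to better than 1e-9); `mw_to_fraction`
rejects MWs outside the clamp range. Spline fits were deliberately
avoided: the log-linear form has a closed-form midpoint
(sqrt(m1*m2) at the index midpoint) that makes the calibration
independently checkable.

All MW-tolerance comparisons downstream are made in kDa, not fractions,
because the acceptance rule for band shifts is stated in kDa. One
consequence worth knowing: the MW width of one fraction varies strongly
along the lane — roughly 8–9 kDa per fraction near 240 kDa but well
under 1 kDa per fraction near 15 kDa for the default 250→10 kDa ladder.

## Baseline estimation and subtraction

Two control incubations accompany a run: empty beads (bead background)
and beads probed with the secondary antibody only (nonspecific
secondary binding). The baseline is the element-wise maximum of the two
control lanes — conservative and order-independent — followed by a
window-3 running median (the window shrinks at the lane edges) to
suppress single-bead spikes. When only one control is available it is
used alone; with neither, quantification refuses to run. The net lane
is `max(0, lane − baseline)` per fraction; clipping keeps AFI
non-negative, and the number of clipped fractions is logged.

## Peak detection and AFI

For each expected MW `m` of an antibody, the search window is every
fraction whose calibrated MW lies within `m ± 10` kDa (the same 10 kDa
used by the match rule; a single tolerance keeps search and acceptance
coherent). Within the window the apex is the local maximum (≥ both
neighbours, one-sided at lane edges) with the largest net value; ties
break toward the fraction whose MW is closest to `m`, then toward the
lower index. Integration boundaries extend outward from the apex while
the net signal exceeds `tau = max(5% of apex height, 10 AU)`, then
include one final shoulder fraction at or below `tau` when it still
carries signal — without that shoulder a sigma-2-fraction Gaussian
loses ≈2% of its mass to truncation, which would dominate the error
budget of AFI recovery. A local minimum below 50% of the apex height
splits adjacent peaks (isoform doublets such as caveolin-1 21/24 kDa);
the valley fraction is assigned to the taller peak. Overlapping search
windows of two expected MWs report two peaks only when such a valley
separates their apexes; otherwise the single underlying band is
reported once, matched to the nearer expected MW. The signal itself is
never smoothed before detection — 96 points is already coarse, and only
the baseline gets the median filter.

AFI is the plain inclusive sum of net values over `[left, right]`,
accumulated sequentially so the reported value is bit-identical to a
brute-force sum over the window. On noiseless Gaussian bands the
recovered AFI agrees with the analytic integral `A·σ·√(2π)` to within
1% for σ ≥ 1 fraction (discretization only).

## Marker-acceptance rules

A peak supports a marker call only if all of the following hold, with
every threshold inclusive:

* peak height ≥ 50 AU (`min_height`);
* AFI ≥ 100 AU (`min_afi`);
* apex MW within 10 kDa of an expected band MW (`mw_tol_kda`; the
  match picks the nearest expected MW, ties toward the lower one);
* the antibody's MW shift is consistent across the run's samples:
  every thresholds-passing peak must match within tolerance and the
  spread of signed shifts (max − min) must not exceed 5 kDa
  (`spread_kda`). "Consistent in all samples" is a qualitative rule in
  the assay's practice; the 5 kDa spread is this package's
  operationalisation and is a plain parameter.

Cells whose antibody is not validated for the sample's species are
reported as not-applicable, never as not-detected; that gating comes
from the panel file, not from the data. Every not-detected cell carries
machine-readable reasons (`no_peak`, `below_min_height`,
`below_min_afi`, `no_mw_match`, `inconsistent_shift`).

Two interactions of these rules deserve a note:

* **Thresholds and consistency are not jointly monotone in adversarial
  cases.** Raising `min_height` can remove a badly-shifted passing peak
  and thereby flip its antibody from inconsistent to consistent. On
  realistic data (shifts consistent by construction) raising thresholds
  only ever removes detections, and that is the property the tests
  assert.
* **The spread rule meets the gel's resolution limit at high MW.**
  Near 240 kDa one fraction spans ~8.6 kDa, more than the 5 kDa spread
  allowance, so apex quantization alone can flag a genuinely consistent
  high-MW marker (fibronectin in the default panel) as inconsistent
  under noise. This is a faithful consequence of applying a kDa-scale
  rule to a log-linear lane coordinate, not a detection failure; it is
  the dominant error mode in the simulated panel-recovery rate (~96–98%
  cell agreement instead of 100%).

## The synthetic-data generator

Each simulated lane is `baseline + secondary bump + Gaussian peaks +
noise`, clipped at zero. Peaks are Gaussian in fraction space with
centers placed through the ladder calibration; Gaussian is the simplest
unimodal shape with an analytic integral, which is what makes truth
records (`afi = A·σ·√(2π)`) exact oracles. The bead map is a seeded
random permutation of the 96 color ids, so lane reconstruction is
genuinely exercised; the two control lanes are emitted under the
wildcard sample `*`. Identical (config, seed) pairs reproduce
byte-identical files.

Defaults, and why (the real instrument's noise and background levels
are not published, so these are order-of-magnitude choices made once):

* `baseline_level = 40` AU — bead-background MFI is a few tens of AU on
  Luminex-class readers.
* `secondary_bump = (fraction 88, 25 AU, width 6)` — one broad low bump
  near the dye front representing nonspecific secondary binding.
* marker amplitudes 300–800 AU, widths 1.6–2.4 fractions — optimized
  antibodies on low-protein-input EV samples give signals of a few
  hundred AU over background.
* `noise_sd = 15` AU, additive Gaussian, clipped at zero — one
  twentieth of the weakest default amplitude. The assay's acceptance
  thresholds (height 50, AFI 100) only make sense if instrument noise
  sits well below 50 AU, so noise of order 10–20 AU is the scale
  consistent with the ruleset. A multiplicative noise mode exists
  (`multiplicative_noise=True`, `noise_sd` then a relative CV) but is
  off by default.

The default 15-antibody panel emulates a four-preparation,
three-species EV run (human milk, human MSC, pig NC, dog NC): nine
general EV markers present everywhere, caveolin-1 as a 21/24 kDa
isoform pair with the 24 kDa band only in milk, CD9 with a consistent
−8 kDa shift and absent from MSC-EVs, SHH valid only for
notochordal-cell species, ITGB1 in two species, and three
coisolated-contaminant markers (keratin 8/18, S6 ribosomal protein)
absent from every EV lane. The SEC series generates one lane set per
pooled fraction set (2–4 … 23–25) with marker amplitudes scaled by
per-set enrichment weights; the default weights center the enrichment
on sets 8–10 and 11–13.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: bead-count-dependent MFI variance and
saturation, antibody cross-reactivity and off-target bands, lane-to-lane
transfer efficiency differences, plate effects, and non-Gaussian band
shapes (smiling, streaking). Recovery rates measured here are
upper bounds for real runs.

## Problem sizes and numerical choices

The shipped checks use: 500 random lanes for the exact-integration
oracle, 200 noisy lanes (amplitude/noise = 20) for apex-MW recovery,
20 simulated panel runs (4 samples × 15 antibodies each) for the
detection-agreement rate, and two SEC series of 4 pooled sets for
enrichment localisation; all complete in seconds on one CPU. All
randomness flows through `numpy.random.default_rng` seeds; apex ties
and boundary assignment are deterministic by rule, so fixed-seed runs
are byte-identical end to end. Floats are serialised with `repr` for
lossless text round trips.

## Rendering

Blot mimics map fraction `f` of lane `k` to a 4-pixel row band of
column `k` (nearest-neighbour upsampling), intensity `255·(1 − v)` with
`v` the normalized net value. Per-lane normalization is the default —
band intensities in mimics are not comparable across samples, the
figure conveys band position only — with a per-figure option. An
optional Gaussian blur (in fractions) is applied before normalization
for visual resemblance to film; tests target the pre-blur array. SEC
heat maps carry the accepted peaks' AFI values verbatim (no
re-computation); cells below detection hold a NaN sentinel rendered as
an "X", which is deliberately distinct from a true AFI of zero.
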