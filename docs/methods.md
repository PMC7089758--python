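# Methods

This note records the models, conventions, parameter defaults and design
decisions behind `cuemap`, in the package's own terms. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and conventions

Sessions are plain containers: a `TrackSession` (sample times, positions
along the track, run labels, spike times per unit, optional ΔF/F per cell)
and an `ArenaSession` (2D position, head direction, spikes). Positions are
in cm, times in seconds, rates in Hz. Track bins are 0-based and half-open
— bin *i* covers [5·i, 5·(i+1)) cm — and a cue whose edge falls mid-bin
marks the whole bin (a bin is "cue" if it overlaps any cue extent). Runs
are delimited by teleports, detected as backward position jumps larger
than half the track length; this threshold is robust to tracking jitter.
All interchange files are UTF-8 TSV with headers; floats are written at
full precision and read back bit-exactly.

Spikes are assigned to their nearest preceding trajectory sample, i.e. to
the sample interval that contains them, matching 50 Hz subsampled
trajectories with 0.02 s bins. Each sample carries the duration up to the
next sample (the last sample inherits the median interval), so raw
occupancy sums to the retained recording time.

## Velocity gating and rate maps

Instantaneous speed comes from consecutive displacements (teleport
intervals inherit the previous within-run value) and is smoothed with a
1 s moving boxcar; only samples whose smoothed speed exceeds 1 cm/s enter
any rate map or score, and spikes inherit the retention of their enclosing
sample. The imaging branch keeps samples at or *equal to* 1 cm/s, the one
place the gate is inclusive.

Rate maps divide smoothed spike counts by smoothed occupancy, each
smoothed separately: on the track a 3-point Gaussian with σ = 1 bin
(weights ∝ [e^{−1/2}, 1, e^{−1/2}]), in the arena a 5×5 Gaussian with
σ = 1 bin, over head direction a 5-bin (15°) boxcar. Angular smoothing is
circular; spatial smoothing is not, and kernels truncated at map edges are
renormalised to sum 1 (this preserves constants and keeps interior mass;
whether the original analyses renormalised at track ends is not
documented, so the choice is recorded here). Arena bins visited for less
than 0.3 s in total have an undefined rate and are masked; undefined
values propagate as NaN, never as 0.

## Spatial firing fields

The gated recording is reduced to 100 ms chunks (5 samples at 50 Hz), each
carrying a spike count and the spatial bin of its mean position. The null
model circularly rotates the count series by an offset drawn uniformly in
[0.05 L, 0.95 L] chunks (snapped to whole chunks) and rebuilds the
smoothed rate map — occupancy is untouched because only spikes rotate. The
per-bin p-value is the fraction of 100 rotations whose rate exceeds the
actual rate, ties counting as not exceeding (conservative); bins with
p < 0.3 are field bins. On untuned units this flags ~30% of bins by
construction — the pipeline's measured value is recomputed by
`scripts/acceptance.py` — so fields are a *relative* notion: a field is a
bin the cell prefers relative to its own overall rate. One consequence,
visible in the perturbation analysis, is that deleting cues from the late
track concentrates a cue cell's activity into the early region and
slightly *raises* early-region exceedance; the with-cues track therefore
shows no one-tailed advantage in the shared region (p ≈ 1) while losing
fields decisively in the altered region.

## Cue score

The lagged correlation between rate and template is evaluated at 5 cm
steps over ±300 cm using only the overlapping segment at each lag (no
padding); lags leaving fewer than 10 overlapping bins are skipped. Sign
convention, applied uniformly: **a positive shift displaces the template
toward larger track positions**. The alignment shift is the strict local
maximum of the lag function nearest zero; a plateau contributes its point
nearest zero, two peaks equidistant from zero resolve to the higher
correlation, and if no local maximum exists the global maximum is used.
Local windows span each cue plus half a cue width on each side, clipped at
track ends and kept only if ≥ 3 bins survive; windows of adjacent cues may
overlap. A cue whose windowed rate is constant has an undefined
correlation and drops out of the mean; if every cue drops out the score is
undefined and the cell unclassifiable.

Classification thresholds pool shuffled scores across all cells: each cell
is re-scored against templates whose cues (same number, same widths,
permuted order) are placed uniformly at random without overlap — starts
are drawn continuously via the uniform-gap construction — and the
threshold is the pooled 95th percentile (linear interpolation). 100
shuffles per cell are used in the spike pipeline and 200 in the imaging
pipeline; both are configurable. Classification requires a score strictly
above the threshold.

Side-specific templates keep only one side's cues. Cells passing both side
thresholds are assigned to the side with the higher score (an exact tie is
left unresolved with a warning). The bilateral score is always
left-minus-right: the preferred template is aligned at its own best shift
S and the other template's local-correlation mean is evaluated at the same
S, so a pure one-side responder is pushed to a large |value| and a
both-sides responder toward 0.

## Classic arena scores

The 2D autocorrelation is "unbiased": a Pearson correlation at every
offset over the mutually valid overlapping bins, undefined below 20
overlapping bins. The grid score takes annuli from the inner radius (the
smallest of: first local minimum of the radial mean, first negative
radius, 10 cm) + 4 bins out to the edge of the autocorrelogram − 4 bins —
the corners matter, because the hexagonal ring of a large-spacing grid
lives beyond the map's half-width — and reports the best over annuli of
max(r60°, r120°) − min(r30°, r90°, r150°), rotations by bilinear
interpolation. Note that under this max-over-annuli rule a parallel-stripe
map scores mildly positive (≈ +0.2–0.35), not negative: the per-annulus
anti-correlation argument does not survive the maximum.

The head-direction score is the mean vector length R = |Σ r_k e^{iθ_k}| /
Σ r_k over bin centres, with the preferred angle its argument; for a
von Mises tuning curve R = I₁(κ)/I₀(κ) exactly, which the tests use as a
closed-form anchor. The border score follows the original formulation for
this cell type: fields are 4-connected components above 30% of the peak
rate covering ≥ 200 cm²; cM is the best single-wall coverage by any field;
dM is the rate-weighted mean distance of field bins to the nearest wall
normalised by half the arena width; the score is (cM − dM)/(cM + dM). All
three constants are configurable. Split-half stability is the Pearson
correlation of the two half-session maps over mutually valid bins (≥ 20
required).

Thresholds for these scores pool 100 circular spike-time shuffles per cell
with offsets uniform in [0.5, 0.95] × recording length, 95th percentile.

Duplicate clusters within a day are flagged when arena-map correlation +
track-map correlation + an ISI-similarity term exceeds 2.25 (keep the
cluster with more spikes). The ISI term is implemented as the mean
correlation of the merged train's log-binned ISI histogram with each
cluster's own histogram — the exact construction used originally is not
documented, so this component is an explicit assumption of this package.
Cross-day duplicates are pairs with arena-map correlation ≥ 0.8 or
track-map correlation ≥ 0.75 (keep the higher arena peak). Inclusion gates
for clusters: ≥ 100 spikes, track-rate minimum ≤ 10 Hz, maximum ≤ 50 Hz.

## Population sequences and the ridge/background ratio

Cue-cell rates normalised to their own maximum and sorted by spatial shift
form the sequence matrix. For the ridge statistic the template is
displaced by the cell's shift; the ridge is the 5-bin (25 cm) window
centred on each cue's central bin (even-width cues take the lower-middle
bin) and the background the bins whose distance from the cue centre lies
in (half-width + 20, half-width + 30] cm on either side, excluding bins
inside any displaced cue (an exclusion the original description leaves
implicit). A flat positive rate gives exactly 1. The null permutes field
segments among themselves and gap segments among themselves (alternation
and total length preserved, values travelling with their segments), then
**re-estimates the shift** of each shuffled rate before recomputing the
ratio — matching the fact that shuffled data are re-sorted by their own
shifts. Two p-values are reported: the ratio form
(#null above)/(#null below), which is ∞ and flagged when the denominator
is zero, and the conventional (#above + 1)/(n + 1).

## Perturbation analysis

Track regions are configured as bin intervals, since the region boundaries
are figure-defined rather than printed; the default boundary is the start
of the first removed cue. Run counts across compared tracks are equalised
by truncating to the earliest runs. Two per-cell measures are compared by
one-tailed paired t-tests: the lagged template correlation at the
nearest-zero peak within the region, and the region field fraction.

## Imaging branch

ΔF/F = (F − F₀)/F₀ with F₀ a rolling 8th-percentile baseline over a
configurable window (60 s default); the percentile estimator is an
assumption consistent with the ΔF/F literature, as the original
description does not specify it. Significant transients are excursions
above k·σ lasting ≥ d s, with σ from the median absolute deviation and
(k, d) searched over k ∈ {2, 2.5, 3, 3.5, 4} and d ∈ {0.2 … 1.0} s; the
most sensitive pair whose matching negative-going excursions amount to at
most 1% of the positive events is used, so that artefactual fluctuations
account for < 1% of detections.

Per-bin p-values come from 1000 circular rotations of the gated ΔF/F
trace (offsets uniform in [0.05 N, 0.95 N] samples): p = fraction of
rotations whose bin mean exceeds the real mean. In-field periods are runs
of ≥ 3 adjacent bins with p ≤ 0.2 (≥ 2 suffice at the track ends) in which
at least 10% of runs contain a significant transient — a transient merely
*overlapping* the period counts, the laxer reading of an ambiguous rule —
and out-of-field periods are runs of ≥ 2 bins with p ≥ 0.75. Candidate cue
cells must have at least one of each. The cue score of an imaged cell is
computed by the very same alignment/scoring code as for spikes, applied to
the mean ΔF/F per 5 cm bin.

Cross-environment identity uses the fraction of one track's cue cells that
remain cue cells on the other, against a band (mean ± SD) from 50 random
reassignments preserving each track's class counts, and the Pearson
correlation of the spatial shifts of common cue cells.

## Synthetic data: what it emulates, and what it does not

Defaults define the simulated study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| track length / runs | 800 cm, 40 runs | 8 m track, ≈ 27 min session |
| sampling | 50 Hz (0.02 s) | subsampled trajectory rate |
| running speed | 20 ± 4 cm/s, brief 0.3 cm/s pauses | sustained treadmill running; pauses exercise the 1 cm/s gate |
| cue template | five 25 cm cues, non-uniform spacing | landmark-rich corridor |
| cue cell | Gaussian bump per cue, σ = 10 cm, peak 8 Hz, baseline 0.5 Hz, per-cue amplitude jitter 25% | sparse cue-locked firing with per-cue rate variation |
| cue shifts | uniform ± 20 cm | mostly small shifts around cues |
| arena | 50 cm box, 1800 s, reflecting smooth walk | 10–20 min foraging with full 2.5 cm-bin coverage |
| grid cells | thresholded 3-cosine sum, spacing 30–50 cm, peak 10 Hz | spacings a 0.5 m arena can express: a 54–60 cm period leaves ≤ 2 fields in the box, its autocorrelation contains no complete 60° ring, and detection is at chance under any annulus score (verified empirically), so larger modules are excluded from the generator rather than from the scorer |
| border cells | exp decay from one wall, 4 cm length scale, peak 8 Hz | wall-hugging fields |
| HD cells | von Mises, κ ∈ [2, 4], peak 10 Hz | moderate angular tuning |
| untuned cells | homogeneous Poisson, ~2 Hz | null class |
| calcium kernel | rise 50 ms, decay 400 ms, peak-normalised, noise σ 0.05 | fast indicator dynamics |

Spikes are drawn by thinning an inhomogeneous Poisson process whose rate
is interpolated along the trajectory. All randomness flows from one seeded
generator per session.

The generator reproduces the statistical structure the analysis assumes —
tuning shapes, occupancy patterns, Poisson variability, calcium kernels —
but not several properties of real recordings: no theta or other temporal
spike structure, no conjunctive tuning, no slow drift or remapping, no
motion artefacts or neuropil contamination in the traces, and arena
trajectories are statistically homogeneous rather than behaviourally
biased. Passing calibration and recovery tests therefore establishes that
the pipeline is correct and well-calibrated under its own model
assumptions, not that real recordings would yield any particular cue-cell
percentage.

## Numerical choices and degenerate inputs

Pearson correlations of constant vectors are undefined (NaN) and excluded
from means; every tie in a shuffle comparison counts as "not exceeding";
thresholds require strictly greater scores; percentiles use linear
interpolation. Zero-spike units get all-false field masks with p ≡ 1.
Undefined scores propagate as NaN and such cells are excluded (with
warnings where the exclusion is silent otherwise). Shuffle offsets are
drawn continuously and snapped to whole bins where the null lives on a
grid.

## Problem sizes in the test suite

The suite runs the calibrations at 200 null cells (100 shuffles each), the
mixed-population recovery at 60 cells (30% cue, 20% grid, 10% border, 20%
HD, 20% untuned; ≈ 27 min track and 30 min arena sessions), the
perturbation comparison at 20 cue cells × 15 runs per track, and the
cross-environment analysis at 30 cells on two tracks — sizes chosen so the
binomial error of each calibration stays well inside its acceptance band
while the whole suite completes in a few minutes.

## Known limitations

The within-day duplicate ISI component and the imaging F₀ estimator are
explicit assumptions (above). Grid modules with periods exceeding the
arena cannot be detected by construction. The lag scan treats track edges
by truncation, not padding, so cells whose only cue sits at a track end
lose part of their local window. The CLI covers the simulation → scoring →
sequence path plus perturbation and imaging utilities; arena scoring is
driven through the library API.
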