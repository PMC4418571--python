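# Methods

`tonorep` re-implements, on synthetic data with known ground truth, an
analysis chain for studying repetition suppression inside tonotopically
defined early-stage auditory areas: travelling-wave tonotopic mapping,
gradient-reversal parcellation of the supratemporal patch into ten areas,
acoustic matching of REP/CTRL stimulus sets, and slope-based segmentation of
block BOLD time courses with per-frame repetition statistics.  This note
documents the models, the defaults and the reasoning behind the open design
choices.

## Synthetic cortical sheet

The sheet is a flat 3D slab (default 42 x 24 x 2 voxels of 1.5 mm): a
geometric stand-in for the supratemporal plane with no cortical folding.
Its core holds two mirror-symmetric primary gradients along the
posterior-to-anterior axis — A1 descending from 8 kHz to 88 Hz, R ascending
back to 8 kHz — sharing a low-frequency ridge ("high-low-low-high").  Each
of the 14 half-octave tones of the mapping paradigm occupies one voxel row
per gradient (core 28 x 10 x 2 voxels).  A six-voxel surround, divided into
four antero-posterior sectors with medial and lateral halves (M1–M4,
L1–L4), is frequency-selective without an orderly gradient: every surround
voxel draws its best frequency at random from the 14 tones.  A one-voxel
non-responsive margin surrounds the patch.  Right-hemisphere sheets mirror
the medial–lateral axis.  Per-voxel response gains are jittered uniformly
within ±20%.

## Hemodynamic model

The impulse response is a double gamma parameterised by peak delay and
dispersion (mode and standard deviation of the gamma lobe), normalised to
unit integral so a sustained unit drive saturates at the configured
response amplitude.  The default is deliberately compact — peak 4.2 s,
dispersion 0.7 s, undershoot disabled — because the study conditions the
generator emulates have block responses that saturate by ~6 s after block
onset and return to baseline between 18 and 22 s.  A textbook slow
response (peak 5 s, 1/6 undershoot peaking near 15 s) saturates only
around 10–12 s when convolved with a 16-s boxcar and cannot produce those
windows; it remains available as `HemodynamicModel.canonical()` and every
simulator accepts any model.  The undershoot is off by default because,
superposed across 30-s blocks, it adds a systematic negative slope during
the plateau that the block paradigm under study does not show; it can be
re-enabled through `undershoot_ratio`.

## Simulators

Signal model per voxel, in scanner units with baseline 100:
`data = baseline + amplitude · gain_voxel · (HRF ∗ neural) + global(t) + ε`.
Default amplitude 1.0 equals a 1% signal change.  Noise has a thermal
component per voxel and frame (SD 0.8, i.e. temporal SNR 125) and a global
component shared by all voxels of a frame (SD 0.15) standing in for
physiological fluctuations; without the shared term, ROI averaging over
hundreds of voxels would make between-subject slope estimates unrealistically
precise and every minuscule systematic slope statistically significant.

*Tonotopy runs* present the 14 tones for 2 s each plus a 4-s pause (32-s
cycle, 15 cycles, 240 frames at TR 2 s), ascending and descending.  Voxels
respond to each tone with Gaussian tuning on the log-frequency axis
(SD 0.5 octave, matching the half-octave step size).

*Repetition runs* follow the 16-block design (8 REP, 8 CTRL alternating;
16 s stimulation + 14 s silence; eight stimulus onsets at 2-s spacing).
CTRL blocks drive a unit boxcar over the stimulation period.  REP blocks
drive the same boxcar scaled, after an initial unsuppressed period
(`advance`, default 2 s), by the ROI's suppression factor.  The default
profile sets the factor to 0.8 everywhere except L2 and L3 (1.0), so the
lateral mid areas show no repetition effect; the advance reproduces the
earlier REP peak.  Because no numeric effect sizes are available for the
emulated conditions, these defaults were calibrated once to reproduce the
qualitative pattern (lower REP plateau, REP peak ~2 s earlier, L2/L3
unaffected) and are not revisited.

*Cohorts* add between-subject variability: a multiplicative response gain
N(1, 0.15²) and a uniform ±0.2-s jitter of the HRF peak delay.

*Sound pools* contain 500-ms waveforms at 44.1 kHz with 50-ms linear
ramps and common peak normalisation.  Each sound is a sparse tonal
complex: 2–5 sinusoidal partials at log-uniform random frequencies under a
random attack–decay envelope.  This family was chosen deliberately: its
amplitude spectra vary across exemplars through a handful of latent
factors, giving strongly correlated p-values across spectral bins and
long-tailed per-bin magnitude distributions on which the unpaired t-test
is conservative.  Both properties are what let the iterative matched-set
selection reach the <1% criterion, as it does for recorded environmental
sounds.  Pools of broadband noise — whose spectral bins fluctuate
independently across sounds — pin the significant fraction at the nominal
5% for every split, and no amount of iteration can pass the criterion;
matching feasibility is a property of the stimulus family, not of the
selection loop.

## Tonotopic mapping

The reference time course is the steady-state periodic response to a
single 2-s tone at cycle start, HRF-convolved and sampled at TR (16
samples per cycle).  Each voxel is Pearson-correlated against the
reference at all 16 cyclic lags; the best lag (ties to the earliest)
dates the driving stimulus step.  Because the reference embeds the
assumed hemodynamic delay, the lag maps directly to a stimulus onset; a
wrong assumed delay biases ascending and descending estimates by the same
amount in opposite directions along the frequency axis.  Lags falling in
the silent pause are resolved to the circularly closer band edge and kept
as real-valued "virtual" positions beyond the band; combination of the two
directions averages the positions on the half-octave step axis (equivalent
to the geometric mean frequency) before snapping to the nearest presented
tone (half-step ties toward the lower tone).  Working with virtual
positions keeps the delay-bias cancellation exact at the band edges, where
clamping first would leave a residual half-step error.  Voxels whose two
direction estimates disagree by more than two steps are flagged unreliable
and excluded.  Constant voxels have no defined correlation and are
excluded with reason `constant`.

Significance of r uses the exact t transform with n−2 degrees of freedom;
with the 240 frames of a run, the r > 0.13 mask threshold corresponds to
p ≈ 0.044, i.e. p ≤ 0.05 uncorrected.  At the default SNR this mask covers
more than 95% of truly responsive voxels.

## Parcellation

The suprathreshold patch is the largest 26-connected component of the
mask, with interior holes filled per depth slice (an outlined patch is
contiguous; isolated subthreshold voxels inside it still belong to it).
Best frequencies are median-smoothed over the 3x3 neighbourhood orthogonal
to the posterior-to-anterior axis, which suppresses single-voxel errors
without blurring the gradient.

The delineation automates drawing rules as deterministic geometry:

1. *Column test.*  Every medial–lateral column's log-frequency profile is
   compared to a symmetric V template over a window of one full gradient
   span on each side of its trough.  A column is core-like when the V
   correlation is ≥ 0.8 and both flanks rise by at least half the
   log-frequency range (3.25 octaves).  The largest connected block of such
   columns anchors the core.
2. *Straight borders.*  The posterior and anterior borders (outermost
   window maxima, i.e. the outer high-frequency representations) and the
   A1/R border (centre of the trough run, posterior-biased for odd runs)
   are taken as medians over anchor columns — the borders are straight
   lines, mirroring border "extension" in a manual protocol.
3. *Core width.*  Columns meeting a weaker criterion (correlation ≥ 0.6,
   half the span requirement) extend the core's medial–lateral extent, but
   only where their trough lies within one voxel of the anchor ridge; this
   keeps smoothing bleed at the core's flanks from recruiting surround
   columns.  A1 spans posterior border to ridge, R ridge to anterior
   border, over all kept columns.
4. *Surround.*  The three border lines cut the patch into four sectors;
   each sector's surround splits into medial and lateral halves at the
   core's mid-line (ties go to the medial label), giving M1–M4 and L1–L4
   numbered posterior to anterior.  A1 is always the posterior gradient;
   in right-hemisphere maps the medial side is mirrored.

A map without a reversal (e.g. a single monotone gradient) raises an
explicit "no core found" error.  Empty strip ROIs (core touching the patch
edge) are emitted with a warning.  On noiseless maps the delineation
reproduces the generator's labels exactly; at the default SNR the Dice
overlap for A1 and R is typically ≥ 0.93 and the full labelling changes
for well under 5% of voxels when the noise level moves by ±10%.

The volumetric projection writes labels restricted to a slab of
configurable half-width around the sheet's mid-plane, always keeping the
nearest slice(s).

## Stimulus matching

Envelope (rectified amplitude in 500 1-ms bins) and one-sided amplitude
spectrum (11025 bins, DC dropped) are compared point-by-point between
candidate REP and CTRL sets with two-sided pooled-variance unpaired
t-tests at alpha 0.05, uncorrected — deliberately so, since correcting
would hide real differences that a matching control needs to see.  Points
with zero variance in both sets get p = 1.  Draws are stratified by
semantic category when the pool is tagged.  The first draw with fewer than
1% significant points (envelope and spectrum pooled; both families are
also reported separately) is accepted; if the iteration cap (default
1000) is reached, the result is flagged failed with the best fraction
found, never returned as a silently unmatched set.  The mean-spectrum
control compares per-sound amplitude spectra bin-wise and reports the raw
significant-bin count, the count after Bonferroni correction over the
11025 bins, and the raw count as a fraction.

## Time-course statistics

Extraction: ROI-mean signal, per-block 15-frame windows from block onset,
baseline = mean of the two pre-onset frames (the first block, which has
none, uses the run's first frames; with the response lagging stimulation
by ~2 s those frames are still at baseline), percent signal change,
average across same-condition blocks and runs, then subtraction of the
first frame.  Subtraction rather than division is used for the first-frame
normalisation because the values are already ratio-normalised percent
changes and division by a near-zero first frame would be ill-posed.

Segmentation: the 14 frame-to-frame differences are tested against zero
with paired t-tests across subjects (two-sided, alpha 0.05, uncorrected).
Significantly positive slopes mark a rise, negative a decay, anything else
a plateau.  Reported windows come from runs of at least two consecutive
agreeing transitions — the "minimum of two consecutive frames" restriction
— with two well-formedness rules: the decay window must begin after at
least one non-rise transition past the rise (a decay cannot abut the rise
with no plateau between), and the plateau spans the interval from rise end
to decay start.  For display, isolated single-transition labels are
absorbed into their surroundings (ties toward plateau).  Deriving windows
from raw runs rather than from absorbed labels matters: a transient
mid-course dip (e.g. the REP overshoot settling) is an isolated labelled
transition that must not extend or split a phase window.

The repetition verdict requires at least two consecutive frames with a
significant paired CTRL > REP difference lying inside the plateau window.
The 2x2 ANOVA (hemisphere x condition, both within subject) is computed
frame-by-frame from the closed-form sums-of-squares decomposition with
each effect tested against its subject interaction (df 1, n−1); degenerate
zero-variance cells return F = 0.  The implementation is verified against
`statsmodels` AnovaRM to 6 decimals in the tests.  Extrema statistics take
per-subject maxima, minima and amplitudes over the 15 frames and compare
conditions with paired t-tests.  The sounds-vs-rest localizer fits a
single-regressor GLM (HRF-convolved stimulation boxcar plus intercept) per
voxel.

## What the synthetic data do and do not show

The generator reproduces the paradigm's timing, the mirror-symmetric
gradient geometry, a configurable multiplicative suppression effect and
realistic thermal/global noise with between-subject gain and latency
variability.  It does not emulate cortical folding or surface topology,
scanner noise spectra or drift (preprocessing is out of scope), loudness
equalisation, HG anatomical variants, or semantic structure in the
sounds.  Passing tests therefore validate the analysis logic — recovery of
known ground truth under controlled noise — not in-vivo effect sizes or
which real areas show suppression.

## Problem sizes and numerical choices

Defaults used by the analysis scripts, the acceptance script and the
tests: sheet 42 x 24 x 2 voxels (1760 responsive); 240-frame runs at TR
2 s; 9 subjects x 2 repetition runs; 300-sound pools with 64 REP / 236
CTRL draws.  Monte-Carlo suites use 100–200 replicates (type-I
calibration, power) and 40 seeds per suppression factor; at these sizes
the Monte-Carlo standard errors are an order of magnitude below the
tolerances being checked.  Convolution uses a 0.1-s grid.  All generators
are pure functions of (parameters, seed); every consumer of randomness
takes an explicit seed and the pipeline manifest records all of them.

Known limitations: the flat-slab geometry makes the medial/lateral split a
straight line, which is a convention, not an inference about real border
placement; the border between A1 and R inherits a half-voxel ambiguity
when the trough run has even length (resolved posterior-biased); the
matching loop's runtime distribution is heavy-tailed (acceptance usually
in tens of iterations, occasionally hundreds).
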