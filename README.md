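# tonorep

Tonotopic mapping and repetition-suppression analysis of early-stage
auditory areas, on synthetic 7T-like fMRI data with known ground truth.

Human primary auditory cortex contains two mirror-symmetric frequency
gradients (fields A1 and R) that can be located with a travelling-wave
paradigm: 14 pure tones in half-octave steps from 88 Hz to 8 kHz, 2 s per
tone plus a 4-s pause, cycled 15 times per run, so that each voxel's
response latency encodes its best frequency.  Correlating every voxel
against a canonical single-tone response at all 16 cyclic lags yields a
best-frequency map; ascending and descending runs are averaged on the
log-frequency axis, which cancels the hemodynamic-delay bias.  Thresholding
at r > 0.13 (p ≤ 0.05 at n = 240 frames) defines a contiguous patch that is
parcellated into 10 areas per hemisphere — A1, R, and eight surrounding
frequency-selective areas (M1–M4 medial, L1–L4 lateral) — from the
"high-low-low-high" reversal geometry.

Repetition suppression is then assessed with a block paradigm: 30-s blocks
(16 s of eight 500-ms sounds at 2-s intervals, 14 s silence) that present
either eight exemplars of the same sound source (REP) or eight different
sources (CTRL), with the two stimulus sets iteratively matched until fewer
than 1% of acoustic comparison points (envelope time points and amplitude-
spectrum bins, unpaired t-tests at p < 0.05) differ.  Per-ROI block time
courses (15 frames at TR 2 s, % signal change) are segmented into rise /
plateau / decay by paired t-tests of consecutive-frame slopes against zero
(≥ 2 consecutive agreeing transitions), and a repetition effect is declared
when CTRL exceeds REP on ≥ 2 consecutive significant frames within the
plateau.

Since no real acquisitions are bundled, a first-class synthetic-data module
generates every input with known ground truth: tonotopic cortical sheets,
travelling-wave and block runs with configurable suppression profiles and
noise, and sound pools.  See `docs/methods.md` for models, defaults and
design rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study and write their
tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_map_tonotopy.py
python analysis/03_parcellate.py
python analysis/04_match_stimuli.py
python analysis/05_repetition_stats.py
```

Output of steps 02–05 (seed 1):

```
LH: r>0.13 covers 99.5% of responsive voxels; 83.0% assigned the true tone.
RH: r>0.13 covers 99.7% of responsive voxels; 83.5% assigned the true tone.
r = 0.13 at n = 240 frames corresponds to p = 0.0442.
LH: 10 areas; A1 Dice 0.952, R Dice 0.952
RH: 10 areas; A1 Dice 1.000, R Dice 1.000
matching accepted after 18 iterations; significant fraction 0.92%
mean-spectrum control: 99 of 11025 bins at p<0.05 (0.90%); 0 after Bonferroni.
phase windows (s): {'rise': (2.0, 6.0), 'plateau': (6.0, 18.0), 'decay': (18.0, 22.0)}
repetition effect detected in 17 of 20 area x hemisphere cells
```

Reading this: the suprathreshold mask recovers essentially all responsive
voxels and the parcellation finds exactly the 10 ground-truth areas with
near-perfect overlap for A1 and R; the stimulus matching converges well
under its 1000-iteration cap with 0.92% of comparison points significant
(the paper-style mean-spectrum control sits at ~1% of bins before
correction and none after Bonferroni); the segmentation recovers the
built-in response phases (rise 2–6 s, plateau 6–18 s, decay 18–22 s); and
the per-area contrast detects the simulated suppression in all 16
suppressed area x hemisphere cells while the two unsuppressed areas (L2,
L3) stay mostly silent (one false positive at this seed).

The same steps are available as a CLI (`tonorep simulate`, `matchsounds`,
`tonotopy`, `parcellate`, `repstats`, `pipeline`, `report`) for running on
files instead of in-memory objects.

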