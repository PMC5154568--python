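# Methods

## The measurement being modelled

Laser speckle flowgraphy records the mean blur rate (MBR) — a relative
blood-flow-velocity index in arbitrary units (AU) — over the optic nerve
head as a short video: 118 frames at 30 frames/s (~4 s), 750×360 pixels.
Within that window the instrument's analysis identifies the cardiac cycles,
folds them onto one normalised cycle, and summarises the waveform's shape
with a set of pulse indices. This package reimplements that chain on
synthetic data whose statistical structure mimics a healthy 80-subject
test–retest cohort.

## Analytic pulse model

One cardiac period `T = 60/HR` is split at the systolic rise fraction
`f ∈ (0, 0.5)`:

* **upstroke** (`phase < f`): raised cosine from the end-diastolic level to
  `b + A` (baseline `b`, pulse amplitude `A`, both AU);
* **decay** (`phase ≥ f`): exponential toward `b` with time constant `τ`
  (seconds), the Windkessel discharge of the arterial compliance.

The upstroke starts at the level the decay reached at the end of the
previous cycle, so the curve is continuous and periodic with a single
maximum per cycle at phase `f`. With `A = 0` it degenerates to the constant
baseline. The true minimum sits at the cycle boundary at
`b + A·exp(−(1−f)T/τ)`; `b` is the *asymptotic* diastolic floor, reached
only as `τ → 0`.

Arterial stiffening with age is encoded as linear age maps with Gaussian
between-subject scatter:

| parameter | at age 18 | slope / year | subject SD |
|---|---|---|---|
| diastolic decay τ (s) | 0.75 | −0.006 | 0.10 |
| systolic rise fraction f | 0.30 | −0.0004 | 0.03 |
| tissue baseline b (AU) | 7.5 | −0.030 | 1.2 |
| pulse amplitude A (AU) | 10 | 0 | 1.5 |
| heart rate (bpm) | 75 | −0.10 | 9 |

plus sex-shifted blood pressures (systolic +4.3 mmHg for male subjects,
−4.3 for female, matching the direction of population summaries) and IOP
drawn at 12.8 ± 2.4 mmHg. The slopes and scatters were fixed once, by
calibration, so that the cohort-level correlations with age carry the
directions — falling rate and resistivity rising, blowout time and the
MBR levels falling — and roughly the magnitudes reported for healthy-eye
flowgraphy cohorts; they are a modelling choice, not an estimate.

Each scan adds: a uniform random cardiac phase at scan start, a per-scan
baseline offset (SD 0.35 AU, the "between-scan" component), and white
per-frame noise (SD 0.4 AU) truncated at zero. Scans fail as Bernoulli
events (default 15/240 undilated, 3/240 dilated — pupil-size-driven
failures disappear under mydriasis). Pupil dilation itself is a condition
label with small constant index offsets; no pharmacological model is
attempted.

**Noise-free configuration.** `GeneratorConfig.noise_free()` zeroes every
SD and failure probability *and fixes the scan phase*. The last point
matters: even at zero noise, two scans starting at different cardiac phases
sample the 30 fps grid at different offsets and their composite cycles
differ in the last decimal places, so exact ICC = 1 / COV = 0 requires the
phase to be pinned as well. This is the sense in which every generator
collapses to its analytic core.

## Waveform analysis

* **Cycle detection.** The series is smoothed with a 3-sample moving
  average; local minima (diastolic troughs) are found with a minimum
  spacing of one cycle at 120 bpm and a prominence of 5% of the series
  range; consecutive troughs whose spacing implies 40–120 bpm bound the
  cycles (the longest admissible run is kept). No admissible cycle → a
  `NoCycleError`, the analogue of a scan-quality exclusion.
* **Composite cycle.** Each cycle is linearly interpolated onto 30 equally
  spaced phase bins (≈ one bin per frame at 60 bpm) and cycles are averaged
  pointwise. Indices are computed on the composite, not per cycle — with
  3–4 cycles per record the composite is the lower-variance choice and
  matches the folding-then-summarising order of the instrument's described
  processing.
* **Tie-breaks and conventions.** Extrema take the first occurrence; all
  indices use 0-based bins and half-open cycles; a flat cycle has BOT = 100
  (with a warning), RI = 0, FAI = 0, while skew and the limb rates are
  errors (their defining moments vanish). BOS is clipped into [0, 100] with
  a warning if a pathological cycle drives it outside.

Two vendor-underspecified choices are exposed in `WaveformConfig`:

* **BOT half-level** — `(min+max)/2` by default (the standard half-width
  level; the alternative `(min+max)/4` reading of "half of the mean of the
  minimum and maximum" is selectable).
* **Skew** — implemented as the standardised third moment of the
  *amplitude-weighted phase distribution* (the waveform treated as a
  distribution of flow over the cycle), times a scale constant (default 10;
  the vendor scaling is unpublished). A value-histogram skewness was
  rejected because it is blind to time reversal: a slow-rise/fast-fall
  waveform has the same value multiset as its early-peaked mirror image,
  yet the index is meant to change sign between them. The weighted-phase
  form is exactly zero for time-symmetric cycles, positive for early peaks,
  negated by time mirroring, and invariant to MBR rescaling.

Rising/falling rate are the mean per-bin increment (decrement) over the
trough→peak (peak→trough) limb, divided by the cycle mean, ×100 — scale-free
and strictly increasing as `τ` falls (FR).

## ONH maps

The composite map averages only frames inside complete detected cycles
(detection runs on the ROI-mean series). Pixels belong to the elliptical
ROI if their centre lies inside the rotated ellipse (boundary-inclusive,
with a 1e−9 tolerance so boundary pixels are stable under rotated
coordinates). Vessel extraction thresholds the in-ROI intensity
distribution with Otsu's between-class-variance criterion (a percentile
rule is available); the instrument's proprietary "cross-section analysis"
is not claimed to be equivalent, only to share the automatic,
deterministic contract. The regional means satisfy
`MA = f·MV + (1−f)·MT` exactly, and `MV > MT` whenever the split is
non-degenerate.

## Statistics

* COV (%) = mean within-subject SD (n−1 denominator) over the grand mean.
* ICC from two-way repeated-measures ANOVA mean squares; default ICC(3,1)
  (mixed, consistency, single measurement), with ICC(2,1) and the one-way
  form switchable. Subjects with incomplete repeats are dropped first.
  The implementation is checked against `pingouin.intraclass_corr` in the
  test suite.
* Pearson r with a two-sided t-test on n−2 df; the regression line carries
  a pointwise 95% confidence band for the mean response. Age and sex
  analyses use the per-subject mean of the dilated scans, mirroring the
  study convention.
* Paired and independent t-tests (pooled variance by default, Welch
  optional); identical paired samples return p = 1, a constant non-zero
  shift returns p = 0 — the zero-variance limits scipy leaves as NaN.
* Success rates compared with the uncorrected Pearson chi-square on the
  2×2 table (1 df). The continuity correction is off by default because
  the uncorrected statistic reproduces the conventional reporting on
  counts of this size; it can be switched on. No multiple-testing
  correction is applied anywhere, matching the single-comparison reporting
  style of this literature.
* MAP uses the standard `DBP + (SBP−DBP)/3`. The variant
  `SBP + (SBP−DBP)/3` that sometimes appears in print is internally
  inconsistent with the summary tables it accompanies (it would give
  MAP ≈ 144 where 96 is reported) and is kept only behind
  `map_formula="printed"`.

## Problem sizes

The default cohort is 80 subjects × 2 conditions × 3 repeats = 480 scans,
each a 118-frame series pushed through the full waveform chain (~1 s for
the whole cohort). The Monte-Carlo properties use 100 cohort seeds for the
age-sign pattern, 2000 replicates for the paired-test null calibration, and
1000 random physiological cycles for the BOS–RI identity. Rendered frame
stacks in the demonstrations use a reduced raster (e.g. 180×375) —
geometry-proportional to the full 360×750 frame, which the generator also
supports.

## Known limitations

* The single-exponential decay cannot produce a dicrotic notch, and at a
  physiological resistivity (RI ≈ 0.37) it yields blowout times near 40%
  rather than the ~50% typical of real ONH waveforms — real diastolic
  decay is closer to linear over the cycle. Sign structure and
  reliability behaviour, which are what the simulation is used to test,
  are unaffected.
* Skew magnitudes (≈ 1–3 with the default scale) sit below the ≈ 12 of the
  vendor's (unpublished) scaling; all skew tests are scale-free.
* Scan failures are age-independent by default; any pupil-size–age link is
  not modelled.
* Acceleration time index repeatability is limited by the one-bin
  quantisation of the peak position at 30 phase bins; its synthetic ICC is
  therefore lower than the other indices'.
* The generator starts at the MBR level; no speckle statistics or raw
  interferograms are modelled, and validation against the proprietary
  instrument software is out of scope.
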