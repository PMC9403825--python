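# Methods

## The counting model

The counter consumes the Euclidean magnitude of 3-axis wrist
acceleration sampled uniformly at 20 Hz, in units of g. Magnitude is
orientation-invariant, which matters on the wrist where the device may
rotate. Processing is a two-phase pipeline over 5-second windows
(100 samples):

1. **Gate.** The window's raw magnitude is summarized by seven
   time-domain features (mean, sample SD, min, max, energy of the
   mean-removed signal, zero crossings, range) and classified into
   low / moderate / vigorous activity. Only moderate and vigorous
   windows are counted; this is what keeps random hand motion, desk
   work and vehicle vibration out of the step total.
2. **Detector.** The full day's stream is conditioned by two strictly
   causal filters and peaks are counted on the result:
   - zero-meaning: `z[i] = m[i] − mean(m[max(0, i−20) .. i−1])`,
     removing the gravity baseline and slow drift;
   - moving average: `f[i] = mean(z[max(0, i−3) .. i−1])`, suppressing
     sample-level jitter.

   A step is a point where the discrete slope of `f` changes from
   positive to negative and the peak value exceeds the cut-off
   threshold `T` (in g, strict inequality).

### Warm-up and tie conventions

Both filters are defined with strictly preceding samples. At the start
of a stream the preceding window is shorter than nominal; we use the
mean of whatever preceding samples exist, with `z[0] = 0` and
`f[0] = z[0]`. "The 3 preceding samples" is read literally as indices
`i−3 .. i−1`; a causal window including the current sample is a
defensible alternative reading, and the filter length is configurable
if a user prefers it.

Zero slopes inherit the sign of the last nonzero slope, so a
flat-topped peak is counted once and attributed to the first sample of
its plateau; a rising staircase is not a peak. The first and last
samples of an isolated window cannot be peaks (slope change is
undefined there).

### Continuous detection, windowed gating

Filters and peak detection run over the whole day's stream; the
5-second windows exist only for classification and reporting. Each
detected peak is attributed to the window containing its sample, and
zeroed if that window is low-activity. Detecting peaks independently
per window was tried and rejected: excluding each window's edge
samples silently loses the ~2% of steps whose filtered peak lands on a
window boundary (one peak every ~24 windows at normal cadence), which
is both a real undercount and inconsistent with the continuous
on-device stream the design assumes. A trailing partial window is
dropped (< 5 s per day at 20 Hz).

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| sampling rate | 20 | Hz | device logging rate; all sample-count parameters assume it |
| window length | 5 | s | classification and counting granularity |
| zero-mean history | 20 | samples (1 s) | removes gravity while passing ~2 Hz step peaks |
| smoothing length | 3 | samples | kills single-sample jitter without merging adjacent steps |
| peak cut-off `T` | calibrated, 0.05 | g | see calibration below |
| candidate grid | 0.05–0.25 in 0.05 steps | g | the tuning search space; five values spanning plausible filtered step-peak heights |
| wear threshold | 675 | min/day | 75% of a 15-hour waking day, inclusive |
| reference worn rule | > 100 | steps/day | strict; a reference day at or below 100 steps is treated as not worn |

Irregularly sampled input is rejected rather than resampled: the
filter lengths and window size are sample counts, and silent
resampling would change behavior.

## The activity gate

Two interchangeable models implement the gate. The default is a
two-cut-off rule on the window's magnitude SD (`sd_threshold`):
moderate above the first cut-off, vigorous above the second. It needs
no training data; its cut-offs come from the calibration battery
(midpoint between the largest SD seen in rest/hand-motion/non-wear
windows and the smallest SD seen in walking windows; the vigorous
cut-off is the midpoint of the normal- and fast-walk mean SDs). A
linear max-margin classifier (`linear_margin`, one-vs-rest on
standardized features) can be trained on labeled windows when such
data exist; `loso_cv` scores it by leave-one-subject-out
cross-validation. Models serialize to a flat, schema-versioned YAML so
a trained gate is portable. Only moderate and vigorous windows open
the gate.

## Threshold calibration and tuning

`calibrate_defaults` re-enacts the empirical determination of the
default parameters on the simulator: it runs a fixed battery of 120 s
bouts (normal / fast / stairs with zero sensor noise and nominal
amplitudes — a controlled, lab-style walk — plus rest, hand motion and
non-wear at their defaults), sets the gate cut-offs from their window
SDs, and selects as default cut-off the **smallest** grid candidate
that both recovers the deterministic normal-walking bout exactly and
yields zero steps on all confounder bouts. Smallest, because the
target population steps more softly than the nominal bout and
sensitivity to weak steps is the scarce quantity — false positives are
already held at zero by the gate and the confounder requirement. That
candidate is 0.05 g.

`tune_threshold` is the field procedure: count every paired day under
each candidate, compare to the reference device by percentage
difference `100 (watch − ref)/ref`, and select the candidate with the
smallest |mean percentage difference| (ties to the smaller threshold,
which can only over-count, never silently drop steps). Per-candidate
R² of watch-on-reference regression is reported alongside but is not
the selection criterion, because a threshold that scales all days by a
constant factor can have perfect correlation and terrible error.

## Agreement evaluation

Days pass the wear filter when the watch was worn ≥ 675 minutes
(inclusive) and the reference reports > 100 steps (strict). On the
paired days: OLS of watch on reference (r² = squared Pearson
correlation), mean and SD of the daily percentage difference, and
Bland-Altman limits at `mean(d) ± 2·SD(d)` for `d = watch − reference`
with the sample (n−1) SD. The 2 SD multiplier (not 1.96) follows the
protocol this package implements. Days with `|d − mean| > 2 SD` in
either tail are flagged as outliers; in free-living data these are
typically days one device was removed early.

## The simulator

`gait_simulator` emits what the detector actually consumes: a 1 g
baseline, one raised-cosine pulse (0.3 s wide) per step with per-step
amplitude drawn from a truncated normal, Gaussian sensor noise, and
step intervals at the nominal cadence with ±10% jitter. Pattern
parameters are field-realistic choices, fixed once:

| pattern | cadence (steps/min) | pulse amp (g, mean ± SD) | noise SD (g) |
|---|---|---|---|
| normal | 100 | 0.30 ± 0.05 | 0.02 |
| fast | 130 | 0.45 ± 0.07 | 0.02 |
| stairs | 80 | 0.18 ± 0.03 | 0.02 |
| intermittent | 100, alternating 20 s walk / 10 s rest | 0.30 ± 0.05 | 0.02 |
| rest | — | — | 0.01 |
| hand motion | — | 0.05 drift (0.4 + 0.23 Hz tones) | 0.01 |
| non-wear | — | — | 0.002 |

`simulate_day` concatenates scheduled bouts with continuous
timestamps; an hour is flagged not-worn only when every sample in it
comes from a non-wear bout. `simulate_reference_device` models the
commercial comparator as `round(truth · (1 + bias%) · (1 + ε))`,
`ε ~ N(0, noise%)` — a bias plus day-level noise, nothing more. All
draws come from one `numpy.random.default_rng(seed)` per scenario; the
same seed is bit-reproducible.

### What the simulator does and does not establish

Passing tests on simulated gait shows the implementation is faithful
to its definitions (filters match their naive re-evaluation exactly,
peaks match a brute-force local-maxima oracle, tuning recovers the
generative threshold, the gate provably zeroes low windows). It does
**not** establish accuracy on real wrists: the simulator has no arm
swing, no orientation change, no pushing-a-cart attenuation, no
per-person amplitude/cadence distributions — in particular, none of
the gait changes that accompany obesity or advanced age. Error rates
on simulated stairs/fast bouts are near zero here, whereas real
devices show pattern-dependent signed errors; only the ordering
(stairs hardest, under-counted) carries over. Claims about a real
population require the lab/field protocol this package implements, run
on that population.

## Problem sizes

Tests and the acceptance script use deliberately small workloads: 1000
random windows/series for the oracle-equivalence and monotonicity
checks, 120–300 s bouts, a 14-day corpus (3 seeds) for tuning
recovery, and a 20-day corpus of ~13-hour days for the agreement
protocol. These sizes give stable statistics (binomial SE on the ±2 SD
coverage check at n = 10⁵ is 0.07%) while keeping the full suite under
a minute.

## Known limitations

- The gate's default SD cut-offs are simulator-calibrated; on real
  data the `linear_margin` model should be trained on labeled windows.
- Step detection on the filtered signal compares the *filtered* peak
  value to the cut-off; if a deployment compares the raw magnitude
  peak instead, the calibrated cut-off does not transfer.
- Wear minutes are hour-granular (60 minutes per worn hour), matching
  the hourly wear flag the watch records.
- `pct_diff` requires a positive reference count; days where the
  reference reports 0 steps are excluded upstream by the wear filter.
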