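# Methods

This note documents the models, conventions and design choices behind
`hypnoscore`, and what the synthetic-cohort experiments do and do not show.

## Problem setting

Wrist actigraphy scores 30-s epochs as wake or sleep from movement counts
alone; its specificity is notoriously poor because quiet wakefulness looks
like sleep to an accelerometer. Cardiac autonomic state carries the missing
information: heart rate falls through NREM sleep and rises again in REM, and
the sympathovagal balance summarized by the LF/HF ratio of heart-rate
variability (HRV) is elevated in REM. `hypnoscore` fuses both channels: for
every epoch it combines the activity count with 17 HRV metrics computed over
a trailing window, and classifies a 21-epoch context window with a
convolutional-recurrent network (DeepConvLSTM) into W/NREM/REM (or a binary
sleep/wake head). The classic UCSD weighted-window algorithm is provided as
the count-only comparator, and an evaluation layer reproduces the standard
device-vs-PSG statistics battery.

## HRV metrics

Intervals belong to a window when their **terminating beat** falls in the
half-open span `(t_end − L, t_end]`, with `L ∈ {30 s, 180 s, 300 s}` and
`t_end` at the scored epoch's end (trailing/causal alignment; a centered
alignment is available via `align="centered"` — nothing in the underlying
measurement fixes this choice, and the causal default means features never
depend on future data). Windows clipped at the record start are computed on
the available beats and flagged, not dropped.

Conventions, chosen to match mainstream HRV software:

- **MeanHR** is the mean of per-beat instantaneous HR (60000/RR); a switch
  (`hr_from_mean_rr=True`) gives 60000/MeanRR instead.
- **Min/Max HR** use a 5-beat moving average of instantaneous HR; windows
  with fewer than 5 beats fall back to MeanHR (detectable by equality).
- **HRVti / TINN** use a 1/128-s histogram whose bins are aligned to the
  absolute time axis. TINN is the baseline width of the least-squares
  triangular fit to that histogram; with fewer than three occupied bins the
  fallback is the occupied-bin span. The squared error of the fit separates
  at the modal bin, so the left and right feet are optimized independently
  (an exact, not approximate, speedup — verified against the exhaustive
  O(B²) scan in the tests).
- **Stress index** is √(AMo / (2·Mo·MxDMn)) from a 50-ms histogram, with Mo
  the modal-bin center in seconds; constant windows return NaN (undefined).
- **Spectra**: the tachogram (RR vs terminating-beat time) is resampled at
  4 Hz with a cubic spline, linearly detrended, and fed to Welch's method —
  150-s segments with 50% overlap for 300-s windows, a single segment
  otherwise. Band power integrates the PSD over VLF (0–0.04 Hz), LF
  (0.04–0.15 Hz) and HF (0.15–0.4 Hz); the peak is the argmax frequency in
  the band. VLF fields are NaN for windows shorter than 50 s (two periods
  of the upper band edge). LF/HF is NaN when HF power is zero.
- **PNN50** divides the count of successive differences above 50 ms by the
  *total number of intervals* in the window (so 19 qualifying diffs among 20
  intervals give 95%, not 100%).

Degenerate inputs propagate NaN sentinels per epoch rather than raising, so
a few unanalyzable epochs never lose a record.

**Artifacts.** The artifact detector is a deliberately simple, documented
rule: the fraction of intervals deviating more than 20% from an 11-beat
running median, reported as a percentage; records at or above 5% are
excluded from training and evaluation. It makes no attempt to correct beats.

## UCSD comparator

Counts are aggregated to minutes by pairwise summation (an odd trailing
epoch is carried as a flagged half-minute). The decision statistic is a
7-min weighted span, minutes −4…+2 around the scored minute, with the
PIM-mode coefficients of the original publication stored in a versioned YAML
(never hard-coded); `D < threshold` scores sleep, and each minute's label is
duplicated to its two 30-s epochs. Record edges are zero-padded, which
biases the first four and last two minutes toward sleep; the output flags
this. The scorer is monotone: increasing any count can only move epochs
toward wake.

## DeepConvLSTM scorer

Input windows span 21 epochs (±10 around the scored epoch) × C channels
(C = 1 for counts alone, 18 with the HRV block). Record edges are padded by
replicating the terminal epoch's channel vector. Channels are standardized
with statistics computed on **training subjects only** and reused verbatim
everywhere else; NaN feature cells are imputed with the training mean. All
splits are by subject, never by epoch, and subject overlap between any two
of train/validation/test is a hard error.

The architecture is a stack of same-padded 1-D convolutions along the epoch
axis, each followed by batch normalization and ReLU, then LSTM layers whose
final hidden state feeds the head: one sigmoid unit with binary
cross-entropy for sleep/wake, or a 3-way softmax for W/NREM/REM (the
default; the binary task is the `n_classes=2` mode). Convolution kernels
carry an L2 penalty. Training uses Adam with inverse-frequency class
weights, and the returned weights are those of the minimum-validation-loss
epoch (early stopping on patience). The reference depth is 9 convolution
layers and 4 LSTM layers; per-layer widths have no published values, so the
defaults are kernel 3, 32 filters, 32 LSTM units, L2 1e-4, Adam 1e-3, all
exposed in `ModelConfig`.

The network core is a self-contained float64 numpy implementation with
manual backpropagation; gradients of every layer are verified against
central finite differences in the test suite, and training is
bit-reproducible given the seed.

**Desk scale.** CPU-scale experiments use `ModelConfig.desk_scale()`:
2 convolution layers / 1 LSTM layer at width 16, ≤30 training epochs, and
cohorts of 20 subjects × 480 epochs (4-h records). These sizes are the
package's default experimental conditions; the full 9/4 architecture and
longer records are configuration away.

**Random search** samples the published hyperparameter axes (regularization
rate, learning rate, convolution depth, filters, hidden units, LSTM depth —
the last only for DeepConvLSTM candidates), trains each candidate on a
subject-level 70/30 split, ranks by validation loss, and re-scores the top
five by subject-level 5-fold cross-validation. Desk default is 5 + 5
candidates; the full 50 + 50 is a parameter.

## Sleep parameters

Record bounds come from the SpO2 coverage channel: consecutive,
non-overlapping 5-min (10-epoch) blocks counted from recording start; the
record runs from the first block holding ≥30 s of samples to the end of the
last such block. Every parameter is computed strictly within those bounds.

Sleep onset is the first epoch of the first 10-min span with at least half
its epochs scored sleep. The span slides epoch-by-epoch by default; a
tumbling fixed-block variant is available (`sliding_onset=False`) since the
block phrasing is ambiguous. SOL runs from lights-off (default: bound
start) to the span start. WASO counts wake from the first epoch actually
scored sleep at or after that span start — the latency inside the onset
span belongs to SOL, not to wakefulness after sleep onset. TST is 0.5 min
per sleep epoch in bounds, SE = TST/SPT × 100, and REM/NREM minutes
partition TST.

## Evaluation statistics

Epoch-by-epoch accuracy, sensitivity, specificity and Cohen's kappa are
computed per subject for a stated positive class (sleep, or one-vs-rest
REM/NREM) and reported in percent; kappa uses marginal-product chance
agreement and is 0 by convention when either rater is constant. Cohort
summaries are subject-level means with t-based 95% CIs (normal-quantile mode
behind a flag); NaN subjects are excluded and counted.

Bland–Altman differences are **reference minus device** (PSG − IA), so a
positive bias means the device underestimates. Limits of agreement are
bias ± 1.96·SD; the bias is paired-t tested against zero; proportional bias
is the OLS slope of the differences on the pair means; MAE is the mean
absolute difference. Two devices' biases over the same subjects are
compared with a paired t-test on the difference of their difference vectors.

One symmetry worth stating precisely: swapping reference and prediction
leaves accuracy and kappa unchanged but exchanges sensitivity with *PPV*
(not specificity); it is flipping the positive class that swaps sensitivity
with specificity. The tests assert the true symmetries.

## Synthetic cohort

The generator produces the statistical structure the scorer exploits, not
physiology per se:

- **Hypnogram**: first-order Markov chain over {W, N1, N2, N3, REM} per
  30-s epoch, started in wake. Default self-transitions encode realistic
  bout lengths (minutes-long wake/N1 bouts, ~10-min consolidated N2/N3
  bouts, ~12-min REM periods). Because the chain is sticky, single-night
  empirical stage frequencies scatter several points around the stationary
  distribution; the eigen-analysis oracle is therefore checked on long
  chains (3×10⁴ epochs) where sampling noise is small.
- **Activity**: zero-inflated negative binomial per stage — wake epochs
  high-mean and overdispersed (burst probability 0.95, mean 150), sleep
  epochs mostly zero with rare small bursts. Emulates PIM-mode counts.
- **RR series**: piecewise-stationary per stage — baseline 60000/HR plus a
  0.1-Hz LF sinusoid, an HF sinusoid at the stage's respiratory frequency
  (0.25 Hz), and white jitter, floored at 250 ms. Defaults encode mean HR
  wake (70) > REM (64) > NREM (55–62) bpm, beat-to-beat variability
  shrinking from wake into deep NREM, and an LF amplitude elevated in REM
  (35 ms vs 5–15 ms) so the measured LF/HF is higher in REM than NREM.
- **SpO2 coverage**: near-30-s coverage per epoch with optional
  leading/trailing dropout to exercise bound detection.

Per-subject seeds derive from the master seed; identical parameters give
bit-identical cohorts. The split helper sends `round(0.65·N)` subjects to
training (13/7 at N = 20).

What it does **not** emulate: ECG waveforms and QRS detection, apneas,
arousal microstructure, circadian drift, movement artifacts in the count
channel, or between-subject covariance of cardiac and motor parameters.
Consequently, passing the learning-recovery tests shows the pipeline is
correct and the classifier can exploit exactly the planted count/HR/LF-HF
structure — it says nothing about accuracy on real polysomnography, where
stage-conditional distributions overlap far more.

## Known limitations

- The UCSD coefficients ship as the published PIM-mode defaults; other
  count modes reuse the same kernel unless overridden.
- The Welch spectrum of a 30-s window has ~0.033-Hz resolution; VLF metrics
  are undefined there by construction and LF peaks are coarse. This is a
  property of the window length, not of the implementation.
- `random_search` at desk scale explores a small grid of small models;
  rankings between near-tied candidates are noise-dominated.
- The simulator's stage-conditional parameters are chosen for testability
  and plausibility, not estimated from any cohort.
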