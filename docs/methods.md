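# Methods

`iscmusic` measures how strongly a piece of music "grips" a group of
listeners by the inter-subject correlation (ISC) of their EEG: when a
time-locked stimulus drives the brain responses of different people in the
same way, linear combinations of their electrodes become correlated across
subjects. The package implements the full chain from raw multi-channel
recordings to condition-level statistics, together with a synthetic-study
generator that makes every stage testable against known ground truth.

## Correlated component analysis

For subject $i$ with demeaned data $X_i \in \mathbb{R}^{C \times T}$
(channels x samples), define the pooled covariances

$$R_w = \sum_i X_i X_i^\top, \qquad R_b = \sum_{i \ne j} X_i X_j^\top .$$

A single set of projection vectors $W$, shared by all subjects, maximises
between-subject correlation; its columns solve the generalized eigenproblem
$R_b w = \lambda R_w w$, taken in descending eigenvalue order. This is
canonical correlation analysis constrained to use identical projections for
every subject. Design choices:

* **Summation over pairs** (not averaging) in $R_b$, and **demeaning per
  subject per segment**; multiple segments contribute additively. These
  conventions are configurable because different conventions rescale
  eigenvalues without changing eigenvectors.
* **Shrinkage** $\gamma$ (default 0.1) replaces $R_w$ by
  $(1-\gamma)R_w + \gamma\,\mathrm{diag}(R_w)$. With 64 channels and
  thousands of samples the unregularized problem is well posed, but
  leave-one-piece-out training on subsets benefits from the ridge; a
  near-singular $R_w$ without shrinkage raises an error that names the fix.
* **Forward model** $A = R_w W (W^\top R_w W)^{-1}$: the scalp topography of
  each component, used for interpretation and for ground-truth recovery
  checks ($W^\top A = I$ holds to machine precision).
* **Sign convention**: each component is flipped so the largest-magnitude
  entry of its forward-model column is positive, making topographies
  deterministic.
* **Reported statistic**: ISC of subject $i$, component $k$ is the mean
  over other subjects $j$ of the Pearson correlation between the projected
  courses $w_k^\top X_i$ and $w_k^\top X_j$; the group ISC is the mean over
  subjects. Eigenvalues only order the components.
* **Masks**: samples zeroed by the outlier stage are excluded *pairwise*
  from covariance and correlation sums rather than entering as zeros, which
  would bias correlations toward zero. (Literal zero-filling is what the
  zeroing stage alone would imply; the exclusion is the package's choice
  and is confined to `pooled_covariances` / `isc_per_subject`.)

Components are *identifiable* only when their shared-signal strengths
differ; planting several components at exactly equal amplitude leaves the
recovered basis rotation-degenerate within their subspace. The generator
therefore exposes `component_scales` for separated amplitudes.

## Significance: cross-validation and the circular-shift null

A model fitted and evaluated on the same data overstates ISC, so
significance is assessed on held-out pieces: for each piece the model is
trained on all *attentive* segments (all repeats) of the remaining pieces
and evaluated on every segment of the held-out piece. Whether the original
protocol's training set included the distracted pass is not documented;
training on attentive segments only is the package default and is
configurable.

The null rotates each subject's projected time course by an independent
offset uniform on $[1, T-1]$ (per segment, per shuffle): rotation preserves
each subject's autocorrelation and marginal statistics while destroying
inter-subject alignment. The familywise threshold is the single largest
shuffle ISC over **all** components and all 100 shuffles; components whose
held-out group ISC exceed it are significant, and the reported per-subject
ISC is the sum over significant components (an empty set yields 0 with an
explicit flag). Under exchangeability the probability that any component
beats the threshold in null data is $1/(n_\text{shuffles}+1) \approx 0.01$;
this calibration is verified empirically (200 independent-noise studies)
and holds *because* the evaluation is cross-validated — training and
testing on the same data would break exchangeability and inflate the rate.

Implementation note: the correlation of two circularly shifted courses
depends only on their relative offset, so the pairwise circular
cross-correlation at every lag is computed once per segment by FFT and each
shuffle reduces to a table lookup; results are identical to explicitly
rolling the data. Group ISC across segments is the mean of per-segment
group ISCs. The null ignores validity masks (rotation misaligns them
anyway); zeroed samples are rare and dilute all shuffles equally.

## Condition statistics

* **Repeated-measures ANOVA**: classical balanced sums-of-squares
  decomposition with subject as the random factor, supporting two or three
  within factors and one between-subject factor (musical training) with
  subjects nested in groups. Each within effect (and its interaction with
  the between factor) is tested against its interaction with
  subjects-within-groups; the between effect against subjects-within-groups.
  Degrees of freedom are computed from first principles. The design must be
  complete and balanced: pieces are averaged within each subject x cell
  first (`aggregate_cells`). Verified against an independent implementation
  (pingouin) and the paired-$t^2$ identity.
* **Repetition slopes**: per piece, the OLS slope of ISC against repeat
  index 1..R; the conventional x1000 scaling is applied only at the
  reporting layer. Familiar vs unfamiliar slopes are compared with an
  equal-variance two-sample t-test (df $= n_1 + n_2 - 2$).
* **Attention contrast**: per subject and familiarity, the mean over pieces
  of summed ISC at the first attentive repetition minus the distracted
  pass.
* **Preference split**: pieces are median-split by mean rating; ties are
  broken by ascending piece id so group sizes stay equal and the split is
  deterministic. Identical ratings everywhere admit no split and are
  rejected.

## Preprocessing

Stage order: 0.5 Hz high-pass → 60 Hz notch (Q = 30) → robust PCA →
64 Hz low-pass → polyphase resampling to 128 Hz → bad-channel
interpolation → segmentation → per-segment EOG regression → per-channel
outlier zeroing. All filters are zero-phase (forward–backward 4th-order
Butterworth, IIR notch), preserving the inter-subject time alignment that
ISC requires. Interpolation is applied to the continuous recording; being
a per-sample linear map it commutes with segmentation.

* **Robust PCA** is principal component pursuit
  ($\min \|L\|_* + \lambda\|S\|_1$ s.t. $L+S=M$), solved by inexact
  augmented-Lagrange iterations with $\lambda = 1/\sqrt{\max(C, T)}$;
  the low-rank term is retained. It is run once per recording (per-segment
  operation is configurable). Two practical caveats: recovery guarantees
  assume a not-too-flat matrix (with very few channels and many samples the
  sparse term can absorb genuine signal), and on synthetic data whose
  sensor noise is spatially independent the low-rank term removes most of
  that noise along with the artifacts — real EEG is strongly spatially
  correlated, so the stage is far less aggressive there. The stage can be
  disabled (`run_rpca: false`).
* **Interpolation**: electrode positions are projected onto a plane by the
  azimuthal-equidistant map and bad channels are rebuilt by
  inverse-distance-weighted (power 2) sums of all good scalp channels; a
  coincident electrode is copied exactly. Bad channels come from a config
  list; a variance-z-score > 4 suggestion helper is deliberately separate
  from the pipeline because manual identification is the reference
  behaviour.
* **EOG regression** (least-squares noise cancellation) is computed per
  segment to respect nonstationarity of ocular activity; the residual is
  orthogonal to every EOG channel and never has higher variance than the
  input. Rank-deficient EOG falls back to the pseudoinverse with a warning.
* **Outlier zeroing**: per channel, samples whose absolute median-centred
  value exceeds 4x the interquartile range are zeroed together with
  round(0.04 · rate) samples on each side; zeroed samples are flagged in
  the segment mask. A constant channel (IQR = 0) passes through with a
  warning.

## Stimulus spectral dynamics

128 gammatone filters, centre frequencies equally spaced on the ERB-rate
(critical band) scale from 50 Hz to 0.9x Nyquist; each 4th-order filter is
realized as a cascade of four second-order sections (the single
transfer-function form is numerically unstable at low centre frequencies),
peak gain normalized to 1. Band power is the Hann-weighted mean square in
20 ms frames advancing 10 ms; flux is the Euclidean distance between
successive frames; aggregation applies a sliding 95th-percentile filter
(1 s window) then a sliding median (5 s window), both with centred windows
truncated at the series edges so no artificial extremes are fabricated.
The familiarity balance test pools the aggregated values of all pieces per
category and applies Welch's (unequal-variance) t-test; pooled frame counts
differ between categories, hence Welch. Pooled frames are heavily
dependent, so the test is descriptive — it is used, as in the original
selection procedure, to *choose* a piece assignment whose categories are
acoustically matched, not as a calibrated hypothesis test.

## Synthetic studies

The generator emulates the study design: N subjects (default 20) hear
8 pieces (half familiar style) three times in a row, time-locked, followed
by one distracted pass per piece; half the subjects are musically trained;
64-channel 10/10 cap (BioSemi layout) plus 4 EOG channels, raw rate 256 Hz,
60 s segments.

* **Shared sources**: K (default 3) time courses per presentation —
  band-limited (0.5–16 Hz) Gaussian noise convolved with a 300 ms
  exponential kernel, i.e. smooth, sub-second-scale "evoked" activity —
  mixed into the scalp through a common orthonormal topography.
* **Condition encoding** (`snr_by_cell`): shared-signal amplitude per
  (familiarity, repeat, attention, training) cell. Defaults: familiar
  (1.0, 0.8, 0.6) across repeats, unfamiliar (0.8, 0.8, 0.8), distracted
  listening x0.4, trained x1.2 / untrained x0.8 — the qualitative pattern
  the analyses are meant to detect, with the repeat ladder matching the
  scaled-study acceptance conditions. The base amplitude is 3 uV against
  10 uV channel noise.
* **Noise**: 50/50 variance split of 1/f-shaped and white noise per
  channel. **Artifacts**: ~200 ms blinks (12/min) leaking into scalp
  channels with a front-to-back gradient and recorded at higher gain on
  the EOG channels; Poisson outlier bursts; bad channels replaced by
  high-variance noise.
* All randomness flows from one integer seed through spawned substreams;
  a fixed seed reproduces a study bit for bit.
* `simulate_audio` builds amplitude-modulated multi-tone excerpts;
  octave-spaced, slightly detuned tones keep any two tones out of a common
  auditory band so that depth 0 really is stationary (negligible flux).

What the generator does **not** emulate: volume conduction from a head
model (mixing is random orthonormal, not anatomical), spatially correlated
sensor noise, non-stationary artifact regimes (electrode drift, sweating),
and real music. Passing tests therefore demonstrate correctness of the
algorithms and the recoverability of planted effects under realistic SNR,
not performance on any specific real dataset.

## Problem sizes and numerical choices

Statistical verification runs at sizes chosen to make the checks sharp yet
cheap: component recovery uses the full 64-channel, 60 s configuration with
10 subjects and component amplitudes 8x/6.5x/5x the noise SD; the
repetition-effect study uses 20 subjects, 4+4 pieces, 3 repeats, 16
channels and 30 s segments; null calibration uses 200 independent-noise
studies of 8 subjects, 8 channels and 6 s pieces with 100 shuffles each.
The acceptance script's end-to-end study uses 20 subjects, 8 pieces,
3 repeats + distract, 16 channels and 30 s segments through the full raw
pipeline.

Other numerical choices: robust PCA stops at relative residual 1e-6 (1e-7
library default) or 200 iterations with a warning; the generalized
eigensolver requires the shrunk $R_w$ to be positive definite and says so
when it is not; zero-variance component courses drop the affected pairs
from ISC with a warning; polyphase resampling uses the rational
approximation of the rate ratio. Known limitations: the ANOVA is the
classical balanced decomposition (no sphericity correction, no missing
cells), the null's exchangeability argument is approximate for strongly
non-stationary data, and principal component pursuit should not be applied
to matrices with very few rows.
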