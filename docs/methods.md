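# Methods

`ssvepsr` implements an untrained decoder for steady-state visual evoked
potentials (SSVEPs) in the motion-checkerboard regime: stimuli that evoke
a nearly harmonic-free, spectrally concentrated occipital response, on
which classical CCA and filter-bank CCA under-perform.  The decoder
collapses the multichannel epoch to one dimension, passes it through an
underdamped bistable stochastic-resonance filter, and recognizes the
gazed frequency from the enhanced signal.  This note records the model,
the parameter choices, the numerics, and what the synthetic evaluation
does and does not show.

## Signal model and synthetic data

An epoch is `X ∈ R^{C×N}` (microvolts), `C = 8` occipital channels (POz,
PO3-PO6, Oz, O1, O2), sampled at `fs = 1000 Hz` for 3 s of stimulation.
The candidate stimuli are the 35 frequencies 3, 3.5, …, 20 Hz.  Reference
templates are

    Y_f = [cos(2πf t); sin(2πf t); …; cos(2πk f t); sin(2πk f t)],
    t = 1/fs, …, N/fs,

with `k = 2` harmonics by default (fundamental plus first harmonic — the
only components with appreciable energy in this regime).  The discrete
time axis starts at `1/fs` in every module.

The generator emulates one trial as

    x_c(t) = g_c A [ sin(2πf t + φ) + r sin(4πf t + φ₂) ] + n_c(t)

with per-channel gains `g_c` (all-ones with seeded ±20% jitter, standing
in for the unknown scalp projection), harmonic ratio `r = 0.1` (weak
first harmonic, the motion-checkerboard signature), seeded uniform random
phases, and background `n_c` composed of 1/f^α colored noise (α = 1)
plus white noise at 10% of the colored power — a minimal resting-EEG-like
spectrum.  The background is rescaled per channel so the SSVEP-to-
background power ratio equals `snr_db` exactly (verified to 1e−9 by
noiseless regeneration).  `snr_db = −16 dB` is the default: it was fixed,
once, so that the plain-CCA baseline classifies at ≈60% with 2 s windows
and 35 targets — the mid-range operating point of published
motion-checkerboard benchmarks — and is not tuned per experiment.

Not modelled: eye blinks, electrode artifacts, non-stationarity within a
trial, inter-subject variability, volume-conduction correlations between
channels (channel noise is independent).  Passing tests therefore show
algorithmic correctness and qualitative behaviour (resonance, graceful
degradation, method ordering at one operating point), not expected
accuracy on real recordings.

## Preprocessing

Butterworth band-pass 3–40 Hz, order 4, applied forward-backward
(zero-phase) with odd-reflect padding of one filter startup length.
Zero-phase application keeps spectral peaks phase-aligned with the
templates; the trade-off is edge transients, which on short windows leak
a few percent of a line's power to nearby frequencies (see PSDA
limitations below).  Band edges, order and phase mode are configurable.

## Dimensionality reduction

The stochastic-resonance stage integrates a scalar ODE, so the epoch must
become a single time series.  Five unsupervised reducers are provided;
MDS and LLE view the N time samples as points in R^C — the only
orientation that returns a length-N series.

* **CAR** — reference electrode (Oz by default) minus the per-sample mean
  of all electrodes.
* **PCA** — first principal-component score series of the channel
  covariance.
* **MDS** — first principal coordinate of classical (Torgerson) scaling.
  Computed from the leading singular pair of the centred point cloud,
  which is mathematically identical to the eigendecomposition of the
  double-centred Gram matrix but avoids the N×N matrix.  Point clouds
  above `max_points` (default 2000) are subsampled and linearly
  interpolated back.
* **LLE** — barycentric reconstruction weights over `K = 40` nearest
  neighbours (local Gram conditioned with a ridge of `1e−3·trace`), then
  the eigenvector of `(I−W)ᵀ(I−W)` with smallest non-zero eigenvalue,
  rescaled to zero mean and unit variance.  Implemented in-package
  because the method's contracts (explicit weights, unit-variance
  embedding) are part of the module surface; scikit-learn's LLE serves as
  an independent cross-check in the tests.
* **CCA** — the channel weights `w_x` of the first canonical pair between
  `X` and `Y_f`, i.e. the projection `w_xᵀX` most correlated with the
  sinusoidal reference at `f`.

### Canonical correlation numerics

`cca_fit` solves the whitened cross-covariance SVD
`C_xx^{−1/2} C_xy C_yy^{−1/2} = U S Vᵀ`; ρ is the leading singular value
(clipped to [0, 1]), and the weights scale both projections to unit
variance.  Rank-deficient covariances are handled by *spectral
truncation*: eigendirections below `1e−12` times the leading eigenvalue
are dropped, pseudo-inverse style.  A fixed additive ridge was rejected:
it biases ρ by ~1e−4 for weakly correlated inputs and breaks the
invariance of ρ under invertible channel remixing, which the truncated
whitening preserves to ~1e−11.  Degenerate inputs (rank-1 epochs, 1-row
trajectories, constant signals) stay well-defined: a fully zero
covariance yields ρ = 0.  Sign convention: (w_x, w_y) are flipped
together so the X projection correlates non-negatively with the
template's first (cosine, fundamental) row, and ρ is reported
non-negative.

Because nothing in an untrained pipeline singles out one projection, the
CCA reducer is *per candidate frequency* by default (`cca_scope =
per_frequency`): each candidate f gets its own projection fitted against
Y_f, its own filter pass, and is scored at f only, which is what yields a
candidate-resolved coefficient spectrum.  A `single_best` scope (one
projection at the plain-CCA argmax, reused for all candidates) is
available for comparison.

## The stochastic-resonance filter

The underdamped second-order bistable system

    x'' = a x − b x³ − β x' + s(t) + n(t)

has potential `U(x) = −(a/2)x² + (b/4)x⁴`, stable wells at ±√(a/b) and
barrier `a²/(4b)`.  Parameters follow the established optimum for this
task: `[a, b, β, h] = [0.1, 1, 0.35, 0.1]`, giving wells at ±0.316 and a
barrier of 0.0025.  For a weak periodic drive, an intermediate noise
level synchronizes inter-well hopping with the drive — stochastic
resonance — so the response at the drive frequency rises and then falls
with noise intensity (the test suite verifies the interior maximum on a
sub-threshold drive, amplitude 0.005 < escape threshold √(4a³/27b) ≈
0.012).  In the decoding pipeline the EEG's own broadband background
plays the role of `n(t)`; an extra seeded Gaussian term of intensity `D`
(added to the drive as √(2D)·ξ per sample, zero-order held) is available
and off by default.

Integration is classical fixed-step RK4 on `(x' = v, v' = …)`, one step
of size `h = 0.1` per input sample, drive held constant across the four
stages (linear interpolation at the half-step is available; the two modes
agree exactly on constant drives).  One step per sample at `h = 0.1`
means the integrator's internal time axis compresses real seconds 100× at
1 kHz — the usual secondary-sampling treatment in SR signal processing,
and the only reading under which `h` is a free model parameter.
Sample-aligned periodicity is preserved, so the output is scored against
templates on the original time axis.  Correctness of the integrator is
pinned by: exact hold of the well fixed point, 1e−4 agreement with an
h/100 reference integration, fourth-order global-error scaling on the
linearized damped-oscillator limit (slope 4 ± 0.05 measured), and exact
odd symmetry.

Because the barrier is ~2.5e−3, raw microvolt amplitudes are meaningless
to the system: the reduced signal is standardized to zero mean, unit
variance, and multiplied by `input_scale` (default 1) before
integration.  Initial state defaults to `x₀ = v₀ = 0`.  A divergence
guard signals |x| > 1e3 with the offending sample index.  The output
passed downstream is the mean-removed position series.

## Recognition

* **CCA score** — ρ between the (filtered) epoch and each Y_f.
* **FBCCA score** — sub-band decomposition with weights
  `w_i = i^{−1.25} + 0.25`; the discriminant is `Σ w_i ρ_i²`.  Sub-band
  edges are not canonical for a 3–20 Hz stimulus range; the default is a
  harmonic-progressive bank of N = 5 bands `[3i, 40] Hz`, fully
  config-driven.
* **PSDA score** — squared spectral amplitude evaluated *exactly* at each
  candidate (plus 2f by default) by direct single-frequency projection:
  the 0.5 Hz grid does not align with FFT bins at 1–3 s lengths, so
  bin-snapping would be wrong.  Convention: a unit sinusoid over integer
  periods scores (N/2)².
* **USSR pipelines** — reduce → filter → score.  Non-CCA reducers reduce
  and filter once and score the trajectory at every candidate; the CCA
  reducer runs per candidate as described above.  Scoring a 1-D
  trajectory "by CCA" degenerates to the maximal correlation between the
  trajectory and the best linear combination of template rows — this is
  the coefficient-spectrum definition used for the 1–40 Hz spectra.

Classification restricts the argmax to the stimulus set even when a
spectrum covers 1–40 Hz; exact ties break toward the lowest frequency and
are flagged.

### PSDA limitations

With harmonic summing, the score at f/2 contains the full power at f, so
a pure tone at f beats its subharmonic only through genuine harmonic
content or noise asymmetry.  Zero-phase filter edge transients leak a few
percent of line power across the spectrum on short windows (~4% at f/2
for 1 s at 250 Hz), which can flip the argmax to f/2 on otherwise clean
epochs.  Windows ≥ 1.5 s make this negligible in practice.

## Evaluation

Accuracy is percent exact frequency matches.  The information transfer
rate is the Wolpaw formula

    ITR = (60/T) [ log₂M + σ log₂σ + (1−σ) log₂((1−σ)/(M−1)) ]

in bits/min, with `0·log 0 := 0` at the endpoints; it is zero exactly at
chance (σ = 1/M), strictly increasing above chance, and scales exactly as
1/T.  Data-length sweeps truncate each epoch to its first T seconds
(stimulus-onset aligned, as in online use) and re-run the full pipeline.
Method contrasts use paired two-sided t-tests on per-unit accuracies;
identical vectors are reported as (t = 0, p = 1).  Reported summary
statistics use the sample SD (n−1).

The package ships a 42-subject reference benchmark (per-subject accuracy
and ITR for CCA, FBCCA, CAR-USSR and PCA-USSR at T = 2 s, M = 35) as a
regression fixture for the ITR arithmetic: every printed pair satisfies
the formula within 0.01 bits/min, and the accuracy summary row matches
the column statistics to 2 d.p.  One summary cell (the CCA mean ITR) is
internally inconsistent in the source table and is documented rather than
asserted; the other ITR mean cells follow the ITR-of-mean-accuracy
convention.

## Problem sizes used by the test suite

Simulations run at the study conditions (8 channels, 1 kHz, 35 targets)
with 2 s windows — the benchmark's evaluation length: the noiseless
recognition sweep uses 35 epochs per scorer; the SNR ladder uses 50
epochs (25 frequencies × 2 trials) at each of −10/−16/−22 dB; the
resonance sweep integrates 20 000 samples at 7 noise levels.  Oracle
tests (brute-force CCA, power iteration, explicit Gram MDS, LLE
constraints) run on 100–600-sample instances where the independent
computation is exact.
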