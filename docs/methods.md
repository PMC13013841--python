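# Methods

This note documents the models, numerical choices, and limitations behind the
package. Notation: `z(t) ∈ ℂ^N` is the multichannel theta-band analytic LFP,
θ the carrier (first complex principal component), pθ a position-tuned
oscillatory component.

## Signal representation

Raw LFPs are decimated to 25 Hz (zero-phase order-8 Chebyshev-I anti-alias
filter at 0.4·f_out, applied in stages of ≤ 10 for numerical stability),
high-pass filtered at 2 Hz (order-2 Butterworth, zero-phase), and Hilbert
transformed per channel. 25 Hz comfortably contains the 6–10 Hz theta band
while keeping every downstream matrix small. The Hilbert transform is
computed over the whole session; the first and last second are flagged as
edge samples and excluded from model training by default.

**Carrier.** θ(t) is the first left singular vector of the complex T×N
matrix, scaled by its singular value; the explained-variance fraction is
s₁²/Σs_k². The SVD's arbitrary global phase is fixed by rotating so the
largest-magnitude channel weight is real positive; the carrier's
counterclockwise rotation is intrinsic to analytic signals and unaffected by
a constant rotation. With exactly tied singular values the decomposition
order of the underlying LAPACK routine breaks the tie.

**Demodulation** multiplies each channel by the conjugate of the carrier's
unit phasor: magnitudes are preserved bit-exactly up to rounding, and any
phase common to carrier and channels cancels. Samples where |θ| = 0 take
carrier phase 0 by convention (the channel passes through unchanged).

**Whitening.** The score matrix U·S of the complex SVD is rescaled per
column by 1/√(var + ε·Σvar) with ε = 10⁻⁵. This is exact whitening for
dominant components but shrinks the smallest (noisiest) dimensions instead
of amplifying them — the same reasoning as ridge regression. Because ε
couples to the total variance, the output is invariant to a global rescaling
of the input.

**Theta-power deciles** use relative power |θ(t)|²/Σ_n|z_n(t)|² (robust to
broadband transients such as ripples) with equal-count binning; tied values
all receive the lowest eligible decile, for determinism. **Ripple
detection** estimates 150–250 Hz band power in 50 ms windows with 50 %
overlap (the window length is this package's choice), averages across
channels, z-scores over the session, and counts local maxima above z = 2.

## The LFP simulator

Place cells tile a unit circular track; cell c at center x_c responds

    r_c(t) = a·exp(−d(x,x_c)²/(2σ²)) · exp(i(φ_θ(t) + m·d(x,x_c) + ε_c(t)))

with d the *signed* wrapped displacement in [−0.5, 0.5), a = 1, σ = e⁻²,
precession slope m = −π/(√2·e⁻²) rad per track unit (the phase advances by
−π across the ±√2σ extent of the field), and theta frequency 8 Hz. Gaussian
tuning uses |d|; the precession term uses the sign. The LFP is the linear
superposition z = r·Aᵀ with Re(A), Im(A) ~ U[0,1] i.i.d. (uniform rather
than zero-mean so that neurons do not phase-cancel). When smooth mixing is
requested, columns of A are convolved along the electrode axis with a
unit-sum 16-tap Gaussian window (shape parameter 4). The convolution is
circular, which preserves column means exactly and maps a delta column to
the normalized window; an edge-truncated variant would do neither.

Phase noise ε is white Gaussian (σ_ε rad), either one series per cell
(private) or one series broadcast to all cells (shared). Time-series
simulations low-pass the white series with a zero-phase order-4 Butterworth
filter (8 Hz shared / 4 Hz private at σ_ε = 1 / 2 respectively); the filter
attenuates variance and the series is *not* rescaled back to σ_ε — σ_ε
describes the pre-filter series, and the opposite convention is one flag
away. Experiments that sample time points i.i.d. use the unfiltered noise.

**Template decoding.** Noiseless, theta-off responses at 25 bin centers,
mixed through A, form the template matrix X (bins × electrodes). The
demixer is W = X(XᴴX + Λ)⁻¹ with Λ = 0.1·diag(diag(XᴴX)) — the quotient is
read as right-multiplication by the regularized inverse, with the Hermitian
transpose, since that is the only reading producing a bins×electrodes
demixer. W is applied as a matched filter (conjugate inner product), so
that applying it to its own templates yields X(XᴴX+Λ)⁻¹Xᴴ, a near-identity
map. Carrier-based decoding takes argmax over bins of Re(pθ·e^{−iφ_θ});
carrier-free takes argmax |pθ|; ties go to the lowest bin.

The decoding study uses 10 sessions of 5000 i.i.d. samples (positions and
theta phases uniform), 1000 cells, σ_ε = 1, electrode grid
{2,4,8,16,32,64,128} (powers of two; smaller arrays reuse the first rows of
the session's mixing matrix so the curves are nested). 5000 samples is
enough for the s.e.m. over sessions to resolve the ordering of the two
decoding modes at every electrode count.

## The carrier-free network

Architecture and objective are as in the README. Implementation notes:

* **Gradients.** For real loss L and a = x·conj(W₁)ᵀ, the update direction
  is 2∂L/∂W₁* = (∂L/∂|a| · conj(a)/|a|)ᵀx, whose real and imaginary parts
  are the ordinary partials with respect to Re W₁ and Im W₁ — so Adam runs
  on the real view of the parameters. The analytic gradients match central
  finite differences to < 10⁻⁵ (tested).
* **Unit-norm constraint** on W₁ rows (real and imaginary parts jointly,
  one L2 norm per row — the norm that gauges a node's output magnitude) is
  enforced by projection after every optimizer step.
* **Optimization.** Adam, lr 10⁻³, at most 100 epochs, early stopping with
  patience 1 on a held-out fold's loss, restoring the best-epoch weights.
  The validation fold is never the final test fold. Batch size defaults to
  64: with the fixed learning rate and epoch cap, this supplies enough
  optimizer steps to converge on session-sized data (a few thousand
  samples); larger batches underfit within the cap. Full batch is available
  via the config.
* **Restarts.** The hidden-layer softmax competition admits collapsed local
  optima in which two nodes share one behavioral state; these occur for
  roughly one in five random initializations, do not resolve with more
  epochs, and are unambiguous in the validation loss. Training therefore
  runs `n_restarts = 3` fresh initializations and keeps the run with the
  lowest validation loss.
* W₂ is real (hidden activations are real after |·| and softmax) and has a
  bias. With no output layer the softmaxed hidden amplitudes are themselves
  the prediction — the configuration used for pose decoding under the KL
  objective, where the unit-norm constraint is dropped so the projection
  scale can act as an inverse temperature.
* Hidden nodes have no intrinsic order; analyses that need one sort by
  activation timing or peak position.

## Baseline decoders

Arm/section classification uses one-vs-rest lasso-penalized logistic
regression (liblinear, C = 1, tol 10⁻⁴, max 1000 iterations) on the split
real/imaginary demodulated LFP (carrier-based) or on spike-rate features
(counts binned at 25 Hz, zero-phase order-8 Butterworth low-pass at 3 Hz,
per-neuron std normalization within behavioral condition; silent neurons are
dropped with a warning). Run periods use 12 classes (each arm divided into
four equal quarters of normalized position) scored at arm level; stays use 3.

Trials are assigned to 5 folds by drawing 100 random assignments and keeping
the one that maximizes the per-(fold, arm) training quota after balancing —
training sets are subsampled so every arm contributes equally and all folds
train on the same amount of data; the first candidate wins ties.

The Bayesian decoder assumes independent Poisson counts and a uniform prior:
MAP bin = argmax_x Σᵢ nᵢ·log fᵢ(x) − Σᵢ fᵢ(x), with tuning curves fᵢ
estimated as occupancy-normalized mean counts floored at 10⁻³ to keep the
log finite; ties go to the lowest bin. The linear alternative ridge-regresses
(penalty 1.0, standardized features) onto a 10-per-arm Gaussian RBF encoding
of track position (centers at 0, 1/9, …, 1; σ_x = 1/9, concordant with the
spacing; responses normalized to sum to 1) and decodes the argmax basis.

Multiclass CSP solves C_i v = λ C v per class (class covariance against the
covariance of all data) on the complex signals, keeps the top eigenvectors
per class, and feeds the projection amplitudes to the logistic classifier.
A trace-scaled shrinkage floor keeps the pooled matrix invertible.

## Open-field pose decoding

Pose (x, y, φ) is encoded on a 10×10×10 RBF grid: Gaussian in normalized
position (centers 0…1, σ_xy = 1/9) and wrapped Gaussian in orientation
(centers every 2π/10 rad, σ_φ = 1/10, distance min(|Δφ|, 2π−|Δφ|)), the
1000 responses normalized to sum to 1. Decoders minimize KL(target‖pred)
(equal to cross-entropy up to the target entropy; targets are clipped at
10⁻¹² before normalization). The predicted field is smoothed circularly in
orientation (σ_φ grid {0, 0.2, 0.4, 0.8} rad) and in time (Gaussian FIR, τ
grid {0, 0.4, 1.6, 6.4, 25.6} s); the smoothing is chosen by exhaustive grid
search minimizing mean *training* position error, and the pose estimate is
the center of the maximal basis. Position error is Euclidean in normalized
units (×152.4 for cm); orientation error is wrapped to [0, π].

Chance position error is the Monte-Carlo mean distance between true
positions and uniform noise on [0,1]². Chance *orientation* decoding must
account for position-dependent orientation preferences, so the baseline
predicts, at each estimated position, the most likely training orientation
from the joint occupancy (outer product of position-only and
orientation-only RBF encodings). Velocity analyses low-pass position (3.2 Hz
open field / 2 Hz maze), stratify error by velocity decile, and summarize
slow-vs-fast performance as log(err_slow/err_fast).

## Statistics

**Position information** (bits): Info = Σᵢ Pᵢ(Rᵢ/R)log₂(Rᵢ/R) over arms,
with Pᵢ occupancy probability, Rᵢ mean response in arm i, R the overall
mean; Rᵢ = 0 terms contribute 0 by continuity. Sparse signals bias this
upward, so the mean over 100 circular shifts of the occupancy series is
subtracted; shift offsets are uniform on [0.1T, 0.9T] to avoid near-identity
shifts.

**θ/pθ selectivity**: each neuron's analytic signal (spike counts binned at
25 Hz, 10 Hz order-8 low-pass, 2 Hz order-2 high-pass, Hilbert — the same
chain as the LFP) is regressed on [θ, pθ] by complex least squares (ridge
floor 10⁻⁸ of the mean design eigenvalue; near-collinear regressors warn and
get a heavier ridge), and s = (|w_θ|−|w_pθ|)/(|w_θ|+|w_pθ|) ∈ [−1, 1].

**Variance partitioning** predicts the multichannel LFP jointly from θ and
the pθs (joint, so θ explains away shared variance — any random projection
of so correlated a signal would otherwise appear to explain a lot), then
reports each regressor's reconstruction variance over the evaluation samples
as a fraction of total LFP variance, summing the pθ fractions.

**Correlated t-test** for overlapping cross-validation folds:
t = x̄/√(σ²(1/n + 1/(n−1))) with n−1 degrees of freedom; the extra 1/(n−1)
inflates the variance term, effectively reducing the sample size. p₁ is the
upper tail; p₂ = 2·(1−T_{n−1}(|t|)) — the absolute-value form, which keeps
p₂ ≤ 1 for negative t. σ² = 0 is flagged degenerate. A Monte-Carlo check
(2000 replicates of equicorrelated null folds, ρ = 0.1) verifies the
corrected test holds its nominal size where the naive paired t does not.

**Circular–linear regression** recovers the precession slope by maximizing
the mean resultant of (φ − m·x) over a dense slope grid (±4π per unit-x
span) followed by a golden-section refinement.

## Spike-phase prediction

Three nested complex linear models predict a cell's theta-band signal:
(1) θ × a 20-dimensional raised-cosine position basis (evenly spaced bumps
with half overlap — a partition of unity — multiplied by θ, which lets the
model express any smooth position-dependent phase offset, i.e. phase
precession); (2) the same plus the other recorded cells' complex signals;
(3) the complex LFP of all electrodes. Columns are standardized to zero
mean, unit variance (one convention for both basis-derived and raw-signal
columns). Models are fit on the first half of the session and scored on the
second: in-sample scoring with ~120 regressors mechanically reduces
residuals even when the extra regressors carry no usable signal, whereas
held-out scoring isolates the effect of interest.

Prediction quality is the circular variance (1 − mean resultant length) of
the phase error ∠s(t) − ∠ŝ(t), weighted by the cell's activity |s(t)|; for
recorded spike trains, the distribution of predicted phases at spike times
is used instead. Histograms use 36 bins over [−π, π); the histogram-based
circular variance applies the grouped-data correction (π/n)/sin(π/n), after
which the two computations agree to 10⁻³. "Narrower distribution" is
operationalized as lower circular variance throughout.

## Synthetic sessions

The maze generator emulates a three-arm sequence task (left, center, right,
center — so the center arm is visited twice as often, which is why decoders
balance arms): each trial is a 2 s run along one arm followed by a 3 s stay
at the reward port, at 25 Hz, with the three arms mapped onto thirds of the
simulator's circular track. Place fields use σ = 0.04 track units (≈ 26 cm
at the scale of a ~2 m arm) — realistic field widths, and necessary for
within-arm structure to exist at all; the abstract unit-track study keeps
the wider σ = e⁻². Spikes are inhomogeneous Poisson with rate 5·|r_c(t)| Hz.
The open-field generator drives a reflected Ornstein–Uhlenbeck walk in the
unit arena (velocity autocorrelation 1 s, mean speed 0.15 arena/s ≈ 23 cm/s)
with heading from the velocity; cells have 2-D Gaussian fields (σ = 0.08)
and precess along the instantaneous direction of motion, which is what makes
the LFP pattern orientation-dependent.

Sessions serialize to HDF5 with complex arrays stored as paired real arrays
and HDF5 timestamps disabled, so identical seeds give byte-identical files.

One generator-specific caveat: because the synthetic LFP contains *only*
place cells, a carrier estimated from it by PCA tracks their common phase,
and demodulation then cancels purely shared noise — unlike real recordings,
where theta is dominated by pacemaker and interneuron sources that do not
follow place-cell noise correlations. Analyses that probe the shared-noise
sensitivity of carrier-based decoding on synthetic sessions therefore
demodulate by the pacemaker (theta-input) phase, which the generator knows
exactly.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* the analyses target — phase
precession, linear mixing, private vs shared phase noise, run/stay
structure, orientation-dependent precession — under exactly known ground
truth. It omits much of real recordings: broadband non-theta background,
volume-conduction geometry, electrode artifacts, theta frequency and
amplitude nonstationarity, behavioral variability, spike-sorting errors, and
cell-type diversity. Passing tests therefore demonstrate that the
implementations are correct and that the decoding dissociations follow from
the stated mechanisms; they do not by themselves establish effect sizes in
physiological data.

## Known limitations

* The carrier-free network is trained by plain minibatch Adam in numpy;
  very large hidden layers (≫10³ nodes) would benefit from a GPU framework.
* Carrier extraction is computed per behavioral condition; a single shared
  carrier across conditions is one call away but not the default.
* The Bayesian stay-period variant decodes 3 one-per-arm bins; the tuning
  window for stays is otherwise the same as for runs.
* Fold exclusion (e.g. for distributional shift across a session) is a
  manual list, not an automatic criterion.
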