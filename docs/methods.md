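# Methods

## The task world

M-Pong is a deterministic interception task. The frame is a square of
`frame_span` = 20 degrees of visual angle; coordinates use an origin at the
bottom-left with y increasing upward (the renderer converts to row-major
image convention with row 0 at the top). A trial is defined by the ball's
initial position (x0, y0) and velocity (dx0, dy0); the ball moves at
constant speed, reflecting specularly off the top and bottom walls, until it
reaches the paddle plane at the right edge. Kinematics are stepped at the
network timestep dt = 624.9/15 = 41.66 ms, not at the 16.6 ms screen
refresh: the networks consume one frame per timestep, so that is the
granularity at which anything downstream can differ. The paddle moves 0.17°
per refresh, i.e. ~0.01 °/ms; the paddle itself is never rendered and no
motor plant is applied to model outputs — models emit positions directly.

A full-height occluder covers the rightmost 35 % of the frame
(`occluder_frac` = 0.65, configurable). With the occluder a fixed band, the
occluded duration depends only on horizontal speed, which keeps the
published epoch-duration constraints expressible as bounds on dx. Visibility
is determined by the ball *center* crossing the occluder edge; the ball
radius (0.25°, configurable) is ignored for kinematics and visibility and
used only by the renderer.

Condition sampling is by rejection: start position uniform over the visible
region, heading uniform in (−60°, +60°) from horizontal, speed uniform in
[span/90, span/20] °/timestep, accepting conditions whose visible epoch and
occluded epoch each last 15–45 timesteps, with at most one wall bounce and
at most 90 timesteps overall. The proposal distribution is a package choice
(only the acceptance constraints are externally fixed); the acceptance rate
under these ranges is roughly 15 %, and the sampler raises with a diagnostic
of violated constraints if it falls below a configurable floor.

The renderer draws the ball as a filled disk with a one-pixel soft edge on a
100×100 grid, blank during occlusion. The soft edge keeps the blob centroid
within a small fraction of a pixel of the true position, which the test
suite uses as the renderer/simulator agreement oracle.

## Input encoders

Networks receive 100-dimensional inputs. `pixel_pca` fits an incremental
PCA over flattened frames, streamed in batches of whole trials from a
shuffled subset; `gabor_pca` first maps the (2× spatially down-sampled)
stream through 16 spatiotemporal Gabor energy channels (8 directions × 2
spatial-frequency/speed pairs, quadrature pairs squared and summed, with the
temporal DC removed per spatial location so static patterns yield ~zero
energy) and then applies the same incremental PCA. The Gabor bank is a
conventional motion-energy approximation of cortical-area-MT front ends, not
a calibrated physiological model; its parameters are exposed on
`GaborBank`. PCA bases are fitted once per encoder kind and shared across
all networks; fitting uses whole trials (blank occluded frames included).

Full-scale fitting streams batches of 32 trials from a subset of 512. The
desk-scale pipeline default is 4-trial batches from a subset of 64 — the
incremental SVD of a 10,000-dimensional batch dominates runtime otherwise —
and the agreement of incremental with full-batch PCA is verified on a
synthetic stream with a well-separated eigen-spectrum. (On ball-disk frames
the top eigenvalues are nearly degenerate, so the top subspace itself is
ill-determined; no estimator could pin it down, and nothing downstream
depends on it.)

Encoded inputs are standardized to unit global SD (scale estimated on the
training trials and shared with the test split): PCA projections of
mostly-blank frames are otherwise of order 0.04, which badly conditions
optimization.

## Networks, losses, training

Models are single-layer LSTM (gates: input, input-modulation, forget,
output) or GRU (gates: reset, update, plus the candidate block) networks
with 10 or 20 units and 7 independent linear read-out channels. The forward
pass and back-propagation-through-time are implemented directly in numpy —
at these sizes (≤ 20 units, ≤ 91 timesteps) a framework is unnecessary —
and the analytic gradients are validated against central finite differences
to 1e-4 relative tolerance in the test suite.

Channel 0 (movement) is supervised at exactly two timepoints per trial: the
central paddle position at t = 0 and the interception height at t_end; in
between the output is free-running. The optimization regimes differ only in
which further channels carry loss: none (`no_sim`), ball (x, y) while
visible (`vis_sim`), over the whole trial (`all_sim`), or on separate
channels for visible and occluded epochs (`all_sim2`, 5 contributing
channels). `simple_dynamics` adds three hidden-state regularizers — mean
squared activity, mean squared temporal difference, and their ratio — each
with its own weight (default grid 1e-3/1e-2/1e-1). The overall loss is the
unweighted mean of the per-channel masked MSEs, plus optional L1/L2
regularization of the read-out weights (strengths 0.01/0.1 in the zoo
grid).

All supervised targets are normalized through (v − span/2)/(span/2) so
every channel lives on a ~[−1, 1] scale commensurate with the hidden-state
range; the movement output is mapped back to degrees at the behavior
interface. This matters: with degree-scale targets the two-point movement
loss has a deep constant-output basin (predict the mean endpoint
everywhere) that small networks do not leave at desk scale, whereas
normalized targets let even task-only (`no_sim`) networks learn the
interception mapping.

Initialization is a seeded uniform ±1/√fan-in with carry-friendly gate
biases (LSTM forget bias 1, GRU update bias 1) so information survives the
blank-input occluded epoch; a literal all-zeros initialization is available
(`init="zero"`) but leaves hidden units permutation-symmetric under
gradient descent and is not a useful default. Training is full
back-propagation-through-time with Adam (default lr 1e-2, batch 32), a
seeded shuffled batch order, and divergence protection (on a NaN loss the
last finite parameter state is restored and the run is flagged). Training
is bit-deterministic given the spec seed.

Desk-scale defaults (300 training conditions, 200 epochs, 10 units) are
chosen so a matched eight-model zoo trains in minutes on one CPU; the
full-scale regime this emulates trains hundreds of networks on up to
212,480 conditions for 100–500 epochs. All sizes are config knobs.

## Behavioral metrics

A trial table holds (condition id, repetition, final paddle height). The
error-vector residualizes trial-level paddle heights on the ground-truth
interception heights with a single least-squares slope/intercept, then
averages residuals within condition. Residualizing (rather than
subtracting) means correlating two systems' error-vectors equals the
partial correlation of their raw endpoints controlling for the ground
truth; the test suite checks this identity to 1e-10.

Consistency between systems m and h: per split, each system's trials are
divided into two stratified halves (every condition retained in both
halves); internal reliabilities ϱ(m,m), ϱ(h,h) are the correlations between
a system's own half error-vectors; the cross term ϱ(m,h) averages the four
half-by-half cross correlations (all estimates use equal amounts of data,
so no Spearman-Brown extrapolation is involved); the score is
ϱ(m,h)/√(ϱ(m,m)ϱ(h,h)). Ten random splits give a mean and SD. Deterministic
systems (RNNs, one repetition) are treated as noiseless: their full
error-vector is used with internal reliability fixed at 1. Negative internal
reliabilities flag the score as unreliable rather than silently producing
NaN.

## Representational metrics

ISDP fits a linear map (with intercept) from hidden states to the ball
(x, y), trained on visible + occluded epochs and scored only on occluded
points, under a 2 × 2 cross-validation: conditions are split into two folds
and timepoints into two folds (even/odd), the decoder trains on (training
conditions × training timepoints) and is scored on (held-out conditions ×
held-out timepoints); the error is the mean of |Δx| and |Δy| over the four
fold cells (a Euclidean variant is available via a flag). Lower = stronger
explicit latent tracking.

Participation ratio is (Σλ)²/Σλ² over the eigenvalues of the covariance of
the (trials·timesteps) × units matrix. Speed and curvature are per-trial
ratios of the time-mean norm of the first/second temporal difference to the
time-mean activity norm, averaged over trials, computed over the whole
trial. Both are invariant to global scaling; PR is rotation-invariant.

Feedback control takes each gate's recurrent matrix, treats each unit's
incoming weight vector (columns under the `h @ Wh` storage convention; a
row flag exists since the convention is arbitrary) and averages |cos| with
the unit-normalized movement read-out across units and gates; a null
distribution uses random unit-sphere read-outs.

Velocity-decoding maps bin the frame into a 10×10 grid of ball positions
and, within each sufficiently populated bin, fit trial-grouped
cross-validated linear decoders from hidden states to (dx, dy). Scores are
held-out coefficients of determination (1 − SSE/SST, floored at zero):
unlike squared Pearson correlation this is not positively biased for
uninformative decoders on small bins, which is what makes the two controls
meaningful — "pixels" decodes from the encoded inputs (≈ 0 during occlusion,
when inputs are constant), "null" decodes from the in-bin ball position
(≈ 0 by construction). Under-populated bins are reported missing, never
imputed. A single-global-decoder variant scores per bin from one fit.

The attribution utilities implement eigenvalue-weighted cross-validated R²
(PCA-orthogonalize the target matrix, predict each dimension with 5-fold CV
linear regression, combine per-dimension squared Pearson r with weights
proportional to the eigenvalues — here squared Pearson is retained since
this statistic is defined that way) and squared partial Pearson correlation
(both sides residualized on covariates by least squares; near-constant
residuals raise rather than returning an arbitrary number).

## Process model

The simulator starts each Monte-Carlo sample at the last visible position
with the velocity carrying the ball into occlusion (sign flips from
visible-epoch bounces included). Each occluded timestep draws
dx_t ~ N(dx, σ²_occ) and dy_t ~ N(dy·w_bias, σ²_occ) — the bias is applied
once to the mean at occlusion onset — steps the position, and folds it back
into the frame; each wall contact flips the mean vertical velocity and adds
one draw of N(0, σ²_bounce) to it (injecting bounce noise into the *mean*
is what gives the noise a lasting effect; adding it to a single resampled
step would be forgotten immediately). The prediction is the mean final
height over n = 100 samples. In the noiseless limit (σ → 0, w_bias = 1) the
sampler reproduces the deterministic kinematics exactly, which the tests
assert to 1e-6°.

Fitting minimizes the MSE between predicted and observed per-condition
endpoints over (σ²_occ, σ²_bounce, w_bias), each bounded to (0, 2], with
L-BFGS-B and finite-difference gradients. Two numerical choices make this
work: (i) common random numbers — the per-condition standard-normal noise
tables are drawn once, indexed by (sample, step), and reused at every
objective evaluation, so predictions vary continuously with the parameters
(consuming a generator as samples terminate would decorrelate draws across
evaluations and destroy the finite-difference gradients); (ii) start-point
screening — a seeded pool of candidate parameter vectors is evaluated once,
and L-BFGS-B descends from the provided initial point plus the best
screened candidates — because the finite-difference gradients degrade near
the lower variance bound and a single start can stall there. Parameter
recovery on synthetic endpoints (200 conditions, known parameters) recovers
w_bias well within ±0.1.

## Synthetic behavioral systems

A synthetic system's condition-level mean endpoint is the process-model
prediction plus a system-specific Gaussian condition bias; trials add
independent Gaussian motor noise. Defaults — w_bias = 0.7,
σ²_occ = 0.05, σ²_bounce = 0.1, bias SD 0.6°, motor SD 1.0°, 40
repetitions — produce an MAE near 1.8°, split-half reliabilities near 0.9,
and error magnitudes that increase with occluded vertical displacement,
i.e. the statistical signatures real interception behavior shows. Two
tables drawn from the same spec with different trial seeds are replicas
(shared condition structure, independent motor noise); their expected
consistency is 1.

Paired systems with controlled similarity use an *unbiased* endpoint core
(ground-truth endpoints) plus condition biases built from shared and
private standard-normal components with weights √ρ and √(1−ρ): the biases
then correlate at exactly ρ_shared, and because the unbiased core
contributes no error structure, ρ_shared is also the true consistency
between the pair. A shared biased-process core would add common error
structure on top and break that equality, which is why the calibration and
independence constructions use the neutral core while the replica and
phenomenology constructions use the biased one. A single pair's realized
bias correlation fluctuates around ρ_shared with SD ≈ (1−ρ²)/√200, so
calibration claims are made about means over several independent
realizations.

What the generator does *not* emulate: paddle trajectories over time,
reaction times, eye movements, heavy-tailed or condition-dependent motor
noise, and learning across sessions. Passing tests therefore validate the
estimators and the comparison machinery, not any claim about a specific
organism.

## The desk-scale zoo experiment

The pipeline trains matched pairs of `no_sim` and `all_sim2` networks
(same cell type, size, seed) on a shared encoder, evaluates them on a
held-out condition set, and scores each model's consistency against a
synthetic reference observer built from the biased process model
(bias SD 0.3° for the reference, so the biased-extrapolation structure
dominates its error-vector). At the default desk scale this reproduces the
qualitative structure of the full-scale result: latent-tracking supervision
lowers the occluded-position decode error in every matched pair, and across
the zoo the decode error predicts reference-consistency more strongly than
overall performance does (both correlations are negative — lower error,
higher consistency). Eight models at this scale give a directional, not a
quantitative, result; the correlation magnitudes move with the seed and the
reference parameters.

## Known limitations

- The Gabor bank approximates an MT-like front end generically; its exact
  spatiotemporal tuning is not fitted to physiology.
- ISDP's 2×2 condition/timepoint cross-validation is one of several
  reasonable schemes; the choice is fixed and documented rather than swept.
- The process-model objective is piecewise smooth in the parameters (bounce
  events switch discretely); the common-random-numbers + multi-start
  scheme handles this in practice but a fully smooth estimator would need a
  different formulation.
- Zoo conclusions at desk scale are directional; magnitudes (correlation
  strengths, consistency levels) depend on training budget and reference
  parameters.
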