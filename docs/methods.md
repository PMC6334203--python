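# Methods

This note records the models implemented, the parameter choices that
matter, the numerical decisions, and what the synthetic-data generator does
and does not emulate.

## Diffusion model and scenario generator

The field v(x, y, t) obeys ∂v/∂t = ∇·(D∇v) on Ω = [−2, 2]² with v = 0 on
∂Ω, where D = diag(d₀(x, y), d₁(x, y)) is diagonal (no cross-diffusion
terms; curved scars and 3D domains are out of scope).

**Scenario distribution.** A straight partition line with orientation
θ ~ U[0, π) and signed perpendicular offset β ~ U[−1, 1] from the domain
centre splits Ω into a healthy and a scar region. Within each region the
larger-to-smaller diffusivity ratio is the anisotropy ratio γ ~ U[1, 3];
between regions the healthy/scar ratio on both axes is the heterogeneity
ratio λ ~ U[2, 7]. The axis carrying the faster healthy diffusivity is a
fair coin flip, and that diffusivity is drawn from U[3.2, 3.8]
(dimensionless units). These identities are imposed by construction, so
they hold to machine precision for every sample. Which side of the line is
scar is an independent coin flip; β ~ U[−1, 1] keeps both regions
non-degenerate with high probability.

**Initial conditions.** A complex spectrum on a 128×128 generation grid has
amplitude envelope (f_x² + f_y² + f_c)^{α/2} with corner frequency f_c = 3
cycles per domain length, exponent α drawn uniformly from {−1, −2}, and a
hard cut-off (zero amplitude) wherever f_x² + f_y² ≥ f₀², with f₀ drawn
uniformly from {8, 12, 16}. Each bin is multiplied by independent N(0, 1)
amplitude noise and a uniform phase; conjugate symmetry is imposed by
averaging each bin with the conjugate of its mirror, which makes the
inverse transform real to round-off. The field is tapered to zero with a
separable raised-cosine window over the outer 10% of each half-width
(exactly zero on the boundary ring) and then scaled so max |v₀| equals the
configured contrast (default 1); windowing before normalisation guarantees
the normalisation survives. Interpolation onto solver cell centres is
bilinear.

**Discretisation.** Cell-centred second-order flux-conservative finite
differences: face diffusivities are arithmetic means of the adjacent cells,
and the Dirichlet condition enters through ghost cells mirrored with a sign
flip, keeping the wall value at zero. Time integration is explicit Euler
with automatic sub-stepping under dt ≤ min(dx, dy)²/(4·max D) (a 0.9 safety
factor is applied inside `simulate`; `step` itself enforces the bound and
reports the admissible dt on violation). The default solver grid is
128×128, restricted to the 64×64 observation grid by 2×2 cell averaging
(anti-aliasing). Against the closed-form heat kernel for a centred Gaussian
bump under homogeneous isotropic diffusion the solver is second-order
accurate (measured order ≈ 2.0, relative L2 error ≈ 0.08% at 128²).

**Cadence.** The model does not prescribe an output cadence; the default is
20 frames at an interval of 10⁻³ time units, chosen so the dominant
retained modes decay noticeably but not completely across the 14 frames a
forecasting sample needs. The cadence is recorded in every archive and is
deliberately configurable — the forecasting problem is only meaningful when
the field changes appreciably between frames.

## Surrogate forecaster

Architecture (defaults): three encoder stages of 5×5 same-padded
convolution + batch normalisation + ReLU + 2×2 max-pooling with channels
(64, 32, 32), so a 64×64 frame maps to an 8×8 latent grid; a 32-channel
convolutional LSTM with 5×5 gate convolutions; and a decoder of three 4×4
stride-2 transposed convolutions with channels (32, 64, 1), batch-norm +
ReLU after the first two and a linear final layer (field values are
signed). The encoder consumes the K_b ∈ {2, 3} input frames sequentially to
warm the recurrent state; the cell then free-runs K_out = 11 steps on its
own hidden/cell state with zero exogenous input (a teacher-forced variant,
where the encoded ground-truth frame is fed during training rollout, is
available behind a flag), and each step's hidden state is decoded to one
frame. Decoding each rollout step with a single-channel head is the
information-equivalent of a K-channel head decoding all frames at once.

Training minimises MSE over the first K_t ∈ [1, 7] predicted frames only,
with Adam (initial learning rate 5·10⁻⁴, dropped ×10 at epoch 700 of 1000),
weight decay 10⁻⁵ (the magnitude is a free choice), batch 64, inputs
standardised by the training set's global standard deviation, 20% of the
training simulations held aside for validation, and the best-validation
weights restored. Evaluation reports per-simulation MSE over all K_out
frames, the last-input baseline (repeat the final observed frame), NMSE per
step with a mean-square denominator (dimensionless and scale-invariant;
the literal L2-norm variant would differ only by a constant grid factor),
and a two-sided Wilcoxon signed-rank p-value on the paired per-simulation
MSEs. 5-fold cross-validation splits by simulation.

The layers live in `epmodkit.nn`: a deliberately small numpy library
(im2col convolution, transposed convolution, max-pooling, batch-norm,
ConvLSTM cell, Adam) with explicit forward caches and hand-written
backward passes, each verified against central finite differences in the
test suite. This keeps the whole toolkit dependency-light and the
backpropagation-through-time path fully inspectable, at the cost of
training speed — which drives the scaled-down study sizes below.

## Latent parameter readout

The ConvLSTM hidden state at each of the 11 rollout steps is captured and
stacked along the channel axis (11 × 32 channels on the 8×8 latent grid at
default scale; the cell state is available behind a flag). The readout is
two convolutions (default channels (128, 64), 6×6 filters, stride 2 — sized
for the 8×8 latent grid; filter/stride are configurable for smaller
latents) with ReLU, then one linear layer. Targets are standardised per
parameter on the training split; the axial orientation θ (period π) is
regressed as (sin 2θ, cos 2θ) and mapped back via atan2 before scoring,
with predictions unwrapped by ±π toward the truth before computing Pearson
correlations (an axial variable's raw correlation is corrupted by
wraparound). Degenerate (zero-variance) targets report NaN rather than
raising.

## Scaled-down forecasting study

The full-scale conditions (1600 simulations, 64×64 frames, 1000 epochs) are
summarised above; the bundled study that the tests and the acceptance
script run uses reduced problem sizes chosen once:

* 400 simulations (300 train incl. the 20% validation split, 100 held out),
  solver 32², observed on 16², 14 frames;
* spectrum cut-offs f₀ ∈ {2, 3, 4} — the default set {8, 12, 16} scaled
  with the grid so the shortest retained wavelength still spans ≥ 4 cells,
  as it does at full scale. Without this the observed fields carry
  pixel-scale structure that max-pooling cannot preserve, and the network
  memorises instead of generalising;
* frame interval 3.2·10⁻² so the field visibly decays across the 11-frame
  horizon (the last-input baseline is otherwise nearly unbeatable and the
  forecasting task trivially static);
* encoder/LSTM/decoder channels (16, 16, 16)/16/(16, 16, 1), K_b = 3,
  K_t = 4, 100 epochs, batch 16, learning rate 2·10⁻³ dropped at epoch 75;
* readout: channels (32, 32), 3×3 filters, stride 1 on the 2×2 latent grid,
  300 epochs.

At these sizes the trained surrogate beats the last-input baseline on
~80–95% of held-out simulations (signed-rank p well below 10⁻⁴), and the
readout recovers the boundary orientation reliably (r(θ) ≈ 0.65). The
diffusivity and offset correlations are positive but small at this scale
(r ≈ 0.1–0.25 at the study seed) and fluctuate with the seed — the 2×2
latent grid simply retains little of the spatial detail that encodes the
regional diffusivities. Passing these tests demonstrates the pipeline's
mechanics and the qualitative ordering (orientation easiest), not the
full-scale correlation magnitudes.

## Sodium channel and protocols

Gates relax as g' = (g_∞(V) − g)/τ_g(V); at a fixed clamp voltage the
update g(t+dt) = g_∞ + (g − g_∞)e^{−dt/τ} is exact and is a convex
combination, so gates cannot leave [0, 1]. τ_m's removable singularity at
V = −p₄ is evaluated by its analytic limit −p₃/p₅ inside a |V + p₄| < 10⁻⁷
guard. The fast/slow inactivation time constants are fixed
(voltage-independent defaults τ_h = 5 ms, τ_j = 50 ms, configurable): the
protocols are steady-state-dominated and the generator and fitter only need
to share them. E_Na defaults to +65 mV and G_Na to 1 — every protocol
summary is normalised to unit peak magnitude, so conductance cancels
(verified by a ×10 scaling test).

Protocol defaults (all configurable): holding −80 mV; activation steps −60
to +30 mV in 5 mV, 20 ms; inactivation availability from 500 ms prepulses
at −120…−20 mV followed by a −20 mV test pulse; a 20-pulse train at −20 mV
(20 ms pulses, 50 ms gaps); recovery from paired −20 mV pulses at 12
log-spaced intervals between 1 and 500 ms. Peak currents are detected on an
analytic gate trajectory sampled at 0.01 ms. The exact experimental
protocols behind the published fits are not reproducible here; these
defaults are explicit stand-ins with the same structure.

## ABC-SMC engine

Uniform independent priors (the nine kinetic parameters default to bounds
roughly an order of magnitude around the published values). The distance is
the mean over summary curves of the per-curve RMS difference; curves are
already normalised to unit peak so no further rescaling is applied.
Generation 0 proposes from the prior; the initial tolerance ε₀ is the
median of a pilot population's distances, and ε_{g+1} is the median of
generation g's accepted distances (a standard, robust schedule; the
quantiles are configurable). Later generations resample the previous
population by weight and perturb with a multivariate Gaussian kernel whose
covariance is twice the weighted empirical covariance (regularised by a
tiny diagonal), rejecting proposals outside the prior support; importance
weights are prior density over the kernel mixture density, normalised per
generation. Stopping: 12 generations (default), tolerance target 10⁻⁴, or
acceptance rate below 1% (a hard abort also triggers if a generation
cannot fill after an excessive number of proposals). Effective sample size
is tracked per generation. An optional population-adaptation mode doubles
the population when ESS < N/2 (off by default, N = 500).

With noise-free steady-state activation/inactivation observations generated
from the published parameter values, the posterior concentrates on
p₁, p₂, q₁, q₂ (posterior SD ≈ 2–4% of the prior width at 12 generations)
while p₅ and p₇ — which only enter τ_m — remain at the prior (posterior SD
≈ the prior's own SD, width/√12). Note that no distribution supported on
the prior interval can exceed SD = width/2, and a flat posterior has SD =
width/√12 ≈ 0.289·width; "near-prior" is therefore judged against the
prior's SD, not its width. Engine validity is checked independently on a
conjugate-Gaussian toy problem where the analytic posterior is known.

## Known limitations

* The diffusion kernel has no reaction term: no action-potential
  propagation, and no bidomain/monodomain electrophysiology.
* The synthetic fields are band-limited smoothed noise with a straight-line
  two-region tensor; real scar geometry, fibre fields and mapping noise are
  not emulated, so passing tests bounds solver/learning correctness, not
  clinical performance.
* The numpy network library is single-threaded BLAS-bound; full-scale
  training (64×64, 1600 simulations, 1000 epochs) is out of reach with it,
  which is why the bundled study is scaled down.
* ABC results depend on the summary curves supplied; with kinetic protocols
  included, p₃–p₇ become partially identifiable and runtimes grow
  accordingly (the steady-state summaries used by default are analytic and
  fast).
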