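# Methods

## Model class and truncation

A reaction network is a list of species, each with a finite population cap
`N_max`, and reaction channels with integer stoichiometry changes and
nonnegative propensities (stochastic mass action `c · Π_s (x_s)_(r_s)`, an
arithmetic expression over species names, or an arbitrary callable — the
propensities need not be linear).  Truncation is by *suppression*: a
reaction whose firing would push any species above its cap simply cannot
fire, in the generator and in the simulator alike.  This makes the
truncated CTMC an exactly self-consistent model (simulated histograms
converge to the CME solution with no boundary leakage), at the price of a
small distortion near the caps relative to the untruncated chain.  Caps are
user-supplied; `choose_caps` grows them until the stationary mass at the
boundary drops below a tail threshold (default 1e-8), which is our
concrete reading of "large enough to be negligible".

States are enumerated lexicographically with species in declaration order;
`StateSpace.index` is `ravel_multi_index` on the count grid and is exactly
invertible.  Species that no reaction changes and that are replicated at
division (a chromosomal gene copy, say) can be declared `fixed`: they are
substituted into propensities as constants and excluded from enumeration,
so the transcription–translation model needs 21 × 151 = 3171 states rather
than 6342.

The generator uses the column convention `dρ/dt = Aρ`: `A[i, j]` (i ≠ j) is
the rate from state j to state i and every column sums to zero (closure is
by construction; tests assert < 1e-12).

## CME solves

`Propagator` computes `exp(A·dt)·v` three ways; all must pass the same
invariant suite (mass conservation 1e-8, semigroup 1e-7, adjoint identity):

* **uniformization** (default): with `λ = max_j |A_jj|` and
  `P = I + A/λ`, `exp(At)v = Σ_k Poisson(k; λt) P^k v`.  The Poisson series
  is truncated at tail mass 1e-15 and horizons are split into chunks with
  `λ·Δt ≤ 50` so weights never underflow.  The jump matrix is built once
  per generator, so repeated fixed-interval steps (a microscopy sampling
  grid) cost a handful of sparse matvecs each.  This is why it is the
  default: `scipy`'s `expm_multiply` re-estimates operator norms on every
  call (~50 ms per call on the 3171-state system versus ~14 ms here, and
  far worse when applied to matrices).
* **expm**: `scipy.sparse.linalg.expm_multiply`, the cross-check.
* **ode**: BDF integration with rtol 1e-8 / atol 1e-10 (configurable), the
  stiffness-tolerant fallback for time-varying extensions.

`steady_state` solves `Ap = 0, 1ᵀp = 1` by replacing one balance row with
the normalization constraint (sparse LU), after verifying via strongly
connected components that exactly one closed communicating class exists;
the residual must satisfy `‖Ap‖_∞ < 1e-10`.

## Observers and numerics

**Discrete-time filter.**  Pre- and post-update vectors at every
observation time are both first-class outputs (`sides` = "pre"/"post");
the evaluation grid adds a configurable number of interior points per
inter-observation interval (default 20).  The forward vector is
renormalized after every step, with the log normalizer accumulated into the
log-evidence, so arbitrarily long records cannot underflow.

**Backward pass.**  `β` is stored max-normalized with an explicit running
log scale.  `β ≡ 1` after the final observation; crossing an observation
multiplies by the density vector; between observations `β(t) =
exp(Aᵀ(t'−t))β(t')`.

**Smoothing.**  `π ∝ ρ∘β`, pairing pre with pre and post with post (the
two products agree after normalization, which is exactly the continuity of
the smoothed posterior across observation times; asserted to 1e-6 TV in
tests while the filter jump is > 1e-3).  If the forward and backward grids
differ, missing backward values are recovered by re-propagation from the
nearest later grid point — never by interpolating probabilities, which
would not respect the dynamics.

**Continual observer.**  The implementation propagates the *unnormalized*
conditional vector under the within-class block `A_{y,y}` restricted to
the current output class (the class is invariant, so this restriction is
exact), normalizing afterwards and moving the normalizer into the path
log-density; jumps apply the dense class-to-class sub-block.  Class
restriction is what makes the 9513-state composed discrimination run
interactive: the active class holds 63 states, not 9513.  The normalized
nonlinear form `dρ/dt = A_{y,y}ρ − (1ᵀA_{y,y}ρ)ρ` is implemented as an
independent cross-check backend (`form="nonlinear"`, BDF at rtol 1e-10);
the two agree to 1e-8 in tests.  We made the exact linear form the default
and the nonlinear ODE the reference — the mathematically equivalent pair
could be wired either way, and the linear form is both exact and faster.
Prior mass outside the initial output class is zeroed with a warning, since
the initial symbol is itself an observation.

**Zero likelihood.**  For a single model, an impossible observation raises
`ZeroLikelihoodError` naming the index and time: the model, sensor and
prior are jointly wrong.  In composed multi-model filtering the same event
only zeroes the offending block — that is evidence against the model, not
an error — which the block-diagonal normalization does automatically.

## Colonies

The division kernel factorizes over species: binomial species partition
molecule-by-molecule with probability `p` (default 1/2, the fair-partition
assumption) so `x_d1 + x_d2 = x_m` exactly; replicate species are copied.
Because of the conservation coupling, the backward "pinch" of two daughter
likelihoods is the *coupled* convolution
`L(m) = Σ_{d1} K(d1, m−d1 | m) β₁(d1) β₂(m−d1)`, computed per mother state
with separable per-species binomial weights (no joint daughter product
space is enumerated).  A `independent_daughters=True` switch implements the
literal product-of-two-sublineage-factors reading for comparison; the
coupled form is the default because it is the exact likelihood.

Colony smoothing runs three sweeps: (i) a plain forward pass down the tree
(daughters seeded by the kernel marginal of the mother's final filter);
(ii) a backward pass up the tree, pinching at every division; (iii) a final
forward sweep in which each daughter's birth message combines the mother's
filtered state with the *sibling subtree's* backward likelihood
(`pinch_down`), making the within-cell forward–backward product the exact
posterior given all lineage observations.  A subtlety worth recording: the
daughter's smoothed birth distribution is *not* the kernel marginal of the
mother's smoothed division-time posterior — given future observations the
daughters are dependent — so the division-consistency identity is stated
and tested through the observation-reweighted kernel
(`posterior_division_update`).  End-to-end correctness is tested against an
independent discretized tree-HMM oracle (1e-4 TV).

Division times are inputs (observed from microscopy); the simulator's
fixed 20-minute interval is only its default.  Observations stamped exactly
at a division time belong to the mother cell.

## Discrimination and distinguishability

Model posteriors from the composed system equal the softmax of per-model
log-evidences plus log-priors (asserted to 1e-6 against separate
single-model runs).  The distinguishability test compares, per entry
context `(y_prev, y)` with stationary flux above a relative floor (1e-12)
and per destination `y'`, the hazard curves `h_{y'}(τ)` on a shared dwell
grid: 200 log-spaced points from 1e-3 to 10 times the reciprocal of the
smallest off-class exit rate carrying stationary mass.  The verdict is
"indistinguishable" iff every compared curve agrees within a relative
tolerance (default 1e-6, scaled by the larger curve's sup); a context or
destination alive in only one model is an immediate structural witness.  A
finite grid is the practical surrogate for the all-τ condition; halving the
grid step changes reported discrepancies by < 10 % (tested), and an
optional Taylor-coefficient check (`1ᵀA_{y',y}A_{y,y}^k ρ₀`, k ≤ 25) gives
a finite sufficient family for analytic equality on the truncated space.
The stationary output distribution is compared and reported separately
from the verdict: whether it belongs to the dwell-hazard condition proper
is left open, so both numbers are surfaced.

## Synthetic data

The Gillespie direct method draws per-event exponential waiting times and
channel choices from the same propensity tables as the generator, with the
same cap suppression; all-zero propensity is absorption, not an error.
Colonies divide every `division_interval` seconds (default 1200); at each
division the kernel's sampler partitions the mother's final state.
Everything is reproducible bit-for-bit from a seed.

Reference parameter sets (all overridable):

* birth–death: `k = 10`, `γ = 1`, cap 30 — stationary truncated
  Poisson(10), centred in the 7–13 "MEDIUM" band of the three-band sensor.
  The coarse-sensor literature leaves the Poisson parameter unspecified;
  10 keeps all three bands visited at stationarity.
* transcription–translation trio: transcription 0.05 s⁻¹, mRNA degradation
  0.01 s⁻¹, translation 0.05 s⁻¹ per mRNA, protein degradation 0.005 s⁻¹;
  M2 scales the protein pair ×10, M3 the mRNA pair ×10.  This gives mean
  mRNA 5 and mean protein 50 — small-copy-number regimes in which single
  protein steps are informative.  The trio's *means* coincide, but the
  stationary laws do not: the stationary protein Fano factor is
  `1 + k_P/(γ_M + γ_P)` (4.33, 9.32 and 1.48 for M1/M2/M3 here), so the
  variants are distinguishable even from stationary data, and any exact
  shared-steady-state expectation holds only for the mRNA marginal and the
  means.  Only a global time rescaling preserves the full stationary law.

What the generator does **not** emulate: sensor photophysics
(photobleaching, maturation, autofluorescence), cell growth and asymmetric
division volumes, cell death, time-varying rates, or extrinsic noise.
Passing tests therefore demonstrate the estimator-side mathematics on data
matching the model class, not robustness to real-microscopy artefacts or
model misspecification.

## Problem sizes used in the test suite

Oracle comparisons use a Δ = 1e-3 uniformized discrete-time HMM on models
with ≤ 40 states, where the surrogate is exact to floating point because
all event times sit on the grid.  Simulator fidelity uses 1e5 birth–death
runs (TV < 0.02 against the CME).  Discrimination timing uses 11 seeded
replicates per generating model over 300 s (M2) and 4000 s (M3) windows;
colony estimation uses 20 replicates of a 7-cell colony over 3500 s with
protein counts each 60 s, against a division-aware no-observation prior
predictor.  The empirical dwell-hazard check uses 2e4 stationary sojourns
with a three-standard-error band.

## Known limitations

State spaces are exponential in the number of species; beyond a few
low-copy species the CME solves and (especially) the coupled pinch become
the bottleneck.  The continual observer requires a noise-free partition;
noisy sensors go through the discrete-time path.  Parameters are assumed
known — no joint state/parameter estimation — and generators are
time-invariant (the propagator interface would admit time dependence, but
none is implemented).
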