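# Methods

## Model

A coarse-grained configuration is N identical sites in an orthorhombic
periodic box (minimum-image convention throughout; coordinates in Å).
Site *n* is encoded by K radial symmetry functions
G²_{n,i} = Σ_{k≠n} exp(−η_i (r_nk − r_{s,i})²) f_c(r_nk) with the cosine
cutoff f_c(r) = ½[cos(πr/r_c)+1] for r ≤ r_c and 0 beyond.  A single
feed-forward network shared by all sites maps G²_n to a site energy:
ReLU hidden layers, identity output, and **no bias parameters**, so an
isolated site (all-zero descriptors) has exactly zero energy and the
network is positively homogeneous in its inputs.  The total energy is
the site sum in ascending index order (bit-reproducible).  Energies are
in units of k_BT (β = 1 internally); only βE ever enters the method, so
the energy unit is a convention, not a parameter.

Built-in descriptor sets:

* **Set 1** (8 functions): one wide Gaussian at 0 Å with η = 0.125 Å⁻²
  plus seven with η = 4.0 Å⁻² centered 3.0–6.0 Å in 0.5 Å steps.
* **Set 2** (24 functions): Set 1 plus a wider η = 0.02 Å⁻² at 0 Å, nine
  η = 16.0 Å⁻² centered 3–5 Å (0.25 Å steps) and six η = 2.0 Å⁻²
  centered 3–8 Å (1.0 Å steps).  The wide-center counts and η values are
  fixed; the uniform spacings and the six-member medium family are this
  package's choice, made so that Set 2 has exactly 24 members (the
  network architectures are described with 24 inputs, but the companion
  list of additional functions sums to 23; we resolve in favor of 24).

Default architectures: linear (no hidden layer), Model 1 = 3×20 hidden,
Model 2 = 3×40 hidden.

## Sampling

Standard Metropolis Monte Carlo with single-particle displacements drawn
uniformly from a cube of half-width `max_disp`, acceptance
min(1, e^(−βΔE)); non-finite ΔE is rejected.  ΔE is evaluated
incrementally: a move touches only the moved site's descriptor row and
the rows of sites within r_c of its old or new position; the N×K matrix
and per-site energies are updated in place and fully rebuilt every
`refresh_interval` (default 2·10⁵) steps to cap floating-point drift.
The tracked total energy agrees with a from-scratch recomputation to
~1e-15 per step in practice; the rebuild is a guard, not a correction.
`max_disp` adapts multiplicatively every 10³ steps **during equilibration
only** (factor 1 + 0.5(acc − target), clipped to [10⁻³, box/4]) and is
frozen for production, since adapting while measuring violates detailed
balance.

Observables are accumulated every `output_freq` steps after
equilibration: the pair-distance histogram (RDF), and for training runs
⟨∂E/∂ω⟩ and the bin×weight cross moment ⟨g_α ∂E/∂ω_i⟩; for tabulated
potentials optionally the histogram second moments ⟨S_α S_γ⟩ used by the
IMC update.  The RDF normalization divides bin counts by
N(N−1)/2 · 4πr²Δr/V at the bin center (an exact-shell variant is a
flag; every consumer in the package uses the same estimator).

All samplers run inside numba kernels seeded explicitly: identical seeds
give bit-identical trajectories.  Multi-system sampling derives one seed
per system from the master seed, so results are independent of execution
order and worker count (execution itself is sequential).

## Training

Per system, L = Σ_α (⟨g_α⟩^NN − g_α^ref)², and
∂⟨g_α⟩/∂ω_i = −β(⟨g_α ∂E/∂ω_i⟩ − ⟨g_α⟩⟨∂E/∂ω_i⟩).  Gradients are summed
over systems (the total loss is the sum), and one AMSGrad step closes an
iteration; each iteration restarts every system's chain from a randomly
chosen reference frame.  The AMSGrad here bias-corrects both moments
(the PyTorch convention): with the second moment uncorrected, the first
update is lr/√(1−β₂) ≈ 10·lr per weight, which we found sufficient to
collapse marginally-stable nonlinear potentials in a single step.
`train` also tracks the best-loss checkpoint; production models are the
best checkpoint, not the last iterate, mirroring common practice of
selecting an intermediate iteration.

Pretraining regresses single-move energy changes onto the PMF
prediction: V(r_α) = −kT ln g_α on populated bins and, below the first
populated bin α₀, the linear ramp V(r_α) = V(r_{α₀}) + (α₀−α)ΔV with
ΔV = V(r_{α₀}) − V(r_{α₀+1}); pair energies use floor-bin lookup and
vanish beyond the grid.  Each pretraining step picks one frame and one
site per system, displaces it uniformly (default half-width 0.5 Å),
forms (ΔE^NN − ΔE^PMF)², and averages gradients across systems.
Reference frames never move, so their descriptor matrices are memoized.

Optimizer presets, tuned once on the desk-scale LJ case: pretraining
lr = 0.3, β₁ = 0.7; RDF training lr = 0.2, β₁ = 0.5, β₂ = 0.99.  The
high training rate is safe because AMSGrad's max-locked second moment
acts as built-in annealing (early large gradients permanently damp late
steps); low momentum suppresses the oscillations the noisy fluctuation
gradients otherwise excite.  The generic `OptimizerState` default is a
conservative lr = 0.005.  Learning-rate schedules and gradient clipping
are deliberately absent.

### Warm-starting deep networks

PMF pretraining of a *random-weight* deep no-bias ReLU network is
unreliable: small-displacement moves never constrain the high-density
corner of descriptor space, leaving energy surfaces that collapse under
tiny weight perturbations, while large displacements drive the net to
the dead-ReLU zero solution.  Because descriptors and hidden activations
are nonnegative, a deep network can represent any linear model exactly
through identity sub-blocks; `NetworkParams.embed_linear` builds that
embedding (plus small symmetry-breaking noise) so deep training starts
from the robust pretrained linear solution.  The multi-state study uses
this warm start; the uniform [−1, 1] initialization remains the default
elsewhere.

## IMC baseline

With energy E = Σ_α ω_α S_α over the pair histogram, the same
fluctuation identity is exact and one iteration solves
Cov(S) Δω = Δ⟨S⟩/β via pseudo-inverse (relative singular-value cutoff
1e-10), scaled by a regularization factor in (0, 1] (default schedule:
five iterations at 0.5, then at 1.0).  The covariance needs dense
sampling: the desk runs accumulate every 50 steps (~6·10³ samples for a
170-bin grid); at sparse cadences the noisy covariance makes the update
diverge.  The linear-network correspondence is quantified by
`linear_nn_imc_equivalence`: with indicator descriptors the two energy
forms are identical to round-off (each pair enters two site sums, hence
the factor 2 between network weights and table values); with narrow
Gaussians at the bin centers, soft counts are compared to hard counts
after dividing by the mean bin mass √(π/η)/Δr.  The residual is a
per-pair ripple (the normalized Gaussian comb over- and under-weights
pairs by their offset within the bin), so the per-configuration RMS
deviation falls as 1/√n_pairs; the packaged study therefore evaluates it
on 512-atom liquid-argon configurations, where η = 400 Å⁻² at
Δr = 0.25 Å sits below 2% RMS.  Pointwise in η the deviation is *not*
monotone to zero — a narrowing Gaussian tends to a delta function, not a
bin indicator — but over the packaged sweep (η = 16, 50, 400) it
decreases on the fixed config set.

## Synthetic reference data

`refgen` replaces atomistic references with a truncated (unshifted)
Lennard-Jones fluid sampled by the same engine.  Defaults are the
liquid-argon state point: 512 atoms, T = 95 K, ρ = 1374 kg/m³ (29.1 Å
box), σ = 3.405 Å, ε/k_B = 119.8 K, RDF grid 0–10 Å × 400 bins, target
acceptance 0.5, 200 saved frames.  Reference budgets default to 2·10⁷
steps (10⁶ equilibration); the full production protocol (1.2·10⁹
steps, 6·10⁷ equilibration, 10⁶-step output) is available via
`production_scale=True`.  A state-point *series* varies density and,
optionally, well depth per state — emulating how a solute concentration
series changes both packing and the effective pair potential, which is
the problem shape that makes a single tabulated potential
non-transferable.

What the generator does **not** emulate: molecular shape and hydrogen
bonding (no angular structure beyond what a pair potential induces),
many-body solvent-mediated forces, and long-range electrostatics.
Passing the packaged studies therefore shows the trainer recovers and
transfers *pair-structured* interactions; it does not certify accuracy
for strongly directional real-liquid structure.

## Desk-scale study conditions

The packaged studies (test suite and `scripts/acceptance.py`) use sizes
one CPU core completes in minutes, stated here as the package's standard
conditions:

* LJ recovery: N = 125 (18.2 Å box, cutoff and RDF range 8.5 Å, 170
  bins), 2·10⁶-step reference, 5·10³ pretraining steps, 15 training
  iterations × 4·10⁵ steps (10⁵ equilibration, output every 200).  The
  noise floor is the mean RDF loss of five independent resamplings of
  the exact LJ potential at the training budget; the final loss is the
  mean of the last three iterations (per-iteration losses are stochastic
  estimates).
* Transferability: four state points, N = 125, T = 95 K, densities
  1250/1330/1410/1490 kg/m³ with ε/k_B = 86/95/104/113 K (all dense
  liquid, clear of the LJ binodal).  Model-1 architecture trained on
  states 1, 2, 4 (35 iterations × 2·10⁵ steps, lr 0.003, β₁ 0.8, linear
  warm start); IMC tables trained on each of the same three states; all
  validated on all four states with 3·10⁵-step fixed-weight runs.  The
  comparison metric is the mean RDF loss over the four states.
* Gradient-estimator check: 20 sites, 4-weight linear model, 10⁶-step
  runs, δω = 0.05, six replicas per estimate; cells with reference
  ⟨g⟩ ≤ 0.1 are excluded (both estimators are exactly zero there and a
  3σ comparison is ill-posed).

## Numerical choices and edge cases

* ReLU′(0) := 0 everywhere (kernels and reference implementation).
* RDF bin α covers [αΔr, (α+1)Δr); pair-energy tables use the same
  floor-bin convention; pairs beyond a table contribute zero.
* PMF tables bridge interior zero-g holes by linear interpolation
  between populated neighbors so tables stay finite.
* Overlapping sites (r = 0) are legal inputs (f_c finite); NaN positions
  are rejected at construction.
* Model files store weights as hexadecimal floats — binary-exact round
  trips, unlike decimal text.
* Angular distributions are per-bin probabilities multiplied by the bin
  count, so a flat angle distribution maps to 1.0 regardless of binning;
  no sin θ deconvolution is applied, and reference and model curves use
  the identical convention, so comparisons are self-consistent.
* The trajectory dialect is extended-XYZ with a diagonal
  `Lattice="..."` box; only orthorhombic cells are accepted.

## Known limitations

* Single CG site type; no angular (three-body) symmetry functions —
  many-body effects enter only through the nonlinearity of the network
  over radial descriptors.
* NVT only; single-process sampling (per-system streams are seeded for
  order independence, but nothing runs concurrently).
* The 15-iteration desk budget recovers the LJ structure for typical
  random initializations; occasional poor draws of the uniform [−1, 1]
  init leave pretraining (5·10³ steps) with a worse starting point than
  the budget can fully polish.  The production-scale budgets (5·10⁴
  pretraining steps, 50 × 8·10⁶-step iterations) have no such
  sensitivity in our experience with longer desk runs.
* IMC requires dense covariance sampling and a start (PMF) within the
  linear-response regime; it is not globally convergent.
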