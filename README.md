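# nncg — neural-network coarse-grained potentials from structural data

`nncg` trains a Behler–Parrinello-style neural network to act as the
interaction potential of a coarse-grained (CG) fluid, so that Metropolis
Monte Carlo sampling under the network reproduces reference radial
distribution functions (RDFs).  It is aimed at people building bottom-up
CG models — one site per molecule, solvent implicit — who want a single
potential that stays accurate across several thermodynamic state points
(a concentration or density series), where a classic tabulated pair
potential fitted at one state point does not transfer.

## The method

Each CG site *n* is described by radial symmetry functions

    G2_{n,i} = Σ_{k≠n} exp(−η_i (r_nk − r_s,i)²) · f_c(r_nk),
    f_c(r) = ½ [cos(π r / r_c) + 1]   for r ≤ r_c, else 0,

which feed a bias-free feed-forward network (ReLU hidden layers, linear
output) returning a site energy E_n; the total energy is E = Σ_n E_n.
The loss for one reference system is

    L = Σ_α ( ⟨g(r_α)⟩^NN − g(r_α)^ref )²,

and, because the sampled RDF is not a differentiable network output, the
chain-rule factor comes from the statistical-mechanical fluctuation
(inverse-Monte-Carlo) identity

    ∂⟨g(r_α)⟩ / ∂ω_i = −β ( ⟨g(r_α) ∂E/∂ω_i⟩ − ⟨g(r_α)⟩⟨∂E/∂ω_i⟩ ),

whose three averages the Metropolis sampler accumulates during each run.
Per-system gradients are summed over reference state points and applied
with AMSGrad.  Training starts from a PMF-matching pretraining stage:
random single-site displacements of reference frames are scored by both
the network and the potential of mean force V(r) = −kT ln g(r) (with a
linear repulsive ramp where g = 0), and the squared energy-change
mismatch is regressed away.

With a linear network (no hidden layers) and histogram-like descriptors
the scheme reduces exactly to classic inverse Monte Carlo with a
tabulated pair potential; the `imc_baseline` module implements that
method both as a comparison baseline and as a correspondence check.
Atomistic reference data are replaced by a self-contained Lennard-Jones
generator (`refgen`), including multi-state-point families whose density
and well depth co-vary — the same "one network, many reference RDFs"
problem shape as a solute concentration series.

## Worked example

Train the 8-descriptor linear model against a desk-scale liquid-argon
reference and compare the recovered structure:

```python
import numpy as np
from nncg import protocols

study = protocols.lj_recovery_study(seed=1)
print(f"reference acceptance ratio: "
      f"{study.bundle.log['acceptance_ratio']:.3f}")
print(f"RDF loss after pretraining: {study.loss_after_pretrain:.2f}")
print(f"RDF loss after 5 iterations: {study.loss_iter5:.2f}")
print(f"final RDF loss: {study.final_loss:.3f}")
print(f"sampling-noise floor:       {study.noise_floor:.3f}")
```

prints (seed 1):

```
reference acceptance ratio: 0.490
RDF loss after pretraining: 4.00
RDF loss after 5 iterations: 0.65
final RDF loss: 0.112
sampling-noise floor:       0.033
```

Reading: the Metropolis step size was adapted to the 0.5 target
acceptance; PMF pretraining alone leaves a summed squared RDF error of
about 4 over the 170 bins; five fluctuation-gradient iterations cut it
almost an order of magnitude; after 15 iterations the sampled RDF
differs from the reference by about three times the error two
independent samplings of the *exact* LJ potential show against each
other — i.e. the network has essentially recovered the pair structure,
limited by sampling noise.

The same workflow is available from the shell on plain-text artifacts
(extended-XYZ frames, two-column RDF tables, JSON model files):

```bash
nncg genref  ref.yaml --outdir ref/ --seed 1
nncg pretrain train.yaml --out pre.json  --seed 1
nncg train    train.yaml --start-model pre.json --out model.json --seed 1
nncg sample   model.json ref/lj.xyz --out sampled.rdf
nncg validate model.json train.yaml --outdir validation/
nncg imc      imc.yaml  --out imc.table
```

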