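# cueqs

Evolutionary dynamics of **cue-based quorum sensing** in a threshold
public goods game, as a four-tier model family: mean-field ODEs, exact
configuration-field dynamics over finite random groups, a non-spatial
agent-based simulation, and a spatially explicit toroidal lattice
simulation.

## The scientific problem

Quorum sensing (QS) lets microbes switch on costly cooperation — e.g.
bacteriocin production — only when enough cooperators are nearby.  QS
is doubly cheatable: *laggards* free-ride on the public good, and
*liars* fake the signal to trigger cooperation they never provide.  In
*cue-based* QS systems (nisin in *Lactococcus lactis* is the classic
case) the signal is an inevitable low-level byproduct of the
cooperation machinery itself, so honest cooperators signal for free
while cheaters must pay for the same signal.  This package implements
that game and lets you recompute where cooperation, communication, and
cheating survive.

Each agent carries three binary loci — cooperate `C`, extra signal
`S`, respond to signal `R` — giving 8 strategies (Lazy `csr`, Voyeur
`csR`, Liar `cSr`, Curious liar `cSR`, Trusty `Csr`, Smart `CsR`,
Bouncer `CSr`, Nerd `CSR`).  In a group of N = 9, a conditional
cooperator (`CR`) activates iff the group's signal doses reach the
quorum threshold Q, the benefit b arrives iff at least κ members are
active cooperators, and the realized metabolic cost of an agent is

```
C_i = (1 − θ·b) · (c0 + γ·c·[C] + s·[S] + r·[R])
```

Evolution proceeds by pairwise cost-difference imitation,
`p_ij = ½(1 + σ·ΔC/ΔC_max)` with `ΔC_max = c + s + r + b·c0`, plus
per-locus mutation.  See `docs/methods.md` for the full model account.

## Worked example

Fixed points of the configuration-field dynamics for the three feasible
strategies (Lazy, Trusty, Smart) in the benefit-rich regime
(b = 0.5, r = 0.01, c = 0.3, κ = 3):

```python
import numpy as np
from cueqs.core import ModelParams
from cueqs.configfield import cf_fixed_points

for fp in sorted(cf_fixed_points(ModelParams(b=0.5, r=0.01)),
                 key=lambda f: f.location):
    print(f"{fp.stability:9s} x(La,Tr,Sm) = {np.round(fp.location, 4)}")
```

```
unstable  x(La,Tr,Sm) = [0. 0. 1.]
saddle    x(La,Tr,Sm) = [0. 1. 0.]
stable    x(La,Tr,Sm) = [0.6517 0.     0.3483]
saddle    x(La,Tr,Sm) = [0.964 0.    0.036]
stable    x(La,Tr,Sm) = [1. 0. 0.]
```

Two attractors coexist: the all-Lazy state and a **Smart/Lazy
polymorphism** at ≈ 35% quorum-sensing cooperators — honest,
cue-driven cooperation resists free-riders even in a fully mixed
population.  The companion saddle at ≈ 3.6% Smart is the invasion
barrier separating the two basins.

An 8-strategy lattice run with mutation (100×100 torus, κ = 3,
c = 0.2, b = 0.8, s = r = 0.05, D = 0.5, ρ = 1e-4):

```python
from cueqs.lattice import LatticeState, run

p = ModelParams(c=0.2, b=0.8, s=0.05, r=0.05, kappa=3, D=0.5, rho=1e-4)
state = LatticeState.random(np.full(8, 1/8), 100, seed=11)
print(run(state, p, 2000, record_every=500).round(3).to_string(index=False))
```

```
 generation   csr   csR   cSr   cSR   Csr   CsR   CSr   CSR
          0 0.125 0.125 0.125 0.125 0.125 0.125 0.125 0.125
        500 0.417 0.002 0.017 0.000 0.191 0.354 0.013 0.005
       1000 0.377 0.003 0.000 0.000 0.111 0.506 0.000 0.002
       1500 0.389 0.007 0.000 0.000 0.045 0.557 0.000 0.000
       2000 0.376 0.005 0.001 0.000 0.041 0.570 0.000 0.006
```

The steady state is a Smart/Lazy coexistence (`CsR` ≈ 0.57,
`csr` ≈ 0.38); Liars (`cSr`) and the signal-exaggerating cooperators
(Bouncer `CSr`, Nerd `CSR`) are held at mutation–selection-balance
frequencies — paying for a signal that cooperators emit for free never
pays off.

## Command line

```bash
cueqs mf-field      --out-dir out                 # mean-field vector field
cueqs cf-field      --out-dir out                 # CF field + fixed-point JSON
cueqs abm-run       --config params.yaml --seed 1
cueqs lattice-run   --eight-strategies --seed 1
cueqs vector-field  --model lattice --resolution 5
cueqs sweep         --kappa 2 --kappa 3 --d 0.0 --d 0.5
```

`--paper-scale` switches any run to the full published problem sizes
(300×300 lattice, 10,000 generations, P = 90,000).  YAML configs use
the standard symbol names (`c0, c, s, r, b, sigma, kappa, Q, N, P, M,
G, D, rho`).

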