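# kelchdyn

Trajectory analysis of β-propeller stability: the anti-parallel β-sheet
order parameter, superposition metrics, hydrogen-bond networks, backbone
dihedral comparison, and order-parameter-based classification of point
mutants as destabilizing or neutral/stabilizing.

## The problem

The Kelch domain of KEAP1 — a six-bladed β-propeller (residues ~325–609)
that binds NRF2 — is frequently hit by cancer missense mutations. Several
of these mutants are insoluble and cannot be characterized at the bench,
so their effect on fold stability has to be read out of conformational
ensembles (molecular-dynamics trajectories) instead. This package
implements the post-processing side of that workflow for anyone analysing
ensembles of β-propeller (or any β-rich) proteins: given a wild-type
ensemble and mutant ensembles, it quantifies how much anti-parallel
β-structure each one retains and turns the difference into a stability
call.

## The order parameter

The central quantity is the anti-parallel β-sheet order parameter

    Saβ = Σᵢᴺ (1 − xᵢⁿ) / (1 − xᵢᵐ),     xᵢ = (rᵢ − d₀) / r₀

where `rᵢ` is the backbone RMSD (nm) of the i-th six-residue segment pair
— two three-residue fragments, 30 backbone atoms (N, CA, CB, C, O) —
from an ideal anti-parallel two-strand template after optimal
superposition, and `N` is the number of segment pairs scored. Defaults are
`r₀ = 0.08 nm`, `n = 8`, `m = 12`, `d₀ = 0`, the parameters of the
collective-variable formulation the order parameter originates from. A
fully sheeted structure scores near `N`, a disordered one near zero.

A mutant is classified from the change relative to the wild type
(block-averaged means, uncertainties summed in quadrature):

* ΔSaβ + σ < −2 → **destabilizing** (a two-or-more point drop),
* ΔSaβ − σ > −1 → **neutral/stabilizing**,
* otherwise → **inconclusive**.

Around this sit the standard ensemble metrics (RMSD/moving-RMSD/RMSF after
least-squares backbone fit, radius of gyration, block-averaged statistics),
blade-wise decomposition for the Kelch propeller, geometric hydrogen-bond
occupancy ("lifetime") networks and their wild-type/mutant differences,
residue contact maps, and periodic Ramachandran kernel densities compared
by Jensen–Shannon distance.

Because real trajectories of this system are tens of microseconds long and
not redistributable, the package ships a synthetic-ensemble generator
(`kelchdyn.synthetic_data`) producing sheets, stylized propellers and coils
with known ground truth — jitter amplitude, injected disorder, bond
occupancies — against which every analysis stage is tested.

## Worked example

```python
from kelchdyn import (EnsembleSpec, classify, delta_sa_beta,
                      enumerate_segment_pairs, make_ensemble, sa_beta_series)
from kelchdyn.synthetic_data import DisorderSpec, PropellerBase

spec = dict(base=PropellerBase(), jitter_sigma=0.25, n_frames=40)
wt, _ = make_ensemble(EnsembleSpec(seed=1, **spec))
mut, _ = make_ensemble(EnsembleSpec(
    seed=2, disorder=[DisorderSpec(start=66, end=71, magnitude=90.0)], **spec))

pairs = enumerate_segment_pairs(wt.topology)
delta, sigma = delta_sa_beta(sa_beta_series(mut, pairs).totals,
                             sa_beta_series(wt, pairs).totals)
print(f"dSab = {delta:.2f} +/- {sigma:.2f} -> {classify(delta, sigma)}")
```

prints

```
dSab = -4.08 +/- 0.03 -> destabilizing
```

the six-residue strand whose torsions were scrambled (residues 66–71, one
strand of blade II) destroys every segment pair it participates in, the
order parameter drops by about four points, and the mutant is called
destabilizing. The same analysis is available from the shell:

```sh
kelchdyn simulate --base propeller --n-frames 40 --seed 1 -o wt.pdb
kelchdyn simulate --base propeller --n-frames 40 --seed 2 \
    --disorder 66:71:90 -o mut.pdb
kelchdyn classify wt.pdb mut.pdb
```

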