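# Methods

## The anti-parallel β-sheet order parameter

Saβ sums a switching-function score over all pairs of three-residue
backbone fragments that are far enough apart in sequence. Each pair is a
30-atom rigid body — N, CA, CB, C, O for each of six residues — whose
RMSD `r` (in nm, after optimal Kabsch superposition) from an ideal
two-strand anti-parallel template is mapped through

    s(r) = (1 − xⁿ) / (1 − xᵐ),   x = (r − d₀)/r₀.

The score is 1 at `r = d₀`, passes `n/m = 2/3` at `x = 1` (the removable
singularity is handled by evaluating the equivalent geometric-series form
`Σ_{k<n} xᵏ / Σ_{k<m} xᵏ`, which is exact for every x ≥ 0 and continuous
at 1), and decays like `x^{n−m}` for large x. Defaults:

| parameter | default | meaning |
|---|---|---|
| r₀ | 0.08 nm | RMSD scale of the switch |
| n, m | 8, 12 | switch steepness (m > n) |
| d₀ | 0 nm | RMSD offset |
| min. separation | 5 residues | gap between a pair's fragments |

r₀ deserves a note: the literature around this order parameter prints the
radius inconsistently as "0.8" with the fragment RMSD "in nm", but the
original collective-variable implementation uses 0.08 nm (0.8 Å), and only
at that scale does the parameter discriminate: with r₀ = 0.8 nm a compact
random coil scores ≈ 0.6·N (nearly everything within a nanometre of the
template counts as sheet), whereas at 0.08 nm the same coil scores
≈ 0.001·N and an ideal sheet still scores ≈ N. We therefore default to
0.08 nm; the value is a plain config field for anyone who wants the other
reading.

### Template

The template is built deterministically from internal coordinates: a
three-residue strand at canonical β torsions (φ = −139°, ψ = +135°, trans
ω) with Engh–Huber-style bond geometry, plus a copy rotated 180° about the
sheet normal (derived from the strand axis and the central carbonyl
direction) and translated so the central residue pair forms both canonical
inter-strand hydrogen bonds at N···O = 2.9 Å, with symmetric end-to-end
registry. The three translation components are solved by a least-squares
root find from a fixed starting point, so the construction has no
randomness. CB positions (including the virtual CB synthesised for
glycine) are placed at the ideal tetrahedral position: 1.53 Å from CA,
110.5° to both N and C, L-chirality.

### Segment enumeration and attribution

Fragments are triples of consecutively numbered residues within one chain;
numbering gaps are treated as chain breaks and never spanned. All ordered
pairs with `start(b) − end(a) ≥ 5` are scored (the pair-of-fragments
semantics of the original collective variable; a contiguous six-residue
window would describe a hairpin only and cannot see inter-strand order).
Scores are attributed equally (1/6 each) to a pair's six residues so the
per-residue field sums exactly to the total; blade values are the blade's
residue sum divided by the blade residue count, which keeps blades of
different lengths comparable and avoids double counting pairs that
straddle a blade boundary.

Per-frame evaluation is vectorised: all pair coordinate blocks are
gathered into an (N, 30, 3) array and superposed against the template with
a batched SVD identity (RMSD² from the singular values of the 3×3
cross-covariance, smallest value negated when the determinant is
negative), which keeps a 144-residue propeller (~4 400 pairs) at ~20 ms a
frame.

## Superposition and deviation metrics

Kabsch superposition is the SVD route with the reflection guard; fits are
mass-unweighted and the fit selection and measured selection are the same
backbone atoms (N, CA, C, O) unless a separate measure selection is passed.
RMSF defaults to the *initial-structure* reference — the deviation of a
residue from its initial position — which is deliberate and loud: most
trajectory tools default to the mean structure, so a `reference_mode`
switch provides that convention too. For an isotropic jitter of σ per
coordinate, fluctuation about the mean is σ√3 per residue; about a clean
initial frame it is also σ√3, but about a jittered first frame it is σ√6 —
tests use whichever reference matches the closed form they check.

Moving RMSD is the lag-based reading: element t compares frame t+lag with
frame t after fitting (series length n−lag). Block averaging splits a
series into five contiguous near-equal blocks by default — the natural
reading of one block per microsecond over a five-microsecond production
window — with the remainder spread over leading blocks; the reported mean
is the mean of block means and σ the (n−1) deviation of block means.

## Hydrogen bonds and contacts

Analysis structures usually carry no hydrogens, so the primary criterion
is heavy-atom geometric: all N/O atoms of different residues within
3.5 Å. When hydrogens are present, donors must carry one and a D–H–A
angle ≥ 150° is additionally required. Both cutoffs are config fields and
are echoed in every output header, since published analyses typically name
the tool but not its thresholds. "Lifetime" means occupancy — the
percentage of frames in which the bond exists — not continuous dwell
time. Network differencing keys bonds on (chain, residue index, atom name)
of both partners, so a side chain removed by mutation shows up as the full
negative wild-type occupancy. Contact maps count frames where the minimum
heavy-atom distance between two residues is below 4.5 Å, with the
|i−j| ≤ 2 band masked.

## Dihedral densities

φ/ψ are stored in degrees in (−180, 180]. Ramachandran densities are
wrapped Gaussian KDEs on a fixed 72×72 (5°) grid — each kernel is summed
over the ±360° images so clusters straddling the wrap stay single modes —
normalised to integrate to one. Dihedral-space change between two
ensembles is the base-2 Jensen–Shannon *distance* between grids (0 for
identical sampling, 1 for disjoint), with a declared flag threshold of
0.2; bandwidth defaults to 15°. These are plotting-level choices made
explicit so that "the dihedral space shifted" becomes a testable number.

## Classification

ΔSaβ = blockmean(mutant) − blockmean(wild type), σ = quadrature sum of the
two block σs. The destabilizing boundary (−2, the "two-or-more point
drop") comes from the stability analysis this package operationalises; the
neutral boundary (−1) and the σ-overlap rule that yields "inconclusive"
are this package's declared operationalization of "minimal changes or
increases" — a mutant whose uncertainty band straddles both boundaries is
not forced into either class. Both thresholds are config keys.

Accuracy scoring reports both inconclusive policies side by side (counted
as wrong, or excluded from the denominator) because a single headline
accuracy is ambiguous whenever a method is allowed to abstain: on the
packaged 12-mutant published label table the two policies give 91.7% and
100%, and restricting to the nine experimentally characterized mutants
gives 88.9%.

## The synthetic generator

The generator emulates the statistical signatures the analyses assume, not
physics: no force field, no solvent, no thermodynamics.

* **Bases.** Ideal sheets tile the scoring template exactly: strand k is
  the k-th power of (anti-parallel flip ∘ screw^(3−L)), which makes the
  in-registry fragment pairs of adjacent strands rigid copies of the
  template (at every second offset — only alternate residue pairs of an
  anti-parallel sheet are doubly hydrogen bonded). The propeller is a
  stylized ring of such sheets — the topology of a β-propeller, not the
  geometry of any particular protein. Coils draw φ/ψ uniformly.
* **Jitter** is isotropic Gaussian noise of stated σ per coordinate.
* **Disorder** is a persistent structural perturbation: φ/ψ kicks of
  stated magnitude drawn once per ensemble and rebuilt through internal
  coordinates, so the damage is local in sequence but propagates in space,
  as real unfolding does (Cartesian noise of any plausible size barely
  moves the order parameter). Per-frame jitter is applied on top.
* **Two-state bonds** displace the acceptor 3 Å beyond criterion with
  probability 1 − p_bound, independently per frame.
* **Rigid motion** applies a uniform random rotation and a ±20 Å
  translation per frame.

Everything injected is recorded in a GroundTruth object serialized next to
the ensemble; generation is byte-reproducible from the seed.

Mutant/wild-type contrast pairs calibrate the disorder magnitude by
bisection against the designed ΔSaβ (−4 for destabilizing, −1.5 for the
deliberately ambiguous "moderate" level), evaluating the expectation over
a few fixed jitter draws because jitter depresses partially disordered
pairs more than intact ones. The packaged benchmark is ten pairs — five
destabilizing, five neutral (same conditions, different seed) — at 40
frames each with the disorder window rotating through the blades.

**What passing these tests shows — and does not.** Recovery of designed
labels on generated ensembles validates the bookkeeping and the decision
rule end to end under known noise; it says nothing about force-field
accuracy, sampling convergence, or whether five microseconds of real
dynamics suffice to expose a mutant's instability. Real trajectories also
have correlated, anisotropic fluctuations the jitter model does not mimic
— which is precisely why the error bars here come from block averaging
rather than from any i.i.d. assumption.

## Numerical choices and problem sizes

Scores are evaluated with the geometric-series form of the switch, which
is monotone and continuous at x = 1 in exact arithmetic; in double
precision the switch is flat (exactly 1.0) for x below ~0.1 because x⁸
underflows the resolution of 1.0 — tests assert strict decrease only
where a step is representable. RMSD values near zero carry a ~1e-7 Å
cancellation floor from the sum-of-squares identity. PDB round trips are
exact at the format's three-decimal coordinate precision. Default problem
sizes — a 6×4×6-residue propeller, 40-frame ensembles, 20–30-residue
coils for oracle comparisons — were chosen so the entire suite and the
acceptance script each run in about two minutes on one CPU while keeping
every statistical check well away from its threshold.

## Known limitations

* Insertion codes are rejected rather than carried (the reference crystal
  structure of the target domain has none); altloc handling keeps the
  highest-occupancy conformer.
* Cross-chain segment pairs are not enumerated (sequence separation is
  undefined across chains); all synthetic bases are single-chain.
* Hydrogen-bond chemistry is deliberately naive at the heavy-atom level
  (every N/O is both donor and acceptor candidate); with hydrogens present
  the angle criterion restores directionality.
* Parallel-sheet and helical analogues of the order parameter are natural
  extensions and are not implemented.
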