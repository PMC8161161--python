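"""Synthetic structures and ensembles with known ground truth.

The generator emulates the statistical signatures the analysis stages
assume, without any physics: ideal anti-parallel sheet geometry (tiled from
the same template the order parameter scores against), isotropic Gaussian
thermal jitter, localized loss of beta structure injected as persistent
phi/psi perturbations rebuilt through internal coordinates (local in
sequence, propagating in space, as real unfolding does), two-state
hydrogen-bond occupancy with a known bound probability, and per-frame
rigid-body motion.  Every injected parameter is recorded in a
:class:`GroundTruth` object so downstream tests never re-derive design
values.  Generation is fully reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _peptide
from .beta_order import (_strand_atoms, antiparallel_neighbor_transform,
                         enumerate_segment_pairs, sa_beta,
                         strand_screw_transform)
from .structure_io import Atom, BladeScheme, Ensemble, Structure

__all__ = [
    "SheetBase", "PropellerBase", "CoilBase", "DisorderSpec", "HBondState",
    "EnsembleSpec", "GroundTruth", "SheetInfo", "PropellerInfo",
    "make_sheet", "make_propeller", "make_coil", "make_ensemble",
    "make_mutant_pair", "make_benchmark", "apply_dihedral_kicks",
]

_RESIDUE_ATOM_ORDER = ("N", "CA", "C", "O", "CB")
_STRAND_GAP = 5  # numbering gap between strands; also a chain break


# ---------------------------------------------------------------------------
# base specifications

@dataclass
class SheetBase:
    n_strands: int = 4
    strand_len: int = 6
    origin: int = 1


@dataclass
class PropellerBase:
    n_blades: int = 6
    strands_per_blade: int = 4
    strand_len: int = 6
    radius: float = 28.0
    origin: int = 1


@dataclass
class CoilBase:
    n_res: int = 20
    origin: int = 1


@dataclass
class DisorderSpec:
    """Persistent phi/psi disorder over an inclusive residue range.

    ``magnitude`` is the standard deviation (degrees) of the Gaussian
    torsion kicks drawn once per ensemble."""
    start: int
    end: int
    magnitude: float


@dataclass
class HBondState:
    """Two-state toggling of one donor/acceptor pair: in each frame the bond
    is intact with probability ``p_bound``; otherwise the acceptor atom is
    displaced beyond any geometric criterion."""
    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    p_bound: float

    def __post_init__(self):
        if not 0.0 <= self.p_bound <= 1.0:
            raise ValueError("p_bound must lie in [0, 1]")


@dataclass
class EnsembleSpec:
    base: SheetBase | PropellerBase | CoilBase
    jitter_sigma: float = 0.25  # A per coordinate
    n_frames: int = 40
    disorder: list[DisorderSpec] = field(default_factory=list)
    hbond_states: list[HBondState] = field(default_factory=list)
    rigid_motion: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Record of everything the generator injected."""
    spec: dict
    kicks: dict[int, tuple[float, float]] = field(default_factory=dict)
    hbond_bound_fraction: dict[str, float] = field(default_factory=dict)
    designed_delta_sa_beta: float | None = None
    true_label: str | None = None

    def to_json(self) -> str:
        payload = dict(self.spec)
        payload["kicks"] = {str(k): list(v) for k, v in self.kicks.items()}
        payload["hbond_bound_fraction"] = self.hbond_bound_fraction
        payload["designed_delta_sa_beta"] = self.designed_delta_sa_beta
        payload["true_label"] = self.true_label
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# rigid-transform helpers

def _compose(r2, t2, r1, t1):
    return r2 @ r1, r2 @ t1 + t2

def _power(r, t, k):
    rr, tr = np.eye(3), np.zeros(3)
    rb, tb = (r, t) if k >= 0 else (r.T, -r.T @ t)
    for _ in range(abs(k)):
        rr, tr = _compose(rb, tb, rr, tr)
    return rr, tr


def _structure_from_blocks(blocks, chain_id="A", residue_name="ALA"):
    """blocks: list of (start_residue_index, (5*L, 3) strand coords)."""
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    atoms = []
    for start, coords in blocks:
        n_res = coords.shape[0] // 5
        for i in range(n_res):
            res = coords[5 * i:5 * i + 5]  # N, CA, CB, C, O layout
            by_name = {"N": res[0], "CA": res[1], "CB": res[2],
                       "C": res[3], "O": res[4]}
            for name in _RESIDUE_ATOM_ORDER:
                atoms.append(Atom(name=name, element=elements[name],
                                  residue_index=start + i,
                                  residue_name=residue_name,
                                  chain_id=chain_id,
                                  position=by_name[name]))
    return Structure(atoms)


@dataclass
class SheetInfo:
    strand_ranges: list[tuple[int, int]]
    designed_pairs: list[tuple[tuple[int, int, int], tuple[int, int, int]]]


@dataclass
class PropellerInfo:
    scheme: BladeScheme
    blade_strand_ranges: dict[str, list[tuple[int, int]]]
    designed_pairs: list[tuple[tuple[int, int, int], tuple[int, int, int]]]


def _sheet_blocks(n_strands: int, strand_len: int, origin: int):
    """Tile ideal strands into an anti-parallel sheet.

    Strand k is the k-th power of the composed transform
    (anti-parallel flip) o (screw^(3 - L)); with that stagger the
    in-registry fragment pairs of adjacent strands reproduce the scoring
    template exactly (odd local offsets i, partner offset L - 1 - i).
    """
    if n_strands < 2 or strand_len < 3:
        raise ValueError("need n_strands >= 2 and strand_len >= 3")
    L = strand_len
    strand = _strand_atoms(_peptide.build_beta_strand(L), L)
    rs, ts = strand_screw_transform()
    rf, tf = antiparallel_neighbor_transform()
    rsp, tsp = _power(rs, ts, 3 - L)
    ru, tu = _compose(rf, tf, rsp, tsp)
    blocks, ranges = [], []
    rk, tk = np.eye(3), np.zeros(3)
    for k in range(n_strands):
        start = origin + k * (L + _STRAND_GAP)
        blocks.append((start, strand @ rk.T + tk))
        ranges.append((start, start + L - 1))
        rk, tk = _compose(ru, tu, rk, tk)
    pairs = []
    for k in range(n_strands - 1):
        sa, sb = ranges[k][0], ranges[k + 1][0]
        for i in range(1, L - 1, 2):  # 1-based odd offsets
            j = L - 1 - i
            if j < 1 or j + 2 > L:
                continue
            ta = tuple(sa + i - 1 + d for d in range(3))
            tb = tuple(sb + j - 1 + d for d in range(3))
            pairs.append((ta, tb))
    return blocks, SheetInfo(strand_ranges=ranges, designed_pairs=pairs)


def make_sheet(n_strands: int, strand_len: int, origin: int = 1
               ) -> tuple[Structure, SheetInfo]:
    """An ideal anti-parallel sheet with full backbone (N, CA, C, O, CB).

    Residues are numbered sequentially within each strand from ``origin``,
    with a numbering gap between strands acting as a chain break.
    ``SheetInfo.designed_pairs`` lists the in-registry fragment pairs that
    match the scoring template exactly.
    """
    blocks, info = _sheet_blocks(n_strands, strand_len, origin)
    return _structure_from_blocks(blocks), info


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def make_propeller(n_blades: int = 6, strands_per_blade: int = 4,
                   strand_len: int = 6, radius: float = 28.0,
                   origin: int = 1) -> tuple[Structure, PropellerInfo]:
    """A stylized beta-propeller: a ring of anti-parallel sheets.

    This mimics the topology of a propeller domain (blades of anti-parallel
    strands arranged around an axis), not the geometry of any particular
    protein.  Each blade occupies its own residue-number block so a
    :class:`BladeScheme` over the result is well defined.
    """
    L = strand_len
    blade_span = strands_per_blade * (L + _STRAND_GAP)
    blade_gap = 2 * _STRAND_GAP
    all_blocks = []
    names = []
    ranges: dict[str, list[tuple[int, int]]] = {}
    strand_ranges: dict[str, list[tuple[int, int]]] = {}
    for b in range(n_blades):
        start = origin + b * (blade_span + blade_gap)
        blocks, info = _sheet_blocks(strands_per_blade, L, start)
        coords = np.vstack([c for _, c in blocks])
        center = coords.mean(axis=0)
        theta = 2.0 * np.pi * b / n_blades
        rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                        [np.sin(theta), np.cos(theta), 0.0],
                        [0.0, 0.0, 1.0]])
        shift = radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        placed = [(s, (c - center) @ rot.T + shift) for s, c in blocks]
        all_blocks.extend(placed)
        name = _ROMAN[b]
        names.append(name)
        ranges[name] = list(info.strand_ranges)
        strand_ranges[name] = info.strand_ranges
    structure = _structure_from_blocks(all_blocks)
    pairs = []
    for name in names:
        srs = strand_ranges[name]
        for k in range(len(srs) - 1):
            sa, sb = srs[k][0], srs[k + 1][0]
            for i in range(1, L - 1, 2):
                j = L - 1 - i
                if j < 1 or j + 2 > L:
                    continue
                pairs.append((tuple(sa + i - 1 + d for d in range(3)),
                              tuple(sb + j - 1 + d for d in range(3))))
    scheme = BladeScheme(names=names, ranges=ranges)
    return structure, PropellerInfo(scheme=scheme,
                                    blade_strand_ranges=strand_ranges,
                                    designed_pairs=pairs)


def make_coil(n_res: int, rng: np.random.Generator, origin: int = 1) -> Structure:
    """A random coil: uniform phi/psi torsions."""
    phi = rng.uniform(-180.0, 180.0, n_res)
    psi = rng.uniform(-180.0, 180.0, n_res)
    bb = _peptide.build_backbone(phi, psi)
    coords = _strand_atoms(bb, n_res)
    return _structure_from_blocks([(origin, coords)])


# ---------------------------------------------------------------------------
# dihedral perturbation by internal-coordinate rebuild

def _rotate_about(points, p0, axis, angle_deg):
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = axis
    v = points - p0
    return (v * np.cos(a)
            + np.cross(k, v) * np.sin(a)
            + np.outer(v @ k, k) * (1.0 - np.cos(a))) + p0


def _contiguous_runs(structure: Structure):
    runs = []
    cur = []
    for key in structure.residues:
        if cur and (key[0] != cur[-1][0] or key[1] != cur[-1][1] + 1):
            runs.append(cur)
            cur = []
        cur.append(key)
    if cur:
        runs.append(cur)
    return runs


def apply_dihedral_kicks(structure: Structure, coords: np.ndarray,
                         kicks: dict[int, tuple[float, float]]) -> np.ndarray:
    """Apply phi/psi kicks (degrees) and propagate downstream.

    Rotating about N-CA (phi) carries the residue's CB, C, O and every later
    residue of the contiguous run; rotating about CA-C (psi) carries the
    later residues.  Numbering gaps bound the propagation.
    """
    coords = np.array(coords, dtype=float)
    runs = _contiguous_runs(structure)
    for run in runs:
        run_resis = [r for _, r in run]
        chain = run[0][0]
        for pos, resi in enumerate(run_resis):
            if resi not in kicks:
                continue
            dphi, dpsi = kicks[resi]
            idx = lambda r, n: structure.atom_index(chain, r, n)
            downstream = []
            for later in run_resis[pos + 1:]:
                downstream.extend(structure.residue_atom_indices(chain, later))
            if dphi:
                moving = [idx(resi, n) for n in ("CB", "C", "O")
                          if structure.has_atom(chain, resi, n)] + downstream
                n_pos, ca_pos = coords[idx(resi, "N")], coords[idx(resi, "CA")]
                coords[moving] = _rotate_about(coords[moving], ca_pos,
                                               ca_pos - n_pos, dphi)
            if dpsi and downstream:
                ca_pos, c_pos = coords[idx(resi, "CA")], coords[idx(resi, "C")]
                coords[downstream] = _rotate_about(coords[downstream], c_pos,
                                                   c_pos - ca_pos, dpsi)
    return coords


# ---------------------------------------------------------------------------
# ensemble generation

def _build_base(spec: EnsembleSpec, rng: np.random.Generator):
    base = spec.base
    if isinstance(base, SheetBase):
        structure, info = make_sheet(base.n_strands, base.strand_len, base.origin)
    elif isinstance(base, PropellerBase):
        structure, info = make_propeller(base.n_blades, base.strands_per_blade,
                                         base.strand_len, base.radius, base.origin)
    elif isinstance(base, CoilBase):
        structure, info = make_coil(base.n_res, rng, base.origin), None
    else:
        raise TypeError(f"unknown base spec {type(base).__name__}")
    return structure, info


def make_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, GroundTruth]:
    """Generate an ensemble and its ground-truth record from a spec."""
    seq = np.random.SeedSequence(spec.seed)
    rng_base, rng_kick, rng_frames = (np.random.default_rng(s)
                                      for s in seq.spawn(3))
    structure, _info = _build_base(spec, rng_base)
    resis = {r for _, r in structure.residues}
    kicks: dict[int, tuple[float, float]] = {}
    for dis in spec.disorder:
        span = set(range(dis.start, dis.end + 1))
        if not span <= resis:
            raise ValueError(
                f"disorder range {dis.start}-{dis.end} outside base residues")
        for r in sorted(span):
            dphi, dpsi = dis.magnitude * rng_kick.standard_normal(2)
            kicks[r] = (float(dphi), float(dpsi))
    base_coords = structure.coords
    if kicks:
        base_coords = apply_dihedral_kicks(structure, base_coords, kicks)
    hb_index = []
    for hb in spec.hbond_states:
        di = structure.atom_index(*hb.donor)
        ai = structure.atom_index(*hb.acceptor)
        hb_index.append((hb, di, ai))
    bound_counts = {i: 0 for i in range(len(hb_index))}
    frames = []
    for _t in range(spec.n_frames):
        coords = base_coords + rng_frames.normal(
            scale=spec.jitter_sigma, size=base_coords.shape)
        for i, (hb, di, ai) in enumerate(hb_index):
            if rng_frames.random() < hb.p_bound:
                bound_counts[i] += 1
            else:
                direction = coords[ai] - coords[di]
                direction = direction / np.linalg.norm(direction)
                coords[ai] = coords[ai] + 3.0 * direction
        if spec.rigid_motion:
            q = rng_frames.standard_normal(4)
            q = q / np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            coords = coords @ rot.T + rng_frames.uniform(-20.0, 20.0, 3)
        frames.append(coords)
    truth = GroundTruth(
        spec={"base": {"kind": type(spec.base).__name__, **asdict(spec.base)},
              "jitter_sigma": spec.jitter_sigma, "n_frames": spec.n_frames,
              "rigid_motion": spec.rigid_motion, "seed": spec.seed,
              "disorder": [asdict(d) for d in spec.disorder],
              "hbond_states": [asdict(h) for h in spec.hbond_states]},
        kicks=kicks,
        hbond_bound_fraction={
            f"{hb.donor}->{hb.acceptor}": bound_counts[i] / spec.n_frames
            for i, (hb, _d, _a) in enumerate(hb_index)},
    )
    return Ensemble(topology=structure, frames=frames), truth


# ---------------------------------------------------------------------------
# wild-type / mutant contrast pairs

_LEVELS = ("neutral", "moderate", "destabilizing")
_LEVEL_TARGET = {"moderate": -1.5, "destabilizing": -4.0}
_LEVEL_LABEL = {"neutral": "neutral/stabilizing",
                "moderate": "inconclusive",
                "destabilizing": "destabilizing"}


@dataclass
class MutantPair:
    wildtype: Ensemble
    mutant: Ensemble
    true_label: str
    truth: GroundTruth
    info: PropellerInfo
    probe_residue: int


def _calibrate_magnitude(structure: Structure, pair_set, window,
                         target: float, kick_seed: int,
                         jitter_sigma: float = 0.25) -> float:
    """Bisect the disorder magnitude so that the expected ensemble change in
    Sa-beta hits the designed target (deterministic given the seed).

    The expectation is taken over a few fixed thermal-jitter draws, because
    jitter depresses partially disordered fragment pairs more than intact
    ones and would otherwise bias the achieved drop past the design value.
    """
    rng = np.random.default_rng(kick_seed)
    units = {r: tuple(rng.standard_normal(2)) for r in range(window[0], window[1] + 1)}
    base = structure.coords
    jitters = [rng.normal(scale=jitter_sigma, size=base.shape) for _ in range(3)]
    refs = [sa_beta(base + j, pair_set).total for j in jitters]

    def delta(mag: float) -> float:
        kicks = {r: (mag * u[0], mag * u[1]) for r, u in units.items()}
        coords = apply_dihedral_kicks(structure, base, kicks)
        devs = [sa_beta(coords + j, pair_set).total - ref
                for j, ref in zip(jitters, refs)]
        return float(np.mean(devs))

    lo, hi = 0.0, 160.0
    if delta(hi) > target:  # even the largest kick does not reach the target
        return hi
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if delta(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_mutant_pair(level: str, seed: int,
                     n_frames: int = 40, jitter_sigma: float = 0.25,
                     blade_index: int = 1, strand_index: int = 1) -> MutantPair:
    """A wild-type/mutant ensemble pair with a known stability contrast.

    ``neutral`` re-generates the same conditions under a different seed;
    ``moderate`` injects persistent disorder calibrated to a designed
    Sa-beta drop between -2 and -1 (an inconclusive call by design);
    ``destabilizing`` calibrates the drop to -4, well past the
    destabilizing boundary.  The disorder window is one strand of one blade.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    seq = np.random.SeedSequence([seed, _LEVELS.index(level)])
    wt_seed, mut_seed, kick_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                    for s in seq.spawn(3))
    base = PropellerBase()
    structure, info = make_propeller(base.n_blades, base.strands_per_blade,
                                     base.strand_len, base.radius, base.origin)
    blade = info.scheme.names[blade_index]
    window = info.blade_strand_ranges[blade][strand_index]
    wt, _wt_truth = make_ensemble(EnsembleSpec(
        base=base, jitter_sigma=jitter_sigma, n_frames=n_frames, seed=wt_seed))
    disorder = []
    designed = None
    if level != "neutral":
        pair_set = enumerate_segment_pairs(structure)
        magnitude = _calibrate_magnitude(structure, pair_set, window,
                                         _LEVEL_TARGET[level], kick_seed,
                                         jitter_sigma)
        disorder = [DisorderSpec(start=window[0], end=window[1],
                                 magnitude=magnitude)]
        designed = _LEVEL_TARGET[level]
    mut_spec = EnsembleSpec(base=base, jitter_sigma=jitter_sigma,
                            n_frames=n_frames, disorder=disorder, seed=mut_seed)
    # the mutant's persistent kicks must be the calibrated ones
    if disorder:
        mut, truth = _make_ensemble_with_kicks(mut_spec, kick_seed)
    else:
        mut, truth = make_ensemble(mut_spec)
    truth.designed_delta_sa_beta = designed
    truth.true_label = _LEVEL_LABEL[level]
    probe = (window[0] + window[1]) // 2
    return MutantPair(wildtype=wt, mutant=mut, true_label=truth.true_label,
                      truth=truth, info=info, probe_residue=probe)


def _make_ensemble_with_kicks(spec: EnsembleSpec, kick_seed: int):
    """As :func:`make_ensemble` but with the kick draws taken from an
    explicit seed so a calibrated magnitude reproduces its designed drop."""
    seq = np.random.SeedSequence(spec.seed)
    rng_base, _rng_kick, rng_frames = (np.random.default_rng(s)
                                       for s in seq.spawn(3))
    structure, _info = _build_base(spec, rng_base)
    rng = np.random.default_rng(kick_seed)
    kicks: dict[int, tuple[float, float]] = {}
    for dis in spec.disorder:
        for r in range(dis.start, dis.end + 1):
            dphi, dpsi = dis.magnitude * rng.standard_normal(2)
            kicks[r] = (float(dphi), float(dpsi))
    base_coords = apply_dihedral_kicks(structure, structure.coords, kicks)
    frames = [base_coords + rng_frames.normal(scale=spec.jitter_sigma,
                                              size=base_coords.shape)
              for _ in range(spec.n_frames)]
    truth = GroundTruth(
        spec={"base": {"kind": type(spec.base).__name__, **asdict(spec.base)},
              "jitter_sigma": spec.jitter_sigma, "n_frames": spec.n_frames,
              "rigid_motion": spec.rigid_motion, "seed": spec.seed,
              "disorder": [asdict(d) for d in spec.disorder],
              "hbond_states": []},
        kicks=kicks)
    return Ensemble(topology=structure, frames=frames), truth


def make_benchmark(seed: int = 0, n_pairs: int = 10,
                   n_frames: int = 40) -> list[MutantPair]:
    """The packaged classification benchmark: half destabilizing, half
    neutral wild-type/mutant pairs, disorder windows rotating through the
    blades."""
    pairs = []
    for i in range(n_pairs):
        level = "destabilizing" if i % 2 == 0 else "neutral"
        pairs.append(make_mutant_pair(level, seed=seed * 1000 + i,
                                      n_frames=n_frames,
                                      blade_index=i % 6,
                                      strand_index=1 + (i % 2)))
    return pairs
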