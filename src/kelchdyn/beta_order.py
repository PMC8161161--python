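"""The anti-parallel beta-sheet order parameter Sa-beta.

Sa-beta scores how much anti-parallel beta structure a conformation carries.
Every pair of three-residue backbone fragments that is sufficiently separated
in sequence is compared, as a 30-atom rigid body (N, CA, CB, C, O per
residue), with an ideal two-strand anti-parallel template.  The fragment-pair
RMSD r (in nm, after optimal superposition) is mapped through the rational
switching function

    s(r) = (1 - x^n) / (1 - x^m),    x = (r - d0) / r0,

with defaults r0 = 0.08 nm, n = 8, m = 12, d0 = 0 (the switching-function
parameters of the collective variable this order parameter originates
from), and the scores are summed:
a fully sheeted structure scores near N (the number of pairs), a disordered
one near zero.  The per-segment scores are also attributed equally to each
pair's six residues, giving a per-residue decomposition whose blade averages
localise order changes within a beta-propeller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.optimize import least_squares

from . import _peptide
from .geometry import block_stats, kabsch_superpose
from .structure_io import (BackboneSelection, BladeScheme, Ensemble,
                           Structure, backbone_selection)

__all__ = [
    "SaBetaParams", "SegmentPair", "SegmentPairSet", "SaBetaResult",
    "SaBetaSeries", "ideal_antiparallel_template", "strand_screw_transform",
    "antiparallel_neighbor_transform", "enumerate_segment_pairs",
    "pairs_from_triples", "switching_score", "sa_beta", "sa_beta_series",
    "delta_sa_beta",
]

ANGSTROM_PER_NM = 10.0
HBOND_NO_TARGET = 2.9  # A, canonical inter-strand N...O distance


@dataclass
class SaBetaParams:
    """Switching-function and enumeration parameters.

    r0 (nm) sets the RMSD scale of the switch, n < m its steepness, d0 (nm)
    the offset inside the switch; ``min_sequence_separation`` (residues) is
    the minimum gap between the two fragments of a scored pair.

    The default r0 = 0.08 nm is the original collective-variable default:
    a fragment pair within ~0.8 A of the ideal template scores near one,
    and a disordered pair scores near zero, which is what makes the total
    discriminate sheeted from disordered conformations.
    """
    r0: float = 0.08
    n: int = 8
    m: int = 12
    d0: float = 0.0
    min_sequence_separation: int = 5

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (self.m > self.n > 0):
            raise ValueError("exponents must satisfy m > n > 0")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SaBetaParams":
        return cls(**json.loads(text))


@dataclass
class SegmentPair:
    """Two three-residue fragments scored as one 30-atom unit.

    ``atom_indices`` index into the sheet-backbone coordinate layout of the
    owning :class:`SegmentPairSet` (5 atoms per residue, fragment a then
    fragment b)."""
    fragment_a: tuple[int, int, int]
    fragment_b: tuple[int, int, int]
    atom_indices: np.ndarray

    @property
    def residues(self) -> tuple[int, ...]:
        return self.fragment_a + self.fragment_b


@dataclass
class SegmentPairSet:
    """All scored fragment pairs of a structure plus the backbone selection
    used to extract their coordinates from a frame."""
    structure: Structure
    selection: BackboneSelection
    pairs: list[SegmentPair]
    params: SaBetaParams

    def __len__(self) -> int:
        return len(self.pairs)

    def gather(self, frame_coords: np.ndarray) -> np.ndarray:
        """(n_pairs, 30, 3) fragment-pair coordinates for one frame."""
        sheet = self.selection.extract(frame_coords)
        idx = np.stack([p.atom_indices for p in self.pairs])
        return sheet[idx]


@dataclass
class SaBetaResult:
    """Sa-beta of a single frame: total, per-segment scores in (0, 1], and
    the equal-attribution per-residue decomposition (sums to the total)."""
    total: float
    per_segment: np.ndarray
    per_residue: dict[int, float]
    n_segments: int
    pairs: SegmentPairSet | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# ideal template

_TEMPLATE_CACHE: dict[str, np.ndarray] = {}


def _strand_atoms(bb: dict[str, np.ndarray], n_res: int) -> np.ndarray:
    """Stack builder output as (n_res*5, 3) in N, CA, CB, C, O order."""
    rows = []
    for i in range(n_res):
        for name in ("N", "CA", "CB", "C", "O"):
            rows.append(bb[name][i])
    return np.asarray(rows)


def strand_screw_transform() -> tuple[np.ndarray, np.ndarray]:
    """Exact rigid screw mapping residue i of an ideal strand onto residue
    i+1 (constant torsions make the strand exactly screw-periodic)."""
    bb = _peptide.build_beta_strand(4)
    a = _strand_atoms(bb, 4)
    sup = kabsch_superpose(a[0:15], a[5:20])
    return sup.rotation, sup.translation


def antiparallel_neighbor_transform() -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform placing the anti-parallel partner strand.

    The partner is a 180-degree flip of the strand about the axis normal to
    the pleat, translated so that the two canonical inter-strand hydrogen
    bonds of the central residue pair measure 2.9 A (N...O) and the
    end-to-end registry is symmetric.  The translation is solved
    deterministically with a least-squares root find.
    """
    bb = _peptide.build_beta_strand(3)
    ca = bb["CA"]
    axis = ca[2] - ca[0]
    axis = axis / np.linalg.norm(axis)
    # the central carbonyl points along the hydrogen-bonding (lateral)
    # direction; the sheet normal is perpendicular to both
    co = bb["O"][1] - bb["C"][1]
    lateral = co - (co @ axis) * axis
    lateral = lateral / np.linalg.norm(lateral)
    normal = np.cross(axis, lateral)
    normal = normal / np.linalg.norm(normal)
    flip = 2.0 * np.outer(normal, normal) - np.eye(3)  # 180 deg about normal
    t0 = ca[1] + 5.3 * lateral - flip @ ca[1]

    def residuals(t):
        n_b = bb["N"] @ flip.T + t
        o_b = bb["O"] @ flip.T + t
        ca_b = bb["CA"] @ flip.T + t
        return np.array([
            np.linalg.norm(bb["N"][1] - o_b[1]) - HBOND_NO_TARGET,
            np.linalg.norm(bb["O"][1] - n_b[1]) - HBOND_NO_TARGET,
            np.linalg.norm(ca[0] - ca_b[2]) - np.linalg.norm(ca[2] - ca_b[0]),
        ])

    sol = least_squares(residuals, t0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return flip, sol.x


def ideal_antiparallel_template() -> np.ndarray:
    """30-atom ideal anti-parallel two-strand template (A).

    Two three-residue strands at canonical beta torsions (phi = -139,
    psi = +135, trans omega), the second strand anti-parallel with the
    central residue pair doubly hydrogen bonded at N...O = 2.9 A.  Atom
    order is strand A residues 1-3 then strand B residues 1-3, five atoms
    (N, CA, CB, C, O) per residue.  The construction is deterministic.
    """
    if "template" not in _TEMPLATE_CACHE:
        bb = _peptide.build_beta_strand(3)
        a = _strand_atoms(bb, 3)
        rot, trans = antiparallel_neighbor_transform()
        b = a @ rot.T + trans
        _TEMPLATE_CACHE["template"] = np.vstack([a, b])
    return _TEMPLATE_CACHE["template"].copy()


# ---------------------------------------------------------------------------
# fragment enumeration

def _fragment_triples(structure: Structure) -> list[tuple[str, tuple[int, int, int]]]:
    """All (chain, (i, i+1, i+2)) triples of consecutively numbered residues;
    numbering gaps are treated as chain breaks and never spanned."""
    triples = []
    residues = structure.residues
    for k in range(len(residues) - 2):
        (c0, r0), (c1, r1), (c2, r2) = residues[k], residues[k + 1], residues[k + 2]
        if c0 == c1 == c2 and r1 == r0 + 1 and r2 == r0 + 2:
            triples.append((c0, (r0, r1, r2)))
    return triples


def _pair_from_triples(selection: BackboneSelection,
                       pos_of: dict[tuple[str, int], int],
                       chain_a: str, tri_a: tuple[int, int, int],
                       chain_b: str, tri_b: tuple[int, int, int]) -> SegmentPair:
    idx = []
    for chain, tri in ((chain_a, tri_a), (chain_b, tri_b)):
        for r in tri:
            p = pos_of[(chain, r)]
            idx.extend(range(5 * p, 5 * p + 5))
    return SegmentPair(fragment_a=tuple(tri_a), fragment_b=tuple(tri_b),
                       atom_indices=np.asarray(idx, dtype=int))


def enumerate_segment_pairs(structure: Structure,
                            params: SaBetaParams | None = None,
                            residue_subset=None) -> SegmentPairSet:
    """Enumerate all scored fragment pairs of a structure.

    Fragments are triples of consecutively numbered residues in one chain;
    ordered pairs (a before b) are kept when the sequence gap between the
    end of a and the start of b is at least ``min_sequence_separation``.
    ``residue_subset`` (iterable of residue indices) restricts both
    fragments to lie wholly inside the subset.
    """
    params = params or SaBetaParams()
    selection = backbone_selection(structure, "sheet-backbone")
    pos_of = {key: i for i, key in enumerate(selection.residues)}
    subset = None if residue_subset is None else set(residue_subset)
    triples = _fragment_triples(structure)
    if subset is not None:
        triples = [(c, t) for c, t in triples if all(r in subset for r in t)]
    pairs = []
    for ia, (ca_chain, ta) in enumerate(triples):
        for cb_chain, tb in triples[ia + 1:]:
            if ca_chain != cb_chain:
                continue
            if tb[0] - ta[2] < params.min_sequence_separation:
                continue
            pairs.append(_pair_from_triples(selection, pos_of,
                                            ca_chain, ta, cb_chain, tb))
    return SegmentPairSet(structure=structure, selection=selection,
                          pairs=pairs, params=params)


def pairs_from_triples(structure: Structure,
                       triples: list[tuple[tuple[int, int, int], tuple[int, int, int]]],
                       params: SaBetaParams | None = None,
                       chain_id: str = "A") -> SegmentPairSet:
    """Build a pair set from explicit residue-index triples (e.g. the
    designed in-registry pairs of a synthetic sheet)."""
    params = params or SaBetaParams()
    selection = backbone_selection(structure, "sheet-backbone")
    pos_of = {key: i for i, key in enumerate(selection.residues)}
    pairs = [_pair_from_triples(selection, pos_of, chain_id, ta, chain_id, tb)
             for ta, tb in triples]
    return SegmentPairSet(structure=structure, selection=selection,
                          pairs=pairs, params=params)


# ---------------------------------------------------------------------------
# scoring

def switching_score(r, params: SaBetaParams | None = None):
    """Rational switching function of a fragment RMSD (nm).

    Evaluated in the geometric-series form
    ``sum_{k<n} x^k / sum_{k<m} x^k`` which is exact for all x >= 0 and
    continuous through the removable singularity at x = 1 (value n/m).
    x is clamped at 0 for r < d0, so s(d0) = 1; s decreases strictly to 0.
    """
    params = params or SaBetaParams()
    r = np.asarray(r, dtype=float)
    x = np.clip((r - params.d0) / params.r0, 0.0, None)
    powers = x[..., None] ** np.arange(params.m)
    num = powers[..., :params.n].sum(axis=-1)
    den = powers.sum(axis=-1)
    out = num / den
    return float(out) if out.ndim == 0 else out


def _fragment_rmsds(coords: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Batched optimal-superposition RMSD (A) of (n_pairs, 30, 3) coordinate
    blocks against one template, via the SVD singular-value identity."""
    tc = template - template.mean(axis=0)
    t_ss = float((tc * tc).sum())
    pc = coords - coords.mean(axis=1, keepdims=True)
    p_ss = (pc * pc).sum(axis=(1, 2))
    h = np.einsum("pni,nj->pij", pc, tc)
    s = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    trace = s[:, 0] + s[:, 1] + np.where(det < 0, -s[:, 2], s[:, 2])
    ssd = np.maximum(p_ss + t_ss - 2.0 * trace, 0.0)
    return np.sqrt(ssd / coords.shape[1])


def sa_beta(frame_coords: np.ndarray, pair_set: SegmentPairSet,
            template: np.ndarray | None = None,
            params: SaBetaParams | None = None) -> SaBetaResult:
    """Sa-beta of a single frame over a fixed pair set."""
    if len(pair_set) == 0:
        raise ValueError("pair set is empty")
    params = params or pair_set.params
    if template is None:
        template = ideal_antiparallel_template()
    coords = pair_set.gather(np.asarray(frame_coords, dtype=float))
    rmsd_nm = _fragment_rmsds(coords, template) / ANGSTROM_PER_NM
    scores = switching_score(rmsd_nm, params)
    per_residue: dict[int, float] = {}
    for pair, score in zip(pair_set.pairs, scores):
        share = score / 6.0
        for r in pair.residues:
            per_residue[r] = per_residue.get(r, 0.0) + share
    return SaBetaResult(total=float(scores.sum()), per_segment=scores,
                        per_residue=per_residue, n_segments=len(pair_set),
                        pairs=pair_set)


@dataclass
class SaBetaSeries:
    """Per-frame Sa-beta over an ensemble with optional blade decomposition."""
    totals: np.ndarray
    n_segments: int
    stats: "object"
    per_residue_mean: dict[int, float]
    blade_series: dict[str, np.ndarray] | None = None
    blade_stats: dict[str, "object"] | None = None


def sa_beta_series(ensemble: Ensemble, pair_set: SegmentPairSet | None = None,
                   scheme: BladeScheme | None = None,
                   params: SaBetaParams | None = None,
                   n_blocks: int = 5) -> SaBetaSeries:
    """Sa-beta along an ensemble.

    When a blade scheme is given, the per-residue attribution is averaged
    over each blade per frame (the per-residue blade value: blade residue
    sum divided by blade size).  Means and standard deviations are block
    averaged.
    """
    params = params or SaBetaParams()
    if pair_set is None:
        pair_set = enumerate_segment_pairs(ensemble.topology, params)
    template = ideal_antiparallel_template()
    n_pairs = len(pair_set)
    if n_pairs == 0:
        raise ValueError("pair set is empty")
    score_mat = np.empty((ensemble.n_frames, n_pairs))
    for t, frame in enumerate(ensemble.frames):
        coords = pair_set.gather(frame)
        rmsd_nm = _fragment_rmsds(coords, template) / ANGSTROM_PER_NM
        score_mat[t] = switching_score(rmsd_nm, params)
    totals = score_mat.sum(axis=1)
    mean_scores = score_mat.mean(axis=0)
    per_residue_mean: dict[int, float] = {}
    for pair, score in zip(pair_set.pairs, mean_scores):
        for r in pair.residues:
            per_residue_mean[r] = per_residue_mean.get(r, 0.0) + score / 6.0
    blade_series = None
    blade_st = None
    if scheme is not None:
        weights = np.zeros((n_pairs, len(scheme.names)))
        for j, name in enumerate(scheme.names):
            members = set(scheme.residues(name))
            size = scheme.size(name)
            for i, pair in enumerate(pair_set.pairs):
                inside = sum(1 for r in pair.residues if r in members)
                if inside:
                    weights[i, j] = inside / 6.0 / size
        series = score_mat @ weights
        blade_series = {name: series[:, j] for j, name in enumerate(scheme.names)}
        blade_st = {name: block_stats(blade_series[name], n_blocks)
                    for name in scheme.names}
    return SaBetaSeries(totals=totals, n_segments=n_pairs,
                        stats=block_stats(totals, n_blocks),
                        per_residue_mean=per_residue_mean,
                        blade_series=blade_series, blade_stats=blade_st)


def delta_sa_beta(mutant_series: np.ndarray, wildtype_series: np.ndarray,
                  n_blocks: int = 5) -> tuple[float, float]:
    """Change in Sa-beta of a mutant relative to the wild type.

    Returns (delta, sigma): the difference of block means and the
    quadrature sum of the two block standard deviations.
    """
    ms = block_stats(np.asarray(mutant_series, dtype=float), n_blocks)
    ws = block_stats(np.asarray(wildtype_series, dtype=float), n_blocks)
    return ms.mean - ws.mean, float(np.hypot(ms.std, ws.std))
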