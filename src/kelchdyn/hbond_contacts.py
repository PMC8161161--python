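"""Hydrogen-bond detection, occupancy and network differencing; contact maps.

Detection is geometric.  The primary criterion is the donor-heavy-atom to
acceptor distance (default 3.5 A) between N/O atoms of different residues;
a D-H-A angle criterion (default 150 degrees) applies only when the
topology actually carries hydrogens, since analysis structures usually do
not.  "Lifetime" (the occupancy of a bond) is the fraction of ensemble
frames in which the criterion holds — a percentage of the sampled
trajectory, not a continuous dwell time.

Network differencing matches bonds between wild type and mutant on
(chain, residue index, atom name) of both partners, so bonds lost with a
mutated side chain appear with the full negative wild-type occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Ensemble, Structure

__all__ = [
    "HBondCriteria", "HBondRecord", "NetworkDiff", "detect_hbonds",
    "hbond_occupancy", "network_diff", "contact_map",
]

logger = logging.getLogger("kelchdyn")

_MAIN_CHAIN_POLAR = {"N", "O", "OXT"}

AtomKey = tuple[str, int, str]  # (chain, residue index, atom name)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``da_cutoff``: donor-heavy-atom to acceptor distance, A.
    ``angle_cutoff``: minimum D-H-A angle in degrees, applied only when the
    donor has a bound hydrogen in the topology.
    ``classes``: which main/side-chain pairings to keep (mm, ms, ss).
    """
    da_cutoff: float = 3.5
    angle_cutoff: float = 150.0
    classes: frozenset = frozenset({"mm", "ms", "ss"})

    def __post_init__(self):
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle_cutoff must lie in (0, 180]")


@dataclass
class HBondRecord:
    """A donor/acceptor pair with its occupancy over an ensemble."""
    donor: AtomKey
    acceptor: AtomKey
    occupancy: float
    pair_class: str = "mm"

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")


@dataclass
class NetworkDiff:
    """Wild-type vs mutant occupancy differences, in percent of trajectory.

    ``bonds`` rows are (donor, acceptor, class, wt %, mut %, delta %),
    delta = mut - wt exactly; a bond absent from one state contributes 0%."""
    bonds: list[tuple] = field(default_factory=list)


def _pair_class(donor_name: str, acceptor_name: str) -> str:
    d_main = donor_name in _MAIN_CHAIN_POLAR
    a_main = acceptor_name in _MAIN_CHAIN_POLAR
    if d_main and a_main:
        return "mm"
    if d_main or a_main:
        return "ms"
    return "ss"


def _polar_atoms(structure: Structure) -> list[int]:
    idx = [i for i, a in enumerate(structure.atoms) if a.element in ("N", "O")]
    if not idx and structure.n_atoms:
        if not any(a.element for a in structure.atoms):
            raise ValueError("topology lacks element information")
    return idx


def _hydrogen_map(structure: Structure, coords: np.ndarray,
                  polar: list[int]) -> dict[int, list[int]]:
    """Covalently bound hydrogens per polar heavy atom (empty if the
    structure carries no hydrogens)."""
    hydro = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
    out: dict[int, list[int]] = {}
    if not hydro:
        return out
    hpos = coords[hydro]
    for i in polar:
        d = np.linalg.norm(hpos - coords[i], axis=1)
        att = [hydro[k] for k in np.nonzero(d < 1.25)[0]
               if (structure.atoms[hydro[k]].chain_id,
                   structure.atoms[hydro[k]].residue_index)
               == (structure.atoms[i].chain_id, structure.atoms[i].residue_index)]
        if att:
            out[i] = att
    return out


def _key(structure: Structure, i: int) -> AtomKey:
    a = structure.atoms[i]
    return (a.chain_id, a.residue_index, a.name)


def detect_hbonds(coords: np.ndarray, structure: Structure,
                  criteria: HBondCriteria | None = None
                  ) -> set[tuple[AtomKey, AtomKey]]:
    """Hydrogen bonds of one frame as (donor, acceptor) key pairs.

    All N/O atoms act as potential donors and acceptors; intra-residue
    pairs are excluded.  Without hydrogens each undirected pair is reported
    once, the donor being the lexicographically smaller key.  With
    hydrogens the donor must carry one and the D-H-A angle criterion
    applies.
    """
    criteria = criteria or HBondCriteria()
    coords = np.asarray(coords, dtype=float)
    if any(not a.element for a in structure.atoms):
        raise ValueError("topology lacks element information")
    polar = _polar_atoms(structure)
    hmap = _hydrogen_map(structure, coords, polar)
    has_h = bool(hmap)
    pos = coords[polar]
    tree = cKDTree(pos)
    found: set[tuple[AtomKey, AtomKey]] = set()
    for ia, ib in tree.query_pairs(criteria.da_cutoff):
        i, j = polar[ia], polar[ib]
        ai, aj = structure.atoms[i], structure.atoms[j]
        if (ai.chain_id, ai.residue_index) == (aj.chain_id, aj.residue_index):
            continue
        cls = _pair_class(ai.name, aj.name)
        if cls not in criteria.classes:
            continue
        if not has_h:
            ki, kj = _key(structure, i), _key(structure, j)
            found.add((ki, kj) if ki <= kj else (kj, ki))
            continue
        for d, a in ((i, j), (j, i)):
            if d not in hmap:
                continue
            for h in hmap[d]:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= criteria.angle_cutoff:
                    found.add((_key(structure, d), _key(structure, a)))
                    break
    return found


def hbond_occupancy(ensemble: Ensemble, criteria: HBondCriteria | None = None,
                    min_occupancy: float = 0.0) -> list[HBondRecord]:
    """Per-pair occupancy over an ensemble; pairs below ``min_occupancy``
    are dropped.  Records are sorted by partner keys."""
    criteria = criteria or HBondCriteria()
    logger.debug("hbond criteria: d(D..A) <= %.2f A, angle >= %.0f deg",
                 criteria.da_cutoff, criteria.angle_cutoff)
    counts: dict[tuple[AtomKey, AtomKey], int] = {}
    for frame in ensemble.frames:
        for pair in detect_hbonds(frame, ensemble.topology, criteria):
            counts[pair] = counts.get(pair, 0) + 1
    records = []
    n = ensemble.n_frames
    for (donor, acceptor), c in sorted(counts.items()):
        occ = c / n
        if occ >= min_occupancy:
            records.append(HBondRecord(donor=donor, acceptor=acceptor,
                                       occupancy=occ,
                                       pair_class=_pair_class(donor[2],
                                                              acceptor[2])))
    return records


def network_diff(wt: list[HBondRecord], mut: list[HBondRecord],
                 min_occupancy: float = 0.2) -> NetworkDiff:
    """Occupancy differences over the union of bonds passing
    ``min_occupancy`` in either state, as percentages of the trajectory."""
    wt_map = {(r.donor, r.acceptor): r for r in wt}
    mut_map = {(r.donor, r.acceptor): r for r in mut}
    keys = set()
    for key, r in wt_map.items():
        if r.occupancy >= min_occupancy:
            keys.add(key)
    for key, r in mut_map.items():
        if r.occupancy >= min_occupancy:
            keys.add(key)
    bonds = []
    for key in sorted(keys):
        donor, acceptor = key
        wt_pct = 100.0 * wt_map[key].occupancy if key in wt_map else 0.0
        mut_pct = 100.0 * mut_map[key].occupancy if key in mut_map else 0.0
        cls = (wt_map.get(key) or mut_map[key]).pair_class
        bonds.append((donor, acceptor, cls, wt_pct, mut_pct, mut_pct - wt_pct))
    return NetworkDiff(bonds=bonds)


def contact_map(ensemble: Ensemble, cutoff: float = 4.5,
                selection: list[int] | None = None
                ) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Residue-residue contact frequency matrix.

    Entry (i, j) is the fraction of frames in which the minimum heavy-atom
    distance between residues i and j is below ``cutoff``.  The diagonal
    band |i - j| <= 2 (in residue order) is masked to zero.
    """
    topo = ensemble.topology
    atom_idx = (list(range(topo.n_atoms)) if selection is None
                else list(selection))
    atom_idx = [i for i in atom_idx if topo.atoms[i].element != "H"]
    res_keys = topo.residues
    res_pos = {key: k for k, key in enumerate(res_keys)}
    rid = np.array([res_pos[(topo.atoms[i].chain_id,
                             topo.atoms[i].residue_index)] for i in atom_idx])
    nres = len(res_keys)
    counts = np.zeros((nres, nres))
    flat_rid = rid[:, None] * nres + rid[None, :]
    for frame in ensemble.frames:
        pos = frame[atom_idx]
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        mind = np.full(nres * nres, np.inf)
        np.minimum.at(mind, flat_rid.ravel(), d.ravel())
        counts += (mind.reshape(nres, nres) < cutoff)
    freq = counts / ensemble.n_frames
    ii, jj = np.indices((nres, nres))
    freq[np.abs(ii - jj) <= 2] = 0.0
    freq = np.maximum(freq, freq.T)  # symmetry guard; distances already symmetric
    return freq, res_keys
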