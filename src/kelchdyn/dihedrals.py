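"""Backbone torsions, Ramachandran densities and dihedral-space shifts.

Extracts phi/psi series from ensembles, estimates periodic (wrapped)
Gaussian kernel densities on a fixed 5-degree Ramachandran grid, and
quantifies mutation-induced changes of the sampled dihedral space as the
Jensen-Shannon distance between densities — turning the visual comparison
of Ramachandran plots into a declared numeric shift metric.

Angles are stored in degrees throughout, in (-180, 180].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .structure_io import Ensemble

__all__ = [
    "DihedralSeries", "RamachandranDensity", "dihedral_angle",
    "phi_psi_series", "ramachandran_density", "dihedral_shift",
    "GRID_STEP_DEG", "DEFAULT_BANDWIDTH_DEG", "SHIFT_FLAG_THRESHOLD",
]

logger = logging.getLogger("kelchdyn")

GRID_STEP_DEG = 5.0
GRID_SIZE = 72
DEFAULT_BANDWIDTH_DEG = 15.0
# JS distance above which a dihedral-space shift is flagged as significant
SHIFT_FLAG_THRESHOLD = 0.2


def _wrap(angle):
    """Map angles into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return out


@dataclass
class DihedralSeries:
    """Per-frame phi/psi of one residue, degrees in (-180, 180]."""
    residue: int
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi series must have equal length")


@dataclass
class RamachandranDensity:
    """Wrapped-KDE density on a fixed (phi, psi) grid.

    ``grid`` has units of probability per square degree and integrates to
    one over the torus."""
    grid: np.ndarray
    bandwidth: float
    centers: np.ndarray

    def probabilities(self) -> np.ndarray:
        return self.grid * GRID_STEP_DEG ** 2


def _dihedral_batch(p1, p2, p3, p4):
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    if np.any(norm1 < 1e-9) or np.any(norm2 < 1e-9):
        raise ValueError("collinear atoms: torsion undefined")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = (n1 * n2).sum(axis=-1)
    y = (np.cross(n1, n2) * b2u).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return _wrap(ang)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in (-180, 180], IUPAC sign
    convention.  Raises on collinear consecutive points."""
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    return float(_dihedral_batch(*pts))


def phi_psi_series(ensemble: Ensemble, residue: int,
                   chain_id: str = "A") -> DihedralSeries:
    """phi/psi of one residue along an ensemble.

    phi = C(i-1)-N-CA-C and psi = N-CA-C-N(i+1); the residue therefore
    needs both sequence neighbours present in the same chain.
    """
    topo = ensemble.topology
    keys = {(chain_id, residue + d) for d in (-1, 0, 1)}
    if not keys <= set(topo.residues):
        missing = sorted(k[1] for k in keys - set(topo.residues))
        raise ValueError(
            f"residue {residue} lacks chain neighbour(s) {missing}: "
            f"terminal residues have no complete phi/psi")
    idx = {
        "C_prev": topo.atom_index(chain_id, residue - 1, "C"),
        "N": topo.atom_index(chain_id, residue, "N"),
        "CA": topo.atom_index(chain_id, residue, "CA"),
        "C": topo.atom_index(chain_id, residue, "C"),
        "N_next": topo.atom_index(chain_id, residue + 1, "N"),
    }
    frames = np.stack(ensemble.frames)  # (T, n_atoms, 3)
    phi = _dihedral_batch(frames[:, idx["C_prev"]], frames[:, idx["N"]],
                          frames[:, idx["CA"]], frames[:, idx["C"]])
    psi = _dihedral_batch(frames[:, idx["N"]], frames[:, idx["CA"]],
                          frames[:, idx["C"]], frames[:, idx["N_next"]])
    return DihedralSeries(residue=residue, phi=phi, psi=psi)


def ramachandran_density(series: DihedralSeries,
                         bandwidth: float = DEFAULT_BANDWIDTH_DEG
                         ) -> RamachandranDensity:
    """Periodic bivariate Gaussian KDE on a 72 x 72 (5-degree) grid.

    The kernel is wrapped across the +/-180 boundary so clusters straddling
    the wrap stay single modes; the density integrates to one.
    """
    if series.phi.size < 10:
        raise ValueError("need at least 10 samples for a density estimate")
    phi = _wrap(series.phi)
    psi = _wrap(series.psi)
    centers = -180.0 + GRID_STEP_DEG * (np.arange(GRID_SIZE) + 0.5)
    # wrapped 1-D kernels: nearest periodic image plus both neighbours
    def kernels(samples):
        diff = centers[None, :] - samples[:, None]
        k = np.zeros_like(diff)
        for shift in (-360.0, 0.0, 360.0):
            k += np.exp(-0.5 * ((diff + shift) / bandwidth) ** 2)
        return k
    kphi = kernels(phi)
    kpsi = kernels(psi)
    grid = kphi.T @ kpsi  # (72, 72): phi rows, psi columns
    grid /= grid.sum() * GRID_STEP_DEG ** 2
    return RamachandranDensity(grid=grid, bandwidth=bandwidth, centers=centers)


def dihedral_shift(wt: RamachandranDensity, mut: RamachandranDensity) -> float:
    """Jensen-Shannon distance (base 2, in [0, 1]) between two
    Ramachandran densities on the same grid."""
    if wt.grid.shape != mut.grid.shape:
        raise ValueError("density grids do not match")
    p = wt.probabilities().ravel()
    q = mut.probabilities().ravel()
    return float(jensenshannon(p, q, base=2))
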