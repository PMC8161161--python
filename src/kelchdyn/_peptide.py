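"""Internal-coordinate construction of peptide backbones.

Backbones are grown atom by atom with the NeRF (natural extension reference
frame) placement rule from ideal bond lengths and angles, so a chain is fully
determined by its (phi, psi, omega) torsion sequence.  Used to build ideal
beta-strand templates, tiled sheets, and random coils, and to re-apply
dihedral perturbations to existing structures.

All coordinates are in Angstrom, all angles in degrees.
"""

from __future__ import annotations

import numpy as np

# Engh-Huber-style ideal backbone geometry
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5

# canonical anti-parallel beta-strand torsions
BETA_PHI = -139.0
BETA_PSI = 135.0
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D bonded to C given bond length C-D, angle B-C-D and
    torsion A-B-C-D (IUPAC sign convention)."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n = n / nn
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(chi),
                               np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from backbone N, CA, C.

    Placed at 1.53 A from CA with equal N-CA-CB and C-CA-CB angles of 110.5
    degrees and L-amino-acid chirality.  Used both for building full
    backbones and for synthesising a CB on glycine.
    """
    n1 = n - ca
    n1 = n1 / np.linalg.norm(n1)
    n2 = c - ca
    n2 = n2 / np.linalg.norm(n2)
    bis = -(n1 + n2)
    bis = bis / np.linalg.norm(bis)
    perp = np.cross(n1, n2)
    perp = perp / np.linalg.norm(perp)
    cos_target = np.cos(np.deg2rad(ANGLE_N_CA_CB))
    cos_alpha = cos_target / float(bis @ n1)
    cos_alpha = min(1.0, max(-1.0, cos_alpha))
    sin_alpha = np.sqrt(1.0 - cos_alpha ** 2)
    # +perp gives L chirality (matches the standard CB direction used for
    # reconstructing side chains from backbone traces)
    direction = cos_alpha * bis + sin_alpha * perp
    return ca + BOND_CA_CB * direction


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Build an n-residue backbone from torsions.

    ``phi[0]`` is unused (no preceding carbonyl); ``psi[-1]`` only orients
    the final carbonyl oxygen.  Returns arrays of shape (n, 3) for atoms
    N, CA, C, O, CB.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(n_res, OMEGA_TRANS)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed frame for residue 0
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi[i])
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        O[i] = place_atom(N[i], CA[i], C[i],
                          BOND_C_O, ANGLE_CA_C_O, psi[i] - 180.0)
        CB[i] = virtual_cb(N[i], CA[i], C[i])
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def build_beta_strand(n_res: int) -> dict[str, np.ndarray]:
    """An ideal extended anti-parallel beta strand of ``n_res`` residues."""
    phi = np.full(n_res, BETA_PHI)
    psi = np.full(n_res, BETA_PSI)
    return build_backbone(phi, psi)
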