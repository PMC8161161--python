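"""Independent oracles used by the test suite.

Each oracle deliberately avoids the code path it checks: superposition RMSD
comes from the quaternion characteristic-polynomial eigenproblem, fragment
scoring from a naive double loop with a third-party superposition routine,
hydrogen bonds from an exhaustive all-pairs scan, and torsions from
biotite.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def qcp_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD via the largest eigenvalue of the 4x4 quaternion key
    matrix (Theobald's characteristic-polynomial formulation, solved here
    by direct symmetric eigendecomposition)."""
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    ssd = (p * p).sum() + (q * q).sum() - 2.0 * lam
    return float(np.sqrt(max(ssd, 0.0) / p.shape[0]))


def align_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Superposition RMSD through scipy's align_vectors (a third,
    library-based route)."""
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    _rot, rssd = Rotation.align_vectors(qc, pc)
    return float(rssd / np.sqrt(p.shape[0]))


def brute_switching(r: float, r0=0.08, n=8, m=12, d0=0.0) -> float:
    x = max(r - d0, 0.0) / r0
    if abs(x - 1.0) < 1e-9:
        return n / m
    return (1.0 - x ** n) / (1.0 - x ** m)


def brute_sa_beta(structure, params, template) -> float:
    """Naive double-loop total: enumerate fragments directly from the
    residue list, superpose each 30-atom pair with the quaternion oracle."""
    order = ("N", "CA", "CB", "C", "O")
    from kelchdyn._peptide import virtual_cb

    def sheet_atoms(chain, tri):
        rows = []
        for r in tri:
            have = {}
            for name in ("N", "CA", "C", "O"):
                have[name] = structure.atoms[structure.atom_index(chain, r, name)].position
            if structure.has_atom(chain, r, "CB"):
                have["CB"] = structure.atoms[structure.atom_index(chain, r, "CB")].position
            else:
                have["CB"] = virtual_cb(have["N"], have["CA"], have["C"])
            rows.extend(have[name] for name in order)
        return np.asarray(rows)

    residues = structure.residues
    triples = []
    for k in range(len(residues) - 2):
        (c0, r0_), (c1, r1), (c2, r2) = residues[k], residues[k + 1], residues[k + 2]
        if c0 == c1 == c2 and r1 == r0_ + 1 and r2 == r0_ + 2:
            triples.append((c0, (r0_, r1, r2)))
    total = 0.0
    for i, (ca, ta) in enumerate(triples):
        for cb, tb in triples[i + 1:]:
            if ca != cb or tb[0] - ta[2] < params.min_sequence_separation:
                continue
            coords = np.vstack([sheet_atoms(ca, ta), sheet_atoms(cb, tb)])
            r = qcp_rmsd(coords, template) / 10.0  # A -> nm
            total += brute_switching(r, params.r0, params.n, params.m, params.d0)
    return total


def brute_hbonds(coords, structure, cutoff=3.5):
    """Exhaustive all-pairs heavy-atom detection (no hydrogens)."""
    found = set()
    n = structure.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            ai, aj = structure.atoms[i], structure.atoms[j]
            if ai.element not in ("N", "O") or aj.element not in ("N", "O"):
                continue
            if (ai.chain_id, ai.residue_index) == (aj.chain_id, aj.residue_index):
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                ki = (ai.chain_id, ai.residue_index, ai.name)
                kj = (aj.chain_id, aj.residue_index, aj.name)
                found.add((ki, kj) if ki <= kj else (kj, ki))
    return found


def brute_contact_map(ensemble, cutoff=4.5):
    """Direct per-frame, per-residue-pair minimum-distance scan."""
    topo = ensemble.topology
    res = topo.residues
    nres = len(res)
    counts = np.zeros((nres, nres))
    groups = [topo.residue_atom_indices(c, r) for c, r in res]
    for frame in ensemble.frames:
        for a in range(nres):
            for b in range(nres):
                if abs(a - b) <= 2:
                    continue
                da = frame[groups[a]]
                db = frame[groups[b]]
                dmin = np.min(np.linalg.norm(da[:, None] - db[None, :], axis=2))
                counts[a, b] += dmin < cutoff
    return counts / ensemble.n_frames


def biotite_dihedral(p1, p2, p3, p4) -> float:
    import biotite.structure as struc
    return float(np.degrees(struc.dihedral(
        np.asarray(p1, float), np.asarray(p2, float),
        np.asarray(p3, float), np.asarray(p4, float))))
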