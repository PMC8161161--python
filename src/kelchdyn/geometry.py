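"""Superposition and deviation/fluctuation metrics.

Implements the least-squares (Kabsch) rigid superposition and the standard
trajectory post-processing metrics built on it: RMSD series against a
reference, moving (lagged) RMSD, per-residue RMSF, radius of gyration,
block-averaged statistics of correlated series, and per-blade averaging of
per-residue quantities.

All fits are mass-unweighted; fit atoms and measured atoms are the same
selection unless a separate measure selection is passed explicitly.
Coordinates and all deviation metrics are in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import BladeScheme, Ensemble

__all__ = [
    "SuperpositionResult", "SeriesStats", "kabsch_superpose", "rmsd_series",
    "moving_rmsd", "rmsf", "radius_of_gyration", "block_stats",
    "per_residue_blade_average",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid map ``x -> rotation @ x + translation`` (mobile onto
    reference), with the residual RMSD in Angstrom."""
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class SeriesStats:
    """Block-averaged mean and standard deviation of a correlated series."""
    mean: float
    std: float
    n_blocks: int


def _check_points(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got {x.shape}")
    return x


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections excluded) and translation that
    minimise the mass-unweighted RMSD, via SVD of the cross-covariance
    matrix.  Requires at least three non-collinear points.
    """
    mobile = _check_points("mobile", mobile)
    reference = _check_points("reference", reference)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    p = mobile - mc
    q = reference - rc
    if (np.linalg.matrix_rank(p, tol=1e-8) < 2
            or np.linalg.matrix_rank(q, tol=1e-8) < 2):
        raise ValueError("degenerate (collinear) point set")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = rc - rotation @ mc
    ssd = float((p * p).sum() + (q * q).sum()) - 2.0 * float(s[0] + s[1] + d * s[2])
    rmsd = float(np.sqrt(max(ssd, 0.0) / n))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _resolve_selection(selection) -> np.ndarray:
    """Accept an index array or a BackboneSelection-like object."""
    if hasattr(selection, "extract"):
        return selection
    sel = np.asarray(selection, dtype=int)
    if sel.ndim != 1 or sel.size == 0:
        raise ValueError("selection must be a non-empty 1-D index array")
    return sel


def _select(coords: np.ndarray, selection) -> np.ndarray:
    if hasattr(selection, "extract"):
        return selection.extract(coords)
    return coords[selection]


def rmsd_series(ensemble: Ensemble, reference: np.ndarray, selection) -> np.ndarray:
    """Per-frame backbone RMSD (A) from a reference after a least-squares
    fit of the same selection onto the reference."""
    selection = _resolve_selection(selection)
    ref = _select(np.asarray(reference, dtype=float), selection)
    out = np.empty(ensemble.n_frames)
    for t, frame in enumerate(ensemble.frames):
        out[t] = kabsch_superpose(_select(frame, selection), ref).rmsd
    return out


def moving_rmsd(ensemble: Ensemble, lag: int, selection) -> np.ndarray:
    """Lagged frame-to-frame RMSD: element ``t`` compares frame ``t + lag``
    with frame ``t`` after fitting.  Series length is ``n_frames - lag``."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= ensemble.n_frames:
        raise ValueError(
            f"lag {lag} >= number of frames {ensemble.n_frames}")
    selection = _resolve_selection(selection)
    out = np.empty(ensemble.n_frames - lag)
    for t in range(ensemble.n_frames - lag):
        a = _select(ensemble.frames[t + lag], selection)
        b = _select(ensemble.frames[t], selection)
        out[t] = kabsch_superpose(a, b).rmsd
    return out


def rmsf(ensemble: Ensemble, selection=None, reference_mode: str = "initial"
         ) -> dict[tuple[str, int], float]:
    """Per-residue root-mean-square fluctuation (A).

    Frames are least-squares fitted to the first frame; the displacement
    reference is the initial structure by default (deviation of a residue
    from its initial position).  ``reference_mode="mean"`` instead measures
    fluctuation about the mean structure, the convention most trajectory
    tools default to.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if reference_mode not in ("initial", "mean"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    from .structure_io import backbone_selection
    if selection is None:
        selection = backbone_selection(ensemble.topology, "fit-backbone")
    if hasattr(selection, "residues"):
        residues = selection.residues
        slices = selection.residue_slices()
    else:
        sel = _resolve_selection(selection)
        by_res: dict[tuple[str, int], list[int]] = {}
        for pos, i in enumerate(sel):
            atom = ensemble.topology.atoms[int(i)]
            by_res.setdefault((atom.chain_id, atom.residue_index), []).append(pos)
        residues = list(by_res)
        slices = [np.asarray(v, dtype=int) for v in by_res.values()]
    ref = _select(ensemble.frames[0], selection)
    fitted = np.empty((ensemble.n_frames, ref.shape[0], 3))
    for t, frame in enumerate(ensemble.frames):
        fitted[t] = kabsch_superpose(_select(frame, selection), ref).apply(
            _select(frame, selection))
    target = ref if reference_mode == "initial" else fitted.mean(axis=0)
    sq = ((fitted - target) ** 2).sum(axis=2)  # (n_frames, n_atoms)
    out: dict[tuple[str, int], float] = {}
    for key, sl in zip(residues, slices):
        out[key] = float(np.sqrt(sq[:, sl].mean()))
    return out


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (A) about the centre of mass."""
    coords = _check_points("coords", coords)
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    if masses.shape != (coords.shape[0],):
        raise ValueError("masses must match the number of atoms")
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def block_stats(series, n_blocks: int = 5) -> SeriesStats:
    """Block-averaged mean and standard deviation of a correlated series.

    The series is split into ``n_blocks`` contiguous near-equal blocks (any
    remainder spread over the leading blocks); the mean is the mean of block
    means and the standard deviation is the sample (n-1) deviation of the
    block means.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_blocks > series.size:
        raise ValueError(
            f"n_blocks {n_blocks} exceeds series length {series.size}")
    means = np.array([b.mean() for b in np.array_split(series, n_blocks)])
    return SeriesStats(mean=float(means.mean()),
                       std=float(means.std(ddof=1)),
                       n_blocks=n_blocks)


def per_residue_blade_average(per_residue_values: dict[int, float],
                              scheme: BladeScheme) -> dict[str, float]:
    """Average a residue-indexed quantity over each blade.

    The blade value is the sum of member-residue values divided by the full
    blade residue count, so blades of slightly different lengths remain
    comparable.  Residues outside the scheme are ignored; a blade with no
    covered residue is an error.
    """
    out: dict[str, float] = {}
    for name in scheme.names:
        members = scheme.residues(name)
        covered = [per_residue_values[r] for r in members if r in per_residue_values]
        if not covered:
            raise ValueError(f"blade {name} has no covered residues")
        out[name] = float(sum(covered) / scheme.size(name))
    return out
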