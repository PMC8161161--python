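"""Mutant stability classification and the end-to-end analysis pipeline.

The decision rule operates on the change of the anti-parallel beta-sheet
order parameter relative to the wild type: a drop of two or more points is
called destabilizing, minimal changes or increases neutral/stabilizing, and
mutants whose uncertainty band straddles both boundaries inconclusive.
This module also scores such predictions against reference labels, carries
the published per-blade missense-mutation counts of the KEAP1 Kelch domain
and the NRF2-binding-site residue list for RMSF reporting, and orchestrates
all analysis stages over wild-type/mutant ensemble pairs into deterministic
TSV/JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beta_order import (SaBetaParams, delta_sa_beta, enumerate_segment_pairs,
                         sa_beta_series)
from .dihedrals import (SHIFT_FLAG_THRESHOLD, dihedral_shift, phi_psi_series,
                        ramachandran_density)
from .geometry import per_residue_blade_average, rmsf
from .hbond_contacts import HBondCriteria, contact_map, hbond_occupancy, network_diff
from .structure_io import (BladeScheme, Ensemble, backbone_selection,
                           read_ensemble)

__all__ = [
    "DESTABILIZING", "NEUTRAL_STABILIZING", "INCONCLUSIVE",
    "ClassificationThresholds", "ClassificationResult", "BindingSiteReport",
    "PipelineConfig", "classify", "score_predictions",
    "aggregate_blade_counts", "binding_site_rmsf", "run_pipeline",
    "KELCH_BLADE_MUTATION_COUNTS", "KELCH_ANCHOR_EXTRA_COUNTS",
    "KELCH_BINDING_SITE_RESIDUES", "kelch_reference_labels",
]

logger = logging.getLogger("kelchdyn")

DESTABILIZING = "destabilizing"
NEUTRAL_STABILIZING = "neutral/stabilizing"
INCONCLUSIVE = "inconclusive"
_LABELS = (DESTABILIZING, NEUTRAL_STABILIZING, INCONCLUSIVE)

# COSMIC missense-mutation counts per Kelch blade; the separate ANCHOR
# hotspot at the R470 site in blade IV is never merged silently.
KELCH_BLADE_MUTATION_COUNTS = {"I": 71, "II": 64, "III": 79,
                               "IV": 62, "V": 45, "VI": 53}
KELCH_ANCHOR_EXTRA_COUNTS = {"IV": 24}

# Kelch-domain residues hydrogen-bonding the NRF2 Neh2 ETGE/DLG motifs
# (PISA interface determination, consumed here as data)
KELCH_BINDING_SITE_RESIDUES = [334, 364, 380, 382, 414, 415,
                               483, 508, 530, 555, 602]

# experimental (in vitro) and MD-predicted labels for the 12 KEAP1 Kelch
# cancer mutants, loaded as published data for scoring comparisons
_KELCH_LABELS = {
    "G333C": ("D", "D"), "G350S": ("S/N", "S/N"), "G364C": ("S/N", "S/N"),
    "G379D": ("D", "D"), "R413L": ("D", "D"), "R415G": ("S/N", "S/N"),
    "A427V": ("S/N", "I"), "G430C": ("D", "D"), "R470C": ("S/N", "S/N"),
    "R470H": ("S/N", "S/N"), "R470S": ("S/N", "S/N"), "G476R": ("D", "D"),
}
_CODE_TO_LABEL = {"D": DESTABILIZING, "S/N": NEUTRAL_STABILIZING,
                  "I": INCONCLUSIVE}


def kelch_reference_labels() -> tuple[dict[str, str], dict[str, str]]:
    """(experimental, MD-predicted) stability labels of the 12 Kelch cancer
    mutants, as published."""
    exp = {k: _CODE_TO_LABEL[v[0]] for k, v in _KELCH_LABELS.items()}
    sim = {k: _CODE_TO_LABEL[v[1]] for k, v in _KELCH_LABELS.items()}
    return exp, sim


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision boundaries on the order-parameter change.

    ``t_destab``: a mutant whose delta plus its uncertainty stays below this
    is destabilizing (default -2, the two-point-drop rule).
    ``t_neutral``: a mutant whose delta minus its uncertainty stays above
    this is neutral/stabilizing (default -1, the operationalization of
    "minimal changes or increases").  Everything else is inconclusive.
    """
    t_destab: float = -2.0
    t_neutral: float = -1.0


@dataclass
class ClassificationResult:
    mutant: str
    delta_sabeta: float
    sigma: float
    label: str
    thresholds: ClassificationThresholds


@dataclass
class BindingSiteReport:
    """Binding-site RMSF (A) per variant, with wild-type-relative deltas."""
    residues: list[int]
    rmsf: dict[str, dict[int, float]]
    deltas: dict[str, dict[int, float]]


def classify(delta: float, sigma: float,
             thresholds: ClassificationThresholds | None = None) -> str:
    """Label a mutant from its order-parameter change and uncertainty."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t = thresholds or ClassificationThresholds()
    if delta + sigma < t.t_destab:
        return DESTABILIZING
    if delta - sigma > t.t_neutral:
        return NEUTRAL_STABILIZING
    return INCONCLUSIVE


def score_predictions(predicted: dict[str, str], reference: dict[str, str],
                      inconclusive_policy: str = "wrong"
                      ) -> tuple[float, list[dict]]:
    """Fraction of predictions agreeing with reference labels.

    ``inconclusive_policy="wrong"`` counts an inconclusive prediction as an
    error; ``"excluded"`` drops those mutants from the denominator.  The
    returned table lists every disagreement.
    """
    if inconclusive_policy not in ("wrong", "excluded"):
        raise ValueError(f"unknown policy {inconclusive_policy!r}")
    if set(predicted) != set(reference):
        missing = set(predicted) ^ set(reference)
        raise KeyError(f"mutant keys differ between maps: {sorted(missing)}")
    table = []
    correct = 0
    denominator = 0
    for name in sorted(predicted):
        pred, ref = predicted[name], reference[name]
        if pred == INCONCLUSIVE and inconclusive_policy == "excluded":
            table.append({"mutant": name, "predicted": pred, "reference": ref,
                          "counted": False, "agree": None})
            continue
        denominator += 1
        agree = pred == ref
        correct += agree
        if not agree:
            table.append({"mutant": name, "predicted": pred, "reference": ref,
                          "counted": True, "agree": False})
    if denominator == 0:
        raise ValueError("no predictions left to score under this policy")
    return correct / denominator, table


def aggregate_blade_counts(per_blade: dict[str, int],
                           groups: list[list[str]],
                           extra: dict[str, int] | None = None) -> dict:
    """Sum per-blade counts over blade groups.

    Extra annotated counts (a hotspot listed separately from its blade's
    total) are reported per group but never added to the sums.
    """
    if any(v < 0 for v in per_blade.values()):
        raise ValueError("counts must be non-negative")
    extra = extra or {}
    out = {"groups": [], "extra": []}
    for group in groups:
        unknown = [b for b in group if b not in per_blade]
        if unknown:
            raise KeyError(f"unknown blade(s) in group: {unknown}")
        out["groups"].append(sum(per_blade[b] for b in group))
        out["extra"].append(sum(extra.get(b, 0) for b in group))
    return out


def binding_site_rmsf(rmsf_by_variant: dict[str, dict[int, float]],
                      site: list[int], reference: str = "WT"
                      ) -> BindingSiteReport:
    """Restrict per-residue RMSF maps to the binding-site residues and
    compute deltas relative to the reference variant."""
    if reference not in rmsf_by_variant:
        raise KeyError(f"reference variant {reference!r} not in RMSF maps")
    table: dict[str, dict[int, float]] = {}
    for variant, values in rmsf_by_variant.items():
        row = {}
        for r in site:
            if r not in values:
                raise KeyError(
                    f"residue {r} missing from RMSF map of variant {variant}")
            row[r] = values[r]
        table[variant] = row
    deltas = {variant: {r: table[variant][r] - table[reference][r]
                        for r in site}
              for variant in table}
    return BindingSiteReport(residues=list(site), rmsf=table, deltas=deltas)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Ensembles may be given as objects or as multi-model PDB paths.
    ``probe_residues`` names the mutated (or probed) residue per mutant for
    the dihedral-shift report.
    """
    wild_type: Ensemble | str | None = None
    mutants: dict[str, Ensemble | str] = field(default_factory=dict)
    scheme: BladeScheme | None = None
    params: SaBetaParams = field(default_factory=SaBetaParams)
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    probe_residues: dict[str, int] = field(default_factory=dict)
    n_blocks: int = 5
    min_occupancy: float = 0.2
    contact_cutoff: float = 4.5
    outdir: str | None = None


def _load(ens) -> Ensemble:
    if isinstance(ens, Ensemble):
        return ens
    return read_ensemble(ens)


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _per_residue_rmsd(ensemble: Ensemble, selection) -> dict[int, float]:
    """Mean per-residue deviation (A) from the initial structure after a
    global backbone fit — RMSF with the initial-structure reference, which
    is exactly the per-residue deviation the blade-wise reports use."""
    values = rmsf(ensemble, selection, reference_mode="initial")
    return {resi: v for (_c, resi), v in values.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage for each mutant against the wild type.

    Per mutant: global and per-blade order-parameter change, per-blade
    deviation change, RMSF, dihedral shift at the probed residue, hydrogen
    bond network differences, contact-map difference, and the stability
    classification.  Deterministic given the config; reports are written as
    TSV/JSON when ``outdir`` is set.
    """
    if config.wild_type is None:
        raise ValueError("pipeline config names no wild-type ensemble")
    if not config.mutants:
        raise ValueError("pipeline config names no mutant ensembles")
    stage = "load wild type"
    try:
        wt = _load(config.wild_type)
        selection = backbone_selection(wt.topology, "fit-backbone")
        pair_set = enumerate_segment_pairs(wt.topology, config.params)
        stage = "wild-type order parameter"
        wt_series = sa_beta_series(wt, pair_set, scheme=config.scheme,
                                   params=config.params, n_blocks=config.n_blocks)
        wt_rmsd = _per_residue_rmsd(wt, selection)
        wt_rmsf = {r: v for (_c, r), v in rmsf(wt, selection).items()}
        stage = "wild-type hydrogen bonds"
        wt_hbonds = hbond_occupancy(wt, config.criteria)
        wt_contacts, res_keys = contact_map(wt, config.contact_cutoff)
        report: dict = {
            "wild_type": {
                "sa_beta_mean": wt_series.stats.mean,
                "sa_beta_std": wt_series.stats.std,
                "n_segments": wt_series.n_segments,
            },
            "mutants": {},
        }
        out = Path(config.outdir) if config.outdir else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
        for name in sorted(config.mutants):
            stage = f"mutant {name}"
            mut = _load(config.mutants[name])
            mut_pair_set = enumerate_segment_pairs(mut.topology, config.params)
            mut_series = sa_beta_series(mut, mut_pair_set, scheme=config.scheme,
                                        params=config.params,
                                        n_blocks=config.n_blocks)
            delta, sigma = delta_sa_beta(mut_series.totals, wt_series.totals,
                                         config.n_blocks)
            label = classify(delta, sigma, config.thresholds)
            entry: dict = {
                "delta_sa_beta": delta,
                "sigma": sigma,
                "label": label,
            }
            if config.scheme is not None:
                blade_delta = {}
                for blade in config.scheme.names:
                    d, s = delta_sa_beta(mut_series.blade_series[blade],
                                         wt_series.blade_series[blade],
                                         config.n_blocks)
                    blade_delta[blade] = {"delta": d, "sigma": s}
                entry["blade_delta_sa_beta"] = blade_delta
                mut_rmsd = _per_residue_rmsd(mut, selection)
                wt_blade = per_residue_blade_average(wt_rmsd, config.scheme)
                mut_blade = per_residue_blade_average(mut_rmsd, config.scheme)
                entry["blade_delta_rmsd"] = {
                    b: mut_blade[b] - wt_blade[b] for b in config.scheme.names}
            mut_rmsf = {r: v for (_c, r), v in rmsf(mut, selection).items()}
            entry["rmsf_max_delta"] = max(
                abs(mut_rmsf[r] - wt_rmsf[r]) for r in wt_rmsf)
            probe = config.probe_residues.get(name)
            if probe is not None:
                stage = f"mutant {name} dihedrals"
                wt_d = ramachandran_density(phi_psi_series(wt, probe))
                mut_d = ramachandran_density(phi_psi_series(mut, probe))
                js = dihedral_shift(wt_d, mut_d)
                entry["dihedral_shift"] = {
                    "residue": probe, "js_distance": js,
                    "flag": js > SHIFT_FLAG_THRESHOLD}
            stage = f"mutant {name} hydrogen bonds"
            mut_hbonds = hbond_occupancy(mut, config.criteria)
            diff = network_diff(wt_hbonds, mut_hbonds, config.min_occupancy)
            entry["hbond_diff_count"] = len(diff.bonds)
            entry["hbond_max_abs_delta_pct"] = (
                max(abs(b[5]) for b in diff.bonds) if diff.bonds else 0.0)
            mut_contacts, _ = contact_map(mut, config.contact_cutoff)
            entry["contact_map_max_abs_delta"] = float(
                np.abs(mut_contacts - wt_contacts).max())
            report["mutants"][name] = entry
            if out is not None:
                _write_mutant_reports(out, name, config, mut_series,
                                      wt_series, diff, entry)
        if out is not None:
            (out / "report.json").write_text(
                json.dumps(report, sort_keys=True, indent=1))
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from err


def _write_mutant_reports(out: Path, name: str, config: PipelineConfig,
                          mut_series, wt_series, diff, entry) -> None:
    lines = ["# metric: sa_beta (dimensionless)\t"
             f"n_blocks={config.n_blocks}",
             "frame\twild_type\tmutant"]
    n = min(len(wt_series.totals), len(mut_series.totals))
    for t in range(n):
        lines.append(f"{t}\t{_fmt(wt_series.totals[t])}\t"
                     f"{_fmt(mut_series.totals[t])}")
    (out / f"{name}_sabeta.tsv").write_text("\n".join(lines) + "\n")
    hl = [f"# hbond network diff, min occupancy {config.min_occupancy:.2f}, "
          f"cutoff {config.criteria.da_cutoff:.2f} A",
          "donor\tacceptor\tclass\twt_pct\tmut_pct\tdelta_pct"]
    for donor, acceptor, cls, wt_pct, mut_pct, delta in diff.bonds:
        hl.append("\t".join([
            f"{donor[0]}{donor[1]}:{donor[2]}",
            f"{acceptor[0]}{acceptor[1]}:{acceptor[2]}",
            cls, _fmt(wt_pct), _fmt(mut_pct), _fmt(delta)]))
    (out / f"{name}_hbond_diff.tsv").write_text("\n".join(hl) + "\n")
    (out / f"{name}_summary.json").write_text(
        json.dumps(entry, sort_keys=True, indent=1))
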