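"""The anti-parallel beta-sheet order parameter."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from kelchdyn.beta_order import (SaBetaParams, delta_sa_beta,
                                 enumerate_segment_pairs, pairs_from_triples,
                                 sa_beta, sa_beta_series, switching_score,
                                 _fragment_rmsds)
from kelchdyn.structure_io import Ensemble
from kelchdyn.synthetic_data import (DisorderSpec, EnsembleSpec, SheetBase,
                                     apply_dihedral_kicks, make_coil,
                                     make_ensemble, make_propeller, make_sheet)

from oracles import brute_sa_beta, brute_switching


class TestTemplate:
    def test_thirty_atoms(self, template):
        assert template.shape == (30, 3)

    def test_zero_rmsd_against_itself(self, template):
        assert _fragment_rmsds(template[None], template)[0] == pytest.approx(
            0.0, abs=1e-12)

    def test_canonical_hbond_distances(self, template):
        # central residue pair of the two strands is doubly hydrogen bonded
        names = ["N", "CA", "CB", "C", "O"]
        atom = lambda s, r, n: template[15 * s + 5 * r + names.index(n)]
        assert np.linalg.norm(atom(0, 1, "N") - atom(1, 1, "O")) == pytest.approx(2.9, abs=1e-6)
        assert np.linalg.norm(atom(0, 1, "O") - atom(1, 1, "N")) == pytest.approx(2.9, abs=1e-6)

    def test_pulled_apart_strands_regression_anchor(self, template):
        # separating the strands by 5 A along the inter-strand axis gives a
        # fragment RMSD of 0.250 nm (frozen from the deterministic
        # construction: each strand ends up displaced by half the pull)
        axis = template[15:].mean(0) - template[:15].mean(0)
        axis /= np.linalg.norm(axis)
        apart = template.copy()
        apart[15:] += 5.0 * axis
        r_nm = _fragment_rmsds(apart[None], template)[0] / 10.0
        assert r_nm == pytest.approx(0.250, abs=0.005)
        assert r_nm > 0.2


class TestEnumeration:
    def _chain(self, n):
        return make_coil(n, np.random.default_rng(0))

    def test_twelve_residue_hand_count(self):
        # fragments start at 1..10; pair needs start(b) - end(a) >= 5
        structure = self._chain(12)
        pairs = enumerate_segment_pairs(structure)
        expected = [((i, i + 1, i + 2), (j, j + 1, j + 2))
                    for i in range(1, 11) for j in range(i + 7, 11)]
        got = [(p.fragment_a, p.fragment_b) for p in pairs.pairs]
        assert got == expected
        assert len(pairs) == 6

    def test_six_residues_no_pairs(self):
        assert len(enumerate_segment_pairs(self._chain(6))) == 0

    def test_subset_filter(self):
        structure, info = make_propeller()
        blade = info.scheme.names[1]
        subset = set()
        for lo, hi in info.scheme.ranges[blade]:
            subset |= set(range(lo, hi + 1))
        pairs = enumerate_segment_pairs(structure, residue_subset=subset)
        assert len(pairs) > 0
        for p in pairs.pairs:
            assert set(p.residues) <= subset

    def test_numbering_gap_is_a_chain_break(self):
        structure, info = make_sheet(2, 6)
        pairs = enumerate_segment_pairs(structure)
        (lo1, hi1), (lo2, hi2) = info.strand_ranges
        for p in pairs.pairs:
            for tri in (p.fragment_a, p.fragment_b):
                inside_one_strand = (lo1 <= tri[0] and tri[2] <= hi1) or \
                                    (lo2 <= tri[0] and tri[2] <= hi2)
                assert inside_one_strand  # fragments never span the gap


class TestSwitchingScore:
    def test_unity_at_d0(self):
        assert switching_score(0.0) == 1.0
        p = SaBetaParams(d0=0.1)
        assert switching_score(0.05, p) == 1.0  # clamped below d0

    def test_removable_singularity_limit(self):
        p = SaBetaParams()
        assert switching_score(p.r0 + p.d0, p) == pytest.approx(8 / 12, abs=1e-12)
        for eps in (1e-9, -1e-9):
            x = 1.0 + eps
            assert switching_score(x * p.r0, p) == pytest.approx(8 / 12, abs=1e-6)

    def test_decreasing_on_dense_grid(self):
        # never increasing anywhere; strictly decreasing wherever the step
        # is representable in double precision (x^8 underflows the 1-ulp
        # resolution of 1.0 for x below ~0.1)
        x = np.linspace(0.0, 6.0, 10_000)
        s = switching_score(x * 0.08, SaBetaParams())
        assert np.all(np.diff(s) <= 0)
        strict = x[:-1] >= 0.1
        assert np.all(np.diff(s)[strict] < 0)
        assert s[-1] < 1e-3  # tail decays like x^(n - m) = x^-4

    def test_matches_naive_formula(self):
        p = SaBetaParams()
        for r in (0.01, 0.05, 0.08, 0.2, 0.9):
            assert switching_score(r, p) == pytest.approx(
                brute_switching(r, p.r0, p.n, p.m, p.d0), abs=1e-12)


class TestSaBeta:
    def test_perfect_sheet_scores_n(self, sheet_4x6):
        structure, info = sheet_4x6
        pairs = pairs_from_triples(structure, info.designed_pairs)
        res = sa_beta(structure.coords, pairs)
        assert res.total == pytest.approx(res.n_segments, abs=1e-9)
        assert np.all(res.per_segment > 1 - 1e-9)

    def test_rigid_motion_invariance(self, sheet_4x6):
        structure, info = sheet_4x6
        pairs = pairs_from_triples(structure, info.designed_pairs)
        base = sa_beta(structure.coords, pairs)
        rot = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
        moved = structure.coords @ rot.T + np.array([5.0, -3.0, 12.0])
        res = sa_beta(moved, pairs)
        assert res.total == pytest.approx(base.total, abs=1e-9)

    def test_random_coil_is_near_zero(self):
        coil = make_coil(30, np.random.default_rng(0))
        pairs = enumerate_segment_pairs(coil)
        res = sa_beta(coil.coords, pairs)
        assert res.total < 0.05 * res.n_segments

    def test_per_residue_attribution_sums_to_total(self, random_structure_20):
        pairs = enumerate_segment_pairs(random_structure_20)
        res = sa_beta(random_structure_20.coords, pairs)
        assert sum(res.per_residue.values()) == pytest.approx(res.total, abs=1e-9)

    def test_agrees_with_brute_force_oracle(self, template):
        params = SaBetaParams()
        for seed in (1, 2, 3):
            coil = make_coil(20, np.random.default_rng(seed))
            pairs = enumerate_segment_pairs(coil, params)
            mine = sa_beta(coil.coords, pairs, params=params).total
            oracle = brute_sa_beta(coil, params, template)
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_bounds_invariant(self, random_structure_20):
        pairs = enumerate_segment_pairs(random_structure_20)
        res = sa_beta(random_structure_20.coords, pairs)
        assert 0.0 <= res.total <= res.n_segments

    def test_empty_pairs_rejected(self, random_structure_20):
        pairs = pairs_from_triples(random_structure_20, [])
        with pytest.raises(ValueError):
            sa_beta(random_structure_20.coords, pairs)

    def test_disordering_more_pairs_never_increases_total(self):
        structure, info = make_sheet(4, 6)
        pairs = pairs_from_triples(structure, info.designed_pairs)
        rng = np.random.default_rng(13)
        totals = []
        base = structure.coords
        kicks = {}
        strands = info.strand_ranges
        for k in range(len(strands)):
            totals.append(sa_beta(
                apply_dihedral_kicks(structure, base, kicks) if kicks else base,
                pairs).total)
            lo, hi = strands[k]
            for r in range(lo, hi + 1):
                kicks[r] = tuple(90 * rng.standard_normal(2))
        totals.append(sa_beta(apply_dihedral_kicks(structure, base, kicks),
                              pairs).total)
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))


class TestSaBetaSeries:
    def test_static_sheet_constant_n(self, sheet_4x6):
        structure, info = sheet_4x6
        pairs = pairs_from_triples(structure, info.designed_pairs)
        ens = Ensemble(topology=structure,
                       frames=[structure.coords.copy() for _ in range(6)])
        series = sa_beta_series(ens, pairs, n_blocks=3)
        np.testing.assert_allclose(series.totals, len(pairs), atol=1e-9)
        assert series.stats.std == pytest.approx(0.0, abs=1e-12)

    def test_uniform_attribution_gives_equal_blades(self):
        structure, info = make_propeller()
        ens = Ensemble(topology=structure, frames=[structure.coords.copy(),
                                                   structure.coords.copy()])
        pairs = pairs_from_triples(structure, info.designed_pairs)
        series = sa_beta_series(ens, pairs, scheme=info.scheme, n_blocks=2)
        values = [series.blade_stats[b].mean for b in info.scheme.names]
        assert max(values) - min(values) < 1e-9

    def test_disorder_localizes_to_its_blade(self):
        structure, info = make_propeller()
        blade = info.scheme.names[2]
        lo, hi = info.blade_strand_ranges[blade][1]
        wt, _ = make_ensemble(EnsembleSpec(
            base=__import__("kelchdyn.synthetic_data", fromlist=["PropellerBase"]).PropellerBase(),
            jitter_sigma=0.1, n_frames=10, seed=20))
        mut, _ = make_ensemble(EnsembleSpec(
            base=__import__("kelchdyn.synthetic_data", fromlist=["PropellerBase"]).PropellerBase(),
            jitter_sigma=0.1, n_frames=10, seed=21,
            disorder=[DisorderSpec(start=lo, end=hi, magnitude=90.0)]))
        pairs = enumerate_segment_pairs(structure)
        wt_series = sa_beta_series(wt, pairs, scheme=info.scheme, n_blocks=2)
        mut_series = sa_beta_series(mut, pairs, scheme=info.scheme, n_blocks=2)
        deltas = {b: mut_series.blade_stats[b].mean - wt_series.blade_stats[b].mean
                  for b in info.scheme.names}
        assert deltas[blade] < -0.05
        for b in info.scheme.names:
            if b != blade:
                assert abs(deltas[b]) < 0.02


class TestDeltaSaBeta:
    def test_identical_series(self):
        rng = np.random.default_rng(14)
        x = rng.normal(10, 0.1, 50)
        delta, sigma = delta_sa_beta(x, x)
        assert delta == 0.0
        assert sigma < 0.2

    def test_constant_offset(self):
        rng = np.random.default_rng(15)
        wt = rng.normal(10, 0.05, 50)
        delta, _sigma = delta_sa_beta(wt - 2.0, wt)
        assert delta == pytest.approx(-2.0, abs=1e-12)

    def test_designed_destabilization_exceeds_two_points(self):
        structure, info = make_sheet(4, 8)
        pairs = pairs_from_triples(structure, info.designed_pairs)
        lo, hi = info.strand_ranges[1]
        spec = dict(base=SheetBase(n_strands=4, strand_len=8),
                    jitter_sigma=0.15, n_frames=10)
        wt, _ = make_ensemble(EnsembleSpec(seed=30, **spec))
        mut, truth = make_ensemble(EnsembleSpec(
            seed=31, disorder=[DisorderSpec(start=lo, end=hi, magnitude=100.0)],
            **spec))
        wt_totals = sa_beta_series(wt, pairs, n_blocks=2).totals
        mut_totals = sa_beta_series(mut, pairs, n_blocks=2).totals
        delta, _ = delta_sa_beta(mut_totals, wt_totals, n_blocks=2)
        # strand 2 participates in >= 3 designed pairs, all destroyed
        assert delta < -2.0


@given(st.floats(0.0, 10.0), st.floats(0.0, 10.0))
def test_switching_monotone_pairwise(r1, r2):
    """s(r) never increases with r."""
    s1, s2 = switching_score(r1), switching_score(r2)
    if r1 < r2:
        assert s1 >= s2
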