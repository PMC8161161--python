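"""Superposition, deviation metrics, block statistics, blade averaging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from kelchdyn.geometry import (block_stats, kabsch_superpose, moving_rmsd,
                               per_residue_blade_average, radius_of_gyration,
                               rmsd_series, rmsf)
from kelchdyn.structure_io import Ensemble, kelch_blade_scheme
from kelchdyn.synthetic_data import make_sheet

from oracles import qcp_rmsd


def _cloud(rng, n=10):
    return rng.normal(size=(n, 3)) * 3.0


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        x = _cloud(rng)
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = _cloud(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(y, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.apply(y), x, atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(200):
            a, b = _cloud(rng), _cloud(rng)
            worst = max(worst, abs(kabsch_superpose(a, b).rmsd - qcp_rmsd(a, b)))
        assert worst < 1e-8

    def test_rejects_reflection(self):
        # mirrored cloud: optimal orthogonal map would be a reflection
        rng = np.random.default_rng(3)
        x = _cloud(rng, 20)
        y = x * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(y, x)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1

    @pytest.mark.parametrize("bad", [
        (np.zeros((2, 3)), np.zeros((2, 3))),
        (np.zeros((4, 3)), np.zeros((5, 3))),
    ])
    def test_size_errors(self, bad):
        with pytest.raises(ValueError):
            kabsch_superpose(*bad)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line)


def _static_ensemble(coords, n):
    from kelchdyn.synthetic_data import make_sheet
    structure, _ = make_sheet(2, 3)
    return Ensemble(topology=structure, frames=[coords.copy() for _ in range(n)])


class TestRmsdSeries:
    def setup_method(self):
        self.structure, _ = make_sheet(2, 3)
        self.sel = np.arange(self.structure.n_atoms)

    def test_static_is_zero(self):
        ens = _static_ensemble(self.structure.coords, 4)
        np.testing.assert_allclose(
            rmsd_series(ens, ens.frames[0], self.sel), 0.0, atol=1e-9)

    def test_fit_removes_rigid_motion(self):
        rng = np.random.default_rng(4)
        base = self.structure.coords
        frames = []
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(base @ rot.T + rng.uniform(-10, 10, 3))
        ens = Ensemble(topology=self.structure, frames=frames)
        np.testing.assert_allclose(rmsd_series(ens, base, self.sel), 0.0,
                                   atol=1e-9)

    def test_jitter_mean_matches_direct_oracle(self):
        rng = np.random.default_rng(5)
        base = self.structure.coords
        frames = [base + rng.normal(0, 0.2, base.shape) for _ in range(200)]
        ens = Ensemble(topology=self.structure, frames=frames)
        series = rmsd_series(ens, base, self.sel)
        oracle = np.array([qcp_rmsd(f, base) for f in frames])
        np.testing.assert_allclose(series, oracle, atol=1e-8)

    def test_empty_selection_rejected(self):
        ens = _static_ensemble(self.structure.coords, 2)
        with pytest.raises(ValueError):
            rmsd_series(ens, ens.frames[0], np.array([], dtype=int))


class TestMovingRmsd:
    def setup_method(self):
        self.structure, _ = make_sheet(2, 3)
        self.sel = np.arange(self.structure.n_atoms)

    def test_static_lag1_zeros(self):
        ens = _static_ensemble(self.structure.coords, 5)
        np.testing.assert_allclose(moving_rmsd(ens, 1, self.sel), 0.0, atol=1e-12)

    def test_max_lag_single_element(self):
        rng = np.random.default_rng(6)
        frames = [self.structure.coords + rng.normal(0, 0.3, (30, 3))
                  for _ in range(4)]
        ens = Ensemble(topology=self.structure, frames=frames)
        out = moving_rmsd(ens, 3, self.sel)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(qcp_rmsd(frames[3], frames[0]), abs=1e-10)

    @pytest.mark.parametrize("lag", [1, 10])
    def test_matches_pairwise_oracle(self, lag):
        rng = np.random.default_rng(7)
        frames = [self.structure.coords + rng.normal(0, 0.2, (30, 3))
                  for _ in range(20)]
        ens = Ensemble(topology=self.structure, frames=frames)
        out = moving_rmsd(ens, lag, self.sel)
        oracle = [qcp_rmsd(frames[t + lag], frames[t])
                  for t in range(20 - lag)]
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_lag_out_of_range(self):
        ens = _static_ensemble(self.structure.coords, 3)
        with pytest.raises(ValueError):
            moving_rmsd(ens, 3, self.sel)
        with pytest.raises(ValueError):
            moving_rmsd(ens, 0, self.sel)


class TestRmsf:
    def test_static_is_zero(self):
        structure, _ = make_sheet(2, 3)
        ens = _static_ensemble(structure.coords, 3)
        values = rmsf(ens)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in values.values())

    def test_single_frame_rejected(self):
        structure, _ = make_sheet(2, 3)
        ens = _static_ensemble(structure.coords, 1)
        with pytest.raises(ValueError):
            rmsf(ens)

    def test_jittered_residue_recovers_sigma_sqrt3(self):
        # large frozen scaffold keeps fit compensation negligible
        structure, _ = make_sheet(4, 10)
        rng = np.random.default_rng(8)
        target = structure.residues[5]
        idx = structure.residue_atom_indices(*target)
        base = structure.coords
        frames = [base.copy()]  # clean initial reference frame
        for _ in range(1000):
            f = base.copy()
            f[idx] += rng.normal(0, 0.3, (len(idx), 3))
            frames.append(f)
        ens = Ensemble(topology=structure, frames=frames)
        values = rmsf(ens)
        expected = 0.3 * np.sqrt(3)
        assert values[target] == pytest.approx(expected, rel=0.1)
        others = [v for k, v in values.items() if k != target]
        assert max(others) < 0.2 * expected

    def test_mean_vs_initial_reference_on_two_state_flip(self):
        # symmetric flip of amplitude a: fluctuation about the mean is a,
        # while the initial-position reference mixes 0 and 2a displacements
        structure, _ = make_sheet(4, 10)
        target = structure.residues[5]
        idx = structure.residue_atom_indices(*target)
        a = 0.8
        base = structure.coords
        frames = []
        for t in range(200):
            f = base.copy()
            f[idx, 0] += a if t % 2 == 0 else -a
            frames.append(f)
        ens = Ensemble(topology=structure, frames=frames)
        about_mean = rmsf(ens, reference_mode="mean")[target]
        about_initial = rmsf(ens, reference_mode="initial")[target]
        assert about_mean == pytest.approx(a, rel=0.05)
        # frames alternate between displacement 0 and 2a about the initial
        assert about_initial == pytest.approx(a * np.sqrt(2), rel=0.05)


class TestRadiusOfGyration:
    def test_single_atom(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_matches_definition(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(50, 3)) * 4
        masses = rng.uniform(1, 16, 50)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        expected = np.sqrt((masses * ((coords - com) ** 2).sum(1)).sum()
                           / masses.sum())
        assert radius_of_gyration(coords, masses) == pytest.approx(
            expected, abs=1e-12)


class TestBlockStats:
    def test_constant_series(self):
        out = block_stats([3.0] * 10, 5)
        assert (out.mean, out.std) == (3.0, 0.0)

    def test_two_blocks_arithmetic(self):
        out = block_stats([1.0, 2.0, 3.0, 4.0], 2)
        assert out.mean == pytest.approx(2.5)
        assert out.std == pytest.approx(np.std([1.5, 3.5], ddof=1))

    def test_ar1_series_matches_direct_oracle(self):
        rng = np.random.default_rng(10)
        x = np.zeros(5000)
        for t in range(1, 5000):
            x[t] = 0.9 * x[t - 1] + rng.normal()
        out = block_stats(x, 5)
        blocks = np.array_split(x, 5)
        means = np.array([b.mean() for b in blocks])
        assert out.mean == pytest.approx(means.mean(), abs=1e-12)
        assert out.std == pytest.approx(means.std(ddof=1), abs=1e-12)

    def test_equal_blocks_mean_is_plain_mean(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        assert block_stats(x, 5).mean == pytest.approx(x.mean(), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            block_stats([1.0, 2.0], 3)
        with pytest.raises(ValueError):
            block_stats([1.0, 2.0, 3.0], 1)


class TestBladeAverage:
    def test_uniform_values_normalize_to_one(self):
        scheme = kelch_blade_scheme()
        values = {r: 1.0 for r in range(325, 610)}
        out = per_residue_blade_average(values, scheme)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_single_residue_spike(self):
        scheme = kelch_blade_scheme()
        values = {r: 0.0 for r in range(325, 610)}
        values[430] = 47.0  # one blade-III residue; blade III has 47 residues
        out = per_residue_blade_average(values, scheme)
        assert out["III"] == pytest.approx(1.0)
        assert all(out[b] == 0.0 for b in ("I", "II", "IV", "V", "VI"))

    def test_matches_direct_mean(self):
        scheme = kelch_blade_scheme()
        rng = np.random.default_rng(12)
        values = {r: float(rng.normal()) for r in range(325, 610)}
        out = per_residue_blade_average(values, scheme)
        for name in scheme.names:
            members = scheme.residues(name)
            assert out[name] == pytest.approx(
                np.mean([values[r] for r in members]))

    def test_uncovered_blade_is_an_error(self):
        scheme = kelch_blade_scheme()
        with pytest.raises(ValueError, match="blade"):
            per_residue_blade_average({326: 1.0}, scheme)


@given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60),
       st.integers(2, 4))
def test_block_mean_between_extremes(series, n_blocks):
    """Block-averaged mean always lies within the series range."""
    if n_blocks > len(series):
        n_blocks = len(series)
    out = block_stats(series, n_blocks)
    assert min(series) - 1e-9 <= out.mean <= max(series) + 1e-9
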