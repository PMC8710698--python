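"""Rg, end-to-end, SASA, solvation, PMF and convergence machinery."""

import numpy as np
import pytest

from phf6agg._geom import random_rotation
from phf6agg.model import Atom, Frame, Residue, Topology, Trajectory, ValidationError
from phf6agg.observables import (
    GAS_CONSTANT_KCAL,
    convergence_report,
    end_to_end_distance,
    jensen_shannon_divergence,
    pmf2d,
    radius_of_gyration,
    shrake_rupley_sasa,
)
from phf6agg.synthetic import EnsembleSpec, build_labeled_ensemble, build_strand


def _bare_topology(elements, radii):
    """Topology of free-floating atoms in one pseudo-residue (for the
    closed-form SASA checks)."""
    atoms = [
        Atom(index=i, name=f"{el}{i}", element=el, residue_index=0,
             is_backbone=True, is_water=False, vdw_radius=r)
        for i, (el, r) in enumerate(zip(elements, radii))
    ]
    res = Residue(name="VAL", seq_label=1, atoms=atoms, chain_index=0)
    res.has_atom = lambda name: True  # bypass backbone completeness check
    topo = Topology.__new__(Topology)
    topo.chains = [[res]]
    topo.waters = []
    topo._index_atoms()
    return topo


class TestRg:
    def test_two_unit_mass_points(self):
        topo = _bare_topology(["H", "H"], [0.12, 0.12])
        frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        rg = radius_of_gyration(frame, topo, selection=np.array([0, 1]))
        assert rg == pytest.approx(0.5, abs=1e-12)

    def test_single_atom_is_zero(self):
        topo = _bare_topology(["C"], [0.17])
        frame = Frame(np.array([[1.0, 2.0, 3.0]]))
        assert radius_of_gyration(frame, topo, selection=np.array([0])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_definition_on_random_frames(self, rng):
        topo = _bare_topology(["C"] * 100, [0.17] * 100)
        for _ in range(5):
            X = rng.normal(size=(100, 3))
            frame = Frame(X)
            m = topo.mass
            com = np.average(X, axis=0, weights=m)
            expected = np.sqrt(np.average(np.sum((X - com) ** 2, axis=1), weights=m))
            assert radius_of_gyration(frame, topo) == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        topo = _bare_topology(["C"] * 20, [0.17] * 20)
        X = rng.normal(size=(20, 3))
        R = random_rotation(rng)
        a = radius_of_gyration(Frame(X), topo)
        b = radius_of_gyration(Frame(X @ R.T + 5.0), topo)
        assert a == pytest.approx(b, abs=1e-12)


class TestEndToEnd:
    def test_extended_strand_length(self):
        topo, frame = build_strand()
        d = end_to_end_distance(topo.chains[0], frame)
        assert 1.55 <= d <= 1.80

    def test_coil_is_more_compact_than_strand(self):
        from phf6agg.synthetic import build_random_coil

        topo_s, frame_s = build_strand()
        ext = end_to_end_distance(topo_s.chains[0], frame_s)
        vals = []
        for seed in range(8):
            topo_c, frame_c = build_random_coil(1, seed=seed)
            vals.append(end_to_end_distance(topo_c.chains[0], frame_c))
        assert np.mean(vals) < ext

    def test_single_residue_chain_raises(self):
        topo, frame = build_strand(sequence=("VAL",))
        with pytest.raises(ValidationError):
            end_to_end_distance(topo.chains[0], frame)


class TestSASA:
    def test_isolated_atom_matches_analytic_sphere(self):
        topo = _bare_topology(["X"], [0.15])
        frame = Frame(np.zeros((1, 3)))
        _, _, total = shrake_rupley_sasa(frame, topo, probe=0.14, n_points=960)
        analytic = 4 * np.pi * 0.29**2
        assert abs(total - analytic) / analytic < 0.01

    def test_two_spheres_match_cap_formula(self):
        # two identical atoms at distance d: each loses a spherical cap of
        # area 2*pi*R*h with h = R - d/2 (equal radii)
        R0, probe, d = 0.15, 0.14, 0.25
        R = R0 + probe
        topo = _bare_topology(["X", "X"], [R0, R0])
        frame = Frame(np.array([[0.0, 0, 0], [d, 0, 0]]))
        _, _, total = shrake_rupley_sasa(frame, topo, probe=probe, n_points=2000)
        h = R - d / 2
        analytic = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
        assert abs(total - analytic) / analytic < 0.02

    def test_buried_atom_has_zero_area(self):
        topo = _bare_topology(["X", "X"], [0.05, 0.4])
        frame = Frame(np.zeros((2, 3)))
        per_atom, _, _ = shrake_rupley_sasa(frame, topo, probe=0.14)
        assert per_atom[0] == 0.0

    def test_approaching_chain_only_reduces_area(self):
        topo, frame = build_strand()
        base = shrake_rupley_sasa(frame, topo, n_points=240)[2]
        topo2, frame2, _ = __import__("phf6agg.synthetic", fromlist=["build_sheet"]).build_sheet(2)
        per_atom, _, _ = shrake_rupley_sasa(frame2, topo2, n_points=240)
        half = per_atom[: len(per_atom) // 2].sum()
        assert half < base


class TestPMF:
    def test_two_bin_ratio_gives_rt_ln3(self):
        x = np.array([0.0, 0.0, 0.0, 1.0])
        y = np.zeros(4)
        grid = pmf2d(x, y, temperature=310.0, bins=(np.array([-0.5, 0.5, 1.5]), np.array([-0.5, 0.5])))
        vals = grid.values.ravel()
        delta = vals.max() - vals.min()
        expected = GAS_CONSTANT_KCAL * 310.0 * np.log(3.0)
        assert delta == pytest.approx(expected, abs=1e-9)
        assert vals.min() == 0.0

    def test_uniform_histogram_is_flat_zero(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        grid = pmf2d(x, y, bins=(2, 2))
        assert np.allclose(grid.values, 0.0)

    def test_count_doubling_invariance(self):
        x = np.array([0, 0, 1, 1, 1, 2])
        y = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        g1 = pmf2d(x, y, bins=(3, 2))
        g2 = pmf2d(np.repeat(x, 2), np.repeat(y, 2), bins=(3, 2))
        fin = np.isfinite(g1.values)
        assert np.array_equal(fin, np.isfinite(g2.values))
        assert np.allclose(g1.values[fin], g2.values[fin])

    def test_empty_bins_are_not_numeric(self):
        x = np.array([0.0, 1.0])
        y = np.array([0.0, 1.0])
        grid = pmf2d(x, y, bins=(2, 2))
        assert np.isinf(grid.values[0, 1]) and np.isinf(grid.values[1, 0])

    def test_min_shift_against_manual_formula(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, 200).astype(float)
        y = rng.uniform(1.0, 2.0, 200)
        grid = pmf2d(x, y, temperature=310.0)
        H, _, _ = np.histogram2d(x, y, bins=(grid.x_edges, grid.y_edges))
        P = H / H.sum()
        with np.errstate(divide="ignore"):
            manual = -GAS_CONSTANT_KCAL * 310.0 * np.log(P)
        manual -= manual[P > 0].min()
        fin = P > 0
        assert np.allclose(grid.values[fin], manual[fin], atol=1e-12)


class TestConvergence:
    def test_identical_windows_have_zero_divergence(self):
        spec = EnsembleSpec(n_frames=30, seed=9)
        traj, _ = build_labeled_ensemble(spec)
        t_max = traj.frames[-1].time
        rep = convergence_report(traj, ((0.0, t_max), (0.0, t_max)))
        assert (rep.metrics["js_divergence"] == 0.0).all()
        assert (rep.metrics["max_abs_diff"] == 0.0).all()
        assert rep.is_converged()

    def test_contrasting_windows_are_flagged(self):
        """Sheet-rich first half vs coil-only second half: per-residue
        beta-sheet probabilities differ by far more than 0.2."""
        sheet_spec = EnsembleSpec(n_frames=25, seed=3, weights={"sheet": 1.0})
        coil_spec = EnsembleSpec(n_frames=25, seed=4, weights={"coil": 1.0})
        ts, _ = build_labeled_ensemble(sheet_spec)
        tc, _ = build_labeled_ensemble(coil_spec)
        frames = []
        for k, f in enumerate(ts.frames + tc.frames):
            f2 = f.copy()
            f2.time = float(k * 100)
            frames.append(f2)
        traj = Trajectory(ts.topology, frames)
        rep = convergence_report(traj, ((0.0, 2400.0), (2500.0, 4900.0)))
        assert rep.metrics.loc["ss_beta_per_residue", "max_abs_diff"] > 0.2
        assert not rep.is_converged()

    def test_overlapping_windows_rejected(self):
        spec = EnsembleSpec(n_frames=10, seed=1)
        traj, _ = build_labeled_ensemble(spec)
        with pytest.raises(ValidationError):
            convergence_report(traj, ((0.0, 500.0), (400.0, 900.0)))

    def test_js_divergence_basics(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        assert jensen_shannon_divergence(p, p) == 0.0
        assert jensen_shannon_divergence(p, q) == pytest.approx(np.log(2.0))
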