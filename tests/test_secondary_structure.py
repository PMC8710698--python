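"""Kabsch-Sander assignment, category statistics and strand lengths."""

import numpy as np
import pytest

from phf6agg._geom import random_rotation
from phf6agg.model import Frame, Trajectory, ValidationError
from phf6agg.secondary_structure import (
    CATEGORIES,
    KS_ENERGY_CUTOFF,
    SSMatrix,
    assign_secondary_structure,
    backbone_hbond_energy,
    compute_ss_matrix,
    ss_statistics,
    strand_length_distribution,
)
from phf6agg.synthetic import build_random_coil, build_sheet, build_strand


class TestHBondEnergy:
    def test_sheet_pair_is_bonded(self, anti_sheet2):
        topo, frame, _ = anti_sheet2
        std = topo.standard_residues()
        best = min(
            backbone_hbond_energy(d, a, frame)
            for d in std for a in std
            if d.chain_index != a.chain_index
        )
        assert best < KS_ENERGY_CUTOFF

    def test_distant_residues_have_negligible_energy(self):
        topo, frame, _ = build_sheet(2, inter_strand_spacing=3.0)
        std = topo.standard_residues()
        d = [r for r in std if r.chain_index == 0][2]
        a = [r for r in std if r.chain_index == 1][2]
        assert abs(backbone_hbond_energy(d, a, frame)) < 0.1

    def test_missing_backbone_raises(self, anti_sheet2):
        topo, frame, _ = anti_sheet2
        std = topo.standard_residues()
        broken = std[0]
        removed = [a for a in broken.atoms if a.name != "O"]
        orig = broken.atoms
        broken.atoms = removed
        try:
            with pytest.raises(ValidationError):
                backbone_hbond_energy(std[6], broken, frame)
        finally:
            broken.atoms = orig


class TestAssignment:
    def test_sheet_interiors_are_strand(self, anti_sheet2):
        topo, frame, _ = anti_sheet2
        codes = assign_secondary_structure(frame, topo)
        for chain in (codes[1:5], codes[7:11]):
            assert set(chain) == {"E"}

    def test_isolated_strand_has_no_e(self):
        topo, frame = build_strand()
        codes = assign_secondary_structure(frame, topo)
        assert "E" not in codes and "B" not in codes

    def test_rotation_translation_invariance(self, parallel_sheet12, rng):
        topo, frame, _ = parallel_sheet12
        ref = assign_secondary_structure(frame, topo)
        R = random_rotation(rng)
        moved = Frame(frame.coords @ R.T + rng.uniform(-3, 3, 3), box=None)
        assert np.array_equal(assign_secondary_structure(moved, topo), ref)

    def test_short_chain_is_all_coil(self):
        topo, frame = build_strand(sequence=("VAL", "GLN"))
        assert list(assign_secondary_structure(frame, topo)) == ["C", "C"]


class TestStatistics:
    def test_probabilities_sum_to_one(self, small_mixture):
        traj, _ = small_mixture
        ssm = compute_ss_matrix(traj)
        stats = ss_statistics(ssm)
        assert stats["overall"].sum() == pytest.approx(1.0, abs=1e-12)
        rows = stats["per_residue"].sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-12)

    def test_all_coil_matrix(self):
        ssm = SSMatrix(
            codes=np.full((3, 6), "C"),
            chain=np.zeros(6, dtype=int),
            pos=np.arange(6),
            seq_label=np.arange(275, 281),
        )
        stats = ss_statistics(ssm)
        assert stats["overall"]["coil"] == 1.0
        assert stats["overall"]["beta_sheet"] == 0.0

    def test_planted_sheet_rate_recovered(self):
        """Overall E probability tracks (sheet-frame rate) x (E fraction
        within a sheet frame)."""
        from phf6agg.synthetic import EnsembleSpec, build_labeled_ensemble

        spec = EnsembleSpec(
            n_frames=120, seed=5, weights={"sheet": 0.3, "coil": 0.7}
        )
        traj, truths = build_labeled_ensemble(spec)
        ssm = compute_ss_matrix(traj)
        overall = ss_statistics(ssm)["overall"]["beta_sheet"]
        sheet_frames = [i for i, g in enumerate(truths) if g.kind == "sheet"]
        in_sheet_e = np.mean(ssm.codes[sheet_frames] == "E")
        expected = len(sheet_frames) / len(traj) * in_sheet_e
        assert overall == pytest.approx(expected, abs=0.02)


class TestStrandLengths:
    def _matrix(self, rows, n_chains=1):
        codes = np.array(rows)
        ncol = codes.shape[1]
        per = ncol // n_chains
        return SSMatrix(
            codes=codes,
            chain=np.repeat(np.arange(n_chains), per),
            pos=np.tile(np.arange(per), n_chains),
            seq_label=np.tile(np.arange(275, 275 + per), n_chains),
        )

    def test_fully_extended_chain(self):
        ssm = self._matrix([list("EEEEEE")])
        dist = strand_length_distribution(ssm)
        assert dist.to_dict() == {6: 1.0}

    def test_planted_three_residue_strands(self):
        ssm = self._matrix([list("CEEECC") * 3], n_chains=3)
        dist = strand_length_distribution(ssm)
        assert list(dist.index) == [3]
        assert dist[3] == pytest.approx(1.0)

    def test_no_strands_gives_empty_distribution(self):
        ssm = self._matrix([list("CCTTSC")])
        assert strand_length_distribution(ssm).empty

    def test_run_not_merged_across_chains(self):
        # E at the end of chain 0 and start of chain 1 are separate strands
        ssm = self._matrix([list("CCCCEE" "EECCCC")], n_chains=2)
        dist = strand_length_distribution(ssm, per_chain=False)
        assert dist.to_dict() == {2: 1.0}


class TestReferenceAgreement:
    def test_matches_mdtraj_dssp_on_synthetic_frames(self, tmp_path):
        """E/B/H agreement with the reference DSSP implementation >= 95%
        over a mixed panel of sheets, barrels and coils."""
        mdtraj = pytest.importorskip("mdtraj")
        from phf6agg.io import write_structure
        from phf6agg.synthetic import build_barrel

        panel = []
        panel.append(build_sheet(12, parallel=True)[:2])
        panel.append(build_sheet(6, parallel=False)[:2])
        panel.append(build_sheet(2, parallel=False)[:2])
        for n in (4, 5, 6, 7, 8):
            panel.append(build_barrel(n)[:2])
        for seed in range(12):
            panel.append(build_random_coil(12, seed=seed))
        assert len(panel) >= 20
        agree, total = 0, 0
        for k, (topo, frame) in enumerate(panel):
            ours = assign_secondary_structure(frame, topo)
            path = tmp_path / f"frame{k}.pdb"
            write_structure(topo, frame, path)
            t = mdtraj.load(str(path))
            dssp = mdtraj.compute_dssp(t, simplified=False)[0]
            keep = [r.name not in ("ACE", "NH2", "NME", "HOH") for r in t.topology.residues]
            ref = np.array([c for c, m in zip(dssp, keep) if m])
            ref[ref == " "] = "C"
            ref[ref == "NA"] = "C"
            assert len(ref) == len(ours)
            focus = np.isin(ours, list("EBH")) | np.isin(ref, list("EBH"))
            agree += int(np.sum((ours == ref)[focus]))
            total += int(np.sum(focus))
        assert agree / total >= 0.95


class TestTemperatureSeries:
    def test_one_value_per_replica_label(self):
        from phf6agg.secondary_structure import category_vs_temperature
        from phf6agg.synthetic import EnsembleSpec, build_labeled_ensemble

        trajs = {}
        for k, (temp, w) in enumerate([(310.0, 0.6), (350.0, 0.3), (400.0, 0.0)]):
            spec = EnsembleSpec(n_frames=10, seed=50 + k,
                                weights={"sheet": w, "coil": 1.0 - w})
            trajs[temp], _ = build_labeled_ensemble(spec)
        series = category_vs_temperature(trajs)
        assert list(series.index) == [310.0, 350.0, 400.0]
        # sheet weight decreases with the label, so must the probability
        assert series[310.0] > series[350.0] > series[400.0]
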