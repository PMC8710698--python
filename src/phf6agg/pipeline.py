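"""Configuration-driven end-to-end analysis runner.

Reproduces the full oligomer-analysis battery on one or two trajectories
(e.g. wild-type vs K280-acetylated): secondary-structure statistics,
Daura clustering with per-cluster SS, strand-length / oligomer-size /
barrel-size distributions, the (H-bond count, Rg) free-energy surface,
SASA and solvation profiles, H-bond PDFs, residue-pair H-bond and contact
maps with occupancies, plus system difference maps and an optional
two-window convergence report.  All outputs are CSV/JSON tables under the
configured output directory, with a manifest recording the software
version, configuration hash and per-stage log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import barrel_size_distribution, oligomer_size_distribution
from .clustering import cluster_ss_profile, daura_cluster
from .interactions import (
    ContactCriteria,
    HBondCriteria,
    contact_residue_map,
    difference_map,
    hbond_count_series,
    hbond_occupancy,
    hbond_residue_map,
)
from .io import load_structure, load_trajectory, write_structure
from .model import Trajectory, ValidationError
from .observables import (
    ANALYSIS_TEMPERATURE,
    convergence_report,
    end_to_end_distance,
    pmf2d,
    radius_of_gyration,
    shrake_rupley_sasa,
    solvation_count,
)
from .secondary_structure import (
    compute_ss_matrix,
    ss_statistics,
    strand_length_distribution,
)

log = logging.getLogger("phf6agg")

#: donor/acceptor pairs whose occupancies are tabulated (the published
#: N279/K280 sidechain-mainchain and sidechain-sidechain H-bonds)
OCCUPANCY_PAIRS = [
    ("N279@ND2", "K280@O"),
    ("K280@N", "N279@OD1"),
    ("K280@NZ", "N279@OD1"),
    ("N279@ND2", "K280@OI2"),
]


@dataclass
class RunConfig:
    systems: dict[str, dict[str, str]]
    out_dir: str = "results"
    window: tuple[float, float] | None = None
    temperature: float = ANALYSIS_TEMPERATURE
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    contact: ContactCriteria = field(default_factory=ContactCriteria)
    cluster_cutoff: float = 0.45
    seed: int = 0
    sasa_stride: int = 10
    sasa_points: int = 240
    convergence_windows: tuple[tuple[float, float], tuple[float, float]] | None = None
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        systems = raw.get("systems")
        if not systems:
            raise ValidationError("config must define at least one system")
        if base is not None:
            systems = {
                name: {k: str((base / v)) if not Path(v).is_absolute() else v
                       for k, v in sys.items()}
                for name, sys in systems.items()
            }
        for name, sys in systems.items():
            for key in ("topology", "trajectory"):
                if key not in sys:
                    raise ValidationError(f"system {name!r} lacks {key!r}")
                if not Path(sys[key]).exists():
                    raise ValidationError(f"{key} path {sys[key]!r} does not exist")
        hb = HBondCriteria(**raw.get("hbond", {}))
        ct = ContactCriteria(**raw.get("contact", {}))
        cutoff = float(raw.get("cluster_cutoff", 0.45))
        if cutoff <= 0:
            raise ValidationError("cluster cutoff must be positive")
        window = raw.get("window")
        conv = raw.get("convergence_windows")
        return cls(
            systems=systems,
            out_dir=str(raw.get("out_dir", "results")),
            window=tuple(window) if window else None,
            temperature=float(raw.get("temperature", ANALYSIS_TEMPERATURE)),
            hbond=hb,
            contact=ct,
            cluster_cutoff=cutoff,
            seed=int(raw.get("seed", 0)),
            sasa_stride=int(raw.get("sasa_stride", 10)),
            sasa_points=int(raw.get("sasa_points", 240)),
            convergence_windows=tuple(map(tuple, conv)) if conv else None,
        )

    def digest(self) -> str:
        payload = {
            "systems": self.systems,
            "window": self.window,
            "temperature": self.temperature,
            "hbond": (self.hbond.d_no_max, self.hbond.angle_min),
            "contact": (self.contact.d_carbon, self.contact.d_other),
            "cluster_cutoff": self.cluster_cutoff,
            "seed": self.seed,
            "version": __version__,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_system(cfg: RunConfig, name: str) -> Trajectory:
    sys = cfg.systems[name]
    topo, _ = load_structure(sys["topology"])
    traj = load_trajectory(sys["trajectory"], topo, window=cfg.window)
    return traj


def _analyze_system(cfg: RunConfig, name: str, out: Path) -> dict:
    t_start = time.time()
    results: dict = {"name": name}
    traj = _load_system(cfg, name)
    topo = traj.topology
    sysdir = out / name
    sysdir.mkdir(parents=True, exist_ok=True)
    log.info("[%s] %d frames, %d chains", name, len(traj), topo.n_chains)

    # -- secondary structure -------------------------------------------------
    t0 = time.time()
    ssm = compute_ss_matrix(traj)
    stats = ss_statistics(ssm)
    stats["overall"].to_csv(sysdir / "ss_overall.csv", header=["probability"])
    stats["per_residue"].to_csv(sysdir / "ss_per_residue.csv")
    strand_length_distribution(ssm).to_csv(sysdir / "strand_length.csv")
    results["ss_overall"] = stats["overall"].to_dict()
    results["ss_per_residue_beta"] = stats["per_residue"]["beta_sheet"].to_dict()
    log.info("[%s] secondary structure done (%.1fs)", name, time.time() - t0)

    # -- clustering ----------------------------------------------------------
    t0 = time.time()
    cl = daura_cluster(traj, cutoff=cfg.cluster_cutoff)
    pd.DataFrame(
        {"frame": np.arange(len(traj)), "cluster": cl.assignments}
    ).to_csv(sysdir / "cluster_assignments.csv", index=False)
    with open(sysdir / "cluster_populations.json", "w") as f:
        json.dump(
            {
                "cutoff_nm": cl.cutoff,
                "n_clusters": cl.n_clusters,
                "populations": cl.populations.tolist(),
                "centers": [int(c) for c in cl.centers],
            },
            f,
            indent=1,
        )
    cluster_ss_profile(cl, ssm).to_csv(sysdir / "cluster_ss_profile.csv")
    write_structure(topo, traj.frames[cl.centers[0]], sysdir / "top_cluster_center.pdb")
    results["n_clusters"] = cl.n_clusters
    log.info("[%s] clustering done: %d clusters (%.1fs)", name, cl.n_clusters, time.time() - t0)

    # -- assembly ------------------------------------------------------------
    t0 = time.time()
    for weighting in ("component", "chain"):
        oligomer_size_distribution(
            traj, cfg.contact, weighting=weighting
        ).to_csv(sysdir / f"oligomer_sizes_{weighting}.csv")
    barrels = barrel_size_distribution(traj)
    barrels.to_csv(sysdir / "barrel_sizes.csv")
    results["barrel_sizes"] = barrels.to_dict()
    log.info("[%s] assembly done (%.1fs)", name, time.time() - t0)

    # -- interactions --------------------------------------------------------
    t0 = time.time()
    counts, pdf = hbond_count_series(traj, criteria=cfg.hbond)
    pdf.to_csv(sysdir / "hbond_total_pdf.csv")
    results["hbond_mean"] = float(np.mean(counts)) if counts.size else 0.0
    for cls in ("MC-MC", "MC-SC", "SC-SC"):
        _, cpdf = hbond_count_series(traj, cls=cls, criteria=cfg.hbond)
        cpdf.to_csv(sysdir / f"hbond_{cls.replace('-', '')}_pdf.csv")
        hmap = hbond_residue_map(traj, cls=cls, criteria=cfg.hbond)
        hmap.to_csv(sysdir / f"hbond_map_{cls.replace('-', '')}.csv")
        results[f"hbond_map_{cls}"] = hmap
    occ_rows = []
    for don, acc in OCCUPANCY_PAIRS:
        try:
            occ = hbond_occupancy(traj, don, acc, criteria=cfg.hbond)
        except ValidationError:
            continue  # pair not in this system (e.g. OI2 in the wild type)
        occ_rows.append({"donor": don, "acceptor": acc, **occ})
    pd.DataFrame(occ_rows).to_csv(sysdir / "hbond_occupancy.csv", index=False)
    for cls in ("MC-SC", "SC-SC", "any"):
        cmap = contact_residue_map(traj, cls=cls, criteria=cfg.contact)
        cmap.to_csv(sysdir / f"contact_map_{cls.replace('-', '')}.csv")
        results[f"contact_map_{cls}"] = cmap
    log.info("[%s] interactions done (%.1fs)", name, time.time() - t0)

    # -- observables ---------------------------------------------------------
    t0 = time.time()
    rg = np.array([radius_of_gyration(f, topo) for f in traj])
    e2e = np.array(
        [end_to_end_distance(ch, f) for f in traj for ch in topo.chains]
    )
    pd.DataFrame({"time_ps": [f.time for f in traj], "rg_nm": rg}).to_csv(
        sysdir / "rg.csv", index=False
    )
    pd.Series(e2e, name="e2e_nm").to_csv(sysdir / "end_to_end.csv", index=False)
    pmf = pmf2d(counts.astype(float), rg, temperature=cfg.temperature)
    with open(sysdir / "pmf_hbonds_rg.json", "w") as f:
        json.dump(
            {
                "x_edges": pmf.x_edges.tolist(),
                "y_edges": pmf.y_edges.tolist(),
                "values_kcal_mol": np.where(
                    np.isfinite(pmf.values), pmf.values, None
                ).tolist(),
                "temperature_K": pmf.temperature,
                "minimum": pmf.minimum,
            },
            f,
        )
    results["pmf_minimum"] = pmf.minimum
    results["rg_mean"] = float(rg.mean())
    sasa_frames = traj.frames[:: max(cfg.sasa_stride, 1)]
    per_res_acc = None
    for f in sasa_frames:
        _, per_res, _ = shrake_rupley_sasa(f, topo, n_points=cfg.sasa_points)
        per_res_acc = per_res if per_res_acc is None else per_res_acc + per_res
    sasa_mean = per_res_acc / len(sasa_frames)
    labels = [
        f"{topo.residues[i].name}{topo.residues[i].seq_label}"
        for i in sasa_mean.index
    ]
    pd.DataFrame({"residue": labels, "sasa_nm2": sasa_mean.values}).to_csv(
        sysdir / "sasa_per_residue.csv", index=False
    )
    if topo.waters:
        solv = {
            part: {
                int(lab): solvation_count(traj, lab, part=part)
                for lab in sorted({r.seq_label for r in topo.standard_residues()})
            }
            for part in ("mainchain", "sidechain")
        }
        with open(sysdir / "solvation.json", "w") as f:
            json.dump(solv, f, indent=1)
    log.info("[%s] observables done (%.1fs)", name, time.time() - t0)

    if cfg.convergence_windows:
        rep = convergence_report(traj, cfg.convergence_windows, criteria=cfg.hbond)
        rep.metrics.to_csv(sysdir / "convergence.csv")
        results["convergence"] = rep.metrics.to_dict()

    results["runtime_s"] = time.time() - t_start
    return results


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the full battery for every configured system, then emit
    pairwise difference maps (first system minus second) when two systems
    are configured.  Re-running a completed configuration is a no-op
    unless ``force`` is set (idempotence by config hash)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    digest = cfg.digest()
    if manifest_path.exists() and not cfg.force:
        with open(manifest_path) as f:
            old = json.load(f)
        if old.get("config_hash") == digest and old.get("completed"):
            log.info("config %s already analysed; use force to re-run", digest)
            return old
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        per_system = {}
        for name in cfg.systems:
            try:
                per_system[name] = _analyze_system(cfg, name, out)
            except Exception as exc:
                raise RuntimeError(f"analysis stage failed for system {name!r}: {exc}") from exc
        names = list(cfg.systems)
        if len(names) == 2:
            a, b = names
            diffdir = out / f"diff_{a}_minus_{b}"
            diffdir.mkdir(exist_ok=True)
            for key in ("hbond_map_MC-MC", "hbond_map_MC-SC", "hbond_map_SC-SC",
                        "contact_map_MC-SC", "contact_map_SC-SC", "contact_map_any"):
                d = difference_map(per_system[a][key], per_system[b][key])
                d.to_csv(diffdir / f"{key.replace('-', '')}.csv")
            beta_a = pd.Series(per_system[a]["ss_per_residue_beta"])
            beta_b = pd.Series(per_system[b]["ss_per_residue_beta"])
            (beta_a - beta_b).to_csv(diffdir / "beta_sheet_per_residue.csv",
                                     header=["delta_probability"])
        manifest = {
            "version": __version__,
            "config_hash": digest,
            "completed": True,
            "runtime_s": time.time() - t0,
            "criteria": {
                "hbond_d_no_max_nm": cfg.hbond.d_no_max,
                "hbond_angle_min_deg": cfg.hbond.angle_min,
                "contact_d_carbon_nm": cfg.contact.d_carbon,
                "contact_d_other_nm": cfg.contact.d_other,
                "cluster_cutoff_nm": cfg.cluster_cutoff,
                "temperature_K": cfg.temperature,
            },
            "systems": {
                name: {
                    k: v
                    for k, v in res.items()
                    if isinstance(v, (int, float, str, dict, list, tuple))
                }
                for name, res in per_system.items()
            },
        }
        with open(manifest_path, "w") as f:
            json.dump(manifest, f, indent=1, default=float)
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
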