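"""Scalar and field observables: Rg, end-to-end distance, Shrake-Rupley
SASA, solvation counts, 2-D free-energy surfaces and convergence checks.

The 2-D potential of mean force is -RT ln H(x, y) over the normalised
histogram of two reaction coordinates (by convention here: the inter-chain
H-bond count and the radius of gyration of the whole peptide assembly),
shifted so the lowest occupied bin is zero; empty bins are left as +inf.
The analysis temperature defaults to 310 K and R is expressed in
kcal/(mol K) so surfaces come out in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import rel_entr

from .interactions import HBondCriteria, detect_hbonds
from .model import (
    Frame,
    Residue,
    Topology,
    Trajectory,
    ValidationError,
    min_image_displacement,
)
from .secondary_structure import compute_ss_matrix, ss_statistics

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ANALYSIS_TEMPERATURE",
    "radius_of_gyration",
    "end_to_end_distance",
    "shrake_rupley_sasa",
    "solvation_count",
    "pmf2d",
    "PMFGrid",
    "jensen_shannon_divergence",
    "convergence_report",
    "ConvergenceReport",
]

#: gas constant, kcal/(mol K)
GAS_CONSTANT_KCAL = 0.0019872
#: default analysis temperature, K (physiological)
ANALYSIS_TEMPERATURE = 310.0


def radius_of_gyration(frame: Frame, topology: Topology,
                       selection: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (nm) of the selected atoms.

    The default selection is every peptide heavy atom of all chains, i.e.
    one Rg per frame for the whole assembly.
    """
    if selection is None:
        selection = topology.atom_indices(heavy=True, peptide_only=True)
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size == 0:
        raise ValidationError("empty selection for radius of gyration")
    x = frame.coords[selection]
    m = topology.mass[selection]
    com = np.average(x, axis=0, weights=m)
    d2 = np.sum((x - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def end_to_end_distance(chain: list[Residue], frame: Frame,
                        box: np.ndarray | None = None) -> float:
    """Distance (nm) between the C-alpha of the first and last standard
    residue of one chain; caps are excluded."""
    std = [r for r in chain if r.is_standard]
    if len(std) < 2:
        raise ValidationError("end-to-end distance needs at least 2 residues")
    for r in (std[0], std[-1]):
        if not r.has_atom("CA"):
            raise ValidationError(f"residue {r.name}{r.seq_label} has no CA")
    a = frame.coords[std[0].atom("CA").index]
    b = frame.coords[std[-1].atom("CA").index]
    if box is None:
        box = frame.box
    return float(np.linalg.norm(min_image_displacement(a, b, box)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere points (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(frame: Frame, topology: Topology, probe: float = 0.14,
                       n_points: int = 960,
                       radii: dict[str, float] | None = None):
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    Spheres of radius (vdW + probe) are sampled with ``n_points``
    quasi-uniform points; a point survives if no other inflated sphere
    covers it.  Waters are excluded both as surface and as occluders.
    Returns ``(per_atom, per_residue, total)`` with per_residue a pandas
    Series over topology residue indices.
    """
    topo = topology
    sel = np.nonzero(topo.is_heavy & ~topo.is_water)[0]
    if sel.size == 0:
        raise ValidationError("no heavy peptide atoms for SASA")
    if radii:
        r_atom = np.array(
            [radii.get(topo.atom_element[i], topo.vdw_radius[i]) for i in sel]
        )
    else:
        r_atom = topo.vdw_radius[sel]
    R = r_atom + probe
    X = frame.coords[sel]
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(X)
    per_atom = np.zeros(topo.n_atoms)
    rmax = R.max()
    for k in range(sel.size):
        pts = X[k] + R[k] * sphere
        neigh = [j for j in tree.query_ball_point(X[k], R[k] + rmax) if j != k]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - X[j], axis=1)
            exposed &= d >= R[j]
            if not exposed.any():
                break
        per_atom[sel[k]] = exposed.mean() * 4.0 * np.pi * R[k] ** 2
    n_res = len(topo.residues)
    per_res = pd.Series(np.zeros(n_res), index=pd.RangeIndex(n_res, name="residue"))
    for i in sel:
        per_res.iloc[topo.atom_residue[i]] += per_atom[i]
    return per_atom, per_res, float(per_atom.sum())


def solvation_count(traj: Trajectory, seq_label: int, part: str = "mainchain",
                    cutoff: float = 0.35, whole_molecule: bool = False) -> float:
    """Mean number of water molecules within ``cutoff`` nm of the given
    part (mainchain/sidechain) of residue ``seq_label``, averaged over
    frames and chains.  Distances are measured from the part's heavy
    atoms.

    Water position defaults to the oxygen atom; ``whole_molecule=True``
    counts a water when any of its atoms is within the cutoff.
    """
    if part not in ("mainchain", "sidechain"):
        raise ValidationError("part must be 'mainchain' or 'sidechain'")
    topo = traj.topology
    water_atoms: list[tuple[int, int]] = []  # (water residue id, atom index)
    for res in topo.waters:
        for a in res.atoms:
            if whole_molecule or a.element == "O":
                water_atoms.append((res.index, a.index))
    if not water_atoms:
        return 0.0
    wat_res = np.array([w for w, _ in water_atoms])
    wat_idx = np.array([i for _, i in water_atoms])
    want_bb = part == "mainchain"
    groups = []  # per chain: atom indices of the requested part
    for chain in topo.chains:
        for res in chain:
            if res.is_standard and res.seq_label == seq_label:
                idx = [
                    a.index
                    for a in res.atoms
                    if a.is_backbone == want_bb and a.is_heavy
                ]
                groups.append(np.array(idx, dtype=np.intp))
    if not groups:
        raise ValidationError(f"no residue with label {seq_label}")
    total = 0.0
    n_obs = 0
    for f in traj:
        for idx in groups:
            n_obs += 1
            if idx.size == 0:
                continue  # glycine-like part: count 0
            d = min_image_displacement(
                f.coords[idx][:, None, :], f.coords[wat_idx][None, :, :], f.box
            )
            within = np.sqrt(np.sum(d * d, axis=-1)) < cutoff
            hit = within.any(axis=0)
            total += len(np.unique(wat_res[hit]))
    return total / n_obs


@dataclass
class PMFGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # kcal/mol; +inf for empty bins
    temperature: float

    @property
    def minimum(self) -> tuple[float, float]:
        """(x, y) bin centres of the global free-energy minimum."""
        i, j = np.unravel_index(np.argmin(np.where(np.isfinite(self.values), self.values, np.inf)), self.values.shape)
        xc = 0.5 * (self.x_edges[i] + self.x_edges[i + 1])
        yc = 0.5 * (self.y_edges[j] + self.y_edges[j + 1])
        return float(xc), float(yc)


def pmf2d(x: np.ndarray, y: np.ndarray, temperature: float = ANALYSIS_TEMPERATURE,
          bins: tuple | None = None) -> PMFGrid:
    """2-D potential of mean force -RT ln H(x, y), min-shifted to zero.

    ``bins`` follows numpy.histogram2d; the default is unit-width integer
    bins on x (H-bond counts) and 0.02 nm bins on y (Rg).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValidationError("x and y series must be equal-length, non-empty")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if bins is None:
        x_edges = np.arange(np.floor(x.min()) - 0.5, np.ceil(x.max()) + 1.5, 1.0)
        y_edges = np.arange(y.min() - 0.01, y.max() + 0.03, 0.02)
        bins = (x_edges, y_edges)
    H, xe, ye = np.histogram2d(x, y, bins=bins)
    P = H / H.sum()
    with np.errstate(divide="ignore"):
        pmf = -GAS_CONSTANT_KCAL * temperature * np.log(P)
    occupied = P > 0
    if not occupied.any():
        raise ValidationError("all-empty histogram")
    pmf = pmf - pmf[occupied].min()
    pmf[~occupied] = np.inf
    return PMFGrid(xe, ye, pmf, temperature)


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JS divergence in nats between two histograms (normalised inside)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValidationError("histograms must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


@dataclass
class ConvergenceReport:
    windows: tuple[tuple[float, float], tuple[float, float]]
    metrics: pd.DataFrame  # index metric, columns: js_divergence, max_abs_diff

    def is_converged(self, js_tol: float = 0.02, abs_tol: float = 0.05) -> bool:
        return bool(
            (self.metrics["js_divergence"] <= js_tol).all()
            and (self.metrics["max_abs_diff"] <= abs_tol).all()
        )


def _histogram(vals: np.ndarray, edges: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(vals, bins=edges)
    return h.astype(float)


def convergence_report(traj: Trajectory,
                       windows: tuple[tuple[float, float], tuple[float, float]],
                       rg_bin: float = 0.1, e2e_bin: float = 0.1,
                       criteria: HBondCriteria | None = None) -> ConvergenceReport:
    """Compare observable distributions between two time windows (ps).

    Metrics: overall SS category probabilities, per-residue beta-sheet
    probability, and the PDFs of the inter-chain H-bond count, assembly
    Rg and per-chain end-to-end distance.  For each metric the report
    holds the Jensen-Shannon divergence (nats) and the maximum absolute
    difference of the two distributions.
    """
    (a0, a1), (b0, b1) = windows
    # identical windows are allowed (a self-check that must give zero
    # divergence); partially overlapping ones are not
    if (a0, a1) != (b0, b1) and a0 < b1 and b0 < a1:
        raise ValidationError("windows must not overlap")
    wa = traj.select_window(a0, a1)
    wb = traj.select_window(b0, b1)
    rows = {}

    def add(name, pa, qa):
        pa = np.asarray(pa, dtype=float)
        qa = np.asarray(qa, dtype=float)
        js = jensen_shannon_divergence(pa, qa) if pa.sum() > 0 and qa.sum() > 0 else 0.0
        pa_n = pa / pa.sum() if pa.sum() > 0 else pa
        qa_n = qa / qa.sum() if qa.sum() > 0 else qa
        rows[name] = (js, float(np.max(np.abs(pa_n - qa_n))))

    stats = [ss_statistics(compute_ss_matrix(w)) for w in (wa, wb)]
    add("ss_overall", stats[0]["overall"].values, stats[1]["overall"].values)
    beta = [s["per_residue"]["beta_sheet"].values for s in stats]
    rows["ss_beta_per_residue"] = (
        jensen_shannon_divergence(beta[0] + 1e-12, beta[1] + 1e-12),
        float(np.max(np.abs(beta[0] - beta[1]))),
    )

    def hb_counts(w):
        from .interactions import hbond_count_series

        counts, _ = hbond_count_series(w, criteria=criteria)
        return counts

    ca, cb = hb_counts(wa), hb_counts(wb)
    lo, hi = int(min(ca.min(), cb.min())), int(max(ca.max(), cb.max()))
    edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    add("hbond_count_pdf", _histogram(ca, edges), _histogram(cb, edges))

    def series(w, fn):
        return np.array([fn(f) for f in w])

    rga = series(wa, lambda f: radius_of_gyration(f, traj.topology))
    rgb = series(wb, lambda f: radius_of_gyration(f, traj.topology))
    lo, hi = min(rga.min(), rgb.min()), max(rga.max(), rgb.max())
    edges = np.arange(lo - rg_bin / 2, hi + rg_bin, rg_bin)
    add("rg_pdf", _histogram(rga, edges), _histogram(rgb, edges))

    def e2e_all(w):
        vals = []
        for f in w:
            for chain in traj.topology.chains:
                vals.append(end_to_end_distance(chain, f))
        return np.array(vals)

    ea, eb = e2e_all(wa), e2e_all(wb)
    lo, hi = min(ea.min(), eb.min()), max(ea.max(), eb.max())
    edges = np.arange(lo - e2e_bin / 2, hi + e2e_bin, e2e_bin)
    add("end_to_end_pdf", _histogram(ea, edges), _histogram(eb, edges))

    metrics = pd.DataFrame(
        rows, index=["js_divergence", "max_abs_diff"]
    ).T
    return ConvergenceReport(windows=windows, metrics=metrics)
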