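"""Kabsch superposition, pairwise C-alpha RMSD and Daura (GROMOS) clustering.

The Daura method repeatedly extracts the frame with the most RMSD
neighbours within a cutoff (0.45 nm by default, computed after optimal
superposition of the C-alpha atoms of all chains in a fixed atom order) as
a cluster centre together with its neighbours.  Ties are broken towards
the lowest frame index so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Trajectory, ValidationError
from .secondary_structure import CATEGORIES, DEFAULT_GROUPING, SSMatrix, SS_CODES

__all__ = ["kabsch_superpose", "pairwise_rmsd_matrix", "daura_cluster",
           "ClusterResult", "cluster_ss_profile"]

DAURA_DEFAULT_CUTOFF = 0.45  # nm


def kabsch_superpose(X: np.ndarray, Y: np.ndarray):
    """Least-squares rigid superposition of Y onto X.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (reflections are
    corrected, so a mirror image of a chiral set retains a positive RMSD)
    and ``t`` the translation such that ``Y @ R.T + t`` best fits ``X``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValidationError("point sets must both be (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 points for superposition")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = Y0.T @ X0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:
        raise ValidationError("degenerate (rank-deficient) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = xc - R @ yc
    diff = Y0 @ R.T - X0
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def _rmsd_after_fit(X: np.ndarray, Y: np.ndarray) -> float:
    return kabsch_superpose(X, Y)[2]


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs for (n_frames, n, 3)."""
    m = coords.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = _rmsd_after_fit(coords[i], coords[j])
    return out


@dataclass
class ClusterResult:
    assignments: np.ndarray  # frame -> cluster id (0 = most populated)
    centers: list[int]  # representative frame per cluster
    populations: np.ndarray  # fraction per cluster, decreasing
    cutoff: float
    rmsd_matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, k: int) -> np.ndarray:
        return np.nonzero(self.assignments == k)[0]


def daura_cluster(traj: Trajectory, cutoff: float = DAURA_DEFAULT_CUTOFF,
                  selection: np.ndarray | None = None,
                  block: int = 20000) -> ClusterResult:
    """GROMOS conformational clustering over C-alpha RMSD.

    ``selection`` defaults to the C-alpha atoms of every chain in fixed
    atom order (no chain-permutation matching).  Clusters are relabelled by
    decreasing population; the greedy extraction itself breaks neighbour-
    count ties toward the lowest frame index.
    """
    if len(traj) == 0:
        raise ValidationError("cannot cluster an empty trajectory")
    sel = traj.topology.calpha_indices() if selection is None else selection
    coords = np.array([f.coords[sel] for f in traj])
    m = coords.shape[0]
    # full pairwise matrix; block evaluation keeps memory flat for long runs
    rmsd = np.zeros((m, m))
    for i0 in range(0, m, block):
        for i in range(i0, min(i0 + block, m)):
            for j in range(i + 1, m):
                rmsd[i, j] = rmsd[j, i] = _rmsd_after_fit(coords[i], coords[j])
    neighbors = rmsd < cutoff  # includes self
    remaining = np.ones(m, dtype=bool)
    assignments = np.full(m, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbors[center] & remaining)[0]
        cid = len(centers)
        assignments[members] = cid
        centers.append(center)
        sizes.append(len(members))
        remaining[members] = False
    # order clusters by decreasing population (stable for ties)
    order = np.argsort(-np.array(sizes), kind="stable")
    relabel = np.empty(len(order), dtype=int)
    relabel[order] = np.arange(len(order))
    assignments = relabel[assignments]
    centers = [centers[k] for k in order]
    populations = np.array(sizes, dtype=float)[order] / m
    return ClusterResult(assignments, centers, populations, cutoff, rmsd)


def cluster_ss_profile(result: ClusterResult, ssm: SSMatrix,
                       grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-cluster secondary-structure category probabilities.

    Row k describes cluster k (k=0 the most populated); columns are the
    report categories.  Frame sets of the clustering and the SS matrix
    must match.
    """
    if ssm.n_frames != len(result.assignments):
        raise ValidationError(
            f"SS matrix has {ssm.n_frames} frames, clustering has "
            f"{len(result.assignments)}"
        )
    grouping = dict(DEFAULT_GROUPING if grouping is None else grouping)
    lut = {c: grouping[c] for c in SS_CODES}
    flat = np.vectorize(lut.get)(ssm.codes)
    cols = list(dict.fromkeys(CATEGORIES))
    rows = []
    for k in range(result.n_clusters):
        cells = flat[result.members(k)]
        rows.append([np.mean(cells == cat) for cat in cols])
    return pd.DataFrame(rows, columns=cols, index=pd.RangeIndex(result.n_clusters, name="cluster"))
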