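"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's vectorised/tree-based code paths:
plain loops, explicit 27-image periodic searches, the quaternion (Horn)
superposition method, and a literal transcription of the greedy
neighbour-count clustering rule.
"""

from __future__ import annotations

import numpy as np

from phf6agg.model import (
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    Topology,
)

# ---------------------------------------------------------------------------
# periodic distances
# ---------------------------------------------------------------------------


def min_image_distance_27(a, b, box):
    """Minimum distance over the 27 neighbour images (orthorhombic box)."""
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * box
                d = np.linalg.norm(np.asarray(b) + shift - np.asarray(a))
                best = min(best, d)
    return best


def _dist(a, b, box):
    d = np.asarray(b) - np.asarray(a)
    if box is not None:
        d = d - box * np.round(d / box)
    return float(np.linalg.norm(d))


def _disp(a, b, box):
    d = np.asarray(b) - np.asarray(a)
    if box is not None:
        d = d - box * np.round(d / box)
    return d


# ---------------------------------------------------------------------------
# H-bonds
# ---------------------------------------------------------------------------


def brute_force_hbonds(frame, topology: Topology, d_max=0.35, angle_min=150.0,
                       include_water=False):
    """Set of (donor_heavy, hydrogen, acceptor_heavy) atom-index triples."""
    donors = []  # (heavy_idx, h_idx)
    acceptors = []
    for chain in topology.chains:
        for res in chain:
            if res.name == "ACE":
                acceptors.append(res.atom("O").index)
            elif res.name in ("NH2", "NME"):
                n = res.atom("N").index
                for h in res.atoms:
                    if h.element == "H":
                        donors.append((n, h.index))
            else:
                if res.has_atom("H"):
                    donors.append((res.atom("N").index, res.atom("H").index))
                acceptors.append(res.atom("O").index)
                for heavy, hnames in SIDECHAIN_DONORS.get(res.name, {}).items():
                    if res.has_atom(heavy):
                        for hn in hnames:
                            if res.has_atom(hn):
                                donors.append((res.atom(heavy).index, res.atom(hn).index))
                for acc in SIDECHAIN_ACCEPTORS.get(res.name, ()):
                    if res.has_atom(acc):
                        acceptors.append(res.atom(acc).index)
    if include_water:
        for res in topology.waters:
            o = next(a for a in res.atoms if a.element == "O")
            acceptors.append(o.index)
            for a in res.atoms:
                if a.element == "H":
                    donors.append((o.index, a.index))
    X = frame.coords
    box = frame.box
    out = set()
    # exhaustive donor x acceptor distance matrix; every rule applied
    # explicitly per candidate triple
    dh_arr = np.array([d for d, _ in donors])
    ah_arr = np.array(acceptors)
    disp = X[dh_arr][:, None, :] - X[ah_arr][None, :, :]
    if box is not None:
        disp = disp - box * np.round(disp / box)
    dist = np.sqrt(np.sum(disp * disp, axis=-1))
    for di, ai in zip(*np.nonzero(dist < d_max)):
        dh, hh = donors[di]
        ah = acceptors[ai]
        rd, ra = topology.atom_residue[dh], topology.atom_residue[ah]
        if rd == ra:
            continue
        same_chain = topology.residue_chain[rd] == topology.residue_chain[ra]
        adjacent = (
            abs(topology.residue_chain_pos[rd] - topology.residue_chain_pos[ra]) <= 1
        )
        if same_chain and adjacent and topology.is_backbone[dh] and topology.is_backbone[ah]:
            continue
        if _dist(X[dh], X[ah], box) >= d_max:
            continue
        # angle at H between (donor - H) and (acceptor image - H)
        a_img = X[dh] + _disp(X[dh], X[ah], box)
        v1 = X[dh] - X[hh]
        v2 = a_img - X[hh]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        if ang > angle_min:
            out.add((int(dh), int(hh), int(ah)))
    return out


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def brute_force_contacts(frame, topology: Topology, d_carbon=0.54, d_other=0.46,
                         min_seq_sep=2):
    """Set of sorted heavy-atom index pairs satisfying the contact rule.

    Exhaustive O(N^2): the full minimum-image distance matrix is formed
    (no neighbour trees); the residue/element rules are applied per pair.
    """
    heavy = np.array([i for i in range(topology.n_atoms)
                      if topology.is_heavy[i] and not topology.is_water[i]])
    X = frame.coords
    box = frame.box
    Xh = X[heavy]
    d = Xh[:, None, :] - Xh[None, :, :]
    if box is not None:
        d = d - box * np.round(d / box)
    dist = np.sqrt(np.sum(d * d, axis=-1))
    # candidates below the larger cutoff; per-pair rules checked explicitly
    cand_a, cand_b = np.nonzero(np.triu(dist < d_carbon, k=1))
    out = set()
    for a, b in zip(cand_a, cand_b):
        i, j = int(heavy[a]), int(heavy[b])
        ri, rj = topology.atom_residue[i], topology.atom_residue[j]
        if ri == rj:
            continue
        if topology.residue_chain[ri] == topology.residue_chain[rj] and abs(
            topology.residue_chain_pos[ri] - topology.residue_chain_pos[rj]
        ) < min_seq_sep:
            continue
        cutoff = (
            d_carbon
            if topology.atom_element[i] == "C" or topology.atom_element[j] == "C"
            else d_other
        )
        if dist[a, b] < cutoff:
            out.add((min(i, j), max(i, j)))
    return out


# ---------------------------------------------------------------------------
# superposition (quaternion / Horn method) and greedy clustering
# ---------------------------------------------------------------------------


def quaternion_rmsd(X, Y):
    """Optimal-superposition RMSD via the Horn quaternion eigenvalue
    method (proper rotations only)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Xc
    K = np.empty((4, 4))
    K[0, 0] = S[0, 0] + S[1, 1] + S[2, 2]
    K[0, 1] = K[1, 0] = S[1, 2] - S[2, 1]
    K[0, 2] = K[2, 0] = S[2, 0] - S[0, 2]
    K[0, 3] = K[3, 0] = S[0, 1] - S[1, 0]
    K[1, 1] = S[0, 0] - S[1, 1] - S[2, 2]
    K[1, 2] = K[2, 1] = S[0, 1] + S[1, 0]
    K[1, 3] = K[3, 1] = S[0, 2] + S[2, 0]
    K[2, 2] = -S[0, 0] + S[1, 1] - S[2, 2]
    K[2, 3] = K[3, 2] = S[1, 2] + S[2, 1]
    K[3, 3] = -S[0, 0] - S[1, 1] + S[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = float(np.sum(Xc * Xc) + np.sum(Yc * Yc))
    msd = max(0.0, (e0 - 2.0 * lam) / X.shape[0])
    return np.sqrt(msd)


def greedy_neighbor_clustering(rmsd_matrix, cutoff):
    """Literal transcription of the Daura rule: repeatedly extract the
    structure with most neighbours within the cutoff (lowest index on
    ties) together with its neighbours."""
    m = rmsd_matrix.shape[0]
    remaining = set(range(m))
    assignments = [-1] * m
    clusters = []
    while remaining:
        best_i, best_count, best_members = None, -1, None
        for i in sorted(remaining):
            members = [j for j in sorted(remaining) if rmsd_matrix[i, j] < cutoff]
            if len(members) > best_count:
                best_i, best_count, best_members = i, len(members), members
        clusters.append((best_i, best_members))
        for j in best_members:
            remaining.discard(j)
    # order by decreasing size, stable
    order = sorted(range(len(clusters)), key=lambda k: -len(clusters[k][1]))
    for new_id, k in enumerate(order):
        for j in clusters[k][1]:
            assignments[j] = new_id
    return np.array(assignments)
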