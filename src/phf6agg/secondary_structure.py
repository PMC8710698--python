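"""Kabsch-Sander secondary-structure assignment and strand statistics.

Implements the DSSP algorithm over the package's own data model: the
electrostatic backbone H-bond energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol  (r in A)

with a bond called at E < -0.5 kcal/mol, n-turn / bridge / ladder patterns,
and the code alphabet {H, G, I, E, B, T, S, C}.  Modern DSSP v4 refinements
(pi-helix preference, beta bulges, PPII) are deliberately not reproduced;
on idealised sheet/coil ensembles the dialects agree away from segment
edges.

Capping groups (ACE / NH2) are not residues: they are never assigned a
code and do not participate in the pattern search, but an ACE carbonyl is
used to reconstruct the amide-H direction of the first residue when no
explicit H is present.

The five summary categories used for reporting are coil, beta-sheet (E),
beta-bridge (B), bend (S) and turn (T); helical codes are folded into coil
by default since capped hexapeptides have no meaningful helix content (the
grouping is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Frame, Topology, Trajectory, ValidationError, min_image_displacement

__all__ = [
    "KS_Q1Q2_FACTOR",
    "KS_ENERGY_CUTOFF",
    "SS_CODES",
    "CATEGORIES",
    "DEFAULT_GROUPING",
    "SSMatrix",
    "backbone_hbond_energy",
    "assign_secondary_structure",
    "compute_ss_matrix",
    "ss_statistics",
    "category_vs_temperature",
    "strand_length_distribution",
    "strand_segments",
]

#: Kabsch-Sander electrostatic prefactor, kcal*A/mol.
KS_Q1Q2_FACTOR = 27.888
#: H-bond energy threshold, kcal/mol.
KS_ENERGY_CUTOFF = -0.5
#: cap on the energy to guard against the 1/r singularity for clashes
KS_ENERGY_FLOOR = -9.9

SS_CODES = "HGIEBTSC"
CATEGORIES = ("coil", "beta_sheet", "beta_bridge", "bend", "turn")
#: default aggregation of the 8-letter alphabet into report categories
DEFAULT_GROUPING = {
    "H": "coil",
    "G": "coil",
    "I": "coil",
    "E": "beta_sheet",
    "B": "beta_bridge",
    "T": "turn",
    "S": "bend",
    "C": "coil",
}

_NM2A = 10.0


def ks_energy(don_n, don_h, acc_c, acc_o) -> np.ndarray:
    """Kabsch-Sander energies, (n_donors, n_acceptors) kcal/mol, coords nm."""
    def dist(a, b):
        d = a[:, None, :] - b[None, :, :]
        return np.sqrt(np.sum(d * d, axis=-1)) * _NM2A

    with np.errstate(divide="ignore"):
        e = KS_Q1Q2_FACTOR * (
            1.0 / dist(don_n, acc_o)
            + 1.0 / dist(don_h, acc_c)
            - 1.0 / dist(don_h, acc_o)
            - 1.0 / dist(don_n, acc_c)
        )
    return np.maximum(e, KS_ENERGY_FLOOR)


@dataclass
class _BackboneArrays:
    """Per standard residue backbone coordinates, chain-major order."""

    n: np.ndarray
    h: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    has_h: np.ndarray
    chain: np.ndarray
    pos: np.ndarray  # index within the chain's standard residues
    global_index: np.ndarray  # topology residue index


def _backbone_arrays(frame: Frame, topology: Topology) -> _BackboneArrays:
    N, H, CA, C, O = [], [], [], [], []
    has_h, chain_ids, pos, gidx = [], [], [], []
    for ci, chain in enumerate(topology.chains):
        std = [r for r in chain if r.is_standard]
        # preceding carbonyl for amide-H reconstruction: ACE cap if present
        prev_c = prev_o = None
        cap = chain[0] if chain and chain[0].name == "ACE" else None
        if cap is not None:
            prev_c = frame.coords[cap.atom("C").index]
            prev_o = frame.coords[cap.atom("O").index]
        for k, res in enumerate(std):
            for name, acc in (("N", N), ("CA", CA), ("C", C), ("O", O)):
                if not res.has_atom(name):
                    raise ValidationError(
                        f"residue {res.name}{res.seq_label} lacks backbone atom {name}"
                    )
                acc.append(frame.coords[res.atom(name).index])
            if res.has_atom("H"):
                H.append(frame.coords[res.atom("H").index])
                has_h.append(True)
            elif prev_c is not None:
                co = prev_c - prev_o
                co /= np.linalg.norm(co)
                H.append(N[-1] + 0.10 * co)
                has_h.append(True)
            else:
                H.append(N[-1].copy())
                has_h.append(False)
            prev_c, prev_o = C[-1], O[-1]
            chain_ids.append(ci)
            pos.append(k)
            gidx.append(res.index)
    return _BackboneArrays(
        n=np.array(N).reshape(-1, 3),
        h=np.array(H).reshape(-1, 3),
        ca=np.array(CA).reshape(-1, 3),
        c=np.array(C).reshape(-1, 3),
        o=np.array(O).reshape(-1, 3),
        has_h=np.array(has_h, dtype=bool),
        chain=np.array(chain_ids, dtype=np.intp),
        pos=np.array(pos, dtype=np.intp),
        global_index=np.array(gidx, dtype=np.intp),
    )


def _hbond_matrix(bb: _BackboneArrays, box: np.ndarray | None) -> np.ndarray:
    """hb[i, j] = True iff C=O of residue i accepts the N-H of residue j."""
    nres = bb.n.shape[0]
    if nres == 0:
        return np.zeros((0, 0), dtype=bool)
    if box is not None:
        # fold the acceptor C=O group to a consistent minimum image relative
        # to each donor N (C rides with its O so the four distances agree)
        e = np.zeros((nres, nres))
        for j in range(nres):  # donors
            o_im = bb.n[j] + min_image_displacement(bb.n[j], bb.o, box)
            c_im = o_im + (bb.c - bb.o)
            e[:, j] = ks_energy(bb.n[j][None], bb.h[j][None], c_im, o_im)[0]
    else:
        e = ks_energy(bb.n, bb.h, bb.c, bb.o).T  # (acceptor, donor)
    hb = e < KS_ENERGY_CUTOFF
    hb[:, ~bb.has_h] = False
    # exclude self and chain neighbours (|pos difference| <= 1 in same chain)
    same_chain = bb.chain[:, None] == bb.chain[None, :]
    close = np.abs(bb.pos[:, None] - bb.pos[None, :]) <= 1
    hb[same_chain & close] = False
    return hb


def backbone_hbond_energy(donor, acceptor, frame: Frame,
                          topology: Topology | None = None,
                          box: np.ndarray | None = None) -> float:
    """Kabsch-Sander energy of the (N-H of ``donor``, C=O of ``acceptor``) pair.

    ``donor``/``acceptor`` are :class:`~phf6agg.model.Residue` objects with
    complete backbones; the donor must carry an explicit amide H or be
    preceded by a carbonyl group from which it can be reconstructed.
    """
    for name in ("N", "CA", "C", "O"):
        if not donor.has_atom(name) or not acceptor.has_atom(name):
            raise ValidationError("backbone atoms missing for H-bond energy")
    n = frame.coords[donor.atom("N").index]
    if donor.has_atom("H"):
        h = frame.coords[donor.atom("H").index]
    else:
        raise ValidationError(
            f"donor {donor.name}{donor.seq_label} has no amide H"
        )
    c = frame.coords[acceptor.atom("C").index]
    o = frame.coords[acceptor.atom("O").index]
    if box is None:
        box = frame.box
    if box is not None:
        off = min_image_displacement(n, o, box) - (o - n)
        c = c + off
        o = o + off
    return float(ks_energy(n[None], h[None], c[None], o[None])[0, 0])


def assign_secondary_structure(frame: Frame, topology: Topology,
                               min_image: bool = True) -> np.ndarray:
    """Per-residue DSSP codes for the standard residues, chain-major order.

    Chains shorter than three residues are coded all-C (no pattern can
    form).  Caps do not receive codes.
    """
    codes, _ = assign_with_bridges(frame, topology, min_image=min_image)
    return codes


def assign_with_bridges(frame: Frame, topology: Topology,
                        min_image: bool = True):
    """DSSP codes plus the bridge list [(col_i, col_j, 'P'|'A'), ...].

    Bridge columns index the standard residues in chain-major order, the
    same axis as the code array; the bridge list is what ladder-based
    strand pairing (and hence beta-barrel detection) is built from.
    """
    bb = _backbone_arrays(frame, topology)
    nres = bb.n.shape[0]
    codes = np.full(nres, "C", dtype="<U1")
    if nres == 0:
        return codes, []
    box = frame.box if min_image else None
    hb = _hbond_matrix(bb, box)

    same_chain = bb.chain[:, None] == bb.chain[None, :]
    sep = bb.pos[:, None] - bb.pos[None, :]

    # --- n-turns: Hbond(i, i+n) = CO(i) ... HN(i+n), same chain
    turn = {n: np.zeros(nres, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(nres):
            j = i + n
            if j < nres and bb.chain[i] == bb.chain[j] and bb.pos[j] - bb.pos[i] == n:
                if hb[i, j]:
                    turn[n][i] = True

    # --- bridges
    def neighbor(i: int, step: int) -> int | None:
        """Chain neighbour of residue column i, or None at chain ends."""
        j = i + step
        if 0 <= j < nres and bb.chain[j] == bb.chain[i] and bb.pos[j] - bb.pos[i] == step:
            return j
        return None

    def hbn(a: int | None, b: int | None) -> bool:
        return a is not None and b is not None and hb[a, b]

    bridges: list[tuple[int, int, str]] = []
    for i in range(nres):
        for j in range(i + 1, nres):
            if bb.chain[i] == bb.chain[j] and bb.pos[j] - bb.pos[i] < 3:
                continue  # overlapping stretches cannot bridge
            im1, ip1 = neighbor(i, -1), neighbor(i, +1)
            jm1, jp1 = neighbor(j, -1), neighbor(j, +1)
            para = (hbn(im1, j) and hbn(j, ip1)) or (hbn(jm1, i) and hbn(i, jp1))
            anti = (hb[i, j] and hb[j, i]) or (hbn(im1, jp1) and hbn(jm1, ip1))
            if para:
                bridges.append((i, j, "P"))
            elif anti:
                bridges.append((i, j, "A"))

    bridge_set = {(i, j, t) for i, j, t in bridges}
    in_ladder = set()
    for i, j, t in bridges:
        if t == "P":
            ext = ((i + 1, j + 1, t) in bridge_set) or ((i - 1, j - 1, t) in bridge_set)
        else:
            ext = ((i + 1, j - 1, t) in bridge_set) or ((i - 1, j + 1, t) in bridge_set)
        if ext:
            in_ladder.add((i, j, t))

    # --- assignment with priority H > E > B > G > I > T > S:
    # write low-priority first, overwrite with higher.
    # bend S
    for i in range(nres):
        im2, ip2 = i - 2, i + 2
        if im2 < 0 or ip2 >= nres:
            continue
        if not (bb.chain[im2] == bb.chain[i] == bb.chain[ip2]):
            continue
        if bb.pos[i] - bb.pos[im2] != 2 or bb.pos[ip2] - bb.pos[i] != 2:
            continue
        v1 = bb.ca[i] - bb.ca[im2]
        v2 = bb.ca[ip2] - bb.ca[i]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) > 70.0:
            codes[i] = "S"
    # turn T: residues strictly inside any n-turn
    for n in (3, 4, 5):
        for i in np.nonzero(turn[n])[0]:
            for k in range(i + 1, min(i + n, nres)):
                codes[k] = "T"
    # helices: two consecutive n-turns found a helix over i..i+n-1
    for n, letter in ((5, "I"), (3, "G")):
        for i in range(1, nres):
            if turn[n][i] and turn[n][i - 1]:
                codes[i : i + n] = letter
    # bridges / ladders
    for i, j, t in bridges:
        if (i, j, t) not in in_ladder:
            for k in (i, j):
                if codes[k] not in ("E",):
                    codes[k] = "B"
    for i, j, t in bridges:
        if (i, j, t) in in_ladder:
            codes[i] = "E"
            codes[j] = "E"
    # alpha helix dominates
    for i in range(1, nres):
        if turn[4][i] and turn[4][i - 1]:
            codes[i : i + 4] = "H"
    return codes, bridges


@dataclass
class SSMatrix:
    """frame x residue grid of DSSP codes for the standard residues."""

    codes: np.ndarray  # (n_frames, n_std_residues) of single chars
    chain: np.ndarray  # chain index per column
    pos: np.ndarray  # position within the chain per column
    seq_label: np.ndarray  # author-facing residue label per column

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]


def compute_ss_matrix(traj: Trajectory, min_image: bool = True) -> SSMatrix:
    topo = traj.topology
    rows = [assign_secondary_structure(f, topo, min_image=min_image) for f in traj]
    std = topo.standard_residues()
    chain = np.array([r.chain_index for r in std], dtype=np.intp)
    pos = np.zeros(len(std), dtype=np.intp)
    k = 0
    for ci, chain_res in enumerate(topo.iter_chain_standard()):
        for p, _ in enumerate(chain_res):
            pos[k] = p
            k += 1
    labels = np.array([r.seq_label for r in std], dtype=np.intp)
    return SSMatrix(np.array(rows), chain, pos, labels)


def ss_statistics(ssm: SSMatrix, grouping: dict[str, str] | None = None) -> dict:
    """Overall and per-residue category probabilities.

    Per-residue probabilities pool the (frame x chain) cells of every
    residue position; overall probabilities are the mean over residue
    positions, so both sum to one across categories.
    """
    if ssm.codes.size == 0:
        raise ValidationError("empty secondary-structure matrix")
    grouping = dict(DEFAULT_GROUPING if grouping is None else grouping)
    cats = np.array([grouping[c] for c in SS_CODES])
    lut = {c: grouping[c] for c in SS_CODES}
    flat = np.vectorize(lut.get)(ssm.codes)
    labels = np.unique(ssm.seq_label)
    per_residue = pd.DataFrame(
        0.0, index=labels, columns=list(dict.fromkeys(CATEGORIES))
    )
    for lab in labels:
        cols = ssm.seq_label == lab
        cells = flat[:, cols]
        for cat in per_residue.columns:
            per_residue.loc[lab, cat] = np.mean(cells == cat)
    overall = per_residue.mean(axis=0)
    return {"overall": overall, "per_residue": per_residue}


def category_vs_temperature(trajectories: dict[float, Trajectory],
                            category: str = "beta_sheet",
                            grouping: dict[str, str] | None = None) -> pd.Series:
    """Overall probability of one category across replica trajectories,
    one value per temperature label (e.g. the beta-sheet melting curve)."""
    out = {}
    for temp, traj in trajectories.items():
        stats = ss_statistics(compute_ss_matrix(traj), grouping=grouping)
        out[float(temp)] = float(stats["overall"][category])
    return pd.Series(out, name=category).sort_index()


def strand_segments(codes_row: np.ndarray, chain: np.ndarray, pos: np.ndarray):
    """Maximal runs of E within each chain for one frame.

    Returns a list of (chain_index, start_col, end_col) with inclusive ends.
    """
    segs = []
    ncol = len(codes_row)
    i = 0
    while i < ncol:
        if codes_row[i] == "E":
            j = i
            while (
                j + 1 < ncol
                and codes_row[j + 1] == "E"
                and chain[j + 1] == chain[j]
                and pos[j + 1] - pos[j] == 1
            ):
                j += 1
            segs.append((int(chain[i]), i, j))
            i = j + 1
        else:
            i += 1
    return segs


def strand_length_distribution(ssm: SSMatrix, per_chain: bool = True) -> pd.Series:
    """Probability of beta-strand length L.

    A strand is a maximal run of consecutive E codes within one chain.  The
    default denominator is the number of (frame x chain) observations; with
    ``per_chain=False`` it is the total number of strands observed instead.
    """
    n_chains = len(np.unique(ssm.chain)) if ssm.n_columns else 0
    counts: dict[int, int] = {}
    total_strands = 0
    for row in ssm.codes:
        for _, i, j in strand_segments(row, ssm.chain, ssm.pos):
            L = j - i + 1
            counts[L] = counts.get(L, 0) + 1
            total_strands += 1
    if not counts:
        return pd.Series(dtype=float)
    denom = ssm.n_frames * n_chains if per_chain else total_strands
    lengths = sorted(counts)
    return pd.Series([counts[L] / denom for L in lengths], index=lengths, name="probability")
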