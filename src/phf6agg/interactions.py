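"""Geometric hydrogen-bond and heavy-atom contact detection.

H-bond criterion: donor-heavy to acceptor-heavy (N...O) distance below
0.35 nm and a D-H...A angle at the hydrogen above 150 deg.  Contact
criterion: two heavy atoms of non-sequential residues within 0.54 nm when
at least one is carbon, 0.46 nm otherwise.  Both use minimum-image
distances when the frame carries a periodic box.

Records are typed by the mainchain/sidechain (MC/SC) classes of the two
heavy atoms; the ACE and NH2 caps count as mainchain.  Residue-pair maps
aggregate over frames and the twelve chains the way the published maps
are normalised (mean count per frame divided by the chain count).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    Frame,
    Topology,
    Trajectory,
    ValidationError,
    min_image_displacement,
)

__all__ = [
    "HBondCriteria",
    "ContactCriteria",
    "InteractionRecord",
    "detect_hbonds",
    "detect_contacts",
    "hbond_count_series",
    "hbond_residue_map",
    "hbond_occupancy",
    "contact_residue_map",
    "difference_map",
]


@dataclass(frozen=True)
class HBondCriteria:
    d_no_max: float = 0.35  # nm, donor-heavy to acceptor-heavy
    angle_min: float = 150.0  # deg, D-H...A at the hydrogen

    def __post_init__(self):
        if not self.d_no_max > 0:
            raise ValidationError("H-bond distance cutoff must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValidationError("H-bond angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class ContactCriteria:
    d_carbon: float = 0.54  # nm, C-C or C-heavy
    d_other: float = 0.46  # nm, other heavy-heavy
    min_seq_sep: int = 2  # residues in the same chain must be non-sequential

    def __post_init__(self):
        if not self.d_other > 0 or self.d_carbon < self.d_other:
            raise ValidationError("need d_carbon >= d_other > 0")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected H-bond (donor/hydrogen/acceptor) or atomic contact."""

    kind: str  # "hbond" | "contact"
    atom_i: int  # donor heavy atom / first contact atom
    atom_j: int  # acceptor heavy atom / second contact atom
    hydrogen: int  # H atom index; -1 for contacts
    residue_i: int
    residue_j: int
    chain_i: int
    chain_j: int
    cls: str  # "MC-MC" | "MC-SC" | "SC-SC"
    inter_chain: bool
    donor_is_backbone: bool = False


def _cls(bb_i: bool, bb_j: bool) -> str:
    if bb_i and bb_j:
        return "MC-MC"
    if bb_i or bb_j:
        return "MC-SC"
    return "SC-SC"


def _donor_acceptor_tables(topology: Topology, include_water: bool = False):
    """(donor heavy idx, donor H idx) pairs and acceptor heavy indices."""
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for chain in topology.chains:
        for res in chain:
            if res.name == "ACE":
                acceptors.append(res.atom("O").index)
                continue
            if res.name in ("NH2", "NME"):
                if res.has_atom("N"):
                    n = res.atom("N").index
                    for h in ("HN1", "HN2", "H", "H1", "H2"):
                        if res.has_atom(h):
                            donors.append((n, res.atom(h).index))
                continue
            # backbone amide
            if res.has_atom("N"):
                n = res.atom("N").index
                hs = [a.index for a in res.atoms if a.name in ("H", "HN")]
                if hs:
                    donors.append((n, hs[0]))
            if res.has_atom("O"):
                acceptors.append(res.atom("O").index)
            for heavy, hnames in SIDECHAIN_DONORS.get(res.name, {}).items():
                if not res.has_atom(heavy):
                    continue
                hi = res.atom(heavy).index
                found = [res.atom(h).index for h in hnames if res.has_atom(h)]
                if not found:
                    raise ValidationError(
                        f"sidechain donor {res.name}@{heavy} has no attached H"
                    )
                donors.extend((hi, h) for h in found)
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
    return donors, acceptors


def detect_hbonds(frame: Frame, topology: Topology,
                  criteria: HBondCriteria | None = None,
                  include_water: bool = False,
                  min_image: bool = True) -> list[InteractionRecord]:
    """All (donor, H, acceptor) triples satisfying the geometric criterion.

    Excluded by rule: pairs within one residue, and backbone-to-backbone
    pairs of sequence-adjacent residues (i with i or i+-1), which are
    covalently constrained.
    """
    crit = criteria or HBondCriteria()
    donors, acceptors = _donor_acceptor_tables(topology, include_water)
    if not donors or not acceptors:
        return []
    box = frame.box if min_image else None
    d_heavy = np.array([d for d, _ in donors], dtype=np.intp)
    d_hyd = np.array([h for _, h in donors], dtype=np.intp)
    a_heavy = np.array(acceptors, dtype=np.intp)
    X = frame.coords
    disp = min_image_displacement(X[d_heavy][:, None, :], X[a_heavy][None, :, :], box)
    dist = np.sqrt(np.sum(disp * disp, axis=-1))
    topo = topology
    res_d = topo.atom_residue[d_heavy]
    res_a = topo.atom_residue[a_heavy]
    same_res = res_d[:, None] == res_a[None, :]
    bb_d = topo.is_backbone[d_heavy]
    bb_a = topo.is_backbone[a_heavy]
    same_chain = topo.atom_chain[d_heavy][:, None] == topo.atom_chain[a_heavy][None, :]
    adj = (
        np.abs(
            topo.residue_chain_pos[res_d][:, None] - topo.residue_chain_pos[res_a][None, :]
        )
        <= 1
    )
    excluded = same_res | (same_chain & adj & (bb_d[:, None] & bb_a[None, :]))
    cand = (dist < crit.d_no_max) & ~excluded
    records = []
    cos_min = np.cos(np.deg2rad(crit.angle_min))
    for di, ai in zip(*np.nonzero(cand)):
        h = X[d_hyd[di]]
        v1 = X[d_heavy[di]] - h
        a_img = X[d_heavy[di]] + disp[di, ai]
        v2 = a_img - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        # angle > angle_min  <=>  cos(angle) < cos(angle_min)
        if cosang < cos_min:
            rd, ra = int(res_d[di]), int(res_a[ai])
            records.append(
                InteractionRecord(
                    kind="hbond",
                    atom_i=int(d_heavy[di]),
                    atom_j=int(a_heavy[ai]),
                    hydrogen=int(d_hyd[di]),
                    residue_i=rd,
                    residue_j=ra,
                    chain_i=int(topo.residue_chain[rd]),
                    chain_j=int(topo.residue_chain[ra]),
                    cls=_cls(bool(bb_d[di]), bool(bb_a[ai])),
                    inter_chain=bool(topo.residue_chain[rd] != topo.residue_chain[ra]),
                    donor_is_backbone=bool(bb_d[di]),
                )
            )
    return records


def detect_contacts(frame: Frame, topology: Topology,
                    criteria: ContactCriteria | None = None,
                    min_image: bool = True) -> list[InteractionRecord]:
    """Heavy-atom contacts between non-sequential residues."""
    crit = criteria or ContactCriteria()
    topo = topology
    heavy = np.nonzero(topo.is_heavy & ~topo.is_water)[0]
    if heavy.size == 0:
        return []
    X = frame.coords[heavy]
    box = frame.box if min_image else None
    if box is not None:
        pairs = cKDTree(np.mod(X, box), boxsize=box).query_pairs(crit.d_carbon, output_type="ndarray")
    else:
        pairs = cKDTree(X).query_pairs(crit.d_carbon, output_type="ndarray")
    if pairs.size == 0:
        return []
    ai, aj = heavy[pairs[:, 0]], heavy[pairs[:, 1]]
    ri, rj = topo.atom_residue[ai], topo.atom_residue[aj]
    same_res = ri == rj
    same_chain = topo.atom_chain[ai] == topo.atom_chain[aj]
    seq_adjacent = (
        np.abs(topo.residue_chain_pos[ri] - topo.residue_chain_pos[rj]) < crit.min_seq_sep
    )
    ok = ~(same_res | (same_chain & seq_adjacent))
    has_c = (topo.atom_element[ai] == "C") | (topo.atom_element[aj] == "C")
    d = np.linalg.norm(
        min_image_displacement(frame.coords[ai], frame.coords[aj], box), axis=-1
    )
    ok &= np.where(has_c, d < crit.d_carbon, d < crit.d_other)
    records = []
    for k in np.nonzero(ok)[0]:
        a, b = int(ai[k]), int(aj[k])
        ra, rb = int(ri[k]), int(rj[k])
        records.append(
            InteractionRecord(
                kind="contact",
                atom_i=a,
                atom_j=b,
                hydrogen=-1,
                residue_i=ra,
                residue_j=rb,
                chain_i=int(topo.residue_chain[ra]),
                chain_j=int(topo.residue_chain[rb]),
                cls=_cls(bool(topo.is_backbone[a]), bool(topo.is_backbone[b])),
                inter_chain=bool(topo.residue_chain[ra] != topo.residue_chain[rb]),
            )
        )
    return records


def _filter(records, cls=None, inter_chain=None):
    out = records
    if cls is not None and cls != "any":
        out = [r for r in out if r.cls == cls]
    if inter_chain is not None:
        out = [r for r in out if r.inter_chain == inter_chain]
    return out


def hbond_count_series(traj: Trajectory, cls: str | None = None,
                       inter_chain: bool | None = True,
                       criteria: HBondCriteria | None = None,
                       include_water: bool = False):
    """Per-frame H-bond counts and their probability distribution.

    By default only inter-chain bonds are counted, matching how assembly
    H-bond statistics are reported for oligomer systems; pass
    ``inter_chain=None`` to include intra-chain bonds.
    """
    counts = np.array(
        [
            len(_filter(detect_hbonds(f, traj.topology, criteria, include_water), cls, inter_chain))
            for f in traj
        ],
        dtype=int,
    )
    if counts.size:
        vals, freq = np.unique(counts, return_counts=True)
        pdf = pd.Series(freq / counts.size, index=vals, name="probability")
    else:
        pdf = pd.Series(dtype=float)
    return counts, pdf


def _std_labels(topology: Topology) -> np.ndarray:
    labels = sorted({r.seq_label for r in topology.standard_residues()})
    return np.array(labels, dtype=int)


def hbond_residue_map(traj: Trajectory, cls: str = "MC-SC",
                      criteria: HBondCriteria | None = None,
                      inter_chain: bool | None = None) -> pd.DataFrame:
    """Residue-pair matrix of mean H-bond numbers, averaged over the chains.

    Entry (i, j) for the MC-SC class counts bonds joining the *sidechain*
    of residue label i to the *mainchain* of residue label j (rows are the
    sidechain role).  MC-MC and SC-SC maps are symmetrised.  Every entry is
    the total bond count over all frames and chain pairs divided by
    (n_frames * n_chains).
    """
    topo = traj.topology
    labels = _std_labels(topo)
    lab_of = topo.residue_label
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for f in traj:
        for r in _filter(detect_hbonds(f, topo, criteria), None, inter_chain):
            if r.cls != cls:
                continue
            li = int(lab_of[r.residue_i])
            lj = int(lab_of[r.residue_j])
            if li not in mat.index or lj not in mat.index:
                continue  # cap-attributed bonds are outside the residue map
            if cls == "MC-SC":
                # row = sidechain side, column = mainchain side
                row, col = (lj, li) if r.donor_is_backbone else (li, lj)
                mat.loc[row, col] += 1.0
            else:
                mat.loc[li, lj] += 1.0
                if (li, lj) != (lj, li):
                    mat.loc[lj, li] += 1.0
    n = max(len(traj), 1) * max(topo.n_chains, 1)
    return mat / n


def difference_map(map_a: pd.DataFrame, map_b: pd.DataFrame) -> pd.DataFrame:
    """Entry-wise map difference (system A minus system B)."""
    return map_a.sub(map_b, fill_value=0.0)


_SPEC_RE = re.compile(r"^[A-Za-z]{0,3}(\d+)@([A-Za-z0-9']+)$")


def _resolve_atom_spec(topology: Topology, spec: str):
    """Resolve e.g. 'N279@ND2' -> list of atom indices, one per chain."""
    m = _SPEC_RE.match(spec.strip())
    if not m:
        raise ValidationError(f"cannot parse atom spec {spec!r}")
    label, atom_name = int(m.group(1)), m.group(2)
    hits = []
    for chain in topology.chains:
        for res in chain:
            if res.is_standard and res.seq_label == label and res.has_atom(atom_name):
                hits.append(res.atom(atom_name).index)
    if not hits:
        raise ValidationError(f"atom spec {spec!r} matches no atom")
    return hits


def hbond_occupancy(traj: Trajectory, donor_spec: str, acceptor_spec: str,
                    criteria: HBondCriteria | None = None) -> dict[str, float]:
    """Percentage occupation of a specific donor/acceptor H-bond.

    An *instance* is one (donor chain, acceptor chain) combination of the
    named atoms (intra-chain instances included).  The published
    denominator convention is unstated, so both are reported:
    ``per_observed_pair`` divides by frames x instances that bond at least
    once, ``per_all_pairs`` by frames x all instances.
    """
    topo = traj.topology
    don_atoms = set(_resolve_atom_spec(topo, donor_spec))
    acc_atoms = set(_resolve_atom_spec(topo, acceptor_spec))
    bonded_per_instance: dict[tuple[int, int], int] = {}
    for f in traj:
        seen = set()
        for r in detect_hbonds(f, topo, criteria):
            if r.atom_i in don_atoms and r.atom_j in acc_atoms:
                seen.add((r.atom_i, r.atom_j))
        for inst in seen:
            bonded_per_instance[inst] = bonded_per_instance.get(inst, 0) + 1
    n_frames = len(traj)
    n_all = len(don_atoms) * len(acc_atoms)
    total = sum(bonded_per_instance.values())
    n_obs = len(bonded_per_instance)
    return {
        "per_observed_pair": 100.0 * total / (n_frames * n_obs) if n_obs else 0.0,
        "per_all_pairs": 100.0 * total / (n_frames * n_all) if n_all else 0.0,
    }


def contact_residue_map(traj: Trajectory, cls: str = "any",
                        criteria: ContactCriteria | None = None,
                        inter_chain: bool | None = None) -> pd.DataFrame:
    """Residue-pair matrix of mean atomic contact numbers per frame,
    normalised by the chain count.

    For the directional MC-SC class, rows are the sidechain role and
    columns the mainchain role, so the SC->MC map is the transpose.
    """
    topo = traj.topology
    labels = _std_labels(topo)
    lab_of = topo.residue_label
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    bb = topo.is_backbone
    for f in traj:
        for r in _filter(detect_contacts(f, topo, criteria), None, inter_chain):
            li, lj = int(lab_of[r.residue_i]), int(lab_of[r.residue_j])
            if li not in mat.index or lj not in mat.index:
                continue
            bi, bj = bool(bb[r.atom_i]), bool(bb[r.atom_j])
            if cls == "any":
                mat.loc[li, lj] += 1.0
                if li != lj:
                    mat.loc[lj, li] += 1.0
            elif cls == "MC-SC":
                if r.cls != "MC-SC":
                    continue
                row, col = (lj, li) if bi else (li, lj)
                mat.loc[row, col] += 1.0
            else:
                if r.cls != cls:
                    continue
                mat.loc[li, lj] += 1.0
                if (li, lj) != (lj, li):
                    mat.loc[lj, li] += 1.0
    n = max(len(traj), 1) * max(topo.n_chains, 1)
    return mat / n
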