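"""Internal-coordinate peptide construction.

Builds capped peptide chains from ideal bond lengths/angles (NeRF chain
extension) at prescribed backbone dihedrals, grafting sidechain geometry
from the PDB chemical-component dictionary bundled with biotite.  Only
heavy atoms and polar hydrogens (backbone amide H, sidechain N-H, water H)
are produced; analyzers reconstruct nothing else.

All coordinates are nm.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .model import (
    SIDECHAIN_HEAVY,
    SIDECHAIN_POLAR_H,
    Frame,
    Residue,
    Topology,
    make_atom,
)

# ideal backbone internal coordinates (nm / degrees)
B_N_CA = 0.1458
B_CA_C = 0.1525
B_C_N = 0.1329
B_C_O = 0.1231
B_N_H = 0.100
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.5
A_C_N_H = 119.3
OMEGA = 180.0

#: CCD atom names to graft per residue, with renames applied
#: (acetyl-lysine acetyl oxygen OH -> OI2 to match the K280@OI2 convention).
_CCD_RENAMES = {"ALY": {"OH": "OI2"}}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # np.cross has high overhead for single 3-vectors
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position D bonded to ``a`` with angle(D,a,b) and dihedral(D,a,b,c)."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    b1 = _unit(a - b)
    n = _unit(_cross3(b - c, b1))
    m = _cross3(n, b1)
    d = (
        -bond * np.cos(theta) * b1
        + bond * np.sin(theta) * np.cos(phi) * m
        + bond * np.sin(theta) * np.sin(phi) * n
    )
    return a + d


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


@lru_cache(maxsize=32)
def _ccd_template(resname: str) -> dict[str, np.ndarray]:
    import biotite.structure.info as info

    arr = info.residue(resname)
    renames = _CCD_RENAMES.get(resname, {})
    out = {}
    for name, xyz in zip(arr.atom_name, arr.coord):
        out[renames.get(name, str(name))] = np.asarray(xyz, dtype=float) / 10.0
    return out


def _fit_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper-rotation least-squares fit mapping src points onto dst."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, dc - R @ sc


def _graft_sidechain(resname: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    """Sidechain atoms (name, xyz) placed by superposing the CCD template
    backbone (N, CA, C) onto the built backbone."""
    tmpl = _ccd_template(resname)
    src = np.array([tmpl["N"], tmpl["CA"], tmpl["C"]])
    dst = np.array([n, ca, c])
    R, t = _fit_rigid(src, dst)
    names = list(SIDECHAIN_HEAVY.get(resname, ()))
    names += [h for h, _ in SIDECHAIN_POLAR_H.get(resname, ())]
    return [(nm, R @ tmpl[nm] + t) for nm in names]


class ChainBuild:
    """A built chain: ordered residues of (resname, [(atom_name, xyz nm)])."""

    def __init__(self, residues: list[tuple[str, list[tuple[str, np.ndarray]]]]):
        self.residues = residues

    def coords(self) -> np.ndarray:
        return np.array([xyz for _, atoms in self.residues for _, xyz in atoms])

    def with_coords(self, coords: np.ndarray) -> "ChainBuild":
        out, k = [], 0
        for rname, atoms in self.residues:
            new_atoms = []
            for name, _ in atoms:
                new_atoms.append((name, coords[k].copy()))
                k += 1
            out.append((rname, new_atoms))
        return ChainBuild(out)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ChainBuild":
        return self.with_coords(self.coords() @ R.T + t)

    def atom_xyz(self, res_idx: int, name: str) -> np.ndarray:
        for nm, xyz in self.residues[res_idx][1]:
            if nm == name:
                return xyz
        raise KeyError(f"{self.residues[res_idx][0]}[{res_idx}] has no {name}")


def build_chain(sequence: tuple[str, ...], phis: np.ndarray, psis: np.ndarray,
                cap: bool = True) -> ChainBuild:
    """Build one capped chain at the given backbone dihedrals.

    ``phis``/``psis`` are per standard residue (degrees).  With ``cap=True``
    an ACE group precedes residue 1 and an NH2 group follows the last one.
    """
    if len(phis) != len(sequence) or len(psis) != len(sequence):
        raise ValueError("need one (phi, psi) pair per residue")
    residues: list[tuple[str, list[tuple[str, np.ndarray]]]] = []
    # ACE seed: CH3 at origin, C along +x, O in the xy-plane
    ch3 = np.zeros(3)
    c_prev = np.array([0.152, 0.0, 0.0])
    ang = np.deg2rad(A_CA_C_O)
    o_prev = c_prev + 0.1231 * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    if cap:
        residues.append(("ACE", [("CH3", ch3), ("C", c_prev.copy()), ("O", o_prev.copy())]))
    ca_prev = ch3
    for i, (rname, phi, psi) in enumerate(zip(sequence, phis, psis)):
        n = place_atom(c_prev, ca_prev, o_prev, B_C_N, A_CA_C_N, 180.0)
        h = place_atom(n, c_prev, o_prev, B_N_H, A_C_N_H, 180.0)
        ca = place_atom(n, c_prev, ca_prev, B_N_CA, A_C_N_CA, OMEGA)
        c = place_atom(ca, n, c_prev, B_CA_C, A_N_CA_C, phi)
        # the next amide N is placed anti to O about the C-CA axis, so psi is
        # realised by putting O at torsion psi (the O itself sits anti to N(i+1))
        o = place_atom(c, ca, n, B_C_O, A_CA_C_O, psi + 180.0)
        atoms = [("N", n), ("H", h), ("CA", ca), ("C", c), ("O", o)]
        atoms += _graft_sidechain(rname, n, ca, c)
        residues.append((rname, atoms))
        ca_prev, c_prev, o_prev = ca, c, o
        last_n = n
    if cap:
        n_cap = place_atom(c_prev, ca_prev, o_prev, B_C_N, A_CA_C_N, 180.0)
        h1 = place_atom(n_cap, c_prev, o_prev, B_N_H, A_C_N_H, 180.0)
        h2 = place_atom(n_cap, c_prev, o_prev, B_N_H, 120.5, 0.0)
        residues.append(("NH2", [("N", n_cap), ("HN1", h1), ("HN2", h2)]))
    return ChainBuild(residues)


def canonicalize(chain: ChainBuild) -> ChainBuild:
    """Rotate/translate so Cα centroid is at the origin, the first->last Cα
    vector points along +x and the first N lies in the +y half-plane."""
    ca = np.array(
        [chain.atom_xyz(i, "CA") for i, (rn, _) in enumerate(chain.residues) if rn not in ("ACE", "NH2")]
    )
    centroid = ca.mean(axis=0)
    axis = ca[-1] - ca[0]
    if np.linalg.norm(axis) < 1e-9:  # single residue: centre only
        return chain.with_coords(chain.coords() - centroid)
    x = _unit(axis)
    ref = None
    for i, (rn, _) in enumerate(chain.residues):
        if rn not in ("ACE", "NH2"):
            ref = chain.atom_xyz(i, "N") - ca[0]
            break
    y = ref - np.dot(ref, x) * x
    if np.linalg.norm(y) < 1e-9:
        y = np.array([0.0, 1.0, 0.0])
    y = _unit(y)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])
    return chain.with_coords((chain.coords() - centroid) @ R.T)


def assemble(chains: list[ChainBuild], box: np.ndarray | None = None,
             waters: list[np.ndarray] | None = None,
             seq_labels: tuple[int, ...] | None = None,
             time: float = 0.0) -> tuple[Topology, Frame]:
    """Combine built chains (+ optional water O/H1/H2 triplets) into the
    package Topology/Frame pair."""
    topo_chains: list[list[Residue]] = []
    coords: list[np.ndarray] = []
    for chain in chains:
        residues = []
        std_i = 0
        for rname, atoms in chain.residues:
            if rname in ("ACE", "NH2"):
                label = 0
            else:
                if seq_labels is not None and std_i < len(seq_labels):
                    label = seq_labels[std_i]
                else:
                    label = std_i + 1
                std_i += 1
            residues.append(
                Residue(
                    name=rname,
                    seq_label=label,
                    atoms=[make_atom(rname, nm) for nm, _ in atoms],
                    chain_index=-1,
                )
            )
            coords.extend(xyz for _, xyz in atoms)
        topo_chains.append(residues)
    water_res = []
    if waters:
        for w in waters:
            water_res.append(
                Residue(
                    name="SOL",
                    seq_label=0,
                    atoms=[make_atom("SOL", nm) for nm in ("OW", "HW1", "HW2")],
                    chain_index=-1,
                )
            )
            coords.extend(w)
    topo = Topology(topo_chains, water_res)
    return topo, Frame(np.array(coords), box=box, time=time)


def water_molecule(o_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """3-site rigid water (O, H1, H2) at a random orientation around o_pos."""
    r_oh = 0.09572
    half = np.deg2rad(104.52 / 2.0)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
            [-r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
        ]
    )
    R = random_rotation(rng)
    return local @ R.T + o_pos


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
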