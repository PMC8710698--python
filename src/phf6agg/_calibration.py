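"""Placement calibration for idealised beta-sheet and beta-barrel builders.

The sheet builder places each successive strand with a rigid transform; the
barrel builder places n copies of one (slightly coiled) strand template
with n-fold rotational symmetry about the barrel axis.  The transforms are
found once by least-squares fitting canonical backbone H-bond registries
(donor N...acceptor O distance 0.29 nm, N-H...O collinear) plus steric
floors, and the solutions are frozen in ``data/builder_params.json`` so
construction is fast and bit-reproducible.

Regenerate the table (after changing the backbone geometry constants)
with ``python -m phf6agg._calibration``.
"""

from __future__ import annotations

import json
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from ._geom import (
    A_C_N_CA,
    A_C_N_H,
    A_CA_C_N,
    A_CA_C_O,
    A_N_CA_C,
    B_C_N,
    B_C_O,
    B_CA_C,
    B_N_CA,
    B_N_H,
    place_atom,
)

BETA_PHI = -139.0
BETA_PSI = 135.0
SHEET_SPACING = 0.48  # nm, calibration spacing between strand axes
_DATA_PATH = Path(__file__).parent / "data" / "builder_params.json"

#: canonical backbone H-bond registry for a parallel in-register pair
#: (strand_of_donor, donor_residue, strand_of_acceptor, acceptor_residue)
PARALLEL_TARGETS = [(1, 1, 0, 0), (0, 2, 1, 1), (1, 3, 0, 2), (0, 4, 1, 3), (1, 5, 0, 4)]
#: antiparallel registry with direct (narrow) pairs at even residues
ANTIPARALLEL_TARGETS = [
    (0, 0, 1, 5), (1, 5, 0, 0),
    (0, 2, 1, 3), (1, 3, 0, 2),
    (0, 4, 1, 1), (1, 1, 0, 4),
]
#: reduced central registry used for barrels (rigid pairs under curvature)
BARREL_TARGETS = [(0, 2, 1, 1), (1, 3, 0, 2), (0, 4, 1, 3), (1, 5, 0, 4)]

BARREL_SIZES = tuple(range(4, 13))


def backbone_trace(phis: np.ndarray, psis: np.ndarray):
    """Backbone N,H,CA,C,O coordinate arrays (n_res, 3) for one capped
    chain, matching the geometry of :func:`phf6agg._geom.build_chain`."""
    ch3 = np.zeros(3)
    c_prev = np.array([0.152, 0.0, 0.0])
    ang = np.deg2rad(A_CA_C_O)
    o_prev = c_prev + 0.1231 * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    ca_prev = ch3
    out = [[], [], [], [], []]
    for phi, psi in zip(phis, psis):
        n = place_atom(c_prev, ca_prev, o_prev, B_C_N, A_CA_C_N, 180.0)
        h = place_atom(n, c_prev, o_prev, B_N_H, A_C_N_H, 180.0)
        ca = place_atom(n, c_prev, ca_prev, B_N_CA, A_C_N_CA, 180.0)
        c = place_atom(ca, n, c_prev, B_CA_C, A_N_CA_C, phi)
        o = place_atom(c, ca, n, B_C_O, A_CA_C_O, psi + 180.0)
        for arr, v in zip(out, (n, h, ca, c, o)):
            arr.append(v)
        ca_prev, c_prev, o_prev = ca, c, o
    return [np.array(x) for x in out]


def canonical_frame(bbs):
    """The canonicalisation used by the full builder, on backbone arrays."""
    N, H, CA, C, O = bbs
    centroid = CA.mean(axis=0)
    x = CA[-1] - CA[0]
    x = x / np.linalg.norm(x)
    ref = N[0] - CA[0]
    y = ref - np.dot(ref, x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])
    return [(b - centroid) @ R.T for b in bbs]


def _registry_residuals(b0, b1, targets, w_dist=80.0, w_ang=15.0):
    bs = (b0, b1)
    res = []
    for sd, rd, sa, ra in targets:
        Nd, Hd = bs[sd][0][rd], bs[sd][1][rd]
        Oa = bs[sa][4][ra]
        res.append(np.sqrt(w_dist) * (np.linalg.norm(Nd - Oa) - 0.29))
        v1, v2 = Nd - Hd, Oa - Hd
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        res.append(np.sqrt(w_ang) * (1.0 + cosang))
    return res


def _steric_residual(A, B, floor=0.24, w=400.0):
    dd = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    return np.sqrt(w * np.sum(np.maximum(0.0, floor - dd) ** 2))


def calibrate_sheet_transform(parallel: bool) -> np.ndarray:
    """Rigid transform (rotvec + translation, 6 floats) placing the next
    strand of a flat sheet relative to the canonical beta strand."""
    bbs = canonical_frame(backbone_trace(np.full(6, BETA_PHI), np.full(6, BETA_PSI)))
    A0 = np.vstack(bbs)
    targets = PARALLEL_TARGETS if parallel else ANTIPARALLEL_TARGETS

    def fun(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        b1 = [b @ R.T + p[3:] for b in bbs]
        res = _registry_residuals(bbs, b1, targets)
        res.append(_steric_residual(A0, np.vstack(b1)))
        return np.array(res)

    starts = []
    for rot0 in ([0.0, 0.0, 0.0],) if parallel else ([0.0, np.pi, 0.0], [0.0, 0.0, np.pi]):
        for dy in (SHEET_SPACING, -SHEET_SPACING):
            for dx in (-0.34, 0.0, 0.34):
                for dz in (-0.3, 0.0, 0.3):
                    starts.append(np.array([*rot0, dx, dy, dz]))
    best = None
    for p0 in starts:
        r = least_squares(fun, p0, method="lm", max_nfev=2000)
        if best is None or r.cost < best.cost:
            best = r
    return best.x


def calibrate_barrel_family(sizes=BARREL_SIZES) -> dict[int, np.ndarray]:
    """Per-size barrel placements: 18 floats (translation 3, rotation
    vector 3, per-residue phi deltas 6, psi deltas 6) for the template
    strand; strand k is the template rotated by 2*pi*k/n about z.

    Solved by continuation from the largest (least curved) size downward.
    """
    sizes = sorted(sizes, reverse=True)
    n_top = sizes[0]

    def build0(p):
        phis = BETA_PHI + p[6:12]
        psis = BETA_PSI + p[12:18]
        bbs = canonical_frame(backbone_trace(phis, psis))
        R = Rotation.from_rotvec(p[3:6]).as_matrix()
        return [b @ R.T + p[:3] for b in bbs]

    def make_fun(n):
        a = 2 * np.pi / n
        Ra = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])

        def fun(p):
            b0 = build0(p)
            b1 = [b @ Ra.T for b in b0]
            res = _registry_residuals(b0, b1, BARREL_TARGETS)
            A0, A1 = np.vstack(b0), np.vstack(b1)
            res.append(_steric_residual(A0, A1))
            A2 = np.vstack([b @ Ra.T for b in b1])
            res.append(_steric_residual(A0, A2))
            res.extend(0.05 * p[6:18])  # keep dihedrals near ideal beta
            return np.array(res)

        return fun

    def p0_from(tau_deg, spin, r_rad):
        tau = np.deg2rad(tau_deg)
        u = np.array([0, np.sin(tau), np.cos(tau)])
        h = np.array([0, np.cos(tau), -np.sin(tau)])
        M = np.column_stack([u, h, np.cross(u, h)]) @ Rotation.from_euler(
            "x", spin, degrees=True
        ).as_matrix()
        return np.concatenate([[r_rad, 0, 0], Rotation.from_matrix(M).as_rotvec(), np.zeros(12)])

    fun_top = make_fun(n_top)
    r_rad = n_top * SHEET_SPACING / (2 * np.pi)
    starts = []
    for tau_deg in (0, -15, 15):
        for spin in range(0, 360, 45):
            p0 = p0_from(tau_deg, spin, r_rad)
            starts.append((0.5 * np.sum(fun_top(p0) ** 2), p0))
    starts.sort(key=lambda t: t[0])
    best = None
    for _, p0 in starts[:8]:
        r = least_squares(fun_top, p0, method="lm", max_nfev=1500)
        if best is None or r.cost < best.cost:
            best = r
    sols = {n_top: best.x}
    p = best.x
    prev = n_top
    for n in sizes[1:]:
        p = p.copy()
        p[0] *= n / prev
        p[1] *= n / prev
        r = least_squares(make_fun(n), p, method="lm", max_nfev=2500)
        sols[n] = r.x
        p = r.x
        prev = n
    return sols


@lru_cache(maxsize=1)
def load_builder_params() -> dict:
    """Frozen builder placements (sheet transforms + barrel family)."""
    if _DATA_PATH.exists():
        with open(_DATA_PATH) as f:
            raw = json.load(f)
    else:  # fall back to a fresh calibration (slow, same result)
        raw = _compute_all()
    return {
        "sheet": {
            "parallel": np.array(raw["sheet"]["parallel"]),
            "antiparallel": np.array(raw["sheet"]["antiparallel"]),
            "spacing": raw["sheet"]["spacing"],
        },
        "barrel": {int(k): np.array(v) for k, v in raw["barrel"].items()},
    }


def _compute_all() -> dict:
    return {
        "sheet": {
            "parallel": list(calibrate_sheet_transform(True)),
            "antiparallel": list(calibrate_sheet_transform(False)),
            "spacing": SHEET_SPACING,
        },
        "barrel": {str(n): list(v) for n, v in calibrate_barrel_family().items()},
    }


def main() -> None:
    _DATA_PATH.parent.mkdir(parents=True, exist_ok=True)
    params = _compute_all()
    with open(_DATA_PATH, "w") as f:
        json.dump(params, f, indent=1)
    print(f"wrote {_DATA_PATH}")


if __name__ == "__main__":
    main()
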