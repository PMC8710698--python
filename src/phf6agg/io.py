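"""Structure and trajectory I/O.

File parsing/writing is delegated to MDAnalysis (PDB, GRO, XTC, TRR,
multi-model PDB); this module converts between the MDAnalysis picture
(Å, flat atom table) and the package's :class:`~phf6agg.model.Topology` /
:class:`~phf6agg.model.Frame` (nm, chains of capped residues).

Chain segmentation on load: a new peptide chain starts at every ACE cap,
after every NH2/NME cap, or when the PDB chain identifier changes; water
residues are collected separately.
"""

from __future__ import annotations

import string
import warnings
from pathlib import Path

import numpy as np

import MDAnalysis as mda
from MDAnalysis.coordinates.GRO import GROReader
from MDAnalysis.coordinates.PDB import PDBReader
from MDAnalysis.coordinates.TRR import TRRReader
from MDAnalysis.coordinates.XTC import XTCReader

from .model import (
    CAP_RESNAMES,
    SIDECHAIN_HEAVY,
    WATER_RESNAMES,
    Frame,
    ParseError,
    Residue,
    Topology,
    Trajectory,
    ValidationError,
    make_atom,
)

__all__ = ["load_structure", "write_structure", "load_trajectory", "write_trajectory"]

_KNOWN_RESIDUES = set(SIDECHAIN_HEAVY) | {"GLY", "ALA"} | CAP_RESNAMES | WATER_RESNAMES

_A_PER_NM = 10.0


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"pdb", "gro", "xtc", "trr"}:
        return suffix
    raise ParseError(f"cannot infer file format from {path!r}")


def _build_topology(resnames, resids, chain_ids, atom_names, extra_templates=None):
    """Group a flat residue table into chains/waters and classify atoms."""
    known = _KNOWN_RESIDUES | set(extra_templates or ())
    chains: list[list[Residue]] = []
    waters: list[Residue] = []
    current: list[Residue] | None = None
    prev_chain_id = None
    prev_was_cterm_cap = False
    for rname, rid, cid, names in zip(resnames, resids, chain_ids, atom_names):
        rname = rname.upper()
        if rname not in known:
            raise ParseError(
                f"unknown residue name {rname!r}; supply a template to load it"
            )
        atoms = [make_atom(rname, n) for n in names]
        res = Residue(name=rname, seq_label=int(rid), atoms=atoms, chain_index=-1)
        if res.is_water:
            waters.append(res)
            continue
        start_new = (
            current is None
            or rname == "ACE"
            or prev_was_cterm_cap
            or (cid is not None and cid != prev_chain_id)
        )
        if start_new:
            current = []
            chains.append(current)
        current.append(res)
        prev_chain_id = cid
        prev_was_cterm_cap = rname in {"NH2", "NME"}
    return Topology(chains, waters)


def load_structure(path: str | Path, fmt: str | None = None,
                   extra_templates: set[str] | None = None) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into (Topology, first Frame).

    Coordinates are converted to nm regardless of the on-disk unit
    convention (PDB Å, GRO nm).
    """
    fmt = _infer_format(path, fmt)
    if fmt not in {"pdb", "gro"}:
        raise ParseError(f"load_structure supports pdb/gro, not {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    resnames = [r.resname for r in u.residues]
    resids = [r.resid for r in u.residues]
    if hasattr(u.atoms, "chainIDs"):
        chain_ids = [r.atoms.chainIDs[0] for r in u.residues]
    else:
        chain_ids = [None] * len(u.residues)
    atom_names = [[a.name for a in r.atoms] for r in u.residues]
    topo = _build_topology(resnames, resids, chain_ids, atom_names, extra_templates)
    coords = _reordered_coords(u, resnames, atom_names, topo)
    box = _box_from_dimensions(u.dimensions)
    return topo, Frame(coords, box=box, time=0.0)


def _reordered_coords(u, resnames, atom_names, topo) -> np.ndarray:
    """Coordinates in topology atom order (waters are moved to the end)."""
    # map (file residue order) -> topology residue order: peptide residues
    # keep file order, waters are appended afterwards in file order.
    pep, wat = [], []
    for i, rn in enumerate(resnames):
        (wat if rn.upper() in WATER_RESNAMES else pep).append(i)
    order = pep + wat
    pos = []
    for i in order:
        pos.append(u.residues[i].atoms.positions)
    coords = np.vstack(pos) / _A_PER_NM
    if coords.shape[0] != topo.n_atoms:
        raise ParseError("atom count mismatch while reordering structure")
    return coords


def _box_from_dimensions(dims) -> np.ndarray | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if np.all(dims[:3] > 0):
        return dims[:3] / _A_PER_NM
    return None


def _writer_resids(topology: Topology) -> np.ndarray:
    """Author-facing residue numbers for writing: standard residues keep
    their seq_label (e.g. 275-280), caps take the adjacent number, waters
    are numbered sequentially after the peptide."""
    resids = np.zeros(len(topology.residues), dtype=int)
    for chain in topology.chains:
        std_labels = [r.seq_label for r in chain if r.is_standard]
        first, last = (std_labels[0], std_labels[-1]) if std_labels else (1, 1)
        for r in chain:
            if r.is_standard:
                resids[r.index] = r.seq_label
            elif r.name == "ACE":
                resids[r.index] = max(first - 1, 1)
            else:  # NH2 / NME
                resids[r.index] = last + 1
    for k, r in enumerate(topology.waters):
        resids[r.index] = k + 1
    return resids


def _universe_from(topology: Topology, frame: Frame) -> mda.Universe:
    n_res = len(topology.residues)
    atom_res = topology.atom_residue
    # segment per chain + one for water
    has_water = len(topology.waters) > 0
    n_seg = topology.n_chains + (1 if has_water else 0)
    res_seg = np.array(
        [c if c >= 0 else topology.n_chains for c in topology.residue_chain],
        dtype=int,
    )
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=n_res,
        n_segments=max(n_seg, 1),
        atom_resindex=atom_res,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
    u.add_TopologyAttr("resnames", [r.name for r in topology.residues])
    u.add_TopologyAttr("resids", _writer_resids(topology))
    letters = string.ascii_uppercase + string.ascii_lowercase + string.digits
    seg_letters = [letters[i % len(letters)] for i in range(max(n_seg, 1))]
    if has_water:
        seg_letters[-1] = "z"
    u.add_TopologyAttr("segids", seg_letters)
    u.add_TopologyAttr("chainIDs", [seg_letters[res_seg[ri]] for ri in atom_res])
    u.atoms.positions = frame.coords * _A_PER_NM
    if frame.box is not None:
        u.dimensions = [*(frame.box * _A_PER_NM), 90.0, 90.0, 90.0]
    return u


def write_structure(topology: Topology, frame: Frame, path: str | Path) -> None:
    """Write one conformation as PDB (Å) or GRO (nm) by file extension."""
    u = _universe_from(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB, XTC or TRR by extension."""
    u = _universe_from(traj.topology, traj.frames[0])
    fmt = Path(path).suffix.lower().lstrip(".")
    multiframe = fmt == "pdb"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms,
                        multiframe=multiframe) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coords * _A_PER_NM
                if fr.box is not None:
                    u.dimensions = [*(fr.box * _A_PER_NM), 90.0, 90.0, 90.0]
                u.trajectory.ts.time = fr.time
                w.write(u.atoms)


_READERS = {"pdb": PDBReader, "gro": GROReader, "xtc": XTCReader, "trr": TRRReader}


def load_trajectory(path: str | Path, topology: Topology, fmt: str | None = None,
                    window: tuple[float, float] | None = None,
                    temperature_label: float | None = None) -> Trajectory:
    """Read frames from XTC/TRR/multi-model-PDB against a known topology.

    Frames are kept in file order; ``window=(t_start, t_end)`` (ps) filters by
    frame time after loading.  A frame atom count differing from the topology
    raises :class:`~phf6agg.model.ValidationError`.
    """
    fmt = _infer_format(path, fmt)
    reader_cls = _READERS[fmt]
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    frames: list[Frame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(str(path))
        if reader.n_atoms != topology.n_atoms:
            raise ValidationError(
                f"trajectory has {reader.n_atoms} atoms per frame, "
                f"topology expects {topology.n_atoms}"
            )
        for k, ts in enumerate(reader):
            t = float(ts.time) if ts.time is not None else float(k)
            frames.append(
                Frame(
                    ts.positions / _A_PER_NM,
                    box=_box_from_dimensions(ts.dimensions),
                    time=t,
                    temperature_label=temperature_label,
                )
            )
        reader.close()
    traj = Trajectory(topology, frames)
    if window is not None:
        traj = traj.select_window(*window)
    return traj
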