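"""Core data model for multi-chain capped peptide systems.

The model targets small amyloidogenic peptide assemblies such as the tau
fibril-nucleating hexapeptide PHF6* (275-VQIINK-280), simulated as a dozen
ACE/NH2-capped chains in a periodic water box.  Internal units are nm for
lengths, ps for times, K for temperatures and kcal/mol for energies.

Atoms are classified into three roles used throughout the analyzers:

* **mainchain** (backbone): N, H, CA, C, O of standard residues plus the
  ACE (CH3CO-) and NH2 (-NH2) capping groups, which are backbone extensions
  with no sidechain;
* **sidechain**: every other peptide atom;
* **water**: solvent atoms (never backbone nor sidechain).

Residue numbering is 0-based internally; the author-facing labels 275-280
are kept as display metadata (``seq_label``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Frame",
    "Trajectory",
    "min_image_distance",
    "min_image_displacement",
    "ParseError",
    "ValidationError",
    "STANDARD_SEQ_LABELS",
]


class ParseError(ValueError):
    """A structure or trajectory file could not be interpreted."""


class ValidationError(ValueError):
    """A parsed structure violates a model invariant (e.g. missing backbone atom)."""


# ---------------------------------------------------------------------------
# chemical reference data
# ---------------------------------------------------------------------------

#: Bondi van der Waals radii, nm (overridable per-call in SASA).
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Mainchain atom names of a standard amino-acid residue (polar H included).
BACKBONE_ATOM_NAMES = {"N", "H", "HN", "CA", "C", "O", "OXT", "HA", "HA2", "HA3"}

#: Capping groups; all their atoms belong to the mainchain class.
CAP_RESNAMES = {"ACE", "NH2", "NME"}

WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "TIP3P", "SPC", "T3P"}

#: Wild-type PHF6* sequence and the author-facing residue labels.
PHF6_SEQUENCE = ("VAL", "GLN", "ILE", "ILE", "ASN", "LYS")
STANDARD_SEQ_LABELS = (275, 276, 277, 278, 279, 280)

#: Sidechain heavy-atom composition per residue template (used for
#: validation and for the sidechain H-bond donor/acceptor tables).
SIDECHAIN_HEAVY = {
    "VAL": ("CB", "CG1", "CG2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    # acetyl-lysine: acetyl carbonyl oxygen is named OI2 (as in the
    # H-bond occupancy nomenclature K280@OI2), carbonyl carbon CH,
    # methyl carbon CH3
    "ALY": ("CB", "CG", "CD", "CE", "NZ", "CH", "OI2", "CH3"),
}

#: Sidechain polar hydrogens and the heavy atom they ride on.
SIDECHAIN_POLAR_H = {
    "GLN": (("HE21", "NE2"), ("HE22", "NE2")),
    "ASN": (("HD21", "ND2"), ("HD22", "ND2")),
    "LYS": (("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")),
    "ALY": (("HZ", "NZ"),),
}

#: Sidechain H-bond donors: heavy atom -> names of attached polar H.
SIDECHAIN_DONORS = {
    "GLN": {"NE2": ("HE21", "HE22")},
    "ASN": {"ND2": ("HD21", "HD22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ALY": {"NZ": ("HZ",)},
}

#: Sidechain H-bond acceptors (lone-pair bearing O/N heavy atoms).
SIDECHAIN_ACCEPTORS = {
    "GLN": ("OE1",),
    "ASN": ("OD1",),
    "ALY": ("OI2",),
    "LYS": (),
    "VAL": (),
    "ILE": (),
}


def element_from_name(name: str) -> str:
    """Infer the chemical element from an atom name (first alphabetic char)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    index: int
    name: str
    element: str
    residue_index: int
    is_backbone: bool
    is_water: bool
    vdw_radius: float

    @property
    def is_sidechain(self) -> bool:
        return not self.is_water and not self.is_backbone

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    name: str
    seq_label: int
    atoms: list[Atom]
    chain_index: int
    index: int = -1  # global residue index, set by Topology

    @property
    def is_cap(self) -> bool:
        return self.name in CAP_RESNAMES

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESNAMES

    @property
    def is_standard(self) -> bool:
        return not self.is_cap and not self.is_water

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.seq_label} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


class Topology:
    """Atoms organised into peptide chains plus optional water.

    ``chains`` is an ordered list of chains, each an ordered list of
    :class:`Residue` (including the ACE / NH2 caps).  Water residues live in
    ``waters``.  Flat numpy views over all atoms (coordinates excluded; those
    live on :class:`Frame`) are cached for the vectorised analyzers.
    """

    def __init__(self, chains: Sequence[Sequence[Residue]], waters: Sequence[Residue] = ()):
        self.chains: list[list[Residue]] = [list(c) for c in chains]
        self.waters: list[Residue] = list(waters)
        self._index_atoms()
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _index_atoms(self) -> None:
        self.residues: list[Residue] = []
        idx = 0
        for ci, chain in enumerate(self.chains):
            for res in chain:
                res.chain_index = ci
                res.index = len(self.residues)
                self.residues.append(res)
        for res in self.waters:
            res.chain_index = -1
            res.index = len(self.residues)
            self.residues.append(res)
        self.atoms: list[Atom] = []
        for res in self.residues:
            for a in res.atoms:
                a.index = idx
                a.residue_index = res.index
                self.atoms.append(a)
                idx += 1
        n = len(self.atoms)
        self.atom_name = np.array([a.name for a in self.atoms], dtype=object)
        self.atom_element = np.array([a.element for a in self.atoms], dtype=object)
        self.atom_residue = np.array([a.residue_index for a in self.atoms], dtype=np.intp)
        self.atom_chain = np.array(
            [self.residues[a.residue_index].chain_index for a in self.atoms], dtype=np.intp
        )
        self.is_backbone = np.array([a.is_backbone for a in self.atoms], dtype=bool)
        self.is_water = np.array([a.is_water for a in self.atoms], dtype=bool)
        self.is_heavy = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self.vdw_radius = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        self.mass = np.array(
            [ATOMIC_MASSES.get(a.element, 12.011) for a in self.atoms], dtype=float
        )
        # residue-level metadata
        self.residue_name = np.array([r.name for r in self.residues], dtype=object)
        self.residue_chain = np.array([r.chain_index for r in self.residues], dtype=np.intp)
        self.residue_label = np.array([r.seq_label for r in self.residues], dtype=np.intp)
        # position of the residue within its chain (for sequence-adjacency tests)
        pos = np.zeros(len(self.residues), dtype=np.intp)
        for chain in self.chains:
            for k, res in enumerate(chain):
                pos[res.index] = k
        self.residue_chain_pos = pos

    def _validate(self) -> None:
        for chain in self.chains:
            for res in chain:
                if res.is_water:
                    raise ValidationError("water residue inside a peptide chain")
                if res.is_standard:
                    for req in ("N", "CA", "C", "O"):
                        if not res.has_atom(req):
                            raise ValidationError(
                                f"residue {res.name}{res.seq_label} lacks backbone atom {req}"
                            )

    # -- views ---------------------------------------------------------------

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def sequence(self) -> tuple[str, ...]:
        """Residue codes of the (shared) peptide chain, caps included."""
        if not self.chains:
            return ()
        return tuple(r.name for r in self.chains[0])

    def standard_residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c if r.is_standard]

    def iter_chain_standard(self) -> Iterator[list[Residue]]:
        for chain in self.chains:
            yield [r for r in chain if r.is_standard]

    def atom_indices(self, names: Sequence[str] | None = None, heavy: bool = False,
                     peptide_only: bool = True) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if peptide_only:
            mask &= ~self.is_water
        if heavy:
            mask &= self.is_heavy
        if names is not None:
            mask &= np.isin(self.atom_name, list(names))
        return np.nonzero(mask)[0]

    def calpha_indices(self) -> np.ndarray:
        """Indices of Cα atoms of standard residues, in chain order."""
        out = []
        for chain in self.chains:
            for res in chain:
                if res.is_standard:
                    out.append(res.atom("CA").index)
        return np.array(out, dtype=np.intp)


@dataclass
class Frame:
    """One conformation: coordinates in nm plus an orthorhombic box."""

    coords: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain non-finite values")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValidationError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Frame":
        return Frame(
            self.coords.copy(),
            None if self.box is None else self.box.copy(),
            self.time,
            self.temperature_label,
        )


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        times = [f.time for f in self.frames]
        for f in self.frames:
            if f.n_atoms != n:
                raise ValidationError(
                    f"frame has {f.n_atoms} atoms, topology has {n}"
                )
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def select_window(self, t_start: float, t_end: float) -> "Trajectory":
        """Restrict to frames with t_start <= time <= t_end (ps)."""
        kept = [f for f in self.frames if t_start <= f.time <= t_end]
        if not kept:
            raise ValidationError(
                f"no frames selected in window [{t_start}, {t_end}] ps"
            )
        return Trajectory(self.topology, kept, window=(t_start, t_end))


# ---------------------------------------------------------------------------
# periodic-distance arithmetic
# ---------------------------------------------------------------------------


def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Displacement b-a under the minimum-image convention (orthorhombic box).

    With ``box=None`` this is the plain Euclidean displacement.  Broadcasts
    over leading dimensions.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return d


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float | np.ndarray:
    """Minimum-image distance between positions ``a`` and ``b`` (nm)."""
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def classify_atom(res_name: str, atom_name: str) -> tuple[bool, bool]:
    """Return (is_backbone, is_water) for an atom by residue template."""
    if res_name in WATER_RESNAMES:
        return False, True
    if res_name in CAP_RESNAMES:
        return True, False
    return atom_name in BACKBONE_ATOM_NAMES, False


def make_atom(res_name: str, atom_name: str) -> Atom:
    element = element_from_name(atom_name)
    bb, wat = classify_atom(res_name, atom_name)
    return Atom(
        index=-1,
        name=atom_name,
        element=element,
        residue_index=-1,
        is_backbone=bb,
        is_water=wat,
        vdw_radius=BONDI_RADII_NM.get(element, 0.170),
    )
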