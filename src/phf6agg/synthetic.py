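"""Synthetic multi-chain conformer generator with known ground truth.

Stands in for undeposited simulation data of 12-chain capped VQIINK
(PHF6*) systems: it builds random-coil boxes, flat parallel/antiparallel
beta-sheets, bilayer sheets, closed beta-barrels and mixtures thereof,
each frame carrying a :class:`GroundTruth` record of what was planted
(strand pairings, barrel size, oligomer component sizes, backbone H-bond
registry), so every analyzer can be validated against construction.

Sheets and barrels use placement parameters calibrated once against the
canonical Kabsch-Sander H-bond registry (see ``_calibration``); coils draw
backbone dihedrals from broad basins that exclude the beta and alpha
cores, so planted classes stay separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from ._calibration import BETA_PHI, BETA_PSI, BARREL_TARGETS, PARALLEL_TARGETS, \
    ANTIPARALLEL_TARGETS, load_builder_params
from ._geom import (
    ChainBuild,
    assemble,
    build_chain,
    canonicalize,
    random_rotation,
    water_molecule,
)
from .model import (
    PHF6_SEQUENCE,
    STANDARD_SEQ_LABELS,
    Frame,
    Topology,
    Trajectory,
    ValidationError,
    min_image_displacement,
)

__all__ = [
    "GroundTruth",
    "EnsembleSpec",
    "sequence_for",
    "build_strand",
    "build_sheet",
    "build_barrel",
    "build_bilayer",
    "build_random_coil",
    "solvate_shell",
    "build_labeled_ensemble",
]

DEFAULT_BOX = np.array([6.88, 6.88, 6.88])  # nm, cubic simulation box
#: mixture weights used when an EnsembleSpec does not override them
DEFAULT_WEIGHTS = {"coil": 0.40, "sheet": 0.30, "bilayer": 0.15, "barrel": 0.15}


@dataclass(frozen=True)
class GroundTruth:
    """What was planted in one frame."""

    kind: str  # coil | sheet | bilayer | barrel | strand
    pairings: tuple[tuple[int, int, str], ...] = ()  # (chain_i, chain_j, orientation)
    barrel_size: int | None = None
    component_sizes: tuple[int, ...] = ()
    hbond_registry: tuple[tuple[int, int, int, int], ...] = ()
    # (donor chain, donor residue pos, acceptor chain, acceptor residue pos)


@dataclass(frozen=True)
class EnsembleSpec:
    n_chains: int = 12
    acetylated: bool = False
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    n_frames: int = 100
    seed: int = 0
    box: tuple[float, float, float] = tuple(DEFAULT_BOX)
    frame_spacing_ps: float = 100.0
    noise_sigma: float = 0.0  # nm, optional Gaussian coordinate noise
    coil_pool_size: int = 48  # distinct coil conformers sampled per ensemble
    barrel_sizes: tuple[int, ...] = (4, 5, 6, 7, 8)

    def __post_init__(self):
        w = self.weights
        if any(v < 0 for v in w.values()) or not np.isclose(sum(w.values()), 1.0):
            raise ValidationError("mixture weights must be >= 0 and sum to 1")
        unknown = set(w) - {"coil", "sheet", "bilayer", "barrel"}
        if unknown:
            raise ValidationError(f"unknown mixture classes: {sorted(unknown)}")
        if self.n_chains < 1 or self.n_frames < 1:
            raise ValidationError("n_chains and n_frames must be positive")


def sequence_for(acetylated: bool = False) -> tuple[str, ...]:
    """VQIINK residue codes, with ALY at the lysine when acetylated."""
    seq = list(PHF6_SEQUENCE)
    if acetylated:
        seq[-1] = "ALY"
    return tuple(seq)


def _known(sequence) -> None:
    from .model import SIDECHAIN_HEAVY

    for r in sequence:
        if r not in SIDECHAIN_HEAVY:
            raise ValidationError(f"unknown residue code {r!r}")


def _base_strand(sequence: tuple[str, ...], phi: float, psi: float) -> ChainBuild:
    _known(sequence)
    n = len(sequence)
    return canonicalize(build_chain(sequence, np.full(n, phi), np.full(n, psi)))


def build_strand(sequence: tuple[str, ...] | None = None, phi: float = BETA_PHI,
                 psi: float = BETA_PSI, acetylated: bool = False,
                 box: np.ndarray | None = None) -> tuple[Topology, Frame]:
    """One capped chain at uniform backbone dihedrals (ideal beta strand
    by default)."""
    seq = sequence_for(acetylated) if sequence is None else tuple(sequence)
    chain = _base_strand(seq, phi, psi)
    return assemble([chain], box=box, seq_labels=STANDARD_SEQ_LABELS)


def _sheet_chains(n_strands: int, parallel: bool, spacing: float,
                  sequence: tuple[str, ...]) -> tuple[list[ChainBuild], GroundTruth]:
    params = load_builder_params()["sheet"]
    p = params["parallel" if parallel else "antiparallel"]
    R = Rotation.from_rotvec(p[:3]).as_matrix()
    t = p[3:] * (spacing / params["spacing"])
    base = _base_strand(sequence, BETA_PHI, BETA_PSI)
    coords = base.coords()
    chains = []
    for _ in range(n_strands):
        chains.append(base.with_coords(coords))
        coords = coords @ R.T + t
    orient = "parallel" if parallel else "antiparallel"
    pairings = tuple((k, k + 1, orient) for k in range(n_strands - 1))
    targets = PARALLEL_TARGETS if parallel else ANTIPARALLEL_TARGETS
    registry = tuple(
        (k + sd, rd, k + sa, ra)
        for k in range(n_strands - 1)
        for sd, rd, sa, ra in targets
    )
    gt = GroundTruth(
        kind="sheet",
        pairings=pairings,
        component_sizes=(n_strands,),
        hbond_registry=registry,
    )
    return chains, gt


def build_sheet(n_strands: int, parallel: bool = False,
                inter_strand_spacing: float = 0.48,
                acetylated: bool = False,
                sequence: tuple[str, ...] | None = None,
                box: np.ndarray | None = None):
    """Flat beta-sheet of ``n_strands`` chains in canonical H-bond registry.

    Returns (Topology, Frame, GroundTruth).  Doubling the spacing moves
    the strands beyond every interaction cutoff while keeping the listed
    (now vacuous) pairing metadata out of the ground truth.
    """
    if n_strands < 2:
        raise ValidationError("a sheet needs at least 2 strands")
    seq = sequence_for(acetylated) if sequence is None else tuple(sequence)
    chains, gt = _sheet_chains(n_strands, parallel, inter_strand_spacing, seq)
    if inter_strand_spacing > 0.6:  # beyond all cutoffs: nothing is planted
        gt = GroundTruth(kind="sheet", component_sizes=tuple([1] * n_strands))
    topo, frame = assemble(chains, box=box, seq_labels=STANDARD_SEQ_LABELS)
    return topo, frame, gt


def _barrel_chains(n_strands: int, sequence: tuple[str, ...],
                   radius: float | None) -> tuple[list[ChainBuild], GroundTruth]:
    params = load_builder_params()["barrel"]
    if n_strands not in params:
        raise ValidationError(
            f"no barrel calibration for {n_strands} strands "
            f"(available: {sorted(params)})"
        )
    p = params[n_strands]
    phis = BETA_PHI + p[6:12]
    psis = BETA_PSI + p[12:18]
    _known(sequence)
    template = canonicalize(build_chain(sequence, phis, psis))
    R = Rotation.from_rotvec(p[3:6]).as_matrix()
    X = template.coords() @ R.T + p[:3]
    r_cal = float(np.linalg.norm(p[:2]))
    if radius is not None:
        if radius < 0.8 * r_cal:
            raise ValidationError(
                f"radius {radius:.2f} nm too small for {n_strands} strands "
                f"(strand pairs would overlap; calibrated radius {r_cal:.2f} nm)"
            )
        shift = (radius - r_cal) * p[:3] / max(np.linalg.norm(p[:3]), 1e-12)
        X = X + shift
    a = 2 * np.pi / n_strands
    Rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
    chains = []
    for _ in range(n_strands):
        chains.append(template.with_coords(X))
        X = X @ Rz.T
    pairings = tuple(
        (k, (k + 1) % n_strands, "parallel") for k in range(n_strands)
    )
    registry = tuple(
        (
            (k + sd) % n_strands, rd,
            (k + sa) % n_strands, ra,
        )
        for k in range(n_strands)
        for sd, rd, sa, ra in BARREL_TARGETS
    )
    gt = GroundTruth(
        kind="barrel",
        pairings=pairings,
        barrel_size=n_strands,
        component_sizes=(n_strands,),
        hbond_registry=registry,
    )
    return chains, gt


def build_barrel(n_strands: int, radius: float | None = None,
                 acetylated: bool = False,
                 sequence: tuple[str, ...] | None = None,
                 box: np.ndarray | None = None):
    """Closed beta-barrel: n strands on a cylinder, pairing graph one cycle.

    ``radius`` defaults to the calibrated value for the strand count; small
    deviations shift the ring radially, values below 80% of the calibrated
    radius are rejected (strands would overlap).
    """
    if not 4 <= n_strands <= 12:
        raise ValidationError("barrel size must be between 4 and 12 strands")
    seq = sequence_for(acetylated) if sequence is None else tuple(sequence)
    chains, gt = _barrel_chains(n_strands, seq, radius)
    topo, frame = assemble(chains, box=box, seq_labels=STANDARD_SEQ_LABELS)
    return topo, frame, gt


def build_bilayer(n_per_layer: int = 6, separation: float = 0.95,
                  parallel: bool = True, acetylated: bool = False,
                  box: np.ndarray | None = None):
    """Two stacked flat sheets whose sidechains interdigitate enough to
    form inter-layer contacts (one 2-layer oligomer, no inter-layer
    H-bond registry)."""
    if n_per_layer < 2:
        raise ValidationError("each layer needs at least 2 strands")
    seq = sequence_for(acetylated)
    layer1, gt1 = _sheet_chains(n_per_layer, parallel, 0.48, seq)
    layer2, _ = _sheet_chains(n_per_layer, parallel, 0.48, seq)
    # stack along the sheet normal: the normal of the calibrated sheet is
    # perpendicular to both the strand axis (x) and the stacking direction
    t = load_builder_params()["sheet"]["parallel" if parallel else "antiparallel"][3:]
    x = np.array([1.0, 0.0, 0.0])
    normal = np.cross(x, t)
    normal /= np.linalg.norm(normal)
    offset = separation * normal
    layer2 = [c.with_coords(c.coords() + offset) for c in layer2]
    chains = layer1 + layer2
    orient = "parallel" if parallel else "antiparallel"
    pairings = tuple((k, k + 1, orient) for k in range(n_per_layer - 1)) + tuple(
        (n_per_layer + k, n_per_layer + k + 1, orient) for k in range(n_per_layer - 1)
    )
    registry = tuple(gt1.hbond_registry) + tuple(
        (d + n_per_layer, rd, a + n_per_layer, ra)
        for d, rd, a, ra in gt1.hbond_registry
    )
    gt = GroundTruth(
        kind="bilayer",
        pairings=pairings,
        component_sizes=(2 * n_per_layer,),
        hbond_registry=registry,
    )
    topo, frame = assemble(chains, box=box, seq_labels=STANDARD_SEQ_LABELS)
    return topo, frame, gt


# ---------------------------------------------------------------------------
# random coils
# ---------------------------------------------------------------------------

_BETA_CORE = ((-174.0, -104.0), (100.0, 170.0))
_ALPHA_CORE = ((-98.0, -28.0), (-78.0, -8.0))


def _coil_dihedrals(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    phis, psis = np.empty(n), np.empty(n)
    for i in range(n):
        while True:
            phi = rng.uniform(-180.0, -40.0)
            psi = rng.uniform(-180.0, 180.0)
            in_beta = _BETA_CORE[0][0] < phi < _BETA_CORE[0][1] and _BETA_CORE[1][0] < psi < _BETA_CORE[1][1]
            in_alpha = _ALPHA_CORE[0][0] < phi < _ALPHA_CORE[0][1] and _ALPHA_CORE[1][0] < psi < _ALPHA_CORE[1][1]
            if not in_beta and not in_alpha:
                phis[i], psis[i] = phi, psi
                break
    return phis, psis


def _coil_chain(sequence, rng: np.random.Generator) -> ChainBuild:
    phis, psis = _coil_dihedrals(len(sequence), rng)
    return canonicalize(build_chain(sequence, phis, psis))


def _heavy_mask(ch: ChainBuild) -> np.ndarray:
    return np.array(
        [not nm.startswith("H") for _, atoms in ch.residues for nm, _ in atoms]
    )


def _place_chains(builds: list[ChainBuild], box: np.ndarray,
                  rng: np.random.Generator, min_sep: float = 0.2,
                  max_tries: int = 300) -> list[ChainBuild]:
    """Randomly rotate/translate chains into the box with a minimum
    inter-chain heavy-atom separation (minimum-image).

    A bounding-sphere pre-check skips the detailed atom-pair test for
    clearly separated chains.
    """
    placed: list[ChainBuild] = []
    placed_heavy: list[np.ndarray] = []
    placed_center: list[np.ndarray] = []
    placed_radius: list[float] = []
    half_diag = float(np.linalg.norm(box) / 2.0)
    for ch in builds:
        base = ch.coords()
        base = base - base.mean(axis=0)
        hmask = _heavy_mask(ch)
        radius = float(np.linalg.norm(base[hmask], axis=1).max())
        ok = False
        for _ in range(max_tries):
            R = random_rotation(rng)
            t = rng.uniform(0.0, 1.0, 3) * box
            cand = base @ R.T + t
            ch_heavy = cand[hmask]
            good = True
            for other, oc, orad in zip(placed_heavy, placed_center, placed_radius):
                cdist = np.linalg.norm(min_image_displacement(t, oc, box))
                if cdist > min(radius + orad + min_sep, half_diag):
                    continue
                d = min_image_displacement(
                    ch_heavy[:, None, :], other[None, :, :], box
                )
                if np.min(np.sum(d * d, axis=-1)) < min_sep**2:
                    good = False
                    break
            if good:
                placed.append(ch.with_coords(cand))
                placed_heavy.append(ch_heavy)
                placed_center.append(t)
                placed_radius.append(radius)
                ok = True
                break
        if not ok:
            raise ValidationError(
                f"could not place chain without overlap after {max_tries} tries"
            )
    return placed


def build_random_coil(n_chains: int = 12, seed: int | np.random.Generator = 0,
                      box: np.ndarray | None = None,
                      acetylated: bool = False) -> tuple[Topology, Frame]:
    """Randomly placed random-coil chains in a periodic box (>= 0.2 nm
    heavy-atom separation between chains); bit-deterministic under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    box = DEFAULT_BOX if box is None else np.asarray(box, dtype=float)
    seq = sequence_for(acetylated)
    builds = [_coil_chain(seq, rng) for _ in range(n_chains)]
    placed = _place_chains(builds, box, rng)
    return assemble(placed, box=box, seq_labels=STANDARD_SEQ_LABELS)


def solvate_shell(topology: Topology, frame: Frame, n_waters: int,
                  shell: float = 0.35, seed: int | np.random.Generator = 0,
                  target_atoms: np.ndarray | None = None,
                  min_dist: float = 0.25, max_tries: int = 2000):
    """Place ``n_waters`` rigid 3-site waters with their oxygens at
    0.25..shell nm from randomly chosen target solute atoms, rejecting
    overlaps below ``min_dist``.  Returns a new (Topology, Frame)."""
    if n_waters < 0:
        raise ValidationError("n_waters must be >= 0")
    if n_waters == 0:
        return topology, frame
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target_atoms is None:
        target_atoms = topology.atom_indices(heavy=True, peptide_only=True)
    target_atoms = np.asarray(target_atoms, dtype=np.intp)
    heavy = topology.atom_indices(heavy=True, peptide_only=True)
    occupied = [frame.coords[heavy]]
    waters = []
    for _ in range(n_waters):
        placed = False
        for _try in range(max_tries):
            anchor = frame.coords[rng.choice(target_atoms)]
            r = rng.uniform(min_dist, shell)
            direction = random_rotation(rng) @ np.array([1.0, 0.0, 0.0])
            o = anchor + r * direction
            all_occ = np.vstack(occupied)
            d = np.sqrt(np.sum((all_occ - o) ** 2, axis=1))
            if np.min(d) >= min_dist:
                waters.append(water_molecule(o, rng))
                occupied.append(o[None, :])
                placed = True
                break
        if not placed:
            raise ValidationError("could not place water without overlap")
    # rebuild the topology with waters appended
    chains = []
    k = 0
    coords_iter = frame.coords
    from ._geom import assemble as _assemble

    chain_builds = []
    for chain in topology.chains:
        residues = []
        for res in chain:
            atoms = []
            for a in res.atoms:
                atoms.append((a.name, coords_iter[a.index].copy()))
            residues.append((res.name, atoms))
        chain_builds.append(ChainBuild(residues))
    labels = tuple(
        r.seq_label for r in topology.chains[0] if r.is_standard
    ) if topology.chains else ()
    return _assemble(chain_builds, box=frame.box, waters=waters,
                     seq_labels=labels, time=frame.time)


# ---------------------------------------------------------------------------
# labelled mixture ensembles
# ---------------------------------------------------------------------------


def _isolated_coils(n: int, seq, rng, box, keepout: np.ndarray | None):
    """Coil chains placed with > 0.6 nm separation from keepout coords and
    from each other, so they stay contact-free singleton components."""
    builds = [_coil_chain(seq, rng) for _ in range(n)]
    placed = []
    obstacles = [] if keepout is None else [keepout]
    for ch in builds:
        base = ch.coords() - ch.coords().mean(axis=0)
        done = False
        for _ in range(400):
            R = random_rotation(rng)
            t = rng.uniform(0.0, 1.0, 3) * box
            cand = base @ R.T + t
            ok = True
            for obs in obstacles:
                d = min_image_displacement(cand[:, None, :], obs[None, :, :], box)
                if np.min(np.sqrt(np.sum(d * d, axis=-1))) < 0.62:
                    ok = False
                    break
            if ok:
                placed.append(ch.with_coords(cand))
                obstacles.append(cand)
                done = True
                break
        if not done:
            raise ValidationError("could not isolate coil chain in box")
    return placed


def _frame_chains(kind: str, spec: EnsembleSpec, rng: np.random.Generator,
                  coil_pool: list[ChainBuild]):
    """Chain builds + ground truth for one mixture frame."""
    box = np.asarray(spec.box)
    seq = sequence_for(spec.acetylated)
    n = spec.n_chains
    if kind == "coil":
        builds = [coil_pool[rng.integers(len(coil_pool))] for _ in range(n)]
        placed = _place_chains(builds, box, rng)
        gt = GroundTruth(kind="coil", component_sizes=tuple(), pairings=())
        return placed, gt
    if kind == "sheet":
        parallel = bool(rng.integers(2))
        chains, gt = _sheet_chains(n, parallel, 0.48, seq)
    elif kind == "bilayer":
        chains, gt = _bilayer_chains(n // 2, spec.acetylated)
    elif kind == "barrel":
        size = int(rng.choice(spec.barrel_sizes))
        chains, gt = _barrel_chains(size, seq, None)
    else:
        raise ValidationError(f"unknown mixture class {kind!r}")
    # random rigid placement of the structured block in the box
    block = np.vstack([c.coords() for c in chains])
    center = block.mean(axis=0)
    R = random_rotation(rng)
    t = box / 2.0
    chains = [c.with_coords((c.coords() - center) @ R.T + t) for c in chains]
    block = np.vstack([c.coords() for c in chains])
    extra = n - len(chains)
    if extra > 0:
        coils = _isolated_coils(extra, seq, rng, box, keepout=block)
        chains = chains + coils
        gt = replace(
            gt,
            component_sizes=tuple(list(gt.component_sizes) + [1] * extra),
        )
    return chains, gt


def _bilayer_chains(n_per_layer: int, acetylated: bool):
    seq = sequence_for(acetylated)
    layer1, gt1 = _sheet_chains(n_per_layer, True, 0.48, seq)
    layer2, _ = _sheet_chains(n_per_layer, True, 0.48, seq)
    t = load_builder_params()["sheet"]["parallel"][3:]
    normal = np.cross(np.array([1.0, 0.0, 0.0]), t)
    normal /= np.linalg.norm(normal)
    layer2 = [c.with_coords(c.coords() + 0.95 * normal) for c in layer2]
    pairings = tuple((k, k + 1, "parallel") for k in range(n_per_layer - 1)) + tuple(
        (n_per_layer + k, n_per_layer + k + 1, "parallel")
        for k in range(n_per_layer - 1)
    )
    registry = tuple(gt1.hbond_registry) + tuple(
        (d + n_per_layer, rd, a + n_per_layer, ra)
        for d, rd, a, ra in gt1.hbond_registry
    )
    gt = GroundTruth(
        kind="bilayer",
        pairings=pairings,
        component_sizes=(2 * n_per_layer,),
        hbond_registry=registry,
    )
    return layer1 + layer2, gt


def build_labeled_ensemble(spec: EnsembleSpec) -> tuple[Trajectory, list[GroundTruth]]:
    """Mixture ensemble: frames drawn i.i.d. from the class weights under
    the spec seed, with per-frame ground truth."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box)
    seq = sequence_for(spec.acetylated)
    kinds = [k for k in ("coil", "sheet", "bilayer", "barrel") if spec.weights.get(k, 0) > 0]
    probs = np.array([spec.weights[k] for k in kinds])
    coil_pool = [_coil_chain(seq, rng) for _ in range(spec.coil_pool_size)]
    frames: list[Frame] = []
    truths: list[GroundTruth] = []
    topo: Topology | None = None
    for fi in range(spec.n_frames):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        chains, gt = _frame_chains(kind, spec, rng, coil_pool)
        if topo is None:
            # the topology is identical across frames (same chains, same
            # builder atom order); build it once
            topo, f = assemble(chains, box=box, seq_labels=STANDARD_SEQ_LABELS,
                               time=fi * spec.frame_spacing_ps)
            coords = f.coords
        else:
            coords = np.vstack([c.coords() for c in chains])
            if coords.shape[0] != topo.n_atoms:
                raise ValidationError("inconsistent atom counts across frames")
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames.append(Frame(coords, box=box.copy(), time=fi * spec.frame_spacing_ps))
        truths.append(gt)
    return Trajectory(topo, frames), truths
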