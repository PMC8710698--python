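"""Chain-level aggregation statistics: oligomer size distributions from the
chain-contact graph and beta-barrel detection from strand-pairing topology.

Two peptide chains belong to the same oligomer when they share at least
``min_atom_contacts`` heavy-atom contacts (one by default).  Beta-strands
(maximal runs of E codes) are *paired* when they share at least two
Kabsch-Sander bridges, i.e. when they form a ladder; a closed beta-barrel
is a connected component of the pairing graph that is a single cycle in
which every strand pairs with exactly two neighbours, with at least four
members.  Near-cycles missing a single edge are reported as open barrels
and excluded from the size distribution by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .interactions import ContactCriteria, detect_contacts
from .model import Frame, Topology, Trajectory, ValidationError
from .secondary_structure import assign_with_bridges, strand_segments

__all__ = [
    "chain_adjacency",
    "oligomer_size_distribution",
    "component_sizes",
    "strand_pairing_graph",
    "detect_beta_barrels",
    "barrel_size_distribution",
    "BarrelRecord",
]

MIN_BARREL_SIZE = 4
#: bridges shared by two strands to count as paired (a ladder rung)
MIN_PAIRING_BRIDGES = 2


def chain_adjacency(frame: Frame, topology: Topology,
                    criteria: ContactCriteria | None = None,
                    min_atom_contacts: int = 1) -> nx.Graph:
    """Undirected chain-contact graph: nodes are chain indices, an edge
    joins chains sharing >= min_atom_contacts atomic contacts."""
    if topology.n_chains < 1:
        raise ValidationError("no chains in topology")
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_chains))
    counts: dict[tuple[int, int], int] = {}
    for rec in detect_contacts(frame, topology, criteria):
        if not rec.inter_chain:
            continue
        key = tuple(sorted((rec.chain_i, rec.chain_j)))
        counts[key] = counts.get(key, 0) + 1
    for (i, j), c in counts.items():
        if c >= min_atom_contacts:
            g.add_edge(i, j, n_contacts=c)
    return g


def component_sizes(graph: nx.Graph) -> list[int]:
    """Connected-component sizes, descending; they sum to n_chains."""
    return sorted((len(c) for c in nx.connected_components(graph)), reverse=True)


def oligomer_size_distribution(traj: Trajectory,
                               criteria: ContactCriteria | None = None,
                               min_atom_contacts: int = 1,
                               weighting: str = "component") -> pd.Series:
    """Probability of oligomer size s over all frames.

    ``weighting='component'`` (default) counts every connected component
    once; ``weighting='chain'`` weights each component by its chain count,
    i.e. the probability that a randomly picked chain sits in a size-s
    oligomer.  The published normalisation is unstated, so both are
    available.
    """
    if weighting not in ("component", "chain"):
        raise ValidationError("weighting must be 'component' or 'chain'")
    counts: dict[int, float] = {}
    total = 0.0
    for f in traj:
        g = chain_adjacency(f, traj.topology, criteria, min_atom_contacts)
        for s in component_sizes(g):
            w = float(s) if weighting == "chain" else 1.0
            counts[s] = counts.get(s, 0.0) + w
            total += w
    sizes = sorted(counts)
    return pd.Series([counts[s] / total for s in sizes], index=sizes, name="probability")


@dataclass(frozen=True)
class BarrelRecord:
    members: tuple[tuple[int, int, int], ...]  # (chain, start_col, end_col)
    size: int
    closed: bool


def strand_pairing_graph(frame: Frame, topology: Topology,
                         codes: np.ndarray | None = None,
                         bridges: list[tuple[int, int, str]] | None = None) -> nx.Graph:
    """Pairing graph over beta-strand segments.

    Nodes are maximal E-segments ``(chain, start_col, end_col)``; an edge
    joins two segments sharing >= 2 Kabsch-Sander bridges (a ladder).
    Edges carry an ``orientation`` attribute ('parallel'/'antiparallel')
    determined by the dot product of the two strand direction vectors
    (first to last C-alpha).
    """
    if codes is None or bridges is None:
        codes, bridges = assign_with_bridges(frame, topology)
    std = topology.standard_residues()
    chain_col = np.array([r.chain_index for r in std], dtype=np.intp)
    pos_col = np.array([topology.residue_chain_pos[r.index] for r in std], dtype=np.intp)
    segs = strand_segments(codes, chain_col, pos_col)
    g = nx.Graph()
    col2seg: dict[int, int] = {}
    for si, (ci, a, b) in enumerate(segs):
        g.add_node((ci, a, b))
        for col in range(a, b + 1):
            col2seg[col] = si
    seg_nodes = [tuple(s) for s in segs]
    pair_bridges: dict[tuple[int, int], int] = {}
    for i, j, _t in bridges:
        si, sj = col2seg.get(i), col2seg.get(j)
        if si is None or sj is None or si == sj:
            continue
        key = tuple(sorted((si, sj)))
        pair_bridges[key] = pair_bridges.get(key, 0) + 1
    ca = {}

    def direction(seg):
        ci, a, b = seg
        if seg not in ca:
            ra, rb = std[a], std[b]
            va = frame.coords[ra.atom("CA").index]
            vb = frame.coords[rb.atom("CA").index]
            ca[seg] = vb - va
        return ca[seg]

    for (si, sj), n in pair_bridges.items():
        if n >= MIN_PAIRING_BRIDGES:
            sa, sb = seg_nodes[si], seg_nodes[sj]
            da, db = direction(sa), direction(sb)
            dot = float(np.dot(da, db))
            g.add_edge(sa, sb, n_bridges=n,
                       orientation="parallel" if dot >= 0 else "antiparallel")
    return g


def detect_beta_barrels(pairing: nx.Graph,
                        include_open: bool = False) -> list[BarrelRecord]:
    """Closed barrels: connected components that are single cycles with
    every member of degree exactly 2 and >= 4 members.  With
    ``include_open=True``, path components one edge short of a cycle are
    also reported (closed=False)."""
    out: list[BarrelRecord] = []
    for comp in nx.connected_components(pairing):
        comp = list(comp)
        n = len(comp)
        if n < MIN_BARREL_SIZE:
            continue
        sub = pairing.subgraph(comp)
        degs = [d for _, d in sub.degree()]
        if all(d == 2 for d in degs) and sub.number_of_edges() == n:
            out.append(BarrelRecord(tuple(sorted(comp)), n, True))
        elif include_open and sub.number_of_edges() == n - 1 and max(degs) == 2:
            out.append(BarrelRecord(tuple(sorted(comp)), n, False))
    return out


def barrel_size_distribution(traj: Trajectory,
                             include_open: bool = False) -> pd.Series:
    """Fraction of frames containing a closed barrel of size s."""
    counts: dict[int, int] = {}
    for f in traj:
        g = strand_pairing_graph(f, traj.topology)
        seen = {b.size for b in detect_beta_barrels(g, include_open)}
        for s in seen:
            counts[s] = counts.get(s, 0) + 1
    n = max(len(traj), 1)
    sizes = sorted(counts)
    return pd.Series([counts[s] / n for s in sizes], index=sizes, name="probability")
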