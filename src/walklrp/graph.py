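"""Cutoff neighbor graphs over conformers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformer import Conformer

__all__ = ["NeighborGraph", "build_neighbor_graph"]


@dataclass
class NeighborGraph:
    """Directed cutoff graph: edge (j, k) present iff 0 < r_jk < cutoff.

    Edges come in both directions for every undirected pair; self edges are
    never stored (the model's combine step handles the self-transition).
    """

    n_atoms: int
    cutoff: float
    edges: np.ndarray  # (E, 2) int, rows (j, k): message source j -> target k
    distances: np.ndarray  # (E,) float, Å
    neighbors: list[list[int]] = field(repr=False)  # neighbors[k] = sources j

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_index(self) -> dict[tuple[int, int], int]:
        return {(int(j), int(k)): e for e, (j, k) in enumerate(self.edges)}


def build_neighbor_graph(conformer: Conformer, cutoff: float) -> NeighborGraph:
    """Build the directed neighbor graph within ``cutoff`` Å (exclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = conformer.n_atoms
    dmat = conformer.distance_matrix()
    off = ~np.eye(n, dtype=bool)
    if n > 1 and dmat[off].min() <= 0.0:
        raise ValueError("coincident atoms in conformer")
    src, dst = np.nonzero(off & (dmat < cutoff))
    edges = np.column_stack([src, dst]).astype(int)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for j, k in edges:
        neighbors[int(k)].append(int(j))
    return NeighborGraph(
        n_atoms=n,
        cutoff=float(cutoff),
        edges=edges,
        distances=dmat[src, dst],
        neighbors=neighbors,
    )
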