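"""Edge-list boundary sampling for the lattice Monte Carlo algorithm.

Instead of proposing copies between arbitrary site pairs (almost all of
which are no-ops deep inside a cell), the simulator tracks the set E of
directed boundary pairs -- (site, neighbor) with unequal spins -- in two
mutually indexing arrays:

* ``edge_of_index[i]`` gives the edge number of flattened pair index
  ``i = (y*W + x)*8 + slot`` or -1 when the pair is not a boundary pair;
* ``index_of_edge[k]`` gives, for edge numbers k < |E|, the pair index,
  and -1 beyond.

The 1-to-1 relationship between the two arrays allows O(1) uniform
sampling of a boundary pair and O(1) insertion/removal when a copy is
accepted: a removed edge is back-filled with the edge stored at |E|-1,
so the dense prefix never needs defragmentation.  Both orientations of
every boundary pair are stored, so |E| counts directed pairs; one Monte
Carlo step performs |E|/n_NB copy attempts.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._kernels import N_NB, NBX, NBY
from .lattice import Lattice

__all__ = ["EdgeList", "check_bijection", "brute_force_edges"]


def check_bijection(edge_of_index: np.ndarray, index_of_edge: np.ndarray,
                    n_edges: int | None = None) -> bool:
    """Verify the 1-to-1 relationship between the two edge arrays.

    ``edge_of_index[i] = k`` must hold exactly when
    ``index_of_edge[k] = i`` for k < |E|; all later entries of
    ``index_of_edge`` and all non-boundary entries of ``edge_of_index``
    must be -1.  |E| is inferred from the dense prefix when not given.
    """
    edge_of_index = np.asarray(edge_of_index)
    index_of_edge = np.asarray(index_of_edge)
    valid = index_of_edge >= 0
    if n_edges is None:
        n_edges = int(valid.sum())
    # dense prefix
    if not np.all(valid[:n_edges]) or np.any(valid[n_edges:]):
        return False
    k = np.nonzero(edge_of_index >= 0)[0]
    if len(k) != n_edges:
        return False
    # forward: edge_of_index[index_of_edge[e]] == e
    if not np.array_equal(edge_of_index[index_of_edge[:n_edges]],
                          np.arange(n_edges)):
        return False
    # backward: index_of_edge[edge_of_index[i]] == i for boundary pairs
    return bool(np.array_equal(index_of_edge[edge_of_index[k]], k))


def brute_force_edges(spins: np.ndarray) -> set[int]:
    """Reference edge set: scan all (site, neighbor) pairs directly."""
    h, w = spins.shape
    edges = set()
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            for k in range(N_NB):
                xn, yn = x + NBX[k], y + NBY[k]
                if xn <= 0 or xn >= w - 1 or yn <= 0 or yn >= h - 1:
                    continue
                if spins[yn, xn] != spins[y, x]:
                    edges.add((y * w + x) * N_NB + k)
    return edges


class EdgeList:
    """The paired arrays tracking all boundary site-pairs of a lattice."""

    def __init__(self, lattice: Lattice):
        self.lattice = lattice
        size = lattice.width * lattice.height * N_NB
        self.edge_of_index = np.full(size, -1, dtype=np.int32)
        self.index_of_edge = np.full(size, -1, dtype=np.int32)
        self.n_edges = 0
        self.rebuild()

    def rebuild(self) -> None:
        """Rebuild both arrays from scratch by scanning the lattice."""
        self.n_edges = int(_kernels.build_edge_list(
            self.lattice.spins, self.edge_of_index, self.index_of_edge))

    def __len__(self) -> int:
        return self.n_edges

    @staticmethod
    def decode(i: int, width: int) -> tuple[int, int, int]:
        """Pair index -> (x, y, neighbor slot), 0-based coordinates."""
        p, slot = divmod(int(i), N_NB)
        return p % width, p // width, slot

    def sample_edge(self, rng: np.random.Generator) -> tuple[tuple[int, int], tuple[int, int]]:
        """Uniformly sample a boundary pair; returns (site, neighbor) coords.

        Raises if the configuration has frozen (|E| = 0); the Monte
        Carlo step then simply performs no attempts.
        """
        if self.n_edges == 0:
            raise RuntimeError("no boundary pairs: configuration is frozen")
        i = self.index_of_edge[int(rng.integers(self.n_edges))]
        x, y, slot = self.decode(i, self.lattice.width)
        return (x, y), (x + int(NBX[slot]), y + int(NBY[slot]))

    def update_after_copy(self, x: int, y: int) -> None:
        """Restore the invariant after the spin at (x, y) changed."""
        self.n_edges = int(_kernels.update_edges_after_copy(
            self.lattice.spins, x, y, self.edge_of_index,
            self.index_of_edge, self.n_edges))

    def edge_set(self) -> set[int]:
        """Current edge pair-indices (for comparison against brute force)."""
        return set(self.index_of_edge[:self.n_edges].tolist())

    def validate(self) -> None:
        """Debug check: bijection invariant plus agreement with a fresh scan."""
        if not check_bijection(self.edge_of_index, self.index_of_edge,
                               self.n_edges):
            raise AssertionError("edge-list bijection invariant violated")
        if self.edge_set() != brute_force_edges(self.lattice.spins):
            raise AssertionError("edge list disagrees with lattice scan")

    def to_frame(self):
        """Both arrays as a DataFrame (debug dump / regression tests)."""
        import pandas as pd
        return pd.DataFrame({"index": np.arange(len(self.edge_of_index)),
                             "edgelist": self.edge_of_index,
                             "edgeindices": self.index_of_edge})
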