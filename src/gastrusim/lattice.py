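"""Lattice state, cell bookkeeping and the CPM Hamiltonian.

The lattice is a 2D spin field sigma(x) on a W x H grid with a one-site
frame that is permanently medium and excluded from all neighborhoods
(no adhesion across the frame, no copies into or out of it).  Cells are
the sets of sites sharing a nonzero spin; per-cell bookkeeping (type,
area, raw coordinate moments) is maintained incrementally during Monte
Carlo runs and can always be recomputed exactly from the spin field.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._kernels import N_NB
from .params import CPMParams

__all__ = ["Lattice", "hamiltonian", "cell_length", "metropolis_accept"]

# forward half of the Moore neighborhood: each adjacent pair counted once
_FWD = [(1, 0), (0, 1), (1, 1), (-1, 1)]


class Lattice:
    """Spin field plus per-cell bookkeeping.

    Parameters
    ----------
    width, height : int
        Full allocated lattice size, including the one-site frame.
    max_cells : int
        Highest cell ID that may appear (IDs are 1..max_cells; 0 is
        the medium).
    """

    def __init__(self, width: int, height: int, max_cells: int):
        if width < 4 or height < 4:
            raise ValueError("lattice too small")
        self.width = int(width)
        self.height = int(height)
        self.max_cells = int(max_cells)
        self.spins = np.zeros((self.height, self.width), dtype=np.int32)
        n = self.max_cells + 1
        self.cell_type = np.zeros(n, dtype=np.int32)
        self.area = np.zeros(n, dtype=np.int64)
        self.sx = np.zeros(n, dtype=np.float64)
        self.sy = np.zeros(n, dtype=np.float64)
        self.sxx = np.zeros(n, dtype=np.float64)
        self.syy = np.zeros(n, dtype=np.float64)
        self.sxy = np.zeros(n, dtype=np.float64)
        self.comx = np.zeros(n, dtype=np.float64)
        self.comy = np.zeros(n, dtype=np.float64)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_array(cls, spins: np.ndarray, cell_types: dict[int, int] | None = None,
                   pad_frame: bool = True) -> "Lattice":
        """Build a lattice (and its bookkeeping) from a spin array.

        ``cell_types`` maps cell ID -> type; unlisted cells get type 1.
        With ``pad_frame`` the array is surrounded by a medium frame.
        """
        spins = np.asarray(spins, dtype=np.int32)
        if pad_frame:
            spins = np.pad(spins, 1, constant_values=0)
        h, w = spins.shape
        max_cell = int(spins.max(initial=0))
        lat = cls(w, h, max(max_cell, 1))
        lat.spins[:] = spins
        lat.spins[0, :] = lat.spins[-1, :] = 0
        lat.spins[:, 0] = lat.spins[:, -1] = 0
        for s in range(1, max_cell + 1):
            lat.cell_type[s] = 1
        if cell_types:
            for s, t in cell_types.items():
                lat.cell_type[s] = t
        lat.recompute_stats()
        return lat

    def place_cell(self, cell_id: int, sites: np.ndarray, cell_type: int = 1) -> None:
        """Assign ``sites`` (array of (x, y)) to ``cell_id`` and update stats."""
        sites = np.asarray(sites)
        self.spins[sites[:, 1], sites[:, 0]] = cell_id
        self.cell_type[cell_id] = cell_type
        self._recompute_cell(cell_id)

    # -- bookkeeping ----------------------------------------------------
    def _recompute_cell(self, s: int) -> None:
        ys, xs = np.nonzero(self.spins == s)
        x = xs.astype(np.float64)
        y = ys.astype(np.float64)
        self.area[s] = len(xs)
        self.sx[s] = x.sum()
        self.sy[s] = y.sum()
        self.sxx[s] = (x * x).sum()
        self.syy[s] = (y * y).sum()
        self.sxy[s] = (x * y).sum()
        if len(xs):
            self.comx[s] = self.sx[s] / len(xs)
            self.comy[s] = self.sy[s] / len(xs)
        else:
            self.comx[s] = self.comy[s] = 0.0

    def recompute_stats(self) -> None:
        """Exact from-scratch recomputation of all per-cell statistics."""
        for s in range(1, self.max_cells + 1):
            self._recompute_cell(s)

    def cell_ids(self) -> np.ndarray:
        """IDs of live cells (area > 0)."""
        ids = np.nonzero(self.area[1:] > 0)[0] + 1
        return ids

    def center_of_mass(self, s: int) -> tuple[float, float]:
        if self.area[s] == 0:
            raise ValueError(f"cell {s} has no sites")
        return self.sx[s] / self.area[s], self.sy[s] / self.area[s]

    def centers_of_mass(self) -> np.ndarray:
        """(max_cells+1, 2) array of centers; dead cells get NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            a = self.area.astype(np.float64)
            out = np.stack([self.sx / a, self.sy / a], axis=1)
        out[self.area == 0] = np.nan
        return out

    def cell_major_length(self, s: int) -> float:
        """Major-axis length of cell ``s`` from incremental moments."""
        if self.area[s] == 0:
            raise ValueError(f"cell {s} has no sites")
        return _kernels._major_axis_length(
            self.area[s], self.sx[s], self.sy[s],
            self.sxx[s], self.syy[s], self.sxy[s])

    def tissue_mask(self) -> np.ndarray:
        """Boolean mask of all cell sites (medium and frame are background)."""
        return self.spins > 0

    def check_consistency(self, atol: float = 1e-6) -> None:
        """Verify incremental bookkeeping against a from-scratch scan."""
        areas = np.bincount(self.spins.ravel(), minlength=self.max_cells + 1)
        if not np.array_equal(areas[1:], self.area[1:]):
            raise AssertionError("area bookkeeping inconsistent")
        ref = Lattice.from_array(self.spins, pad_frame=False)
        for name in ("sx", "sy", "sxx", "syy", "sxy"):
            a = getattr(self, name)[1:self.max_cells + 1]
            b = getattr(ref, name)[1:ref.max_cells + 1]
            nb = min(len(a), len(b))
            if not np.allclose(a[:nb], b[:nb], atol=atol):
                raise AssertionError(f"{name} bookkeeping inconsistent")


def cell_length(cell_sites: np.ndarray) -> float:
    """Major-axis extent of a set of sites: 4*sqrt(lambda_max(cov)).

    For a filled disc this equals the diameter (uniform-disc variance is
    r^2/4 along any axis).  A single site has length 0; an empty set is
    an error.
    """
    sites = np.asarray(cell_sites, dtype=np.float64)
    if sites.size == 0:
        raise ValueError("cell has no sites")
    if sites.ndim != 2 or sites.shape[1] != 2:
        raise ValueError("cell_sites must be an (n, 2) array")
    n = sites.shape[0]
    if n == 1:
        return 0.0
    c = sites - sites.mean(axis=0)
    cov = c.T @ c / n
    lam = np.linalg.eigvalsh(cov)[-1]
    return float(4.0 * np.sqrt(max(lam, 0.0)))


def hamiltonian(lattice: Lattice, params: CPMParams) -> float:
    """Total CPM energy: adhesion over adjacent unequal-spin pairs plus
    area and length constraints per cell.

    Adjacent pairs (Moore neighborhood, frame excluded) are counted
    once.  The medium carries no area or length term.  Cells that have
    shrunk to zero area still contribute their constant constraint
    energy, which keeps local energy differences exact; it is an
    additive constant with no effect on the dynamics.
    """
    spins = lattice.spins
    types = lattice.cell_type
    J = params.J
    if int(types[1:lattice.max_cells + 1].max(initial=0)) > params.n_types:
        raise ValueError("cell type not present in the J table")
    inner = spins[1:-1, 1:-1]
    hin, win = inner.shape
    e = 0.0
    for dx, dy in _FWD:  # each adjacent pair visited exactly once
        c0, c1 = max(0, -dx), win - max(0, dx)
        av = inner[0:hin - dy, c0:c1]
        bv = inner[dy:hin, c0 + dx:c1 + dx]
        neq = av != bv
        e += J[types[av[neq]], types[bv[neq]]].sum()
    lam1 = params.lambda_area
    lam2 = params.lambda_length
    AT = params.target_area
    LT = params.target_length
    for s in range(1, lattice.max_cells + 1):
        if lattice.cell_type[s] == 0 and lattice.area[s] == 0:
            continue  # never-registered slot
        A = float(lattice.area[s])
        L = (_kernels._major_axis_length(lattice.area[s], lattice.sx[s],
                                         lattice.sy[s], lattice.sxx[s],
                                         lattice.syy[s], lattice.sxy[s])
             if A > 0 else 0.0)
        e += lam1 * (A - AT) ** 2 + lam2 * (L - LT) ** 2
    return float(e)


def metropolis_accept(delta_h: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Boltzmann acceptance: always accept dH <= 0, else exp(-dH/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_h <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_h / temperature))
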