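"""Filopodial-tension convergent extension with self-organized polarization.

Each cell carries a polarization angle P(s).  Every ``t_interval`` MCS
the cell discards its filopodia and attaches up to ``n_max`` new ones to
cells whose centers of mass lie within a double cone of half-angle
``theta_max`` and radius ``r_max * L_T`` around the line through its
center along +-P(s).  A proposed spin copy that changes the distance
between linked centers of mass contributes
``lambda_f * sum_i (R_i,after - R_i,before)`` to the energy change, so
filopodia act as contractile center-to-center springs of zero rest
length; links are geometric abstractions and are not drawn on the
lattice.

At each refresh the polarization is first updated.  In the default
(Vicsek-style) rule the cell blends its own angle with the circular mean
of the polarizations of the cells it is currently linked to, with a
strong memory weight w:

    P_new = arg(w * e^{iP} + (1 - w) * e^{iP_avg}),
    P_avg = arg(sum_j e^{iP(s_j)}).

Cells without links keep their polarization.  The alternative
location-based rule ("belmonte" mode) reorients toward the mean
displacement vector to the linked cells' centers instead of their
polarization directions; it approximates the repolarization of the
original filopodial-tension model, which also assumed a global
preferred axis that is removed here: all cells start with uniformly
random angles in [0, 2*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import FilopodiaParams

__all__ = ["FilopodiaState", "refresh_filopodia", "delta_h_filopodia",
           "update_polarization_vicsek", "update_polarization_belmonte",
           "circular_mean"]

_TWO_PI = 2.0 * np.pi


def circular_mean(angles: np.ndarray) -> float:
    """arg of the resultant phasor; raises on a zero-magnitude resultant."""
    z = np.exp(1j * np.asarray(angles, dtype=np.float64)).sum()
    if abs(z) < 1e-12:
        raise ValueError("zero-magnitude circular sum")
    return float(np.angle(z) % _TWO_PI)


def update_polarization_vicsek(p: float, linked_polarizations: np.ndarray,
                               w: float) -> float:
    """Memory-weighted circular blend with the linked cells' polarizations.

    No links, w = 1, or an exactly antipodal (zero-resultant) neighbor
    sum all leave the polarization unchanged (documented tie-break).
    """
    linked = np.asarray(linked_polarizations, dtype=np.float64)
    if linked.size == 0:
        return float(p % _TWO_PI)
    try:
        p_avg = circular_mean(linked)
    except ValueError:
        return float(p % _TWO_PI)
    z = w * np.exp(1j * p) + (1.0 - w) * np.exp(1j * p_avg)
    if abs(z) < 1e-12:
        return float(p % _TWO_PI)
    return float(np.angle(z) % _TWO_PI)


def update_polarization_belmonte(p: float, center: np.ndarray,
                                 linked_centers: np.ndarray, w: float) -> float:
    """Location-based repolarization: steer toward the linked cells.

    The target direction is the arg of the summed displacement vectors
    from the cell's center to the linked centers, blended with the old
    angle using the same memory weight as the Vicsek rule.
    """
    linked = np.atleast_2d(np.asarray(linked_centers, dtype=np.float64))
    if linked.size == 0:
        return float(p % _TWO_PI)
    d = linked - np.asarray(center, dtype=np.float64)[None, :]
    v = d.sum(axis=0)
    if np.hypot(v[0], v[1]) < 1e-12:
        return float(p % _TWO_PI)
    p_avg = np.arctan2(v[1], v[0])
    z = w * np.exp(1j * p) + (1.0 - w) * np.exp(1j * p_avg)
    if abs(z) < 1e-12:
        return float(p % _TWO_PI)
    return float(np.angle(z) % _TWO_PI)


@dataclass
class FilopodiaState:
    """Per-cell polarization plus the current set of center-to-center links.

    ``src``/``tgt`` hold the link endpoints (cell IDs); the CSR arrays
    ``link_ptr``/``link_ids`` index, for each cell, the links touching
    it in either role, which is what the energy kernel iterates over.
    """

    polarization: np.ndarray
    src: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    tgt: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    link_ptr: np.ndarray = field(default_factory=lambda: np.zeros(2, np.int64))
    link_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @classmethod
    def random(cls, max_cells: int, rng: np.random.Generator) -> "FilopodiaState":
        pol = rng.uniform(0.0, _TWO_PI, size=max_cells + 1)
        state = cls(polarization=pol)
        state.link_ptr = np.zeros(max_cells + 2, dtype=np.int64)
        return state

    def links_of(self, cell: int) -> np.ndarray:
        return self.link_ids[self.link_ptr[cell]:self.link_ptr[cell + 1]]

    def rebuild_csr(self, max_cells: int) -> None:
        ends = np.concatenate([self.src, self.tgt]).astype(np.int64)
        ids = np.concatenate([np.arange(len(self.src)),
                              np.arange(len(self.tgt))]).astype(np.int64)
        counts = np.bincount(ends, minlength=max_cells + 1)
        self.link_ptr = np.zeros(max_cells + 2, dtype=np.int64)
        np.cumsum(counts, out=self.link_ptr[1:max_cells + 2][:len(counts)])
        self.link_ptr[len(counts) + 1:] = self.link_ptr[len(counts)]
        order = np.argsort(ends, kind="stable")
        self.link_ids = ids[order]


def candidate_targets(centers: np.ndarray, alive: np.ndarray,
                      polarization: np.ndarray, source: int,
                      params: FilopodiaParams, target_length: float,
                      allowed: np.ndarray | None = None,
                      cell_types: np.ndarray | None = None) -> np.ndarray:
    """Cells within the double cone of ``source`` (radius + angle predicate)."""
    c = centers[source]
    d = centers - c
    dist = np.hypot(d[:, 0], d[:, 1])
    with np.errstate(invalid="ignore"):
        ok = alive & (dist > 0) & (dist <= params.r_max * target_length)
        ok &= np.isfinite(dist)
    ang = np.arctan2(d[:, 1], d[:, 0])
    # double cone: acute angle between displacement and the +-P axis
    ok &= np.abs(np.cos(ang - polarization[source])) >= np.cos(
        np.deg2rad(params.theta_max)) - 1e-12
    ok[source] = False
    if allowed is not None and cell_types is not None:
        ok &= allowed[cell_types[source], cell_types]
    return np.nonzero(ok)[0]


def refresh_filopodia(state: FilopodiaState, centers: np.ndarray,
                      areas: np.ndarray, cell_types: np.ndarray,
                      params: FilopodiaParams, target_length: float,
                      rng: np.random.Generator,
                      allowed: np.ndarray | None = None) -> None:
    """Repolarize every cell, then attach a fresh set of filopodia.

    The polarization update uses the links formed at the previous
    refresh; the old links are then discarded and each cell draws up to
    ``n_max`` targets uniformly without replacement from its candidate
    set (cells inside the double cone, restricted by the pulling mask
    ``allowed[type_source, type_target]`` when given).
    """
    max_cells = len(areas) - 1
    alive = areas > 0
    alive[0] = False

    # 1) repolarization from the existing links (outgoing only)
    if len(state.src):
        new_pol = state.polarization.copy()
        for s in np.unique(state.src):
            if not alive[s]:
                continue
            tgts = state.tgt[state.src == s]
            tgts = tgts[alive[tgts]]
            if len(tgts) == 0:
                continue
            if params.repolarization_mode == "vicsek":
                new_pol[s] = update_polarization_vicsek(
                    state.polarization[s], state.polarization[tgts], params.w)
            else:
                new_pol[s] = update_polarization_belmonte(
                    state.polarization[s], centers[s], centers[tgts], params.w)
        state.polarization = new_pol

    # 2) fresh links
    src_list: list[int] = []
    tgt_list: list[int] = []
    for s in np.nonzero(alive)[0]:
        cand = candidate_targets(centers, alive, state.polarization, int(s),
                                 params, target_length, allowed, cell_types)
        if len(cand) == 0:
            continue
        if len(cand) > params.n_max:
            cand = rng.choice(cand, size=params.n_max, replace=False)
        for t in cand:
            src_list.append(int(s))
            tgt_list.append(int(t))
    state.src = np.asarray(src_list, dtype=np.int32)
    state.tgt = np.asarray(tgt_list, dtype=np.int32)
    state.rebuild_csr(max_cells)


def delta_h_filopodia(state: FilopodiaState, areas: np.ndarray,
                      sx: np.ndarray, sy: np.ndarray, lambda_f: float,
                      site: tuple[int, int], s_old: int, s_new: int) -> float:
    """Pulling term of a proposed copy of ``s_new`` onto ``site`` (held by
    ``s_old``), from the closed-form center-of-mass shifts of the two
    affected cells.  Filopodia touching neither cell contribute zero.
    """
    from . import _kernels
    areas = np.asarray(areas, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        comx = np.where(areas > 0, sx / areas, 0.0)
        comy = np.where(areas > 0, sy / areas, 0.0)
    return float(_kernels.delta_h_filopodia(
        areas, sx, sy, comx, comy, lambda_f, state.src, state.tgt,
        state.link_ptr, state.link_ids,
        int(site[0]), int(site[1]), int(s_old), int(s_new)))
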