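"""Composed model presets: differential adhesion and pulling variants.

The differential-adhesion model uses 10 cell types on a linear adhesion
gradient J(tau, tau') = O + |tau - tau'| * S with J(tau, M) = 25, so the
type-type surface tension is gamma(tau, tau') = |tau - tau'| * S and the
tissue-medium tension is gamma(c, M) = 25 - O/2.

The two-cell-type convergent-extension models restrict which cells may
attach filopodia to which: "same_type" (tau_s == tau_t), "all_all"
(no restriction), "yellow_all" (only type 2 extends filopodia) and
"yellow_yellow" (type 2 to type 2 only).
"""

from __future__ import annotations

import numpy as np

from .lattice import Lattice

__all__ = ["adhesion_matrix", "pulling_mask", "pulling_mask_table",
           "presorted_init", "two_type_init", "PULLING_VARIANTS", "MODELS"]

PULLING_VARIANTS = ("same_type", "all_all", "yellow_all", "yellow_yellow")
MODELS = ("diff_adhesion", "ce_one_type", "ce_same_type", "ce_all_all",
          "ce_yellow_all", "ce_yellow_yellow")


def adhesion_matrix(offset: float, slope: float, n_types: int = 10,
                    j_medium: float = 25.0) -> np.ndarray:
    """J table of the 10-type adhesion gradient (index 0 = medium)."""
    if slope < 0:
        raise ValueError("slope must be non-negative")
    t = np.arange(n_types + 1)
    J = offset + np.abs(t[:, None] - t[None, :]) * float(slope)
    J[0, :] = J[:, 0] = j_medium
    J[0, 0] = 0.0
    return J.astype(np.float64)


def pulling_mask(variant: str, tau_source: int, tau_target: int) -> bool:
    """May a cell of type ``tau_source`` attach a filopodium to one of
    type ``tau_target``?  Type 2 is the "yellow" population."""
    if variant == "same_type":
        return tau_source == tau_target
    if variant == "all_all":
        return True
    if variant == "yellow_all":
        return tau_source == 2
    if variant == "yellow_yellow":
        return tau_source == 2 and tau_target == 2
    raise ValueError(f"unknown pulling variant {variant!r}; "
                     f"choose one of {PULLING_VARIANTS}")


def pulling_mask_table(variant: str, n_types: int) -> np.ndarray:
    """Boolean (type x type) lookup of :func:`pulling_mask`."""
    table = np.zeros((n_types + 1, n_types + 1), dtype=bool)
    for s in range(1, n_types + 1):
        for t in range(1, n_types + 1):
            table[s, t] = pulling_mask(variant, s, t)
    return table


def presorted_init(lattice: Lattice, n_types: int = 10) -> None:
    """Assign types in contiguous bands ordered 1..n_types along x.

    Cells are ranked by their center of mass along the band axis and cut
    into ``n_types`` groups whose sizes differ by at most one, which
    prearranges the tissue according to the adhesion gradient.
    """
    ids = lattice.cell_ids()
    xs = np.array([lattice.center_of_mass(int(s))[0] for s in ids])
    order = np.argsort(xs, kind="stable")
    bands = np.array_split(order, n_types)
    for t, band in enumerate(bands, start=1):
        lattice.cell_type[ids[band]] = t


def two_type_init(lattice: Lattice, rng: np.random.Generator,
                  fraction_type2: float = 0.5) -> None:
    """Independently assign each cell type 2 with the given probability.

    The 50/50 default is a documented convention; the split is
    configurable.
    """
    ids = lattice.cell_ids()
    draw = rng.random(len(ids)) < fraction_type2
    lattice.cell_type[ids] = np.where(draw, 2, 1)


def sorting_index(lattice: Lattice) -> float:
    """Fraction of heterotypic cell-cell boundary among all cell-cell
    boundary pairs; decreases when cell types sort, increases when they
    mix."""
    spins = lattice.spins
    types = lattice.cell_type
    hetero = 0
    total = 0
    for dx, dy in ((1, 0), (0, 1), (1, 1), (-1, 1)):
        c0, c1 = max(0, -dx), spins.shape[1] - 2 - max(0, dx)
        a = spins[1:-1, 1:-1][0:spins.shape[0] - 2 - dy, c0:c1]
        b = spins[1:-1, 1:-1][dy:, c0 + dx:c1 + dx]
        both = (a > 0) & (b > 0) & (a != b)
        total += int(both.sum())
        hetero += int((types[a[both]] != types[b[both]]).sum())
    return hetero / total if total else 0.0
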