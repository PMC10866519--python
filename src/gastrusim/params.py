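"""Parameter containers for the Cellular Potts model.

Defaults follow the standard parameterization of the gastruloid
simulations: temperature ``T = 50``, target area ``A_T = 100`` sites,
target length ``L_T = 10`` sites (so cells of target area are roughly
circular), area/length constraint strengths ``lambda_1 = lambda_2 = 5``
and interfacial energies ``J(c, M) = J(c, c) = 10``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CPMParams", "FilopodiaParams", "surface_tensions", "default_j_table"]


def default_j_table(n_types: int = 1, j_cell_medium: float = 10.0,
                    j_cell_cell: float = 10.0,
                    j_cross: float | None = None) -> np.ndarray:
    """Symmetric interfacial-energy table indexed by (type, type).

    Index 0 is the medium.  ``j_cross`` sets the off-diagonal
    cell-cell entries (defaults to ``j_cell_cell``).
    """
    if j_cross is None:
        j_cross = j_cell_cell
    J = np.full((n_types + 1, n_types + 1), float(j_cross))
    J[0, :] = J[:, 0] = float(j_cell_medium)
    J[0, 0] = 0.0
    for t in range(1, n_types + 1):
        J[t, t] = float(j_cell_cell)
    return J


@dataclass
class CPMParams:
    """Hamiltonian parameters: temperature, constraints and adhesion table."""

    temperature: float = 50.0
    lambda_area: float = 5.0
    lambda_length: float = 5.0
    target_area: float = 100.0
    target_length: float = 10.0
    J: np.ndarray = field(default_factory=default_j_table)

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be a square (type x type) table")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")

    @property
    def n_types(self) -> int:
        return self.J.shape[0] - 1


@dataclass
class FilopodiaParams:
    """Filopodial-tension parameters.

    theta_max is the half-angle (degrees) of the double cone around the
    polarization axis; r_max is the cone length in units of the target
    length; n_max the number of filopodia per cell; t_interval the
    refresh cadence in MCS; w the polarization memory weight in [0, 1];
    lambda_f the pulling-force strength.
    """

    theta_max: float = 45.0
    r_max: float = 2.0
    n_max: int = 3
    t_interval: int = 20
    w: float = 0.99
    lambda_f: float = 15.0
    repolarization_mode: str = "vicsek"

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("memory weight w must be in [0, 1]")
        if self.repolarization_mode not in ("vicsek", "belmonte"):
            raise ValueError("repolarization_mode must be 'vicsek' or 'belmonte'")


def surface_tensions(J: np.ndarray) -> np.ndarray:
    """Surface tensions gamma(tau, tau') = J(tau,tau') - (J(tau,tau)+J(tau',tau'))/2.

    With index 0 the medium (J(M, M) = 0) this reduces to
    gamma(c, M) = J(c, M) - J(c, c)/2 for the cell-medium tension.
    Positive gamma(c, M) keeps tissues compact; the sign of
    gamma(tau, tau') controls sorting (positive) versus mixing
    (negative) of cell types.
    """
    J = np.asarray(J, dtype=np.float64)
    diag = np.diag(J)
    return J - 0.5 * (diag[:, None] + diag[None, :])
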