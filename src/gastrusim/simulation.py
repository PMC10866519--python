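"""The simulation driver: initialization, Monte Carlo stepping and
recording of shape trajectories.

A :class:`Simulation` owns a lattice, its edge list, the Hamiltonian
parameters of the configured model and (for the convergent-extension
models) the filopodia state.  Time advances in Monte Carlo steps (MCS);
one MCS performs ceil(|E|/n_NB) copy attempts through the edge-list
sampler.  Filopodia are refreshed every ``t_interval`` MCS at the
Python level; the copy attempts between refreshes run inside a compiled
kernel.

Initialization seeds ``n_cells`` single-site cells uniformly in a disc
at the lattice center and grows them for ``growth_mcs`` (default 100)
Monte Carlo steps with the area and adhesion terms only, which yields a
compact blob of near-target-area cells before the configured model
dynamics start.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import _kernels
from .config import SimConfig
from .edgelist import EdgeList
from .filopodia import FilopodiaState, refresh_filopodia
from .lattice import Lattice
from .models import presorted_init, two_type_init

__all__ = ["Simulation", "RunRecord"]


@dataclasses.dataclass
class RunRecord:
    """Shape trajectory of one run: scaled 2- and 3-lobe coefficients
    sampled every ``record_every`` MCS plus at the final step."""

    mcs: np.ndarray
    l2_over_l1: np.ndarray
    l3_over_l1: np.ndarray

    def final(self) -> tuple[float, float]:
        return float(self.l2_over_l1[-1]), float(self.l3_over_l1[-1])


class Simulation:
    def __init__(self, config: SimConfig | None = None, **overrides):
        if config is None:
            config = SimConfig(**overrides)
        elif overrides:
            config = config.replace(**overrides)
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.params = config.cpm_params()
        self.filo_params = config.filopodia_params()
        self.pulling_table = config.pulling_table()
        self.mcs = 0
        self._frame_warned = False

        size = config.resolved_lattice_size()
        self.lattice = Lattice(size, size, config.n_cells)
        self._seed_cells()
        self._kernel_rng = _kernels.seed_rng_state(
            int(self.rng.integers(1, 2 ** 62)))
        self._assign_types()
        self.edges = EdgeList(self.lattice)
        self._grow_blob()

        self.filopodia: FilopodiaState | None = None
        if config.uses_pulling():
            self.filopodia = FilopodiaState.random(config.n_cells, self.rng)

    # -- initialization -------------------------------------------------
    def _seed_cells(self) -> None:
        cfg = self.config
        lat = self.lattice
        cx = lat.width / 2.0
        cy = lat.height / 2.0
        # disc radius with ~10% margin over the close-packed tissue radius
        radius = 1.07 * np.sqrt(cfg.n_cells * cfg.target_area / np.pi)
        ys, xs = np.mgrid[1:lat.height - 1, 1:lat.width - 1]
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius ** 2
        coords = np.column_stack([xs[inside], ys[inside]])
        if len(coords) < cfg.n_cells:
            raise ValueError("lattice too small for the requested cell count")
        pick = self.rng.choice(len(coords), size=cfg.n_cells, replace=False)
        for i, (x, y) in enumerate(coords[pick], start=1):
            lat.spins[y, x] = i
            lat.cell_type[i] = 1
        lat.recompute_stats()

    def _grow_blob(self) -> None:
        """Growth phase: area + adhesion terms only, no length constraint."""
        cfg = self.config
        if cfg.growth_mcs <= 0:
            return
        lat = self.lattice
        empty = _EMPTY_LINKS
        n_edges, _, _ = _kernels.run_mcs(
            lat.spins, lat.cell_type, lat.area, lat.sx, lat.sy,
            lat.sxx, lat.syy, lat.sxy, lat.comx, lat.comy,
            self.params.J, cfg.temperature, cfg.lambda_area, 0.0,
            cfg.target_area, cfg.target_length,
            self.edges.edge_of_index, self.edges.index_of_edge,
            self.edges.n_edges,
            0.0, empty["src"], empty["tgt"], empty["ptr"], empty["ids"],
            cfg.growth_mcs, self._kernel_rng)
        self.edges.n_edges = int(n_edges)

    def _assign_types(self) -> None:
        model = self.config.model
        if model == "diff_adhesion":
            presorted_init(self.lattice, n_types=10)
        elif model != "ce_one_type":
            two_type_init(self.lattice, self.rng,
                          fraction_type2=self.config.type2_fraction)

    # -- stepping -------------------------------------------------------
    def _refresh(self) -> None:
        assert self.filopodia is not None
        refresh_filopodia(self.filopodia, self.lattice.centers_of_mass(),
                          self.lattice.area, self.lattice.cell_type,
                          self.filo_params, self.config.target_length,
                          self.rng, allowed=self.pulling_table)

    def _links(self) -> dict:
        if self.filopodia is None:
            return _EMPTY_LINKS
        return {"src": self.filopodia.src, "tgt": self.filopodia.tgt,
                "ptr": self.filopodia.link_ptr, "ids": self.filopodia.link_ids}

    def step(self, n_mcs: int = 1) -> None:
        """Advance ``n_mcs`` Monte Carlo steps."""
        cfg = self.config
        lat = self.lattice
        pulling = self.filopodia is not None
        lam_f = cfg.lambda_f if pulling else 0.0
        done = 0
        while done < n_mcs:
            if pulling:
                if self.mcs % cfg.t_interval == 0:
                    self._refresh()
                chunk = min(n_mcs - done,
                            cfg.t_interval - self.mcs % cfg.t_interval)
            else:
                chunk = n_mcs - done
            links = self._links()
            n_edges, _, _ = _kernels.run_mcs(
                lat.spins, lat.cell_type, lat.area, lat.sx, lat.sy,
                lat.sxx, lat.syy, lat.sxy, lat.comx, lat.comy,
                self.params.J, cfg.temperature, cfg.lambda_area,
                cfg.lambda_length, cfg.target_area, cfg.target_length,
                self.edges.edge_of_index, self.edges.index_of_edge,
                self.edges.n_edges,
                lam_f, links["src"], links["tgt"], links["ptr"], links["ids"],
                chunk, self._kernel_rng)
            self.edges.n_edges = int(n_edges)
            self.mcs += chunk
            done += chunk
        self._warn_if_frame_touched()

    def monte_carlo_step(self) -> None:
        """One Monte Carlo step (ceil(|E|/n_NB) edge-sampled attempts)."""
        self.step(1)

    def _warn_if_frame_touched(self) -> None:
        if self._frame_warned:
            return
        lat = self.lattice
        edge_rows = (lat.spins[1, :].max() > 0 or lat.spins[-2, :].max() > 0
                     or lat.spins[:, 1].max() > 0 or lat.spins[:, -2].max() > 0)
        if edge_rows:
            warnings.warn("tissue touches the lattice frame; results near "
                          "the boundary are unreliable", RuntimeWarning)
            self._frame_warned = True

    # -- observables ----------------------------------------------------
    def tissue_mask(self) -> np.ndarray:
        return self.lattice.tissue_mask()

    def shape_ratios(self) -> tuple[float, float]:
        """Scaled 2- and 3-lobe coefficients of the current tissue shape.

        The tissue mask is the union of all cell sites; detached single
        cells are ignored (the spectrum describes the main body)."""
        from .shape import mask_spectrum
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*largest.*")
            spec = mask_spectrum(self.tissue_mask())
        return spec.ratio(2), spec.ratio(3)

    def run(self, n_mcs: int | None = None,
            record_every: int | None = 5000) -> RunRecord:
        """Run for ``n_mcs`` steps (default: the configured budget),
        recording shape ratios every ``record_every`` MCS and at the end."""
        total = self.config.mcs if n_mcs is None else n_mcs
        times, r2, r3 = [], [], []
        remaining = total
        stride = record_every or total
        while remaining > 0:
            chunk = min(stride, remaining)
            self.step(chunk)
            remaining -= chunk
            a, b = self.shape_ratios()
            times.append(self.mcs)
            r2.append(a)
            r3.append(b)
        return RunRecord(np.asarray(times), np.asarray(r2), np.asarray(r3))

    # -- export ---------------------------------------------------------
    def cell_table(self):
        """Per-cell summary: id, type, area, center, length, polarization."""
        import pandas as pd
        ids = self.lattice.cell_ids()
        coms = self.lattice.centers_of_mass()
        pol = (self.filopodia.polarization if self.filopodia is not None
               else np.full(self.config.n_cells + 1, np.nan))
        return pd.DataFrame({
            "cell_id": ids,
            "type": self.lattice.cell_type[ids],
            "area": self.lattice.area[ids],
            "x": coms[ids, 0],
            "y": coms[ids, 1],
            "length": [self.lattice.cell_major_length(int(s)) for s in ids],
            "polarization": pol[ids],
        })


_EMPTY_LINKS = {
    "src": np.empty(0, dtype=np.int32),
    "tgt": np.empty(0, dtype=np.int32),
    "ptr": np.zeros(2, dtype=np.int64),
    "ids": np.empty(0, dtype=np.int64),
}
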