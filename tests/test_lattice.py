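"""Lattice bookkeeping, Hamiltonian and Metropolis acceptance."""

import numpy as np
import pytest

from gastrusim import (CPMParams, Lattice, SimConfig, Simulation, cell_length,
                       hamiltonian, metropolis_accept, surface_tensions)
from gastrusim import _kernels
from gastrusim.params import default_j_table


def brute_force_hamiltonian(lattice, params):
    """Independent oracle: double loop over all site pairs plus explicit
    per-cell area/length terms."""
    spins = lattice.spins
    h, w = spins.shape
    e = 0.0
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            for dx, dy in ((1, 0), (0, 1), (1, 1), (-1, 1)):
                xn, yn = x + dx, y + dy
                if xn <= 0 or xn >= w - 1 or yn <= 0 or yn >= h - 1:
                    continue
                a, b = spins[y, x], spins[yn, xn]
                if a != b:
                    e += params.J[lattice.cell_type[a], lattice.cell_type[b]]
    for s in range(1, lattice.max_cells + 1):
        ys, xs = np.nonzero(spins == s)
        if len(xs) == 0 and lattice.cell_type[s] == 0:
            continue
        A = len(xs)
        L = cell_length(np.column_stack([xs, ys])) if A else 0.0
        e += params.lambda_area * (A - params.target_area) ** 2
        e += params.lambda_length * (L - params.target_length) ** 2
    return e


class TestHamiltonian:
    def test_single_square_cell_adhesion_and_area(self):
        # 10x10 cell (A = A_T = 100) centered on an empty 50x50 lattice:
        # area term vanishes; adhesion = J(c, M) * boundary pair count
        spins = np.zeros((50, 50), dtype=np.int32)
        spins[20:30, 20:30] = 1
        lat = Lattice.from_array(spins, pad_frame=False)
        params = CPMParams()
        # boundary pairs: orthogonal 4*10, plus diagonal contacts
        n_pairs = 0
        for y in range(50):
            for x in range(50):
                for dx, dy in ((1, 0), (0, 1), (1, 1), (-1, 1)):
                    xn, yn = x + dx, y + dy
                    if not (0 < xn < 49 and 0 < yn < 49 and 0 < x < 49
                            and 0 < y < 49):
                        continue
                    if spins[y, x] != spins[yn, xn]:
                        n_pairs += 1
        expected_adhesion = 10.0 * n_pairs
        L = cell_length(np.argwhere(spins.T == 1))
        expected = expected_adhesion + 5.0 * (L - 10.0) ** 2
        assert hamiltonian(lat, params) == pytest.approx(expected)

    def test_empty_lattice_is_zero(self):
        lat = Lattice(20, 20, 1)
        lat.cell_type[1] = 0  # no registered cell
        assert hamiltonian(lat, CPMParams()) == 0.0

    def test_matches_brute_force_on_random_configuration(self, rng):
        spins = rng.integers(0, 4, size=(8, 8)).astype(np.int32)
        lat = Lattice.from_array(spins)
        params = CPMParams(J=default_j_table(1, 10, 6))
        assert hamiltonian(lat, params) == pytest.approx(
            brute_force_hamiltonian(lat, params), rel=1e-12)

    def test_unknown_cell_type_rejected(self):
        lat = Lattice.from_array(np.ones((4, 4), dtype=np.int32),
                                 cell_types={1: 3})
        with pytest.raises(ValueError, match="type"):
            hamiltonian(lat, CPMParams())  # J table only has 1 cell type


class TestDeltaH:
    def test_shrinking_cell_at_target_area_costs_lambda1(self):
        spins = np.zeros((30, 30), dtype=np.int32)
        spins[10:20, 10:20] = 1  # A = A_T = 100
        lat = Lattice.from_array(spins, pad_frame=False)
        p = CPMParams(lambda_length=0.0)
        dh = _kernels.delta_h_base(
            lat.spins, lat.cell_type, lat.area, lat.sx, lat.sy,
            lat.sxx, lat.syy, lat.sxy, p.J, p.lambda_area, p.lambda_length,
            p.target_area, p.target_length, 10, 10, 0)
        # area contribution lambda1*((A_T-1-A_T)^2 - 0) = 5; the rest is
        # the local adhesion change at the corner
        lat2 = Lattice.from_array(lat.spins.copy(), pad_frame=False)
        lat2.spins[10, 10] = 0
        lat2.recompute_stats()
        assert dh == pytest.approx(hamiltonian(lat2, p) - hamiltonian(lat, p))

    def test_equals_full_recompute_on_fuzzed_proposals(self, rng):
        spins = rng.integers(0, 5, size=(12, 12)).astype(np.int32)
        lat = Lattice.from_array(spins)
        p = CPMParams()
        from gastrusim.edgelist import EdgeList
        el = EdgeList(lat)
        worst = 0.0
        for _ in range(1000):
            (x, y), (xs, ys) = el.sample_edge(rng)
            s_new = int(lat.spins[ys, xs])
            dh = _kernels.delta_h_base(
                lat.spins, lat.cell_type, lat.area, lat.sx, lat.sy,
                lat.sxx, lat.syy, lat.sxy, p.J, p.lambda_area,
                p.lambda_length, p.target_area, p.target_length, x, y, s_new)
            h0 = hamiltonian(lat, p)
            old = int(lat.spins[y, x])
            lat.spins[y, x] = s_new
            for s, sgn in ((old, -1), (s_new, +1)):
                if s:
                    lat._recompute_cell(s)
            el.update_after_copy(x, y)
            worst = max(worst, abs(hamiltonian(lat, p) - h0 - dh))
        assert worst < 1e-9

    def test_reflection_symmetric_copies_have_equal_magnitude(self):
        spins = np.zeros((9, 9), dtype=np.int32)
        spins[3:6, 2:5] = 1
        lat_a = Lattice.from_array(spins, pad_frame=False)
        lat_b = Lattice.from_array(spins[:, ::-1].copy(), pad_frame=False)
        p = CPMParams()
        args_a = (lat_a.spins, lat_a.cell_type, lat_a.area, lat_a.sx,
                  lat_a.sy, lat_a.sxx, lat_a.syy, lat_a.sxy, p.J,
                  p.lambda_area, p.lambda_length, p.target_area,
                  p.target_length)
        args_b = (lat_b.spins, lat_b.cell_type, lat_b.area, lat_b.sx,
                  lat_b.sy, lat_b.sxx, lat_b.syy, lat_b.sxy, p.J,
                  p.lambda_area, p.lambda_length, p.target_area,
                  p.target_length)
        # growth of the same cell site, mirrored across the y axis
        dh_a = _kernels.delta_h_base(*args_a, 5, 4, 1)
        dh_b = _kernels.delta_h_base(*args_b, 8 - 5, 4, 1)
        assert dh_a == pytest.approx(dh_b, abs=1e-12)


class TestMetropolis:
    def test_negative_and_zero_delta_always_accepted(self, rng):
        assert all(metropolis_accept(-5.0, 50.0, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 50.0, rng) for _ in range(100))

    def test_acceptance_rate_matches_boltzmann_factor(self, rng):
        # dH = T --> acceptance probability e^-1
        n = 100_000
        hits = sum(metropolis_accept(50.0, 50.0, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sigma

    def test_kernel_rng_acceptance_rate_matches(self):
        # the compiled sampler obeys the same law
        state = _kernels.seed_rng_state(7)
        n = 100_000
        hits = sum(_kernels._rng_uniform(state) < np.exp(-1.0)
                   for _ in range(n))
        p = np.exp(-1.0)
        assert abs(hits - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_temperature_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestCellLength:
    def test_filled_disc_length_is_diameter(self):
        r = 30
        ys, xs = np.mgrid[-r:r + 1, -r:r + 1]
        inside = xs ** 2 + ys ** 2 <= r ** 2
        L = cell_length(np.column_stack([xs[inside], ys[inside]]))
        assert L == pytest.approx(2 * r, rel=0.02)

    def test_single_site_has_zero_length(self):
        assert cell_length(np.array([[3, 4]])) == 0.0

    def test_collinear_row_of_20_sites(self):
        sites = np.column_stack([np.arange(20), np.zeros(20)])
        # exact covariance of 20 equispaced points: var = (n^2-1)/12
        expected = 4.0 * np.sqrt((20 ** 2 - 1) / 12.0)
        assert cell_length(sites) == pytest.approx(expected, rel=1e-12)

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError):
            cell_length(np.empty((0, 2)))


class TestSurfaceTensions:
    @pytest.mark.parametrize("J, pair, expected", [
        (default_j_table(1, 10, 10), (1, 0), 5.0),
        (default_j_table(2, 10, 10, j_cross=6.0), (1, 2), -4.0),
        (np.full((3, 3), 7.0), (1, 2), 0.0),
    ])
    def test_known_tensions(self, J, pair, expected):
        gamma = surface_tensions(J)
        assert gamma[pair] == pytest.approx(expected)
        assert np.allclose(gamma, gamma.T)


class TestConservationAndBookkeeping:
    def test_site_count_conserved_and_stats_exact_after_run(self):
        sim = Simulation(SimConfig(model="ce_one_type", n_cells=8,
                                   lambda_f=15.0, seed=11))
        sim.step(300)
        lat = sim.lattice
        total = lat.width * lat.height
        assert int((lat.spins > 0).sum()) == int(lat.area.sum())
        assert int((lat.spins == 0).sum()) + int(lat.area.sum()) == total
        lat.check_consistency(atol=1e-6)  # incremental == from-scratch

    def test_frozen_configuration_performs_no_attempts(self):
        # uniform lattice: |E| = 0, a step is a no-op rather than an error
        lat = Lattice(10, 10, 1)
        from gastrusim.edgelist import EdgeList
        el = EdgeList(lat)
        assert len(el) == 0
        state = _kernels.seed_rng_state(3)
        links = (np.empty(0, np.int32), np.empty(0, np.int32),
                 np.zeros(3, np.int64), np.empty(0, np.int64))
        p = CPMParams()
        n_edges, attempts, accepted = _kernels.run_mcs(
            lat.spins, lat.cell_type, lat.area, lat.sx, lat.sy, lat.sxx,
            lat.syy, lat.sxy, lat.comx, lat.comy, p.J, 50.0, 5.0, 5.0,
            100.0, 10.0, el.edge_of_index, el.index_of_edge, el.n_edges,
            0.0, *links, 10, state)
        assert (n_edges, attempts, accepted) == (0, 0, 0)
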