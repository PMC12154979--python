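"""Transfer-integral contraction against brute-force quadrature oracles."""

import numpy as np
import pytest

from pbdmelt import (
    CrowderConfig,
    ModelParams,
    build_grid,
    compute_partition,
    compute_restricted_partition,
    log_partition,
    parse_duplex,
)
from pbdmelt.crowders import effective_depths, site_widths
from pbdmelt.potentials import morse, stacking

from conftest import free_depths


def brute_force_log_zc(duplex, depths, params, T, grid):
    """Full tensor-product quadrature of the N-dimensional integral."""
    beta = 1.0 / (params.k_B * T)
    widths = site_widths(duplex, params)
    y, w = grid.nodes, grid.weights
    site = [w * np.exp(-beta * morse(y, depths[i], widths[i]))
            for i in range(duplex.N)]
    S = np.exp(-beta * stacking(y[:, None], y[None, :], params))
    if duplex.N == 1:
        return np.log(site[0].sum())
    if duplex.N == 2:
        Z = np.einsum("i,j,ij->", site[0], site[1], S)
    else:
        Z = np.einsum("i,j,k,ij,jk->", site[0], site[1], site[2], S, S)
    return np.log(Z)


class TestGrid:
    def test_two_node_gauss_legendre(self):
        p = ModelParams(y_min=-1.0, y_max=1.0, y0=0.5, n_grid=2)
        g = build_grid(p)
        np.testing.assert_allclose(g.nodes, [-1 / np.sqrt(3), 1 / np.sqrt(3)])
        np.testing.assert_allclose(g.weights, [1.0, 1.0])

    def test_polynomial_integrated_exactly(self):
        g = build_grid(ModelParams())
        got = g.integrate(g.nodes**2)
        assert got == pytest.approx((200**3 + 5**3) / 3, rel=1e-13)

    def test_default_grid_shape_and_bounds(self):
        g = build_grid(ModelParams())
        assert g.n == 900
        assert np.all(np.diff(g.nodes) > 0)
        assert g.nodes[0] > -5.0 and g.nodes[-1] < 200.0
        assert np.all(g.weights > 0)
        assert g.weights.sum() == pytest.approx(205.0, rel=1e-12)


class TestPartition:
    def test_single_site_matches_1d_quadrature(self, small_params):
        d = parse_duplex("A")
        depths = free_depths(d, small_params)
        g = build_grid(small_params)
        lz = log_partition(d, depths, small_params, 300.0, grid=g)
        oracle = brute_force_log_zc(d, depths, small_params, 300.0, g)
        assert lz == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("seq", ["AA", "GA", "GAG", "AGA"])
    def test_matches_tensor_quadrature_up_to_n3(self, seq, small_params):
        d = parse_duplex(seq)
        depths = free_depths(d, small_params)
        g = build_grid(small_params)
        lz = log_partition(d, depths, small_params, 300.0, grid=g)
        oracle = brute_force_log_zc(d, depths, small_params, 300.0, g)
        assert abs(lz - oracle) / abs(oracle) < 1e-10

    def test_crowded_chain_matches_oracle(self, small_params):
        d = parse_duplex("GAG")
        cc = CrowderConfig(((2, 1.5),))
        depths = effective_depths(d, cc, small_params)
        g = build_grid(small_params)
        lz = log_partition(d, depths, small_params, 280.0, grid=g)
        oracle = brute_force_log_zc(d, depths, small_params, 280.0, g)
        assert abs(lz - oracle) / abs(oracle) < 1e-10

    def test_reversal_invariance(self, params):
        d = parse_duplex("GGGAGAAG")
        cc = CrowderConfig(((2, 1.5), (7, 2.0)))
        depths = effective_depths(d, cc, params)
        lz = log_partition(d, depths, params, 300.0)
        lz_rev = log_partition(d.reversed(), depths[::-1].copy(), params, 300.0)
        assert lz == pytest.approx(lz_rev, abs=1e-9)

    def test_log_zc_monotone_in_temperature(self, small_params):
        d = parse_duplex("GAGA")
        depths = free_depths(d, small_params)
        temps = [150.0, 200.0, 250.0, 300.0, 400.0, 500.0]
        vals = [log_partition(d, depths, small_params, T) for T in temps]
        assert np.all(np.diff(vals) > 0)

    def test_marginals_are_normalized_densities(self, params):
        d = parse_duplex("GGGAGAAG")
        depths = free_depths(d, params)
        res = compute_partition(d, depths, params, 300.0)
        integrals = res.marginals @ res.grid.weights
        np.testing.assert_allclose(integrals, 1.0, atol=1e-8)
        assert np.all(res.site_masses >= 0)

    def test_low_temperature_marginal_concentrates_at_well(self, params):
        d = parse_duplex("GAG")
        depths = free_depths(d, params)
        res = compute_partition(d, depths, params, 20.0)
        mean_y = res.site_masses @ res.grid.nodes
        assert np.all(np.abs(mean_y) < 0.2)

    def test_nonpositive_temperature_rejected(self, small_params):
        d = parse_duplex("GA")
        depths = free_depths(d, small_params)
        with pytest.raises(ValueError):
            log_partition(d, depths, small_params, 0.0)


class TestRestrictedPartition:
    def test_open_plus_closed_equals_full(self, small_params):
        d = parse_duplex("GAGA")
        depths = free_depths(d, small_params)
        T = 250.0
        full = log_partition(d, depths, small_params, T)
        for site in (1, 2, 4):
            lo = compute_restricted_partition(d, depths, small_params, T, site, "open")
            lc = compute_restricted_partition(d, depths, small_params, T, site, "closed")
            assert np.logaddexp(lo, lc) == pytest.approx(full, abs=1e-12)

    def test_restricted_never_exceeds_full(self, small_params):
        d = parse_duplex("GAG")
        depths = free_depths(d, small_params)
        full = log_partition(d, depths, small_params, 300.0)
        lo = compute_restricted_partition(d, depths, small_params, 300.0, 2, "open")
        assert lo <= full

    def test_single_site_open_probability_matches_1d_quadrature(self, params):
        d = parse_duplex("A")
        depths = free_depths(d, params)
        T = 300.0
        g = build_grid(params)
        beta = 1.0 / (params.k_B * T)
        boltz = np.exp(-beta * morse(g.nodes, depths[0], params.a_AT))
        oracle = g.integrate(boltz * (g.nodes >= params.y0)) / g.integrate(boltz)
        lo = compute_restricted_partition(d, depths, params, T, 1, "open", grid=g)
        full = log_partition(d, depths, params, T, grid=g)
        assert np.exp(lo - full) == pytest.approx(oracle, rel=1e-10)

    def test_mask_at_domain_edge_is_noop(self, small_params):
        d = parse_duplex("GA")
        depths = free_depths(d, small_params)
        g = build_grid(small_params)
        full = log_partition(d, depths, small_params, 300.0, grid=g)
        keep_all = g.nodes >= small_params.y_min
        masked = log_partition(d, depths, small_params, 300.0, grid=g,
                               site_mask=(1, keep_all))
        assert masked == pytest.approx(full, abs=1e-14)
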