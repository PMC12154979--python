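"""Opening probabilities, open fraction, mean separation."""

import numpy as np
import pytest

from pbdmelt import (
    CrowderConfig,
    average_separation,
    compute_partition,
    compute_restricted_partition,
    fraction_open,
    log_partition,
    opening_map,
    opening_probability,
    parse_duplex,
)
from pbdmelt.crowders import effective_depths

from conftest import free_depths


class TestOpeningProbability:
    def test_probabilities_lie_in_unit_interval(self, params, chain_a):
        depths = free_depths(chain_a, params)
        res = compute_partition(chain_a, depths, params, 250.0)
        P = opening_probability(res, params)
        assert np.all((P >= 0) & (P <= 1))

    def test_open_plus_closed_is_one(self, params, chain_a):
        depths = free_depths(chain_a, params)
        res = compute_partition(chain_a, depths, params, 250.0)
        open_nodes = res.grid.nodes >= params.y0
        p_open = res.site_masses[:, open_nodes].sum(axis=1)
        p_closed = res.site_masses[:, ~open_nodes].sum(axis=1)
        np.testing.assert_allclose(p_open + p_closed, 1.0, atol=1e-12)

    def test_matches_restricted_partition_ratio(self, small_params):
        """Forward/backward marginal route == masked-contraction route."""
        d = parse_duplex("GAGA")
        depths = free_depths(d, small_params)
        T = 260.0
        res = compute_partition(d, depths, small_params, T)
        full = log_partition(d, depths, small_params, T)
        for site in (1, 3):
            lo = compute_restricted_partition(d, depths, small_params, T, site, "open")
            assert opening_probability(res, small_params, site) == pytest.approx(
                np.exp(lo - full), rel=1e-10
            )

    def test_crowding_a_site_closes_it(self, params, chain_a):
        T = 230.0
        free = compute_partition(chain_a, free_depths(chain_a, params), params, T)
        crowded_depths = effective_depths(chain_a, CrowderConfig(((4, 1.5),)), params)
        crowded = compute_partition(chain_a, crowded_depths, params, T)
        assert opening_probability(crowded, params, 4) < opening_probability(free, params, 4)

    def test_nondecreasing_in_temperature(self, params, chain_a):
        depths = free_depths(chain_a, params)
        prev = None
        for T in (180.0, 220.0, 260.0, 300.0):
            P = opening_probability(compute_partition(chain_a, depths, params, T), params)
            if prev is not None:
                assert np.all(P - prev > -1e-6)
            prev = P


class TestFractionOpen:
    def test_equals_site_mean_of_opening_probabilities(self, params, chain_a):
        depths = free_depths(chain_a, params)
        res = compute_partition(chain_a, depths, params, 260.0)
        assert fraction_open(res, params) == pytest.approx(
            float(np.mean(opening_probability(res, params))), abs=1e-12
        )

    def test_bound_at_low_temperature(self, params, chain_a):
        depths = free_depths(chain_a, params)
        res = compute_partition(chain_a, depths, params, 150.0)
        assert fraction_open(res, params) < 0.01

    def test_fully_open_at_high_temperature(self, params, chain_a):
        depths = free_depths(chain_a, params)
        res = compute_partition(chain_a, depths, params, 500.0)
        assert fraction_open(res, params) > 0.99


class TestAverageSeparation:
    def test_small_at_low_temperature(self, params):
        # at 50 K the grid under-resolves the narrow GC well, so only
        # smallness is asserted there; the Morse-asymmetry positivity is
        # checked at 150 K where the quadrature resolves the well
        d = parse_duplex("GAG")
        y50 = average_separation(
            compute_partition(d, free_depths(d, params), params, 50.0))
        assert np.all(np.abs(y50) < 0.05)
        y100 = average_separation(
            compute_partition(d, free_depths(d, params), params, 100.0))
        assert np.all(y100 > 0) and np.all(y100 < 0.5)

    def test_rises_through_transition(self, params, chain_a):
        depths = free_depths(chain_a, params)
        y_cold = average_separation(
            compute_partition(chain_a, depths, params, 180.0), site=4)
        y_hot = average_separation(
            compute_partition(chain_a, depths, params, 280.0), site=4)
        assert y_cold < 2.0 < y_hot

    def test_single_site_matches_1d_quadrature(self, params):
        from pbdmelt import build_grid
        from pbdmelt.potentials import morse

        d = parse_duplex("A")
        depths = free_depths(d, params)
        T = 300.0
        g = build_grid(params)
        beta = 1.0 / (params.k_B * T)
        boltz = np.exp(-beta * morse(g.nodes, depths[0], params.a_AT))
        oracle = g.integrate(g.nodes * boltz) / g.integrate(boltz)
        res = compute_partition(d, depths, params, T, grid=g)
        assert average_separation(res, site=1) == pytest.approx(oracle, rel=1e-10)


class TestOpeningMap:
    def test_column_means_equal_phi(self, params, chain_a):
        temps = np.array([200.0, 240.0, 280.0])
        omap = opening_map(chain_a, CrowderConfig(), params, temps)
        depths = free_depths(chain_a, params)
        for j, T in enumerate(temps):
            res = compute_partition(chain_a, depths, params, float(T))
            assert omap.P[:, j].mean() == pytest.approx(
                fraction_open(res, params), abs=1e-8
            )

    def test_shape_and_threshold_recorded(self, params, chain_a):
        omap = opening_map(chain_a, CrowderConfig(), params, np.array([250.0]))
        assert omap.P.shape == (8, 1)
        assert omap.y0_used == params.y0
        np.testing.assert_array_equal(omap.sites, np.arange(1, 9))
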