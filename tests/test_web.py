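"""Core GLV algebra: growth rates, steady states, community matrices."""

import json

import numpy as np
import pytest

from evospectra.web import (
    FoodWeb,
    SpeciesParams,
    assemble_linear_system,
    community_matrix,
    is_stable,
    per_capita_growth,
    spectrum,
    steady_state,
    trophic_levels,
)

from conftest import random_feasible_web


class TestPerCapitaGrowth:
    def test_single_producer_at_equilibrium(self, single_producer):
        assert per_capita_growth(single_producer, [0.8])[0] == pytest.approx(0.0)

    def test_zero_biomass_limit(self, pair_web):
        f = per_capita_growth(pair_web, [0.0, 0.0])
        assert f[0] == pytest.approx(1.0 - 0.1)  # producers: k - alpha
        assert f[1] == pytest.approx(-0.2)  # consumers: -alpha

    def test_pair_web_equilibrium(self, pair_web):
        assert per_capita_growth(pair_web, [0.4, 1.0]) == pytest.approx([0.0, 0.0])

    def test_dimension_mismatch_rejected(self, pair_web):
        with pytest.raises(ValueError):
            per_capita_growth(pair_web, [0.4])


class TestSteadyState:
    def test_single_producer_closed_form(self, single_producer):
        ss = steady_state(single_producer)
        assert ss.feasible
        assert ss.populations == pytest.approx([0.8])

    def test_pair_web_hand_algebra(self, pair_web):
        ss = steady_state(pair_web)
        assert ss.feasible
        assert ss.populations == pytest.approx([0.4, 1.0])
        assert ss.residual < 1e-8

    def test_weak_consumer_infeasible(self):
        # beta*eta*(1 - alpha1/k) < alpha2: the consumer cannot persist and
        # its required producer biomass exceeds the carrying capacity.
        eta = np.zeros((2, 2))
        eta[1, 0] = 0.1
        web = FoodWeb([0, 1], [0.1, 0.2], [True, False], eta, [0.9, 0.0],
                      beta=1.0, k=1.0)
        ss = steady_state(web)
        assert not ss.feasible
        assert ss.populations[0] == pytest.approx(2.0)  # alpha2 / (beta eta)
        assert ss.populations[1] < 0

    def test_disconnected_consumer_has_no_unique_state(self):
        web = FoodWeb([0, 1], [0.1, 0.2], [True, False], np.zeros((2, 2)),
                      [0.9, 0.0], beta=1.0, k=1.0)
        ss = steady_state(web)
        assert not ss.unique
        assert not ss.feasible

    def test_linear_system_reproduces_growth_zero(self, pair_web):
        R, K = assemble_linear_system(pair_web)
        S = np.linalg.solve(R, K)
        assert per_capita_growth(pair_web, S) == pytest.approx([0.0, 0.0], abs=1e-12)


class TestCommunityMatrix:
    def test_pair_web_hand_jacobian(self, pair_web):
        cm = community_matrix(pair_web, steady_state(pair_web))
        assert cm.entries == pytest.approx(
            np.array([[-0.4, -0.2], [0.5, 0.0]]), abs=1e-12
        )

    def test_single_producer(self, single_producer):
        cm = community_matrix(single_producer, steady_state(single_producer))
        assert cm.entries == pytest.approx(np.array([[-0.8]]))

    def test_infeasible_fixed_point_rejected(self):
        eta = np.zeros((2, 2))
        eta[1, 0] = 0.1
        web = FoodWeb([0, 1], [0.1, 0.2], [True, False], eta, [0.9, 0.0],
                      beta=1.0, k=1.0)
        with pytest.raises(ValueError):
            community_matrix(web, steady_state(web))

    def test_matches_numerical_jacobian_on_random_webs(self):
        """Analytic Jacobian vs central differences on >=100 random webs."""
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 100:
            web = random_feasible_web(rng)
            if web.n < 2:
                continue
            ss = steady_state(web)
            C = community_matrix(web, ss).entries
            n = web.n
            num = np.empty((n, n))
            h = 1e-6
            for j in range(n):
                up = ss.populations.copy()
                dn = ss.populations.copy()
                up[j] += h
                dn[j] -= h
                dup = up * per_capita_growth(web, up)
                ddn = dn * per_capita_growth(web, dn)
                num[:, j] = (dup - ddn) / (2 * h)
            scale = np.abs(C).max()
            assert np.abs(C - num).max() < 1e-6 * max(scale, 1.0)
            checked += 1


class TestSpectrum:
    def test_pair_web_quadratic_roots(self, pair_web):
        eigs = np.sort_complex(spectrum(community_matrix(pair_web, steady_state(pair_web))))
        expected = np.sort_complex(np.array([-0.2 + 0.24494897j, -0.2 - 0.24494897j]))
        assert eigs == pytest.approx(expected, abs=1e-8)

    def test_conjugate_closure_random_webs(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            web = random_feasible_web(rng)
            eigs = spectrum(community_matrix(web, steady_state(web)))
            assert np.sort_complex(eigs.conj()) == pytest.approx(np.sort_complex(eigs))

    @pytest.mark.parametrize(
        "eigs, stable",
        [
            ([-0.2 + 0.2449j, -0.2 - 0.2449j], True),
            ([0.0], True),  # marginal two-species case counts as stable
            ([0.1, -1.0], False),
        ],
    )
    def test_stability_verdicts(self, eigs, stable):
        assert is_stable(np.array(eigs)) is stable


class TestTrophicLevels:
    def test_chain(self, pair_web):
        assert trophic_levels(pair_web) == pytest.approx([1.0, 2.0])

    def test_mixed_level_resources(self):
        # consumer 3 eats the level-1 producer and the level-2 consumer
        eta = np.zeros((3, 3))
        eta[1, 0] = 0.5
        eta[2, 0] = 0.3
        eta[2, 1] = 0.3
        web = FoodWeb([0, 1, 2], [0.1, 0.2, 0.2], [True, False, False], eta,
                      [0.1, 0.1, 0.1], beta=1.0, k=1.0)
        assert trophic_levels(web) == pytest.approx([1.0, 2.0, 2.5])

    def test_resourceless_consumer_rejected(self):
        web = FoodWeb([0, 1], [0.1, 0.2], [True, False], np.zeros((2, 2)),
                      [0.1, 0.1], beta=1.0, k=1.0)
        with pytest.raises(ValueError):
            trophic_levels(web)


class TestSpeciesParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"decay_rate": -0.1},
            {"decay_rate": 0.1, "efficiency": 0.0},
            {"decay_rate": 0.1, "efficiency": 1.5},
            {"decay_rate": 0.1, "biomass": -1.0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            SpeciesParams(**kwargs)


class TestSerialization:
    def test_round_trip_lossless(self):
        rng = np.random.default_rng(5)
        web = random_feasible_web(rng)
        restored = FoodWeb.from_json(web.to_json())
        assert np.array_equal(restored.ids, web.ids)
        assert np.array_equal(restored.alpha, web.alpha)
        assert np.array_equal(restored.is_producer, web.is_producer)
        assert np.array_equal(restored.eta, web.eta)
        assert np.array_equal(restored.biomass, web.biomass)
        assert restored.beta == web.beta
        assert restored.k == web.k

    def test_snapshot_schema(self, pair_web):
        doc = json.loads(pair_web.to_json())
        assert set(doc) == {"beta", "species", "links"}
        assert doc["links"] == [{"consumer_id": 1, "resource_id": 0, "eta": 0.5}]
        producer = doc["species"][0]
        assert producer["is_producer"] and producer["trophic_level"] == 1.0
        assert producer["k"] == 1.0


class TestEnergyAsymmetry:
    def test_consumer_gain_below_resource_loss_for_beta_below_one(self):
        rng = np.random.default_rng(3)
        web = random_feasible_web(rng, beta=0.5)
        consumers = np.flatnonzero(~web.is_producer)
        for c in consumers:
            for r in web.resources_of(c):
                assert web.beta * web.eta[c, r] < web.eta[c, r]
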