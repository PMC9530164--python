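"""Invader generation and the sequential-invasion evolution loop."""

import numpy as np
import pytest

from evospectra.assembly import (
    AssemblyConfig,
    Invader,
    attempt_invasion,
    draw_invader,
    evolve,
    metrics,
    success_rate,
)
from evospectra.web import FoodWeb, trophic_levels


def chain_web(beta=1.0):
    """Producer -> consumer -> consumer chain with known levels 1, 2, 3."""
    eta = np.zeros((3, 3))
    eta[1, 0] = 0.5
    eta[2, 1] = 0.5
    return FoodWeb([0, 1, 2], [0.1, 0.15, 0.1], [True, False, False], eta,
                   [0.3, 0.5, 0.5], beta, 1.0)


class TestDrawInvader:
    def test_treelike_invaders_have_single_resource(self):
        cfg = AssemblyConfig(mode="treelike", beta=0.75, attempts=1)
        rng = np.random.default_rng(0)
        web = chain_web()
        for _ in range(500):
            inv = draw_invader(cfg, web, rng)
            if not inv.is_producer:
                assert len(inv.resources) == 1

    def test_omnivorous_second_resource_frequency(self):
        cfg = AssemblyConfig(mode="omnivorous", beta=0.75, attempts=1)
        rng = np.random.default_rng(1)
        web = chain_web()
        two = total = 0
        for _ in range(20_000):
            inv = draw_invader(cfg, web, rng)
            if not inv.is_producer:
                total += 1
                two += len(inv.resources) == 2
        assert two / total == pytest.approx(0.5, abs=0.02)

    def test_non_omnivorous_pairs_share_trophic_level(self):
        cfg = AssemblyConfig(mode="non_omnivorous", beta=0.75, attempts=1)
        rng = np.random.default_rng(2)
        # two producers plus one consumer: levels 1, 1, 2
        eta = np.zeros((3, 3))
        eta[2, 0] = 0.5
        web = FoodWeb([0, 1, 2], [0.1, 0.2, 0.15], [True, True, False], eta,
                      [0.3, 0.3, 0.4], 0.75, 1.0)
        levels = trophic_levels(web)
        index = {int(i): lv for i, lv in zip(web.ids, levels)}
        seen_two = False
        for _ in range(2000):
            inv = draw_invader(cfg, web, rng)
            if not inv.is_producer and len(inv.resources) == 2:
                seen_two = True
                assert index[inv.resources[0]] == pytest.approx(index[inv.resources[1]])
        assert seen_two

    def test_producer_fraction(self):
        # default: one producer invasion for every two consumer invasions
        cfg = AssemblyConfig(mode="treelike", beta=0.75, attempts=1)
        rng = np.random.default_rng(3)
        web = chain_web()
        draws = [draw_invader(cfg, web, rng).is_producer for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(1.0 / 3.0, abs=0.01)
        cfg_half = AssemblyConfig(mode="treelike", beta=0.75, attempts=1,
                                  producer_fraction=0.5)
        draws = [draw_invader(cfg_half, web, rng).is_producer for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_parameter_ranges(self):
        cfg = AssemblyConfig(mode="omnivorous", beta=0.75, attempts=1)
        rng = np.random.default_rng(4)
        web = chain_web()
        for _ in range(1000):
            inv = draw_invader(cfg, web, rng)
            assert 0.05 <= inv.alpha <= 0.5
            for e in inv.etas:
                assert 0.01 <= e <= 1.0

    def test_empty_web_rejected(self):
        cfg = AssemblyConfig(mode="treelike", beta=0.75, attempts=1)
        empty = FoodWeb([], [], [], np.zeros((0, 0)), [], 0.75, 1.0)
        with pytest.raises(ValueError):
            draw_invader(cfg, empty, np.random.default_rng(0))


class TestAttemptInvasion:
    def test_fitter_producer_replaces_same_niche_resident(self):
        web = FoodWeb([0], [0.3], [True], np.zeros((1, 1)), [0.7], 0.75, 1.0)
        invader = Invader(alpha=0.1, is_producer=True)
        new_web, record, _ = attempt_invasion(web, invader, 1, attempt_index=1)
        assert record.success
        assert record.extinct_count == 1
        assert new_web.ids.tolist() == [1]
        assert new_web.biomass[0] == pytest.approx(0.9, rel=1e-4)

    def test_less_fit_producer_fails_to_invade(self):
        web = FoodWeb([0], [0.1], [True], np.zeros((1, 1)), [0.9], 0.75, 1.0)
        invader = Invader(alpha=0.3, is_producer=True)
        new_web, record, _ = attempt_invasion(web, invader, 1, attempt_index=1)
        assert not record.success
        assert record.extinct_count == 0
        assert not record.web_changed
        assert new_web.ids.tolist() == [0]

    def test_overconsuming_invader_triggers_cascade(self):
        # producer + weak consumer; a strong second consumer of the producer
        # pushes the weak one out (exploitative competition)
        eta = np.zeros((2, 2))
        eta[1, 0] = 0.3
        web = FoodWeb([0, 1], [0.1, 0.05], [True, False], eta,
                      [0.1667, 2.3333], 1.0, 1.0)
        invader = Invader(alpha=0.05, is_producer=False, resources=[0], etas=[0.9])
        new_web, record, _ = attempt_invasion(web, invader, 2, attempt_index=1)
        assert record.success
        assert record.extinct_count >= 1
        assert 2 in new_web.ids


class TestEvolve:
    def test_seed_reproducibility(self):
        cfg = AssemblyConfig(mode="omnivorous", beta=0.75, attempts=150, seed=9)
        h1, h2 = evolve(cfg), evolve(cfg)
        assert [r.success for r in h1.records] == [r.success for r in h2.records]
        assert [r.richness_after for r in h1.records] == [
            r.richness_after for r in h2.records
        ]
        assert np.array_equal(h1.final_web.biomass, h2.final_web.biomass)
        assert np.array_equal(h1.min_producer_alpha_trace, h2.min_producer_alpha_trace)

    def test_treelike_min_producer_alpha_monotone(self):
        cfg = AssemblyConfig(mode="treelike", beta=0.75, attempts=400, seed=17)
        h = evolve(cfg)
        trace = h.min_producer_alpha_trace
        assert np.all(np.diff(trace) <= 1e-15)

    def test_treelike_history_has_no_two_resource_consumer(self):
        cfg = AssemblyConfig(mode="treelike", beta=0.75, attempts=300, seed=23)
        h = evolve(cfg)
        assert all(w.treelike for w in h.recorded_webs)
        assert h.final_web.is_treelike()

    def test_richness_bounds(self):
        cfg = AssemblyConfig(mode="omnivorous", beta=0.9, attempts=200, seed=29)
        h = evolve(cfg)
        for r in h.records:
            assert 1 <= r.richness_after <= r.attempt_index + 1

    def test_residence_intervals_well_formed(self):
        cfg = AssemblyConfig(mode="non_omnivorous", beta=0.75, attempts=300, seed=31)
        h = evolve(cfg)
        for sid, (arrival, departure) in h.residence.items():
            assert arrival >= 0
            if departure is not None:
                assert departure >= arrival
        # survivors of the final web are exactly the unclosed intervals
        alive = {sid for sid, (_, dep) in h.residence.items() if dep is None}
        assert alive == {int(i) for i in h.final_web.ids}


class TestMetricsAndRates:
    def test_success_rate_counts_survivals(self):
        cfg = AssemblyConfig(mode="treelike", beta=0.75, attempts=200, seed=37)
        h = evolve(cfg)
        expected = sum(r.success for r in h.records) / len(h.records)
        assert success_rate(h) == expected

    def test_richness_histogram_normalised(self):
        cfg = AssemblyConfig(mode="treelike", beta=0.75, attempts=200, seed=41)
        m = metrics(evolve(cfg))
        assert sum(m["richness_histogram"].values()) == pytest.approx(1.0)

    def test_extinction_sizes_are_relative(self):
        cfg = AssemblyConfig(mode="omnivorous", beta=0.75, attempts=300, seed=43)
        m = metrics(evolve(cfg))
        sizes = m["extinction_size_distribution"]
        if sizes.size:
            assert np.all(sizes > 0) and np.all(sizes <= 1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AssemblyConfig(mode="cyclic", beta=0.75, attempts=10)
        with pytest.raises(ValueError):
            AssemblyConfig(mode="treelike", beta=1.5, attempts=10)
        with pytest.raises(ValueError):
            AssemblyConfig(mode="treelike", beta=0.75, attempts=0)
        with pytest.raises(ValueError):
            AssemblyConfig(mode="treelike", beta=0.75, attempts=10,
                           alpha_range=(0.5, 0.05))
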