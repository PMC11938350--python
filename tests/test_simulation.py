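"""Unit behavior of the simulator's elementary operations and scheduler."""

import numpy as np
import pytest

import gcplasma as g
from gcplasma.cells import BcrGenotype
from gcplasma.config import HIGH_AFFINITY_GERMLINE
from gcplasma.simulation import (
    allocate_help,
    capture_antigen,
    division_burst,
    fate_draw,
    mutate,
    myc_from_help,
    reentry_probability,
    serum_avidity_ratio,
)


def _genotype(v="IGHV1-72", heavy=frozenset(), light=frozenset()):
    return BcrGenotype(v, "IGLV1", "AAA", "CCC", frozenset(heavy), frozenset(light))


class TestAffinity:
    def test_unmutated_baseline(self):
        model = g.AffinityModel()
        a0 = model.base_affinity_by_germline[HIGH_AFFINITY_GERMLINE]
        assert g.affinity_of(_genotype(), model) == a0

    def test_single_hotspot_factor(self):
        model = g.AffinityModel()
        got = g.affinity_of(_genotype(heavy={"W33L"}), model)
        assert got == pytest.approx(10.0 * model.mutation_effects["W33L"])

    def test_triple_hotspot_matches_brute_force_product(self):
        model = g.AffinityModel()
        muts = {"W33L", "K59R", "Y99G"}
        expected = model.base_affinity_by_germline[HIGH_AFFINITY_GERMLINE]
        for m in muts:  # independent brute-force product
            expected *= model.mutation_effects[m]
        assert g.affinity_of(_genotype(heavy=muts), model) == pytest.approx(expected)

    def test_neutral_mutations_are_factor_one(self):
        model = g.AffinityModel()
        assert g.affinity_of(_genotype(heavy={"n17u0"}, light={"n4u1"}), model) == 10.0

    def test_unknown_germline(self):
        with pytest.raises(KeyError, match="IGHV999"):
            g.affinity_of(_genotype(v="IGHV999"), g.AffinityModel())


class TestCapture:
    def test_zero_affinity(self):
        assert capture_antigen(0.0, 1.0, g.SimConfig()) == 0.0

    def test_half_saturation(self):
        cfg = g.SimConfig()
        assert capture_antigen(cfg.capture_k, 1.0, cfg) == pytest.approx(0.5)
        cfg2 = cfg.with_(hill=3.0)
        assert capture_antigen(cfg2.capture_k, 1.0, cfg2) == pytest.approx(0.5)

    def test_strictly_increasing_in_affinity(self):
        cfg = g.SimConfig()
        grid = np.linspace(0.01, 200.0, 100)
        caps = [capture_antigen(a, 1.0, cfg) for a in grid]
        assert all(b > a for a, b in zip(caps, caps[1:]))


class TestAllocateHelp:
    def test_single_competitor_takes_all(self):
        assert allocate_help([0.3], 10.0)[0] == pytest.approx(10.0)

    def test_symmetry(self):
        h = allocate_help([0.2] * 8, 40.0)
        assert np.allclose(h, 5.0)

    def test_conservation_random_captures(self):
        rng = np.random.default_rng(1)
        caps = rng.random(50)
        h = allocate_help(caps, 123.4)
        assert abs(h.sum() - 123.4) / 123.4 < 1e-9

    def test_all_zero_captures(self):
        assert allocate_help([0.0, 0.0], 5.0).sum() == 0.0


class TestMycAndBurst:
    def test_myc_linear(self):
        cfg = g.SimConfig(beta=2.0)
        assert myc_from_help(0.0, cfg) == 0.0
        assert myc_from_help(3.0, cfg) == 6.0
        rng = np.random.default_rng(0)
        for h in rng.random(20):
            assert myc_from_help(2 * h, cfg) == pytest.approx(2 * myc_from_help(h, cfg))

    def test_burst_zero_myc(self):
        cfg = g.SimConfig()
        rng = np.random.default_rng(0)
        assert all(division_burst(0.0, cfg, rng) == 0 for _ in range(100))

    def test_burst_mean_matches_poisson(self):
        # alpha * myc = 2 with a high cap: sample mean within 3 SE of 2
        cfg = g.SimConfig(alpha=1.0, n_max=12)
        rng = np.random.default_rng(2)
        draws = [division_burst(2.0, cfg, rng) for _ in range(10_000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 2.0) < 3 * se + 0.01  # cap truncation is tiny

    def test_burst_cap(self):
        cfg = g.SimConfig(alpha=1.0, n_max=8)
        rng = np.random.default_rng(3)
        assert max(division_burst(50.0, cfg, rng) for _ in range(10_000)) <= 8


class TestFateDraw:
    def _cell(self, affinity=10.0):
        return g.Cell(0, 0, _genotype(), "LZ", affinity)

    def test_no_prepc_when_rate_zero(self):
        cfg = g.SimConfig(p_prepc=0.0)
        rng = np.random.default_rng(0)
        fates = {fate_draw(self._cell(), 1.0, cfg, rng) for _ in range(2000)}
        assert "prePC" not in fates

    def test_zero_help_death_or_export(self):
        cfg = g.SimConfig(p_prepc=0.1)
        rng = np.random.default_rng(1)
        fates = [fate_draw(self._cell(), 0.0, cfg, rng) for _ in range(10_000)]
        frac_death = fates.count("death") / len(fates)
        assert fates.count("DZ") == 0
        se = np.sqrt(0.9 * 0.1 / len(fates))
        assert abs(frac_death - 0.9) < 3 * se

    def test_affinity_permissive_export(self):
        """prePC entry must be independent of affinity: high- vs low-affinity
        cohorts differ by < 3 binomial SE over 10,000 draws each."""
        cfg = g.SimConfig()
        rng = np.random.default_rng(4)
        n = 10_000
        hi = sum(fate_draw(self._cell(1000.0), 2.0, cfg, rng) == "prePC" for _ in range(n))
        lo = sum(fate_draw(self._cell(0.01), 0.001, cfg, rng) == "prePC" for _ in range(n))
        p = (hi + lo) / (2 * n)
        se = np.sqrt(2 * p * (1 - p) / n)
        assert abs(hi - lo) / n < 3 * se

    def test_reentry_increases_with_help(self):
        cfg = g.SimConfig()
        ps = [reentry_probability(h, cfg) for h in (0.0, 0.01, 0.1, 1.0)]
        assert ps[0] == 0.0 and all(b > a for a, b in zip(ps, ps[1:]))


class TestMutate:
    def test_mu_zero_unchanged(self):
        gt = _genotype()
        rng = np.random.default_rng(0)
        out, serial = mutate(gt, rng, g.AffinityModel(), 0.0, 0)
        assert out is gt and serial == 0

    def test_non_analog_never_gains_hotspots(self):
        gt = _genotype(v="IGHV9-3")
        model = g.AffinityModel()
        rng = np.random.default_rng(1)
        serial = 0
        for _ in range(10_000):
            out, serial = mutate(gt, rng, model, 1.0, serial)
            if out is not None:
                assert not (out.mutations_heavy & {"W33L", "K59R", "Y99G"})

    def test_lethal_fraction_matches_binomial(self):
        model = g.AffinityModel(lethal_fraction=0.3)
        rng = np.random.default_rng(2)
        gt = _genotype()
        n = 10_000
        dead = 0
        serial = 0
        for _ in range(n):
            out, serial = mutate(gt, rng, model, 1.0, serial)
            dead += out is None
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(dead / n - 0.3) < 3 * se

    def test_mutation_sets_only_grow(self):
        model = g.AffinityModel()
        rng = np.random.default_rng(3)
        gt = _genotype()
        serial = 0
        for _ in range(500):
            out, serial = mutate(gt, rng, model, 1.0, serial)
            if out is None:
                continue
            assert out.mutations_heavy >= gt.mutations_heavy
            assert out.mutations_light >= gt.mutations_light
            gt = out


class TestSerumRatio:
    def test_saturation_limit(self):
        centers = np.array([1e9])
        r = serum_avidity_ratio(np.array([5.0]), centers, 0.01, 0.04)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_hand_evaluated_single_bin(self):
        # a*L_low = 1 and a*L_high = 4: theta ratio (1/2)/(4/5) = 0.625
        centers = np.array([100.0])
        r = serum_avidity_ratio(np.array([2.0]), centers, 0.01, 0.04)
        assert r == pytest.approx(0.625)

    def test_mass_shift_to_high_affinity_increases_ratio(self):
        centers = np.array([1.0, 1000.0])
        grid = np.linspace(0.0, 0.5, 11)
        ratios = [
            serum_avidity_ratio(np.array([1.0 - w, w]), centers, 0.01, 0.04)
            for w in grid
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_empty_serum_rejected(self):
        with pytest.raises(ValueError):
            serum_avidity_ratio(np.zeros(3), np.ones(3), 0.01, 0.04)
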