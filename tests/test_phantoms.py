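"""Phantom samplers, rasterization and the Beltrami coefficient map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbarnet.exceptions import (ConfigurationError, ContractViolation,
                                DomainError)
from dbarnet.grids import ImageGrid
from dbarnet.phantoms import (ACT4Rules, KIT4Rules, ConductivityImage,
                              ConductivityPhantom, Inclusion,
                              conductivity_to_mu, rasterize,
                              sample_act4_phantom, sample_kit4_phantom,
                              scale_to_unit_boundary)


def _square(side, sigma=1.0, **kw):
    s = side / 2
    return Inclusion(np.array([[-s, -s], [s, -s], [s, s], [-s, s]]), sigma, **kw)


class TestThoracicSampler:
    def test_forced_inclusion_gives_five_organs_with_window_sigmas(self):
        rules = ACT4Rules(
            inclusion_probability={k: 1.0 for k in
                                   ["left_lung", "right_lung", "spine",
                                    "heart", "aorta"]},
            injury_probability=0.0)
        ph = sample_act4_phantom(rules, np.random.default_rng(0))
        assert len(ph.inclusions) == 5
        by_label = {i.label: i for i in ph.inclusions}
        assert 0.01 <= by_label["spine"].sigma <= 0.2
        assert 0.5 <= by_label["heart"].sigma <= 0.8
        assert 0.29 <= ph.background_sigma <= 0.31

    def test_inclusion_frequencies_match_stated_probabilities(self):
        rng = np.random.default_rng(7)
        n = 2000
        counts = {k: 0 for k in ["left_lung", "right_lung", "spine",
                                 "heart", "aorta"]}
        expect = {"left_lung": 0.90, "right_lung": 0.90, "spine": 1.00,
                  "heart": 0.95, "aorta": 0.95}
        for _ in range(n):
            ph = sample_act4_phantom(ACT4Rules(), rng)
            for inc in ph.inclusions:
                counts[inc.label] += 1
        assert counts["spine"] == n  # always present
        for organ, p in expect.items():
            sd = np.sqrt(p * (1 - p) / n) if p < 1 else 0.0
            assert abs(counts[organ] / n - p) <= max(3 * sd, 1e-12), organ

    def test_injury_is_horizontal_split_with_wide_window(self):
        rules = ACT4Rules(injury_probability=1.0)
        rng = np.random.default_rng(3)
        ph = sample_act4_phantom(rules, rng)
        lungs = [i for i in ph.inclusions if i.label.endswith("lung")]
        assert lungs and all(l.split is not None for l in lungs)
        for l in lungs:
            assert l.split.normal == (0.0, 1.0)
            injured = {l.split.sigma_pos, l.split.sigma_neg} - {l.sigma}
            for s in injured:
                assert 0.01 <= s <= 1.5

    def test_invalid_probability_rejected(self):
        rules = ACT4Rules(inclusion_probability={
            "left_lung": 1.2, "right_lung": 0.9, "spine": 1.0,
            "heart": 0.95, "aorta": 0.95})
        with pytest.raises(ConfigurationError):
            sample_act4_phantom(rules, np.random.default_rng(0))


class TestEllipseSampler:
    def test_single_unsplit_conductive_draw(self):
        # force one inclusion, no splits
        rules = KIT4Rules(n_inclusions=(1, 1), split_probability=0.0)
        for seed in range(20):
            ph = sample_kit4_phantom(rules, np.random.default_rng(seed))
            assert len(ph.inclusions) == 1
            (inc,) = ph.inclusions
            assert (0.29 <= inc.sigma <= 0.34) or (0.05 <= inc.sigma <= 0.075)
            assert 0.13 <= ph.background_sigma <= 0.145

    def test_every_ellipse_inside_095_disc_and_disjoint(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ph = sample_kit4_phantom(KIT4Rules(), rng)
            polys = [i.polygon for i in ph.inclusions]
            for p in ph.inclusions:
                assert np.max(np.hypot(*p.vertices.T)) <= 0.95 + 1e-12
            for a in range(len(polys)):
                for b in range(a + 1, len(polys)):
                    assert not polys[a].intersects(polys[b])

    def test_split_rate_and_region_fraction(self):
        rng = np.random.default_rng(5)
        n_inc = n_split = 0
        for _ in range(1500):
            ph = sample_kit4_phantom(KIT4Rules(), rng)
            for inc in ph.inclusions:
                n_inc += 1
                if inc.split is not None:
                    n_split += 1
        p = 1.0 / 3.0
        sd = np.sqrt(p * (1 - p) / n_inc)
        assert abs(n_split / n_inc - p) <= 3 * sd

    def test_infeasible_rules_raise_generation_error(self):
        from dbarnet.exceptions import GenerationError
        rules = KIT4Rules(n_inclusions=(3, 3), axis_window=(0.9, 0.95),
                          max_attempts=20)
        with pytest.raises(GenerationError):
            sample_kit4_phantom(rules, np.random.default_rng(0))


class TestRasterize:
    def test_no_inclusions_gives_constant_background(self, image_grid):
        ph = ConductivityPhantom([], 0.25, family="KIT4")
        img = rasterize(ph, image_grid)
        assert np.all(img.values == 0.25)

    def test_disc_node_count_matches_brute_force(self, image_grid):
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        disc = Inclusion(0.5 * np.column_stack([np.cos(t), np.sin(t)]), 2.0)
        ph = ConductivityPhantom([disc], 1.0, family="KIT4")
        img = rasterize(ph, image_grid)
        got = int(np.sum(img.values == 2.0))
        brute = int(np.sum(np.abs(image_grid.z) <= 0.5))
        assert abs(got - brute) <= 4

    def test_deterministic(self, image_grid):
        rng = np.random.default_rng(2)
        ph = sample_kit4_phantom(KIT4Rules(), rng)
        a = rasterize(ph, image_grid).values
        b = rasterize(ph, image_grid).values
        assert np.array_equal(a, b)

    def test_innermost_inclusion_wins(self, image_grid):
        outer = _square(1.0, sigma=2.0)
        inner = _square(0.4, sigma=3.0)
        ph = ConductivityPhantom([outer, inner], 1.0, family="KIT4")
        img = rasterize(ph, image_grid)
        i0 = image_grid.n // 2
        assert img.values[i0, i0] == 3.0

    def test_split_region_respected(self, image_grid):
        from dbarnet.phantoms import SplitSpec
        sq = _square(1.0, sigma=2.0)
        inc = Inclusion(sq.vertices, 2.0,
                        split=SplitSpec((0.0, 0.0), (0.0, 1.0), 5.0, 3.0))
        ph = ConductivityPhantom([inc], 1.0, family="KIT4")
        v = rasterize(ph, image_grid).values
        assert v[41, image_grid.n // 2] == 5.0  # x2 ~ +0.3: positive side
        assert v[22, image_grid.n // 2] == 3.0  # x2 ~ -0.3: negative side


class TestScalingAndMu:
    def test_constant_image_scales_to_one(self, image_grid):
        img = ConductivityImage(np.full((64, 64), 0.3), image_grid, 0.3)
        assert np.all(scale_to_unit_boundary(img).values == 1.0)

    def test_scale_formula_and_round_trip(self, image_grid):
        vals = np.full((64, 64), 0.14)
        vals[30:34, 30:34] = 0.30
        img = ConductivityImage(vals, image_grid, 0.14)
        scaled = scale_to_unit_boundary(img)
        assert np.isclose(scaled.values.max(), 0.30 / 0.14)
        assert np.allclose(scaled.values * 0.14, vals)

    def test_double_scaling_rejected(self, image_grid):
        img = ConductivityImage(np.ones((64, 64)), image_grid, 0.3, scaled=True)
        with pytest.raises(ContractViolation):
            scale_to_unit_boundary(img)

    @pytest.mark.parametrize("sigma,expected", [(1.0, 0.0),
                                                (0.3, 0.7 / 1.3),
                                                (3.0, -0.5)])
    def test_mu_values(self, image_grid, sigma, expected):
        img = ConductivityImage(np.full((64, 64), sigma), image_grid, 1.0,
                                scaled=True)
        mu = conductivity_to_mu(img, sign=+1)
        assert np.allclose(mu, expected)
        assert np.allclose(conductivity_to_mu(img, sign=-1), -expected)

    def test_mu_vanishes_near_boundary_for_generated_phantoms(self, solver_grid):
        rng = np.random.default_rng(8)
        for sampler, rules in [(sample_kit4_phantom, KIT4Rules()),
                               (sample_act4_phantom, ACT4Rules())]:
            for _ in range(10):
                ph = sampler(rules, rng)
                img = scale_to_unit_boundary(rasterize(ph, solver_grid))
                mu = conductivity_to_mu(img)
                assert np.abs(mu).max() < 1.0
                outside = np.abs(solver_grid.z) >= 0.95
                assert np.abs(mu[outside]).max() == 0.0

    def test_unscaled_image_rejected(self, image_grid):
        img = ConductivityImage(np.full((64, 64), 0.3), image_grid, 0.3)
        with pytest.raises(DomainError):
            conductivity_to_mu(img)


@given(sigma=st.floats(0.01, 100.0))
@settings(max_examples=50, deadline=None)
def test_mu_magnitude_below_one(sigma):
    grid = ImageGrid(16)
    img = ConductivityImage(np.full((16, 16), sigma), grid, 1.0, scaled=True)
    mu = conductivity_to_mu(img)
    assert np.all(np.abs(mu) < 1.0)
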