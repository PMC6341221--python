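"""Architecture descriptors: NN statistics, randomness index, Q, S, K, l_p."""

import numpy as np
import pytest

from netarch import FieldSpec, PointPattern
from netarch import synthetic as syn
from netarch.metrics import (
    cable_intensity,
    fit_persistence_length,
    intensity_skewness,
    junction_density,
    mean_nn_distance,
    random_reference,
    randomness_index,
    snake_curvature,
    summarize_network,
    wlc_curvature_pdf,
)
from netarch.network_io import Junction, NetworkModel, Snake
from conftest import brute_force_nn


class TestDensity:
    def test_field_mode(self):
        pts = np.random.default_rng(0).uniform(0, 10, size=(100, 2))
        assert junction_density(PointPattern(pts, FieldSpec(10, 10))) == pytest.approx(1.0)

    def test_hull_mode_at_least_field(self):
        pts = np.random.default_rng(1).uniform(0, 10, size=(100, 2))
        pat = PointPattern(pts, FieldSpec(10, 10))
        assert junction_density(pat, "hull") >= junction_density(pat, "field")

    def test_empty_pattern_errors(self):
        with pytest.raises(ValueError, match="empty"):
            junction_density(PointPattern(np.empty((0, 2)), FieldSpec(10, 10)))

    def test_single_point_density_defined_but_nn_errors(self):
        pat = PointPattern([[5.0, 5.0]], FieldSpec(10, 10))
        assert junction_density(pat) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            mean_nn_distance(pat)


class TestNearestNeighbour:
    def test_two_points_symmetric(self):
        pat = PointPattern([[0.0, 0.0], [1.0, 0.0]], FieldSpec(10, 10))
        r_mean, r_nn = mean_nn_distance(pat)
        assert r_mean == pytest.approx(1.0)
        assert list(r_nn) == [1.0, 1.0]

    def test_collinear_brute_force_example(self):
        """Points at 0, 1, 3 um: r_NN = (1, 1, 2), mean 4/3."""
        pat = PointPattern([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]], FieldSpec(10, 10))
        r_mean, r_nn = mean_nn_distance(pat)
        assert sorted(r_nn) == [1.0, 1.0, 2.0]
        assert r_mean == pytest.approx(4.0 / 3.0)

    def test_duplicates_allowed(self):
        pat = PointPattern([[1.0, 1.0], [1.0, 1.0], [4.0, 4.0]], FieldSpec(10, 10))
        r_mean, r_nn = mean_nn_distance(pat)
        assert np.min(r_nn) == 0.0

    def test_matches_exhaustive_search_exactly(self):
        """k-d tree accelerated NN equals the O(N^2) oracle bit-for-bit."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 500))
            pts = rng.uniform(0, 20, size=(n, 2))
            _, r_nn = mean_nn_distance(PointPattern(pts, FieldSpec(20, 20)))
            assert np.array_equal(np.sort(r_nn), np.sort(brute_force_nn(pts)))


class TestRandomnessIndex:
    @pytest.mark.parametrize("sigma,expected", [(0.25, 1.0), (1.0, 0.5), (4.0, 0.25)])
    def test_random_reference_values(self, sigma, expected):
        assert random_reference(sigma) == pytest.approx(expected)

    def test_coincident_points_give_zero(self):
        pat = PointPattern(np.tile([[5.0, 5.0]], (10, 1)), FieldSpec(10, 10))
        assert randomness_index(pat) == 0.0

    def test_rigid_motion_and_scale_invariance(self):
        """R is unchanged by rotation/translation and uniform rescaling
        (R_NN and r_rand scale identically)."""
        rng = np.random.default_rng(42)
        pts = rng.uniform(2, 18, size=(300, 2))
        base = randomness_index(PointPattern(pts, FieldSpec(20, 20)))
        th = 0.3
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = (pts - 10.0) @ rot.T + 10.0
        # same bounding field; points stay interior by construction
        r_rot = randomness_index(PointPattern(moved, FieldSpec(20, 20)))
        r_scaled = randomness_index(PointPattern(pts * 3.0, FieldSpec(60, 60)))
        assert r_rot == pytest.approx(base, rel=1e-9)
        assert r_scaled == pytest.approx(base, rel=1e-9)

    def test_ordering_clustered_poisson_hexagonal(self):
        """E[R] orders aggregated < random < optimally spaced at matched
        density, over 20 seeds."""
        r_c, r_p, r_h = [], [], []
        for seed in range(20):
            f = FieldSpec(50, 50, seed=seed)
            r_c.append(randomness_index(syn.gen_clustered_pattern(0.02, 10, 0.3, f)))
            r_p.append(randomness_index(syn.gen_poisson_pattern(0.2, f)))
            r_h.append(randomness_index(syn.gen_hexagonal_pattern(0.2, f)))
        assert np.mean(r_c) < np.mean(r_p) < np.mean(r_h)

    def test_default_mode_small_positive_edge_bias(self):
        """Without edge correction, border points inflate R_NN slightly;
        the bias is under half a percent at 10^4 points and removed by the
        guard-zone option."""
        vals_default, vals_guard = [], []
        for seed in range(10):
            p = syn.gen_poisson_pattern(1.0, FieldSpec(100, 100, seed=seed))
            vals_default.append(randomness_index(p))
            vals_guard.append(randomness_index(p, guard=2.0))
        assert 1.0 < np.mean(vals_default) < 1.005
        assert abs(np.mean(vals_guard) - 1.0) < 0.004

    def test_hexagonal_jitter_degrades_order(self):
        f0 = FieldSpec(60, 60, seed=0)
        r_sharp = randomness_index(syn.gen_hexagonal_pattern(1.0, f0))
        r_soft = randomness_index(
            syn.gen_hexagonal_pattern(1.0, FieldSpec(60, 60, seed=1), jitter_sd=3.0),
            guard=2.0,
        )
        assert r_sharp > 2.0
        assert 0.8 < r_soft < 1.35

    def test_thomas_large_spread_approaches_poisson(self):
        """With cluster spread comparable to the field, the clustered
        pattern is statistically indistinguishable from Poisson."""
        rc, rp = [], []
        for seed in range(20):
            f = FieldSpec(50, 50, seed=seed)
            c = syn.gen_clustered_pattern(0.05, 20, 25.0, f)
            rc.append(randomness_index(c, guard=2.0))
            p = syn.gen_poisson_pattern(len(c) / f.area, FieldSpec(50, 50, seed=seed + 1000))
            rp.append(randomness_index(p, guard=2.0))
        diff = np.mean(rc) - np.mean(rp)
        se = np.sqrt(np.var(rc, ddof=1) / 20 + np.var(rp, ddof=1) / 20)
        assert abs(diff) < 3 * se


class TestCableIntensity:
    def make_net(self, values, field=None):
        field = field or FieldSpec(20, 20)
        snakes = [
            Snake(f"s{i}", np.column_stack([np.linspace(1, 5, 4), np.full(4, i + 1.0),
                                            np.full(4, v)]))
            for i, v in enumerate(values)
        ]
        return NetworkModel(snakes=snakes, junctions=[], field=field, c=0.625)

    def test_uniform_snake_value(self):
        q, q_mean = cable_intensity(self.make_net([500.0]))
        assert q_mean == pytest.approx(500.0)

    def test_background_subtraction(self):
        q, q_mean = cable_intensity(self.make_net([500.0]), background=100.0)
        assert q_mean == pytest.approx(400.0)

    def test_rendered_bundle_doubles_q(self):
        field = FieldSpec(50, 50, seed=9)
        s = syn.gen_wlc_snake(50.0, 0.625, 30, FieldSpec(50, 50, seed=8))
        s.points[:, :2] = np.clip(s.points[:, :2], 2, 48)  # keep in field
        img1 = syn.render_network_image([s], field, multiplicity=[1], noise=False,
                                        background=0.0)
        img2 = syn.render_network_image([s], field, multiplicity=[2], noise=False,
                                        background=0.0)
        net = NetworkModel(snakes=[s], junctions=[], field=field, c=0.625)
        _, q1 = cable_intensity(net, image=img1)
        _, q2 = cable_intensity(net, image=img2)
        assert q2 == pytest.approx(2 * q1, rel=1e-9)

    def test_snake_outside_image_errors_with_id(self):
        field = FieldSpec(5, 5)
        net = self.make_net([10.0], field=field)
        img = np.zeros((4, 4))
        with pytest.raises(ValueError, match="s0"):
            cable_intensity(net, image=img)


class TestSkewness:
    def test_symmetric_sample_zero(self):
        assert intensity_skewness([1, 2, 3, 4, 5, 6, 7]) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_sample_near_two(self):
        x = np.random.default_rng(3).exponential(1.0, 200_000)
        assert intensity_skewness(x) == pytest.approx(2.0, abs=0.1)

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            intensity_skewness([5.0, 5.0, 5.0, 5.0])

    def test_adjusted_fisher_pearson_small_sample(self):
        # spreadsheet SKEW of [1, 2, 4] = 0.9352195...
        assert intensity_skewness([1.0, 2.0, 4.0]) == pytest.approx(0.93521953, abs=1e-6)


class TestCurvature:
    def test_straight_snake_zero(self):
        s = Snake("s", np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)]))
        k, dT = snake_curvature(s, 0.5)
        assert k == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("radius", [2.0, 5.0])
    def test_circle_curvature_is_inverse_radius(self, radius):
        th = np.linspace(0, 1.9 * np.pi, 400)
        xy = np.column_stack([radius * np.cos(th), radius * np.sin(th)])
        s = Snake("c", np.column_stack([xy, np.zeros(len(xy))]))
        k, _ = snake_curvature(s, delta_s=radius / 20.0)
        assert k == pytest.approx(1.0 / radius, rel=0.01)

    def test_too_short_snake_raises(self):
        s = Snake("s", np.array([[0, 0, 0], [0.1, 0, 0]], float))
        with pytest.raises(ValueError, match="shorter"):
            snake_curvature(s, 0.5)

    def test_wlc_tangent_variance_matches_model(self):
        """<dT^2> = delta_s / l_p within 3 SE when resampling at the
        generation step."""
        s = syn.gen_wlc_snake(10.0, 0.625, 10_000, FieldSpec(50, 50, seed=5))
        _, dT = snake_curvature(s, 0.625)
        expected = 0.625 / 10.0
        msq = np.mean(dT**2)
        se = expected * np.sqrt(2.0 / len(dT))
        assert abs(msq - expected) < 3 * se


class TestPersistenceLength:
    def test_density_normalizes(self):
        from scipy.integrate import quad

        val, _ = quad(lambda k: wlc_curvature_pdf(k, 6.0, 0.625), 0, np.inf)
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_mle_recovers_halfnormal_samples(self):
        """K drawn from the model density with l_p c = 6.25 is recovered
        within 10% at n = 10^4."""
        rng = np.random.default_rng(12)
        l_p, c = 10.0, 0.625
        k = np.abs(rng.normal(0.0, 1.0 / np.sqrt(l_p * c), size=10_000))
        est, info = fit_persistence_length(k, c)
        assert abs(est - l_p) / l_p < 0.10
        assert info["ks_pvalue"] > 0.01

    def test_all_zero_curvatures_error(self):
        with pytest.raises(ValueError, match="infinite"):
            fit_persistence_length(np.zeros(100), 0.625)

    def test_end_to_end_wlc_recovery(self):
        """Generator + curvature + MLE round trip: l_p = 10 um at
        c = 0.625 um recovered in [9, 11] um."""
        s = syn.gen_wlc_snake(10.0, 0.625, 10_000, FieldSpec(50, 50, seed=5))
        _, dT = snake_curvature(s, 0.625)
        est, _ = fit_persistence_length(dT / 0.625, 0.625)
        assert 9.0 <= est <= 11.0

    def test_resampling_chord_smoothing_bias(self):
        """Resampling at delta_s equal to the chain step is unbiased;
        chords spanning m = 2 steps average the tangent noise, shrinking
        the angle variance by (2m^2+1)/(3m^2) = 3/4 and inflating the
        estimate by 4/3.  delta_s should therefore match the snake
        sampling distance (the default c)."""
        s = syn.gen_wlc_snake(10.0, 0.3125, 20_000, FieldSpec(50, 50, seed=6))
        ests = []
        for ds in (0.3125, 0.625):
            _, dT = snake_curvature(s, ds)
            est, _ = fit_persistence_length(dT / ds, ds)
            ests.append(est)
        assert ests[0] == pytest.approx(10.0, rel=0.10)
        assert ests[1] / ests[0] == pytest.approx(4.0 / 3.0, rel=0.08)


class TestSummarizeNetwork:
    def test_full_summary_fields(self):
        field = FieldSpec(50, 50, seed=31)
        rng = np.random.default_rng(31)
        snakes = []
        for i in range(8):
            s = syn.gen_wlc_snake(10.0, 0.625, 60, FieldSpec(50, 50, seed=100 + i),
                                  snake_id=f"s{i}")
            s.points[:, 2] = rng.normal(500, 50, size=len(s.points)).clip(0)
            snakes.append(s)
        juncs = [Junction(f"j{i}", tuple(xy))
                 for i, xy in enumerate(rng.uniform(0, 50, size=(40, 2)))]
        net = NetworkModel(snakes=snakes, junctions=juncs, field=field, c=0.625)
        summ = summarize_network(net)
        assert summ.n_points == 40
        assert summ.r_rand == pytest.approx(1.0 / (2 * np.sqrt(summ.sigma)))
        assert summ.Q is not None and summ.Q > 0
        assert summ.l_p is not None and summ.l_p > 0
        d = summ.to_dict()
        assert {"sigma", "R_NN", "r_rand", "R", "Q", "S", "K_mean", "l_p"} <= set(d)
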