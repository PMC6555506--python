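import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy import stats

from snakuscules import model, sampling
from snakuscules.model import Snake
from snakuscules.sampling import SamplingConfig, sample_ball_uniform


class TestSampleBallUniform:
    def test_all_points_inside(self):
        pts = sample_ball_uniform(5000, 3.7, 3, seed=0)
        assert pts.shape == (5000, 3)
        assert np.all(np.linalg.norm(pts, axis=1) <= 3.7)

    def test_mean_radius_3d(self):
        # E[r] = 3/4 for the uniform unit ball
        n = 400_000
        pts = sample_ball_uniform(n, 1.0, 3, seed=1)
        r = np.linalg.norm(pts, axis=1)
        se = r.std() / np.sqrt(n)
        assert abs(r.mean() - 0.75) < 3 * se

    def test_mean_radius_2d(self):
        # E[r] = 2/3 for the uniform unit disk
        n = 400_000
        pts = sample_ball_uniform(n, 1.0, 2, seed=2)
        r = np.linalg.norm(pts, axis=1)
        se = r.std() / np.sqrt(n)
        assert abs(r.mean() - 2.0 / 3.0) < 3 * se

    def test_shell_counts_proportional_to_measure(self):
        n = 400_000
        pts = sample_ball_uniform(n, 1.0, 3, seed=3)
        r = np.linalg.norm(pts, axis=1)
        edges = np.linspace(0, 1, 11)
        counts, _ = np.histogram(r, bins=edges)
        expected = n * np.diff(edges**3)
        assert stats.chisquare(counts, expected).pvalue > 0.001

    def test_biased_transform_concentrates_centrally(self):
        # legacy transform r = radius * u has E[r] = 1/2
        n = 200_000
        pts = sample_ball_uniform(n, 1.0, 3, seed=4, radial_bias=True)
        r = np.linalg.norm(pts, axis=1)
        assert abs(r.mean() - 0.5) < 3 * r.std() / np.sqrt(n)

    def test_reproducible(self):
        a = sample_ball_uniform(100, 2.0, 3, seed=9)
        b = sample_ball_uniform(100, 2.0, 3, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sample_ball_uniform(0, 1.0, 3)
        with pytest.raises(ValueError):
            sample_ball_uniform(10, -1.0, 3)


@pytest.fixture(scope="module")
def smooth_blob():
    """Heavily smoothed blob: the MC integrand smoothness assumption holds."""
    grids = np.ogrid[0:64, 0:64, 0:64]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, (31.2, 31.6, 31.9))))
    return ndi.gaussian_filter((r < 10.0).astype(float), 4.0)


@pytest.fixture(scope="module")
def optimal_snake():
    return Snake.from_center_radius((31.2, 31.6, 31.9), 2 ** (1 / 3) * 10.0)


class TestMCEnergy:
    def test_constant_image_within_3se(self, profile3d):
        img = np.full((64, 64, 64), 0.6)
        s = Snake.from_center_radius((31.4, 31.8, 32.1), 12.0)
        cfg = SamplingConfig(n_samples=20_000, seed=0)
        vals = [
            sampling.mc_energy(img, s, profile3d, cfg, rng=np.random.default_rng(k))
            for k in range(30)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_deterministic_for_fixed_seed(self, smooth_blob, optimal_snake, profile3d):
        cfg = SamplingConfig(n_samples=5000, seed=77)
        e1 = sampling.mc_energy(smooth_blob, optimal_snake, profile3d, cfg)
        e2 = sampling.mc_energy(smooth_blob, optimal_snake, profile3d, cfg)
        assert e1 == e2

    def test_rmse_scales_inverse_sqrt_n(self, smooth_blob, optimal_snake, profile3d):
        # quick version of the 1/sqrt(N) law; the acceptance suite runs the
        # full 50-seed, three-decade variant
        e_grid = model.discrete_energy(smooth_blob, optimal_snake, profile3d)
        rmses = []
        for ns in (1000, 10_000):
            vals = [
                sampling.mc_energy(
                    smooth_blob,
                    optimal_snake,
                    profile3d,
                    SamplingConfig(n_samples=ns, seed=k),
                )
                for k in range(30)
            ]
            rmses.append(np.sqrt(np.mean((np.array(vals) - e_grid) ** 2)))
        slope = (np.log(rmses[1]) - np.log(rmses[0])) / np.log(10.0)
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_unbiased_against_grid(self, smooth_blob, optimal_snake, profile3d):
        e_grid = model.discrete_energy(smooth_blob, optimal_snake, profile3d)
        vals = np.array(
            [
                sampling.mc_energy(
                    smooth_blob,
                    optimal_snake,
                    profile3d,
                    SamplingConfig(n_samples=2000, seed=k),
                )
                for k in range(200)
            ]
        )
        se_mean = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - e_grid) < 2 * se_mean

    def test_presmoothing_does_not_increase_variance(self, profile3d):
        # raw binary blob (worst case for MC smoothness)
        grids = np.ogrid[0:64, 0:64, 0:64]
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, (31.2, 31.6, 31.9))))
        img = (r < 10.0).astype(float)
        s = Snake.from_center_radius((31.2, 31.6, 31.9), 12.6)

        def variance(sigma):
            cfg = SamplingConfig(n_samples=2000, seed=0, presmooth_sigma=sigma)
            arr = sampling.prepare_image(img, cfg)
            vals = [
                sampling.mc_energy(
                    arr,
                    s,
                    profile3d,
                    SamplingConfig(n_samples=2000, seed=k),
                )
                for k in range(60)
            ]
            return np.var(vals)

        assert variance(2.0) <= variance(0.0)


class TestMCGradient:
    def test_constant_image_within_3se(self, profile3d):
        img = np.full((64, 64, 64), 0.6)
        s = Snake.from_center_radius((31.4, 31.8, 32.1), 12.0)
        grads = np.array(
            [
                sampling.mc_gradient(
                    img, s, profile3d, SamplingConfig(n_samples=10_000, seed=k)
                )
                for k in range(30)
            ]
        )
        se = grads.std(axis=0) / np.sqrt(len(grads))
        assert np.all(np.abs(grads.mean(axis=0)) < 3 * se + 1e-12)

    def test_converges_to_grid_gradient(self, smooth_blob, profile3d):
        s = Snake.from_center_radius((33.0, 30.5, 31.0), 13.0)
        g_grid = model.energy_gradient(smooth_blob, s, profile3d)
        g_mc = sampling.mc_gradient(
            smooth_blob, s, profile3d, SamplingConfig(n_samples=100_000, seed=5)
        )
        scale = np.max(np.abs(g_grid))
        assert np.max(np.abs(g_mc - g_grid)) < 0.05 * scale

    def test_same_seed_same_gradient(self, smooth_blob, optimal_snake, profile3d):
        cfg = SamplingConfig(n_samples=3000, seed=11)
        g1 = sampling.mc_gradient(smooth_blob, optimal_snake, profile3d, cfg)
        g2 = sampling.mc_gradient(smooth_blob, optimal_snake, profile3d, cfg)
        np.testing.assert_array_equal(g1, g2)

    def test_energy_and_gradient_share_samples(
        self, smooth_blob, optimal_snake, profile3d
    ):
        cfg = SamplingConfig(n_samples=3000, seed=12)
        e, g = sampling.mc_energy_and_gradient(smooth_blob, optimal_snake, profile3d, cfg)
        assert e == sampling.mc_energy(smooth_blob, optimal_snake, profile3d, cfg)
        np.testing.assert_array_equal(
            g, sampling.mc_gradient(smooth_blob, optimal_snake, profile3d, cfg)
        )


class TestSamplingConfig:
    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            SamplingConfig(mode="quadrature")

    def test_invalid_n_samples(self):
        with pytest.raises(ValueError):
            SamplingConfig(n_samples=0)
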