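"""Metrics, paired statistics, sliding-window baseline, device visibility."""

import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from radrecon.evaluation import (
    catheter_visibility,
    metrics,
    normality_check,
    paired_wilcoxon,
    sliding_window_lead_in,
    sliding_window_recon,
)
from radrecon.geometry import SequenceParams, make_trajectory
from radrecon.gridding import CineSeries, degrade_series, forward


class TestMetrics:
    def test_identical_series(self, rng):
        x = rng.uniform(0, 1, (30, 16, 16))
        rep = metrics(x, x, frame_range=(5, 25))
        assert rep.mae == 0 and rep.mse == 0
        assert rep.ssim == pytest.approx(1.0)
        assert rep.psnr == np.inf

    def test_constant_offset_closed_form(self, rng):
        g = rng.uniform(0.2, 0.7, (30, 16, 16))
        p = g + 0.1
        rep = metrics(p, g)
        assert rep.mae == pytest.approx(0.1, abs=1e-7)
        assert rep.mse == pytest.approx(0.01, abs=1e-8)
        assert rep.psnr == pytest.approx(20.0, abs=1e-4)

    def test_ssim_matches_independent_implementation(self, rng):
        # hand-rolled Gaussian-window SSIM as the cross-implementation oracle
        a = rng.uniform(0, 1, (64, 64))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)

        def ssim_oracle(x, y, sigma=1.5, K1=0.01, K2=0.03):
            C1, C2 = (K1 * 1.0) ** 2, (K2 * 1.0) ** 2
            f = lambda im: gaussian_filter(im, sigma, truncate=3.5)
            mx, my = f(x), f(y)
            vx = f(x * x) - mx * mx
            vy = f(y * y) - my * my
            cxy = f(x * y) - mx * my
            s = ((2 * mx * my + C1) * (2 * cxy + C2)) / (
                (mx**2 + my**2 + C1) * (vx + vy + C2)
            )
            pad = 5  # skimage crops the filter radius from the borders
            return s[pad:-pad, pad:-pad].mean()

        rep = metrics(a[None].repeat(2, 0), b[None].repeat(2, 0),
                      frame_range=(1, 2))
        assert rep.ssim == pytest.approx(ssim_oracle(a, b), abs=1e-6)

    def test_frame_range_is_one_based_inclusive(self, rng):
        g = rng.uniform(0, 1, (10, 16, 16))
        p = g.copy()
        p[0] += 0.5  # outside range (5, 10)
        rep = metrics(np.clip(p, 0, 1), g, frame_range=(5, 10))
        assert rep.mae == 0

    def test_range_outside_series_rejected(self, rng):
        x = rng.uniform(0, 1, (10, 8, 8))
        for bad in [(0, 5), (5, 11), (7, 6)]:
            with pytest.raises(ValueError):
                metrics(x, x, frame_range=bad)


def wilcoxon_bruteforce_p(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray([x for x in d if x != 0.0])
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    t_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mean_w) >= t_obs - 1e-12:
            count += 1
    return count / 2**n


class TestPairedWilcoxon:
    def test_five_positive_differences_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        _, p = paired_wilcoxon(a, b)
        assert p == pytest.approx(0.0625, abs=1e-12)

    def test_identical_samples_degenerate(self):
        a = np.arange(6, dtype=float)
        with pytest.raises(ValueError):
            paired_wilcoxon(a, a)

    def test_two_sided_symmetry(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        _, p1 = paired_wilcoxon(a, b)
        _, p2 = paired_wilcoxon(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_exact_mode_matches_brute_force(self, n, rng):
        for _ in range(3):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            _, p = paired_wilcoxon(a, b)
            assert p == pytest.approx(
                wilcoxon_bruteforce_p(a - b), abs=1e-10
            )

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [2.0, 1.0])


class TestNormalityCheck:
    def test_gaussian_sample_passes(self, rng):
        w, p = normality_check(rng.normal(size=500))
        assert p > 0.01 and w <= 1.0

    def test_exponential_sample_fails(self, rng):
        _, p = normality_check(rng.exponential(size=500))
        assert p < 0.01

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError):
            normality_check(np.ones(10))


@pytest.fixture(scope="module")
def stream():
    # moving-phantom spoke stream: 6 frames x 17 spokes, continuous angles
    from radrecon.phantom import PhantomConfig, generate_cine

    gt = generate_cine(
        PhantomConfig(view_class="SAX", matrix=48, n_frames=8, seed=4,
                      noise_sd=0.0)
    )
    params = SequenceParams(n_samples=96)
    spokes = []
    for t in range(6):
        traj = make_trajectory(params, 17, start_index=t * 17)
        spokes.append(forward(gt.frames[t], traj).samples)
    return np.concatenate(spokes), params, gt


class TestSlidingWindow:
    def test_lead_in_spokes(self):
        assert sliding_window_lead_in(99, 17) == 41

    def test_width_equals_step_reproduces_gridded(self, stream):
        spokes, params, gt = stream
        sw = sliding_window_recon(spokes, params, 48, width=17, step=17)
        gridded = degrade_series(
            CineSeries(gt.frames[:6]), params, spokes_per_frame=17
        )
        assert sw.n_frames == 6
        np.testing.assert_allclose(sw.frames, gridded.frames, atol=1e-10)

    def test_frames_emitted_only_with_full_trailing_window(self, stream):
        spokes, params, _ = stream
        # 102 spokes, width 99: frame k needs spoke k*17+8+49
        sw = sliding_window_recon(spokes, params, 48, width=99, step=17)
        assert sw.n_frames == 3

    def test_temporal_smoothing_reduces_frame_to_frame_change(self, stream):
        spokes, params, gt = stream
        sw = sliding_window_recon(spokes, params, 48, width=51, step=17)
        gridded = degrade_series(
            CineSeries(gt.frames[:6]), params, spokes_per_frame=17
        )
        d_sw = np.abs(np.diff(sw.frames, axis=0)).mean()
        d_gr = np.abs(np.diff(gridded.frames[: sw.n_frames], axis=0)).mean()
        assert d_sw <= d_gr

    def test_short_stream_rejected(self, seq_params):
        with pytest.raises(ValueError):
            sliding_window_recon(
                np.zeros((10, 128), complex), seq_params, 48, width=99,
                step=17,
            )


class TestCatheterVisibility:
    def make_scene(self):
        from radrecon.phantom import apply_balloon, balloon_path

        base = CineSeries(np.full((8, 48, 48), 0.8))
        path = balloon_path(8, (24, 24), (24, 24), sd_px=3.0, appear=0,
                            disappear=7, ramp=1)
        path.amplitude[:] = 1.0
        return apply_balloon(base, path), base, path

    def test_perfect_reconstruction_has_unit_ratio(self):
        with_dev, _, path = self.make_scene()
        ratios, full = catheter_visibility(with_dev, with_dev, path)
        assert full.all()
        np.testing.assert_allclose(ratios, 1.0, atol=1e-9)

    def test_device_free_prediction_has_zero_ratio(self):
        with_dev, base, path = self.make_scene()
        ratios, _ = catheter_visibility(base, with_dev, path)
        np.testing.assert_allclose(ratios, 0.0, atol=1e-9)

    def test_path_outside_image_rejected(self):
        with_dev, _, path = self.make_scene()
        path.centers[:] = 200.0
        with pytest.raises(ValueError):
            catheter_visibility(with_dev, with_dev, path)
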