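"""Phantom generator, device simulation, and dataset assembly."""

import numpy as np
import pytest

from radrecon.evaluation import ssim_series
from radrecon.geometry import SequenceParams
from radrecon.phantom import (
    VIEW_CLASSES,
    DevicePath,
    PhantomConfig,
    apply_balloon,
    apply_guidewire,
    balloon_path,
    build_dataset,
    generate_cine,
    guidewire_path,
    loo_split,
    make_corpus_configs,
    render_frame,
)
from radrecon.gridding import CineSeries


class TestGenerateCine:
    def test_deterministic_for_config_and_seed(self):
        cfg = PhantomConfig(view_class="4CH", matrix=48, n_frames=8, seed=7)
        a = generate_cine(cfg)
        b = generate_cine(cfg)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_periodic_over_one_cardiac_cycle(self):
        cfg = PhantomConfig(view_class="SAX", matrix=48, n_frames=10, seed=1)
        np.testing.assert_allclose(
            render_frame(cfg, 1.0), render_frame(cfg, 0.0), atol=1e-12
        )

    def test_intensities_in_unit_interval(self):
        for view in VIEW_CLASSES:
            s = generate_cine(
                PhantomConfig(view_class=view, matrix=48, n_frames=8, seed=2)
            )
            assert s.frames.min() >= 0.0 and s.frames.max() <= 1.0

    def test_views_are_geometrically_distinguishable(self):
        series = {
            v: generate_cine(
                PhantomConfig(view_class=v, matrix=64, n_frames=8, seed=5)
            )
            for v in VIEW_CLASSES
        }
        views = list(VIEW_CLASSES)
        for i, v1 in enumerate(views):
            for v2 in views[i + 1 :]:
                assert ssim_series(series[v1], series[v2]) < 0.9

    def test_contraction_moves_the_heart(self):
        cfg = PhantomConfig(view_class="SAX", matrix=48, n_frames=8, seed=0)
        s = generate_cine(cfg)
        assert np.abs(s.frames[4] - s.frames[0]).max() > 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"view_class": "XXX"},
            {"n_frames": 4},
            {"contraction_fraction": 0.7},
            {"matrix": 31},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomConfig(**kwargs)


class TestDevices:
    def flat_series(self, t=8, n=48, value=1.0):
        return CineSeries(np.full((t, n, n), value))

    def test_balloon_attenuates_exactly_80_percent_at_center(self):
        path = balloon_path(
            8, start_xy=(24, 24), end_xy=(24, 24), sd_px=3.0,
            appear=0, disappear=7, ramp=2,
        )
        # force a frame with full visibility
        path.amplitude[:] = 1.0
        out = apply_balloon(self.flat_series(), path)
        assert out.frames[3, 24, 24] == pytest.approx(0.2, abs=1e-12)

    def test_invisible_device_is_identity(self):
        path = balloon_path(8, (20, 20), (30, 30))
        path.amplitude[:] = 0.0
        s = self.flat_series()
        out = apply_balloon(s, path)
        np.testing.assert_array_equal(out.frames, s.frames)

    def test_attenuation_never_increases_intensity(self, rng):
        s = CineSeries(rng.uniform(0, 1, (8, 48, 48)))
        path = balloon_path(8, (10, 40), (40, 10), sd_px=4.0)
        out = apply_balloon(s, path)
        assert np.all(out.frames <= s.frames + 1e-15)
        assert out.frames.min() >= 0.0

    def test_guidewire_makes_five_minima_along_wire(self):
        path = guidewire_path(
            8, start_xy=(8, 24), end_xy=(8, 24), direction=(1.0, 0.0),
            spacing_px=6.0, sd_px=1.5,
        )
        path.amplitude[:] = 1.0
        out = apply_guidewire(self.flat_series(), path)
        profile = out.frames[0, 24, :]
        interior = profile[1:-1]
        minima = np.sum(
            (interior < profile[:-2]) & (interior < profile[2:])
        )
        assert minima == 5

    def test_balloon_and_guidewire_commute_on_disjoint_supports(self):
        s = self.flat_series()
        b = balloon_path(8, (10, 10), (10, 10), sd_px=2.0)
        g = guidewire_path(8, (30, 38), (30, 38), direction=(1, 0), sd_px=1.0,
                           spacing_px=4.0)
        ab = apply_guidewire(apply_balloon(s, b), g)
        ba = apply_balloon(apply_guidewire(s, g), b)
        np.testing.assert_allclose(ab.frames, ba.frames, atol=1e-12)

    def test_path_length_mismatch_rejected(self):
        path = balloon_path(6, (10, 10), (20, 20))
        with pytest.raises(ValueError):
            apply_balloon(self.flat_series(t=8), path)

    def test_wrong_blob_count_rejected(self):
        path = balloon_path(8, (10, 10), (20, 20))
        with pytest.raises(ValueError):
            apply_guidewire(self.flat_series(), path)
        with pytest.raises(ValueError):
            DevicePath(
                centers=np.zeros((8, 3, 2)), amplitude=np.zeros(8),
                sd_px=2.0, n_blobs=3,
            )


@pytest.fixture(scope="module")
def tiny_params():
    return SequenceParams(n_samples=64)


@pytest.fixture(scope="module")
def tiny_configs():
    base = PhantomConfig(matrix=32, n_frames=8)
    return make_corpus_configs(
        views=("SAX", "4CH"), per_view=3, split_counts=(2, 0, 1),
        base=base, seed=0,
    )


class TestDatasetAssembly:
    def test_specific_mode_fixes_the_rate(self, tiny_configs, tiny_params):
        ds = build_dataset(tiny_configs, tiny_params, ("specific", 17), seed=0)
        assert all(
            s.accel.spokes_per_frame == 17
            and s.accel.r_factor == round(np.pi / 2 * 64 / 17, 1)
            for s in ds
        )

    def test_generic_rate_draw_is_balanced(self):
        from radrecon.phantom import draw_generic_rates

        rng = np.random.default_rng(42)
        pool = (13, 17, 21, 25, 29, 33)
        # 600 draws: every rate represented exactly 100 times (well inside
        # the 99% binomial band 100 +/- 30 an i.i.d. draw would allow)
        rates = draw_generic_rates(600, pool, rng)
        vals, counts = np.unique(rates, return_counts=True)
        assert set(vals) == set(pool)
        assert np.all(counts == 100)
        # non-divisible corpus: counts spread by at most one
        small = draw_generic_rates(14, pool, rng)
        _, c = np.unique(small, return_counts=True)
        assert c.sum() == 14 and c.max() - c.min() <= 1

    def test_generic_mode_assignment_deterministic(self, tiny_configs,
                                                   tiny_params):
        kw = dict(spokes_mode=("generic", (13, 17, 21)), seed=9)
        a = build_dataset(tiny_configs, tiny_params, **kw)
        b = build_dataset(tiny_configs, tiny_params, **kw)
        assert [s.accel.spokes_per_frame for s in a] == [
            s.accel.spokes_per_frame for s in b
        ]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.input.frames, y.input.frames)

    def test_pairs_share_shape_and_unit_range(self, tiny_configs, tiny_params):
        ds = build_dataset(
            tiny_configs, tiny_params, ("specific", 9), seed=0, crop=24
        )
        for s in ds:
            assert s.input.shape == s.target.shape == (8, 24, 24)
            for arr in (s.input.frames, s.target.frames):
                assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_empty_config_list_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            build_dataset([], tiny_params, ("specific", 17))


class TestLooSplit:
    def make_dataset(self):
        # lightweight stand-in samples: only view/split labels matter
        from radrecon.geometry import AccelerationSpec
        from radrecon.phantom import PairedSample

        params = SequenceParams(n_samples=64)
        s = CineSeries(np.zeros((2, 8, 8)))
        ds = []
        for v in VIEW_CLASSES:
            for split in ("train", "train", "val", "test"):
                ds.append(
                    PairedSample(
                        input=s, target=s,
                        accel=AccelerationSpec.from_params(17, params),
                        split=split, view=v, subject=f"{v}-{split}",
                    )
                )
        return ds

    def test_left_out_view_is_isolated(self):
        ds = self.make_dataset()
        train, val, test = loo_split(ds, "PA")
        assert {s.view for s in test} == {"PA"}
        assert "PA" not in {s.view for s in train} | {s.view for s in val}
        assert len({s.view for s in train}) == 6

    def test_splits_partition_the_dataset(self):
        ds = self.make_dataset()
        train, val, test = loo_split(ds, "SAX")
        ids = lambda xs: {id(s) for s in xs}
        assert ids(train) | ids(val) | ids(test) == ids(ds)
        assert not (ids(train) & ids(val)) and not (ids(train) & ids(test))

    def test_seven_splits_cover_each_view_once(self):
        ds = self.make_dataset()
        covered = []
        for v in VIEW_CLASSES:
            _, _, test = loo_split(ds, v)
            covered.extend({s.view for s in test})
        assert sorted(covered) == sorted(VIEW_CLASSES)

    def test_unknown_view_rejected(self):
        with pytest.raises(ValueError):
            loo_split(self.make_dataset(), "APEX")
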