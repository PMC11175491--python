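"""Volumetry, concordance and strain analyses on ground-truth inputs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaa_ilt.errors import (
    DegenerateContourError,
    DegenerateError,
    EmptyCavityError,
    LengthMismatchError,
    MissingDensityError,
    UnknownClassError,
)
from aaa_ilt.geometry import SliceGeometry
from aaa_ilt.imaging import (
    CLASS_LUMEN,
    CLASS_THROMBUS,
    BoundaryTrack,
    LabelVolume,
    circumferential_strain,
    class_volume,
    cluster_by_fraction,
    density_stats,
    lumen_position_index,
    spearman_rank,
    thrombus_fraction_volume,
)
from aaa_ilt.synthdata import make_density_field, make_label_volume


def grid_volume(shape=(4, 5, 6), fill=0, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.full(shape, fill, dtype=np.int64), spacing)


class TestClassVolume:
    def test_voxel_counting(self):
        vol = grid_volume((10, 10, 10), CLASS_THROMBUS, (0.5, 0.5, 0.5))
        assert class_volume(vol, CLASS_THROMBUS) == pytest.approx(1000 * 0.125)

    def test_empty_class_zero(self):
        assert class_volume(grid_volume(), CLASS_THROMBUS) == 0.0

    def test_anisotropic_single_voxel(self):
        vol = grid_volume((1, 1, 1), CLASS_LUMEN, (0.7, 0.7, 1.25))
        assert class_volume(vol, CLASS_LUMEN) == pytest.approx(0.6125)

    def test_unknown_class_rejected(self):
        with pytest.raises(UnknownClassError):
            class_volume(grid_volume(), 7)
        with pytest.raises(UnknownClassError):
            LabelVolume(np.full((2, 2, 2), 9), (1, 1, 1))

    def test_additive_over_disjoint_subvolumes(self):
        vox = np.zeros((8, 8, 8), dtype=np.int64)
        vox[:4] = CLASS_THROMBUS
        vox[4:, :2] = CLASS_THROMBUS
        whole = LabelVolume(vox, (1, 1, 1))
        top = LabelVolume(vox[:4], (1, 1, 1))
        bottom = LabelVolume(vox[4:], (1, 1, 1))
        assert class_volume(whole, CLASS_THROMBUS) == pytest.approx(
            class_volume(top, CLASS_THROMBUS) + class_volume(bottom, CLASS_THROMBUS)
        )

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vox = rng.integers(0, 4, size=(3, 4, 5))
        v1 = class_volume(LabelVolume(vox, (0.5, 0.7, 1.1)), CLASS_THROMBUS)
        v2 = class_volume(
            LabelVolume(vox.transpose(2, 0, 1), (1.1, 0.5, 0.7)), CLASS_THROMBUS
        )
        assert v1 == pytest.approx(v2)


class TestThrombusFraction:
    def test_simple_ratio(self):
        vox = np.zeros((10, 10, 1), dtype=np.int64)
        vox[:8] = CLASS_THROMBUS
        vox[8:] = CLASS_LUMEN
        assert thrombus_fraction_volume(LabelVolume(vox, (1, 1, 1))) == pytest.approx(0.8)

    def test_no_thrombus_zero(self):
        assert thrombus_fraction_volume(grid_volume(fill=CLASS_LUMEN)) == 0.0

    def test_empty_cavity_raises(self):
        with pytest.raises(EmptyCavityError):
            thrombus_fraction_volume(grid_volume(fill=0))

    def test_voxelized_slice_recovery(self):
        geo = SliceGeometry(lumen_radius=11.5)  # fraction 0.75
        vol, truth = make_label_volume(geo, n_slices=4, spacing=(0.5, 0.5, 2.0), seed=0)
        assert thrombus_fraction_volume(vol) == pytest.approx(truth["fraction"], abs=0.02)


class TestPositionIndex:
    def test_concentric_is_zero(self):
        vol, _ = make_label_volume(SliceGeometry(lumen_radius=11.5), n_slices=2,
                                   spacing=(0.25, 0.25, 2.0), seed=0)
        assert lumen_position_index(vol) < 0.01

    def test_offset_recovers_formula(self):
        geo = SliceGeometry(lumen_radius=11.5, lumen_offset=(0.0, -2.5))
        vol, _ = make_label_volume(geo, n_slices=2, spacing=(0.25, 0.25, 2.0), seed=0)
        assert lumen_position_index(vol) == pytest.approx(2.5 / 11.5, abs=0.02)

    def test_tangent_lumen_is_one(self):
        # lumen pressed against the cavity boundary: index saturates at 1
        geo = SliceGeometry(lumen_radius=10.0, lumen_offset=(0.0, 12.9))
        vol, _ = make_label_volume(geo, n_slices=1, spacing=(0.25, 0.25, 2.0), seed=0)
        assert lumen_position_index(vol) > 0.97

    def test_scale_invariance(self):
        sl = np.zeros((120, 120), dtype=np.int64)
        yy, xx = np.mgrid[:120, :120]
        cav = (xx - 60) ** 2 + (yy - 60) ** 2 < 50**2
        lum = (xx - 70) ** 2 + (yy - 60) ** 2 < 20**2
        sl[cav] = CLASS_THROMBUS
        sl[lum & cav] = CLASS_LUMEN
        v1 = lumen_position_index(sl, spacing=(1.0, 1.0))
        v2 = lumen_position_index(sl, spacing=(3.0, 3.0))
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_empty_slice_raises(self):
        with pytest.raises(EmptyCavityError):
            lumen_position_index(np.zeros((10, 10), dtype=np.int64))


class TestClustering:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.45, "0.4-0.6"),
            (0.40, "0.4-0.6"),  # left-closed convention
            (0.15, "out-of-range"),
            (0.2, "0.2-0.4"),
            (0.80, "0.8-0.99"),
            (0.99, "0.8-0.99"),  # last bin closed on the right
            (0.995, "out-of-range"),
        ],
    )
    def test_bin_assignment(self, value, label):
        assert cluster_by_fraction([value]) == [label]


class TestSpearman:
    def test_strictly_increasing_is_one(self):
        rho, _ = spearman_rank([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_hand_example(self):
        rho, _ = spearman_rank([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_exact_permutation_p_for_perfect_monotone(self):
        _, p = spearman_rank([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert p == pytest.approx(2 / 120)

    def test_matches_scipy_with_ties_large_n(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        x = rng.integers(0, 10, size=40).astype(float)  # plenty of ties
        y = x + rng.normal(0, 2, size=40)
        rho, p = spearman_rank(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-6)

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=3,
                    max_size=12, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_self_and_anti_correlation(self, xs):
        x = np.asarray(xs)
        assert spearman_rank(x, x)[0] == pytest.approx(1.0)
        assert spearman_rank(x, -x)[0] == pytest.approx(-1.0)

    def test_errors(self):
        with pytest.raises(LengthMismatchError):
            spearman_rank([1, 2, 3], [1, 2])
        with pytest.raises(LengthMismatchError):
            spearman_rank([1, 2], [1, 2])
        with pytest.raises(DegenerateError):
            spearman_rank([1, 1, 1, 1], [1, 2, 3, 4])


class TestDensityStats:
    def test_constant_density(self):
        vol = grid_volume((5, 5, 5), CLASS_THROMBUS)
        make_density_field(vol, (60.0, 0.0), seed=0)
        s = density_stats(vol)
        assert s.median == pytest.approx(60.0)
        assert s.std == pytest.approx(0.0)

    def test_bimodal_mixture_recovers_component_medians(self):
        rng = np.random.default_rng(3)
        vox = np.full((40, 40, 8), CLASS_THROMBUS, dtype=np.int64)
        mu = 60.0
        density = np.where(
            rng.random(vox.shape) < 0.5,
            rng.normal(mu, 0.05 * mu, vox.shape),
            rng.normal(2 * mu, 0.05 * 2 * mu, vox.shape),
        )
        vol = LabelVolume(vox, (1, 1, 1), density)
        s = density_stats(vol, bins=40)
        vals = density.ravel()
        lo_med = np.median(vals[vals < 1.5 * mu])
        hi_med = np.median(vals[vals >= 1.5 * mu])
        assert lo_med == pytest.approx(mu, rel=0.05)
        assert hi_med == pytest.approx(2 * mu, rel=0.05)
        # histogram shows a gap between the two modes
        hist = np.asarray(s.histogram)
        centers = 0.5 * (np.asarray(s.bin_edges)[:-1] + np.asarray(s.bin_edges)[1:])
        mid = hist[(centers > 1.4 * mu) & (centers < 1.6 * mu)]
        assert mid.max(initial=0) < 0.2 * hist.max()

    def test_empty_class_summary(self):
        vol = grid_volume((3, 3, 3), CLASS_LUMEN)
        make_density_field(vol, (60.0, 5.0), seed=0)
        assert density_stats(vol, CLASS_THROMBUS).empty

    def test_missing_density_raises(self):
        with pytest.raises(MissingDensityError):
            density_stats(grid_volume(fill=CLASS_THROMBUS))


def circle_track(radii_outer, radii_inner, n=24):
    theta = 2 * math.pi * np.arange(n) / n
    e = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    outer = np.stack([r * e for r in radii_outer])
    inner = np.stack([r * e for r in radii_inner])
    times = np.linspace(0, 1, len(radii_outer))
    return BoundaryTrack(outer=outer, lining=inner, times=times)


class TestCircumferentialStrain:
    def test_uniform_dilation_gives_constant_strain(self):
        eps = 0.04
        tr = circle_track([25.0, 25.0 * (1 + eps)], [10.0, 10.0 * (1 + eps)])
        out = circumferential_strain(tr)
        assert np.allclose(out["outer_strain"][1], eps, rtol=1e-12)
        assert out["outer_peak"] == pytest.approx(eps)
        assert out["inner_peak"] == pytest.approx(eps)

    def test_static_track_zero_strain(self):
        tr = circle_track([25.0, 25.0, 25.0], [10.0, 10.0, 10.0])
        out = circumferential_strain(tr)
        assert np.allclose(out["outer_strain"], 0.0)
        assert np.allclose(out["inner_strain"], 0.0)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(DegenerateContourError):
            circumferential_strain(circle_track([25.0, 0.0], [10.0, 10.0]))
        with pytest.raises(DegenerateContourError):
            BoundaryTrack(
                outer=np.zeros((2, 10, 2)), lining=np.zeros((2, 12, 2)),
                times=np.array([0.0, 1.0]),
            )
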