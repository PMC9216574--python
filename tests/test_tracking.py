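"""Normalized cross-correlation interrogation and outlier filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cptvr.tracking import (
    DisplacementField,
    ScoreMap,
    TemplateSpec,
    TrackConfig,
    find_local_maxima,
    ncc_score_map,
    significance_test,
    subpixel_refine,
    track_cptv,
    vector_median_filter,
)


def direct_ncc(ref, def_, cx, cy, L, ux, uy):
    """Scalar-loop evaluation of the zero-normalized cross-correlation."""
    num = 0.0
    ss_r = 0.0
    ss_d = 0.0
    tpl = ref[cy - L : cy + L + 1, cx - L : cx + L + 1]
    win = def_[cy + uy - L : cy + uy + L + 1, cx + ux - L : cx + ux + L + 1]
    mr = tpl.mean()
    md = win.mean()
    for i in range(2 * L + 1):
        for j in range(2 * L + 1):
            a = tpl[i, j] - mr
            b = win[i, j] - md
            num += a * b
            ss_r += a * a
            ss_d += b * b
    return num / np.sqrt(ss_r * ss_d)


class TestNccScoreMap:
    def test_matches_direct_double_sum(self):
        """Frequency-domain NCC equals the direct definition to 1e-6 on
        random patches (oracle equivalence)."""
        rng = np.random.default_rng(0)
        n_checked = 0
        for _ in range(6):
            ref = rng.random((40, 40)) * 100
            def_ = rng.random((40, 40)) * 100
            smap = ncc_score_map(ref, def_, TemplateSpec(4, (20.0, 20.0)), 2)
            assert smap is not None
            for uy in range(-2, 3):
                for ux in range(-2, 3):
                    want = direct_ncc(ref, def_, 20, 20, 4, ux, uy)
                    got = smap.scores[2 + uy, 2 + ux]
                    assert got == pytest.approx(want, abs=1e-6)
                    n_checked += 1
        assert n_checked >= 100

    def test_identical_images_peak_at_zero(self, uniform_pair):
        ref, _, _ = uniform_pair
        smap = ncc_score_map(ref, ref, TemplateSpec(8, (64.0, 64.0)), 5)
        assert smap.scores[5, 5] == pytest.approx(1.0, abs=1e-9)
        assert np.nanargmax(smap.scores) == 5 * 11 + 5

    def test_inverted_image_anticorrelates(self, uniform_pair):
        ref, _, _ = uniform_pair
        inv = ref.max() - ref
        smap = ncc_score_map(ref, inv, TemplateSpec(8, (64.0, 64.0)), 3)
        assert smap.scores[3, 3] == pytest.approx(-1.0, abs=1e-9)

    def test_flat_template_reports_failure(self):
        img = np.full((64, 64), 5.0)
        assert ncc_score_map(img, img, TemplateSpec(5, (32.0, 32.0)), 3) is None

    def test_border_shifts_masked_not_fabricated(self, uniform_pair):
        ref, def_, _ = uniform_pair
        smap = ncc_score_map(ref, def_, TemplateSpec(8, (12.0, 64.0)), 6)
        # shifts whose window leaves the image are NaN, not invented
        assert np.isnan(smap.scores).any()
        assert np.isfinite(smap.scores).any()


class TestPeaksAndSignificance:
    def test_single_paraboloid_peak(self):
        y, x = np.mgrid[-3:4, -3:4].astype(float)
        smap = ScoreMap(scores=1 - 0.05 * (x**2 + y**2), u_max=3)
        peaks = find_local_maxima(smap)
        assert len(peaks) == 1
        assert peaks[0][1] == (0, 0)

    def test_bimodal_ordering(self):
        s = np.zeros((7, 7))
        s[1, 1] = 0.6
        s[5, 5] = 0.9
        smap = ScoreMap(scores=s, u_max=3)
        peaks = find_local_maxima(smap)
        assert [p[1] for p in peaks[:2]] == [(2, 2), (-2, -2)]

    def test_constant_map_no_strict_maxima(self):
        smap = ScoreMap(scores=np.full((7, 7), 0.5), u_max=3)
        assert find_local_maxima(smap) == []

    @pytest.mark.parametrize(
        "peaks,thr,expected",
        [
            ([(1.0, (0, 0))], 0.3, True),  # single peak always passes
            ([(1.0, (0, 0)), (0.95, (2, 2))], 0.9, False),  # 0.95 > 0.9
            ([(1.0, (0, 0)), (0.2, (2, 2))], 0.3, True),  # 0.2 <= 0.3
        ],
    )
    def test_significance_examples(self, peaks, thr, expected):
        assert significance_test(peaks, thr) is expected

    def test_significance_monotone_in_threshold(self):
        peaks = [(1.0, (0, 0)), (0.5, (3, 1))]
        passed = [significance_test(peaks, t) for t in (0.3, 0.5, 0.7, 0.9)]
        assert passed == sorted(passed)  # higher threshold is more generous

    def test_empty_fails(self):
        assert significance_test([], 0.9) is False


class TestSubpixel:
    def test_symmetric_neighborhood_zero_offset(self):
        s = np.zeros((7, 7))
        s[2:5, 2:5] = [[0.5, 0.7, 0.5], [0.7, 1.0, 0.7], [0.5, 0.7, 0.5]]
        smap = ScoreMap(scores=s, u_max=3)
        u, v, ok = subpixel_refine(smap, (0, 0))
        assert u == pytest.approx(0.0, abs=1e-12)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert ok

    @settings(deadline=None, max_examples=25)
    @given(
        vx=st.floats(-0.45, 0.45),
        vy=st.floats(-0.45, 0.45),
    )
    def test_recovers_paraboloid_vertex(self, vx, vy):
        y, x = np.mgrid[-3:4, -3:4].astype(float)
        scores = 1.0 - 0.1 * ((x - vx) ** 2 + (y - vy) ** 2)
        smap = ScoreMap(scores=scores, u_max=3)
        u, v, ok = subpixel_refine(smap, (0, 0))
        assert ok
        assert u == pytest.approx(vx, abs=1e-6)
        assert v == pytest.approx(vy, abs=1e-6)

    def test_border_peak_unrefined(self):
        y, x = np.mgrid[-3:4, -3:4].astype(float)
        smap = ScoreMap(scores=-(x**2 + y**2) * 0.01 + x * 0.2, u_max=3)
        u, v, ok = subpixel_refine(smap, (3, 0))
        assert (u, v) == (3.0, 0.0)
        assert not ok

    def test_offpeak_vertex_clamped(self):
        # strongly skewed neighborhood pushes the vertex beyond +-0.5
        s = np.zeros((7, 7))
        s[3, 2:5] = [0.2, 1.0, 0.99]
        s[2, 2:5] = [0.1, 0.5, 0.5]
        s[4, 2:5] = [0.1, 0.5, 0.5]
        smap = ScoreMap(scores=s, u_max=3)
        u, v, ok = subpixel_refine(smap, (0, 0))
        assert abs(u) <= 0.5 and abs(v) <= 0.5


class TestTrackCptv:
    def test_identity_pair_all_zero(self, uniform_pair):
        ref, _, beads = uniform_pair
        interior = np.all((beads.positions > 20) & (beads.positions < 108), axis=1)
        pts = beads.positions[interior][:60]
        field = track_cptv(ref, ref, pts, TrackConfig(u_max=6))
        tracked = field.status == "tracked"
        assert tracked.mean() > 0.9
        # parabolic sub-pixel fits carry ~0.1 px bias on overlapping-bead
        # texture; zero-shift recovery must be within that
        np.testing.assert_allclose(field.u[tracked], 0.0, atol=0.15)
        np.testing.assert_allclose(field.v[tracked], 0.0, atol=0.15)

    def test_translation_equivariance(self, uniform_pair):
        """Integer-shifted copy yields vectors (3, 2) for interior beads."""
        ref, def_, beads = uniform_pair
        interior = np.all((beads.positions > 25) & (beads.positions < 100), axis=1)
        pts = beads.positions[interior][:60]
        field = track_cptv(ref, def_, pts, TrackConfig(u_max=8))
        tracked = field.status == "tracked"
        assert tracked.mean() > 0.9
        np.testing.assert_allclose(field.u[tracked], 3.0, atol=0.15)
        np.testing.assert_allclose(field.v[tracked], 2.0, atol=0.15)

    def test_accepted_scores_in_unit_interval(self, uniform_pair):
        ref, def_, beads = uniform_pair
        field = track_cptv(ref, def_, beads.positions[:80], TrackConfig(u_max=8))
        ok = field.status == "tracked"
        assert np.all(field.score[ok] > 0) and np.all(field.score[ok] <= 1)
        assert np.all(np.abs(field.u[ok]) <= 8.5)

    def test_empty_detections_rejected(self, uniform_pair):
        ref, def_, _ = uniform_pair
        with pytest.raises(ValueError):
            track_cptv(ref, def_, np.empty((0, 2)))


def make_field(pos, vecs, status=None):
    n = len(pos)
    status = np.array(["tracked"] * n if status is None else status, dtype=object)
    return DisplacementField(
        x=pos[:, 0].astype(float),
        y=pos[:, 1].astype(float),
        u=vecs[:, 0].astype(float),
        v=vecs[:, 1].astype(float),
        score=np.ones(n),
        status=status,
    )


class TestVectorMedianFilter:
    def test_uniform_field_untouched(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 100, (60, 2))
        field = make_field(pos, np.tile([4.0, -1.0], (60, 1)))
        out = vector_median_filter(field, radius=20.0)
        assert (out.status == "tracked").all()

    def test_single_reversed_vector_flagged(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 100, (60, 2))
        vecs = np.tile([4.0, -1.0], (60, 1))
        vecs[17] = [-4.0, 1.0]
        out = vector_median_filter(make_field(pos, vecs), radius=20.0)
        assert out.status[17] == "filtered"
        assert (out.status == "filtered").sum() == 1

    def test_all_failed_unchanged(self):
        pos = np.random.default_rng(3).uniform(0, 50, (10, 2))
        field = make_field(pos, np.full((10, 2), np.nan), status=["failed"] * 10)
        out = vector_median_filter(field, radius=20.0)
        assert (out.status == "failed").all()

    def test_bad_radius(self):
        field = make_field(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            vector_median_filter(field, radius=0.0)
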