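"""Areal texture engine: height, Abbott, functional, volume, feature and
pattern parameter families."""

import math

import numpy as np
import pytest

from hemodrop import synthetic
from hemodrop.topography import (
    HeightMap,
    abbott_curve,
    feature_params,
    full_report,
    functional_params,
    height_params,
    level_surface,
    pattern_params,
    segment_patterns,
    smc,
    volume_params,
)


def hm(z, pitch=1.0):
    return HeightMap(z=np.asarray(z, dtype=float), lateral_pitch=pitch)


@pytest.fixture(scope="module")
def gaussian_map():
    rng = np.random.default_rng(42)
    return hm(rng.normal(0, 1.5, (96, 96)))


@pytest.fixture(scope="module")
def sinusoid_map():
    # whole periods, >= 64 samples/period
    n, periods, A = 256, 4, 2.0
    x = np.arange(n) * 2 * np.pi * periods / n
    return hm(A * np.sin(x)[None, :].repeat(64, axis=0))


class TestLevelSurface:
    def test_tilted_plane_to_zero(self):
        cols, rows = np.meshgrid(np.arange(32), np.arange(32))
        out = level_surface(hm(0.3 * cols - 0.7 * rows + 5.0))
        np.testing.assert_allclose(out.z, 0.0, atol=1e-9)

    def test_plane_plus_sinusoid(self):
        # cosine centered on the grid: even about the midpoint, so the
        # least-squares ramp removes only the added plane
        n = 128
        cols, rows = np.meshgrid(np.arange(n), np.arange(n))
        wave = np.cos(2 * np.pi * (cols - (n - 1) / 2) / 16)
        out = level_surface(hm(wave + 0.05 * cols + 2.0))
        np.testing.assert_allclose(out.z, wave - wave.mean(), atol=1e-9)

    def test_idempotent(self, gaussian_map):
        once = level_surface(gaussian_map)
        twice = level_surface(once)
        np.testing.assert_allclose(twice.z, once.z, atol=1e-10)

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            level_surface(HeightMap(z=np.zeros((4, 4)),
                                    mask=np.zeros((4, 4), dtype=bool)))


class TestHeightParams:
    def test_flat_surface_all_zero(self):
        p = height_params(hm(np.zeros((16, 16))))
        assert all(v == 0.0 for v in p.values())

    def test_sinusoid_closed_forms(self, sinusoid_map):
        # whole periods: already zero-mean, no leveling needed
        p = height_params(sinusoid_map)
        A = 2.0
        assert p["Sq"] == pytest.approx(A / math.sqrt(2), rel=0.01)
        assert p["Sa"] == pytest.approx(2 * A / math.pi, rel=0.01)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, (12, 9))
        z -= z.mean()
        p = height_params(hm(z))
        sq = math.sqrt(sum(v * v for v in z.ravel()) / z.size)
        sa = sum(abs(v) for v in z.ravel()) / z.size
        assert p["Sq"] == pytest.approx(sq, rel=1e-12)
        assert p["Sa"] == pytest.approx(sa, rel=1e-12)
        assert p["Sp"] == pytest.approx(max(z.ravel()))
        assert p["Sv"] == pytest.approx(-min(z.ravel()))

    def test_sz_identity(self, gaussian_map):
        p = height_params(level_surface(gaussian_map))
        assert p["Sz"] == p["Sp"] + p["Sv"]
        assert p["Sq"] >= p["Sa"] >= 0.0


class TestAbbottCurve:
    def test_two_level_step(self):
        z = np.concatenate([np.full(500, 1.0), np.full(500, -1.0)])
        curve = abbott_curve(hm(z.reshape(20, 50)))
        for c in (-0.9, -0.5, 0.0, 0.5, 0.9):
            assert curve.ratio_at_height(c) == pytest.approx(50.0)

    def test_endpoint_ratios(self, gaussian_map):
        curve = abbott_curve(gaussian_map)
        z = gaussian_map.valid_values()
        assert curve.ratio_at_height(z.min()) == pytest.approx(100.0)
        assert curve.ratio_at_height(z.max()) == pytest.approx(100.0 / z.size)

    def test_matches_sorted_heights_oracle(self, gaussian_map):
        curve = abbott_curve(gaussian_map)
        z = gaussian_map.valid_values()
        for c in (-2.0, -0.3, 0.0, 1.1):
            assert curve.ratio_at_height(c) == pytest.approx(
                100.0 * np.sum(z >= c) / z.size)

    def test_height_at_ratio_monotone(self, gaussian_map):
        curve = abbott_curve(gaussian_map)
        p = np.linspace(1, 99, 50)
        c = np.asarray(curve.height_at_ratio(p))
        assert np.all(np.diff(c) <= 1e-12)


class TestSmc:
    def test_symmetric_step_midpoint(self):
        z = np.concatenate([np.full(512, 1.0), np.full(512, -1.0)])
        assert smc(hm(z.reshape(32, 32)), p=50.0) == pytest.approx(0.0, abs=0.01)

    def test_gaussian_median_near_zero(self, gaussian_map):
        assert smc(level_surface(gaussian_map), p=50.0) == pytest.approx(0.0, abs=0.05)

    def test_monotone_in_p(self, gaussian_map):
        assert smc(gaussian_map, 10.0) >= smc(gaussian_map, 60.0)

    def test_p_out_of_range(self, gaussian_map):
        with pytest.raises(ValueError):
            smc(gaussian_map, 0.0)


def _functional_oracle(z, width=40.0, n_grid=1001):
    """Independent step-by-step equivalent-line construction."""
    desc = np.sort(z.ravel())[::-1]
    pos = 100.0 * (np.arange(1, desc.size + 1) - 0.5) / desc.size
    p = np.linspace(0, 100, n_grid)
    c = np.interp(p, pos, desc)
    k = int(round(width / (p[1] - p[0])))
    i = int(np.argmin(c[:-k] - c[k:]))
    slope = (c[i + k] - c[i]) / (p[i + k] - p[i])
    c0 = c[i] - slope * p[i]
    c100 = c0 + slope * 100.0
    sk = c0 - c100
    smr2 = float(np.interp(c100, c[::-1], p[::-1]))
    a2 = float(np.trapezoid(np.clip(c100 - c, 0, None), p))
    svk = 2 * a2 / (100 - smr2) if smr2 < 100 else 0.0
    return sk, svk


class TestFunctionalParams:
    def test_flat_surface(self):
        p = functional_params(hm(np.zeros((16, 16))))
        assert p["Sk"] == 0.0 and p["Svk"] == 0.0

    def test_gaussian_matches_independent_construction(self, gaussian_map):
        lm = level_surface(gaussian_map)
        p = functional_params(lm)
        sk, svk = _functional_oracle(lm.z)
        assert p["Sk"] == pytest.approx(sk, rel=0.02)
        assert p["Svk"] == pytest.approx(svk, rel=0.02)
        # documented band for a Gaussian height distribution
        sq = height_params(lm)["Sq"]
        assert 1.5 * sq < p["Sk"] < 4.0 * sq

    def test_sparse_pits_raise_svk_not_sk(self, gaussian_map):
        lm = level_surface(gaussian_map)
        p0 = functional_params(lm)
        z = lm.z.copy()
        rng = np.random.default_rng(8)
        idx = rng.choice(z.size, size=z.size // 100, replace=False)
        z.ravel()[idx] -= 12.0  # deep sparse pits
        p1 = functional_params(hm(z))
        assert p1["Svk"] > 2.0 * p0["Svk"]
        assert p1["Sk"] == pytest.approx(p0["Sk"], rel=0.10)


class TestVolumeParams:
    def test_flat_surface(self):
        p = volume_params(hm(np.zeros((16, 16))))
        assert p["Vv"] == p["Vmc"] == p["Vvc"] == 0.0

    def test_two_level_step_closed_form(self):
        h = 1.0
        z = np.concatenate([np.full(2048, h), np.full(2048, -h)])
        p = volume_params(hm(z.reshape(64, 64)), p=10.0, q=80.0)
        # rectangular Abbott curve: Vv(10) = h, Vv(80) = 0, Vm(80) = h, Vm(10) = 0
        assert p["Vv"] == pytest.approx(h, rel=0.02)
        assert p["Vmc"] == pytest.approx(h, rel=0.02)
        assert p["Vvc"] == pytest.approx(h, rel=0.02)

    def test_vvc_identity_and_positivity(self, gaussian_map):
        curve = abbott_curve(level_surface(gaussian_map))
        p = volume_params(curve, p=10.0, q=80.0)
        vv80 = volume_params(curve, p=80.0, q=99.0)["Vv"]
        assert p["Vvc"] == pytest.approx(p["Vv"] - vv80, rel=1e-9)
        assert p["Vvc"] >= 0.0

    def test_invalid_ratios(self, gaussian_map):
        with pytest.raises(ValueError):
            volume_params(gaussian_map, p=80.0, q=10.0)


def bump_map(centers, h=5.0, n=128, sigma=3.0, sign=1.0):
    yy, xx = np.mgrid[:n, :n]
    z = np.zeros((n, n))
    for (r, c) in centers:
        z += sign * h * np.exp(-(((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2)))
    return z


class TestFeatureParams:
    CENTERS = [(20, 20), (20, 100), (64, 64), (100, 20), (100, 100)]

    def test_five_identical_bumps(self):
        z = bump_map(self.CENTERS)
        p = feature_params(hm(z))
        # leveling is not applied here; the plane offset is negligible
        assert p["S5p"] == pytest.approx(5.0, rel=0.05)
        assert p["S5v"] < 0.5
        assert p["S10z"] == p["S5p"] + p["S5v"]

    def test_inversion_swaps_peaks_and_pits(self):
        z = bump_map(self.CENTERS)
        p = feature_params(hm(z))
        q = feature_params(hm(-z))
        assert q["S5v"] == pytest.approx(p["S5p"], rel=1e-9)
        assert q["S5p"] == pytest.approx(p["S5v"], rel=1e-9)

    def test_s10z_bounded_by_sz(self, gaussian_map):
        lm = level_surface(gaussian_map)
        p = feature_params(lm)
        assert p["S10z"] <= height_params(lm)["Sz"] + 1e-9

    def test_fewer_than_five_features_flagged(self):
        z = bump_map([(64, 64)])
        p = feature_params(hm(z))
        assert any("significant-peaks" in f for f in p["flags"])


class TestSegmentPatterns:
    def test_two_discs(self):
        yy, xx = np.mgrid[:128, :128]
        z = np.where(np.hypot(yy - 40, xx - 40) <= 12, 3.0, 0.0)
        z += np.where(np.hypot(yy - 90, xx - 90) <= 8, 3.0, 0.0)
        ps = segment_patterns(hm(z), threshold=1.5)
        assert len(ps) == 2
        areas = sorted(ps.table["area_um2"])
        assert areas[0] == pytest.approx(math.pi * 8**2, rel=0.08)
        assert areas[1] == pytest.approx(math.pi * 12**2, rel=0.08)

    def test_disc_diameters(self):
        yy, xx = np.mgrid[:96, :96]
        r = 15
        z = np.where(np.hypot(yy - 48, xx - 48) <= r, 2.0, 0.0)
        ps = segment_patterns(hm(z), threshold=1.0)
        row = ps.table.iloc[0]
        assert row["equiv_diameter_um"] == pytest.approx(2 * r, rel=0.05)
        assert row["max_diameter_um"] == pytest.approx(2 * r, rel=0.05)

    def test_min_area_filter(self):
        z = np.zeros((64, 64))
        z[10:12, 10:12] = 5.0  # 4 px, below the 20 px floor
        with pytest.raises(ValueError):
            segment_patterns(hm(z), threshold=1.0)

    def test_connected_component_oracle(self):
        rng = np.random.default_rng(12)
        from scipy import ndimage

        z = (rng.random((96, 96)) < 0.4).astype(float)
        z = ndimage.binary_closing(z).astype(float) * 2.0
        try:
            ps = segment_patterns(hm(z), threshold=1.0)
        except ValueError:
            pytest.skip("random field produced no large component")
        lbl, _ = ndimage.label(z >= 1.0, structure=np.ones((3, 3)))
        sizes = np.bincount(lbl.ravel())[1:]
        expected = sorted(s for s in sizes if s >= 20)
        got = sorted(int(round(a)) for a in ps.table["area_um2"])
        assert got == expected


class TestPatternParams:
    def test_perfect_disc(self):
        yy, xx = np.mgrid[:128, :128]
        z = np.where(np.hypot(yy - 64, xx - 64) <= 30, 2.0, 0.0)
        pp = pattern_params(segment_patterns(hm(z), threshold=1.0))
        # the Feret diameter of a rasterized disc overshoots 2r by ~1 px
        assert pp["circularity"] == pytest.approx(1.0, abs=0.05)
        assert pp["compactness"] == pytest.approx(1.0, abs=0.05)

    def test_two_to_one_ellipse_compactness(self):
        yy, xx = np.mgrid[:160, :160]
        a, b = 40.0, 20.0
        z = np.where(((xx - 80) / a) ** 2 + ((yy - 80) / b) ** 2 <= 1, 2.0, 0.0)
        pp = pattern_params(segment_patterns(hm(z), threshold=1.0))
        assert pp["compactness"] == pytest.approx(1 / math.sqrt(2), abs=0.03)

    def test_equal_peaks_zero_coplanarity(self):
        yy, xx = np.mgrid[:128, :128]
        z = np.where(np.hypot(yy - 40, xx - 40) <= 10, 3.0, 0.0)
        z += np.where(np.hypot(yy - 90, xx - 90) <= 10, 3.0, 0.0)
        pp = pattern_params(segment_patterns(hm(z), threshold=1.0))
        assert pp["coplanarity"] == pytest.approx(0.0, abs=1e-9)

    def test_peak_difference_sets_coplanarity(self):
        yy, xx = np.mgrid[:128, :128]
        z = np.where(np.hypot(yy - 40, xx - 40) <= 10, 3.0, 0.0)
        z += np.where(np.hypot(yy - 90, xx - 90) <= 10, 5.0, 0.0)
        pp = pattern_params(segment_patterns(hm(z), threshold=1.0))
        assert pp["coplanarity"] == pytest.approx(2.0, abs=0.01)


class TestFullReport:
    def test_flat_map_flagged_zeros(self):
        rep = full_report(hm(np.zeros((32, 32))))
        assert "flat-surface" in rep.flags
        assert rep.Sq == rep.Sz == rep.Vv == rep.circularity == 0.0

    def test_composition_equals_individual_operations(self):
        rec = synthetic.StudyRecord("T23_r00", 23.0, 11.0, 0, 77)
        dep = synthetic.generate_deposit(rec)
        rep = full_report(dep)
        lm = level_surface(dep)
        hp = height_params(lm)
        assert rep.Sq == pytest.approx(hp["Sq"], rel=1e-12)
        assert rep.Sz == pytest.approx(hp["Sz"], rel=1e-12)
        fp = functional_params(abbott_curve(lm))
        assert rep.Sk == pytest.approx(fp["Sk"], rel=1e-12)
        vp = volume_params(abbott_curve(lm))
        assert rep.Vvc == pytest.approx(vp["Vvc"], rel=1e-12)

    def test_report_invariants(self):
        rec = synthetic.StudyRecord("T60_r00", 60.0, 11.0, 0, 78)
        rep = full_report(synthetic.generate_deposit(rec))
        assert rep.Sq >= rep.Sa >= 0
        assert rep.Sz == pytest.approx(rep.Sp + rep.Sv)
        assert rep.S10z <= rep.Sz + 1e-9
        assert 0 < rep.circularity <= 1 and 0 < rep.compactness <= 1

    def test_programmed_temperature_direction(self):
        reps = {}
        for Ts in (23.0, 90.0):
            rec = synthetic.StudyRecord(f"T{Ts:g}", Ts, 11.0, 0, 55)
            reps[Ts] = full_report(synthetic.generate_deposit(rec))
        assert reps[90.0].Sq > reps[23.0].Sq
        assert reps[90.0].Sz > reps[23.0].Sz
        assert reps[90.0].Vv > reps[23.0].Vv

    def test_offset_invariance(self):
        rec = synthetic.StudyRecord("T37_x", 37.0, 11.0, 0, 91)
        dep = synthetic.generate_deposit(rec)
        rep0 = full_report(dep)
        rep1 = full_report(HeightMap(z=dep.z + 17.0,
                                     lateral_pitch=dep.lateral_pitch))
        assert rep1.Sq == pytest.approx(rep0.Sq, rel=1e-9)
        assert rep1.Sa == pytest.approx(rep0.Sa, rel=1e-9)
        assert rep1.Vv == pytest.approx(rep0.Vv, rel=1e-9)
        assert rep1.circularity == pytest.approx(rep0.circularity, rel=1e-9)

    def test_translation_invariance_masked(self):
        # same deposit placed at two positions on a larger canvas, with the
        # mask restricted to the deposit: identical valid pixels, identical
        # reports (mask-aware computation ignores the background entirely)
        rec = synthetic.StudyRecord("T37_x", 37.0, 11.0, 0, 91)
        dep = synthetic.generate_deposit(rec)
        n = dep.z.shape[0]
        reports = []
        for (r0, c0), offset in (((5, 5), 0.0), ((16, 9), 17.0)):
            canvas = np.zeros((n + 32, n + 32)) + offset
            canvas[r0:r0 + n, c0:c0 + n] += dep.z
            mask = np.zeros_like(canvas, dtype=bool)
            mask[r0:r0 + n, c0:c0 + n] = True
            reports.append(full_report(HeightMap(z=canvas, mask=mask,
                                                 lateral_pitch=dep.lateral_pitch)))
        rep0, rep1 = reports
        assert rep1.Sq == pytest.approx(rep0.Sq, rel=1e-9)
        assert rep1.Sa == pytest.approx(rep0.Sa, rel=1e-9)
        assert rep1.Vv == pytest.approx(rep0.Vv, rel=1e-9)
        assert rep1.circularity == pytest.approx(rep0.circularity, rel=1e-9)


class TestAsciiIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        m = hm(rng.normal(0, 1, (20, 30)), pitch=1.76)
        path = tmp_path / "map.txt"
        m.to_ascii(path)
        back = HeightMap.from_ascii(path)
        assert back.z.shape == (20, 30)
        np.testing.assert_allclose(back.z, m.z, atol=1e-4)
        assert back.lateral_pitch == pytest.approx(1.76)
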