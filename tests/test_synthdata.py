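import math

import numpy as np
import pandas as pd
import pytest

from stemvb import geometry
from stemvb.synthdata import (
    Bundle,
    GroundTruth,
    PhenoSimSpec,
    PlacementError,
    SectionSpec,
    bundle_label_raster,
    make_trait_benchmark,
    simulate_bending_curve,
    simulate_cross_section,
    simulate_phenotypes,
    truth_traits,
)
from conftest import small_section_spec


class TestSectionSpec:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SectionSpec(semi_axes=(2000.0, 1000.0), ez_thickness=400.0,
                        pz_thickness=700.0)

    @pytest.mark.parametrize("field,value", [
        ("pixel_size", 0.0),
        ("n_pz_bundles", -1),
        ("intensity_levels", (0, 100, 300, 200)),
    ])
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            small_section_spec(**{field: value})


class TestSimulateCrossSection:
    def test_deterministic_under_seed(self):
        spec = small_section_spec(seed=3)
        img1, truth1 = simulate_cross_section(spec)
        img2, truth2 = simulate_cross_section(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert truth1 == truth2

    def test_different_seeds_differ(self):
        img1, _ = simulate_cross_section(small_section_spec(seed=1))
        img2, _ = simulate_cross_section(small_section_spec(seed=2))
        assert not np.array_equal(img1.pixels, img2.pixels)

    def test_zero_bundles_gives_rings_only(self):
        spec = small_section_spec(n_pz_bundles=0, n_iz_bundles=0)
        img, truth = simulate_cross_section(spec)
        assert len(truth.bundles) == 0
        assert img.pixels.dtype == np.uint8

    def test_bundles_lie_inside_their_zones(self):
        """Independent geometric check: every disk's depth band (distance to
        the outer ellipse, via a brute-force boundary polyline) must sit
        inside its declared zone's thickness band."""
        spec = small_section_spec(n_pz_bundles=40, n_iz_bundles=15, seed=7)
        _, truth = simulate_cross_section(spec)
        assert len(truth.bundles) == 55
        a, b = truth.semi_axes_um
        cx, cy = truth.center_um
        t_ez, t_pz = truth.ez_thickness_um, truth.pz_thickness_um
        for bd in truth.bundles:
            x, y = bd.centroid_um
            assert geometry.point_in_ellipse(x, y, cx, cy, a, b)
            depth = geometry.distance_to_ellipse(x, y, cx, cy, a, b)
            lo, hi = depth - bd.radius_um, depth + bd.radius_um
            if bd.zone == "PZ":
                assert lo > t_ez and hi < t_ez + t_pz
            else:
                assert lo > t_ez + t_pz

    def test_min_separation_honoured(self):
        _, truth = simulate_cross_section(small_section_spec(seed=11))
        pts = np.array([b.centroid_um for b in truth.bundles])
        rad = np.array([b.radius_um for b in truth.bundles])
        d = np.hypot(pts[:, 0:1] - pts[None, :, 0], pts[:, 1:2] - pts[None, :, 1])
        need = rad[:, None] + rad[None, :] + 150.0
        np.fill_diagonal(d, np.inf)
        assert np.all(d >= need - 1e-9)

    def test_unplaceable_raises(self):
        spec = small_section_spec(n_iz_bundles=4000, max_attempts=2000)
        with pytest.raises(PlacementError, match="unplaceable"):
            simulate_cross_section(spec)

    def test_rendered_disk_pixel_areas_match_analytic(self):
        spec = small_section_spec(seed=5)
        _, truth = simulate_cross_section(spec)
        labels = bundle_label_raster(spec, truth)
        px2 = spec.pixel_size**2
        for bd in truth.bundles:
            if bd.radius_um / spec.pixel_size < 5:
                continue
            n_px = int(np.sum(labels == bd.id + 1))
            assert n_px * px2 == pytest.approx(bd.area_um2, rel=0.05)

    def test_contrast_inversion(self):
        plain, _ = simulate_cross_section(small_section_spec(seed=2))
        inv, _ = simulate_cross_section(small_section_spec(seed=2,
                                                           invert_contrast=True))
        assert np.array_equal(inv.pixels, 255 - plain.pixels)


def _truth_with(bundles, a=9000.0, b=8000.0, ez=240.0, pz=2000.0):
    return GroundTruth(center_um=(0.0, 0.0), semi_axes_um=(a, b),
                       ez_thickness_um=ez, pz_thickness_um=pz,
                       bundles=tuple(bundles), seed=0)


class TestTruthTraits:
    def test_single_bundle_moa_arithmetic(self):
        # A = 1 mm² at y = 2 mm from the neutral axis -> MOA = 4 mm⁴
        bd = Bundle(0, (0.0, 2000.0), math.sqrt(1e6 / math.pi), "IZ")
        tv = truth_traits(_truth_with([bd]), SectionSpec())
        assert tv["MOA"] == pytest.approx(4.0, rel=1e-9)

    def test_pmoi_is_moial_plus_moias(self):
        rng = np.random.default_rng(0)
        bundles = [Bundle(i, (rng.uniform(-4000, 4000), rng.uniform(-3000, 3000)),
                          rng.uniform(50, 300), "IZ") for i in range(60)]
        tv = truth_traits(_truth_with(bundles), SectionSpec())
        assert tv["PMOI"] == pytest.approx(tv["MOIAL"] + tv["MOIAS"], rel=1e-9)

    def test_moments_match_explicit_loop(self):
        rng = np.random.default_rng(1)
        bundles = [Bundle(i, (rng.uniform(-4000, 4000), rng.uniform(-3000, 3000)),
                          rng.uniform(50, 300), "PZ" if i % 2 else "IZ")
                   for i in range(100)]
        tv = truth_traits(_truth_with(bundles), SectionSpec())
        moa = sum(b.area_um2 * (b.centroid_um[1]) ** 2 for b in bundles) / 1e12
        pmoi = sum(b.area_um2 * (b.centroid_um[0] ** 2 + b.centroid_um[1] ** 2)
                   for b in bundles) / 1e12
        assert tv["MOA"] == pytest.approx(moa, rel=1e-12)
        assert tv["PMOI"] == pytest.approx(pmoi, rel=1e-12)

    def test_zone_areas_sum_to_section_area(self):
        tv = truth_traits(_truth_with([]), SectionSpec())
        assert tv["EZ_A"] + tv["PZ_A"] + tv["IZ_A"] == pytest.approx(tv["SZ_A"],
                                                                     rel=1e-12)
        assert np.isnan(tv["VB_Aave"])


class TestSimulatePhenotypes:
    def test_all_zero_variances_gives_constant(self):
        spec = PhenoSimSpec(n_lines=4, n_envs=2, n_reps=2, mu=5.0,
                            Vg=0, V_env=0, V_GL=0, V_rep=0, Ve=0)
        tab = simulate_phenotypes(spec)
        assert len(tab) == 16
        assert np.allclose(tab["value"], 5.0)

    def test_genotype_only_variance_structure(self):
        spec = PhenoSimSpec(n_lines=5000, n_envs=2, n_reps=2,
                            Vg=2.0, V_env=0, V_GL=0, V_rep=0, Ve=0, seed=4)
        tab = simulate_phenotypes(spec)
        within = tab.groupby("line")["value"].var(ddof=1)
        assert within.max() < 1e-20
        between = tab.groupby("line")["value"].mean().var(ddof=1)
        se = 2.0 * math.sqrt(2.0 / (5000 - 1))
        assert abs(between - 2.0) < 3 * se

    def test_variance_components_recovered_at_scale(self):
        """Empirical components of a 5,000-line draw match the generating
        variances within 3 standard errors (chi-square SE ~ V*sqrt(2/df))."""
        spec = PhenoSimSpec(n_lines=5000, n_envs=2, n_reps=3,
                            Vg=2.0, V_env=0.5, V_GL=0.8, V_rep=0.2, Ve=1.0,
                            seed=9)
        tab = simulate_phenotypes(spec)
        from stemvb.quantgen import moments_estimates
        est = moments_estimates(tab)
        n = spec.n_lines
        assert abs(est.Vg - 2.0) < 3 * 2.0 * math.sqrt(2 / (n - 1)) + 0.05
        assert abs(est.V_GL - 0.8) < 3 * 0.8 * math.sqrt(2 / (n - 1)) + 0.05
        assert abs(est.Ve - 1.0) < 3 * 1.0 * math.sqrt(2 / (4 * n)) + 0.02

    def test_deterministic(self):
        spec = PhenoSimSpec(seed=3)
        pd.testing.assert_frame_equal(simulate_phenotypes(spec),
                                      simulate_phenotypes(spec))


class TestSimulateBendingCurve:
    def test_peak_is_exact(self):
        curve, info = simulate_bending_curve(120.0, 15.0)
        assert curve["load_N"].max() == 120.0
        peak_d = curve.loc[curve["load_N"].idxmax(), "displacement_mm"]
        assert peak_d == 15.0
        assert info["reaches_10mm"] and not info["post_peak_at_10mm"]

    def test_pre_peak_rise_is_monotone(self):
        curve, _ = simulate_bending_curve(80.0, 12.0)
        rise = curve[curve["displacement_mm"] <= 12.0]["load_N"]
        assert (np.diff(rise) >= 0).all()

    def test_short_peak_flags_post_peak_10mm(self):
        curve, info = simulate_bending_curve(100.0, 8.0)
        assert info["post_peak_at_10mm"]
        assert info["reaches_10mm"]  # decay tail extends past 10 mm
        assert curve["displacement_mm"].max() >= 10.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_bending_curve(-1.0, 10.0)


class TestTraitBenchmark:
    def test_deterministic_and_shaped(self):
        df1 = make_trait_benchmark(n_samples=50, seed=5)
        df2 = make_trait_benchmark(n_samples=50, seed=5)
        pd.testing.assert_frame_equal(df1, df2)
        assert df1.shape == (50, 34)  # sample_id + 32 traits + target

    def test_signal_fraction_realised(self):
        """With the planted design the population R² is frac_signal; the
        realised fraction at n=20,000 should be within sampling error."""
        df = make_trait_benchmark(n_samples=20000, frac_signal=0.7, seed=1)
        from sklearn.linear_model import LinearRegression

        X = df[["VB_A", "PZ_VB_A", "PZ_T", "PZ_A", "MOA"]]
        r2 = LinearRegression().fit(X, df["BMMax"]).score(X, df["BMMax"])
        assert r2 == pytest.approx(0.7, abs=0.02)
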