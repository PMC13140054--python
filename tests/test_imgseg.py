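import numpy as np
import pandas as pd
import pytest

from stemvb import geometry
from stemvb.imgseg import (
    DegenerateZonesError,
    OrphanBundleError,
    SegConfig,
    StemNotFoundError,
    ZoneMask,
    assign_zones,
    detect_vb_candidates,
    filter_candidates,
    partition_zones,
    segment_section,
    segment_stem,
)
from stemvb.synthdata import CrossSectionImage, simulate_cross_section, truth_zone_labels
from stemvb.traits import EZ, PZ, IZ
from stemvb.validate import match_bundles
from conftest import small_section_spec


def _flat_stem_image(shape=(400, 400), a=120, b=100, tissue=100, bg=20):
    """Uniform-intensity elliptical stem, no bundles, no noise."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = geometry.point_in_ellipse(xx, yy, shape[1] / 2, shape[0] / 2, a, b)
    img = np.full(shape, bg, dtype=np.uint8)
    img[mask] = tissue
    return CrossSectionImage(img, 15.0), mask


class TestSegmentStem:
    def test_blank_image_raises(self):
        img = CrossSectionImage(np.zeros((100, 100), dtype=np.uint8), 15.0)
        with pytest.raises(StemNotFoundError):
            segment_stem(img)

    def test_tiny_foreground_raises(self):
        px = np.zeros((200, 200), dtype=np.uint8)
        px[100:105, 100:105] = 200
        with pytest.raises(StemNotFoundError, match="below minimum"):
            segment_stem(CrossSectionImage(px, 15.0))

    def test_mask_area_matches_ellipse(self, default_section):
        spec, image, _ = default_section
        mask = segment_stem(image)
        analytic_px = geometry.ellipse_area(spec.a_px, spec.b_px)
        assert mask.sum() == pytest.approx(analytic_px, rel=0.02)

    def test_mask_single_component_no_holes(self, default_section):
        from scipy import ndimage as ndi

        _, image, _ = default_section
        mask = segment_stem(image)
        _, n = ndi.label(mask)
        assert n == 1
        assert np.array_equal(ndi.binary_fill_holes(mask), mask)


class TestPartitionZones:
    def test_zero_ez_thickness(self):
        _, mask = _flat_stem_image()
        zones = partition_zones(mask, 15.0, SegConfig(t_ez_um=0.0, t_pz_um=600.0))
        assert not np.any(zones.labels == EZ)
        assert np.array_equal((zones.labels == PZ) | (zones.labels == IZ), mask)

    def test_partition_is_exact(self, default_section, default_segmentation):
        _, image, _ = default_section
        zones, _ = default_segmentation
        stem = segment_stem(image)
        assert (zones.labels > 0).sum() == stem.sum()
        counts = [(zones.labels == z).sum() for z in (EZ, PZ, IZ)]
        assert sum(counts) == stem.sum()

    def test_degenerate_zones_raise(self):
        _, mask = _flat_stem_image()
        with pytest.raises(DegenerateZonesError):
            partition_zones(mask, 15.0, SegConfig(t_ez_um=900.0, t_pz_um=900.0))

    def test_zone_agreement_with_truth(self, default_section, default_segmentation):
        spec, _, _ = default_section
        zones, _ = default_segmentation
        truth = truth_zone_labels(spec)
        union = (truth > 0) | (zones.labels > 0)
        agreement = (truth[union] == zones.labels[union]).mean()
        assert agreement >= 0.97


class TestAdaptiveBoundary:
    def test_recovers_pz_iz_transition(self, default_section, default_segmentation):
        from stemvb.imgseg import estimate_pz_iz_boundary, segment_stem

        spec, image, _ = default_section
        _, bundles = default_segmentation
        stem = segment_stem(image)
        boundary = estimate_pz_iz_boundary(bundles, stem, image.pixel_size)
        truth = spec.ez_thickness + spec.pz_thickness
        assert boundary == pytest.approx(truth, rel=0.15)

    def test_needs_enough_bundles(self):
        image, mask = _flat_stem_image()
        few = pd.DataFrame({"centroid_x_um": [100.0], "centroid_y_um": [100.0],
                            "area_um2": [1e4], "accepted": [True]})
        with pytest.raises(ValueError, match="too few"):
            from stemvb.imgseg import estimate_pz_iz_boundary

            estimate_pz_iz_boundary(few, mask, 15.0)


class TestDetectCandidates:
    def test_uniform_stem_yields_no_candidates(self):
        image, mask = _flat_stem_image()
        labels = detect_vb_candidates(image, mask)
        bundles = filter_candidates(labels, image, stem_mask=mask)
        assert bundles["accepted"].sum() == 0

    def test_candidate_count_at_least_truth(self, default_section,
                                            default_segmentation):
        _, _, truth = default_section
        _, bundles = default_segmentation
        assert len(bundles) >= len(truth.bundles)

    def test_well_separated_bundles_get_distinct_labels(self):
        spec = small_section_spec(n_pz_bundles=0, n_iz_bundles=2, seed=21,
                                  min_separation=500.0)
        image, truth = simulate_cross_section(spec)
        mask = segment_stem(image)
        labels = detect_vb_candidates(image, mask)
        bundles = filter_candidates(labels, image, stem_mask=mask)
        assert bundles["accepted"].sum() == 2


class TestFilterCandidates:
    def test_single_pixel_candidate_rejected_for_area(self):
        image, mask = _flat_stem_image()
        labels = np.zeros(image.pixels.shape, dtype=np.int32)
        labels[200, 200] = 1
        out = filter_candidates(labels, image, stem_mask=mask)
        assert len(out) == 1
        assert not out.loc[0, "accepted"]
        assert out.loc[0, "reject_reason"] == "area"

    def test_rendered_disk_is_accepted(self):
        image, mask = _flat_stem_image()
        px = image.pixels.copy()
        yy, xx = np.mgrid[0:px.shape[0], 0:px.shape[1]]
        disk = (xx - 200) ** 2 + (yy - 200) ** 2 <= 20**2
        px[disk] = 200
        image = CrossSectionImage(px, 15.0)
        labels = np.where(disk, 1, 0).astype(np.int32)
        out = filter_candidates(labels, image, stem_mask=mask)
        assert out.loc[0, "accepted"]
        assert out.loc[0, "solidity"] >= 0.95
        assert out.loc[0, "eccentricity"] <= 0.3


class TestAssignZones:
    def _zones(self):
        _, mask = _flat_stem_image()
        return partition_zones(mask, 15.0, SegConfig(t_ez_um=120.0, t_pz_um=450.0))

    def _bundle_at(self, x_um, y_um):
        return pd.DataFrame([{
            "id": 1, "centroid_x_um": x_um, "centroid_y_um": y_um,
            "area_um2": 1e4, "zone": "", "eccentricity": 0.1, "solidity": 1.0,
            "mean_intensity": 150.0, "accepted": True, "reject_reason": "",
        }])

    def test_center_is_inner_zone(self):
        out = assign_zones(self._bundle_at(200 * 15.0, 200 * 15.0), self._zones())
        assert out.loc[0, "zone"] == "IZ"

    def test_epidermis_centroid_reassigned_to_pz(self, caplog):
        # 4 px inside the boundary along +x: depth ~ 60 µm < t_ez = 120 µm
        out = assign_zones(self._bundle_at((200 + 120 - 4) * 15.0, 200 * 15.0),
                           self._zones())
        assert out.loc[0, "zone"] == "PZ"

    def test_orphan_bundle_raises(self):
        with pytest.raises(OrphanBundleError):
            assign_zones(self._bundle_at(15.0, 15.0), self._zones())


class TestEndToEnd:
    def test_detection_matches_truth(self, default_section, default_segmentation):
        _, _, truth = default_section
        _, bundles = default_segmentation
        m = match_bundles(truth, bundles)
        assert m.recall >= 0.95
        assert m.precision >= 0.95
        assert m.area_r2 >= 0.97

    def test_zone_assignment_matches_truth(self, default_section,
                                           default_segmentation):
        _, _, truth = default_section
        _, bundles = default_segmentation
        acc = bundles[bundles["accepted"]]
        tx = np.array([b.centroid_um[0] for b in truth.bundles])
        ty = np.array([b.centroid_um[1] for b in truth.bundles])
        tz = np.array([b.zone for b in truth.bundles])
        tr = np.array([b.radius_um for b in truth.bundles])
        d = np.hypot(acc["centroid_x_um"].to_numpy()[:, None] - tx,
                     acc["centroid_y_um"].to_numpy()[:, None] - ty)
        nearest = d.argmin(axis=1)
        matched = d[np.arange(len(acc)), nearest] <= tr[nearest]
        agree = (acc["zone"].to_numpy()[matched] == tz[nearest[matched]]).mean()
        assert agree >= 0.98

    def test_translation_equivariance(self):
        """Shifting the image content by whole pixels leaves counts and
        areas unchanged and shifts centroids by exactly the shift."""
        spec = small_section_spec(seed=13)
        image, _ = simulate_cross_section(spec)
        dy, dx = 7, -5
        shifted = CrossSectionImage(np.roll(image.pixels, (dy, dx), axis=(0, 1)),
                                    image.pixel_size)
        _, b0 = segment_section(image)
        _, b1 = segment_section(shifted)
        a0 = b0[b0["accepted"]].sort_values(["centroid_y_um", "centroid_x_um"])
        a1 = b1[b1["accepted"]].sort_values(["centroid_y_um", "centroid_x_um"])
        assert len(a0) == len(a1)
        assert np.allclose(np.sort(a0["area_um2"]), np.sort(a1["area_um2"]))
        assert np.allclose(a1["centroid_x_um"].to_numpy()
                           - a0["centroid_x_um"].to_numpy(),
                           dx * image.pixel_size, atol=1e-6)
        assert np.allclose(a1["centroid_y_um"].to_numpy()
                           - a0["centroid_y_um"].to_numpy(),
                           dy * image.pixel_size, atol=1e-6)
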