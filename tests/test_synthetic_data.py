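"""Generator tests: rasterization geometry, pathologies, dataset plumbing."""

import numpy as np
import pytest

from angioseg import synthetic_data as sd


def brute_force_capsule_mask(size, segments):
    """Independent rasterization oracle: per-pixel distance-to-segment test.

    ``segments`` is a list of ((r0, c0), (r1, c1), radius) tuples.
    """
    mask = np.zeros((size, size), dtype=bool)
    for (r0, c0), (r1, c1), rad in segments:
        for i in range(size):
            for j in range(size):
                vr, vc = r1 - r0, c1 - c0
                vv = vr * vr + vc * vc
                if vv == 0:
                    d = np.hypot(i - r0, j - c0)
                else:
                    t = ((i - r0) * vr + (j - c0) * vc) / vv
                    t = min(1.0, max(0.0, t))
                    d = np.hypot(i - (r0 + t * vr), j - (c0 + t * vc))
                if d <= rad:
                    mask[i, j] = True
    return mask


def straight_branch(p0, p1, radius, intensity=0.85):
    n = int(round(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))) + 1
    t = np.linspace(0.0, 1.0, n)
    pts = np.stack([p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1])],
                   axis=1)
    return sd.Branch(points=pts, radii=np.full(n, float(radius)),
                     intensities=np.full(n, float(intensity)))


class TestSpecValidation:
    @pytest.mark.parametrize("field,value", [
        ("root_radius", 0.5),
        ("stenosis_fraction", 1.5),
        ("occlusion_gap", 0),
        ("flow_intensity_factor", 0.0),
        ("radius_decay", 0.0),
        ("noise_sigma", -0.1),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field):
            sd.VesselTreeSpec(**{field: value})

    def test_vessel_must_exceed_background(self):
        with pytest.raises(ValueError, match="vessel_intensity"):
            sd.VesselTreeSpec(vessel_intensity=0.2, background_intensity=0.4)

    def test_label_encoding_is_stable(self):
        assert [l.code for l in sd.ClassLabel] == [0, 1, 2, 3]
        assert sd.ClassLabel.coerce("narrow") is sd.ClassLabel.NARROW
        assert sd.ClassLabel.from_code(3) is sd.ClassLabel.FLOW_REDUCED
        with pytest.raises(ValueError):
            sd.ClassLabel.coerce("bogus")


class TestGeneration:
    def test_empty_scene_is_flat_background(self):
        spec = sd.VesselTreeSpec(n_branches=0, noise_sigma=0.0, seed=5)
        img, gt = sd.generate_vessel_tree(spec)
        assert img.shape == (128, 128)
        np.testing.assert_array_equal(img, np.full((128, 128), 0.25))
        assert gt.mask.sum() == 0

    def test_same_spec_same_seed_bitwise_identical(self):
        spec = sd.VesselTreeSpec(seed=11, pathology="narrow")
        img1, gt1 = sd.generate_vessel_tree(spec)
        img2, gt2 = sd.generate_vessel_tree(spec)
        np.testing.assert_array_equal(img1, img2)
        np.testing.assert_array_equal(gt1.mask, gt2.mask)

    def test_single_straight_vessel_matches_bruteforce_oracle(self):
        b = straight_branch((64.0, 10.0), (64.0, 110.0), radius=3.0)
        _, mask = sd.render([b], 128)
        oracle = brute_force_capsule_mask(
            128, [((64.0, 10.0), (64.0, 110.0), 3.0)])
        np.testing.assert_array_equal(mask, oracle)

    def test_generated_tree_matches_bruteforce_oracle(self):
        spec = sd.VesselTreeSpec(n_branches=3, noise_sigma=0.0, seed=7)
        rng = np.random.default_rng(spec.seed)
        branches = sd.build_tree(spec, rng)
        assert len(branches) == 3
        _, mask = sd.render(branches, spec.image_size)
        segments = [(tuple(b.points[0]), tuple(b.points[-1]), b.radii[0])
                    for b in branches]
        oracle = brute_force_capsule_mask(spec.image_size, segments)
        np.testing.assert_array_equal(mask, oracle)

    def test_mask_covers_brightest_pixels(self):
        # noiseless: every vessel pixel >= every background pixel
        for label in sd.ClassLabel:
            spec = sd.VesselTreeSpec(seed=3, noise_sigma=0.0, pathology=label)
            img, gt = sd.generate_vessel_tree(spec)
            m = gt.mask.astype(bool)
            assert img[m].min() >= img[~m].max()


class TestPathology:
    def test_normal_is_identity(self):
        spec = sd.VesselTreeSpec(seed=2)
        branches = sd.build_tree(spec, np.random.default_rng(2))
        out, info = sd.apply_pathology(branches, "normal", spec)
        assert out is branches
        assert info.kind is sd.ClassLabel.NORMAL

    def test_flow_reduced_scales_intensity(self):
        spec = sd.VesselTreeSpec(vessel_intensity=0.9,
                                 flow_intensity_factor=0.5, noise_sigma=0.0,
                                 seed=4)
        branches = sd.build_tree(spec, np.random.default_rng(4))
        out, _ = sd.apply_pathology(branches, "flow_reduced", spec)
        for b in out:
            np.testing.assert_allclose(b.intensities, 0.45)
        img, gt = sd.render(out, 128, spec.background_intensity)
        assert np.isclose(img.max(), 0.45)

    def test_narrow_thins_the_stenosis_window(self):
        spec = sd.VesselTreeSpec(root_radius=5.0, stenosis_fraction=0.4,
                                 stenosis_length=24, noise_sigma=0.0, seed=9)
        b = straight_branch((64.0, 10.0), (64.0, 110.0), radius=5.0)
        out, info = sd.apply_pathology([b], "narrow", spec,
                                       rng=np.random.default_rng(0))
        nb = out[0]
        np.testing.assert_allclose(nb.radii[info.start:info.stop], 2.0)
        assert nb.radii[:info.start].max() == 5.0
        # row-scan oracle: mask width across the stenosis < width elsewhere
        _, mask = sd.render(out, 128)
        widths = mask.sum(axis=0)
        cols = nb.points[:, 1].astype(int)
        # interior of the window, away from the rounded transition caps
        win_cols = cols[info.start + 6: info.stop - 6]
        far_cols = np.concatenate([cols[8:info.start - 8],
                                   cols[info.stop + 8: -8]])
        assert widths[win_cols].max() <= widths[far_cols].min()
        assert widths[win_cols].max() <= 2 * 2.0 + 1

    def test_block_gap_and_distal_nonopacification(self):
        spec = sd.VesselTreeSpec(seed=6, noise_sigma=0.0)
        rng = np.random.default_rng(spec.seed)
        branches = sd.build_tree(spec, rng)
        out, info = sd.apply_pathology(branches, "block", spec,
                                       rng=np.random.default_rng(1))
        assert len(out) < len(branches)  # downstream subtree removed
        blocked = out[info.branch_index]
        np.testing.assert_allclose(
            blocked.intensities[info.start:info.stop],
            spec.background_intensity)
        # the class renders with strictly less opacified area than normal
        img_n, gt_n = sd.generate_vessel_tree(
            sd.VesselTreeSpec(seed=6, noise_sigma=0.0))
        img_b, gt_b = sd.generate_vessel_tree(
            sd.VesselTreeSpec(seed=6, noise_sigma=0.0, pathology="block"))
        assert gt_b.mask.sum() < gt_n.mask.sum()

    def test_pathology_requires_branches(self):
        spec = sd.VesselTreeSpec(n_branches=0)
        with pytest.raises(ValueError):
            sd.apply_pathology([], "block", spec)


class TestDataset:
    def test_minimal_dataset_one_per_label(self, tmp_path):
        manifest = sd.generate_dataset(tmp_path, n_per_class=1, seed=0)
        assert len(manifest.records) == 4
        assert {r.label for r in manifest.records} == set(sd.ClassLabel)
        for r in manifest.records:
            assert (tmp_path / r.path).exists()
        again = sd.DatasetManifest.from_csv(tmp_path / "manifest.csv")
        assert [r.path for r in again.records] == \
            [r.path for r in manifest.records]

    def test_label_balance(self, tmp_path):
        manifest = sd.generate_dataset(tmp_path, n_per_class=3, seed=1)
        counts = {}
        for r in manifest.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        assert all(c == 3 for c in counts.values()) and len(counts) == 4

    def test_dataset_bytes_reproducible(self, tmp_path):
        m1 = sd.generate_dataset(tmp_path / "a", n_per_class=1, seed=42)
        m2 = sd.generate_dataset(tmp_path / "b", n_per_class=1, seed=42)
        for r1, r2 in zip(m1.records, m2.records):
            assert r1.path == r2.path and r1.label == r2.label
            b1 = (tmp_path / "a" / r1.path).read_bytes()
            b2 = (tmp_path / "b" / r2.path).read_bytes()
            assert b1 == b2

    def test_invalid_count_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            sd.generate_dataset(tmp_path, n_per_class=0)

    def test_duplicate_paths_rejected(self):
        rec = sd.ManifestRecord("x.png", sd.ClassLabel.NORMAL)
        with pytest.raises(ValueError):
            sd.DatasetManifest(records=[rec, rec])
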