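import numpy as np
import pytest
import scipy.ndimage as ndi

import garnettrack as gt
from garnettrack.core_io import ClassCode, VolumeGrid
from garnettrack.segmentation import (clean_partial_volume, classify_pores,
                                      denoise_nlm, detect_particles,
                                      find_thresholds, segment_tentative,
                                      segment_volume)

from _oracles import bfs_clusters, two_threshold_otsu_bruteforce


def make_volume(data, voxel_size=8.0):
    return VolumeGrid(np.asarray(data, dtype=np.float32), voxel_size)


class TestDenoise:
    def test_near_identity_on_clean_input(self):
        data = np.full((24, 24, 24), 100.0, dtype=np.float32)
        data[:, :12] = 40.0
        out = denoise_nlm(make_volume(data), h=2.0)
        assert np.abs(out.data - data).max() <= 2.0

    def test_reduces_noise_in_homogeneous_block(self):
        rng = np.random.default_rng(0)
        data = np.full((32, 32, 32), 100.0) + rng.normal(0, 10, (32, 32, 32))
        out = denoise_nlm(make_volume(data))
        assert out.data[4:-4, 4:-4, 4:-4].std() < 5.0

    def test_preserves_edges_better_than_matched_gaussian(self):
        rng = np.random.default_rng(1)
        data = np.full((24, 24, 24), 40.0)
        data[:, 12:] = 130.0
        noisy = data + rng.normal(0, 10, data.shape)
        nlm = denoise_nlm(make_volume(noisy.astype(np.float32))).data
        # Gaussian with matched variance reduction in the flat region
        flat = (slice(4, 20), slice(2, 8), slice(4, 20))
        target_std = nlm[flat].std()
        best = None
        for s in np.linspace(0.4, 3.0, 14):
            g = ndi.gaussian_filter(noisy, s)
            if best is None or abs(g[flat].std() - target_std) < best[0]:
                best = (abs(g[flat].std() - target_std), g)
        grad_nlm = np.abs(np.diff(nlm, axis=1))[:, 10:13].mean()
        grad_gauss = np.abs(np.diff(best[1], axis=1))[:, 10:13].mean()
        assert grad_nlm >= grad_gauss


class TestFindThresholds:
    def test_trimodal_mixture_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(m, 8, 6000) for m in (40, 130, 220)])
        vals = np.clip(vals, 0, 255)
        th = find_thresholds(make_volume(vals[: 18 * 30 * 30].reshape(18, 30, 30)))
        assert 60 < th.t_low < 110
        assert 150 < th.t_high < 200
        o_low, o_high = two_threshold_otsu_bruteforce(vals[: 18 * 30 * 30], nbins=128)
        assert th.t_low == pytest.approx(o_low, abs=6)
        assert th.t_high == pytest.approx(o_high, abs=6)

    def test_three_distinct_values_isolated(self):
        rng = np.random.default_rng(2)
        data = rng.choice([10.0, 100.0, 200.0], size=(12, 12, 12))
        th = find_thresholds(make_volume(data))
        assert 10 < th.t_low < 100 < th.t_high < 200

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            find_thresholds(make_volume(np.full((8, 8, 8), 7.0)))


class TestSegmentTentative:
    def test_three_value_image_class_counts_exact(self):
        rng = np.random.default_rng(3)
        data = rng.choice([10.0, 100.0, 200.0], size=(12, 12, 12))
        th = find_thresholds(make_volume(data))
        lab = segment_tentative(make_volume(data), th)
        assert (lab.labels == ClassCode.PORE_CONNECTED).sum() == (data == 10).sum()
        assert (lab.labels == ClassCode.MATRIX).sum() == (data == 100).sum()
        assert (lab.labels == ClassCode.PARTICLE).sum() == (data == 200).sum()

    def test_all_pore_volume(self):
        lab = segment_tentative(make_volume(np.zeros((6, 6, 6))),
                                gt.ThresholdPair(10, 20))
        assert (lab.labels == ClassCode.PORE_CONNECTED).all()

    def test_phantom_agreement_outside_interfaces(self, coated_phantom):
        """Thresholding a blur-1/noise-5 phantom matches truth off interfaces."""
        _, truth, gray = coated_phantom
        th = find_thresholds(gray)
        lab = segment_tentative(gray, th)
        true = truth.labels.labels
        pore_t = np.isin(true, (ClassCode.PORE_CONNECTED, ClassCode.PORE_ENCLOSED))
        # non-interface: voxels whose 6-neighbourhood is one phase
        phase = np.select([pore_t, true == ClassCode.MATRIX], [0, 1], 2)
        interior = np.ones(true.shape, dtype=bool)
        for v in (0, 1, 2):
            m = phase == v
            interior &= ~(m ^ ndi.binary_erosion(m)) | ~m
        pore_s = lab.labels == ClassCode.PORE_CONNECTED
        mat_s = lab.labels == ClassCode.MATRIX
        par_s = lab.labels == ClassCode.PARTICLE
        agree = np.where(phase == 0, pore_s, np.where(phase == 1, mat_s, par_s))
        assert agree[interior].mean() >= 0.95


class TestCleanPartialVolume:
    def test_large_block_keeps_interior(self):
        labels = np.full((30, 30, 30), ClassCode.PORE_CONNECTED, dtype=np.uint8)
        labels[5:25, 5:25, 5:25] = ClassCode.MATRIX
        lv = gt.LabelVolume(labels)
        out = clean_partial_volume(lv, d_se=5, min_object=27)
        kept = out.labels[8:22, 8:22, 8:22]
        assert (kept == ClassCode.MATRIX).all()
        rind = (labels == ClassCode.MATRIX) & (out.labels == ClassCode.UNASSIGNED)
        dist_from_edge = ndi.distance_transform_edt(labels == ClassCode.MATRIX)
        assert dist_from_edge[rind].max() <= 3.0

    def test_thin_film_fully_removed(self):
        labels = np.full((20, 20, 20), ClassCode.PORE_CONNECTED, dtype=np.uint8)
        labels[9:11] = ClassCode.MATRIX  # 2-voxel film, thinner than d_SE/2
        out = clean_partial_volume(gt.LabelVolume(labels), d_se=5)
        assert (out.labels[9:11] == ClassCode.UNASSIGNED).all()

    @pytest.mark.parametrize("d_se", [4, 2, 1])
    def test_even_or_small_diameter_rejected(self, d_se):
        with pytest.raises(ValueError):
            clean_partial_volume(gt.LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8)),
                                 d_se=d_se)

    def test_idempotent(self, coated_phantom):
        _, truth, gray = coated_phantom
        th = find_thresholds(gray)
        tentative = segment_tentative(gray, th)
        once = clean_partial_volume(tentative)
        twice = clean_partial_volume(once)
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestDetectParticles:
    def test_single_ball_detected_at_matching_scale(self):
        data = np.zeros((40, 40, 40), dtype=np.float32)
        zz, yy, xx = np.mgrid[:40, :40, :40]
        data[(zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 16] = 200.0
        det, _ = detect_particles(make_volume(data))
        assert len(det) == 1
        from garnettrack.segmentation import DEFAULT_SCALES
        scales = np.array(DEFAULT_SCALES)
        expect = 4 / np.sqrt(3)
        idx = int(np.argmin(np.abs(scales - expect)))
        neighbours = {scales[max(0, idx - 1)], scales[idx],
                      scales[min(len(scales) - 1, idx + 1)]}
        assert det[0].sigma in neighbours
        assert np.allclose(det[0].centroid, (20, 20, 20), atol=1.0)

    def test_constant_image_yields_no_detections(self):
        det, _ = detect_particles(make_volume(np.zeros((16, 16, 16))),
                                  t_high_hyst=1.0, t_low_hyst=0.5)
        assert det == []

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            detect_particles(make_volume(np.zeros((8, 8, 8))), scales=())

    def test_phantom_recall_precision_and_grain_masking(self, coated_phantom):
        from scipy.spatial import cKDTree
        _, truth, gray = coated_phantom
        labels, meta = segment_volume(gray, denoise=False)
        dets = np.array([d["centroid"] for d in meta["detections"]])
        true = np.array([c for c, _ in truth.particles])
        d_det, _ = cKDTree(true).query(dets)
        d_true, _ = cKDTree(dets).query(true)
        assert (d_det <= 3).mean() >= 0.9      # precision
        assert (d_true <= 3).mean() >= 0.9     # recall
        grain = truth.labels.labels == ClassCode.GRAIN
        if grain.any():
            gdist, _ = cKDTree(np.argwhere(grain)).query(dets)
            assert (gdist < 1).sum() == 0      # no detections inside grains


class TestFinalizeAndClassify:
    def test_unconfirmed_garnet_becomes_unassigned(self):
        labels = np.full((10, 10, 10), ClassCode.MATRIX, dtype=np.uint8)
        labels[2, 2, 2] = ClassCode.PARTICLE  # tentative garnet, no LoG support
        out = gt.finalize_segmentation(gt.LabelVolume(labels),
                                       np.zeros((10, 10, 10), dtype=bool))
        assert out.labels[2, 2, 2] == ClassCode.UNASSIGNED

    def test_classes_partition_volume(self, coated_phantom):
        _, _, gray = coated_phantom
        labels, _ = segment_volume(gray, denoise=False)
        assert sum(labels.counts().values()) == labels.labels.size

    def test_true_particle_interiors_recovered(self, coated_phantom):
        """Particle interiors are labeled PARTICLE; only the 1-voxel
        partial-volume shell may fall to UNASSIGNED."""
        _, truth, gray = coated_phantom
        labels, _ = segment_volume(gray, denoise=False)
        pm_true = truth.labels.labels == ClassCode.PARTICLE
        interior = ndi.binary_erosion(pm_true)
        assert (labels.labels[interior] == ClassCode.PARTICLE).mean() >= 0.9

    def test_enclosed_cavity_labeled_enclosed(self):
        labels = np.full((16, 16, 16), ClassCode.MATRIX, dtype=np.uint8)
        labels[7:9, 7:9, 7:9] = ClassCode.PORE_CONNECTED  # provisional
        out = classify_pores(gt.LabelVolume(labels))
        assert (out.labels[7:9, 7:9, 7:9] == ClassCode.PORE_ENCLOSED).all()

    def test_slab_touching_face_is_connected(self):
        labels = np.full((16, 16, 16), ClassCode.MATRIX, dtype=np.uint8)
        labels[0:2] = ClassCode.PORE_ENCLOSED  # provisional
        out = classify_pores(gt.LabelVolume(labels))
        assert (out.labels[0:2] == ClassCode.PORE_CONNECTED).all()

    def test_thin_channel_connects_cavity_under_26_connectivity(self):
        labels = np.full((16, 16, 16), ClassCode.MATRIX, dtype=np.uint8)
        labels[8, 8, 8] = ClassCode.PORE_CONNECTED
        for i in range(8):  # diagonal 1-voxel channel to the face
            labels[i, 8, i] = ClassCode.PORE_CONNECTED
        out = classify_pores(gt.LabelVolume(labels), connectivity=26)
        # brute-force oracle agrees
        pore = out.mask(ClassCode.PORE_CONNECTED, ClassCode.PORE_ENCLOSED)
        sizes = bfs_clusters(pore, 26)
        assert len(sizes) == 1
        assert (out.labels[8, 8, 8] == ClassCode.PORE_CONNECTED)


class TestChainProperties:
    def test_rotation_equivariance(self):
        spec = gt.PhantomSpec(shape=(48, 48, 48), aggregate_radius_range=(5, 8),
                              n_grains=0, coat_coverage=0.02, max_particles=30,
                              seed=9)
        _, truth = gt.generate_packing(spec)
        truth = gt.coat_with_particles(truth)
        gray = gt.render_grayscale(truth)
        th = find_thresholds(gray)
        lab = segment_volume(gray, denoise=False, thresholds=th)[0].labels
        rot = VolumeGrid(np.rot90(gray.data, axes=(1, 2)).copy(), gray.voxel_size)
        lab_rot = segment_volume(rot, denoise=False, thresholds=th)[0].labels
        agreement = (np.rot90(lab, axes=(1, 2)) == lab_rot).mean()
        assert agreement >= 0.999

    def test_noiseless_blur_free_chain_recovers_truth(self):
        spec = gt.PhantomSpec(shape=(48, 48, 48), aggregate_radius_range=(5, 8),
                              n_grains=0, coat_coverage=0.02, max_particles=30,
                              blur_sigma=0.0, noise_sigma=0.0, seed=10)
        _, truth = gt.generate_packing(spec)
        truth = gt.coat_with_particles(truth)
        gray = gt.render_grayscale(truth)
        lab, _ = segment_volume(gray, denoise=False, min_object=1)
        true = truth.labels.labels
        # outside a 1-voxel interface shell
        interface = np.zeros(true.shape, dtype=bool)
        for code in (ClassCode.MATRIX, ClassCode.PARTICLE):
            m = true == code
            interface |= ndi.binary_dilation(m) & ~ndi.binary_erosion(m)
        pore_true = np.isin(true, (ClassCode.PORE_CONNECTED, ClassCode.PORE_ENCLOSED))
        pore_seg = np.isin(lab.labels, (ClassCode.PORE_CONNECTED, ClassCode.PORE_ENCLOSED))
        assert (pore_true == pore_seg)[~interface].all()
        assert ((true == ClassCode.PARTICLE) ==
                (lab.labels == ClassCode.PARTICLE))[~interface].mean() >= 0.999
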