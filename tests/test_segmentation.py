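"""Superpixel partition contracts, cluster selection, and the level set."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from psoriscan.colorspace import rgb_to_lab
from psoriscan.segmentation import (LSMParams, SLICParams, cluster_superpixels,
                                    segment_lsm, segment_slic,
                                    select_lesion_clusters, slic_superpixels)
from psoriscan.similarity import dice
from psoriscan.synthetic import LesionSceneParams, generate_scene


def _disk_image(size=128, r=30, inner=(180, 60, 60), outer=(210, 190, 160)):
    yy, xx = np.mgrid[0:size, 0:size]
    disk = np.hypot(yy - size / 2, xx - size / 2) <= r
    img = np.empty((size, size, 3), np.uint8)
    img[...] = outer
    img[disk] = inner
    return img, disk


class TestSlicSuperpixels:
    def test_uniform_image_tessellates_into_equal_cells(self):
        img = np.full((100, 100, 3), 128, np.uint8)
        labels = slic_superpixels(img, SLICParams(n_superpixels=25, n_centers=2))
        sizes = np.bincount(labels.ravel())
        assert abs(len(sizes) - 25) <= 4  # within 15% of the request
        assert sizes.std() / sizes.mean() < 0.1

    def test_labels_form_partition(self, severe_scene):
        labels = slic_superpixels(severe_scene.image,
                                  SLICParams(n_superpixels=200))
        assert labels.shape == severe_scene.image.shape[:2]
        uniq = np.unique(labels)
        assert uniq[0] == 0 and uniq[-1] == len(uniq) - 1  # compact range

    def test_disk_boundary_recall_within_two_pixels(self):
        img, disk = _disk_image()
        labels = slic_superpixels(img, SLICParams(n_superpixels=100))
        spx_boundary = np.zeros_like(disk)
        spx_boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]
        spx_boundary[1:, :] |= labels[1:, :] != labels[:-1, :]
        dist = ndi.distance_transform_edt(~spx_boundary)
        eroded = ndi.binary_erosion(disk)
        true_boundary = disk & ~eroded
        assert (dist[true_boundary] <= 2).mean() >= 0.95

    def test_too_many_superpixels_rejected(self):
        with pytest.raises(ValueError):
            slic_superpixels(np.zeros((4, 4, 3), np.uint8),
                             SLICParams(n_superpixels=100))


class TestClusterSuperpixels:
    def test_recovers_three_separated_colors(self):
        # three vertical bands of mutually distant Lab colors
        img = np.zeros((30, 90, 3), np.uint8)
        img[:, :30] = (220, 40, 40)
        img[:, 30:60] = (40, 220, 40)
        img[:, 60:] = (40, 40, 220)
        spx = np.repeat(np.arange(9)[None].repeat(30, 0), 10, axis=1)
        lab = rgb_to_lab(img)
        clusters = cluster_superpixels(spx, lab, n_centers=3, seed=0)
        # exhaustive check: each band maps to exactly one cluster id
        for sl in (np.s_[:, :30], np.s_[:, 30:60], np.s_[:, 60:]):
            assert len(np.unique(clusters[sl])) == 1
        assert len(np.unique(clusters)) == 3

    def test_converged_assignment_is_fixed_point(self):
        img = np.zeros((30, 90, 3), np.uint8)
        img[:, :45] = (220, 40, 40)
        img[:, 45:] = (40, 40, 220)
        spx = np.repeat(np.arange(9)[None].repeat(30, 0), 10, axis=1)
        lab = rgb_to_lab(img)
        a = cluster_superpixels(spx, lab, n_centers=2, iters=100, seed=0)
        b = cluster_superpixels(spx, lab, n_centers=2, iters=101, seed=0)
        assert np.array_equal(a, b)

    def test_degenerate_single_color_does_not_crash(self):
        img = np.full((20, 20, 3), 99, np.uint8)
        spx = np.repeat(np.arange(4)[None].repeat(10, 0), 10, axis=1).T
        spx = np.kron(np.arange(4).reshape(2, 2), np.ones((10, 10), int))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clusters = cluster_superpixels(spx, rgb_to_lab(img), n_centers=3,
                                           seed=0)
        assert len(np.unique(clusters)) == 1  # one effective cluster

    def test_more_centers_than_superpixels_rejected(self):
        spx = np.zeros((5, 5), int)
        with pytest.raises(ValueError):
            cluster_superpixels(spx, np.zeros((5, 5, 3)), n_centers=3)


class TestSelectLesionClusters:
    def _fixture(self):
        # clusters 0,1,2 with mean a* = 12, 35, 14
        img = np.zeros((10, 30, 3), np.uint8)
        img[:, :10] = (200, 180, 160)   # a* ~ 3
        img[:, 10:20] = (220, 60, 80)   # strongly red
        img[:, 20:] = (205, 175, 160)
        clusters = np.repeat(np.arange(3), 10)[None].repeat(10, 0)
        return clusters, rgb_to_lab(img)

    def test_max_a_selects_reddest_cluster(self):
        clusters, lab = self._fixture()
        mask = select_lesion_clusters(clusters, lab, rule="max_a")
        assert mask[:, 10:20].all() and not mask[:, :10].any()

    def test_a_above_median_selects_all_red_clusters(self):
        clusters, lab = self._fixture()
        mask = select_lesion_clusters(clusters, lab, rule="a_above_median")
        assert mask[:, 10:20].all()

    def test_manual_and_unknown_rules(self):
        clusters, lab = self._fixture()
        mask = select_lesion_clusters(clusters, lab, rule="manual",
                                      manual_ids=[0, 2])
        assert mask[:, :10].all() and not mask[:, 10:20].any()
        with pytest.raises(ValueError):
            select_lesion_clusters(clusters, lab, rule="bogus")


class TestSegmentSlic:
    def test_severe_scene_recovered(self, severe_scene):
        # the fixture carries heavy scale: the single reddest cluster misses
        # white flakes, while the a-above-median rule captures the full plaque
        res = segment_slic(severe_scene.image, SLICParams(seed=0))
        assert dice(res.mask, severe_scene.lesion_mask) >= 0.8
        assert res.method == "slic"
        assert res.superpixels is not None
        res2 = segment_slic(severe_scene.image,
                            SLICParams(seed=0, rule="a_above_median"))
        assert dice(res2.mask, severe_scene.lesion_mask) >= 0.9

    def test_pure_erythema_scene_recovered_by_default_rule(self):
        sc = generate_scene(LesionSceneParams(
            image_size=(256, 256), erythema_score=4, scale_score=0, seed=11))
        res = segment_slic(sc.image, SLICParams(seed=0))
        assert dice(res.mask, sc.lesion_mask) >= 0.9

    def test_healthy_scene_near_empty(self, healthy_scene):
        res = segment_slic(healthy_scene.image, SLICParams(seed=0))
        assert res.mask.mean() < 0.02

    def test_fixed_seed_identical_mask(self, severe_scene):
        a = segment_slic(severe_scene.image, SLICParams(seed=3))
        b = segment_slic(severe_scene.image, SLICParams(seed=3))
        assert np.array_equal(a.mask, b.mask)


class TestSegmentLsm:
    def test_converges_to_high_contrast_disk(self):
        yy, xx = np.mgrid[0:128, 0:128]
        disk = np.hypot(yy - 64, xx - 64) <= 30
        img = np.where(disk, 200.0, 60.0)
        init = np.hypot(yy - 64, xx - 64) <= 18
        res = segment_lsm(img, LSMParams(init_mask=init))
        assert dice(res.mask, disk) >= 0.9
        assert res.method == "lsm"

    def test_constant_image_keeps_initialization(self):
        yy, xx = np.mgrid[0:64, 0:64]
        init = np.hypot(yy - 32, xx - 32) <= 15
        res = segment_lsm(np.full((64, 64), 100.0), LSMParams(init_mask=init))
        assert abs(res.mask.sum() - init.sum()) / init.sum() < 0.05

    def test_zero_diffusion_is_pure_evolution(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = np.hypot(yy - 32, xx - 32) <= 20
        img = np.where(disk, 180.0, 50.0)
        init = np.hypot(yy - 32, xx - 32) <= 12
        a = segment_lsm(img, LSMParams(init_mask=init, dt2=0.0, iterations=5))
        b = segment_lsm(img, LSMParams(init_mask=init, dt2=0.0, iterations=5))
        assert np.array_equal(a.mask, b.mask)  # deterministic limit case

    def test_empty_init_mask_rejected(self):
        with pytest.raises(ValueError):
            LSMParams(init_mask=np.zeros((4, 4), bool))


def test_monotone_difficulty_mild_vs_severe():
    """Boundary ambiguity at low scores degrades segmentation quality."""
    def mean_dice(score):
        vals = []
        for seed in range(5):
            sc = generate_scene(LesionSceneParams(
                image_size=(192, 192), erythema_score=score, scale_score=0,
                seed=seed))
            res = segment_slic(sc.image, SLICParams(seed=seed))
            vals.append(dice(res.mask, sc.lesion_mask))
        return np.mean(vals)

    assert mean_dice(1) <= mean_dice(4)
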