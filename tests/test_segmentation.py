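"""Tissue segmentation: clustering, thresholds, lesion classification."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest

import strokesem as sk
import strokesem.labels as L
from strokesem.volume import ImageVolume

from conftest import dice


def bfs_component_sizes(mask):
    """Independent 26-connectivity component enumeration."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    sizes = []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask & ~seen)):
        if seen[start]:
            continue
        q, size = deque([start]), 0
        seen[start] = True
        while q:
            v = q.popleft()
            size += 1
            for o in offsets:
                w = tuple(a + b for a, b in zip(v, o))
                if all(0 <= w[d] < mask.shape[d] for d in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        q.append(w)
        sizes.append(size)
    return sizes


class TestClusterFlair:
    def test_parenchyma_cluster_and_reference_stats_on_phantom(self):
        spec = sk.PhantomSpec(
            grid_shape=(40, 40, 32),
            voxel_size=(2, 2, 2),
            lesions=(sk.Lesion("wml", (28, 20, 16), 6.0, flair_offset_sd=6.0),),
            seed=21,
        )
        phantom = sk.make_phantom(spec)
        res = sk.cluster_flair(phantom.flair, phantom.brain_mask)
        truth_par = np.isin(phantom.truth.data, [L.PARENCHYMA, L.NAWM])
        assert dice(res["parenchyma_cluster"], truth_par) >= 0.99
        assert abs(res["reference_mean"] - 300.0) < 1.0

    def test_no_lesion_outlier_cluster_is_csf_only(self):
        phantom = sk.make_phantom(sk.PhantomSpec(grid_shape=(40, 40, 32), seed=22))
        res = sk.cluster_flair(phantom.flair, phantom.brain_mask)
        assert dice(res["outlier_cluster"], phantom.truth.data == L.CSF_OTHER) >= 0.99

    def test_constant_image_is_rejected_as_degenerate(self):
        flair = ImageVolume(np.full((10, 10, 10), 7.0))
        mask = ImageVolume(np.ones((10, 10, 10), dtype=np.uint8))
        with pytest.raises(ValueError, match="degenerate"):
            sk.cluster_flair(flair, mask)


class TestHyperintenseMask:
    def test_strict_threshold_boundary(self):
        data = np.zeros((3, 1, 1))
        mean, sd = 100.0, 10.0
        data[0] = mean + 2.01 * sd
        data[1] = mean + 1.99 * sd
        data[2] = mean + 2.00 * sd  # exactly at the threshold: excluded (strict)
        flair = ImageVolume(data)
        mask = ImageVolume(np.ones_like(data, dtype=np.uint8))
        hyper = sk.hyperintense_mask(flair, mask, mean, sd, k=2.0)
        assert hyper[0, 0, 0] and not hyper[1, 0, 0] and not hyper[2, 0, 0]

    def test_all_below_threshold_gives_empty_mask(self):
        flair = ImageVolume(np.full((4, 4, 4), 50.0))
        mask = ImageVolume(np.ones((4, 4, 4), dtype=np.uint8))
        assert not sk.hyperintense_mask(flair, mask, 100.0, 10.0, 2.0).any()

    def test_planted_lesion_fully_recovered_on_clean_phantom(self, clean_phantom):
        res = sk.cluster_flair(clean_phantom.flair, clean_phantom.brain_mask)
        hyper = sk.hyperintense_mask(
            clean_phantom.flair,
            clean_phantom.brain_mask,
            res["reference_mean"],
            res["reference_sd"],
            2.0,
        )
        planted = np.isin(clean_phantom.truth.data, [L.WML, L.ISCHEMIC])
        assert (hyper & planted).sum() == planted.sum()

    @pytest.mark.parametrize("ks", [(1.0, 2.0), (2.0, 3.0), (0.5, 4.0)])
    def test_increasing_multiplier_never_enlarges_mask(self, clean_phantom, ks):
        res = sk.cluster_flair(clean_phantom.flair, clean_phantom.brain_mask)
        lo = sk.hyperintense_mask(
            clean_phantom.flair, clean_phantom.brain_mask,
            res["reference_mean"], res["reference_sd"], ks[0],
        )
        hi = sk.hyperintense_mask(
            clean_phantom.flair, clean_phantom.brain_mask,
            res["reference_mean"], res["reference_sd"], ks[1],
        )
        assert not (hi & ~lo).any()


class TestClassifyLesions:
    def blob_scene(self, n_blobs=10, small=1):
        """n_blobs cubic lesions on a flat DWI background; ``small`` of them
        are 2-voxel components."""
        shape = (40, 40, 12)
        rng = np.random.default_rng(0)
        hyper = np.zeros(shape, dtype=bool)
        dwi = np.full(shape, 100.0) + rng.normal(0, 1.0, shape)
        positions = [(4 + 7 * (i % 5), 4 + 7 * (i // 5), 5) for i in range(n_blobs)]
        for i, (x, y, z) in enumerate(positions):
            if i < small:
                hyper[x : x + 2, y, z] = True
            else:
                hyper[x : x + 2, y : y + 2, z : z + 2] = True
        dwi[hyper] = 200.0
        return hyper, ImageVolume(dwi), ImageVolume(np.ones(shape, dtype=np.uint8))

    def test_dwi_conjunction_splits_ischemic_from_wml(self):
        hyper, dwi, brain = self.blob_scene(n_blobs=2, small=0)
        # make the second blob DWI-normal -> WML
        dwi.data[hyper] = 200.0
        second = np.zeros_like(hyper)
        second[11:13, 4:6, 5:7] = True
        dwi.data[second] = 100.0
        res = sk.classify_lesions(hyper, dwi, brain)
        assert res["ischemic"][4, 4, 5] and not res["wml"][4, 4, 5]
        assert res["wml"][11, 4, 5] and not res["ischemic"][11, 4, 5]
        # exact set identity with no size filtering
        assert np.array_equal(res["wml"] | res["ischemic"], hyper)

    def test_min_size_filter_matches_brute_force_component_counting(self):
        hyper, dwi, brain = self.blob_scene(n_blobs=10, small=1)
        cfg = sk.SegmentationConfig(min_lesion_voxels=3)
        res = sk.classify_lesions(hyper, dwi, brain, cfg)
        detected = bfs_component_sizes(res["ischemic"])
        assert len(detected) == 9
        # oracle: the same count from independent component enumeration
        oracle = [s for s in bfs_component_sizes(hyper) if s >= 3]
        assert len(detected) == len(oracle)
        assert sum(detected) == sum(oracle)


class TestNawmMask:
    def test_fa_threshold_is_strict(self):
        fa = np.zeros((3, 1, 1))
        fa[0], fa[1], fa[2] = 0.2, 0.45, 0.1999
        maps = sk.DiffusivityMaps(
            fa=ImageVolume(fa),
            md=ImageVolume(fa * 0),
            da=ImageVolume(fa * 0),
            dr=ImageVolume(fa * 0),
            valid_mask=np.ones((3, 1, 1), dtype=bool),
        )
        par = np.ones((3, 1, 1), dtype=bool)
        out = sk.nawm_mask(par, maps)
        assert not out[0, 0, 0]  # FA exactly 0.2 excluded
        assert out[1, 0, 0]
        assert not out[2, 0, 0]

    def test_nawm_recovery_on_phantom(self, clean_phantom, clean_maps):
        res = sk.cluster_flair(clean_phantom.flair, clean_phantom.brain_mask)
        lesion = np.isin(clean_phantom.truth.data, [L.WML, L.ISCHEMIC])
        nawm = sk.nawm_mask(res["parenchyma_cluster"], clean_maps, lesion_mask=lesion)
        assert dice(nawm, clean_phantom.truth.data == L.NAWM) >= 0.98


class TestSummaries:
    def test_volume_arithmetic(self):
        lab = np.zeros((5, 5, 5), dtype=np.int16)
        lab.flat[:10] = L.WML
        seg = sk.TissueSegmentation(
            labels=ImageVolume(lab, (2.0, 2.0, 2.0)),
            reference_mean=0.0,
            reference_sd=1.0,
            icv_mm3=1000.0,
        )
        tab = sk.summarize_tissues(seg)
        assert tab.loc["wml", "volume_mm3"] == 80.0
        assert tab.loc["wml", "relative_volume_pct"] == pytest.approx(8.0)
        # empty class: zero volume, missing diffusivity means
        assert tab.loc["ischemic", "volume_mm3"] == 0.0
        assert np.isnan(tab.loc["ischemic", "mean_md"])

    def test_published_volume_and_icv_give_printed_relative_volume(self):
        lab = np.zeros((160, 160, 80), dtype=np.int16)
        lab.flat[:18203] = L.WML  # 18203 voxels at 1 mm iso
        seg = sk.TissueSegmentation(
            labels=ImageVolume(lab),
            reference_mean=0.0,
            reference_sd=1.0,
            icv_mm3=1348527.0,
        )
        tab = sk.summarize_tissues(seg)
        assert round(tab.loc["wml", "relative_volume_pct"], 1) == 1.3


class TestEndToEnd:
    def test_clean_phantom_class_volumes_within_2pct_and_invariants(
        self, clean_phantom, clean_maps
    ):
        seg = sk.segment_subject(
            clean_phantom.flair,
            clean_phantom.dwi_b1000,
            clean_maps,
            clean_phantom.brain_mask,
        )
        truth = clean_phantom.truth.data
        for code in (L.CSF_OTHER, L.WML, L.ISCHEMIC, L.NAWM):
            planted = (truth == code).sum()
            got = seg.mask(code).sum()
            assert abs(got - planted) <= 0.02 * planted, L.NAMES[code]
            assert dice(seg.mask(code), truth == code) >= 0.98
        # disjointness and containment invariants
        assert not (seg.mask(L.WML) & seg.mask(L.ISCHEMIC)).any()
        assert not (seg.mask(L.WML) & seg.mask(L.NAWM)).any()
        assert (seg.mask(L.NAWM) <= seg.parenchyma).all()
        assert seg.icv_mm3 == clean_phantom.brain_mask.data.sum() * 8.0
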