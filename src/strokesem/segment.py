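"""Semi-automatic multimodal tissue segmentation.

The procedure mirrors a FLAIR-driven lesion segmentation workflow:

1. Two-cluster split of the brain's FLAIR intensities into a parenchymal
   (normal-appearing white + gray matter) cluster and an "other" cluster
   (CSF plus clearly hyperintense areas). Because CSF is dark and lesions are
   bright, the clustering runs on the absolute deviation of intensity from
   the robust parenchymal mode (the median over the brain), so both tails
   fall into the same outlier cluster. k-means with k = 2 and fixed
   quantile-based initialization keeps the step deterministic.
2. Reference statistics (mean, SD) of the parenchymal cluster define the
   hyperintensity threshold: voxels strictly above mean + k*SD (default
   k = 2) are candidate lesions.
3. Conjunction with DWI separates acute ischemic lesions (also hyperintense
   on DWI, same mean + k*SD rule on parenchymal DWI intensities) from
   chronic white-matter lesions (FLAIR-hyperintense only). Connected
   components smaller than ``min_lesion_voxels`` are dropped.
4. Normal-appearing white matter (NAWM) is the parenchymal cluster masked to
   FA strictly above ``fa_min`` (default 0.2, suppressing gray matter and
   partial-volume voxels) minus all detected lesion voxels.

Volumes are reported absolutely (mm^3) and relative to the intracranial
volume (ICV = brain-mask volume), together with per-tissue mean FA/MD/Da/Dr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from . import labels as L
from .dti import DiffusivityMaps, TensorField
from .volume import ImageVolume

__all__ = [
    "SegmentationConfig",
    "TissueSegmentation",
    "cluster_flair",
    "hyperintense_mask",
    "classify_lesions",
    "nawm_mask",
    "summarize_tissues",
    "segment_subject",
]

# 26-connectivity for lesion components
_STRUCT = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    sd_multiplier: float = 2.0
    fa_min: float = 0.2
    dwi_sd_multiplier: float = 2.0
    min_lesion_voxels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0 or self.dwi_sd_multiplier <= 0:
            raise ValueError("SD multipliers must be positive")
        if not (0.0 < self.fa_min < 1.0):
            raise ValueError("fa_min must lie in (0, 1)")
        if self.min_lesion_voxels < 0:
            raise ValueError("min_lesion_voxels must be non-negative")


@dataclass
class TissueSegmentation:
    labels: ImageVolume  # codes from strokesem.labels
    reference_mean: float  # parenchymal FLAIR mean
    reference_sd: float
    icv_mm3: float
    dwi_reference_mean: float | None = None
    dwi_reference_sd: float | None = None

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels.data, codes)

    @property
    def parenchyma(self) -> np.ndarray:
        # the NAWM subset keeps its own code, so the band is the union
        return self.mask(L.PARENCHYMA, L.NAWM)


def _check_grid(a: ImageVolume, b: ImageVolume, what: str) -> None:
    if not a.same_grid(b):
        raise ValueError(f"{what} is not on the same grid")


def cluster_flair(
    flair: ImageVolume, brain_mask: ImageVolume, cfg: SegmentationConfig | None = None
) -> dict:
    """Two-cluster split of brain FLAIR into parenchyma vs CSF/hyperintensity.

    Returns parenchyma/outlier boolean masks plus the parenchymal reference
    mean and SD that drive the hyperintensity threshold.
    """
    cfg = cfg or SegmentationConfig()
    _check_grid(flair, brain_mask, "brain mask")
    brain = brain_mask.data.astype(bool)
    vals = flair.data[brain].astype(float)
    if vals.size == 0:
        raise ValueError("empty brain mask")
    if vals.std() < max(1e-12, 1e-9 * max(abs(vals.mean()), 1.0)):
        raise ValueError("degenerate FLAIR image: near-constant intensities in brain")

    # distance from the robust parenchymal mode; CSF (dark) and lesions
    # (bright) both map to large values
    mode = np.median(vals)
    feature = np.abs(vals - mode)[:, None]
    init = np.array([[np.quantile(feature, 0.25)], [np.quantile(feature, 0.995)]])
    km = KMeans(n_clusters=2, init=init, n_init=1, random_state=cfg.seed).fit(feature)
    parenchyma_id = int(np.argmin(km.cluster_centers_.ravel()))
    assign = km.labels_ == parenchyma_id

    parenchyma = np.zeros(flair.shape, dtype=bool)
    parenchyma[brain] = assign
    outlier = brain & ~parenchyma
    ref = flair.data[parenchyma]
    return {
        "parenchyma_cluster": parenchyma,
        "outlier_cluster": outlier,
        "reference_mean": float(ref.mean()),
        "reference_sd": float(ref.std(ddof=1)),
    }


def hyperintense_mask(
    flair: ImageVolume,
    brain_mask: ImageVolume,
    reference_mean: float,
    reference_sd: float,
    k: float = 2.0,
) -> np.ndarray:
    """Brain voxels strictly above reference_mean + k * reference_sd."""
    if reference_sd <= 0:
        raise ValueError("reference SD must be positive")
    _check_grid(flair, brain_mask, "brain mask")
    return brain_mask.data.astype(bool) & (flair.data > reference_mean + k * reference_sd)


def _drop_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 0 or not mask.any():
        return mask
    lab, n = ndimage.label(mask, structure=_STRUCT)
    sizes = np.bincount(lab.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_voxels
    return keep[lab]


def classify_lesions(
    hyper: np.ndarray,
    dwi: ImageVolume,
    brain_mask: ImageVolume,
    cfg: SegmentationConfig | None = None,
    reference_mask: np.ndarray | None = None,
) -> dict:
    """Split FLAIR-hyperintense voxels into ischemic (DWI-hyperintense too)
    and WML (FLAIR only); drop components below ``min_lesion_voxels``.

    ``reference_mask`` gives the voxels whose DWI intensities define the DWI
    hyperintensity threshold; defaults to non-hyperintense brain.
    """
    cfg = cfg or SegmentationConfig()
    _check_grid(dwi, brain_mask, "brain mask")
    brain = brain_mask.data.astype(bool)
    if reference_mask is None:
        reference_mask = brain & ~hyper
    ref = dwi.data[reference_mask]
    mean, sd = float(ref.mean()), float(ref.std(ddof=1))
    dwi_hyper = dwi.data > mean + cfg.dwi_sd_multiplier * sd
    ischemic = hyper & dwi_hyper & brain
    wml = hyper & brain & ~ischemic
    return {
        "wml": _drop_small_components(wml, cfg.min_lesion_voxels),
        "ischemic": _drop_small_components(ischemic, cfg.min_lesion_voxels),
        "dwi_reference_mean": mean,
        "dwi_reference_sd": sd,
    }


def nawm_mask(
    parenchyma_cluster: np.ndarray,
    maps: DiffusivityMaps,
    cfg: SegmentationConfig | None = None,
    lesion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Parenchymal voxels with FA strictly above fa_min, minus lesions."""
    cfg = cfg or SegmentationConfig()
    out = parenchyma_cluster & (maps.fa.data > cfg.fa_min)
    if lesion_mask is not None:
        out = out & ~lesion_mask
    return out


def summarize_tissues(
    seg: TissueSegmentation, maps: DiffusivityMaps | None = None
) -> pd.DataFrame:
    """Per-tissue voxel counts, absolute/relative volumes and diffusivity means."""
    voxvol = seg.labels.voxel_volume_mm3
    rows = []
    for code in (L.CSF_OTHER, L.PARENCHYMA, L.WML, L.ISCHEMIC, L.NAWM):
        sel = seg.mask(code) if code != L.PARENCHYMA else seg.parenchyma
        n = int(sel.sum())
        row = {
            "tissue": L.NAMES[code],
            "n_voxels": n,
            "volume_mm3": n * voxvol,
            "relative_volume_pct": 100.0 * n * voxvol / seg.icv_mm3,
        }
        for name in ("fa", "md", "da", "dr"):
            if maps is None or n == 0:
                row[f"mean_{name}"] = np.nan
            else:
                use = sel & maps.valid_mask
                row[f"mean_{name}"] = (
                    float(getattr(maps, name).data[use].mean()) if use.any() else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("tissue")


def segment_subject(
    flair: ImageVolume,
    dwi: ImageVolume,
    maps: DiffusivityMaps,
    brain_mask: ImageVolume,
    cfg: SegmentationConfig | None = None,
) -> TissueSegmentation:
    """Full segmentation of one subject from co-registered inputs."""
    cfg = cfg or SegmentationConfig()
    clusters = cluster_flair(flair, brain_mask, cfg)
    hyper = hyperintense_mask(
        flair, brain_mask, clusters["reference_mean"], clusters["reference_sd"], cfg.sd_multiplier
    )
    lesions = classify_lesions(
        hyper, dwi, brain_mask, cfg, reference_mask=clusters["parenchyma_cluster"] & ~hyper
    )
    lesion_any = lesions["wml"] | lesions["ischemic"]
    nawm = nawm_mask(clusters["parenchyma_cluster"], maps, cfg, lesion_mask=lesion_any)

    brain = brain_mask.data.astype(bool)
    lab = np.zeros(flair.shape, dtype=np.int16)
    lab[brain] = L.CSF_OTHER
    lab[clusters["parenchyma_cluster"]] = L.PARENCHYMA
    lab[nawm] = L.NAWM
    lab[lesions["wml"]] = L.WML
    lab[lesions["ischemic"]] = L.ISCHEMIC

    return TissueSegmentation(
        labels=ImageVolume(lab, flair.voxel_size),
        reference_mean=clusters["reference_mean"],
        reference_sd=clusters["reference_sd"],
        icv_mm3=float(brain.sum()) * flair.voxel_volume_mm3,
        dwi_reference_mean=lesions["dwi_reference_mean"],
        dwi_reference_sd=lesions["dwi_reference_sd"],
    )
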