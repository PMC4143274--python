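"""Synthetic multimodal brain phantoms with known tissue labels.

Geometry is deliberately simple and analytically checkable: the brain is an
axis-aligned ellipsoid containing a central ellipsoidal CSF (ventricle)
compartment, an outer gray-matter band and a white-matter interior; lesions
are spheres planted at user-specified voxel coordinates. Every voxel carries
a ground-truth label, so segmentation accuracy can be scored exactly.

Signal model per voxel:

* FLAIR and b0 intensities are drawn from per-class Gaussian distributions
  (arbitrary units); lesion FLAIR intensity is offset from the white-matter
  reference by a stated number of reference standard deviations.
* The diffusion-weighted series follows the monoexponential tensor model
  S = S0 * exp(-b g^T D g) with a per-class diagonal tensor (eigenvalue
  means/SDs in mm^2/s), before optional Gaussian or Rician acquisition noise.
  Acute ischemic tissue gets restricted diffusion, hence DWI hyperintensity;
  chronic WML gets elevated diffusivity, hence no DWI hyperintensity.

Everything is a pure function of (spec, seed): the same spec yields
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import labels as L
from .dti import DiffusionAcquisition, fibonacci_directions
from .volume import ImageVolume

__all__ = ["Lesion", "PhantomSpec", "Phantom", "make_phantom", "DEFAULT_TENSOR_PROFILES"]

# Eigenvalue means (mm^2/s) chosen at typical adult values: white matter and
# white-matter-lesion profiles at (1.2, 0.78, 0.55)e-3 and (1.6, 1.1, 0.97)e-3
# respectively; gray matter and CSF nearly isotropic; acute ischemia with
# restricted diffusion.
DEFAULT_TENSOR_PROFILES: dict[int, tuple[tuple[float, float, float], float]] = {
    L.NAWM: ((1.2e-3, 0.78e-3, 0.55e-3), 4e-5),
    L.PARENCHYMA: ((0.85e-3, 0.80e-3, 0.75e-3), 4e-5),  # gray-matter band
    L.CSF_OTHER: ((3.0e-3, 2.9e-3, 2.8e-3), 1e-4),
    L.WML: ((1.6e-3, 1.1e-3, 0.97e-3), 4e-5),
    L.ISCHEMIC: ((0.40e-3, 0.35e-3, 0.30e-3), 3e-5),
}

DEFAULT_FLAIR = {
    L.NAWM: (300.0, 10.0),
    L.PARENCHYMA: (300.0, 10.0),
    L.CSF_OTHER: (120.0, 10.0),
}
DEFAULT_B0 = {
    L.NAWM: (1000.0, 20.0),
    L.PARENCHYMA: (1000.0, 20.0),
    L.CSF_OTHER: (1600.0, 30.0),
    L.WML: (1100.0, 20.0),
    L.ISCHEMIC: (1000.0, 20.0),
}


@dataclass(frozen=True)
class Lesion:
    """A spherical lesion planted into the phantom.

    ``flair_offset_sd`` is the FLAIR intensity offset in units of the
    white-matter reference SD (hyperintense for positive values).
    """

    tissue: str  # "wml" or "ischemic"
    center: tuple[int, int, int]  # voxel indices
    radius_mm: float
    flair_offset_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.tissue not in ("wml", "ischemic"):
            raise ValueError(f"lesion tissue must be 'wml' or 'ischemic', got {self.tissue!r}")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")

    @property
    def label(self) -> int:
        return L.WML if self.tissue == "wml" else L.ISCHEMIC


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 48, 40)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesions: tuple[Lesion, ...] = ()
    flair_intensities: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FLAIR)
    )
    b0_intensities: dict[int, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_B0))
    tensor_profiles: dict[int, tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: dict(DEFAULT_TENSOR_PROFILES)
    )
    noise_model: str = "gaussian"  # or "rician"
    noise_sigma: float = 0.0
    # Class intensities are truncated Gaussians (bounds at +-k within-class
    # SDs). Real parenchymal FLAIR spread is bounded, and an unbounded
    # Gaussian would place a fixed ~2% of reference tissue above any
    # mean + 2 SD threshold no matter how clean the image; truncation keeps
    # clean phantoms exactly separable. None selects a pure Gaussian.
    intensity_truncation_sd: float | None = 1.5
    b_value: float = 1000.0
    n_directions: int = 15
    brain_fraction: float = 0.94  # ellipsoid semi-axes as fraction of half-extent
    gray_band_inner: float = 0.85  # elliptical radius where the gray band starts
    ventricle_fraction: float = 0.28  # ventricle semi-axes as fraction of brain axes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for lam, _sd in self.tensor_profiles.values():
            l1, l2, l3 = lam
            if not (l1 >= l2 >= l3 > 0):
                raise ValueError(f"tensor profile eigenvalues must satisfy l1>=l2>=l3>0, got {lam}")


@dataclass
class Phantom:
    flair: ImageVolume
    dwi_b0: ImageVolume
    dwi_b1000: ImageVolume
    dwi_series: DiffusionAcquisition
    truth: ImageVolume
    brain_mask: ImageVolume


def _elliptical_radius(spec: PhantomSpec) -> np.ndarray:
    """Normalized elliptical radius of every voxel center (1.0 = brain surface)."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    vox = np.asarray(spec.voxel_size, dtype=float)
    center = (shape - 1) / 2.0 * vox
    axes = spec.brain_fraction * (shape - 1) / 2.0 * vox
    grids = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(spec.grid_shape, vox)], indexing="ij"
    )
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return np.sqrt(rho2)


def _sphere_mask(spec: PhantomSpec, lesion: Lesion) -> np.ndarray:
    vox = np.asarray(spec.voxel_size, dtype=float)
    center_mm = np.asarray(lesion.center, dtype=float) * vox
    grids = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(spec.grid_shape, vox)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= lesion.radius_mm**2


def _truth_labels(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    rho = _elliptical_radius(spec)
    brain = rho <= 1.0
    truth = np.full(spec.grid_shape, L.OUTSIDE, dtype=np.int16)
    truth[brain] = L.NAWM
    truth[brain & (rho > spec.gray_band_inner)] = L.PARENCHYMA
    truth[rho <= spec.ventricle_fraction] = L.CSF_OTHER

    planted = np.zeros(spec.grid_shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        sphere = _sphere_mask(spec, lesion)
        if not sphere.any():
            raise ValueError(f"lesion {i} covers no voxel on this grid")
        if np.any(sphere & ~brain):
            raise ValueError(f"lesion {i} extends outside the brain ellipsoid")
        if np.any(sphere & planted):
            raise ValueError(f"lesion {i} overlaps a previously planted lesion")
        planted |= sphere
        truth[sphere] = lesion.label
    return truth, brain


def _draw_intensity(
    rng: np.random.Generator, mean: float, sd: float, n: int, trunc: float | None
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    if trunc is None:
        return rng.normal(mean, sd, n)
    z = truncnorm.rvs(-trunc, trunc, size=n, random_state=rng)
    return mean + sd * z


def _add_noise(rng: np.random.Generator, img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.noise_sigma == 0:
        return img
    if spec.noise_model == "gaussian":
        return img + rng.normal(0.0, spec.noise_sigma, img.shape)
    # Rician: magnitude of a complex Gaussian centred on the true signal
    re = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    im = rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.sqrt(re**2 + im**2)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate all modalities plus ground truth for one subject."""
    rng = np.random.default_rng(spec.seed)
    truth, brain = _truth_labels(spec)

    flair = np.zeros(spec.grid_shape)
    b0 = np.zeros(spec.grid_shape)
    lam = np.zeros(spec.grid_shape + (3,))

    ref_mean, ref_sd = spec.flair_intensities[L.NAWM]
    for code in (L.CSF_OTHER, L.PARENCHYMA, L.NAWM, L.WML, L.ISCHEMIC):
        sel = truth == code
        n = int(sel.sum())
        if n == 0:
            continue
        if code in (L.WML, L.ISCHEMIC):
            # drawn at the reference; hyperintense offset added per lesion below
            mean, sd = ref_mean, ref_sd
        else:
            mean, sd = spec.flair_intensities[code]
        flair[sel] = _draw_intensity(rng, mean, sd, n, spec.intensity_truncation_sd)
        m0, s0 = spec.b0_intensities[code]
        b0[sel] = _draw_intensity(rng, m0, s0, n, spec.intensity_truncation_sd)
        lam_mean, lam_sd = spec.tensor_profiles[code]
        vals = np.asarray(lam_mean) + rng.normal(0.0, lam_sd, (n, 3))
        vals = np.sort(np.clip(vals, 1e-6, None), axis=1)[:, ::-1]
        lam[sel] = vals

    # hyperintensity offset in reference-SD units, per lesion
    for lesion in spec.lesions:
        flair[_sphere_mask(spec, lesion)] += lesion.flair_offset_sd * ref_sd

    # diffusion series: axis-aligned diagonal tensors
    dirs = fibonacci_directions(spec.n_directions)
    bvals = np.concatenate([[0.0], np.full(spec.n_directions, spec.b_value)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    nvol = 1 + spec.n_directions
    signals = np.zeros(spec.grid_shape + (nvol,))
    signals[..., 0] = b0
    for k, g in enumerate(dirs):
        adc = (lam * g[None, None, None, :] ** 2).sum(axis=-1)
        signals[..., 1 + k] = b0 * np.exp(-spec.b_value * adc)
    signals[~brain] = 0.0

    flair = _add_noise(rng, flair, spec)
    signals = _add_noise(rng, signals, spec)
    flair[~brain] = 0.0
    signals[~brain] = 0.0

    dwi_b1000 = signals[..., 1:].mean(axis=-1)
    vs = spec.voxel_size
    return Phantom(
        flair=ImageVolume(flair, vs),
        dwi_b0=ImageVolume(signals[..., 0], vs),
        dwi_b1000=ImageVolume(dwi_b1000, vs),
        dwi_series=DiffusionAcquisition(signals, bvals, bvecs, vs),
        truth=ImageVolume(truth, vs),
        brain_mask=ImageVolume(brain.astype(np.uint8), vs),
    )
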