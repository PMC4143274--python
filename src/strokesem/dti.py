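"""Diffusion-tensor fitting and scalar map computation.

The tensor is estimated per voxel by ordinary least squares on log-signals
(the classic log-linear estimator): for each diffusion-weighted volume with
b-value b and unit gradient direction g,

    ln S = ln S0 - b * g^T D g,

a linear system in the six unique tensor elements. Eigen-decomposition of the
fitted tensor yields lambda1 >= lambda2 >= lambda3, from which the four
standard maps follow:

    MD = (l1 + l2 + l3) / 3        mean diffusivity
    Da = l1                        axial diffusivity
    Dr = (l2 + l3) / 2             radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy in [0, 1]

Negative eigenvalues (possible under noise) are clamped to zero and the voxel
is flagged; voxels with non-positive b0 signal are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import ImageVolume

__all__ = [
    "DiffusionAcquisition",
    "TensorField",
    "DiffusivityMaps",
    "fit_tensor",
    "diffusivity_maps",
    "fibonacci_directions",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

_MIN_DIRECTIONS = 6


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    dirs = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map the 6 unique tensor elements to b * g^T D g."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return bvals[:, None] * np.stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1
    )


@dataclass
class DiffusionAcquisition:
    """A co-registered DWI series with its b-values and gradient table.

    ``signals`` is a 4-D array (x, y, z, volume); gradient directions are unit
    3-vectors for b > 0 volumes and ignored for b = 0.
    """

    signals: np.ndarray
    b_values: np.ndarray
    gradient_directions: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.gradient_directions = np.asarray(self.gradient_directions, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be a 4-D (x, y, z, volume) array")
        nvol = self.signals.shape[3]
        if self.b_values.shape != (nvol,):
            raise ValueError("one b-value per volume required")
        if self.gradient_directions.shape != (nvol, 3):
            raise ValueError("one gradient 3-vector per volume required")

    @property
    def b0_index(self) -> np.ndarray:
        return self.b_values <= 0

    def validate_for_fit(self) -> None:
        if not np.any(self.b0_index):
            raise ValueError("at least one b=0 volume is required")
        dw = ~self.b0_index
        if dw.sum() < _MIN_DIRECTIONS:
            raise ValueError(f"at least {_MIN_DIRECTIONS} diffusion-weighted volumes required")
        design = _design_matrix(self.b_values[dw], self.gradient_directions[dw])
        if np.linalg.matrix_rank(design) < 6:
            raise ValueError("gradient directions do not span 6 tensor components (collinear set)")


@dataclass
class TensorField:
    """Per-voxel tensor eigensystem, eigenvalues sorted descending (mm^2/s)."""

    eigenvalues: np.ndarray  # (x, y, z, 3)
    eigenvectors: np.ndarray  # (x, y, z, 3, 3), columns are eigenvectors
    valid_mask: np.ndarray  # fit succeeded
    clamped_mask: np.ndarray  # negative eigenvalue clamped to 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class DiffusivityMaps:
    fa: ImageVolume
    md: ImageVolume
    da: ImageVolume
    dr: ImageVolume
    valid_mask: np.ndarray

    def save(self, directory: str | Path, prefix: str = "") -> dict[str, Path]:
        directory = Path(directory)
        out = {}
        for name in ("fa", "md", "da", "dr"):
            out[name] = getattr(self, name).save(directory / f"{prefix}{name}.nii.gz")
        return out


def fit_tensor(acq: DiffusionAcquisition, mask: ImageVolume) -> TensorField:
    """OLS log-linear tensor fit at every voxel of ``mask``."""
    acq.validate_for_fit()
    if mask.data.shape != acq.signals.shape[:3]:
        raise ValueError("mask grid does not match the DWI series")
    shape = acq.signals.shape[:3]
    in_mask = mask.data.astype(bool)

    b0 = acq.signals[..., acq.b0_index].mean(axis=-1)
    dw = ~acq.b0_index
    design = _design_matrix(acq.b_values[dw], acq.gradient_directions[dw])
    pinv = np.linalg.pinv(design)  # (6, ndir); one solve shared by every voxel

    valid = in_mask & (b0 > 0)
    sig = acq.signals[valid][:, dw]  # (nvox, ndir)
    # signals must be positive for the log; tiny clips only arise under noise
    sig = np.clip(sig, 1e-12, None)
    y = np.log(b0[valid])[:, None] - np.log(sig)  # = b g^T D g
    d6 = y @ pinv.T  # (nvox, 6)

    tensors = np.empty((d6.shape[0], 3, 3))
    tensors[:, 0, 0] = d6[:, 0]
    tensors[:, 1, 1] = d6[:, 1]
    tensors[:, 2, 2] = d6[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = d6[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = d6[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = d6[:, 5]

    w, v = np.linalg.eigh(tensors)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    clamped = w < 0
    w = np.clip(w, 0.0, None)

    eigenvalues = np.zeros(shape + (3,))
    eigenvectors = np.zeros(shape + (3, 3))
    eigenvectors[..., :, :] = np.eye(3)
    clamp_map = np.zeros(shape, dtype=bool)
    eigenvalues[valid] = w
    eigenvectors[valid] = v
    clamp_map[valid] = clamped.any(axis=1)

    return TensorField(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        valid_mask=valid,
        clamped_mask=clamp_map,
        voxel_size=mask.voxel_size,
    )


def diffusivity_maps(t: TensorField) -> DiffusivityMaps:
    """FA/MD/Da/Dr maps from a fitted tensor field.

    The identity MD = (Da + 2 Dr) / 3 holds exactly by construction; an
    all-zero tensor gets FA = 0.
    """
    lam = t.eigenvalues
    da = lam[..., 0]
    dr = (lam[..., 1] + lam[..., 2]) / 2.0
    md = (da + 2.0 * dr) / 3.0  # identity MD = (Da + 2 Dr) / 3 holds bitwise
    mean = lam.mean(axis=-1)
    ssq = (lam**2).sum(axis=-1)
    dev = ((lam - mean[..., None]) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(ssq > 0, dev / np.where(ssq > 0, ssq, 1.0), 0.0))
    fa = np.where(ssq > 0, fa, 0.0)
    vs = t.voxel_size
    return DiffusivityMaps(
        fa=ImageVolume(fa, vs),
        md=ImageVolume(md, vs),
        da=ImageVolume(da, vs),
        dr=ImageVolume(dr, vs),
        valid_mask=t.valid_mask.copy(),
    )


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-convention text gradient table: bvals one row, bvecs three rows."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvec table does not match bval count")
    return bvals, bvecs


def write_bvals_bvecs(
    bvals: np.ndarray, bvecs: np.ndarray, bval_path: str | Path, bvec_path: str | Path
) -> None:
    np.savetxt(bval_path, np.asarray(bvals)[None, :], fmt="%g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.8f")
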