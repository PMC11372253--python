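"""Simulated PET acquisition of the filled phantom.

The acquisition model is deliberately simple and matches how the phantom's
images are analysed: a piecewise-constant activity map (compartments fill
uniformly), an isotropic Gaussian point-spread function at the scanner's
effective resolution (6.36 mm FWHM default — the mean reconstructed
resolution within a 10-cm field of view of a clinical TOF PET/CT), optional
block-mean resampling to a coarser PET grid, and an optional voxelwise
Poisson noise surrogate.  Attenuation, scatter, randoms and sinogram-domain
reconstruction are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fill_planner import FillPlan
from .volume import BACKGROUND, ActivityVolume

__all__ = [
    "FWHM_TO_SIGMA",
    "DEFAULT_FWHM_MM",
    "PSFModel",
    "build_activity_map",
    "apply_psf",
    "resample_to_pet_grid",
    "add_noise",
]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_FWHM_MM = 6.36


@dataclass
class PSFModel:
    """Gaussian PSF given as per-axis FWHM in mm."""

    fwhm_mm: float | tuple[float, float, float] = DEFAULT_FWHM_MM

    def __post_init__(self) -> None:
        if np.isscalar(self.fwhm_mm):
            self.fwhm_mm = (float(self.fwhm_mm),) * 3
        else:
            self.fwhm_mm = tuple(float(v) for v in self.fwhm_mm)
        if any(f <= 0 for f in self.fwhm_mm):
            raise ValueError("FWHM must be positive")

    @property
    def sigma_mm(self) -> tuple[float, float, float]:
        return tuple(f * FWHM_TO_SIGMA for f in self.fwhm_mm)


def build_activity_map(model, plan: FillPlan) -> ActivityVolume:
    """Piecewise-constant activity: each voxel takes its compartment's
    scan-time concentration; background is zero."""
    vol = model.labels
    labels = [l for l in vol.counts() if l != BACKGROUND]
    missing = [l for l in labels if l not in plan.concentrations_kBq_per_mL]
    if missing:
        raise ValueError(f"fill plan missing compartments {missing}")
    data = np.zeros(vol.data.shape, dtype=np.float64)
    for lbl in labels:
        data[vol.data == lbl] = plan.concentration(lbl)
    return ActivityVolume(
        data=data,
        voxel_size_mm=vol.voxel_size_mm,
        affine=vol.affine.copy(),
        provenance={"stage": "activity_map"},
    )


def apply_psf(
    act: ActivityVolume, psf: PSFModel, boundary: str = "constant"
) -> ActivityVolume:
    """Separable Gaussian convolution with the PSF.

    Zero-padding boundary by default (the phantom sits in inactive
    surroundings); total activity is conserved as long as the activity keeps
    a few-sigma margin from the grid edge.
    """
    sigma_vox = [s / v for s, v in zip(psf.sigma_mm, act.voxel_size_mm)]
    if any(f < v for f, v in zip(psf.fwhm_mm, act.voxel_size_mm)):
        warnings.warn("PSF FWHM below voxel size: kernel is under-resolved")
    blurred = ndimage.gaussian_filter(act.data, sigma=sigma_vox, mode=boundary, truncate=5.0)
    return act.copy_with(blurred, psf_fwhm_mm=psf.fwhm_mm, stage="blurred")


def resample_to_pet_grid(
    act: ActivityVolume, pet_voxel_mm: float | tuple[float, float, float]
) -> ActivityVolume:
    """Downsample to the PET grid by volume-weighted block mean.

    Integer spacing ratios use exact block averaging (conserves total
    activity); non-integer ratios fall back to trilinear interpolation, with
    a warning, which only approximately conserves activity.
    """
    if np.isscalar(pet_voxel_mm):
        target = (float(pet_voxel_mm),) * 3
    else:
        target = tuple(float(v) for v in pet_voxel_mm)
    src = act.voxel_size_mm
    if any(t < s - 1e-12 for t, s in zip(target, src)):
        raise ValueError("PET voxel size must not be finer than the model grid")
    ratios = [t / s for t, s in zip(target, src)]
    if all(abs(r - round(r)) < 1e-9 for r in ratios):
        block = [int(round(r)) for r in ratios]
        shape = act.data.shape
        trim = [n - n % b for n, b in zip(shape, block)]
        data = act.data[: trim[0], : trim[1], : trim[2]]
        data = data.reshape(
            trim[0] // block[0], block[0], trim[1] // block[1], block[1], trim[2] // block[2], block[2]
        ).mean(axis=(1, 3, 5))
    else:
        warnings.warn("non-integer PET/model spacing ratio: trilinear fallback")
        data = ndimage.zoom(act.data, [1.0 / r for r in ratios], order=1, mode="nearest")
    affine = act.affine.copy()
    scale = np.asarray(target) / np.asarray(src)
    affine[:3, :3] = affine[:3, :3] * scale[None, :]
    return ActivityVolume(
        data=data,
        voxel_size_mm=target,
        affine=affine,
        provenance={**act.provenance, "stage": "pet_grid"},
    )


def add_noise(act: ActivityVolume, counts_per_kBq: float, seed: int) -> ActivityVolume:
    """Voxelwise Poisson noise surrogate: value → Poisson(value·scale)/scale.

    Mean-preserving, so downstream ROI estimators keep their expectation; a
    fixed seed reproduces the identical volume.
    """
    if counts_per_kBq <= 0:
        raise ValueError("counts_per_kBq must be positive")
    rng = np.random.default_rng(seed)
    lam = np.clip(act.data, 0.0, None) * counts_per_kBq
    noisy = rng.poisson(lam).astype(np.float64) / counts_per_kBq
    return act.copy_with(noisy, noise_counts_per_kBq=counts_per_kBq, noise_seed=int(seed), stage="noisy")
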