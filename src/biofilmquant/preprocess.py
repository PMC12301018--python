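"""Shadow (illumination) correction, grayscale conversion and denoising.

These are the first two steps of the four-step analysis pipeline
(shadow correction, grayscale conversion, segmentation, measurement).
Confocal stacks commonly show smooth multiplicative vignetting; the default
correction divides by a heavily smoothed copy of the volume and rescales to
the original mean, which removes low-frequency gain without touching
structures much smaller than the smoothing scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .stack_io import ImageStack

__all__ = ["CorrectionModel", "shadow_correct", "to_grayscale", "denoise", "radius_to_voxels"]

_EPS = 1e-12


@dataclass
class CorrectionModel:
    """Illumination-correction settings.

    method
        ``flatfield_divide`` divides by a fitted second-order polynomial
        illumination surface (the classical vignetting model) and rescales to
        the input mean; ``rolling_ball_subtract`` subtracts a grey-opening
        background estimate with a ball of diameter ``scale``; ``none`` is
        the identity.
    scale
        Structuring length in µm used by the rolling-ball method; must be
        positive unless method is none.
    """

    method: Literal["flatfield_divide", "rolling_ball_subtract", "none"] = "flatfield_divide"
    scale: float = 50.0

    def __post_init__(self) -> None:
        if self.method not in ("flatfield_divide", "rolling_ball_subtract", "none"):
            raise ConfigError(f"unknown correction method {self.method!r}")
        if self.method != "none" and not self.scale > 0:
            raise ConfigError(f"scale must be positive for method {self.method!r}")


def radius_to_voxels(radius_um: float, voxel_size: Sequence[float]) -> tuple[int, ...]:
    """Convert a physical radius to per-axis voxel radii, rounded half-up."""
    if radius_um < 0:
        raise ConfigError("radius must be >= 0")
    return tuple(int(np.floor(radius_um / d + 0.5)) for d in voxel_size)


def _quadratic_surface(volume: np.ndarray) -> np.ndarray:
    """Least-squares fit of a full second-order polynomial in (z, y, x).

    Ten terms: constant, linear, squares and cross terms. Objects much
    smaller than the field average out of the fit, leaving the smooth
    illumination surface; a boundary-free global fit avoids the edge bias a
    windowed smoother would introduce on gradient fields.
    """
    nz, ny, nx = volume.shape
    zz, yy, xx = np.meshgrid(
        np.linspace(0, 1, nz), np.linspace(0, 1, ny), np.linspace(0, 1, nx), indexing="ij"
    )
    cols = [np.ones(volume.size), zz.ravel(), yy.ravel(), xx.ravel()]
    axes = (zz.ravel(), yy.ravel(), xx.ravel())
    cols += [axes[i] * axes[j] for i in range(3) for j in range(i, 3)]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, volume.ravel(), rcond=None)
    return (A @ coef).reshape(volume.shape)


def shadow_correct(
    volume: np.ndarray,
    model: CorrectionModel,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Remove smooth illumination gradients from a 3D intensity volume.

    The output is non-negative; for ``flatfield_divide`` the output mean is
    rescaled to the input mean so absolute intensity scales survive.
    """
    volume = np.asarray(volume, dtype=float)
    if model.method == "none":
        return volume.copy()
    if np.any(volume < 0):
        raise ConfigError("shadow_correct expects non-negative intensities")
    if model.method == "flatfield_divide":
        mean_in = volume.mean()
        if mean_in <= _EPS:  # all-zero volume: nothing to correct
            return volume.copy()
        gain = _quadratic_surface(volume)
        out = volume / np.maximum(gain, _EPS * volume.max())
        out *= mean_in / max(out.mean(), _EPS)
    else:  # rolling_ball_subtract
        radii = radius_to_voxels(model.scale / 2.0, voxel_size)
        size = tuple(2 * r + 1 for r in radii)
        background = ndimage.grey_opening(volume, size=size, mode="nearest")
        out = volume - background
    return np.clip(out, 0.0, None)


def to_grayscale(stack: ImageStack, weights: Sequence[float]) -> np.ndarray:
    """Collapse a multi-channel stack to one volume by a normalized weighted sum.

    Exposed for parity with the standard pipeline; the main quantification
    path segments each channel separately instead.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or len(weights) != stack.n_channels:
        raise ConfigError(
            f"need {stack.n_channels} weights, got {len(np.atleast_1d(weights))}"
        )
    if np.any(weights < 0):
        raise ConfigError("weights must be non-negative")
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ConfigError(f"weights must sum to 1; got {weights.sum():.6g}")
    return np.tensordot(weights, np.asarray(stack.voxels, dtype=float), axes=(0, 0))


def preprocess_stack(
    stack: ImageStack,
    correction: CorrectionModel | None = None,
    denoise_method: Literal["median", "gaussian", "none"] = "none",
    denoise_radius_um: float = 0.0,
) -> ImageStack:
    """Apply shadow correction and denoising to every channel of a stack."""
    channels = []
    for c in range(stack.n_channels):
        vol = np.asarray(stack.voxels[c], dtype=float)
        if correction is not None and correction.method != "none":
            vol = shadow_correct(vol, correction, stack.voxel_size)
        if denoise_method != "none":
            vol = denoise(vol, denoise_method, denoise_radius_um, stack.voxel_size)
        channels.append(vol)
    return ImageStack(
        np.stack(channels), stack.voxel_size, stack.channel_labels, stack.depth_origin
    )


def denoise(
    volume: np.ndarray,
    method: Literal["median", "gaussian", "none"] = "median",
    radius_um: float = 0.5,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Denoise a 3D volume with a median or Gaussian filter of physical radius.

    ``none`` returns the input unchanged (bitwise). Radii are converted to
    per-axis voxel units, respecting anisotropy.
    """
    volume = np.asarray(volume)
    if radius_um < 0:
        raise ConfigError("denoise radius must be >= 0")
    if method == "none":
        return volume.copy()
    if method == "median":
        radii = radius_to_voxels(radius_um, voxel_size)
        size = tuple(2 * r + 1 for r in radii)
        if all(s == 1 for s in size):
            return volume.astype(float, copy=True)
        return ndimage.median_filter(volume.astype(float), size=size, mode="nearest")
    if method == "gaussian":
        sigmas = tuple(radius_um / d for d in voxel_size)
        return ndimage.gaussian_filter(volume.astype(float), sigma=sigmas, mode="nearest")
    raise ConfigError(f"unknown denoise method {method!r}")
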