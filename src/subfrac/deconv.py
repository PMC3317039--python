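"""Fixed-iteration Richardson–Lucy deconvolution of confocal channels.

Richardson–Lucy is the maximum-likelihood restoration for Poisson-corrupted
images blurred by a known point-spread function.  The pipeline runs a small,
fixed number of multiplicative updates (default 3) per channel rather than
iterating to convergence: a handful of iterations sharpens puncta enough for
thresholded counting while avoiding the noise amplification that late
iterations bring.  Boundaries are handled by reflective padding so that rim
structures (the marker ring is always near the field edge of a tightly
framed soma) are not dimmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ValidationError

_EPS = 1e-12


@dataclass
class PSFModel:
    """Gaussian-parametric or explicitly supplied point-spread function."""

    kind: str = "gaussian_parametric"  # or "supplied_kernel"
    sigma_lateral_um: float = 0.2
    sigma_axial_um: float = 0.4
    kernel: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_parametric", "supplied_kernel"):
            raise ValidationError(f"unknown PSF kind {self.kind!r}")
        if self.kind == "supplied_kernel":
            if self.kernel is None:
                raise ValidationError("supplied_kernel PSF needs a kernel array")
            k = np.asarray(self.kernel, dtype=np.float64)
            if k.ndim != 3:
                raise ValidationError("PSF kernel must be 3-D")
            if np.min(k) < 0:
                raise ValidationError("PSF kernel must be non-negative")
            if abs(k.sum() - 1.0) > 1e-9:
                raise ValidationError("PSF kernel must sum to 1")
            self.kernel = k
        else:
            if self.sigma_lateral_um <= 0 or self.sigma_axial_um <= 0:
                raise ValidationError("PSF sigmas must be positive")

    def kernel_for(self, pixel_size_um: float, z_step_um: float,
                   truncate: float = 4.0) -> np.ndarray:
        """Return the normalized 3D kernel at a given voxel spacing."""
        if self.kind == "supplied_kernel":
            return self.kernel
        if pixel_size_um is None or z_step_um is None:
            raise ValidationError("parametric PSF needs pixel_size_um and z_step_um")
        sig = np.array([self.sigma_axial_um / z_step_um,
                        self.sigma_lateral_um / pixel_size_um,
                        self.sigma_lateral_um / pixel_size_um])
        half = np.maximum(1, np.ceil(truncate * sig).astype(int))
        zz, yy, xx = np.mgrid[-half[0]:half[0] + 1,
                              -half[1]:half[1] + 1,
                              -half[2]:half[2] + 1]
        k = np.exp(-(zz ** 2 / (2 * sig[0] ** 2)
                     + yy ** 2 / (2 * sig[1] ** 2)
                     + xx ** 2 / (2 * sig[2] ** 2)))
        return k / k.sum()


def richardson_lucy(
    stack_channel: np.ndarray,
    psf: PSFModel,
    iterations: int = 3,
    *,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> np.ndarray:
    """Apply exactly ``iterations`` Richardson–Lucy updates to one channel.

    ``iterations = 0`` returns the input unchanged (as float).  Output is
    non-negative; total intensity is conserved to within a small fraction of
    a percent per iteration under the reflective boundary handling.
    """
    data = np.asarray(stack_channel, dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError("stack_channel must be 3-D (z, y, x)")
    if np.min(data) < 0:
        raise ValidationError("input intensities must be non-negative")
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    if iterations == 0:
        return data.copy()

    kernel = psf.kernel_for(pixel_size_um, z_step_um)
    mirror = kernel[::-1, ::-1, ::-1]
    estimate = np.clip(data, _EPS, None)
    for _ in range(iterations):
        blurred = ndi.convolve(estimate, kernel, mode="reflect")
        ratio = data / np.clip(blurred, _EPS, None)
        estimate = estimate * ndi.convolve(ratio, mirror, mode="reflect")
        np.clip(estimate, 0, None, out=estimate)
    return estimate


def deconvolve_stack(stack, psf: PSFModel, iterations: int = 3,
                     channels: tuple[str, ...] | None = None,
                     quantize: bool = True):
    """Deconvolve named channels of a :class:`~subfrac.io.ConfocalStack`.

    By default every channel is treated independently with the same PSF;
    pass ``channels=("receptor",)`` to restrict to the receptor label.  With
    ``quantize`` (the default) the restored intensities are rounded back to
    the stored integer domain, since all downstream thresholds operate on
    raw stored values; pass ``quantize=False`` for the float estimates.
    """
    names = channels if channels is not None else tuple(stack.channel_names)
    voxels = stack.voxels.astype(np.float64).copy()
    for name in names:
        idx = stack.channel_names.index(name)
        voxels[idx] = richardson_lucy(
            voxels[idx], psf, iterations,
            pixel_size_um=stack.pixel_size_um, z_step_um=stack.z_step_um,
        )
    from dataclasses import replace
    if quantize:
        voxels = np.clip(np.round(voxels), 0, 65535).astype(np.uint16)
    return replace(stack, voxels=voxels)
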