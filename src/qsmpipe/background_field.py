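"""Background-field removal via the spherical mean value property (V-SHARP).

Fields generated by sources outside the brain are harmonic inside it, so
they are reproduced exactly by their spherical mean; subtracting the
spherical-mean filtered field therefore annihilates the background while
leaving a filtered version of the internal (tissue) field, which is then
restored by deconvolution with truncated singular values. The variable-
kernel variant shrinks the sphere radius toward the brain edge so fewer
voxels are lost to erosion: each voxel takes its value from the largest
sphere that still fits inside the mask around it.
"""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np

from .core import (
    UNITS_RAD,
    DegenerateMaskError,
    FieldMap,
    ParameterError,
    logger,
)

__all__ = ["smv_kernel", "vsharp"]


def smv_kernel(
    radius_mm: float,
    grid_shape: Tuple[int, int, int],
    voxel_size_mm: Tuple[float, float, float],
) -> np.ndarray:
    """Normalized spherical mean value kernel on the anisotropic grid.

    Returns the real-space kernel in wrap-around (origin-at-index-0)
    layout, ready for ``fftn``: the indicator of a sphere of physical
    radius ``radius_mm``, normalized to sum to 1. A radius below the
    largest voxel dimension cannot contain any neighbour and is rejected.
    """
    if any(v <= 0 for v in voxel_size_mm):
        raise ParameterError("voxel sizes must be positive")
    if radius_mm < max(voxel_size_mm):
        raise ParameterError(
            f"radius {radius_mm} mm smaller than the largest voxel "
            f"dimension {max(voxel_size_mm)} mm"
        )
    coords = []
    for n, d in zip(grid_shape, voxel_size_mm):
        c = np.fft.fftfreq(n) * n * d  # signed physical offsets, origin at 0
        coords.append(c)
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    r2 = x**2 + y**2 + z**2
    k = (r2 <= radius_mm**2).astype(float)
    s = k.sum()
    if s < 2:
        raise ParameterError("kernel degenerate: fewer than two voxels in sphere")
    return k / s


def _eroded_mask(mask_f: np.ndarray, kernel_fft: np.ndarray, n_sphere: int) -> np.ndarray:
    """Voxels where the full sphere support lies inside the mask.

    Computed by circular convolution of the mask with the normalized
    sphere; a voxel is kept only if (numerically) all sphere voxels are in
    the mask.
    """
    conv = np.fft.ifftn(np.fft.fftn(mask_f) * kernel_fft).real
    return conv >= 1.0 - 0.5 / n_sphere


def vsharp(
    phase: Union[FieldMap, np.ndarray],
    mask: np.ndarray,
    voxel_size_mm: Tuple[float, float, float] = (0.8, 0.8, 3.0),
    r_max_mm: float = 12.0,
    r_step_mm: float = 1.0,
    truncation: float = 0.05,
) -> Tuple[FieldMap, np.ndarray]:
    """Variable-kernel spherical-mean background removal.

    Sphere radii run from ``r_max_mm`` down to the smallest admissible
    radius (the largest voxel dimension, rounded up to the step grid) in
    steps of ``r_step_mm``. Each voxel receives the high-pass filtered
    field from the largest radius whose sphere fits in the mask around it;
    the result is deconvolved by the ``r_max_mm`` filter in k-space with
    singular values below ``truncation`` discarded. The returned mask is
    the input eroded by the smallest sphere — outside it no sphere fits and
    the tissue field is undefined.

    The operation is linear in the field for fixed masks, and shrinking
    ``r_max_mm`` can only grow the output mask.
    """
    if isinstance(phase, FieldMap):
        values = phase.values
        units = phase.units
        te_eff = phase.effective_te_ms
    else:
        values = np.asarray(phase, dtype=float)
        units = UNITS_RAD
        te_eff = None
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateMaskError("empty mask")
    if values.shape != mask.shape:
        raise ParameterError("field and mask must share a grid")
    if truncation <= 0:
        raise ParameterError("truncation threshold must be positive")

    r_min = max(voxel_size_mm)
    radii = []
    r = float(r_max_mm)
    while r >= r_min - 1e-9:
        radii.append(r)
        r -= r_step_mm
    if not radii:
        raise ParameterError("r_max_mm smaller than the largest voxel dimension")

    shape = values.shape
    mask_f = mask.astype(float)
    field = values * mask_f
    field_fft = np.fft.fftn(field)

    out = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    out_mask = np.zeros(shape, dtype=bool)
    c_max_fft = None
    for i, radius in enumerate(radii):  # largest first
        kern = smv_kernel(radius, shape, voxel_size_mm)
        n_sphere = int(round(1.0 / kern.max()))
        k_fft = np.fft.fftn(kern)
        if i == 0:
            c_max_fft = 1.0 - k_fft
        eroded = _eroded_mask(mask_f, k_fft, n_sphere) & mask
        filtered = np.fft.ifftn((1.0 - k_fft) * field_fft).real
        take = eroded & ~assigned
        out[take] = filtered[take]
        assigned |= eroded
        out_mask = eroded  # smallest radius processed last
    if not out_mask.any():
        raise DegenerateMaskError(
            "mask is thinner than the smallest sphere everywhere"
        )

    # deconvolve by the largest-radius filter with TSVD regularisation
    c = c_max_fft
    inv = np.zeros_like(c)
    keep = np.abs(c) >= truncation
    inv[keep] = 1.0 / c[keep]
    n_disc = int(np.sum(~keep))
    logger.debug("vsharp: %d k-space bins truncated", n_disc)
    tissue = np.fft.ifftn(np.fft.fftn(out * assigned) * inv).real
    tissue = tissue * out_mask
    return (
        FieldMap(values=tissue, units=units, mask=out_mask, effective_te_ms=te_eff),
        out_mask,
    )
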