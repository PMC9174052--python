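"""Shared domain types, units and error classes for the QSM pipeline.

Conventions used throughout the package:

* Volumes are 3D ``numpy`` arrays indexed ``(x, y, z)`` with the slice
  direction along the last axis.
* Susceptibility values are expressed in parts per billion (ppb);
  paramagnetic sources (e.g. tissue iron) are positive, diamagnetic
  sources (myelin, calcification) negative.
* Phase is in radians; wrapped phase lives in ``(-pi, pi]``.
* Field maps carry an explicit units tag (radians at the effective echo
  time, or ppb) so that unit mistakes fail loudly instead of silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

logger = logging.getLogger("qsmpipe")

#: Gyromagnetic ratio of the proton divided by 2*pi, in Hz/T.
GAMMA_BAR_HZ_PER_T = 42.576e6

#: Units tag for a field map expressed as phase (rad) accrued at the
#: effective echo time.
UNITS_RAD = "rad@TE_eff"
#: Units tag for a field map expressed as a fractional field shift in ppb.
UNITS_PPB = "ppb"


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class DuplicateLabelError(ParameterError):
    """Two regions of interest share the same name."""


class UnsupportedInputError(ValueError):
    """Input shape/content is valid data but not supported by this operation."""


class DegenerateMaskError(ValueError):
    """A mask became empty (or too thin) for the operation to proceed."""


class UnitsError(ValueError):
    """A field map carries the wrong units tag for this operation."""


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into ``(-pi, pi]``."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


@dataclass
class PhaseImage:
    """A 3D phase volume in radians.

    ``wrapped`` records whether values are confined to ``(-pi, pi]``.
    Exactly one of ``echo_time_ms`` (single-echo phase) or
    ``effective_te_ms`` (echo-combined phase) is usually set.
    """

    values: np.ndarray
    wrapped: bool
    echo_time_ms: Optional[float] = None
    effective_te_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ParameterError("phase volume must be 3D")


@dataclass
class FieldMap:
    """A 3D field volume with an explicit units tag.

    ``units`` is one of :data:`UNITS_RAD` (phase in rad at
    ``effective_te_ms``) or :data:`UNITS_PPB` (fractional field shift in
    parts per billion). ``mask`` marks where the values are valid.
    """

    values: np.ndarray
    units: str
    mask: Optional[np.ndarray] = None
    effective_te_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.units not in (UNITS_RAD, UNITS_PPB):
            raise UnitsError(f"unknown units tag {self.units!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ParameterError("mask shape does not match values")
            if not np.all(np.isfinite(self.values[self.mask])):
                raise ParameterError("non-finite field values inside mask")


@dataclass
class ReliabilityMap:
    """Per-voxel phase reliability in [0, 1]; 1 means fully reliable."""

    values: np.ndarray
    echo_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ParameterError("reliability values must lie in [0, 1]")


@dataclass
class T2StarMap:
    """Apparent transverse relaxation time (ms) with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ParameterError("valid_mask shape does not match values")


@dataclass
class SusceptibilityMap:
    """A chi map in ppb with a reference tag (``none`` or ``csf``)."""

    values: np.ndarray
    reference: str = "none"
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.reference not in ("none", "csf"):
            raise ParameterError(f"unknown reference tag {self.reference!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class AssociationResult:
    """One IDP-phenotype Pearson association."""

    idp_name: str
    phenotype_name: str
    r: float
    p: float
    n: int
    neglog10p: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ParameterError("|r| must not exceed 1")
        if np.isnan(self.neglog10p) and np.isfinite(self.p) and self.p > 0:
            self.neglog10p = float(-np.log10(self.p))


def fftfreqs_mm(
    grid_shape: Tuple[int, int, int], voxel_size_mm: Tuple[float, float, float]
):
    """Physical spatial frequencies (cycles/mm) along each axis, broadcastable.

    Anisotropic voxels are handled by scaling each axis by its physical
    sampling interval, so the frequency grid is isotropic in cycles/mm even
    when the voxel grid is not.
    """
    if any(v <= 0 for v in voxel_size_mm):
        raise ParameterError("voxel sizes must be positive")
    kx = np.fft.fftfreq(grid_shape[0], d=voxel_size_mm[0])
    ky = np.fft.fftfreq(grid_shape[1], d=voxel_size_mm[1])
    kz = np.fft.fftfreq(grid_shape[2], d=voxel_size_mm[2])
    return (
        kx[:, None, None],
        ky[None, :, None],
        kz[None, None, :],
    )
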