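"""Phase-domain operations: Laplacian unwrapping, phase-reliability masking,
SNR-weighted echo combination and dual-echo T2* estimation.

Unwrapping follows the Fourier-domain Laplacian identity
``Lap(phi) = cos(phi) Lap(sin phi) - sin(phi) Lap(cos phi)``, which is
insensitive to 2*pi wraps because only sin/cos of the phase enter. The
inverse Laplacian is applied spectrally with the DC bin zeroed, so the
result is mean-free; the mean over the supplied mask is removed explicitly
to fix the convention.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    DegenerateMaskError,
    ParameterError,
    PhaseImage,
    ReliabilityMap,
    T2StarMap,
    logger,
    wrap_phase,
)

__all__ = [
    "laplacian_unwrap",
    "phase_reliability",
    "refine_mask",
    "echo_weights",
    "combine_echoes",
    "fit_t2star",
]


def _laplacian_k2(shape: Tuple[int, ...]) -> np.ndarray:
    """Spectral -Laplacian eigenvalues |2 pi k|^2 on the unit-spacing grid.

    Voxel anisotropy cancels between the forward and inverse transforms,
    so unit spacing is used throughout.
    """
    axes = [np.fft.fftfreq(n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return sum((2 * np.pi * g) ** 2 for g in grids)


def _fft_laplace(vol: np.ndarray, k2: np.ndarray) -> np.ndarray:
    return np.fft.ifftn(-k2 * np.fft.fftn(vol)).real


def laplacian_unwrap(
    phase: Union[PhaseImage, np.ndarray],
    mask: Optional[np.ndarray] = None,
) -> PhaseImage:
    """Unwrap a wrapped 3D phase volume via the Fourier Laplacian identity.

    The volume is mirror-padded to twice its size per axis before the
    transforms (making the implicit periodic extension continuous, which
    suppresses boundary ringing) and cropped afterwards. The output mean
    over ``mask`` is set to zero — absolute phase offsets are not
    recoverable, only the spatial structure.
    """
    if isinstance(phase, PhaseImage):
        if not phase.wrapped:
            warnings.warn("input not flagged wrapped; re-wrapping and proceeding")
        vals = wrap_phase(phase.values)
        te = phase.echo_time_ms
        te_eff = phase.effective_te_ms
    else:
        vals = wrap_phase(np.asarray(phase, dtype=float))
        te = te_eff = None
    if vals.ndim != 3:
        raise ParameterError("phase volume must be 3D")
    if mask is None:
        mask = np.ones(vals.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    # outside the mask the phase is meaningless (zero-magnitude voxels carry
    # uniform random phase); zero it so it cannot leak through the global
    # inverse Laplacian into the interior
    vals = np.where(mask, vals, 0.0)

    padded = np.pad(vals, [(0, n) for n in vals.shape], mode="reflect")
    k2 = _laplacian_k2(padded.shape)
    s, c = np.sin(padded), np.cos(padded)
    rhs = c * _fft_laplace(s, k2) - s * _fft_laplace(c, k2)
    spec = np.fft.fftn(rhs)
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = spec / (-k2)
    spec[0, 0, 0] = 0.0
    out = np.fft.ifftn(spec).real
    out = out[: vals.shape[0], : vals.shape[1], : vals.shape[2]]
    if mask.any():
        out = out - out[mask].mean()
    return PhaseImage(values=out, wrapped=False, echo_time_ms=te, effective_te_ms=te_eff)


def phase_reliability(cplx: np.ndarray) -> ReliabilityMap:
    """Wrap-safe neighbour-gradient phase reliability, one volume per call.

    For each voxel, ``g`` is the mean over its six face neighbours of the
    absolute wrapped phase difference ``|angle(S_n conj(S_v))|``; the
    reliability is ``max(0, 1 - g/pi)``: 1 for locally constant phase, 0
    where every neighbour is a half-turn away (e.g. near air/tissue
    interfaces). Neighbours wrap periodically at the volume edges. Only the
    phase of ``cplx`` matters; pass ``exp(1j*phase)`` for magnitude-free
    input.
    """
    cplx = np.asarray(cplx, dtype=complex)
    if cplx.ndim != 3:
        raise ParameterError("expected a single-echo 3D complex volume")
    mag = np.abs(cplx)
    unit = np.where(mag > 0, cplx / np.where(mag > 0, mag, 1.0), 1.0)
    g = np.zeros(cplx.shape)
    for axis in range(3):
        for shift in (1, -1):
            nb = np.roll(unit, shift, axis=axis)
            g += np.abs(np.angle(nb * np.conj(unit)))
    g /= 6.0
    return ReliabilityMap(values=np.maximum(0.0, 1.0 - g / np.pi))


def refine_mask(
    mask: np.ndarray,
    rel_echo1: Union[ReliabilityMap, np.ndarray],
    rel_echo2: Union[ReliabilityMap, np.ndarray],
    thr1: float = 0.7,
    thr2: float = 0.6,
) -> np.ndarray:
    """Drop voxels whose phase reliability falls below the per-echo cutoffs.

    Defaults (0.7 for the first echo, 0.6 for the second) follow the
    empirically determined values used to exclude voxels near sinus
    cavities. Raising either threshold can only remove voxels.
    """
    r1 = rel_echo1.values if isinstance(rel_echo1, ReliabilityMap) else np.asarray(rel_echo1)
    r2 = rel_echo2.values if isinstance(rel_echo2, ReliabilityMap) else np.asarray(rel_echo2)
    mask = np.asarray(mask, dtype=bool)
    if r1.shape != mask.shape or r2.shape != mask.shape:
        raise ParameterError("reliability maps must align with the mask")
    out = mask & (r1 >= thr1) & (r2 >= thr2)
    if not out.any():
        raise DegenerateMaskError("phase-reliability refinement removed every voxel")
    return out


def echo_weights(
    te_ms: Sequence[float] = (9.4, 20.0), t2star_ms: float = 40.0
) -> np.ndarray:
    """SNR-predictive echo weights ``TE_n exp(-TE_n/T2*) / sum_n(...)``.

    With the default dual-echo protocol (9.4/20 ms) and the fixed
    T2* = 40 ms these evaluate to about (0.380, 0.620); they always sum
    to 1 and are strictly positive for positive echo times.
    """
    te = np.asarray(te_ms, dtype=float)
    if te.ndim != 1 or len(te) < 2 or np.any(np.diff(te) <= 0) or np.any(te <= 0):
        raise ParameterError("echo times must be positive and strictly ascending")
    if t2star_ms <= 0:
        raise ParameterError("t2star_ms must be positive")
    w = te * np.exp(-te / t2star_ms)
    return w / w.sum()


def combine_echoes(
    phi1: Union[PhaseImage, np.ndarray],
    phi2: Union[PhaseImage, np.ndarray],
    te_ms: Tuple[float, float] = (9.4, 20.0),
    t2star_ms: float = 40.0,
) -> PhaseImage:
    """Weighted sum of the two unwrapped echo phases.

    Because phase grows linearly with echo time, the weighted sum of
    phases equals the phase that would accrue at the effective echo time
    ``TE_eff = w1 TE1 + w2 TE2``, which is recorded on the output for the
    later conversion to ppb.
    """
    v1 = phi1.values if isinstance(phi1, PhaseImage) else np.asarray(phi1, float)
    v2 = phi2.values if isinstance(phi2, PhaseImage) else np.asarray(phi2, float)
    for p in (phi1, phi2):
        if isinstance(p, PhaseImage) and p.wrapped:
            raise ParameterError("echo combination expects unwrapped phase")
    if v1.shape != v2.shape:
        raise ParameterError("echo volumes must share a grid")
    w = echo_weights(te_ms, t2star_ms)
    te_eff = float(w[0] * te_ms[0] + w[1] * te_ms[1])
    return PhaseImage(
        values=w[0] * v1 + w[1] * v2,
        wrapped=False,
        effective_te_ms=te_eff,
    )


def fit_t2star(
    mag1: np.ndarray,
    mag2: np.ndarray,
    te_ms: Tuple[float, float] = (9.4, 20.0),
    mask: Optional[np.ndarray] = None,
) -> T2StarMap:
    """Two-point mono-exponential T2* estimate (ms).

    ``T2* = (TE2 - TE1) / ln(M1/M2)``. Voxels with nonpositive magnitude
    or non-decaying signal (``M1 <= M2``, implying infinite or negative
    T2*) are flagged invalid rather than raising.
    """
    m1 = np.asarray(mag1, dtype=float)
    m2 = np.asarray(mag2, dtype=float)
    if m1.shape != m2.shape:
        raise ParameterError("magnitude volumes must share a grid")
    if te_ms[1] <= te_ms[0]:
        raise ParameterError("TE2 must exceed TE1")
    valid = (m1 > 0) & (m2 > 0) & (m1 > m2)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    out = np.full(m1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[valid] = (te_ms[1] - te_ms[0]) / np.log(m1[valid] / m2[valid])
    n_bad = int(np.sum(~valid & (mask if mask is not None else True)))
    if n_bad:
        logger.debug("fit_t2star: %d voxels flagged invalid", n_bad)
    return T2StarMap(values=out, valid_mask=valid)
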