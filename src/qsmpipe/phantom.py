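"""Forward-physics susceptibility phantom and acquisition simulator.

Generates ground-truth chi volumes with labelled regions of interest
(subcortical-style spheres, CSF, white matter, a white-matter lesion),
computes the induced fractional field shift through the unit dipole
response, and synthesizes multi-coil dual-echo complex gradient-echo data
with T2* decay, smooth per-coil phase offsets, phase wrapping and complex
Gaussian noise. Every downstream reconstruction stage can therefore be
tested against known truth without any external data.

The default acquisition geometry mirrors a population-imaging
susceptibility-weighted protocol: 0.8 x 0.8 x 3 mm voxels, echo times
9.4/20 ms at 3 T with data saved per receive channel. The default grid is a
desk-scale 64 x 64 x 48; the full 256 x 288 x 48 matrix is supported but
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    GAMMA_BAR_HZ_PER_T,
    UNITS_PPB,
    DuplicateLabelError,
    FieldMap,
    ParameterError,
    logger,
)

__all__ = [
    "ROISpec",
    "PhantomSpec",
    "SusceptibilityPhantom",
    "KSpaceKernel",
    "MultiCoilMultiEchoImage",
    "make_phantom",
    "dipole_kernel",
    "forward_field",
    "synthesize_multicoil",
    "true_phase",
    "default_rois",
    "SUBCORTICAL_STRUCTURES",
]

#: The eight bilateral deep grey-matter structures summarised as IDPs.
SUBCORTICAL_STRUCTURES = (
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "substantia_nigra",
    "thalamus",
)


@dataclass(frozen=True)
class ROISpec:
    """One ellipsoidal/spherical source region.

    ``center_vox`` and ``radii_vox`` are in voxel units; ``chi_ppb`` is the
    region's uniform susceptibility and ``t2star_ms`` its apparent
    transverse relaxation time used for signal decay.
    """

    name: str
    shape: str  # "sphere" | "ellipsoid"
    center_vox: Tuple[float, float, float]
    radii_vox: Tuple[float, float, float]
    chi_ppb: float
    t2star_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ParameterError(f"unknown ROI shape {self.shape!r}")
        if any(r <= 0 for r in self.radii_vox):
            raise ParameterError("ROI radii must be positive")
        if self.t2star_ms <= 0:
            raise ParameterError("ROI t2star_ms must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a simulated acquisition.

    Holds the acquisition constants (field strength, echo times, voxel
    geometry, coil count) together with the source geometry. All randomness
    downstream (coil profiles, noise) is driven by ``seed`` alone, so a
    fixed spec reproduces the simulated data bitwise.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: Tuple[float, float, float] = (0.8, 0.8, 3.0)
    b0_tesla: float = 3.0
    b0_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    echo_times_ms: Tuple[float, ...] = (9.4, 20.0)
    n_coils: int = 8
    rois: Tuple[ROISpec, ...] = ()
    background_sources: Tuple[ROISpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    brain_semiaxes_vox: Optional[Tuple[float, float, float]] = None
    base_t2star_ms: float = 50.0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ParameterError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ParameterError("voxel sizes must be positive")
        if self.b0_tesla <= 0:
            raise ParameterError("b0_tesla must be positive")
        tes = tuple(self.echo_times_ms)
        if any(t <= 0 for t in tes) or any(
            b <= a for a, b in zip(tes, tes[1:])
        ):
            raise ParameterError("echo_times_ms must be strictly ascending and positive")
        if self.n_coils < 1:
            raise ParameterError("n_coils must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise DuplicateLabelError("ROI names must be unique")
        for roi in tuple(self.rois) + tuple(self.background_sources):
            for c, n in zip(roi.center_vox, self.grid_shape):
                if not (0 <= c < n):
                    raise ParameterError(
                        f"ROI {roi.name!r} center {roi.center_vox} outside grid"
                    )

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=int(seed))


@dataclass
class KSpaceKernel:
    """Unit dipole response D(k) = 1/3 - (k.b)^2/|k|^2 on the discrete grid.

    ``values[0,0,0]`` (the DC bin) is set to 0 by convention, which makes
    the forward field mean-free — consistent with susceptibility mapping
    estimating *relative* chi only.
    """

    values: np.ndarray
    voxel_size_mm: Tuple[float, float, float]
    b0_direction: Tuple[float, float, float]


@dataclass
class MultiCoilMultiEchoImage:
    """Complex multi-channel data, shape (coil, echo, x, y, z).

    The stored data's phase is wrapped to ``(-pi, pi]`` (complex storage
    makes this automatic). Per-coil phase-offset and magnitude-profile
    ground truth is retained for testing the channel combination.
    """

    data: np.ndarray
    echo_times_ms: Tuple[float, ...]
    coil_phase_offsets_true: Optional[np.ndarray] = None
    coil_magnitudes_true: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 5:
            raise ParameterError("data must be 5D (coil, echo, x, y, z)")
        if self.data.shape[1] != len(self.echo_times_ms):
            raise ParameterError("echo axis does not match echo_times_ms")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("non-finite complex data")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]


@dataclass
class SusceptibilityPhantom:
    """Ground-truth chi volume with labelled ROIs, masks and T2* map."""

    chi_true: np.ndarray
    labels: np.ndarray
    label_names: Dict[int, str]
    brain_mask: np.ndarray
    csf_mask: np.ndarray
    wm_mask: np.ndarray
    wmh_mask: np.ndarray
    t2star_true_ms: np.ndarray
    chi_background: np.ndarray
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if np.any(self.csf_mask & ~self.brain_mask):
            raise ParameterError("csf_mask must be contained in brain_mask")
        if np.any(self.wmh_mask & ~self.wm_mask):
            raise ParameterError("wmh_mask must be contained in wm_mask")
        if np.any((self.labels != 0) & ~self.brain_mask):
            raise ParameterError("nonzero labels must lie inside brain_mask")


def _ellipsoid_mask(
    grid_shape: Sequence[int],
    center: Sequence[float],
    radii: Sequence[float],
) -> np.ndarray:
    x, y, z = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _roi_mask(grid_shape: Sequence[int], roi: ROISpec) -> np.ndarray:
    radii = roi.radii_vox
    if roi.shape == "sphere" and len(set(radii)) != 1:
        raise ParameterError(f"sphere ROI {roi.name!r} must have equal radii")
    for c, r, n in zip(roi.center_vox, radii, grid_shape):
        if c - r < -0.5 or c + r > n - 0.5:
            raise ParameterError(f"ROI {roi.name!r} extends outside the grid")
    return _ellipsoid_mask(grid_shape, roi.center_vox, radii)


def default_rois(
    grid_shape: Tuple[int, int, int] = (64, 64, 48),
    chi_by_structure: Optional[Dict[str, float]] = None,
) -> Tuple[ROISpec, ...]:
    """A standard labelled geometry: 16 bilateral subcortical-style spheres,
    a ventricle-like CSF region, a white-matter slab and one lesion.

    Susceptibilities default to values typical of deep grey matter iron
    accumulation (tens of ppb, pallidum highest), CSF at 0 and white matter
    slightly diamagnetic. Positions scale with the grid.
    """
    nx, ny, nz = grid_shape
    cx, cy, cz = nx / 2, ny / 2, nz / 2
    chi = {
        "accumbens": 30.0,
        "amygdala": 10.0,
        "caudate": 50.0,
        "hippocampus": 15.0,
        "pallidum": 120.0,
        "putamen": 60.0,
        "substantia_nigra": 100.0,
        "thalamus": 20.0,
    }
    t2s = {
        "accumbens": 50.0,
        "amygdala": 55.0,
        "caudate": 45.0,
        "hippocampus": 55.0,
        "pallidum": 30.0,
        "putamen": 40.0,
        "substantia_nigra": 35.0,
        "thalamus": 50.0,
    }
    if chi_by_structure:
        chi.update(chi_by_structure)
    r_in = max(2.5, nx / 18)  # in-plane radius, survives one 2D 3x3 erosion
    r_z = max(1.5, nz / 24)
    rois: List[ROISpec] = [
        ROISpec("wm", "ellipsoid", (cx, cy, cz), (nx * 0.34, ny * 0.34, nz * 0.30), -30.0, 55.0),
        ROISpec("csf", "ellipsoid", (cx, cy, cz), (nx * 0.06, ny * 0.10, nz * 0.12), 0.0, 200.0),
    ]
    # eight structures per hemisphere on a ring around the ventricle
    for i, name in enumerate(SUBCORTICAL_STRUCTURES):
        ang = np.pi * (0.25 + 0.75 * i / (len(SUBCORTICAL_STRUCTURES) - 1)) - np.pi / 2
        for side, sgn in (("L", -1), ("R", 1)):
            x = cx + sgn * (nx * 0.22) * np.cos(ang)
            y = cy + (ny * 0.22) * np.sin(ang)
            z = cz + (1 if i % 2 else -1) * nz * 0.08
            rois.append(
                ROISpec(
                    f"{name}_{side}", "ellipsoid", (x, y, z),
                    (r_in, r_in, r_z), chi[name], t2s[name],
                )
            )
    rois.append(
        ROISpec(
            "wmh", "ellipsoid",
            (cx + nx * 0.24, cy - ny * 0.18, cz + nz * 0.16),
            (r_in, r_in, r_z), -5.0, 70.0,
        )
    )
    return tuple(rois)


def make_phantom(spec: PhantomSpec) -> SusceptibilityPhantom:
    """Rasterise a :class:`PhantomSpec` into ground-truth volumes.

    Later ROIs overwrite earlier ones where they overlap; region masks are
    clipped to the brain ellipsoid so every nonzero label lies inside the
    brain. Background sources are rasterised into a separate volume
    restricted to voxels outside the brain mask.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    semi = spec.brain_semiaxes_vox or tuple(0.42 * n for n in shape)
    center = tuple((n - 1) / 2 for n in shape)
    brain = _ellipsoid_mask(shape, center, semi)

    chi = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    t2s = np.full(shape, float(spec.base_t2star_ms))
    label_names: Dict[int, str] = {}
    masks: Dict[str, np.ndarray] = {}
    for idx, roi in enumerate(spec.rois, start=1):
        m = _roi_mask(shape, roi) & brain
        chi[m] = roi.chi_ppb
        labels[m] = idx
        t2s[m] = roi.t2star_ms
        label_names[idx] = roi.name
        masks[roi.name] = m
    # overlaps: the label volume keeps the later ROI; name masks follow it
    for idx, name in label_names.items():
        masks[name] = labels == idx

    chi_bg = np.zeros(shape)
    for roi in spec.background_sources:
        m = _ellipsoid_mask(shape, roi.center_vox, roi.radii_vox) & ~brain
        if not m.any():
            logger.warning("background source %r entirely inside brain; skipped", roi.name)
        chi_bg[m] = roi.chi_ppb

    empty = np.zeros(shape, dtype=bool)
    wm = masks.get("wm", empty)
    wmh = masks.get("wmh", empty)
    if wmh.any():
        wm = wm | wmh  # lesions sit inside white matter by construction
        for idx, name in label_names.items():
            if name == "wm":
                labels[wmh & (labels == 0)] = idx
    return SusceptibilityPhantom(
        chi_true=chi,
        labels=labels,
        label_names=label_names,
        brain_mask=brain,
        csf_mask=masks.get("csf", empty),
        wm_mask=wm,
        wmh_mask=wmh,
        t2star_true_ms=t2s,
        chi_background=chi_bg,
        spec=spec,
    )


def dipole_kernel(
    grid_shape: Tuple[int, int, int],
    voxel_size_mm: Tuple[float, float, float],
    b0_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> KSpaceKernel:
    """The unit dipole response on the grid's discrete physical frequencies.

    ``D(k) = 1/3 - (k.b)^2 / |k|^2`` with the DC bin set to 0, bounded in
    ``[-2/3, 1/3]`` and even under ``k -> -k``. Anisotropic voxels enter
    through the physical frequency scaling ``k_i = n_i / (N_i dx_i)``.
    """
    if any(int(n) < 8 for n in grid_shape):
        raise ParameterError("grid must be at least 8 voxels per axis")
    if any(v <= 0 for v in voxel_size_mm):
        raise ParameterError("voxel sizes must be positive")
    b = np.asarray(b0_direction, dtype=float)
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ParameterError("b0_direction must be nonzero")
    b = b / nb
    kx, ky, kz = _physical_freqs(grid_shape, voxel_size_mm)
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d[0, 0, 0] = 0.0
    # enforce exact evenness under k -> -k: the Nyquist planes are
    # ambiguous (+/-0.5 alias onto one bin) for oblique field directions,
    # and an even kernel keeps real volumes real under filtering
    d_neg = np.roll(d[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
    d = 0.5 * (d + d_neg)
    return KSpaceKernel(values=d, voxel_size_mm=tuple(voxel_size_mm), b0_direction=tuple(b))


def _physical_freqs(grid_shape, voxel_size_mm):
    from .core import fftfreqs_mm

    return fftfreqs_mm(tuple(int(n) for n in grid_shape), tuple(voxel_size_mm))


def forward_field(
    phantom: SusceptibilityPhantom,
    kernel: Optional[KSpaceKernel] = None,
    pad_factor: int = 2,
) -> FieldMap:
    """Fractional field shift (ppb) induced by the phantom's chi distribution.

    Computed as ``IFFT[D * FFT[chi]]`` on a grid zero-padded by
    ``pad_factor`` per axis to suppress circular wrap-around, then cropped.
    Background sources contribute; the DC-free kernel makes the result
    mean-free over the padded grid.
    """
    spec = phantom.spec
    shape = phantom.chi_true.shape
    if pad_factor < 1:
        raise ParameterError("pad_factor must be >= 1")
    pshape = tuple(int(n * pad_factor) for n in shape)
    if kernel is None:
        kernel = dipole_kernel(pshape, spec.voxel_size_mm, spec.b0_direction)
    if kernel.values.shape != pshape:
        raise ParameterError(
            f"kernel grid {kernel.values.shape} does not match padded grid {pshape}"
        )
    chi = phantom.chi_true + phantom.chi_background
    chi_pad = np.zeros(pshape)
    chi_pad[: shape[0], : shape[1], : shape[2]] = chi
    delta = np.fft.ifftn(kernel.values * np.fft.fftn(chi_pad)).real
    delta = delta[: shape[0], : shape[1], : shape[2]]
    return FieldMap(values=delta, units=UNITS_PPB, mask=phantom.brain_mask)


#: Physical correlation length (mm) of the curved component of simulated
#: per-coil phase offsets. Receive-coil sensitivity varies over
#: centimetres — a property of the coil array, not of the matrix size.
COIL_OFFSET_SCALE_MM = 25.0
#: Peak-to-peak phase-offset trend across the head (rad); over a small
#: simulated field of view the realized trend scales down proportionally.
COIL_OFFSET_TREND_RAD = np.pi
COIL_HEAD_EXTENT_MM = 200.0
#: Standard deviation (rad) of the curved offset component.
COIL_OFFSET_CURVED_SD_RAD = 0.1


def _coil_profiles(spec: PhantomSpec, rng: np.random.Generator):
    """Smooth coil magnitude (low-order polynomial) and phase-offset maps.

    Offsets follow the structure of a real coil array seen through a
    limited field of view: a random constant, a dominant near-linear
    trend (scaled so the full-head trend would span about
    ``COIL_OFFSET_TREND_RAD``), and a weak curved component with a fixed
    physical correlation length.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    coords = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij"
    )
    extent_mm = [n * d for n, d in zip(shape, spec.voxel_size_mm)]
    mags = np.empty((spec.n_coils,) + shape)
    offs = np.empty((spec.n_coils,) + shape)
    sigma = [max(1.0, COIL_OFFSET_SCALE_MM / d) for d in spec.voxel_size_mm]
    for c in range(spec.n_coils):
        lin = rng.uniform(-0.3, 0.3, size=3)
        quad = rng.uniform(-0.15, 0.15, size=3)
        m = 1.0 + sum(a * x for a, x in zip(lin, coords))
        m += sum(a * x**2 for a, x in zip(quad, coords))
        mags[c] = np.clip(m, 0.1, None)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        trend = sum(
            0.5
            * COIL_OFFSET_TREND_RAD
            * (e / COIL_HEAD_EXTENT_MM)
            * direction[i]
            * coords[i]
            for i, e in enumerate(extent_mm)
        )
        curved = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        curved *= COIL_OFFSET_CURVED_SD_RAD / max(curved.std(), 1e-12)
        offs[c] = trend + curved + rng.uniform(-np.pi, np.pi)
    return mags, offs


def true_phase(field: FieldMap, b0_tesla: float, te_ms: float) -> np.ndarray:
    """Unwrapped phase (rad) accrued by a ppb field shift at echo time ``te_ms``."""
    if field.units != UNITS_PPB:
        raise ParameterError("true_phase expects a ppb field map")
    return (
        2.0
        * np.pi
        * GAMMA_BAR_HZ_PER_T
        * b0_tesla
        * field.values
        * 1e-9
        * te_ms
        * 1e-3
    )


def synthesize_multicoil(
    phantom: SusceptibilityPhantom,
    field: FieldMap,
    uniform_coils: bool = False,
) -> MultiCoilMultiEchoImage:
    """Simulate the dual-echo multi-channel complex acquisition.

    Per coil ``c`` and echo ``n``:
    ``S = M rho_c exp(-TE_n/T2*) exp(i(theta_c + 2 pi gamma_bar B0 delta 1e-9 TE_n))``
    plus complex Gaussian noise of standard deviation ``spec.noise_sd`` per
    real/imaginary component. ``uniform_coils=True`` forces ``rho_c = 1``
    and ``theta_c = 0`` (useful for oracle tests); otherwise smooth random
    profiles drawn from ``spec.seed`` are used and stored as ground truth.
    """
    spec = phantom.spec
    shape = phantom.chi_true.shape
    rng = np.random.default_rng(spec.seed)
    if uniform_coils:
        mags = np.ones((spec.n_coils,) + shape)
        offs = np.zeros((spec.n_coils,) + shape)
    else:
        mags, offs = _coil_profiles(spec, rng)
    m0 = phantom.brain_mask.astype(float)
    data = np.empty(
        (spec.n_coils, len(spec.echo_times_ms)) + shape, dtype=complex
    )
    for n, te in enumerate(spec.echo_times_ms):
        decay = np.exp(-te / phantom.t2star_true_ms)
        phi = true_phase(field, spec.b0_tesla, te)
        for c in range(spec.n_coils):
            data[c, n] = m0 * mags[c] * decay * np.exp(1j * (offs[c] + phi))
    if spec.noise_sd > 0:
        noise = rng.normal(scale=spec.noise_sd, size=data.shape + (2,))
        data = data + noise[..., 0] + 1j * noise[..., 1]
    return MultiCoilMultiEchoImage(
        data=data,
        echo_times_ms=tuple(spec.echo_times_ms),
        coil_phase_offsets_true=offs,
        coil_magnitudes_true=mags,
    )
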