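"""End-to-end reconstruction: chaining the stages of the chi pipeline.

``reconstruct`` is the in-memory pipeline (channel combination ->
reliability-refined masking -> Laplacian unwrapping -> echo combination ->
background removal -> dipole inversion -> CSF referencing); ``run_recon``
wraps it with NIfTI input/output and a machine-readable log. ``simulate_
dataset`` writes a phantom acquisition in the on-disk layout ``run_recon``
expects. Cohort helpers simulate many participants at a scaled-down grid
for cross-scan reproducibility and association studies.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from . import io as qio
from .background_field import vsharp
from .coil_combine import combine_channels_mcpc3ds
from .config import PipelineConfig
from .core import (
    UNITS_PPB,
    UNITS_RAD,
    DegenerateMaskError,
    FieldMap,
    logger,
)
from .dipole_inversion import csf_reference, field_to_ppb, ilsqr, tkd
from .idp import (
    build_idp_table,
    extract_subcortical_idps,
    extract_wmh_idp,
    field_gradient_confound,
)
from .phantom import (
    MultiCoilMultiEchoImage,
    PhantomSpec,
    ROISpec,
    SusceptibilityPhantom,
    forward_field,
    make_phantom,
    synthesize_multicoil,
)
from .phase_ops import (
    combine_echoes,
    fit_t2star,
    laplacian_unwrap,
    phase_reliability,
    refine_mask,
)

__all__ = [
    "reconstruct",
    "run_recon",
    "simulate_dataset",
    "extract_participant_idps",
    "recovery_phantom_spec",
    "run_recovery",
    "simulate_cohort_idps",
    "cohort_spec",
]


def reconstruct(
    mc: MultiCoilMultiEchoImage,
    brain_mask: np.ndarray,
    config: Optional[PipelineConfig] = None,
    csf_mask: Optional[np.ndarray] = None,
) -> Dict[str, object]:
    """Run the full reconstruction in memory.

    Returns a dict of stage outputs: combined echoes, reliability maps,
    the mask lineage (``mask1`` input -> ``mask2`` reliability-refined ->
    ``mask3`` post-background-removal), unwrapped and echo-combined phase,
    the tissue field in rad and ppb, the chi map (CSF-referenced when a
    CSF mask is supplied) and the two-echo T2* fit.
    """
    cfg = config or PipelineConfig()
    mask1 = np.asarray(brain_mask, dtype=bool)
    out: Dict[str, object] = {"mask1": mask1, "config": cfg}

    combined = combine_channels_mcpc3ds(
        mc,
        mask1,
        offset_smooth_sigma_vox=cfg.offset_smooth_sigma_vox,
        voxel_size_mm=cfg.voxel_size_mm,
    )
    out["combined"] = combined

    cplx = combined.magnitude * np.exp(1j * combined.phase)
    rel1 = phase_reliability(cplx[0])
    rel2 = phase_reliability(cplx[1])
    out["rel_echo1"], out["rel_echo2"] = rel1, rel2
    mask2 = refine_mask(
        mask1, rel1, rel2, cfg.reliability_thr_echo1, cfg.reliability_thr_echo2
    )
    out["mask2"] = mask2

    phi1 = laplacian_unwrap(
        combined.phase[0], mask2
    )
    phi2 = laplacian_unwrap(combined.phase[1], mask2)
    out["phi_unwrapped"] = (phi1, phi2)
    phase_comb = combine_echoes(
        phi1, phi2, te_ms=cfg.echo_times_ms, t2star_ms=cfg.t2star_default_ms
    )
    out["phase_combined"] = phase_comb

    tissue, vmask = vsharp(
        FieldMap(
            values=phase_comb.values,
            units=UNITS_RAD,
            mask=mask2,
            effective_te_ms=phase_comb.effective_te_ms,
        ),
        mask2,
        voxel_size_mm=cfg.voxel_size_mm,
        r_max_mm=cfg.vsharp_r_max_mm,
        r_step_mm=cfg.vsharp_r_step_mm,
        truncation=cfg.vsharp_truncation,
    )
    out["tissue_field_rad"] = tissue
    mask3 = refine_mask(
        vmask, rel1, rel2, cfg.reliability_thr_echo1, cfg.reliability_thr_echo2
    )
    out["mask3"] = mask3

    field_ppb = field_to_ppb(tissue, cfg.b0_tesla)
    field_ppb = FieldMap(
        values=field_ppb.values * mask3,
        units=UNITS_PPB,
        mask=mask3,
        effective_te_ms=field_ppb.effective_te_ms,
    )
    out["field_ppb"] = field_ppb

    mag_weight = combined.magnitude.mean(axis=0)
    if cfg.inversion == "ilsqr":
        chi = ilsqr(
            field_ppb,
            weights=mag_weight,
            mask=mask3,
            voxel_size_mm=cfg.voxel_size_mm,
            max_iter=cfg.lsqr_max_iter,
            tol=cfg.lsqr_tol,
            d_thr=cfg.ilsqr_d_thr,
            streak_max_iter=cfg.streak_max_iter,
        )
    else:
        chi = tkd(
            field_ppb,
            threshold=cfg.tkd_threshold,
            voxel_size_mm=cfg.voxel_size_mm,
        )
    out["chi"] = chi
    if csf_mask is not None:
        try:
            out["chi_ref"] = csf_reference(chi, np.asarray(csf_mask, bool) & mask3)
        except DegenerateMaskError:
            logger.warning("CSF mask empty after refinement; chi left unreferenced")
    out["t2star"] = fit_t2star(
        combined.magnitude[0], combined.magnitude[1],
        te_ms=cfg.echo_times_ms, mask=mask1,
    )
    return out


# ---------------------------------------------------------------------------
# on-disk dataset layout
# ---------------------------------------------------------------------------

def simulate_dataset(
    spec: PhantomSpec,
    out_dir: Union[str, Path],
    config: Optional[PipelineConfig] = None,
) -> Path:
    """Simulate an acquisition and write it in the layout ``run_recon`` reads.

    Writes ground truth (``chi_true``, labels + name sidecar, masks) and
    per-coil magnitude/phase NIfTI pairs per echo.
    """
    cfg = config or PipelineConfig(
        echo_times_ms=tuple(spec.echo_times_ms),
        b0_tesla=spec.b0_tesla,
        voxel_size_mm=tuple(spec.voxel_size_mm),
        seed=spec.seed,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom = make_phantom(spec)
    field = forward_field(phantom)
    mc = synthesize_multicoil(phantom, field)
    h = cfg.content_hash()
    vx = spec.voxel_size_mm

    def w(vol, name, units=None):
        qio.save_nifti(vol, out_dir / name, voxel_size_mm=vx, units=units, config_hash=h)

    w(phantom.chi_true, "chi_true.nii.gz", UNITS_PPB)
    w(field.values, "field_true.nii.gz", UNITS_PPB)
    w(phantom.labels, "labels.nii.gz")
    w(phantom.brain_mask, "brain_mask.nii.gz")
    w(phantom.csf_mask, "csf_mask.nii.gz")
    w(phantom.wm_mask, "wm_mask.nii.gz")
    w(phantom.wmh_mask, "wmh_mask.nii.gz")
    (out_dir / "labels.json").write_text(
        json.dumps({str(k): v for k, v in phantom.label_names.items()}, indent=1)
    )
    for c in range(mc.n_coils):
        for e in range(mc.n_echoes):
            w(np.abs(mc.data[c, e]), f"coil{c:02d}_echo{e + 1}_mag.nii.gz")
            w(np.angle(mc.data[c, e]), f"coil{c:02d}_echo{e + 1}_phase.nii.gz", "rad")
    cfg.to_yaml(out_dir / "config.yaml")
    return out_dir


def _read_dataset(input_dir: Path, cfg: PipelineConfig):
    mags, phases = [], []
    c = 0
    while (input_dir / f"coil{c:02d}_echo1_mag.nii.gz").exists():
        per_echo_m, per_echo_p = [], []
        e = 1
        while (input_dir / f"coil{c:02d}_echo{e}_mag.nii.gz").exists():
            m, _, _ = qio.load_nifti(input_dir / f"coil{c:02d}_echo{e}_mag.nii.gz")
            p, _, _ = qio.load_nifti(input_dir / f"coil{c:02d}_echo{e}_phase.nii.gz")
            per_echo_m.append(m)
            per_echo_p.append(p)
            e += 1
        mags.append(per_echo_m)
        phases.append(per_echo_p)
        c += 1
    if not mags:
        raise FileNotFoundError(f"no per-coil volumes (coil00_echo1_mag.nii.gz) in {input_dir}")
    mask_path = input_dir / "brain_mask.nii.gz"
    if not mask_path.exists():
        raise FileNotFoundError(f"missing {mask_path}")
    brain, _, _ = qio.load_nifti(mask_path)
    data = np.asarray(mags, dtype=float) * np.exp(
        1j * np.asarray(phases, dtype=float)
    )
    mc = MultiCoilMultiEchoImage(data=data, echo_times_ms=tuple(cfg.echo_times_ms))
    csf = None
    if (input_dir / "csf_mask.nii.gz").exists():
        csf, _, _ = qio.load_nifti(input_dir / "csf_mask.nii.gz")
        csf = csf.astype(bool)
    return mc, brain.astype(bool), csf


def run_recon(
    config: Optional[PipelineConfig],
    input_dir: Union[str, Path],
    output_dir: Optional[Union[str, Path]] = None,
) -> Path:
    """Disk-to-disk reconstruction; writes every stage plus a JSON log."""
    input_dir = Path(input_dir)
    if config is None:
        cfg_path = input_dir / "config.yaml"
        config = (
            PipelineConfig.from_yaml(cfg_path) if cfg_path.exists() else PipelineConfig()
        )
    output_dir = Path(output_dir) if output_dir else input_dir / "recon"
    output_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    mc, brain, csf = _read_dataset(input_dir, config)
    res = reconstruct(mc, brain, config, csf_mask=csf)
    h = config.content_hash()
    vx = config.voxel_size_mm

    def w(vol, name, units=None):
        qio.save_nifti(vol, output_dir / name, voxel_size_mm=vx, units=units, config_hash=h)

    combined = res["combined"]
    for e in range(combined.phase.shape[0]):
        w(combined.phase[e], f"combined_phase_echo{e + 1}.nii.gz", "rad")
        w(combined.magnitude[e], f"combined_mag_echo{e + 1}.nii.gz")
    w(res["mask1"], "mask1.nii.gz")
    w(res["mask2"], "mask2.nii.gz")
    w(res["mask3"], "mask3.nii.gz")
    w(res["tissue_field_rad"].values, "tissue_field.nii.gz", UNITS_RAD)
    w(res["field_ppb"].values, "field_ppb.nii.gz", UNITS_PPB)
    w(res["chi"].values, "chi.nii.gz", UNITS_PPB)
    if "chi_ref" in res:
        w(res["chi_ref"].values, "chi_csf.nii.gz", UNITS_PPB)
    t2 = res["t2star"]
    w(np.nan_to_num(t2.values, nan=0.0), "t2star_ms.nii.gz", "ms")
    w(t2.valid_mask, "t2star_valid.nii.gz")
    log = {
        "config_hash": h,
        "effective_te_ms": res["phase_combined"].effective_te_ms,
        "n_mask1": int(res["mask1"].sum()),
        "n_mask2": int(res["mask2"].sum()),
        "n_mask3": int(res["mask3"].sum()),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (output_dir / "recon_log.json").write_text(json.dumps(log, indent=1))
    config.to_yaml(output_dir / "config_used.yaml")
    return output_dir


def extract_participant_idps(
    chi: np.ndarray,
    t2star: np.ndarray,
    labels: np.ndarray,
    label_names: Dict[int, str],
    wmh_mask: np.ndarray,
    wm_mask: np.ndarray,
    total_field: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """The 18 + 18 IDPs (chi and T2*) for one participant.

    Keys are ``qsm_<region>`` / ``t2star_<region>`` plus ``qsm_wmh`` and
    ``t2star_wmh`` (lesion contrast; the volume-regressed variants are
    cohort-level and added by :func:`qsmpipe.idp.build_idp_table`). When
    the pre-background-removal total field is given, per-region
    field-gradient confounds are included as ``fieldgrad_<region>``.
    """
    row: Dict[str, float] = {}
    for name, val in extract_subcortical_idps(chi, labels, label_names).items():
        row[f"qsm_{name}"] = val
    for name, val in extract_subcortical_idps(
        t2star, labels, label_names, sn_exclude_negative=False
    ).items():
        row[f"t2star_{name}"] = val
    row["qsm_wmh"] = extract_wmh_idp(chi, wmh_mask, wm_mask)
    row["t2star_wmh"] = extract_wmh_idp(t2star, wmh_mask, wm_mask)
    if total_field is not None:
        for name, val in field_gradient_confound(
            total_field, labels, label_names
        ).items():
            row[f"fieldgrad_{name}"] = val
    return row


# ---------------------------------------------------------------------------
# reference validation phantoms and scaled-down cohort simulation
# ---------------------------------------------------------------------------

def recovery_phantom_spec(
    seed: int,
    grid_shape: Tuple[int, int, int] = (64, 64, 48),
    n_coils: int = 32,
    snr: float = 50.0,
) -> PhantomSpec:
    """The parameter-recovery benchmark phantom.

    Deep regions at +100, +60 and -50 ppb around a central 0 ppb
    ventricle, acquired with the full 32-channel coil set at magnitude
    SNR ~ 50. Placement keeps every region inside the volume that
    survives the 12 mm background-removal erosion, as deep grey-matter
    structures do in vivo.
    """
    nx, ny, nz = grid_shape
    cx, cy, cz = nx / 2, ny / 2, nz / 2
    rois = (
        ROISpec("csf", "ellipsoid", (cx, cy, cz), (3, 4, 5), 0.0, 200.0),
        ROISpec("roi_p100", "ellipsoid", (cx - 9, cy - 5, cz - 4), (5, 5, 2), 100.0, 35.0),
        ROISpec("roi_p60", "ellipsoid", (cx + 9, cy - 5, cz + 4), (5, 5, 2), 60.0, 45.0),
        ROISpec("roi_m50", "ellipsoid", (cx, cy + 10, cz), (5, 5, 2), -50.0, 55.0),
    )
    return PhantomSpec(
        grid_shape=grid_shape, rois=rois, n_coils=n_coils,
        noise_sd=1.0 / snr, seed=int(seed),
    )


def run_recovery(seed: int) -> Dict[str, float]:
    """Simulate, reconstruct and extract ROI medians for one seed.

    Returns the CSF-referenced median chi (ppb) per region; reconstruction
    voxels outside the final mask are treated as missing.
    """
    spec = recovery_phantom_spec(seed)
    phantom = make_phantom(spec)
    field = forward_field(phantom)
    mc = synthesize_multicoil(phantom, field)
    res = reconstruct(mc, phantom.brain_mask, csf_mask=phantom.csf_mask)
    chi = np.where(
        res["mask3"], res.get("chi_ref", res["chi"]).values, np.nan
    )
    out: Dict[str, float] = {}
    for idx, name in phantom.label_names.items():
        v = chi[phantom.labels == idx]
        v = v[np.isfinite(v)]
        out[name] = float(np.median(v)) if v.size else float("nan")
    return out


#: Template susceptibilities (ppb) and T2* (ms) for the cohort's
#: high-contrast deep grey-matter structures.
_COHORT_STRUCTURES = {
    "pallidum": (120.0, 30.0),
    "substantia_nigra": (100.0, 35.0),
    "putamen": (60.0, 40.0),
}


def cohort_spec(
    rng: np.random.Generator,
    grid_shape: Tuple[int, int, int] = (48, 48, 32),
    n_coils: int = 8,
    snr: float = 50.0,
    between_subject_sd: float = 0.25,
    age: Optional[float] = None,
    age_slope_ppb_per_year: float = 0.0,
) -> PhantomSpec:
    """One participant's phantom spec with biological chi variation.

    A compact bilateral geometry (pallidum, substantia nigra, putamen —
    the iron-rich structures — plus ventricle, white matter and one
    lesion) sized so the deep structures survive background-removal
    erosion at desk scale. Region susceptibilities are scaled by
    independent factors ``N(1, between_subject_sd)``; an optional linear
    age effect adds ``age_slope * (age - 60)`` ppb to the iron-rich
    regions. Noise is set for the requested magnitude SNR.
    """
    nx, ny, nz = grid_shape
    cx, cy, cz = nx / 2, ny / 2, nz / 2
    r_in, r_z = max(2.5, nx / 16), max(1.2, nz / 16)
    rois = [
        ROISpec("wm", "ellipsoid", (cx, cy, cz), (nx * 0.3, ny * 0.3, nz * 0.3), -30.0, 55.0),
        ROISpec("csf", "ellipsoid", (cx, cy, cz), (2.5, 3.0, 3.0), 0.0, 200.0),
    ]
    for i, (name, (chi, t2s)) in enumerate(_COHORT_STRUCTURES.items()):
        factor = max(0.2, rng.normal(1.0, between_subject_sd))
        val = chi * factor
        if age is not None and chi >= 50:
            val += age_slope_ppb_per_year * (age - 60.0)
        # iron shortens T2*: scale the relaxation rate with the chi factor
        t2s = t2s / max(0.3, factor)
        dy = (i - 1) * ny * 0.15
        dz = (1 if i % 2 else -1) * 2.0
        for side, sgn in (("L", -1), ("R", 1)):
            rois.append(
                ROISpec(
                    f"{name}_{side}", "ellipsoid",
                    (cx + sgn * nx * 0.15, cy + dy, cz + dz),
                    (r_in, r_in, r_z), val, t2s,
                )
            )
    rois.append(
        ROISpec("wmh", "ellipsoid", (cx, cy, cz + nz * 0.2), (2.0, 2.0, 1.0), -5.0, 70.0)
    )
    return PhantomSpec(
        grid_shape=grid_shape,
        n_coils=n_coils,
        noise_sd=1.0 / snr,
        seed=int(rng.integers(0, 2**31 - 1)),
        rois=tuple(rois),
    )


def _cohort_config(grid_shape: Tuple[int, int, int]) -> PipelineConfig:
    # small head: scale the maximum background-removal kernel down with
    # the in-plane extent so erosion leaves usable brain
    cfg = PipelineConfig(lsqr_max_iter=30, streak_max_iter=15)
    extent_mm = grid_shape[0] * cfg.voxel_size_mm[0]
    cfg.vsharp_r_max_mm = float(np.clip(extent_mm / 5.0, 4.0, 12.0))
    return cfg


def simulate_cohort_idps(
    n_participants: int,
    seed: int,
    grid_shape: Tuple[int, int, int] = (48, 48, 32),
    n_noise_realizations: int = 1,
    snr: float = 50.0,
    ages: Optional[np.ndarray] = None,
    age_slope_ppb_per_year: float = 0.0,
    config: Optional[PipelineConfig] = None,
) -> list:
    """Simulate and reconstruct a cohort; returns one IDP table per scan.

    Each participant has fixed anatomy/chi across the
    ``n_noise_realizations`` scans; only acquisition noise and coil
    profiles differ (fresh acquisition seeds), emulating repeat imaging
    visits. Grid and kernel sizes are scaled down so a cohort is
    tractable on one CPU; the reconstruction chain itself is the standard
    one.
    """
    master = np.random.default_rng(seed)
    cfg = config or _cohort_config(grid_shape)
    tables = [dict() for _ in range(n_noise_realizations)]
    for i in range(n_participants):
        age = None if ages is None else float(ages[i])
        spec = cohort_spec(
            master, grid_shape=grid_shape, snr=snr, age=age,
            age_slope_ppb_per_year=age_slope_ppb_per_year,
        )
        phantom = make_phantom(spec)
        field = forward_field(phantom)
        for rep in range(n_noise_realizations):
            acq_seed = int(master.integers(0, 2**31 - 1))
            phantom_rep = SusceptibilityPhantom(
                chi_true=phantom.chi_true,
                labels=phantom.labels,
                label_names=phantom.label_names,
                brain_mask=phantom.brain_mask,
                csf_mask=phantom.csf_mask,
                wm_mask=phantom.wm_mask,
                wmh_mask=phantom.wmh_mask,
                t2star_true_ms=phantom.t2star_true_ms,
                chi_background=phantom.chi_background,
                spec=spec.with_seed(acq_seed),
            )
            mc = synthesize_multicoil(phantom_rep, field)
            res = reconstruct(mc, phantom.brain_mask, cfg, csf_mask=phantom.csf_mask)
            chi = np.where(
                res["mask3"], res.get("chi_ref", res["chi"]).values, np.nan
            )
            t2v = np.where(res["t2star"].valid_mask, res["t2star"].values, np.nan)
            row = extract_participant_idps(
                chi, t2v, phantom.labels, phantom.label_names,
                phantom.wmh_mask, phantom.wm_mask,
            )
            tables[rep][f"sub{i:03d}"] = row
    return [build_idp_table(t) for t in tables]
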