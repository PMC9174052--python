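"""Region-wise imaging-derived phenotypes (IDPs) from chi and T2* maps.

Per participant and modality the pipeline emits 18 IDPs: the median over
each of 16 bilateral subcortical regions (masks eroded slice-wise with a
2D 3x3 kernel, except the substantia nigra which instead drops
negative-chi voxels), plus the white-matter-lesion contrast (lesion mean
minus normal-appearing white matter median) raw and with lesion volume
regressed out. A per-region macroscopic field-gradient summary (median
absolute through-slice gradient of the total field) is produced as a
confound for T2* IDPs, whose large-voxel estimates are biased by intra-
voxel dephasing along the slice direction.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .core import ParameterError, logger

__all__ = [
    "erode_mask_2d",
    "extract_subcortical_idps",
    "extract_wmh_idp",
    "regress_out_scalar",
    "field_gradient_confound",
    "build_idp_table",
]

#: 8-connected in-plane structuring element; no through-slice extent.
_STRUCT_2D = np.ones((3, 3, 1), dtype=bool)


def erode_mask_2d(mask: np.ndarray) -> np.ndarray:
    """Binary erosion with a 3x3 kernel applied independently per axial slice."""
    return binary_erosion(np.asarray(mask, dtype=bool), structure=_STRUCT_2D)


def extract_subcortical_idps(
    volume: np.ndarray,
    labels: np.ndarray,
    label_names: Mapping[int, str],
    roi_names: Optional[Iterable[str]] = None,
    sn_exclude_negative: bool = True,
) -> Dict[str, float]:
    """Median map value per subcortical region, one IDP per region.

    Every region except the substantia nigra is eroded slice-wise with a
    2D 3x3 kernel before taking the median (guarding against partial
    volume at the region edge). Substantia nigra regions are not eroded;
    instead, voxels with negative values are excluded once before the
    median when ``sn_exclude_negative`` (appropriate for chi, where the
    structure is reliably paramagnetic; disable for T2* input). A region
    that ends up empty yields NaN and a log message.
    """
    volume = np.asarray(volume, dtype=float)
    labels = np.asarray(labels)
    if volume.shape != labels.shape:
        raise ParameterError("volume and labels must share a grid")
    wanted = set(roi_names) if roi_names is not None else None
    out: Dict[str, float] = {}
    for idx, name in label_names.items():
        if wanted is not None and name not in wanted:
            continue
        if wanted is None and name in ("csf", "wm", "wmh"):
            continue
        roi = labels == idx
        if "substantia_nigra" in name:
            sel = roi & (volume > 0) if sn_exclude_negative else roi
        else:
            sel = erode_mask_2d(roi)
        vals = volume[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.info("IDP %s empty after erosion/refinement; missing", name)
            out[name] = float("nan")
        else:
            out[name] = float(np.median(vals))
    return out


def extract_wmh_idp(
    volume: np.ndarray, wmh_mask: np.ndarray, wm_mask: np.ndarray
) -> float:
    """Lesion-vs-normal white matter contrast.

    ``mean(volume | lesions) - median(volume | wm \\ lesions)``. Isolates
    properties unique to lesions from global white-matter trends; any
    global reference offset cancels in the subtraction. Empty lesion mask
    gives NaN; empty normal-appearing white matter is an error.
    """
    volume = np.asarray(volume, dtype=float)
    wmh = np.asarray(wmh_mask, dtype=bool)
    wm = np.asarray(wm_mask, dtype=bool)
    nawm = wm & ~wmh
    if not nawm.any():
        raise ParameterError("normal-appearing white matter mask is empty")
    if not wmh.any():
        logger.info("empty lesion mask; WMH IDP missing")
        return float("nan")
    lesion_vals = volume[wmh]
    nawm_vals = volume[nawm]
    lesion_vals = lesion_vals[np.isfinite(lesion_vals)]
    nawm_vals = nawm_vals[np.isfinite(nawm_vals)]
    if lesion_vals.size == 0 or nawm_vals.size == 0:
        return float("nan")
    return float(np.mean(lesion_vals) - np.median(nawm_vals))


def regress_out_scalar(
    idp_column: Sequence[float], covariate: Sequence[float]
) -> np.ndarray:
    """Residualize one IDP column on a scalar covariate (with intercept).

    Least squares on complete pairs; missing values propagate. A constant
    covariate carries no information, so the centered IDP is returned with
    a warning.
    """
    y = np.asarray(idp_column, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ParameterError("column lengths differ")
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise ParameterError("need at least 3 complete pairs")
    out = np.full_like(y, np.nan)
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0:
        warnings.warn("constant covariate; returning centered IDP")
        out[ok] = ys - ys.mean()
        return out
    X = np.column_stack([np.ones(ok.sum()), xs])
    beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
    out[ok] = ys - X @ beta
    return out


def field_gradient_confound(
    field: np.ndarray,
    labels: np.ndarray,
    label_names: Mapping[int, str],
    slice_axis: int = 2,
    roi_names: Optional[Iterable[str]] = None,
) -> Dict[str, float]:
    """Per-region median absolute through-slice gradient of the total field.

    Uses central differences (one-sided at volume edges and hence at
    single-slice regions) in per-voxel units. Intended as a confound
    regressor for T2* IDPs only; chi estimates are not biased by
    macroscopic gradients.
    """
    field = np.asarray(field, dtype=float)
    labels = np.asarray(labels)
    if field.shape != labels.shape:
        raise ParameterError("field and labels must share a grid")
    grad = np.abs(np.gradient(field, axis=slice_axis))
    wanted = set(roi_names) if roi_names is not None else None
    out: Dict[str, float] = {}
    for idx, name in label_names.items():
        if wanted is not None and name not in wanted:
            continue
        roi = labels == idx
        out[name] = float(np.median(grad[roi])) if roi.any() else float("nan")
    return out


def build_idp_table(
    rows: Mapping[str, Mapping[str, float]],
    wmh_volume: Optional[Mapping[str, float]] = None,
    wmh_column: str = "wmh",
) -> pd.DataFrame:
    """Assemble per-participant IDP rows into a table.

    ``rows`` maps participant ID to a dict of named IDPs. When
    ``wmh_volume`` is given, an additional ``<wmh_column>_volreg`` column
    holds the lesion IDP with lesion volume regressed out, completing the
    18-IDP set per modality.
    """
    table = pd.DataFrame.from_dict(dict(rows), orient="index").sort_index()
    table.index.name = "participant_id"
    if table.columns.duplicated().any():
        raise ParameterError("duplicate IDP column names")
    if wmh_volume is not None:
        if wmh_column not in table.columns:
            raise ParameterError(f"no {wmh_column!r} column to regress")
        vol = pd.Series(dict(wmh_volume)).reindex(table.index)
        table[f"{wmh_column}_volreg"] = regress_out_scalar(
            table[wmh_column].to_numpy(), vol.to_numpy()
        )
    return table
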