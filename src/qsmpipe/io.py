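"""NIfTI input/output with explicit unit tagging.

Every volume the pipeline writes carries its units and the configuration
hash in the NIfTI description field, so a map can never be silently
mistaken for the wrong quantity (rad vs ppb). Voxel size is encoded in a
diagonal affine; voxel indices are 0-based and world coordinates are
``affine @ index``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple, Union

import nibabel as nib
import numpy as np

from .core import ParameterError

__all__ = ["save_nifti", "load_nifti", "nifti_roundtrip", "affine_from_voxel_size"]


def affine_from_voxel_size(voxel_size_mm: Tuple[float, float, float]) -> np.ndarray:
    # the NIfTI header stores the transform in float32; quantize up front
    # so that a written affine reads back bit-identical
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.float32(voxel_size_mm)
    return aff


def save_nifti(
    volume: np.ndarray,
    path: Union[str, Path],
    affine: Optional[np.ndarray] = None,
    voxel_size_mm: Optional[Tuple[float, float, float]] = None,
    units: Optional[str] = None,
    config_hash: Optional[str] = None,
) -> Path:
    """Write a volume as NIfTI; floats as float32, booleans as uint8.

    Non-finite voxels are rejected (with a count) except for NaN, which is
    the conventional missing-value marker in statistical maps.
    """
    volume = np.asarray(volume)
    if affine is None:
        affine = affine_from_voxel_size(voxel_size_mm or (1.0, 1.0, 1.0))
    n_inf = int(np.isinf(volume).sum())
    if n_inf:
        raise ParameterError(f"{n_inf} infinite voxels; refusing to write")
    if volume.dtype == bool:
        data = volume.astype(np.uint8)
    elif np.issubdtype(volume.dtype, np.integer):
        data = volume.astype(np.int32)
    else:
        data = volume.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    descrip = ";".join(
        s for s in (f"units={units}" if units else "", f"cfg={config_hash}" if config_hash else "")
        if s
    )
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_nifti(path: Union[str, Path]):
    """Load a NIfTI volume; returns (data, affine, description string)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    return data, img.affine, descrip


def nifti_roundtrip(
    volume: np.ndarray,
    affine: Optional[np.ndarray] = None,
    tmpdir: Optional[Union[str, Path]] = None,
) -> np.ndarray:
    """Save then reload a volume; data to float32 precision, affine exact."""
    import tempfile

    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        p = save_nifti(volume, Path(d) / "vol.nii.gz", affine=affine)
        data, aff, _ = load_nifti(p)
    if affine is not None and not np.array_equal(aff, affine):
        raise ParameterError("affine changed in round-trip")
    return data
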