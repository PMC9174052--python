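"""Pipeline configuration: every tunable in one serializable record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .core import ParameterError

__all__ = ["PipelineConfig", "PACKAGE_VERSION"]

PACKAGE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """All tunable parameters of the reconstruction and statistics stages.

    Defaults are the pipeline's operating point: dual echoes at
    9.4/20 ms and 3 T with 0.8 x 0.8 x 3 mm voxels; a fixed T2* of 40 ms
    in the echo-combination weights; phase-reliability cutoffs 0.7 (echo
    1) and 0.6 (echo 2); a 12 mm maximum spherical kernel with 0.05
    truncation for background removal; up to 50 LSQR iterations at
    relative tolerance 1e-3 with an ill-conditioned cone at |D| < 0.1 for
    the inversion; the 6 x MAD outlier rule and alpha 0.05 for the
    statistics.
    """

    echo_times_ms: Tuple[float, float] = (9.4, 20.0)
    b0_tesla: float = 3.0
    voxel_size_mm: Tuple[float, float, float] = (0.8, 0.8, 3.0)
    t2star_default_ms: float = 40.0
    reliability_thr_echo1: float = 0.7
    reliability_thr_echo2: float = 0.6
    offset_smooth_sigma_vox: float = 4.0
    vsharp_r_max_mm: float = 12.0
    vsharp_r_step_mm: float = 1.0
    vsharp_truncation: float = 0.05
    lsqr_max_iter: int = 50
    lsqr_tol: float = 1e-3
    ilsqr_d_thr: float = 0.1
    streak_max_iter: int = 30
    tkd_threshold: float = 0.2
    inversion: str = "ilsqr"  # "ilsqr" | "tkd"
    mad_factor: float = 6.0
    alpha: float = 0.05
    min_n_assoc: int = 40
    seed: int = 0
    version: str = PACKAGE_VERSION
    created: Optional[str] = None

    def __post_init__(self) -> None:
        te = tuple(self.echo_times_ms)
        if len(te) != 2 or te[0] >= te[1] or te[0] <= 0:
            raise ParameterError("echo_times_ms must be two ascending positive values")
        self.echo_times_ms = te
        self.voxel_size_mm = tuple(self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ParameterError("voxel sizes must be positive")
        if self.inversion not in ("ilsqr", "tkd"):
            raise ParameterError("inversion must be 'ilsqr' or 'tkd'")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.created is None:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["echo_times_ms"] = list(self.echo_times_ms)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Short hash over the parameters (provenance fields excluded)."""
        d = self.to_dict()
        d.pop("created", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]
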