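"""Image/table I/O and pipeline configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .puncta import PunctaParams
from .segmentation import SegmentationParams
from .sg_calling import SGCallParams

log = logging.getLogger(__name__)

__all__ = ["Field", "FieldInput", "PipelineConfig", "read_field"]

CHANNEL_ROLES = ("nuclei", "membrane", "marker1", "marker2")


@dataclass
class Field:
    """One registered field of view: grayscale channels keyed by role."""

    channels: dict[str, np.ndarray]
    field_id: str = "field"
    pixel_size_um: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __post_init__(self) -> None:
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shape mismatch: {shapes}")
        for role, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {role!r} is not a 2D grayscale image")


@dataclass
class FieldInput:
    """Pointer to one field on disk plus its experimental annotation."""

    field_id: str
    channel_paths: dict[str, str | Path]
    condition: str = ""
    replicate: str = ""


def read_field(paths: dict[str, str | Path], field_id: str = "field") -> Field:
    """Load one field from per-channel grayscale TIFFs.

    All four roles (nuclei, membrane, marker1, marker2) must be present with
    identical dimensions.  8- and 16-bit files may be mixed; intensities are
    kept in their native scale (a note is logged when bit depths differ).
    """
    missing = [r for r in CHANNEL_ROLES if r not in paths]
    if missing:
        raise ValueError(f"missing channel roles: {missing}")
    channels: dict[str, np.ndarray] = {}
    dtypes = set()
    for role in CHANNEL_ROLES:
        p = Path(paths[role])
        if not p.exists():
            raise FileNotFoundError(f"channel {role!r}: {p}")
        img = tifffile.imread(p)
        if img.ndim != 2:
            raise ValueError(f"channel {role!r} in {p} is not single-channel grayscale")
        dtypes.add(img.dtype)
        channels[role] = img.astype(np.float64)
    shapes = {r: c.shape for r, c in channels.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"channel shape mismatch: {shapes}")
    if len(dtypes) > 1:
        log.info("field %s mixes bit depths (%s); intensities kept in native scale",
                 field_id, sorted(str(d) for d in dtypes))
    return Field(channels=channels, field_id=field_id)


@dataclass
class PipelineConfig:
    """All tunable parameters of the quantification and screen stages.

    Round-trips unchanged through ``to_yaml``/``from_yaml``; ``config_hash``
    identifies the parameter set in run manifests.
    """

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    puncta: PunctaParams = field(default_factory=PunctaParams)
    sg_calling: SGCallParams = field(default_factory=SGCallParams)
    # statistics
    replicate_unit: str = "replicate"  # or "field"
    fdr_q: float = 0.01
    equal_var_ttest: bool = False
    # screen
    hit_threshold_sd: float = 2.0
    two_sided_hits: bool = False
    control_sd_ddof: int = 1
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("segmentation", SegmentationParams),
            ("puncta", PunctaParams),
            ("sg_calling", SGCallParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output directory is not part
        of the parameter set)."""
        d = self.to_dict()
        d.pop("outdir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
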