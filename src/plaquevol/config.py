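"""Pipeline configuration: every stage parameter, validated, in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the quantification pipeline with their defaults.

    ``alpha`` / ``alpha_seg`` are the detection / segmentation contrast
    thresholds (fraction of the local annulus median), ``window`` the
    in-plane annulus window in voxels, ``depth_margin`` and ``min_r2`` the
    long-TE filter settings, ``connectivity`` the 3-D neighborhood for
    component counting, ``min_voxels`` the speckle-suppression floor on the
    resampled grid, ``out_spacing`` the semi-3D grid in (row, col, slice) mm.
    """

    alpha: float = 0.6
    alpha_seg: float = 0.57
    window: int = 7
    depth_margin: float = 0.05
    min_r2: float = 0.9
    connectivity: int = 26
    min_voxels: int = 2
    out_spacing: tuple[float, float, float] = (0.0625, 0.0625, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.alpha_seg < 1:
            raise ValueError("alpha and alpha_seg must lie in (0, 1)")
        if self.window % 2 == 0 or self.window < 5:
            raise ValueError("window must be odd and >= 5")
        if self.depth_margin < 0 or not 0 <= self.min_r2 <= 1:
            raise ValueError("depth_margin must be >= 0 and min_r2 in [0, 1]")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if len(self.out_spacing) != 3 or any(s <= 0 for s in self.out_spacing):
            raise ValueError("out_spacing must be three positive lengths (mm)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "out_spacing" in d:
            d["out_spacing"] = tuple(float(s) for s in d["out_spacing"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_spacing"] = list(self.out_spacing)
        return d
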