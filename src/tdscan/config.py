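"""Pipeline configuration shared by the caller stages.

All tunables default to the published operating point of the method:
1 kb bins, TV penalty 0.15, boxplot factor 0.6, neighbour fraction 0.2,
split-read search multiplier 2, 100 bp reads, 20 bp minimum clip.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Tunables for the tandem-duplication caller.

    Attributes
    ----------
    lb:
        Bin length in bases (``Lb``). Bins are contiguous and non-overlapping.
    tv_lambda:
        Total-variation penalty applied when smoothing the per-bin RD and MQ
        signals; recommended range [0.15, 0.30].
    theta:
        Boxplot fence factor: candidate threshold is ``UQ + theta * IQR`` of
        the outlier scores.
    k_fraction:
        Neighbour count for the KNN outlier score, as a fraction of the number
        of scored objects (``k = round(k_fraction * n)``).
    m:
        Breakpoint search multiplier; the split-read/discordant-pair search
        radius is ``S = m * lb``.
    r_l:
        Read length in bases.
    min_clip:
        Minimum soft-clip length for a split read to count as breakpoint
        evidence.
    cbs_alpha:
        Permutation p-value threshold for accepting a segmentation split.
    cbs_permutations:
        Number of permutations per tested split.
    seed:
        Seed for the segmentation permutation RNG (the only stochastic step
        of the caller); fixed seed makes the pipeline deterministic.
    """

    lb: int = 1000
    tv_lambda: float = 0.15
    theta: float = 0.6
    k_fraction: float = 0.2
    m: int = 2
    r_l: int = 100
    min_clip: int = 20
    cbs_alpha: float = 0.01
    cbs_permutations: int = 1000
    seed: int = 0

    @property
    def search_radius(self) -> int:
        """Breakpoint search radius ``S = m * lb`` in bases."""
        return self.m * self.lb

    def validate(self) -> None:
        if self.lb < 100:
            raise ValueError(f"bin length lb must be >= 100, got {self.lb}")
        if self.tv_lambda < 0:
            raise ValueError("tv_lambda must be non-negative")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if not 0 < self.k_fraction <= 1:
            raise ValueError("k_fraction must be in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 1 <= self.min_clip < self.r_l:
            raise ValueError("min_clip must satisfy 1 <= min_clip < r_l")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a TOML config file; keyword arguments override file values."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg
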