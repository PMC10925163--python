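"""Run configuration: one structured record of every path and parameter.

Defaults encode the analysis conventions used throughout the package: a
200 bp scan window centred at the peak summit, a 2-mismatch consensus budget,
spacers of 0-8 N, 25 bp motif-neighbourhood distance, 500 bp peak merging,
+/-1 kb promoter distance, 12.5 kb super-enhancer stitching with a slope-1
cutoff, and pseudocount 1 in the screen ratio.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input paths (unused stages may leave theirs empty)
    genome: str | None = None
    peaks_wt: str | None = None
    peaks_ko: str | None = None
    track: str | None = None
    motifs: str | None = None
    counts: str | None = None
    outdir: str = "cistrokit_out"

    # parameters
    window: int = 200
    max_mismatch: int = 2
    spacer_max: int = 8
    neighbor_dist: int = 25
    merge_gap: int = 500
    promoter_dist: int = 1000
    stitch_dist: int = 12500
    slope: float = 1.0
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def override(self, **kwargs) -> "RunConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return RunConfig(**{**asdict(self), **clean})
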