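"""Super-enhancer calling by rank-curve slope analysis.

Peaks are stitched into regions (transitive closure of "gap <= stitch
distance", default 12,500 bp), scored by total signal over their constituent
peaks, ranked ascending, and scaled to the unit square. Super-enhancers are
the regions past the point where the curve's tangent slope reaches 1: the
cutoff is located where the unit-slope line is tangent to the scaled curve
(the rank minimising y - x), and every region beyond it is a call. When the
curve runs parallel to the unit line (slope exactly 1 over a plateau) the
plateau itself qualifies, so a perfectly linear curve calls every region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, PeakSet, SignalTrack

__all__ = ["StitchedRegion", "SECurve", "stitch_peaks", "score_regions",
           "call_superenhancers"]


@dataclass
class StitchedRegion:
    """A stitched enhancer cluster with its constituent source peaks."""

    interval: GenomicInterval
    constituents: list[GenomicInterval]
    score: float = 0.0


def stitch_peaks(peaks: PeakSet, stitch_dist: int = 12500) -> list[StitchedRegion]:
    """Stitch peaks whose gaps are <= ``stitch_dist`` into single regions.

    The relation is closed transitively along each chromosome; each region's
    interval spans the union of its constituents. Idempotent.
    """
    if not peaks.intervals:
        return []
    ivs = sorted(peaks.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    regions: list[StitchedRegion] = []
    cur = [ivs[0]]
    cur_end = ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur[0].chrom and iv.start - cur_end <= stitch_dist:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            regions.append(_close_region(cur, len(regions)))
            cur = [iv]
            cur_end = iv.end
    regions.append(_close_region(cur, len(regions)))
    return regions


def _close_region(constituents: list[GenomicInterval], idx: int) -> StitchedRegion:
    start = min(iv.start for iv in constituents)
    end = max(iv.end for iv in constituents)
    return StitchedRegion(
        interval=GenomicInterval(constituents[0].chrom, start, end,
                                 name=f"region_{idx + 1}",
                                 score=float(len(constituents))),
        constituents=list(constituents),
    )


def score_regions(regions: list[StitchedRegion], track: SignalTrack) -> list[StitchedRegion]:
    """Score each region by track signal summed over its constituent bp."""
    for region in regions:
        region.score = sum(
            track.sum(iv.chrom, iv.start, iv.end) for iv in region.constituents
        )
    return regions


@dataclass
class SECurve:
    """Unit-scaled rank curve with its slope-based super-enhancer cutoff.

    ``regions`` are ranked ascending by score; ``x`` is rank scaled to [0, 1],
    ``y`` score scaled to [0, 1]. ``cutoff_index`` is the 0-based index of the
    lowest-ranked region called super; every region at or above it is a call.
    """

    regions: list[StitchedRegion]
    x: np.ndarray
    y: np.ndarray
    slope: np.ndarray
    cutoff_index: int
    slope_at_cutoff: float

    @property
    def calls(self) -> list[StitchedRegion]:
        return self.regions[self.cutoff_index:]

    @property
    def n_super(self) -> int:
        return len(self.regions) - self.cutoff_index

    def to_frame(self, all_regions: bool = True) -> pd.DataFrame:
        rows = []
        for i, region in enumerate(self.regions):
            if not all_regions and i < self.cutoff_index:
                continue
            iv = region.interval
            rows.append({
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "name": iv.name, "n_constituents": len(region.constituents),
                "score": region.score, "rank": i + 1,
                "x": self.x[i], "y": self.y[i], "slope": self.slope[i],
                "is_super": i >= self.cutoff_index,
            })
        return pd.DataFrame(rows)


def call_superenhancers(regions: list[StitchedRegion], min_slope: float = 1.0) -> SECurve:
    """Classify scored regions by tangent slope of the unit-scaled rank curve.

    Scores are ranked ascending (ties broken by coordinates), x = (rank-1)/(N-1),
    y = score/max(score). The cutoff is the tangent point of the line of
    slope ``min_slope``: the rank minimising y - min_slope*x. Every region
    strictly past the tangent point is a super-enhancer; if the minimum is
    attained on a plateau (curve locally parallel to the threshold line,
    i.e. slope exactly ``min_slope``) the plateau's first rank starts the
    calls, so a perfectly linear curve calls all regions. Past the tangent
    point the discrete slope (y[i]-y[i-1])/(x[i]-x[i-1]) is >= ``min_slope``
    by construction. Calls are invariant to positive rescaling of scores.
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 scored regions")
    ordered = sorted(
        regions,
        key=lambda r: (r.score, r.interval.chrom, r.interval.start, r.interval.end),
    )
    scores = np.array([r.score for r in ordered], dtype=float)
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate curve: all region scores equal")
    n = len(ordered)
    x = np.arange(n) / (n - 1)
    y = scores / scores.max()
    # discrete slope of the segment arriving at each rank; one-sided at rank 1
    slope = np.empty(n)
    slope[1:] = np.diff(y) / np.diff(x)
    slope[0] = slope[1]
    # tangent point of the threshold line against the scaled curve
    d = y - min_slope * x
    d_min = float(d.min())
    tol = 1e-9 * max(1.0, abs(d_min))
    plateau = np.flatnonzero(d <= d_min + tol)
    if plateau.size > 1 and np.all(np.diff(plateau) == 1):
        # curve parallel to the threshold line over the plateau: include it
        cutoff = int(plateau[0])
    else:
        cutoff = int(plateau[-1]) + 1
    if cutoff >= n:
        return SECurve(ordered, x, y, slope, n, float("nan"))
    return SECurve(ordered, x, y, slope, cutoff, float(slope[cutoff]))
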