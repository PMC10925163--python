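"""Peak-set algebra, dependency partitioning, motif enrichment, signal matrices.

Overlap semantics follow the usual ChIP-seq comparison contract: two intervals
overlap iff they share at least one base in half-open coordinates. Peaks
closer than a configurable gap (default 500 bp) are reduced to single peaks
before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GenomicInterval, PeakSet, SequenceStore, SignalTrack
from .motifs import ConsensusMotif, CompositeMotif, scan_peaks

__all__ = [
    "OverlapPartition",
    "DependencyClasses",
    "Gene",
    "merge_within",
    "partition_overlap",
    "classify_dependency",
    "annotate_location",
    "gc_matched_background",
    "motif_enrichment",
    "motif_foldchange_between_sets",
    "signal_matrix",
]


def merge_within(peaks: PeakSet, maxgap: int = 500) -> PeakSet:
    """Reduce peaks within ``maxgap`` bp of each other to single peaks.

    Two peaks are joined when the gap between them (next.start - prev.end;
    negative for overlap) is <= ``maxgap``. Output spans the union of each
    merged run, sorted and non-overlapping; the operation is idempotent.
    Summit of a merged peak is dropped (midpoint used downstream).
    """
    if not peaks.intervals:
        return PeakSet(peaks.label, [])
    ivs = sorted(peaks.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end, n = ivs[0].chrom, ivs[0].start, ivs[0].end, 1
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= maxgap:
            cur_end = max(cur_end, iv.end)
            n += 1
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end,
                                          name=f"{peaks.label or 'peak'}_{len(merged) + 1}",
                                          score=float(n)))
            cur_chrom, cur_start, cur_end, n = iv.chrom, iv.start, iv.end, 1
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end,
                                  name=f"{peaks.label or 'peak'}_{len(merged) + 1}",
                                  score=float(n)))
    return PeakSet(peaks.label, merged)


@dataclass
class OverlapPartition:
    """Two-condition overlap partition for a Venn summary.

    Every merged input peak lands in exactly one of ``a_only``, ``b_only`` or
    ``shared`` (shared holds peaks from both sides; ``counts`` reports the
    per-side shared tallies separately).
    """

    a_only: PeakSet
    b_only: PeakSet
    shared: PeakSet
    labels: tuple[str, str]

    @property
    def counts(self) -> dict[str, int]:
        shared_a = sum(1 for iv in self.shared if iv.name.startswith("A:"))
        shared_b = len(self.shared) - shared_a
        return {
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "shared_a": shared_a,
            "shared_b": shared_b,
        }


def _overlap_tree(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def partition_overlap(a: PeakSet, b: PeakSet) -> OverlapPartition:
    """Partition two (pre-merged) peak sets by >=1 bp overlap.

    A peak is "shared" iff it overlaps at least one base of any peak of the
    other set (half-open: abutting peaks do not overlap). Shared peaks keep
    an ``A:``/``B:`` name prefix so per-side Venn tallies remain available.
    """
    trees_a, trees_b = _overlap_tree(a), _overlap_tree(b)

    def split(peaks: PeakSet, other: dict[str, IntervalTree], tag: str):
        only, shared = [], []
        for iv in peaks:
            tree = other.get(iv.chrom)
            if tree is not None and tree.overlaps(iv.start, iv.end):
                shared.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                              name=f"{tag}:{iv.name}", score=iv.score,
                                              strand=iv.strand))
            else:
                only.append(iv)
        return only, shared

    a_only, a_shared = split(a, trees_b, "A")
    b_only, b_shared = split(b, trees_a, "B")
    return OverlapPartition(
        a_only=PeakSet(f"{a.label}_only", a_only),
        b_only=PeakSet(f"{b.label}_only", b_only),
        shared=PeakSet("shared", a_shared + b_shared),
        labels=(a.label, b.label),
    )


@dataclass
class DependencyClasses:
    """Condition-dependency classes of a two-condition cistrome.

    ``lost`` = condition-A-only peaks (dependent on the perturbed factor),
    ``retained`` = shared, ``gained`` = condition-B-only.
    """

    lost: PeakSet
    retained: PeakSet
    gained: PeakSet
    fraction_lost: float

    @property
    def counts(self) -> dict[str, int]:
        return {
            "lost": len(self.lost),
            "retained": len(self.retained),
            "gained": len(self.gained),
        }


def classify_dependency(wt: PeakSet, ko: PeakSet) -> DependencyClasses:
    """Label peaks lost/retained/gained between wild-type and knock-out sets.

    ``fraction_lost`` = |lost| / |wt| — the dependent fraction of the
    wild-type cistrome. Retained peaks are reported in wild-type coordinates.
    """
    if not wt.intervals:
        raise ValueError("wild-type peak set is empty")
    part = partition_overlap(wt, ko)
    retained = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name.removeprefix("A:"),
                        score=iv.score, strand=iv.strand)
        for iv in part.shared
        if iv.name.startswith("A:")
    ]
    return DependencyClasses(
        lost=part.a_only.with_label("lost"),
        retained=PeakSet("retained", retained),
        gained=part.b_only.with_label("gained"),
        fraction_lost=len(part.a_only) / len(wt),
    )


@dataclass(frozen=True)
class Gene:
    """Minimal gene model for peak annotation. TSS derives from strand."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def annotate_location(
    peaks: PeakSet,
    genes: Sequence[Gene],
    promoter_dist: int = 1000,
) -> pd.DataFrame:
    """Assign each peak a genomic category by its centre position.

    Categories, in precedence order: promoter (centre within +/-``promoter_dist``
    bp of a TSS), exon, intron (inside a gene body but not an exon), and
    distal_intergenic.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    exon_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for g in genes:
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        for es, ee in g.exons:
            exon_trees.setdefault(g.chrom, IntervalTree()).addi(es, ee)

    rows = []
    for idx, iv in enumerate(peaks):
        c = iv.center
        category = "distal_intergenic"
        tss = tss_by_chrom.get(iv.chrom)
        if tss is not None and tss.size:
            j = int(np.searchsorted(tss, c))
            near = min(
                (abs(c - int(tss[k])) for k in (j - 1, j) if 0 <= k < tss.size),
                default=None,
            )
            if near is not None and near <= promoter_dist:
                category = "promoter"
        if category != "promoter":
            et = exon_trees.get(iv.chrom)
            if et is not None and et.overlaps(c, c + 1):
                category = "exon"
            else:
                bt = body_trees.get(iv.chrom)
                if bt is not None and bt.overlaps(c, c + 1):
                    category = "intron"
        rows.append({"peak_index": idx, "chrom": iv.chrom, "start": iv.start,
                     "end": iv.end, "name": iv.name, "category": category})
    return pd.DataFrame(rows, columns=["peak_index", "chrom", "start", "end",
                                       "name", "category"])


def _gc_fraction(seq: str) -> float:
    informative = sum(1 for b in seq if b in "ACGT")
    if informative == 0:
        return 0.0
    return sum(1 for b in seq if b in "GC") / informative


def gc_matched_background(
    fg: PeakSet,
    genome: SequenceStore,
    n_per_fg: int = 1,
    gc_bin_width: float = 0.05,
    seed: int = 0,
    max_tries: int = 2000,
) -> PeakSet:
    """Sample background intervals length-matched and GC-matched to ``fg``.

    For each foreground interval, ``n_per_fg`` intervals of the same length
    are drawn whose GC content falls in the same GC bin, rejected if they
    overlap any foreground interval. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    fg_trees = _overlap_tree(fg)
    chroms = genome.chroms
    lengths = np.array([genome.length(c) for c in chroms])
    weights = lengths / lengths.sum()

    out: list[GenomicInterval] = []
    deficits: dict[int, int] = {}
    for i, iv in enumerate(fg):
        width = len(iv)
        target_bin = int(_gc_fraction(genome.fetch(iv.chrom, iv.start, iv.end)) / gc_bin_width)
        found = 0
        for _ in range(max_tries):
            if found == n_per_fg:
                break
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            if lengths[ci] <= width:
                continue
            start = int(rng.integers(0, lengths[ci] - width))
            tree = fg_trees.get(chrom)
            if tree is not None and tree.overlaps(start, start + width):
                continue
            gc_bin = int(_gc_fraction(genome.fetch(chrom, start, start + width)) / gc_bin_width)
            if gc_bin != target_bin:
                continue
            out.append(GenomicInterval(chrom, start, start + width,
                                       name=f"bg_{i}_{found}"))
            found += 1
        if found < n_per_fg:
            deficits[target_bin] = deficits.get(target_bin, 0) + (n_per_fg - found)
    if deficits:
        detail = ", ".join(
            f"GC bin {b * gc_bin_width:.2f}-{(b + 1) * gc_bin_width:.2f}: short {d}"
            for b, d in sorted(deficits.items())
        )
        raise RuntimeError(f"insufficient eligible genome for GC-matched background ({detail})")
    return PeakSet("background", out)


def _presence_counts(
    peaks: PeakSet,
    genome: SequenceStore,
    motifs: Sequence[ConsensusMotif | CompositeMotif],
    window: int,
) -> dict[str, int]:
    df = scan_peaks(peaks, genome, motifs, window=window)
    return df.groupby("motif", sort=False)["present"].sum().astype(int).to_dict()


def motif_enrichment(
    fg: PeakSet,
    bg: PeakSet,
    genome: SequenceStore,
    motifs: Sequence[ConsensusMotif | CompositeMotif],
    window: int = 200,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Known-motif enrichment of foreground peaks against a background set.

    Presence is the per-peak flag from :func:`scan_peaks`. The p-value is the
    upper-tail hypergeometric probability of drawing >= fg_hits motif-positive
    peaks when |fg| peaks are drawn from the pooled fg+bg population; q-values
    are Benjamini-Hochberg across the motif list. log2 fold change uses a
    pseudocount on hit counts so zero counts stay finite.
    """
    if not fg.intervals or not bg.intervals:
        raise ValueError("foreground and background must be non-empty")
    fg_counts = _presence_counts(fg, genome, motifs, window)
    bg_counts = _presence_counts(bg, genome, motifs, window)
    n_fg, n_bg = len(fg), len(bg)
    rows = []
    for m in motifs:
        name = (m.derived if isinstance(m, CompositeMotif) else m).name
        k_fg = fg_counts.get(name, 0)
        k_bg = bg_counts.get(name, 0)
        total_hits = k_fg + k_bg
        # P(X >= k_fg), X ~ Hypergeom(M=n_fg+n_bg, n=total_hits, N=n_fg)
        p = float(stats.hypergeom.sf(k_fg - 1, n_fg + n_bg, total_hits, n_fg))
        fg_frac = k_fg / n_fg
        bg_frac = k_bg / n_bg
        log2fc = float(
            np.log2(((k_fg + pseudocount) / n_fg) / ((k_bg + pseudocount) / n_bg))
        )
        rows.append({
            "motif_name": name,
            "fg_hits": k_fg, "fg_total": n_fg,
            "bg_hits": k_bg, "bg_total": n_bg,
            "fg_fraction": fg_frac, "bg_fraction": bg_frac,
            "log2_fold_change": log2fc, "p_value": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    df["q_value"] = np.maximum(df["q_value"], df["p_value"])
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def motif_foldchange_between_sets(
    set_a: PeakSet,
    set_b: PeakSet,
    genome: SequenceStore,
    motifs: Sequence[ConsensusMotif | CompositeMotif],
    window: int = 200,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-motif presence fractions in two peak sets and their log2 ratio.

    Significance is the same two-group hypergeometric as
    :func:`motif_enrichment` with ``set_a`` as the drawn group.
    """
    if not set_a.intervals or not set_b.intervals:
        raise ValueError("both peak sets must be non-empty")
    df = motif_enrichment(set_a, set_b, genome, motifs,
                          window=window, pseudocount=pseudocount)
    return df.rename(columns={
        "fg_hits": "a_hits", "fg_total": "a_total",
        "bg_hits": "b_hits", "bg_total": "b_total",
        "fg_fraction": "a_fraction", "bg_fraction": "b_fraction",
    })


def signal_matrix(
    track: SignalTrack,
    intervals: PeakSet,
    half_width: int,
    bin: int = 25,
) -> pd.DataFrame:
    """Reference-point signal matrix: mean signal per fixed-width bin.

    Rows are intervals; columns are ``bin``-bp bins spanning
    [centre - half_width, centre + half_width) around the summit (midpoint
    fallback). Positions without track coverage contribute zeros, keeping the
    matrix rectangular. Column labels are bin-centre offsets from the
    reference point.
    """
    if (2 * half_width) % bin != 0:
        raise ValueError(f"bin size {bin} does not divide window {2 * half_width}")
    n_bins = (2 * half_width) // bin
    centers = np.arange(n_bins) * bin - half_width + bin / 2
    mat = np.zeros((len(intervals), n_bins))
    for i, iv in enumerate(intervals):
        ref = iv.summit
        vals = _window_values(track, iv.chrom, ref - half_width, ref + half_width)
        mat[i] = vals.reshape(n_bins, bin).mean(axis=1)
    df = pd.DataFrame(mat, columns=centers)
    df.attrs["half_width"] = half_width
    df.attrs["bin"] = bin
    return df


def _window_values(track: SignalTrack, chrom: str, start: int, end: int) -> np.ndarray:
    """Track values over [start, end) tolerating negative start (zero-padded)."""
    if start >= 0:
        return track.values(chrom, start, end)
    pad = -start
    return np.concatenate([np.zeros(pad), track.values(chrom, 0, end)])
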