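"""Stage orchestration: run the analysis stages in dependency order.

``run_pipeline`` executes whichever stages the configuration provides inputs
for (scan -> classify -> enrich -> super-enhancer; screen ranking is
independent), writes every stage's outputs under the configured output
directory, and returns a run report listing files, parameters and per-file
checksums. Inputs are validated before any stage runs; no stage mutates
another stage's inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import cistrome, screen, superenhancer
from .config import RunConfig
from .io_formats import (
    read_bed,
    read_bedgraph,
    read_fasta,
    read_guide_counts,
    write_bed,
)
from .motifs import read_motif_file, scan_peaks

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("cistrokit")


class PipelineError(RuntimeError):
    """A named pre-flight or stage failure."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(config: RunConfig, stage: str, *keys: str) -> None:
    missing = [k for k in keys if getattr(config, k) is None]
    if missing:
        raise PipelineError(f"stage {stage!r} requires config keys {missing}")
    absent = [k for k in keys if not Path(getattr(config, k)).exists()]
    if absent:
        raise PipelineError(
            f"stage {stage!r}: input files not found: "
            + ", ".join(f"{k}={getattr(config, k)}" for k in absent)
        )


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: every stage with inputs configured).

    Returns the run report (also written to ``<outdir>/report.json``).
    """
    available = {
        "scan": ("genome", "peaks_wt", "motifs"),
        "classify": ("peaks_wt", "peaks_ko"),
        "enrich": ("genome", "peaks_wt", "peaks_ko", "motifs"),
        "superenhancer": ("peaks_wt", "track"),
        "screen-rank": ("counts",),
    }
    if stages is None:
        stages = [s for s, keys in available.items()
                  if all(getattr(config, k) is not None for k in keys)]
    unknown = [s for s in stages if s not in available]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    # pre-flight: every referenced input must exist before anything runs
    for stage in stages:
        _require(config, stage, *available[stage])

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    report: dict = {"stages": {}, "outputs": {}, "config": str(outdir / "config.yaml")}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            outputs = _STAGE_FUNCS[stage](config, outdir)
            elapsed = time.perf_counter() - t0
            log.info("stage %s: done in %.2fs", stage, elapsed)
            report["stages"][stage] = {
                "seconds": round(elapsed, 3),
                "outputs": [str(p) for p in outputs],
            }
            for p in outputs:
                report["outputs"][str(p)] = _sha256(p)
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return report


def _stage_scan(config: RunConfig, outdir: Path) -> list[Path]:
    genome = read_fasta(config.genome)
    peaks = read_bed(config.peaks_wt)
    motifs = read_motif_file(config.motifs)
    df = scan_peaks(peaks, genome, motifs, window=config.window)
    out = outdir / "scan.tsv"
    df.to_csv(out, sep="\t", index=False)
    return [out]


def _stage_classify(config: RunConfig, outdir: Path) -> list[Path]:
    wt = cistrome.merge_within(read_bed(config.peaks_wt), maxgap=config.merge_gap)
    ko = cistrome.merge_within(read_bed(config.peaks_ko), maxgap=config.merge_gap)
    classes = cistrome.classify_dependency(wt, ko)
    outputs = []
    for name, ps in (("lost", classes.lost), ("retained", classes.retained),
                     ("gained", classes.gained)):
        path = outdir / f"{name}.bed"
        write_bed(ps, path)
        outputs.append(path)
    summary = outdir / "venn.json"
    with open(summary, "w") as fh:
        json.dump({**classes.counts, "fraction_lost": classes.fraction_lost},
                  fh, indent=2)
        fh.write("\n")
    outputs.append(summary)
    return outputs


def _stage_enrich(config: RunConfig, outdir: Path) -> list[Path]:
    genome = read_fasta(config.genome)
    wt = cistrome.merge_within(read_bed(config.peaks_wt), maxgap=config.merge_gap)
    ko = cistrome.merge_within(read_bed(config.peaks_ko), maxgap=config.merge_gap)
    motifs = read_motif_file(config.motifs)
    classes = cistrome.classify_dependency(wt, ko)
    if not classes.lost.intervals or not classes.retained.intervals:
        raise PipelineError("enrich: need non-empty lost and retained classes")
    df = cistrome.motif_foldchange_between_sets(
        classes.lost, classes.retained, genome, motifs, window=config.window
    )
    out = outdir / "enrichment_lost_vs_retained.tsv"
    df.to_csv(out, sep="\t", index=False)
    return [out]


def _stage_superenhancer(config: RunConfig, outdir: Path) -> list[Path]:
    peaks = cistrome.merge_within(read_bed(config.peaks_wt), maxgap=config.merge_gap)
    track = read_bedgraph(config.track)
    regions = superenhancer.score_regions(
        superenhancer.stitch_peaks(peaks, stitch_dist=config.stitch_dist), track
    )
    curve = superenhancer.call_superenhancers(regions, min_slope=config.slope)
    table = outdir / "superenhancers.tsv"
    curve.to_frame(all_regions=True).to_csv(table, sep="\t", index=False)
    calls = outdir / "superenhancers.bed"
    from .io_formats import PeakSet
    write_bed(PeakSet("superenhancers", [r.interval for r in curve.calls]), calls)
    return [table, calls]


def _stage_screen(config: RunConfig, outdir: Path) -> list[Path]:
    table = read_guide_counts(config.counts)
    ranks = screen.rank_guides(screen.normalize_cpm(table),
                               pseudocount=config.pseudocount)
    genes = screen.aggregate_genes(ranks)
    out_g = outdir / "guide_ranks.tsv"
    out_gene = outdir / "gene_scores.tsv"
    ranks.to_csv(out_g, sep="\t", index=False)
    genes.to_csv(out_gene, sep="\t", index=False)
    return [out_g, out_gene]


_STAGE_FUNCS = {
    "scan": _stage_scan,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
    "superenhancer": _stage_superenhancer,
    "screen-rank": _stage_screen,
}
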