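"""Seeded synthetic-data generators with ground-truth manifests.

Every generator is a pure function of its seed and parameters. Each dataset
ships with a :class:`TruthManifest` recording the planted structure (site
positions, mismatch counts, dependent fraction, super-enhancer count,
enriched guides), sufficient to recompute every expected recovery value
without re-running the generator.

Background DNA is i.i.d. with a configurable GC content. After planting,
windows that are scanned downstream are scrubbed of chance motif matches
(offending background positions are redrawn), so the manifest is exact truth
for presence and best-mismatch recovery rather than truth-up-to-background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import GenomicInterval, PeakSet, SequenceStore, SignalTrack
from .motifs import (
    CompositeMotif,
    ConsensusMotif,
    IUPAC_SETS,
    build_composite,
    match_consensus,
)

__all__ = [
    "TruthManifest",
    "gen_genome",
    "plant_composite_sites",
    "gen_two_condition_cistrome",
    "gen_hockey_signal",
    "gen_screen_counts",
    "DEFAULT_DEPENDENT_MOTIF",
    "DEFAULT_INDEPENDENT_MOTIF",
]

# Default planted motifs. The chimeric composite juxtaposes a forkhead-type
# element with the AR half-site AGAACA; the full-site default is the 15 bp
# palindromic ARE (two inverted AGAACA half-sites, 3 bp spacer). The forkhead
# consensus here is a synthetic stand-in for scanner exercises, not a curated
# matrix.
_FKHD = ConsensusMotif("FKHD", "TGTTTAC", 2)
_AR_HALF = ConsensusMotif("AR-half", "AGAACA", 2)
DEFAULT_DEPENDENT_MOTIF = build_composite(_FKHD, _AR_HALF, spacer=0, order="AB",
                                          orient_b="same").derived
DEFAULT_INDEPENDENT_MOTIF = build_composite(_AR_HALF, _AR_HALF, spacer=3,
                                            order="AB", orient_b="revcomp").derived


@dataclass
class TruthManifest:
    """Planted ground truth for one synthetic dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"kind": self.kind, "seed": self.seed, "params": self.params,
                 "records": self.records, "warnings": self.warnings},
                fh, indent=2, default=_jsonable,
            )
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(kind=obj["kind"], seed=obj["seed"], params=obj["params"],
                   records=obj["records"], warnings=obj.get("warnings", []))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytearray(_BASES[rng.choice(4, size=n, p=p)].tobytes())


def gen_genome(
    seed: int,
    n_chrom: int = 1,
    chrom_len: int = 100_000,
    gc: float = 0.41,
) -> SequenceStore:
    """I.i.d. random genome with P(G or C) = ``gc``; deterministic per seed."""
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    store = SequenceStore()
    for i in range(n_chrom):
        store.add(f"chr{i + 1}", _random_bases(rng, chrom_len, gc).decode())
    return store


def _realize_consensus(rng: np.random.Generator, consensus: str, n_mismatch: int) -> str:
    """A concrete DNA instance of an IUPAC consensus with exactly ``n_mismatch``
    mismatching positions, never at consensus-N (spacer) positions."""
    bases = [rng.choice(sorted(IUPAC_SETS[c])) for c in consensus]
    informative = [i for i, c in enumerate(consensus) if c != "N"]
    if n_mismatch > len(informative):
        raise ValueError("more mismatches requested than informative positions")
    for i in rng.choice(len(informative), size=n_mismatch, replace=False):
        pos = informative[int(i)]
        options = sorted(set("ACGT") - IUPAC_SETS[consensus[pos]])
        bases[pos] = rng.choice(options)
    return "".join(bases)


def _scrub_window(
    chrom_seq: bytearray,
    lo: int,
    hi: int,
    motifs: Sequence[ConsensusMotif],
    protected: set[tuple[int, int]],
    rng: np.random.Generator,
    gc: float,
    max_rounds: int = 50,
) -> None:
    """Redraw background bases until no chance match survives in [lo, hi).

    Matches whose footprint is in ``protected`` are planted truth and kept;
    protected positions are never redrawn.
    """
    protected_pos = set()
    for s, e in protected:
        protected_pos.update(range(s, e))
    for _ in range(max_rounds):
        window = chrom_seq[lo:hi].decode()
        offenders = []
        for motif in motifs:
            for m in match_consensus(window, motif, offset=lo):
                if (m.interval.start, m.interval.end) not in protected:
                    offenders.append(m)
        if not offenders:
            return
        redraw = sorted(
            {p for m in offenders
             for p in range(m.interval.start, m.interval.end)} - protected_pos
        )
        fresh = _random_bases(rng, len(redraw), gc)
        for p, b in zip(redraw, fresh):
            chrom_seq[p] = b


def plant_composite_sites(
    genome: SequenceStore,
    composite: CompositeMotif | ConsensusMotif,
    n_sites: int,
    mismatch_dist: dict[int, float] | None = None,
    seed: int = 0,
    peak_width: int = 200,
    gc: float = 0.41,
    scrub: bool = True,
) -> tuple[SequenceStore, PeakSet, TruthManifest]:
    """Plant composite-motif instances into a genome, one per 200 bp peak.

    Each planted instance realises the consensus with a mismatch count drawn
    from ``mismatch_dist`` (mutations never fall on spacer Ns); a peak of
    ``peak_width`` bp is centred on every site, with the summit at the site.
    Sites never overlap each other or peak boundaries. Returns the modified
    genome, the peak set, and the truth manifest.
    """
    motif = composite.derived if isinstance(composite, CompositeMotif) else composite
    if mismatch_dist is None:
        mismatch_dist = {0: 1.0}
    if abs(sum(mismatch_dist.values()) - 1.0) > 1e-9:
        raise ValueError("mismatch_dist probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(genome.sequence(c).encode()) for c in genome.chroms}

    slot = peak_width + 10
    slots: list[tuple[str, int]] = []  # (chrom, peak start)
    for chrom in genome.chroms:
        n_slots = genome.length(chrom) // slot
        slots.extend((chrom, i * slot + 5) for i in range(n_slots))
    if n_sites > len(slots):
        raise ValueError(
            f"genome too small: {len(slots)} candidate sites for {n_sites} requested"
        )
    chosen = [slots[int(i)] for i in rng.choice(len(slots), size=n_sites, replace=False)]
    chosen.sort()

    mm_levels = sorted(mismatch_dist)
    mm_probs = np.array([mismatch_dist[k] for k in mm_levels])
    L = len(motif)
    intervals, site_records = [], []
    for i, (chrom, start) in enumerate(chosen):
        center = start + peak_width // 2
        site_start = center - L // 2
        n_mm = int(np.asarray(mm_levels)[rng.choice(len(mm_levels), p=mm_probs)])
        instance = _realize_consensus(rng, motif.consensus, n_mm)
        seqs[chrom][site_start : site_start + L] = instance.encode()
        intervals.append(
            GenomicInterval(chrom, start, start + peak_width, name=f"site_{i + 1}",
                            summit_offset=center - start)
        )
        site_records.append(
            {"name": f"site_{i + 1}", "chrom": chrom, "peak_start": start,
             "site_start": site_start, "site_end": site_start + L,
             "mismatches": n_mm}
        )
    if scrub:
        for iv, rec in zip(intervals, site_records):
            protected = set()
            if rec["mismatches"] <= motif.max_mismatch:
                protected.add((rec["site_start"], rec["site_end"]))
            half = peak_width // 2
            lo = max(0, iv.summit - half)
            hi = min(len(seqs[iv.chrom]), iv.summit + half)
            _scrub_window(seqs[iv.chrom], lo, hi, [motif], protected, rng, gc)

    out = SequenceStore()
    for chrom in genome.chroms:
        out.add(chrom, seqs[chrom].decode())
    manifest = TruthManifest(
        kind="planted_composite_sites",
        seed=seed,
        params={"motif": motif.consensus, "motif_name": motif.name,
                "max_mismatch": motif.max_mismatch, "n_sites": n_sites,
                "peak_width": peak_width,
                "mismatch_dist": {str(k): v for k, v in mismatch_dist.items()}},
        records={
            "sites": site_records,
            "expected_presence": float(
                sum(mismatch_dist.get(k, 0.0) for k in mismatch_dist
                    if k <= motif.max_mismatch)
            ),
            "mean_planted_mismatch": float(
                np.mean([r["mismatches"] for r in site_records])
            ) if site_records else float("nan"),
        },
    )
    return out, PeakSet("planted", intervals), manifest


def gen_two_condition_cistrome(
    seed: int,
    n_wt: int = 1000,
    dependent_frac: float = 0.65,
    motif_dependent: ConsensusMotif | CompositeMotif | None = None,
    motif_independent: ConsensusMotif | CompositeMotif | None = None,
    purity_dependent: float = 1.0,
    purity_independent: float = 1.0,
    cross_frac: float = 0.0,
    n_gained: int = 0,
    peak_width: int = 200,
    gap: int = 600,
    gc: float = 0.41,
) -> tuple[PeakSet, PeakSet, SequenceStore, TruthManifest]:
    """Two-condition cistrome with a known dependent fraction and motif classes.

    The wild-type set holds ``n_wt`` peaks of which ``round(n_wt *
    dependent_frac)`` are dependent (lost in the knock-out); the knock-out set
    is the independent subset plus ``n_gained`` novel peaks. The chimeric
    composite is planted in ``purity_dependent`` of dependent peaks, the
    full-site motif in ``purity_independent`` of independent peaks, and the
    chimeric motif additionally in ``cross_frac`` of independent peaks.
    Adjacent peaks are separated by ``gap`` bp (default 600, beyond the 500 bp
    merge distance, so merging leaves them intact).
    """
    if not 0 <= dependent_frac <= 1:
        raise ValueError("dependent_frac must be in [0, 1]")
    m_dep = motif_dependent or DEFAULT_DEPENDENT_MOTIF
    m_ind = motif_independent or DEFAULT_INDEPENDENT_MOTIF
    m_dep = m_dep.derived if isinstance(m_dep, CompositeMotif) else m_dep
    m_ind = m_ind.derived if isinstance(m_ind, CompositeMotif) else m_ind

    rng = np.random.default_rng(seed)
    n_dep = round(n_wt * dependent_frac)
    n_ind = n_wt - n_dep
    n_total = n_wt + n_gained
    stride = peak_width + gap
    margin = 500
    chrom_len = n_total * stride + 2 * margin
    genome_seq = _random_bases(rng, chrom_len, gc)
    chrom = "chr1"

    # class layout along the chromosome is itself randomised
    classes = (["dependent"] * n_dep + ["independent"] * n_ind + ["gained"] * n_gained)
    classes = [classes[int(i)] for i in rng.permutation(n_total)]

    def pick(indices: list[int], frac: float) -> set[int]:
        k = round(len(indices) * frac)
        if k == 0:
            return set()
        return {indices[int(i)] for i in rng.choice(len(indices), size=k, replace=False)}

    dep_idx = [i for i, c in enumerate(classes) if c == "dependent"]
    ind_idx = [i for i, c in enumerate(classes) if c == "independent"]
    gained_idx = [i for i, c in enumerate(classes) if c == "gained"]
    with_dep_motif = pick(dep_idx, purity_dependent)
    with_ind_motif = pick(ind_idx, purity_independent) | pick(gained_idx, purity_independent)
    with_cross_motif = pick(ind_idx, cross_frac)

    peak_records = []
    intervals = []
    for i in range(n_total):
        start = margin + i * stride
        center = start + peak_width // 2
        planted = []
        # chimeric motif left of centre, full site right, so both fit in the
        # scan window when a peak carries both
        if i in with_dep_motif or i in with_cross_motif:
            s = center - 40 - len(m_dep) // 2
            genome_seq[s : s + len(m_dep)] = _realize_consensus(
                rng, m_dep.consensus, 0).encode()
            planted.append({"motif": m_dep.name, "start": s, "end": s + len(m_dep)})
        if i in with_ind_motif:
            s = center + 40 - len(m_ind) // 2
            genome_seq[s : s + len(m_ind)] = _realize_consensus(
                rng, m_ind.consensus, 0).encode()
            planted.append({"motif": m_ind.name, "start": s, "end": s + len(m_ind)})
        intervals.append(
            GenomicInterval(chrom, start, start + peak_width,
                            name=f"peak_{i + 1}", summit_offset=peak_width // 2)
        )
        peak_records.append({"name": f"peak_{i + 1}", "class": classes[i],
                             "start": start, "planted": planted})

    motif_by_name = {m_dep.name: m_dep, m_ind.name: m_ind}
    for iv, rec in zip(intervals, peak_records):
        protected = {(p["start"], p["end"]) for p in rec["planted"]}
        half = peak_width // 2
        lo, hi = iv.summit - half, iv.summit + half
        _scrub_window(genome_seq, max(0, lo), min(chrom_len, hi),
                      list(motif_by_name.values()), protected, rng, gc)

    genome = SequenceStore({chrom: genome_seq.decode()})
    wt = PeakSet("wt", [iv for iv, r in zip(intervals, peak_records)
                        if r["class"] != "gained"])
    ko = PeakSet("ko", [iv for iv, r in zip(intervals, peak_records)
                        if r["class"] != "dependent"])
    manifest = TruthManifest(
        kind="two_condition_cistrome",
        seed=seed,
        params={"n_wt": n_wt, "dependent_frac": dependent_frac,
                "purity_dependent": purity_dependent,
                "purity_independent": purity_independent,
                "cross_frac": cross_frac, "n_gained": n_gained,
                "motif_dependent": m_dep.consensus,
                "motif_independent": m_ind.consensus,
                "peak_width": peak_width},
        records={
            "peaks": peak_records,
            "n_dependent": n_dep,
            "n_independent": n_ind,
            "true_dependent_frac": n_dep / n_wt,
            "frac_dep_motif_in_dependent": len(with_dep_motif) / n_dep if n_dep else 0.0,
            "frac_dep_motif_in_independent": len(with_cross_motif) / n_ind if n_ind else 0.0,
            "frac_ind_motif_in_independent": (
                len(with_ind_motif) / (n_ind + n_gained) if n_ind + n_gained else 0.0
            ),
        },
    )
    return wt, ko, genome, manifest


def gen_hockey_signal(
    seed: int,
    n_typical: int = 990,
    n_super: int = 10,
    typical_range: tuple[float, float] = (1.0, 10.0),
    super_range: tuple[float, float] = (100.0, 200.0),
    region_len: int = 1000,
    gap: int = 20_000,
) -> tuple[SignalTrack, PeakSet, TruthManifest]:
    """Hockey-stick-ranked enhancer signal with a known super-enhancer count.

    ``n_typical`` regions draw scores from ``typical_range`` and ``n_super``
    from ``super_range``; each region is a ``region_len`` bp rectangle of
    constant signal whose total (value x bp) equals its score. Regions are
    ``gap`` bp apart (beyond the 12.5 kb stitch distance by default), so
    stitching keeps them separate.
    """
    rng = np.random.default_rng(seed)
    manifest_warnings = []
    if n_super and super_range[0] <= typical_range[1]:
        manifest_warnings.append(
            f"score ranges overlap: typical {typical_range} vs super {super_range}"
        )
    scores = np.concatenate([
        rng.uniform(*typical_range, size=n_typical),
        rng.uniform(*super_range, size=n_super) if n_super else np.zeros(0),
    ])
    order = rng.permutation(scores.size)
    scores = scores[order]
    is_super = np.concatenate([
        np.zeros(n_typical, dtype=bool), np.ones(n_super, dtype=bool)
    ])[order]

    chrom = "chr1"
    stride = region_len + gap
    intervals, steps, records = [], [], []
    for i, (score, sup) in enumerate(zip(scores, is_super)):
        start = 1000 + i * stride
        end = start + region_len
        intervals.append(GenomicInterval(chrom, start, end, name=f"enh_{i + 1}"))
        steps.append((start, end, score / region_len))
        records.append({"name": f"enh_{i + 1}", "start": start, "end": end,
                        "score": float(score), "is_super": bool(sup)})
    track = SignalTrack({chrom: steps})
    manifest = TruthManifest(
        kind="hockey_signal",
        seed=seed,
        params={"n_typical": n_typical, "n_super": n_super,
                "typical_range": list(typical_range),
                "super_range": list(super_range), "region_len": region_len,
                "gap": gap},
        records={"regions": records, "n_super": n_super},
        warnings=manifest_warnings,
    )
    return track, PeakSet("enhancers", intervals), manifest


def gen_screen_counts(
    seed: int,
    n_guides: int = 1500,
    n_genes: int = 200,
    frac_enriched: float = 0.02,
    effect_fold: float = 4.0,
    dispersion: float = 0.1,
    frac_depleted: float = 0.0,
    mean_count: float = 500.0,
):
    """Overdispersed sorted-screen guide counts with planted enriched guides.

    The two sorted bins partition one infected cell pool, so each guide's
    abundance fluctuation (infection multiplicity, clonal growth) is shared
    between bins: a per-guide Gamma factor with variance ``dispersion``
    multiplies both bin means, and bin-level sequencing sampling is Poisson.
    Marginal counts are therefore negative binomial with
    Var = mu + dispersion * mu^2, while the LOW/HIGH ratio carries only
    sampling noise, as in a real sorted screen. Null guides share a mean
    between bins; enriched guides have their LOW-bin mean multiplied by
    ``effect_fold`` (depleted guides, if any, the HIGH-bin mean). Returns
    ``(DataFrame, TruthManifest)``; the table carries guide, gene, count_low,
    count_high, count_input.
    """
    import pandas as pd

    if frac_enriched + frac_depleted >= 1:
        raise ValueError("planted fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    guides_per_gene = int(np.ceil(n_guides / n_genes))
    guide_ids = [f"sg{i + 1:05d}" for i in range(n_guides)]
    genes = [f"GENE{(i // guides_per_gene) + 1:04d}" for i in range(n_guides)]

    base_mu = mean_count * rng.lognormal(mean=0.0, sigma=0.5, size=n_guides)
    n_enriched = round(n_guides * frac_enriched)
    n_depleted = round(n_guides * frac_depleted)
    planted = rng.choice(n_guides, size=n_enriched + n_depleted, replace=False)
    enriched_idx = np.sort(planted[:n_enriched])
    depleted_idx = np.sort(planted[n_enriched:])

    mu_low = base_mu.copy()
    mu_high = base_mu.copy()
    mu_low[enriched_idx] *= effect_fold
    mu_high[depleted_idx] *= effect_fold

    # shared Gamma abundance factor (mean 1, variance = dispersion) makes the
    # marginals NB(mu, dispersion) while the ratio sees only Poisson noise
    if dispersion > 0:
        shared = rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=n_guides)
    else:
        shared = np.ones(n_guides)
    table = pd.DataFrame({
        "guide": guide_ids,
        "gene": genes,
        "count_low": rng.poisson(mu_low * shared),
        "count_high": rng.poisson(mu_high * shared),
        "count_input": rng.poisson(base_mu * shared),
    })
    manifest = TruthManifest(
        kind="screen_counts",
        seed=seed,
        params={"n_guides": n_guides, "n_genes": n_genes,
                "frac_enriched": frac_enriched, "frac_depleted": frac_depleted,
                "effect_fold": effect_fold, "dispersion": dispersion,
                "mean_count": mean_count},
        records={
            "enriched_guides": [guide_ids[i] for i in enriched_idx],
            "depleted_guides": [guide_ids[i] for i in depleted_idx],
        },
    )
    return table, manifest
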