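"""Composite-motif construction and IUPAC consensus scanning.

The unit of scanning is a :class:`ConsensusMotif`: an IUPAC consensus string
with a Hamming mismatch budget. A sequence base mismatches a consensus
position iff it is not a member of that position's IUPAC set; consensus ``N``
never mismatches, which makes the spacer positions of a composite motif free.
An ``N`` in the *sequence* counts as a mismatch at every non-``N`` consensus
position.

A :class:`CompositeMotif` juxtaposes two elements with a 0-8 bp ``N`` spacer
in either order, with the downstream element optionally reverse-complemented.
The canonical androgen response element (ARE) is the special case of two
inverted AGAACA half-sites with a 3 bp spacer: ``AGAACANNNTGTTCT``, 15 bp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, PeakSet, SequenceStore

__all__ = [
    "IUPAC_SETS",
    "ConsensusMotif",
    "CompositeMotif",
    "MotifMatch",
    "reverse_complement",
    "build_composite",
    "sweep_composites",
    "match_consensus",
    "scan_peaks",
    "neighborhood_cooccurrence",
    "read_motif_file",
    "write_motif_file",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(consensus: str) -> str:
    """Reverse-complement an IUPAC consensus (involution; R<->Y, S<->S, ...)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(consensus.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class ConsensusMotif:
    """An IUPAC consensus string with a mismatch budget."""

    name: str
    consensus: str
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        object.__setattr__(self, "consensus", cons)
        bad = set(cons) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC characters {sorted(bad)}")
        if len(cons) < 4:
            raise ValueError(f"{self.name}: consensus shorter than 4 bp")
        if not 0 <= self.max_mismatch < len(cons):
            raise ValueError(f"{self.name}: max_mismatch must be in [0, length)")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.consensus) == self.consensus

    def reverse_complemented(self) -> "ConsensusMotif":
        return ConsensusMotif(self.name, reverse_complement(self.consensus), self.max_mismatch)

    def _allowed_matrix(self) -> np.ndarray:
        """Boolean (length x 5) table: allowed[j, base] for A,C,G,T,N in seq.

        A sequence N is allowed only where the consensus itself is N.
        """
        allowed = np.zeros((len(self.consensus), 5), dtype=bool)
        for j, code in enumerate(self.consensus):
            for b in IUPAC_SETS[code]:
                allowed[j, _BASE_INDEX[b]] = True
            if code == "N":
                allowed[j, 4] = True
        return allowed


@dataclass(frozen=True)
class CompositeMotif:
    """Two consensus elements joined by an N spacer, order/orientation tagged."""

    element_a: ConsensusMotif
    element_b: ConsensusMotif
    spacer: int
    order: str  # "AB" | "BA"
    orient_b: str  # "same" | "revcomp"
    derived: ConsensusMotif = field(init=False)

    def __post_init__(self) -> None:
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")
        if self.order not in ("AB", "BA"):
            raise ValueError("order must be AB or BA")
        if self.orient_b not in ("same", "revcomp"):
            raise ValueError("orient_b must be same or revcomp")
        a = self.element_a.consensus
        b = self.element_b.consensus
        if self.orient_b == "revcomp":
            b = reverse_complement(b)
        first, second = (a, b) if self.order == "AB" else (b, a)
        cons = first + "N" * self.spacer + second
        budget = max(self.element_a.max_mismatch, self.element_b.max_mismatch)
        name = (
            f"{self.element_a.name}-{'N' * self.spacer}-{self.element_b.name}"
            f"[{self.order},{self.orient_b}]"
        )
        object.__setattr__(self, "derived", ConsensusMotif(name, cons, budget))

    def __len__(self) -> int:
        return len(self.derived)


def build_composite(
    a: ConsensusMotif,
    b: ConsensusMotif,
    spacer: int,
    order: str = "AB",
    orient_b: str = "same",
    max_spacer: int = 8,
) -> CompositeMotif:
    """Assemble a composite motif: elements joined by ``spacer`` free Ns.

    ``build_composite(AGAACA, AGAACA, spacer=3, orient_b="revcomp")`` yields the
    15 bp palindromic ARE consensus ``AGAACANNNTGTTCT``.
    """
    if spacer > max_spacer:
        raise ValueError(f"spacer {spacer} exceeds configured maximum {max_spacer}")
    return CompositeMotif(a, b, spacer, order, orient_b)


def sweep_composites(
    a: ConsensusMotif,
    b: ConsensusMotif,
    spacer_range: Iterable[int] = range(0, 9),
    orders: Iterable[str] = ("AB", "BA"),
    orientations: Iterable[str] = ("same", "revcomp"),
) -> list[CompositeMotif]:
    """Cartesian sweep over spacer/order/orientation, deduplicated.

    Two configurations are duplicates when their derived consensus strings are
    identical (e.g. AB and BA collapse for a palindromic pairing); the first
    configuration in sweep order is kept.
    """
    spacers = list(spacer_range)
    if not spacers or not list(orders) or not list(orientations):
        raise ValueError("sweep ranges must be non-empty")
    out: list[CompositeMotif] = []
    seen: set[str] = set()
    for spacer, order, orient in itertools.product(spacers, orders, orientations):
        comp = CompositeMotif(a, b, spacer, order, orient)
        if comp.derived.consensus not in seen:
            seen.add(comp.derived.consensus)
            out.append(comp)
    return out


@dataclass(frozen=True)
class MotifMatch:
    """One scored occurrence of a motif on the genome."""

    interval: GenomicInterval
    strand: str
    mismatches: int
    motif_name: str

    @property
    def center(self) -> int:
        return self.interval.center


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _mismatch_profile(encoded: np.ndarray, motif: ConsensusMotif) -> np.ndarray:
    """Mismatch count of the motif against every window start of ``encoded``."""
    L = len(motif)
    n = encoded.size
    if n < L:
        return np.zeros(0, dtype=np.int64)
    allowed = motif._allowed_matrix()  # (L, 5)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)  # (n-L+1, L)
    ok = allowed[np.arange(L)[None, :], windows]  # (n-L+1, L)
    return (~ok).sum(axis=1)


def match_consensus(
    seq: str,
    motif: ConsensusMotif | CompositeMotif,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifMatch]:
    """All windows of ``seq`` (both strands) within the motif's mismatch budget.

    Minus-strand hits are reported on plus-strand coordinates of their
    footprint. For a palindromic consensus, the plus- and minus-strand hits at
    one footprint are the same site; the plus-strand record is kept.
    """
    if isinstance(motif, CompositeMotif):
        motif = motif.derived
    encoded = _encode(seq)
    L = len(motif)
    matches: list[MotifMatch] = []
    fwd = _mismatch_profile(encoded, motif)
    for i in np.flatnonzero(fwd <= motif.max_mismatch):
        matches.append(
            MotifMatch(
                GenomicInterval(chrom, offset + int(i), offset + int(i) + L),
                "+", int(fwd[i]), motif.name,
            )
        )
    if motif.is_palindromic:
        return matches
    rev = _mismatch_profile(encoded, motif.reverse_complemented())
    for i in np.flatnonzero(rev <= motif.max_mismatch):
        matches.append(
            MotifMatch(
                GenomicInterval(chrom, offset + int(i), offset + int(i) + L),
                "-", int(rev[i]), motif.name,
            )
        )
    matches.sort(key=lambda m: (m.interval.start, m.strand))
    return matches


def scan_peaks(
    peaks: PeakSet,
    genome: SequenceStore,
    motifs: Sequence[ConsensusMotif | CompositeMotif],
    window: int = 200,
    keep_matches: bool = False,
) -> pd.DataFrame:
    """Scan a window centred on each peak summit for each motif.

    The scan covers ``window`` bp centred at the summit (interval midpoint when
    no summit is recorded), clipped to chromosome bounds. One row per
    (peak, motif) reporting presence and the best (fewest-mismatch) hit.

    Returns a DataFrame with columns peak_index, chrom, peak_start, peak_end,
    motif, present, best_mismatches, match_start, match_end, match_strand.
    With ``keep_matches`` the full per-window match list is attached under
    ``df.attrs["matches"]``.
    """
    missing = sorted({iv.chrom for iv in peaks} - set(genome.chroms))
    if missing:
        raise KeyError(f"chromosomes absent from genome: {missing}")
    mlist = [m.derived if isinstance(m, CompositeMotif) else m for m in motifs]
    half = window // 2
    rows = []
    all_matches: list[MotifMatch] = []
    for idx, iv in enumerate(peaks):
        center = iv.summit
        lo = max(0, center - half)
        hi = min(genome.length(iv.chrom), center + half)
        seq = genome.fetch(iv.chrom, lo, hi) if hi > lo else ""
        for motif in mlist:
            hits = match_consensus(seq, motif, chrom=iv.chrom, offset=lo) if seq else []
            best = min(hits, key=lambda m: (m.mismatches, m.interval.start)) if hits else None
            rows.append(
                {
                    "peak_index": idx,
                    "chrom": iv.chrom,
                    "peak_start": iv.start,
                    "peak_end": iv.end,
                    "peak_name": iv.name,
                    "motif": motif.name,
                    "present": best is not None,
                    "best_mismatches": best.mismatches if best else pd.NA,
                    "match_start": best.interval.start if best else pd.NA,
                    "match_end": best.interval.end if best else pd.NA,
                    "match_strand": best.strand if best else pd.NA,
                }
            )
            if keep_matches:
                all_matches.extend(hits)
    df = pd.DataFrame(
        rows,
        columns=[
            "peak_index", "chrom", "peak_start", "peak_end", "peak_name", "motif",
            "present", "best_mismatches", "match_start", "match_end", "match_strand",
        ],
    )
    if keep_matches:
        df.attrs["matches"] = all_matches
    return df


def neighborhood_cooccurrence(
    anchor_matches: Sequence[MotifMatch],
    partner_matches: Sequence[MotifMatch],
    max_dist: int = 25,
    peaks: PeakSet | None = None,
    n_shuffle: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Partner-motif co-occurrence within ``max_dist`` bp of each anchor.

    A partner co-occurs with an anchor when their centre-to-centre distance is
    <= ``max_dist`` on the same chromosome. Reports, per partner motif, the
    fraction of anchors with at least one co-occurring partner and an
    enrichment ratio against a positional null in which partner centres are
    re-drawn uniformly within the peaks that contain them (``peaks`` required
    for the null; without it the ratio is NaN).
    """
    anchors_by_chrom: dict[str, list[int]] = {}
    for m in anchor_matches:
        anchors_by_chrom.setdefault(m.interval.chrom, []).append(m.center)
    n_anchors = len(anchor_matches)

    def observed_fraction(centers_by_chrom: dict[str, np.ndarray]) -> dict[str, float]:
        hit = 0
        for m in anchor_matches:
            partners = centers_by_chrom.get(m.interval.chrom)
            if partners is not None and np.any(np.abs(partners - m.center) <= max_dist):
                hit += 1
        return hit / n_anchors if n_anchors else float("nan")

    by_motif: dict[str, list[MotifMatch]] = {}
    for m in partner_matches:
        by_motif.setdefault(m.motif_name, []).append(m)

    rng = np.random.default_rng(seed)
    peak_lookup = None
    if peaks is not None:
        peak_lookup = sorted(peaks, key=lambda iv: (iv.chrom, iv.start))

    rows = []
    for motif_name, plist in sorted(by_motif.items()):
        centers: dict[str, np.ndarray] = {}
        for m in plist:
            centers.setdefault(m.interval.chrom, [])
            centers[m.interval.chrom].append(m.center)
        centers = {c: np.asarray(v) for c, v in centers.items()}
        obs = observed_fraction(centers)
        null_frac = float("nan")
        if peak_lookup is not None and n_shuffle > 0:
            fracs = []
            homes = [_containing_peak(m, peak_lookup) for m in plist]
            for _ in range(n_shuffle):
                shuf: dict[str, list[int]] = {}
                for m, home in zip(plist, homes):
                    if home is None:
                        pos = m.center
                    else:
                        pos = int(rng.integers(home.start, home.end))
                    shuf.setdefault(m.interval.chrom, []).append(pos)
                fracs.append(
                    observed_fraction({c: np.asarray(v) for c, v in shuf.items()})
                )
            null_frac = float(np.mean(fracs))
        ratio = obs / null_frac if null_frac and null_frac > 0 else float("nan")
        rows.append(
            {
                "partner_motif": motif_name,
                "n_anchors": n_anchors,
                "n_partners": len(plist),
                "cooccur_fraction": obs,
                "null_fraction": null_frac,
                "enrichment_ratio": ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["partner_motif", "n_anchors", "n_partners",
                 "cooccur_fraction", "null_fraction", "enrichment_ratio"],
    )


def _containing_peak(match: MotifMatch, peaks: list[GenomicInterval]) -> GenomicInterval | None:
    c = match.center
    for iv in peaks:
        if iv.chrom == match.interval.chrom and iv.start <= c < iv.end:
            return iv
    return None


# ---------------------------------------------------------------------------
# motif file: one motif per line, "name<TAB>IUPAC<TAB>max_mismatch"


def read_motif_file(path: str | Path) -> list[ConsensusMotif]:
    motifs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>IUPAC<TAB>max_mismatch")
            motifs.append(ConsensusMotif(parts[0], parts[1], int(parts[2])))
    return motifs


def write_motif_file(motifs: Sequence[ConsensusMotif], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"{m.name}\t{m.consensus}\t{m.max_mismatch}\n")
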