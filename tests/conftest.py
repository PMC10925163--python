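import numpy as np
import pytest

from cistrokit import ConsensusMotif, SequenceStore, build_composite
from cistrokit.motifs import IUPAC_SETS

AR_HALF = ConsensusMotif("AR-half", "AGAACA", 2)
FKHD = ConsensusMotif("FKHD", "TGTTTAC", 2)


@pytest.fixture
def ar_half():
    return AR_HALF


@pytest.fixture
def fkhd():
    return FKHD


@pytest.fixture
def canonical_are():
    """The 15 bp palindromic ARE: two inverted AGAACA half-sites, 3 bp spacer."""
    return build_composite(AR_HALF, AR_HALF, spacer=3, order="AB", orient_b="revcomp")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


def brute_force_matches(seq: str, motif: ConsensusMotif):
    """Independent per-window Hamming oracle for consensus scanning.

    Returns a set of (start, strand, mismatches) using direct IUPAC set
    membership, both strands, sequence N mismatching every non-N consensus
    position. Palindromic motifs report plus-strand only.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
            "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
            "N": "N"}

    def rc(s):
        return "".join(comp[c] for c in reversed(s))

    def mismatches(window, consensus):
        n = 0
        for base, code in zip(window, consensus):
            if code == "N":
                continue
            if base == "N" or base not in IUPAC_SETS[code]:
                n += 1
        return n

    L = len(motif.consensus)
    out = set()
    palindromic = rc(motif.consensus) == motif.consensus
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        m = mismatches(window, motif.consensus)
        if m <= motif.max_mismatch:
            out.add((start, "+", m))
        if not palindromic:
            m = mismatches(window, rc(motif.consensus))
            if m <= motif.max_mismatch:
                out.add((start, "-", m))
    return out


def make_store(**seqs) -> SequenceStore:
    return SequenceStore(seqs)
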