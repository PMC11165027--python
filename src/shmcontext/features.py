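"""Local sequence-context features of AGCT-centred k-mers.

For an AGCT k-mer the features are: the number of pyrimidine dimers
(PyPy) in the 6 nt immediately 5' of the AGCT's A, the identities of the
bases flanking the AGCT, and the E-box indicator (flanks C and G, i.e.
the 6-mer spanning AGCT plus flanks is CAGCTG).  The genetic-code
synonymy check used by the contingency analysis also lives here.

Positions: in a 15-mer with the AGCT's G central, the motif occupies
window positions 7-10, so the flanks are positions 6 and 11 and the PyPy
window is positions 1-6.  With the C central the motif sits at 6-9
(flanks 5 and 10); its upstream 6-nt window would start one base before
the window, so the PyPy count is undefined within the 15-mer and raises.
The upstream window is taken on the forward strand only.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .kmers import KmerRecord
from .simulate import count_pypy


@dataclass(frozen=True)
class ContextFeatures:
    pypy_count: int
    flank5: str
    flank3: str
    ebox: bool

    def __post_init__(self) -> None:
        if not 0 <= self.pypy_count <= 5:
            raise ValueError("pypy_count must be between 0 and 5")
        if self.ebox != (self.flank5 == "C" and self.flank3 == "G"):
            raise ValueError("ebox must equal (flank5 == 'C' and flank3 == 'G')")


def _require_agct(record: KmerRecord) -> None:
    if record.agct_role not in ("central_G", "central_C"):
        raise ValueError("record is not AGCT-centred (agct_role is 'none')")


def pypy_count_upstream(record: KmerRecord, convention: str = "overlapping") -> int:
    """PyPy dimers in the 6 nt immediately upstream of the AGCT's A.

    ``convention='overlapping'`` counts all 5 adjacent pairs in the 6-nt
    window; ``'disjoint'`` counts the 3 non-overlapping pairs.
    """
    _require_agct(record)
    if convention not in ("overlapping", "disjoint"):
        raise ValueError("convention must be 'overlapping' or 'disjoint'")
    c = (len(record.kmer) - 1) // 2
    a_pos = c - 1 if record.agct_role == "central_G" else c - 2
    if a_pos - 6 < 0:
        raise ValueError(
            "the 6-nt upstream window extends beyond the k-mer "
            f"(AGCT starts at window position {a_pos + 1})"
        )
    window = record.kmer[a_pos - 6 : a_pos]
    return count_pypy(window, overlapping=(convention == "overlapping"))


def flank_pair(record: KmerRecord) -> tuple[str, str]:
    """Bases immediately 5' and 3' of the AGCT motif."""
    _require_agct(record)
    c = (len(record.kmer) - 1) // 2
    a_pos = c - 1 if record.agct_role == "central_G" else c - 2
    if a_pos - 1 < 0 or a_pos + 4 >= len(record.kmer):
        raise ValueError("AGCT flanks extend beyond the k-mer")
    return record.kmer[a_pos - 1], record.kmer[a_pos + 4]


def ebox_indicator(record: KmerRecord) -> bool:
    """True iff the 6-mer spanning the AGCT plus its flanks is CAGCTG."""
    flank5, flank3 = flank_pair(record)
    return flank5 == "C" and flank3 == "G"


def context_features(record: KmerRecord, pypy_convention: str = "overlapping") -> ContextFeatures:
    """Bundle all context features; requires the full upstream window,
    so only central-G records qualify for the PyPy count."""
    flank5, flank3 = flank_pair(record)
    return ContextFeatures(
        pypy_count=pypy_count_upstream(record, convention=pypy_convention),
        flank5=flank5,
        flank3=flank3,
        ebox=(flank5 == "C" and flank3 == "G"),
    )


def is_synonymous(codon_before: str, codon_after: str) -> bool:
    """True iff the two codons encode the same amino acid (standard code)."""
    for codon in (codon_before, codon_after):
        if len(codon) != 3 or set(codon) - set("ACGT"):
            raise ValueError(f"invalid codon {codon!r}")
    return str(Seq(codon_before).translate()) == str(Seq(codon_after).translate())
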