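"""PWM machinery and E-box motif census.

A JASPAR counts matrix is converted to a log-odds position weight matrix
with a background-distributed pseudocount:

    log_odds[b, j] = log((counts[b, j] + pc * bg[b]) / (colsum_j + pc)) - log(bg[b])

A window's score is the sum of its per-position log-odds entries; hits
are reported only above a score threshold derived from a p-value on the
background distribution of scores, computed by dynamic programming over
per-column score distributions (exact for motif widths up to
``_MAX_EXACT_WIDTH``, discretised beyond that).  The IUPAC census counts
CAGCTG / CANNTG E-box occurrences per allele subregion.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio.Data.IUPACData import ambiguous_dna_values

from .kmers import ROW_ORDER
from .simulate import SUBREGION_ORDER, VAllele

_MAX_EXACT_WIDTH = 12
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PWM:
    """Counts matrix plus derived log-odds scoring matrix."""

    counts: np.ndarray  # 4 x m, rows A, C, G, T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0
    motif_id: str = ""
    log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x m matrix (rows A, C, G, T)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive (zero counts would give -inf)")
        colsum = counts.sum(axis=0)
        lo = np.log((counts + self.pseudocount * bg[:, None]) / (colsum[None, :] + self.pseudocount))
        lo -= np.log(bg)[:, None]
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "log_odds", lo)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def score(self, word: str) -> float:
        """Log-odds score of a width-matched word."""
        if len(word) != self.width:
            raise ValueError(f"word length {len(word)} != motif width {self.width}")
        return float(sum(self.log_odds[ROW_ORDER.index(b), j] for j, b in enumerate(word)))


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based forward-strand start of the window
    strand: str  # "+" | "-"
    score: float


def load_jaspar_counts(text: str) -> tuple[np.ndarray, str]:
    """Parse one JASPAR-format matrix block into a 4 x m counts matrix.

    Rows are keyed by their base letter, so file row order is irrelevant;
    the returned matrix is always ordered A, C, G, T.  Headerless 4-row
    blocks are accepted as plain ACGT-ordered count rows.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty matrix block")
    fmt = "jaspar" if text.startswith(">") or re.match(r"^[ACGT]\s*\[", text) else "pfm"
    try:
        motif = bio_motifs.read(_io.StringIO(text + "\n"), fmt)
    except Exception as exc:
        raise ValueError(f"cannot parse JASPAR matrix: {exc}") from exc
    counts = np.array([motif.counts[b] for b in ROW_ORDER], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    motif_id = getattr(motif, "matrix_id", None) or motif.name or ""
    return counts, motif_id


def write_jaspar(counts: np.ndarray, motif_id: str, path: str | Path) -> None:
    counts = np.asarray(counts)
    lines = [f">{motif_id} {motif_id}"]
    for i, base in enumerate(ROW_ORDER):
        row = " ".join(f"{v:g}" for v in counts[i])
        lines.append(f"{base} [ {row} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def build_pwm(
    counts: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    motif_id: str = "",
) -> PWM:
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(counts=np.asarray(counts, float), background=bg,
               pseudocount=pseudocount, motif_id=motif_id)


def _score_distribution(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the score of a random background sequence.

    Returns (unique scores ascending, probabilities).  State count is at
    most 4^width, so this is reserved for small widths.
    """
    scores = np.zeros(1)
    probs = np.ones(1)
    for j in range(pwm.width):
        col = pwm.log_odds[:, j]
        new_scores = (scores[:, None] + col[None, :]).ravel()
        new_probs = (probs[:, None] * pwm.background[None, :]).ravel()
        uniq, inverse = np.unique(new_scores, return_inverse=True)
        scores = uniq
        probs = np.bincount(inverse, weights=new_probs, minlength=uniq.size)
    return scores, probs


def _score_distribution_discretized(pwm: PWM, scale: float = 1000.0):
    """Discretised DP (integer grid of 1/scale) for wide motifs."""
    int_lo = np.rint(pwm.log_odds * scale).astype(np.int64)
    offset = int_lo.min(axis=0)
    span = int(np.sum(int_lo.max(axis=0) - offset))
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    pos = 0
    for j in range(pwm.width):
        col = int_lo[:, j] - offset[j]
        new = np.zeros_like(dist)
        for b in range(4):
            new[col[b] :] += pwm.background[b] * dist[: dist.size - col[b] if col[b] else dist.size]
        dist = new
        pos += 1
    base = int(offset.sum())
    support = np.nonzero(dist)[0]
    return (support + base) / scale, dist[support]


def score_threshold(pwm: PWM, pvalue: float = 0.001) -> float:
    """Smallest achievable score t with P(background score >= t) <= pvalue.

    If even the maximal score is more probable than ``pvalue`` (degenerate
    matrices), the returned threshold lies just above the maximal score so
    that no window can match.
    """
    if not 0.0 < pvalue <= 1.0:
        raise ValueError("pvalue must be in (0, 1]")
    if pwm.width <= _MAX_EXACT_WIDTH:
        scores, probs = _score_distribution(pwm)
    else:
        scores, probs = _score_distribution_discretized(pwm)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= scores[i])
    ok = tail <= pvalue
    if not ok.any():
        return float(np.nextafter(scores[-1], np.inf))
    return float(scores[np.argmax(ok)])


def ebox_counts_matrix(n_obs: int = 100, consensus_weight: float = 0.85) -> np.ndarray:
    """Synthetic E-box-like counts matrix (consensus CAGCTG).

    A stand-in constructed from the E-box consensus, not a measured
    binding matrix: each column gives ``consensus_weight`` of ``n_obs``
    observations to the consensus base and splits the rest evenly.  The
    matrix is reverse-complement symmetric, matching the palindromy of
    CAGCTG.
    """
    consensus = "CAGCTG"
    other = n_obs * (1.0 - consensus_weight) / 3.0
    counts = np.full((4, len(consensus)), other)
    for j, base in enumerate(consensus):
        counts[ROW_ORDER.index(base), j] = n_obs * consensus_weight
    return counts


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _window_scores(seq: str, log_odds: np.ndarray) -> np.ndarray:
    m = log_odds.shape[1]
    idx = np.array([ROW_ORDER.index(b) for b in seq], dtype=np.intp)
    n_win = len(seq) - m + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, m)
    return log_odds[windows, np.arange(m)[None, :]].sum(axis=1) if n_win > 0 else np.empty(0)


def scan_sequence(seq: str, pwm: PWM, threshold: float, strands: str = "both") -> list[MotifHit]:
    """All windows scoring at or above ``threshold``.

    Reverse-strand hits score the reverse complement of the window and
    are reported at the forward-strand start coordinate.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    bad = set(seq) - set(ROW_ORDER)
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    if len(seq) < pwm.width:
        return []
    hits = []
    fwd = _window_scores(seq, pwm.log_odds)
    for i, s in enumerate(fwd):
        if s >= threshold:
            hits.append(MotifHit(position=i + 1, strand="+", score=float(s)))
    if strands == "both":
        # scoring the reverse complement of window i equals scoring the
        # forward window with a reverse-complemented log-odds matrix
        lo_rc = pwm.log_odds[::-1, ::-1]
        rev = _window_scores(seq, lo_rc)
        for i, s in enumerate(rev):
            if s >= threshold:
                hits.append(MotifHit(position=i + 1, strand="-", score=float(s)))
    return sorted(hits, key=lambda h: (h.position, h.strand))


def best_hit_score(seq: str, pwm: PWM, threshold: float, strands: str = "both") -> float | None:
    """Best passing window score in a sequence, or None if nothing passes."""
    hits = scan_sequence(seq, pwm, threshold, strands=strands)
    return max(h.score for h in hits) if hits else None


_IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in _IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {ch!r}")
        values = ambiguous_dna_values[ch]
        parts.append(values if len(values) == 1 else f"[{values}]")
    return re.compile("(?=" + "".join(parts) + ")")


def count_iupac(seq: str, pattern: str) -> int:
    """Count all (possibly overlapping) forward-strand matches of an
    IUPAC pattern."""
    bad = set(seq) - set(ROW_ORDER)
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return len(_iupac_regex(pattern).findall(seq))


def ebox_census(alleles: list[VAllele], pattern: str = "CAGCTG") -> pd.DataFrame:
    """Per-allele x per-subregion count of IUPAC motif occurrences.

    The full allele is scanned and each match is assigned to the
    subregion containing its start position, so boundary-spanning motifs
    are counted once, in their start subregion.
    """
    regex = _iupac_regex(pattern)
    rows = {}
    for allele in alleles:
        counts = {name: 0 for name in SUBREGION_ORDER}
        for m in regex.finditer(allele.sequence):
            counts[allele.subregion_of(m.start() + 1)] += 1
        rows[allele.allele_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(SUBREGION_ORDER))
    df.index.name = "allele_id"
    return df
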