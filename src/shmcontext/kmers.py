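"""The 15-mer dataset: window extraction, observed mutation frequencies,
AGCT-centred filtering, subregion assignment, and one-hot encoding.

Coordinates are 1-based inclusive throughout; the centre of a k-mer window
is position (k+1)/2 of the window (position 8 for 15-mers).  An AGCT k-mer
has either the G (window positions 7-10 spell AGCT) or the C (positions
6-9) as its central base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Repertoire, VAllele

ROW_ORDER = "ACGT"
_ROW_INDEX = {b: i for i, b in enumerate(ROW_ORDER)}


@dataclass(frozen=True)
class KmerRecord:
    """One sliding-window k-mer and the observed mutability of its centre."""

    allele_id: str
    kmer: str
    central_pos: int  # 1-based position of the central base in the allele
    central_base: str
    subregion: str
    agct_role: str  # "none" | "central_G" | "central_C"
    mut_freq: float | None = None
    n_total: int = 0

    def __post_init__(self) -> None:
        k = len(self.kmer)
        if k % 2 == 0:
            raise ValueError("k-mer length must be odd")
        if self.kmer[(k - 1) // 2] != self.central_base:
            raise ValueError("central_base does not match the k-mer centre")
        if self.mut_freq is not None and not 0.0 <= self.mut_freq <= 1.0:
            raise ValueError(f"mut_freq must be in [0, 1], got {self.mut_freq}")


def _agct_role(kmer: str) -> str:
    c = (len(kmer) - 1) // 2  # 0-based centre
    if kmer[c - 1 : c + 3] == "AGCT":
        return "central_G"
    if kmer[c - 2 : c + 2] == "AGCT":
        return "central_C"
    return "none"


def assign_subregion(central_pos: int, boundaries) -> str:
    """Subregion whose 1-based inclusive interval contains ``central_pos``."""
    for name, start, end in boundaries:
        if start <= central_pos <= end:
            return name
    raise ValueError(f"position {central_pos} is outside every subregion interval")


def extract_kmers(allele: VAllele, k: int = 15) -> list[KmerRecord]:
    """Slide a k-wide window over the allele; one record per full window.

    Windows overhanging either end are skipped (no padding), so a
    length-L sequence yields max(0, L - k + 1) records.  ``mut_freq`` is
    left unset.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    seq = allele.sequence
    half = (k - 1) // 2
    records = []
    for start in range(len(seq) - k + 1):
        kmer = seq[start : start + k]
        central_pos = start + half + 1
        records.append(
            KmerRecord(
                allele_id=allele.allele_id,
                kmer=kmer,
                central_pos=central_pos,
                central_base=kmer[half],
                subregion=assign_subregion(central_pos, allele.boundaries),
                agct_role=_agct_role(kmer),
            )
        )
    return records


def compute_site_frequencies(germline: str, clones) -> tuple[np.ndarray, int]:
    """Observed per-site mutation frequency across clonally independent
    sequences: the fraction of clones whose base differs from germline.

    ``clones`` may be a list of strings or an (n, L) byte matrix.
    Returns ``(mut_freq, n_total)``.
    """
    if isinstance(clones, np.ndarray):
        mat = np.asarray(clones, dtype="S1")
    else:
        clones = list(clones)
        if clones and len({len(c) for c in clones}) > 1:
            raise ValueError("clones must all have the same length")
        mat = (
            np.frombuffer("".join(clones).encode("ascii"), dtype="S1").reshape(len(clones), -1)
            if clones
            else np.empty((0, 0), dtype="S1")
        )
    if mat.shape[0] == 0:
        raise ValueError("mutation frequency is undefined for an empty clone list")
    germ = np.frombuffer(germline.encode("ascii"), dtype="S1")
    if mat.shape[1] != germ.size:
        raise ValueError(
            f"clone length {mat.shape[1]} does not match germline length {germ.size}"
        )
    freqs = (mat != germ[None, :]).mean(axis=0)
    return freqs, mat.shape[0]


def attach_frequencies(
    records: list[KmerRecord], freqs: np.ndarray, n_total: int
) -> list[KmerRecord]:
    """Fill ``mut_freq``/``n_total`` of each record from a per-site array."""
    return [
        replace(r, mut_freq=float(freqs[r.central_pos - 1]), n_total=n_total)
        for r in records
    ]


def select_agct_centered(records: list[KmerRecord]) -> list[KmerRecord]:
    """Keep only k-mers with the G or the C of an AGCT as central base."""
    return [r for r in records if r.agct_role != "none"]


def one_hot_encode(kmer: str) -> np.ndarray:
    """Encode a k-mer as a 4 x k binary matrix, rows ordered A, C, G, T."""
    mat = np.zeros((4, len(kmer)), dtype=np.int8)
    for j, base in enumerate(kmer):
        try:
            mat[_ROW_INDEX[base], j] = 1
        except KeyError:
            raise ValueError(f"non-ACGT character {base!r} at position {j + 1}") from None
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    mat = np.asarray(matrix)
    if mat.ndim != 2 or mat.shape[0] != 4 or not (mat.sum(axis=0) == 1).all():
        raise ValueError("not a valid one-hot matrix (columns must sum to 1)")
    return "".join(ROW_ORDER[i] for i in mat.argmax(axis=0))


def encode_batch(kmers: list[str]) -> np.ndarray:
    """Stack one-hot matrices into an (N, 4, k) float array."""
    return np.stack([one_hot_encode(k) for k in kmers]).astype(float)


def kmer_table(
    alleles: list[VAllele],
    repertoires: dict[str, Repertoire] | None = None,
    k: int = 15,
    agct_only: bool = False,
) -> pd.DataFrame:
    """Build the k-mer dataset for a set of alleles as a DataFrame.

    When repertoires are given, observed per-site mutation frequencies are
    attached; otherwise mut_freq is NaN.
    """
    rows = []
    for allele in alleles:
        records = extract_kmers(allele, k=k)
        if repertoires is not None:
            rep = repertoires[allele.allele_id]
            freqs, n_total = compute_site_frequencies(allele.sequence, rep.seqs)
            records = attach_frequencies(records, freqs, n_total)
        if agct_only:
            records = select_agct_centered(records)
        rows.extend(records)
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df = df[
            ["allele_id", "central_pos", "kmer", "central_base", "agct_role",
             "subregion", "mut_freq", "n_total"]
        ]
    return df


def write_kmer_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_kmer_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def records_from_frame(df: pd.DataFrame) -> list[KmerRecord]:
    """Rehydrate KmerRecords from a k-mer table (e.g. read from TSV)."""
    return [
        KmerRecord(
            allele_id=r.allele_id,
            kmer=r.kmer,
            central_pos=int(r.central_pos),
            central_base=r.central_base,
            subregion=r.subregion,
            agct_role=r.agct_role,
            mut_freq=None if pd.isna(r.mut_freq) else float(r.mut_freq),
            n_total=int(r.n_total),
        )
        for r in df.itertuples()
    ]
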