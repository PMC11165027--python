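"""FASTA / TSV readers and writers for the pipeline's on-disk artifacts.

Sequences go through Bio.SeqIO; tabular artifacts are plain TSV via
pandas.  Coordinates in the boundaries file are 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Repertoire, SiteRateMap, VAllele


def write_alleles_fasta(alleles: list[VAllele], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.allele_id, description=f"family={a.family}")
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def write_boundaries_tsv(alleles: list[VAllele], path: str | Path) -> None:
    rows = [
        {"allele_id": a.allele_id, "subregion": name, "start": start, "end": end}
        for a in alleles
        for name, start, end in a.boundaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alleles(fasta_path: str | Path, boundaries_path: str | Path) -> list[VAllele]:
    bounds = pd.read_csv(boundaries_path, sep="\t")
    grouped = {
        aid: tuple(
            (r.subregion, int(r.start), int(r.end)) for r in grp.itertuples()
        )
        for aid, grp in bounds.groupby("allele_id", sort=False)
    }
    alleles = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        family = rec.id.split("-")[0]
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.removeprefix("family=")
        alleles.append(
            VAllele(
                allele_id=rec.id,
                family=family,
                sequence=str(rec.seq).upper(),
                boundaries=grouped[rec.id],
            )
        )
    return alleles


def write_repertoire_fasta(rep: Repertoire, path: str | Path) -> None:
    records = (
        SeqRecord(Seq(clone), id=f"{rep.allele_id}|clone{i + 1}", description="")
        for i, clone in enumerate(rep.clones)
    )
    SeqIO.write(records, str(path), "fasta")


def read_repertoire_fasta(path: str | Path) -> Repertoire:
    clones, allele_id = [], None
    for rec in SeqIO.parse(str(path), "fasta"):
        allele_id = rec.id.rsplit("|", 1)[0]
        clones.append(str(rec.seq).upper())
    if allele_id is None:
        raise ValueError(f"no sequences in {path}")
    return Repertoire.from_strings(allele_id, clones)


def write_rates_tsv(rate_maps: list[SiteRateMap], path: str | Path) -> None:
    rows = [
        {"allele_id": rm.allele_id, "position": i + 1, "rate": rate}
        for rm in rate_maps
        for i, rate in enumerate(rm.rates)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_rates_tsv(path: str | Path) -> list[SiteRateMap]:
    df = pd.read_csv(path, sep="\t")
    return [
        SiteRateMap(aid, grp.sort_values("position")["rate"].to_numpy())
        for aid, grp in df.groupby("allele_id", sort=False)
    ]
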