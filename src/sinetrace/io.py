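"""File formats: FASTA via Biopython, BED6 / GFF3 / TSV via pandas.

Tabular outputs carry a comment header recording the package version and the
seed so that runs are replayable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .characterize import InsertRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_tsv",
    "read_tsv",
    "write_bed",
    "write_gff3",
    "write_cohort_fasta",
    "read_cohort_fasta",
    "write_flank_repeats",
    "read_flank_repeats",
    "write_json",
]


def _header(seed=None) -> str:
    extra = f" seed={seed}" if seed is not None else ""
    return f"# sinetrace v{__version__}{extra}\n"


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    """BED6 (0-based half-open); score 0, strand from a 'strand' column or '.'"""
    with open(path, "w") as fh:
        for row in df.itertuples():
            name = getattr(row, name_col) if name_col else "."
            strand = getattr(row, "strand", ".")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{strand}\n")


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Gene models as GFF3 (1-based inclusive coordinates)."""
    type_map = {"gene": "gene", "intron": "intron", "CDS": "CDS",
                "five_prime_UTR": "five_prime_UTR", "three_prime_UTR": "three_prime_UTR"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            ftype = type_map.get(row.feature, row.feature)
            attr = (
                f"ID={row.gene_id}" if row.feature == "gene" else f"Parent={row.gene_id}"
            )
            fh.write(
                f"{row.chrom}\tsinetrace\t{ftype}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attr}\n"
            )


def write_cohort_fasta(records: Sequence[InsertRecord], path) -> None:
    seqs: dict[str, str] = {}
    for r in records:
        seqs[f"{r.id}_pre"] = r.pre_locus
        seqs[f"{r.id}_post"] = r.post_locus
    write_fasta(seqs, path)


def read_cohort_fasta(path, drivers: dict[str, str] | None = None) -> list[InsertRecord]:
    seqs = read_fasta(path)
    ids = sorted({name.rsplit("_", 1)[0] for name in seqs})
    records = []
    for rid in ids:
        pre, post = seqs.get(f"{rid}_pre"), seqs.get(f"{rid}_post")
        if pre is None or post is None:
            raise ValueError(f"cohort record {rid} lacks a pre/post pair")
        records.append(
            InsertRecord(
                id=rid,
                pre_locus=pre,
                post_locus=post,
                driver=(drivers or {}).get(rid, "unknown"),
            )
        )
    return records


def write_flank_repeats(records: Sequence[InsertRecord], path) -> None:
    rows = []
    for r in records:
        for family, seq in r.flank_repeats:
            rows.append({"record_id": r.id, "family": family, "sequence": seq})
    write_tsv(pd.DataFrame(rows, columns=["record_id", "family", "sequence"]), path)


def read_flank_repeats(path) -> dict[str, tuple[tuple[str, str], ...]]:
    df = read_tsv(path)
    out: dict[str, list[tuple[str, str]]] = {}
    for row in df.itertuples():
        out.setdefault(row.record_id, []).append((row.family, row.sequence))
    return {k: tuple(v) for k, v in out.items()}


def write_json(obj, path, seed=None) -> None:
    payload = {"sinetrace_version": __version__}
    if seed is not None:
        payload["seed"] = seed
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
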