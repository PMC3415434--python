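"""Karyotype-weighted random insertion placement.

The genome is mapped to consecutive integer space with each region allocated
``width x copy_number`` integers, so sampling integers uniformly reproduces
insertion rates proportional to somatic copy number (aneuploid lines gain or
lose integer space accordingly).  Sampled positions are summarized by the
G+C and repeat content of their flanking regions, mirroring the
random-insertion baseline used to contrast recovered insertion sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "KaryotypeProfile",
    "IntegerMap",
    "build_integer_map",
    "sample_insertions",
    "summarize_flanks",
]


@dataclass(frozen=True)
class KaryotypeProfile:
    """Copy-number regions: columns chrom, start, end, copy_number; regions
    must tile each chromosome without overlap."""

    regions: pd.DataFrame

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        df = self.regions
        if (df["copy_number"] < 0).any():
            raise ValueError("copy numbers must be non-negative")
        for chrom, length in chrom_lengths.items():
            sub = df[df["chrom"] == chrom].sort_values("start")
            if sub.empty:
                raise ValueError(f"karyotype missing chromosome {chrom}")
            expected = 0
            for row in sub.itertuples():
                if row.start != expected:
                    raise ValueError(
                        f"karyotype gap/overlap on {chrom} at {row.start} (expected {expected})"
                    )
                expected = row.end
            if expected != length:
                raise ValueError(f"karyotype does not tile {chrom} to {length}")

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], copy_number: int = 2) -> "KaryotypeProfile":
        rows = [
            {"chrom": c, "start": 0, "end": n, "copy_number": copy_number}
            for c, n in chrom_lengths.items()
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_tsv(cls, path) -> "KaryotypeProfile":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


@dataclass
class IntegerMap:
    """Genome regions mapped to disjoint consecutive integer spans."""

    spans: pd.DataFrame  # chrom, start, end, copy_number, int_start, int_end

    @property
    def total(self) -> int:
        return int(self.spans["int_end"].iloc[-1]) if len(self.spans) else 0

    def integer_to_position(self, u: int) -> tuple[str, int]:
        """Map an integer to a genomic base position (0-based)."""
        if not 0 <= u < self.total:
            raise ValueError("integer outside map")
        i = int(np.searchsorted(self.spans["int_end"].to_numpy(), u, side="right"))
        row = self.spans.iloc[i]
        width = row["end"] - row["start"]
        return row["chrom"], int(row["start"] + (u - row["int_start"]) % width)

    def position_to_integer(self, chrom: str, pos: int, copy_index: int = 0) -> int:
        for row in self.spans.itertuples():
            if row.chrom == chrom and row.start <= pos < row.end:
                width = row.end - row.start
                if not 0 <= copy_index < row.copy_number:
                    raise ValueError("copy index outside span copy number")
                return int(row.int_start + copy_index * width + (pos - row.start))
        raise ValueError(f"position {chrom}:{pos} not covered by map")


def build_integer_map(
    chrom_lengths: dict[str, int], karyotype: KaryotypeProfile
) -> IntegerMap:
    """Allocate ``width x copy_number`` consecutive integers per region;
    zero-copy regions receive no integer space.  Only relative copy-number
    weights matter for sampling, so absolute ploidy is not normalized."""
    karyotype.validate(chrom_lengths)
    rows = []
    cursor = 0
    for row in karyotype.regions.sort_values(["chrom", "start"]).itertuples():
        if row.copy_number == 0:
            continue
        width = (row.end - row.start) * int(row.copy_number)
        rows.append(
            {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "copy_number": int(row.copy_number),
                "int_start": cursor,
                "int_end": cursor + width,
            }
        )
        cursor += width
    if not rows:
        raise ValueError("integer map is empty (all copy numbers zero?)")
    return IntegerMap(pd.DataFrame(rows))


def sample_insertions(
    imap: IntegerMap, n: int, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Sample ``n`` insertion points uniformly over integer space.

    Each draw selects a genomic nucleotide; the insertion is recorded as the
    inter-base position between that nucleotide and the next (column
    ``position`` = 0-based index of the following base).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = rng.integers(0, imap.total, size=n)
    ends = imap.spans["int_end"].to_numpy()
    idx = np.searchsorted(ends, draws, side="right")
    starts = imap.spans["start"].to_numpy()[idx]
    widths = (imap.spans["end"] - imap.spans["start"]).to_numpy()[idx]
    int_starts = imap.spans["int_start"].to_numpy()[idx]
    pos = starts + (draws - int_starts) % widths
    chroms = imap.spans["chrom"].to_numpy()[idx]
    return pd.DataFrame({"chrom": chroms, "position": pos + 1})


def _repeat_trees(annotations: pd.DataFrame) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for row in annotations.itertuples():
        trees.setdefault(row.family, {}).setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end
        )
    return trees


def summarize_flanks(
    positions: pd.DataFrame,
    chromosomes: dict[str, str],
    annotations: pd.DataFrame,
    flank_total: int = 20000,
) -> dict[str, float]:
    """Mean %G+C and % repeat coverage of the flanks around each insertion
    point (half the total on each side, clipped at chromosome ends; percent
    denominators use the realized flank lengths)."""
    half = flank_total // 2
    families = sorted(annotations["family"].unique()) if len(annotations) else []
    trees = _repeat_trees(annotations)
    gc_bases = 0
    total_bases = 0
    covered = {f: 0 for f in families}
    for row in positions.itertuples():
        seq = chromosomes[row.chrom]
        lo = max(0, row.position - half)
        hi = min(len(seq), row.position + half)
        flank = seq[lo:hi]
        total_bases += len(flank)
        gc_bases += flank.count("G") + flank.count("C")
        for fam in families:
            tree = trees.get(fam, {}).get(row.chrom)
            if tree is None:
                continue
            cov = 0
            for iv in tree.overlap(lo, hi):
                cov += min(iv.end, hi) - max(iv.begin, lo)
            covered[fam] += cov
    out = {"pct_gc": 100.0 * gc_bases / total_bases if total_bases else 0.0}
    for fam in families:
        out[f"pct_{fam}"] = 100.0 * covered[fam] / total_bases if total_bases else 0.0
    return out
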