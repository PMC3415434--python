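"""Synthetic fixtures: an annotated multi-chromosome genome, a karyotype
copy-number profile, a per-window feature table, and simulated insertion
cohorts with full ground truth.

The fixture genome stands in for a reference assembly plus its repeat /
gene / conservation tracks: repeat intervals are *planted* (the annotation is
truth by construction), genes carry exon/intron/UTR/CDS substructure, and
planted Alu copies receive genuinely Alu-like (divergent-copy) sequence so
that chimeric-recombination events have a real homology donor.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .construct import ConstructReference, SYNTHETIC_ALU_BODY
from .enrichment import INSTABILITY_13MER, count_motif
from .karyotype import KaryotypeProfile
from .tprt import (
    SlippageParams,
    en_site_scores,
    make_atypical,
    integrate,
    reverse_transcribe_tail,
    revcomp as _revcomp,
    scan_consensus_sites,
)
from .characterize import InsertRecord, estimate_cleavage

__all__ = [
    "GenomeParams",
    "SyntheticGenome",
    "generate_genome",
    "generate_feature_windows",
    "generate_cohort",
    "default_karyotype",
    "CohortError",
]

# repeat-class genome fractions emulating genome-wide repeat content
_DEFAULT_REPEAT_DENSITIES = {
    "Alu": 0.106,
    "L1": 0.169,
    "L2": 0.032,
    "MIR": 0.025,
    "MaLR": 0.036,
}
_REPEAT_LENGTHS = {
    "Alu": (295, 295),
    "L1": (500, 6000),
    "L2": (200, 500),
    "MIR": (150, 300),
    "MaLR": (300, 1000),
}
_ALU_TAIL_LEN = 20


class CohortError(RuntimeError):
    pass


@dataclass(frozen=True)
class GenomeParams:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 150_000}
    )
    gc: float = 0.41
    repeat_densities: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REPEAT_DENSITIES)
    )
    gene_density: float = 0.30
    conserved_density: float = 0.01
    en_site_density: float = 2e-4    # extra planted perfect consensus sites per bp
    alu_divergence: float = 0.15

    def __post_init__(self) -> None:
        for size in self.chrom_sizes.values():
            if size < 10_000:
                raise ValueError("chromosomes must be >= 10 kb")
        dens = list(self.repeat_densities.values()) + [
            self.gene_density,
            self.conserved_density,
        ]
        if any(not 0.0 <= d <= 1.0 for d in dens):
            raise ValueError("densities must lie in [0, 1]")
        if sum(self.repeat_densities.values()) > 0.9:
            raise ValueError("repeat densities cannot be tiled (sum too high)")


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    repeats: pd.DataFrame      # chrom, start, end, family, strand
    genes: pd.DataFrame        # chrom, start, end, strand, gene_id, feature
    conserved: pd.DataFrame    # chrom, start, end
    params: GenomeParams
    seed: int | None = None

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    @property
    def annotations(self) -> pd.DataFrame:
        """Repeat intervals in the (chrom, start, end, family) shape used by
        flank-content summaries."""
        return self.repeats[["chrom", "start", "end", "family"]].copy()


def _divergent_alu(rng: np.random.Generator, divergence: float) -> str:
    """A divergent genomic copy of the Alu-like body plus a short A-tail.
    Every 20-nt window is guaranteed to differ from the construct body so
    that exact-seed anchoring never lands on a genomic copy."""
    body = list(SYNTHETIC_ALU_BODY)
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for i in range(len(body)):
        if rng.random() < divergence:
            body[i] = others[body[i]][rng.integers(0, 3)]
    for i in range(3, len(body), 8):  # >= 2 forced differences per 20-nt window
        if body[i] == SYNTHETIC_ALU_BODY[i]:
            body[i] = others[body[i]][rng.integers(0, 3)]
    return "".join(body) + "A" * _ALU_TAIL_LEN


def _place_intervals(
    rng: np.random.Generator,
    size: int,
    target_bp: int,
    length_range: tuple[int, int],
    occupied: IntervalTree,
    max_tries: int = 20000,
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    bp = 0
    tries = 0
    while bp < target_bp and tries < max_tries:
        tries += 1
        lo, hi = length_range
        length = int(rng.integers(lo, hi + 1))
        if length >= size:
            continue
        start = int(rng.integers(0, size - length))
        if occupied.overlap(start, start + length):
            continue
        occupied.addi(start, start + length)
        placed.append((start, start + length))
        bp += length
    if bp < 0.8 * target_bp and target_bp > 0:
        raise ValueError("could not tile requested density")
    return placed


def generate_genome(
    params: GenomeParams | None = None, seed: int | None = 0
) -> SyntheticGenome:
    """Generate the annotated fixture genome (deterministic under seed).

    The background base composition is adjusted for the GC content of the
    planted Alu copies so that realized chromosome GC matches ``params.gc``.
    """
    params = params or GenomeParams()
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    rep_rows, gene_rows, cons_rows = [], [], []

    for chrom, size in params.chrom_sizes.items():
        occupied = IntervalTree()
        alu_seqs: list[tuple[int, str]] = []
        for family, density in params.repeat_densities.items():
            intervals = _place_intervals(
                rng, size, int(density * size), _REPEAT_LENGTHS[family], occupied
            )
            for start, end in intervals:
                strand = "+" if rng.random() < 0.5 else "-"
                rep_rows.append(
                    {"chrom": chrom, "start": start, "end": end, "family": family, "strand": strand}
                )
                if family == "Alu":
                    alu_seqs.append((start, _divergent_alu(rng, params.alu_divergence)))

        # genes with exon/intron/UTR/CDS substructure (may overlap repeats)
        gene_occupied = IntervalTree()
        gene_iv = _place_intervals(
            rng, size, int(params.gene_density * size), (3000, 15000), gene_occupied
        )
        for gi, (gstart, gend) in enumerate(sorted(gene_iv)):
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{chrom}_g{gi}"
            gene_rows.append(
                {"chrom": chrom, "start": gstart, "end": gend, "strand": strand,
                 "gene_id": gid, "feature": "gene"}
            )
            n_exons = int(rng.integers(2, 7))
            length = gend - gstart
            cuts = np.sort(rng.choice(np.arange(200, length - 200), size=2 * n_exons - 2, replace=False))
            bounds = [0, *cuts.tolist(), length]
            exon_role = {0: "five_prime_UTR", n_exons - 1: "three_prime_UTR"}
            for k in range(2 * n_exons - 1):
                fs, fe = gstart + bounds[k], gstart + bounds[k + 1]
                if fs >= fe:
                    continue
                if k % 2 == 0:
                    feature = exon_role.get(k // 2, "CDS")
                else:
                    feature = "intron"
                gene_rows.append(
                    {"chrom": chrom, "start": fs, "end": fe, "strand": strand,
                     "gene_id": gid, "feature": feature}
                )

        cons_occupied = IntervalTree()
        for start, end in _place_intervals(
            rng, size, int(params.conserved_density * size), (100, 400), cons_occupied
        ):
            cons_rows.append({"chrom": chrom, "start": start, "end": end})

        # background composition adjusted for planted-Alu GC
        alu_bp = sum(len(s) for _, s in alu_seqs)
        alu_gc = sum(s.count("G") + s.count("C") for _, s in alu_seqs)
        bg_bp = size - alu_bp
        bg_gc = (params.gc * size - alu_gc) / bg_bp if bg_bp else params.gc
        bg_gc = float(np.clip(bg_gc, 0.0, 1.0))
        p = [(1 - bg_gc) / 2, bg_gc / 2, bg_gc / 2, (1 - bg_gc) / 2]
        seq = rng.choice(np.array(list("ACGT")), size=size, p=p)
        for start, s in alu_seqs:
            seq[start : start + len(s)] = list(s)
        n_extra = int(params.en_site_density * size)
        if n_extra:
            alu_tree = IntervalTree()
            for start, s in alu_seqs:
                alu_tree.addi(start, start + len(s))
            planted = 0
            attempts = 0
            while planted < n_extra and attempts < 50 * n_extra:
                attempts += 1
                pos = int(rng.integers(10, size - 10))
                if alu_tree.overlap(pos, pos + 6):
                    continue
                motif = "TTAAAA" if rng.random() < 0.5 else "TTTTAA"
                seq[pos : pos + 6] = list(motif)
                planted += 1
        chromosomes[chrom] = "".join(seq)

    cols_rep = ["chrom", "start", "end", "family", "strand"]
    cols_gene = ["chrom", "start", "end", "strand", "gene_id", "feature"]
    return SyntheticGenome(
        chromosomes=chromosomes,
        repeats=pd.DataFrame(rep_rows, columns=cols_rep).sort_values(
            ["chrom", "start"], ignore_index=True
        ),
        genes=pd.DataFrame(gene_rows, columns=cols_gene).sort_values(
            ["chrom", "start"], ignore_index=True
        ),
        conserved=pd.DataFrame(cons_rows, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start"], ignore_index=True
        ),
        params=params,
        seed=seed,
    )


def default_karyotype(
    genome: SyntheticGenome, rng: np.random.Generator | int | None = None
) -> KaryotypeProfile:
    """A mildly aneuploid copy-number profile over the fixture genome: each
    chromosome split into 2-3 regions with copy numbers in 1-4 around a
    near-triploid baseline."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        n_regions = int(rng.integers(2, 4))
        cuts = np.sort(rng.integers(1, length, size=n_regions - 1))
        bounds = [0, *cuts.tolist(), length]
        for i in range(n_regions):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(bounds[i]),
                    "end": int(bounds[i + 1]),
                    "copy_number": int(rng.integers(1, 5)),
                }
            )
    return KaryotypeProfile(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Feature windows

def generate_feature_windows(
    genome: SyntheticGenome,
    window_size: int = 10_000,
    motif: str = INSTABILITY_13MER,
) -> pd.DataFrame:
    """Non-overlapping genome-tiling windows with per-window features: gene
    content (fraction covered), SINE count, GC content, conserved-element
    count, and degenerate-motif count (both strands)."""
    if window_size > max(genome.chrom_lengths.values()):
        raise ValueError("window_size exceeds every chromosome")
    gene_iv = genome.genes[genome.genes["feature"] == "gene"]
    sines = genome.repeats[genome.repeats["family"].isin(["Alu", "MIR"])]
    rows = []
    wid = 0
    for chrom, seq in genome.chromosomes.items():
        n_win = len(seq) // window_size
        gsub = gene_iv[gene_iv["chrom"] == chrom]
        ssub = sines[sines["chrom"] == chrom]
        csub = genome.conserved[genome.conserved["chrom"] == chrom]
        for w in range(n_win):
            lo, hi = w * window_size, (w + 1) * window_size
            wseq = seq[lo:hi]
            cover = 0
            for g in gsub.itertuples():
                cover += max(0, min(g.end, hi) - max(g.start, lo))
            smid = (ssub["start"] + ssub["end"]) // 2
            cmid = (csub["start"] + csub["end"]) // 2
            rows.append(
                {
                    "window_id": f"w{wid}",
                    "chrom": chrom,
                    "start": lo,
                    "end": hi,
                    "gene_content": cover / window_size,
                    "sine_count": int(((smid >= lo) & (smid < hi)).sum()),
                    "gc_content": (wseq.count("G") + wseq.count("C")) / window_size,
                    "conserved_count": int(((cmid >= lo) & (cmid < hi)).sum()),
                    "motif_count": count_motif(wseq, motif),
                }
            )
            wid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort generation

def _flanked_occurrences(tail: str, d: str) -> int:
    """Non-overlapping exact occurrences of a disruption string bounded by
    adenosines (or the tail ends) on both sides -- the way a disruption copy
    is identifiable in a recovered A-tail."""
    n = 0
    start = 0
    while True:
        p = tail.find(d, start)
        if p < 0:
            return n
        left_ok = p == 0 or tail[p - 1] == "A"
        right_ok = p + len(d) == len(tail) or tail[p + len(d)] == "A"
        if left_ok and right_ok:
            n += 1
            start = p + len(d)
        else:
            start = p + 1


def _dup_disruption_count(tail: str, disruptions: tuple[str, ...]) -> int:
    n = 0
    for d in set(disruptions):
        expected = sum(1 for x in disruptions if x == d)
        n += max(0, _flanked_occurrences(tail, d) - expected)
    return n


def _observed_segment_lengths(
    copied: list[int], template, junction_a: int
) -> tuple[dict[int, int], int | None]:
    """Per-template-segment copied A counts (with the junction A-run added to
    the terminal segment) and the terminal (priming) segment index."""
    spans = template.segment_spans()

    def seg_of(pos: int) -> int | None:
        for i, (s, e) in enumerate(spans):
            if s <= pos < e:
                return i + 1
        return None

    lens: dict[int, int] = {}
    max_a = None
    for t in copied:
        seg = seg_of(t)
        if seg is not None:
            lens[seg] = lens.get(seg, 0) + 1
            if max_a is None or t > max_a:
                max_a = t
    if max_a is None:
        return lens, None
    terminal = seg_of(max_a)
    lens[terminal] = lens.get(terminal, 0) + junction_a
    return lens, terminal


def generate_cohort(
    genome: SyntheticGenome,
    construct: ConstructReference,
    n: int = 226,
    class_mix: dict[str, float] | None = None,
    slippage: SlippageParams | None = None,
    seed: int | None = 0,
    flank: int = 1000,
    tsd_range: tuple[int, int] = (5, 27),
    truncation_prob: float = 0.035,
    driver_mix: tuple[float, float] = (178 / 226, 48 / 226),
) -> tuple[list[InsertRecord], pd.DataFrame]:
    """Simulate a recovered-insert cohort with full ground truth.

    ``class_mix`` defaults to the observed 96.5 / 2.7 / 0.8 % split of
    typical, chimeric-recombination and endonuclease-independent events.
    Ground-truth TSD length and tail are recorded in *observable* terms under
    the tail-first junction convention (junction adenosines counted as tail),
    computed analytically from the construction -- never by running the
    characterizer.
    """
    class_mix = class_mix or {
        "typical": 0.965,
        "chimeric": 0.027,
        "endonuclease_independent": 0.008,
    }
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    slippage = slippage or SlippageParams()
    rng = np.random.default_rng(seed)
    order = ["typical", "chimeric", "endonuclease_independent"]
    counts = rng.multinomial(n, [class_mix.get(k, 0.0) for k in order])
    n_typ, n_chi, n_eni = (int(c) for c in counts)

    # eligible perfect consensus sites (room for flanks; junction A-run short
    # enough that TSD + run stays within the detection cap)
    sites = []
    for chrom, seq in genome.chromosomes.items():
        for cut, strand, score in scan_consensus_sites(seq, min_score=6):
            if not flank <= cut <= len(seq) - flank - 60:
                continue
            window_after = seq[cut : cut + 40] if strand == "+" else seq[max(0, cut - 40) : cut]
            run = _leading_a(window_after) if strand == "+" else _trailing_t(window_after)
            if run <= 20:
                sites.append((chrom, cut, strand))
    if n_typ > len(sites):
        raise CohortError(
            f"cohort needs {n_typ} typical sites but only {len(sites)} are available"
        )
    chosen = rng.choice(len(sites), size=n_typ, replace=False)

    alus = genome.repeats[genome.repeats["family"] == "Alu"]
    eligible_alus = []
    for row in alus.itertuples():
        seqlen = genome.chrom_lengths[row.chrom]
        if row.end >= flank and row.end <= seqlen - flank - 60:
            eligible_alus.append(row)
    if n_chi > 0 and not eligible_alus:
        raise CohortError("chimeric events requested but no genomic Alu available")

    records: list[InsertRecord] = []
    truth_rows: list[dict] = []
    rep_trees: dict[str, IntervalTree] = {}
    for row in genome.repeats.itertuples():
        rep_trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.family
        )

    def flank_repeats(chrom: str, lo: int, hi: int) -> tuple[tuple[str, str], ...]:
        tree = rep_trees.get(chrom)
        if tree is None:
            return ()
        out = []
        for iv in sorted(tree.overlap(lo, hi)):
            out.append((iv.data, genome.chromosomes[chrom][iv.begin : iv.end]))
        return tuple(out)

    def driver() -> str:
        return "ORF2" if rng.random() < driver_mix[0] else "L1"

    idx = 0

    for si in chosen:
        chrom, cut, strand = sites[si]
        seq = genome.chromosomes[chrom]
        pre = seq[cut - flank : cut + flank]
        realized, q, events, copied = reverse_transcribe_tail(construct.tail, slippage, rng)
        # a tail ending in T (initial deletion slip stopping mid-disruption)
        # is indistinguishable from the TT of the consensus site at the 3'
        # junction, making the TSD inherently ambiguous; redraw those
        for _ in range(20):
            if not realized.endswith("T"):
                break
            realized, q, events, copied = reverse_transcribe_tail(
                construct.tail, slippage, rng
            )
        tsd_len = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
        trunc = 0
        if rng.random() < truncation_prob:
            # avoid truncation points where the junction is inherently
            # ambiguous (last TSD base equal to the body base 5' of the
            # truncation): such events cannot be recovered exactly by any
            # sequence-based method
            oriented = pre if strand == "+" else _revcomp(pre)
            cut_o = flank if strand == "+" else flank  # symmetric window
            run = _leading_a(oriented[cut_o:])
            last_tsd_base = oriented[cut_o + run + tsd_len - 1]
            for _ in range(50):
                trunc = int(rng.integers(1, len(construct.body) // 2))
                if construct.body[trunc - 1] != last_tsd_base:
                    break
            else:
                trunc = 0
        body_part = construct.body[trunc:]
        post, tsd_seq, dup_total, obs_tail, junction_a = integrate(
            pre, flank, strand, body_part, realized, tsd_len
        )
        seg_lens, term_seg = _observed_segment_lengths(copied, construct.tail, junction_a)
        rid = f"ins{idx:04d}"
        idx += 1
        records.append(
            InsertRecord(
                id=rid,
                pre_locus=pre,
                post_locus=post,
                driver=driver(),
                chrom=chrom,
                position=cut,
                strand=strand,
                flank_repeats=flank_repeats(chrom, cut - flank, cut + flank),
            )
        )
        truth_rows.append(
            {
                "id": rid,
                "class": "TPRT_typical",
                "chrom": chrom,
                "position": cut,
                "strand": strand,
                "tsd_len": tsd_len,
                "tsd_seq": tsd_seq,
                "dup_total_len": dup_total,
                "en_score": 6,
                "truncation_5p": trunc,
                "primed_position": q,
                "priming_segment": term_seg,
                "realized_tail": realized,
                "observable_tail": obs_tail,
                "segment_lengths": ",".join(
                    str(seg_lens.get(i, 0)) for i in range(1, construct.tail.n_segments + 1)
                ),
                "n_slip_events": len(events),
                "dup_disruption_count": _dup_disruption_count(
                    obs_tail, construct.tail.disruptions
                ),
            }
        )

    for _ in range(n_chi):
        row = eligible_alus[int(rng.integers(0, len(eligible_alus)))]
        chrom = row.chrom
        cut = int(row.end)
        seq = genome.chromosomes[chrom]
        pre = seq[cut - flank : cut + flank]
        donor = seq[row.start : row.end - _ALU_TAIL_LEN]
        realized, q, events, _ = reverse_transcribe_tail(construct.tail, slippage, rng)
        bp = int(rng.integers(90, 200))
        deletion = int(rng.integers(0, 400))
        post, insert, bp_eff = make_atypical(
            pre,
            flank,
            "chimeric",
            construct,
            realized,
            rng,
            genomic_alu=donor,
            body_breakpoint=bp,
            deletion=deletion,
        )
        rid = f"ins{idx:04d}"
        idx += 1
        records.append(
            InsertRecord(
                id=rid,
                pre_locus=pre,
                post_locus=post,
                driver=driver(),
                chrom=chrom,
                position=cut,
                strand="+",
                flank_repeats=flank_repeats(chrom, cut - flank, cut + flank),
            )
        )
        truth_rows.append(
            {
                "id": rid,
                "class": "chimeric_recombination",
                "chrom": chrom,
                "position": cut,
                "strand": "+",
                "tsd_len": 0,
                "tsd_seq": "",
                "dup_total_len": 0,
                "en_score": -1,
                "truncation_5p": bp_eff,
                "primed_position": q,
                "priming_segment": None,
                "realized_tail": realized,
                "observable_tail": realized,
                "segment_lengths": "",
                "n_slip_events": len(events),
                "dup_disruption_count": 0,
                "flank_deletion": deletion,
            }
        )

    eni_placed = 0
    attempts = 0
    score_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    while eni_placed < n_eni and attempts < 5000:
        attempts += 1
        chrom = list(genome.chromosomes)[int(rng.integers(0, len(genome.chromosomes)))]
        seq = genome.chromosomes[chrom]
        cut = int(rng.integers(flank, len(seq) - flank))
        if chrom not in score_cache:
            score_cache[chrom] = en_site_scores(seq)
        plus, minus = score_cache[chrom]
        pre = seq[cut - flank : cut + flank]
        realized, q, events, _ = reverse_transcribe_tail(construct.tail, slippage, rng)
        post, insert, trunc = make_atypical(
            pre, flank, "endonuclease_independent", construct, realized, rng
        )
        # the apparent junction can drift 5' where flank bases chance-match
        # the (truncated) body start; reproduce that walk analytically
        j, k = flank - 1, trunc - 1
        while j >= 0 and k >= 0 and pre[j] == construct.body[k]:
            j -= 1
            k -= 1
        s_exp = j + 1
        # the characterizer scores the site at the 5' edge of the junction
        # A-run; require a sub-threshold site there, on both orientations
        c_est = estimate_cleavage(seq, cut - flank + s_exp)
        if max(int(plus[c_est]), int(minus[c_est])) >= 4:
            continue
        # a chance direct repeat at the blunt junction would make the event
        # indistinguishable from TPRT; skip such placements
        eff_insert = pre[s_exp:flank] + insert
        L = 0
        while (
            L < 50
            and L < s_exp
            and L < len(eff_insert)
            and eff_insert[-(L + 1)] == pre[s_exp - (L + 1)]
        ):
            L += 1
        while L > 0 and pre[s_exp - L] == "A":
            L -= 1
        if L >= 5:
            continue
        rid = f"ins{idx:04d}"
        idx += 1
        records.append(
            InsertRecord(
                id=rid,
                pre_locus=pre,
                post_locus=post,
                driver=driver(),
                chrom=chrom,
                position=cut,
                strand="+",
                flank_repeats=flank_repeats(chrom, cut - flank, cut + flank),
            )
        )
        truth_rows.append(
            {
                "id": rid,
                "class": "endonuclease_independent",
                "chrom": chrom,
                "position": cut,
                "strand": "+",
                "tsd_len": 0,
                "tsd_seq": "",
                "dup_total_len": 0,
                "en_score": int(max(plus[c_est], minus[c_est])),
                "truncation_5p": trunc,
                "primed_position": q,
                "priming_segment": None,
                "realized_tail": realized,
                "observable_tail": realized,
                "segment_lengths": "",
                "n_slip_events": len(events),
                "dup_disruption_count": 0,
            }
        )
        eni_placed += 1
    if eni_placed < n_eni:
        raise CohortError("could not place endonuclease-independent events")

    truth = pd.DataFrame(truth_rows)
    return records, truth


def _leading_a(seq: str) -> int:
    n = 0
    for ch in seq:
        if ch != "A":
            break
        n += 1
    return n


def _trailing_t(seq: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != "T":
            break
        n += 1
    return n
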