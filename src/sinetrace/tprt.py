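"""Target-primed reverse transcription (TPRT) simulator for tagged SINEs.

Models the canonical L1-machinery insertion pathway: the endonuclease nicks
the bottom strand at a 5'-TTTT/AA-3' consensus site, the exposed T-rich 3'-OH
primes reverse transcription on the element RNA's A-tail, and second-strand
resolution duplicates the target sequence (TSD).  The reverse-transcription
step is slippage-prone on the homopolymeric tail: before each incorporated
nucleotide the nascent cDNA may dissociate with probability
``p_dissoc0 * exp(-L/decay_scale)`` (L = current cDNA length) and re-anneal
either 3'-ward on the RNA (duplicating already-copied template positions) or
5'-ward (deleting).  Because dissociation decays with cDNA length, expansions
concentrate at the tail's 3' end.

Two atypical resolution modes are also generated: chimeric recombination with
a genomic Alu (no TSD, optional flank deletion) and endonuclease-independent
blunt insertion at a non-consensus site (no TSD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .construct import ConstructReference, TailTemplate

__all__ = [
    "SlippageParams",
    "SlipEvent",
    "SimulatedInsertion",
    "NoTargetSiteError",
    "EN_CONSENSUS",
    "revcomp",
    "en_site_scores",
    "scan_consensus_sites",
    "select_target_site",
    "eligible_priming_positions",
    "reverse_transcribe_tail",
    "replay_slips",
    "integrate",
    "make_atypical",
]

EN_CONSENSUS = "TTTTAA"  # bottom-strand hexamer, cleaved between T4 and A1

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class NoTargetSiteError(ValueError):
    """No endonuclease site scores above threshold anywhere in the genome."""


@dataclass(frozen=True)
class SlippageParams:
    """Tunables of the slippage-prone reverse transcription model.

    min_prime_offset
        Priming is disallowed closer than this many nt to the tail's 5' end
        (the recovered cDNA prefix is always at least this long).
    p_dissoc0
        Per-nucleotide dissociation probability at cDNA length 0.
    decay_scale
        nt scale of the exponential decay of dissociation with cDNA length.
    p_duplicate
        Probability a slip re-anneals 3'-ward (duplicating template
        positions) rather than 5'-ward (deleting).
    slip_span_mean / slip_span_max
        Re-anneal offset is geometric with this mean, truncated at the max.
    p_cross_disruption
        Probability that a slip whose re-anneal span crosses a non-A
        disruption is tolerated; otherwise the span is truncated to the
        homopolymer run (re-annealing out of register requires adenosines,
        which keeps duplicated disruptions rare).
    """

    min_prime_offset: int = 20
    p_dissoc0: float = 0.4
    decay_scale: float = 80.0
    p_duplicate: float = 0.9
    slip_span_mean: float = 3.0
    slip_span_max: int = 10
    p_cross_disruption: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_dissoc0 <= 1.0 and 0.0 <= self.p_duplicate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be positive")
        if self.min_prime_offset < 0:
            raise ValueError("min_prime_offset must be >= 0")


@dataclass(frozen=True)
class SlipEvent:
    """One dissociation/re-anneal during reverse transcription."""

    cdna_length: int   # nascent cDNA length when the slip occurred
    offset: int        # signed re-anneal offset on the RNA (+ = 3'-ward/duplication)
    substring: str     # template positions duplicated (offset>0) or deleted (<0)


@dataclass
class SimulatedInsertion:
    chrom: str
    cut: int                      # 0-based inter-base genomic cut position
    strand: str
    class_label: str              # TPRT_typical | chimeric_recombination | endonuclease_independent
    tsd_len: int                  # observable TSD length (tail-first convention)
    tsd_seq: str
    dup_total_len: int            # total duplicated genomic length incl. junction A-run
    en_score: int
    truncation_5p: int
    primed_position: int          # nt from the tail's 5' end (cDNA prefix length)
    realized_tail: str
    observable_tail: str          # realized tail + junction A's assigned to it
    slip_events: list[SlipEvent] = field(default_factory=list)
    pre_locus: str = ""
    post_locus: str = ""
    cut_in_window: int = 0


# ---------------------------------------------------------------------------
# Endonuclease site model

def _window_scores(arr: np.ndarray, pattern: str, start_off: int) -> np.ndarray:
    """Per-cut-position match counts of a fixed pattern placed at
    cut+start_off .. cut+start_off+len(pattern)."""
    n = len(arr)
    k = len(pattern)
    scores = np.full(n + 1, -1, dtype=np.int8)  # indexed by cut position 0..n
    lo = max(0, -start_off)
    hi = n + 1 - max(0, start_off + k)
    if hi <= lo:
        return scores
    cuts = np.arange(lo, hi)
    acc = np.zeros(len(cuts), dtype=np.int8)
    pat = np.frombuffer(pattern.encode(), dtype="S1")
    for i in range(k):
        acc += arr[cuts + start_off + i] == pat[i]
    scores[cuts] = acc
    return scores


def en_site_scores(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(plus, minus) consensus scores (0-6, -1 where clipped) for every cut
    position 0..len(seq).

    A plus-orientation site has the bottom strand reading 5'-TTTT/AA-3'
    across the cut, i.e. the top strand reads TT|AAAA (cut after the TT); a
    minus-orientation site reads TTTT|AA on the top strand.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    plus = _window_scores(arr, "TTAAAA", -2)   # revcomp(TTTTAA) on top strand
    minus = _window_scores(arr, "TTTTAA", -4)
    return plus, minus


def scan_consensus_sites(seq: str, min_score: int = 6) -> list[tuple[int, str, int]]:
    """All (cut, strand, score) with consensus score >= min_score."""
    plus, minus = en_site_scores(seq)
    out = []
    for cut in np.nonzero(plus >= min_score)[0]:
        out.append((int(cut), "+", int(plus[cut])))
    for cut in np.nonzero(minus >= min_score)[0]:
        out.append((int(cut), "-", int(minus[cut])))
    out.sort()
    return out


def select_target_site(
    genome: dict[str, str] | str,
    rng: np.random.Generator | int | None = None,
    min_score: int = 6,
) -> tuple[str, int, str, int]:
    """Draw one endonuclease site, weighted by consensus match score.

    ``genome`` is a chrom->sequence mapping (a bare string is treated as a
    single chromosome named "chr").  Returns (chrom, cut, strand, score).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(genome, str):
        genome = {"chr": genome}
    sites: list[tuple[str, int, str, int]] = []
    for chrom, seq in genome.items():
        sites.extend((chrom, c, s, sc) for c, s, sc in scan_consensus_sites(seq, min_score))
    if not sites:
        raise NoTargetSiteError(f"no site with consensus score >= {min_score}")
    w = np.array([s[3] for s in sites], dtype=float)
    idx = rng.choice(len(sites), p=w / w.sum())
    return sites[idx]


# ---------------------------------------------------------------------------
# Slippage-prone reverse transcription

def eligible_priming_positions(template: TailTemplate, min_prime_offset: int) -> list[int]:
    """Priming points q (cDNA prefix lengths) allowed by the model: q >=
    min_prime_offset and the primed base (tail position q-1) lies within a
    polyA segment -- the T-rich genomic primer anneals to adenosine runs, not
    to isolated A's inside a disruption."""
    spans = template.segment_spans()

    def in_segment(pos: int) -> bool:
        return any(s <= pos < e for s, e in spans)

    rendered_len = template.rendered_length
    return [
        q
        for q in range(max(1, min_prime_offset), rendered_len + 1)
        if in_segment(q - 1)
    ]


def _draw_span(rng: np.random.Generator, params: SlippageParams) -> int:
    span = int(rng.geometric(1.0 / params.slip_span_mean))
    return min(span, params.slip_span_max)


def reverse_transcribe_tail(
    template: TailTemplate,
    params: SlippageParams,
    rng: np.random.Generator | int | None = None,
    primed_position: int | None = None,
) -> tuple[str, int, list[SlipEvent], list[int]]:
    """Simulate reverse transcription of the tail, 3'->5' along the RNA from
    the priming point toward the tail's 5' end.

    Returns (realized_tail, primed_position, slip_events, copied_indices)
    where copied_indices are the template positions visited in copy order
    (realized_tail is their bases in reverse).  With ``p_dissoc0 == 0`` the
    realized tail is exactly the template prefix ``rendered[:primed_position]``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rendered = template.render()
    if len(rendered) <= params.min_prime_offset:
        raise ValueError("rendered tail not longer than min_prime_offset")
    if primed_position is None:
        eligible = eligible_priming_positions(template, params.min_prime_offset)
        if not eligible:
            raise ValueError("no eligible priming positions")
        primed_position = int(rng.choice(eligible))
    q = primed_position
    if not 1 <= q <= len(rendered):
        raise ValueError("primed_position outside tail")

    copied: list[int] = []
    events: list[SlipEvent] = []
    t = q - 1
    while t >= 0:
        lc = len(copied)
        if params.p_dissoc0 > 0 and rng.random() < params.p_dissoc0 * math.exp(
            -lc / params.decay_scale
        ):
            span = _draw_span(rng, params)
            cross_ok = rng.random() < params.p_cross_disruption
            if rng.random() < params.p_duplicate:
                # re-anneal 3'-ward: on the A-rich template the register can
                # shift past the original priming point, bounded only by the
                # template's 3' end
                new_t = min(t + span, len(rendered) - 1)
                if not cross_ok:
                    while new_t > t and "A" * (new_t - t) != rendered[t + 1 : new_t + 1]:
                        new_t -= 1
                if new_t > t:
                    events.append(
                        SlipEvent(lc, new_t - t, rendered[t + 1 : new_t + 1])
                    )
                    t = new_t
                    continue
                # span truncated to nothing: incorporate normally
            else:
                new_t = max(t - span, -1)
                if not cross_ok:
                    while new_t < t and "A" * (t - new_t) != rendered[new_t + 1 : t + 1]:
                        new_t += 1
                if new_t < t:
                    events.append(
                        SlipEvent(lc, new_t - t, rendered[new_t + 1 : t + 1])
                    )
                    t = new_t
                    continue
        copied.append(t)
        t -= 1
    realized = "".join(rendered[i] for i in reversed(copied))
    return realized, q, events, copied


def replay_slips(template: TailTemplate, primed_position: int, events: Sequence[SlipEvent]) -> str:
    """Deterministically replay recorded slip events on the template; the
    result must equal the simulated realized tail (conservation check)."""
    rendered = template.render()
    q = primed_position
    copied: list[int] = []
    queue = list(events)
    t = q - 1
    while t >= 0:
        if queue and queue[0].cdna_length == len(copied):
            ev = queue.pop(0)
            t = t + ev.offset if ev.offset > 0 else max(t + ev.offset, -1)
            continue
        copied.append(t)
        t -= 1
    if queue:
        raise ValueError("unconsumed slip events during replay")
    return "".join(rendered[i] for i in reversed(copied))


# ---------------------------------------------------------------------------
# Integration

def _leading_a_run(seq: str) -> int:
    n = 0
    for ch in seq:
        if ch != "A":
            break
        n += 1
    return n


def integrate(
    pre_window: str,
    cut: int,
    strand: str,
    insert_body: str,
    realized_tail: str,
    tsd_len: int,
    chrom: str = "chr",
    window_start: int = 0,
) -> tuple[str, str, int, str, int]:
    """Integrate an element at ``cut`` within ``pre_window`` with an
    observable TSD of ``tsd_len`` nt.

    The duplicated genomic region is extended 5'-ward by the A-run that abuts
    the cut (at a consensus site the AA.. of TTTT/AA), because under the
    tail-first junction convention those adenosines are indistinguishable
    from tail sequence; the *observable* TSD is the requested length and
    starts with a non-A base.  Returns (post_window, tsd_seq, dup_total_len,
    observable_tail, junction_a_run).
    """
    if strand == "-":
        post, tsd_seq, dup_total, obs_tail, k = integrate(
            revcomp(pre_window),
            len(pre_window) - cut,
            "+",
            insert_body,
            realized_tail,
            tsd_len,
        )
        return revcomp(post), tsd_seq, dup_total, obs_tail, k

    k = _leading_a_run(pre_window[cut:])
    dup_total = tsd_len + k
    if cut + dup_total > len(pre_window):
        raise ValueError("TSD extends past the window; use a larger flank")
    tsd_seq = pre_window[cut + k : cut + dup_total]
    insert = insert_body + realized_tail
    post = pre_window[: cut + dup_total] + insert + pre_window[cut:]
    observable_tail = realized_tail + "A" * k
    return post, tsd_seq, dup_total, observable_tail, k


def make_atypical(
    pre_window: str,
    cut: int,
    mode: str,
    construct: ConstructReference,
    realized_tail: str,
    rng: np.random.Generator,
    genomic_alu: str | None = None,
    body_breakpoint: int | None = None,
    deletion: int = 0,
) -> tuple[str, str, int]:
    """Build an atypical post-insertion window.

    chimeric: recombination between the nascent element and a genomic Alu --
    the integrated element's 5' part is the genomic Alu's sequence up to the
    (body-aligned) breakpoint, its 3' part the tagged construct from the
    breakpoint on; no TSD; ``deletion`` nt of the 3' flank may be lost.
    endonuclease_independent: blunt insertion of the (possibly truncated)
    construct at a non-consensus site, no TSD.

    Returns (post_window, insert_seq, effective_truncation).
    """
    if mode == "chimeric":
        if not genomic_alu:
            raise ValueError("chimeric mode requires a genomic Alu sequence")
        bp = (
            body_breakpoint
            if body_breakpoint is not None
            else int(rng.integers(len(construct.body) // 3, len(construct.body) // 2))
        )
        bp = min(bp, len(genomic_alu), len(construct.body))
        insert = genomic_alu[:bp] + construct.body[bp:] + realized_tail
        post = pre_window[:cut] + insert + pre_window[cut + deletion :]
        return post, insert, bp
    if mode == "endonuclease_independent":
        trunc = int(rng.integers(0, len(construct.body) // 4))
        insert = construct.body[trunc:] + realized_tail
        post = pre_window[:cut] + insert + pre_window[cut:]
        return post, insert, trunc
    raise ValueError(f"unknown atypical mode: {mode}")
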