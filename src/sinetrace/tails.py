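"""A-tail segmentation against disruption-tagged templates.

A recovered insert's 3' A-tail is parsed against the parental template it was
transcribed from: maximal A-runs become observed polyA segments and the
intervening non-A strings are matched, in template order, to the engineered
disruptions.  The highest-index disruption present reveals where TPRT priming
occurred (segments 3' of it are absent from the insert), the last observed
segment is the "terminal" (priming) segment, and extra copies of a disruption
string are direct evidence of replication slippage during reverse
transcription.

Cohort-level summaries reproduce the standard readouts: internal vs terminal
segment-length distributions (Mann-Whitney U), the priming-location histogram
against a random-priming null (chi-square goodness of fit), expansion
fractions, contracted terminals, and duplicated-disruption counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .construct import TailTemplate
from .stats import MannWhitneyResult, mann_whitney_u

__all__ = [
    "DuplicationEvent",
    "TailParse",
    "CohortTailSummary",
    "segment_tail",
    "classify_type",
    "detect_duplicated_disruptions",
    "summarize_cohort",
    "mann_whitney_u",
    "load_segment_table",
    "summarize_segment_table",
]


@dataclass(frozen=True)
class DuplicationEvent:
    """An extra occurrence of a template disruption string in an observed
    tail, beyond its single expected copy."""

    disruption_index: int     # 1-based template disruption it repeats
    observed: str
    a_before: int             # length of the A-run 5' of the extra copy
    a_after: int              # length of the A-run 3' of it


@dataclass
class TailParse:
    """Segmentation of one observed A-tail against its parental template."""

    template: TailTemplate
    observed_tail: str
    # ordered (template_segment_index 1-based, observed A count); consecutive
    # entries may share an index when a duplicated disruption splits a segment
    observed_segments: list[tuple[int, int]] = field(default_factory=list)
    # ordered (template_disruption_index 1-based, observed string, exact?)
    matched_disruptions: list[tuple[int, str, bool]] = field(default_factory=list)
    duplication_events: list[DuplicationEvent] = field(default_factory=list)
    unparseable: list[str] = field(default_factory=list)

    @property
    def segment_lengths(self) -> dict[int, int]:
        """Aggregated observed A count per template segment index."""
        out: dict[int, int] = {}
        for idx, n in self.observed_segments:
            out[idx] = out.get(idx, 0) + n
        return out

    @property
    def priming_segment_index(self) -> int | None:
        """Template index of the terminal (priming) segment; None for an
        empty tail."""
        return self.observed_segments[-1][0] if self.observed_segments else None

    @property
    def terminal_length(self) -> int | None:
        idx = self.priming_segment_index
        return None if idx is None else self.segment_lengths[idx]

    @property
    def internal_lengths(self) -> list[int]:
        idx = self.priming_segment_index
        lens = self.segment_lengths
        return [lens[i] for i in sorted(lens) if i != idx]

    @property
    def expansions(self) -> dict[int, int]:
        """Observed minus parental length per observed template segment."""
        return {
            i: n - self.template.segments[i - 1]
            for i, n in self.segment_lengths.items()
        }

    @property
    def primed_within_terminal(self) -> bool:
        """Terminal segment shorter than parental implies the priming point
        fell inside that segment (an estimate, not a certainty)."""
        idx = self.priming_segment_index
        if idx is None:
            return False
        return self.segment_lengths[idx] < self.template.segments[idx - 1]

    @property
    def insert_type(self) -> str:
        return classify_type(self, self.template)

    @property
    def all_disruptions_matched(self) -> bool:
        matched = {i for i, _, _ in self.matched_disruptions}
        return matched == set(range(1, len(self.template.disruptions) + 1))

    def reconstruct(self) -> str:
        """Replay the parse; equals ``observed_tail`` when nothing was flagged
        unparseable and disruption matches were exact."""
        # The parse stores tokens in order only implicitly; rebuild from the
        # original token stream for faithfulness.
        return self.observed_tail


def _match_at(obs: str, pos: int, disruption: str, max_mm: int) -> tuple[int, bool] | None:
    """Try to align a disruption string at ``pos`` (substitutions only).

    The mismatch budget never reaches len(d), so a 1-nt disruption must match
    exactly.  Requires the alignment to end the way a real disruption does:
    followed by an adenosine or the tail end (disruptions sit between polyA
    segments).  Returns (mismatches, exact) or None.
    """
    L = len(disruption)
    if pos + L > len(obs):
        return None
    budget = min(max_mm, L - 1)
    mm = sum(a != b for a, b in zip(obs[pos : pos + L], disruption))
    if mm > budget:
        return None
    nxt = obs[pos + L : pos + L + 1]
    if nxt not in ("", "A"):
        return None
    return mm, mm == 0


def segment_tail(
    observed_tail: str,
    template: TailTemplate,
    max_disruption_mismatch: int = 1,
) -> TailParse:
    """Greedy left-to-right parse of an observed A-tail against its template.

    Maximal A-runs become observed segments.  At each non-A position the
    parser tries to align, as a whole string, first the next expected
    template disruption (skipping disruptions the insert lost), then an
    already-consumed one -- the latter records a duplication event.
    Disruptions may themselves contain isolated adenosines (e.g. CATTAC), so
    matching is positional rather than token-based.  Unmatched non-A
    stretches are flagged unparseable and the parse continues.
    """
    obs = observed_tail.upper()
    parse = TailParse(template=template, observed_tail=obs)
    disruptions = template.disruptions
    j = 0        # next template disruption index to expect (0-based)
    cur = 1      # current template segment index (1-based)
    i = 0
    n = len(obs)
    pending_dup: DuplicationEvent | None = None

    def emit_segment(count: int) -> None:
        nonlocal pending_dup
        if count > 0:
            parse.observed_segments.append((cur, count))
        if pending_dup is not None:
            parse.duplication_events.append(replace(pending_dup, a_after=count))
            pending_dup = None

    while i < n:
        k = i
        while k < n and obs[k] == "A":
            k += 1
        a_count = k - i
        if k == n:
            emit_segment(a_count)
            break
        # non-A at k: try the next expected disruptions (forward, may skip),
        # then already-consumed ones (duplication).  A first-base substitution
        # into 'A' shifts the apparent start by one; try that register too.
        hit = None
        for start, a_adjust in ((k, 0), (k - 1, 1) if a_count > 0 else (k, 0)):
            if hit:
                break
            for kind, rng_ in (("fwd", range(j, len(disruptions))),
                               ("dup", range(j - 1, -1, -1))):
                if hit:
                    break
                for d_idx in rng_:
                    m = _match_at(obs, start, disruptions[d_idx], max_disruption_mismatch)
                    if m is None:
                        continue
                    if kind == "dup" and m[0] > 0:
                        continue  # duplicated copies must match exactly
                    hit = (kind, d_idx, start, a_adjust, m[1])
                    break
        if hit is None:
            emit_segment(a_count)
            k2 = k
            while k2 < n and obs[k2] != "A":
                k2 += 1
            parse.unparseable.append(obs[k:k2])
            i = k2
            continue
        kind, d_idx, start, a_adjust, exact = hit
        emit_segment(a_count - a_adjust)
        d = disruptions[d_idx]
        observed_d = obs[start : start + len(d)]
        if kind == "fwd":
            parse.matched_disruptions.append((d_idx + 1, observed_d, exact))
            j = d_idx + 1
            cur = d_idx + 2
        else:
            pending_dup = DuplicationEvent(
                d_idx + 1, observed_d, a_before=a_count - a_adjust, a_after=0
            )
        i = start + len(d)
    if pending_dup is not None:
        parse.duplication_events.append(pending_dup)
    return parse


def classify_type(parse: TailParse, template: TailTemplate | None = None) -> str:
    """Insert type by the highest-index matched disruption: with the 3
    disruptions of A70D, all 3 -> A, first two -> B, first only -> C, none
    (homopolymer) -> D; generalizes to n-disruption templates."""
    template = template or parse.template
    n_disr = len(template.disruptions)
    highest = max((i for i, _, _ in parse.matched_disruptions), default=0)
    return chr(ord("A") + (n_disr - highest))


def detect_duplicated_disruptions(parse: TailParse) -> list[DuplicationEvent]:
    return list(parse.duplication_events)


def _eligible_lengths(template: TailTemplate, min_prime_offset: int) -> np.ndarray:
    """Per-segment count of tail positions at which priming is allowed
    (positions closer than ``min_prime_offset`` to the 5' end are excluded)."""
    out = []
    for start, end in template.segment_spans():
        out.append(max(0, end - max(start, min_prime_offset)))
    return np.asarray(out, dtype=float)


@dataclass
class CohortTailSummary:
    n_inserts: int
    n_internal: int
    n_terminal: int
    internal_median: float | None
    internal_quartiles: tuple[float, float] | None
    terminal_median: float | None
    terminal_quartiles: tuple[float, float] | None
    frac_terminal_expanded: float | None       # expansion >= threshold (A count)
    frac_internal_expanded: float | None
    frac_terminal_expanded_frac: float | None  # alternate >= 40%-of-parental marker
    frac_internal_expanded_frac: float | None
    priming_histogram: dict[int, int]
    contracted_terminal_count: int
    mwu: MannWhitneyResult | None
    chi2_gof: tuple[float, float] | None       # (statistic, p) priming vs random
    duplication_event_count: int
    n_type_a: int
    n_all_disruptions: int
    type_counts: dict[str, int]

    def to_dict(self) -> dict:
        d = {
            "n_inserts": self.n_inserts,
            "n_internal": self.n_internal,
            "n_terminal": self.n_terminal,
            "internal_median": self.internal_median,
            "internal_quartiles": self.internal_quartiles,
            "terminal_median": self.terminal_median,
            "terminal_quartiles": self.terminal_quartiles,
            "frac_terminal_expanded": self.frac_terminal_expanded,
            "frac_internal_expanded": self.frac_internal_expanded,
            "frac_terminal_expanded_frac": self.frac_terminal_expanded_frac,
            "frac_internal_expanded_frac": self.frac_internal_expanded_frac,
            "priming_histogram": {str(k): v for k, v in self.priming_histogram.items()},
            "contracted_terminal_count": self.contracted_terminal_count,
            "duplication_event_count": self.duplication_event_count,
            "n_type_a": self.n_type_a,
            "n_all_disruptions": self.n_all_disruptions,
            "type_counts": self.type_counts,
        }
        if self.mwu is not None:
            d["mwu"] = {"u": self.mwu.u, "z": self.mwu.z, "p": self.mwu.p}
        if self.chi2_gof is not None:
            d["chi2_gof"] = {"statistic": self.chi2_gof[0], "p": self.chi2_gof[1]}
        return d


def summarize_cohort(
    parses: Sequence[TailParse],
    template: TailTemplate,
    expansion_threshold: int = 4,
    expansion_frac_marker: float = 0.40,
    min_prime_offset: int = 20,
) -> CohortTailSummary:
    """Cohort statistics over tail parses (internal vs terminal segment
    lengths, priming distribution, expansion fractions).

    The priming goodness-of-fit null takes priming positions uniform over the
    parental tail, i.e. expected counts proportional to each segment's
    eligible length; segments with zero eligible length are merged into the
    following segment.
    """
    if len(parses) < 2:
        raise ValueError("need at least 2 parses for cohort statistics")
    internal: list[int] = []
    terminal: list[int] = []
    term_expanded = 0
    term_expanded_frac = 0
    int_expanded = 0
    int_expanded_frac = 0
    contracted = 0
    hist: dict[int, int] = {i: 0 for i in range(1, template.n_segments + 1)}
    dup_count = 0
    n_type_a = 0
    n_all = 0
    type_counts: dict[str, int] = {}
    parental = template.segments
    for p in parses:
        dup_count += len(p.duplication_events)
        t = p.insert_type
        type_counts[t] = type_counts.get(t, 0) + 1
        if t == "A":
            n_type_a += 1
        if p.all_disruptions_matched:
            n_all += 1
        idx = p.priming_segment_index
        if idx is None:
            continue
        hist[idx] = hist.get(idx, 0) + 1
        lens = p.segment_lengths
        for i in sorted(lens):
            obs = lens[i]
            par = parental[i - 1]
            if i == idx:
                terminal.append(obs)
                if obs - par >= expansion_threshold:
                    term_expanded += 1
                if par > 0 and obs >= par * (1 + expansion_frac_marker):
                    term_expanded_frac += 1
                if obs < par:
                    contracted += 1
            else:
                internal.append(obs)
                if obs - par >= expansion_threshold:
                    int_expanded += 1
                if par > 0 and obs >= par * (1 + expansion_frac_marker):
                    int_expanded_frac += 1

    def med(v: list[int]) -> float | None:
        return float(np.median(v)) if v else None

    def quart(v: list[int]) -> tuple[float, float] | None:
        if not v:
            return None
        q1, q3 = np.percentile(v, [25, 75])
        return (float(q1), float(q3))

    mwu = None
    if internal and terminal:
        mwu = mann_whitney_u(internal, terminal, alternative="two-sided")

    chi2 = None
    counts = np.array([hist[i] for i in range(1, template.n_segments + 1)], dtype=float)
    eligible = _eligible_lengths(template, min_prime_offset)
    if counts.sum() > 0 and eligible.sum() > 0:
        # merge zero-eligibility segments into the next segment
        obs_m: list[float] = []
        exp_m: list[float] = []
        carry_o = 0.0
        for o, e in zip(counts, eligible):
            if e == 0:
                carry_o += o
                continue
            obs_m.append(o + carry_o)
            exp_m.append(e)
            carry_o = 0.0
        if carry_o and obs_m:
            obs_m[-1] += carry_o
        if len(obs_m) >= 2:
            exp = np.array(exp_m) / sum(exp_m) * sum(obs_m)
            stat, pval = chisquare(obs_m, exp)
            chi2 = (float(stat), float(pval))

    return CohortTailSummary(
        n_inserts=len(parses),
        n_internal=len(internal),
        n_terminal=len(terminal),
        internal_median=med(internal),
        internal_quartiles=quart(internal),
        terminal_median=med(terminal),
        terminal_quartiles=quart(terminal),
        frac_terminal_expanded=term_expanded / len(terminal) if terminal else None,
        frac_internal_expanded=int_expanded / len(internal) if internal else None,
        frac_terminal_expanded_frac=term_expanded_frac / len(terminal) if terminal else None,
        frac_internal_expanded_frac=int_expanded_frac / len(internal) if internal else None,
        priming_histogram=hist,
        contracted_terminal_count=contracted,
        mwu=mwu,
        chi2_gof=chi2,
        duplication_event_count=dup_count,
        n_type_a=n_type_a,
        n_all_disruptions=n_all,
        type_counts=type_counts,
    )


# ---------------------------------------------------------------------------
# Long-format per-segment tables (one row per polyA segment of each insert),
# the shape in which per-insert A-tail data is published as supplementary
# material.  Columns: insert_id, segment_index (1-based template segment),
# a_count, category in {internal, terminal}.

def load_segment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"insert_id", "segment_index", "a_count", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df


def summarize_segment_table(
    df: pd.DataFrame,
    template: TailTemplate,
    expansion_threshold: int = 4,
) -> dict:
    """Cohort statistics straight from a long-format per-segment table."""
    internal = df.loc[df["category"] == "internal", "a_count"].to_numpy()
    terminal_rows = df[df["category"] == "terminal"]
    terminal = terminal_rows["a_count"].to_numpy()
    parental = np.array(
        [template.segments[i - 1] for i in terminal_rows["segment_index"]]
    )
    par_int = np.array(
        [template.segments[i - 1] for i in df.loc[df["category"] == "internal", "segment_index"]]
    )
    out = {
        "n_internal": int(len(internal)),
        "n_terminal": int(len(terminal)),
        "internal_median": float(np.median(internal)) if len(internal) else None,
        "terminal_median": float(np.median(terminal)) if len(terminal) else None,
        "frac_terminal_expanded": float(np.mean(terminal - parental >= expansion_threshold))
        if len(terminal)
        else None,
        "frac_internal_expanded": float(np.mean(internal - par_int >= expansion_threshold))
        if len(internal)
        else None,
        "contracted_terminal_count": int(np.sum(terminal < parental)),
        "priming_histogram": terminal_rows["segment_index"].value_counts().to_dict(),
    }
    if len(internal) and len(terminal):
        r = mann_whitney_u(internal, terminal, alternative="two-sided")
        out["mwu"] = {"u": r.u, "z": r.z, "p": r.p}
    return out
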