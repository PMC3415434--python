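"""Tagged-SINE construct model: disruption-tagged A-tail templates and the
construct reference the rest of the pipeline consumes.

The engineered rescue constructs replace the natural homopolymeric A-tail of
the element with an A-rich tract in which short non-adenosine "disruption"
strings are interleaved between polyA segments.  Because the disruptions are
unique, the priming location of target-primed reverse transcription (TPRT)
and any slippage-driven duplication of tail sequence can be read directly
from recovered inserts.  Two tail variants are built in:

* ``A70D`` -- four polyA segments of 17/18 adenosines separated by the
  disruptions ``CATTAC``, ``G`` and ``CACAC`` (rendered length 82 nt).
* ``A30D`` -- three polyA segments of 10 adenosines separated by ``CT`` and
  ``TAC`` (rendered length 35 nt).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "TailTemplate",
    "ConstructReference",
    "TemplateNotFoundError",
    "builtin_template",
    "render_tail",
    "load_templates",
    "default_construct",
    "SYNTHETIC_ALU_BODY",
]


class TemplateNotFoundError(KeyError):
    """Requested tail template is not built in and no definition file names it."""


@dataclass(frozen=True)
class TailTemplate:
    """Parental A-tail composition: ordered polyA segment lengths and the
    non-A disruption strings placed between consecutive segments."""

    name: str
    segments: tuple[int, ...]
    disruptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        segments = tuple(int(s) for s in self.segments)
        disruptions = tuple(str(d).upper() for d in self.disruptions)
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "disruptions", disruptions)
        if not segments:
            raise ValueError("template needs at least one polyA segment")
        if any(s < 0 for s in segments):
            raise ValueError("segment lengths must be non-negative")
        if len(disruptions) != len(segments) - 1:
            raise ValueError(
                f"{self.name}: expected {len(segments) - 1} disruptions, "
                f"got {len(disruptions)}"
            )
        for d in disruptions:
            if not d:
                raise ValueError("disruptions must be non-empty")
            if "AAAA" in d:
                raise ValueError(f"disruption {d!r} contains an A-run >= 4")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def rendered_length(self) -> int:
        return sum(self.segments) + sum(len(d) for d in self.disruptions)

    def render(self) -> str:
        """Concatenate A^s1 + d1 + A^s2 + ... into the parental tail sequence."""
        parts: list[str] = []
        for i, seg in enumerate(self.segments):
            parts.append("A" * seg)
            if i < len(self.disruptions):
                parts.append(self.disruptions[i])
        return "".join(parts)

    def segment_spans(self) -> list[tuple[int, int]]:
        """0-based half-open [start, end) of each polyA segment in the
        rendered tail."""
        spans = []
        pos = 0
        for i, seg in enumerate(self.segments):
            spans.append((pos, pos + seg))
            pos += seg
            if i < len(self.disruptions):
                pos += len(self.disruptions[i])
        return spans


def render_tail(template: TailTemplate) -> str:
    return template.render()


_BUILTINS: Mapping[str, TailTemplate] = {
    # Segment order within A70D is [17, 18, 17, 18]; only the per-segment
    # range (17 or 18 adenosines, total 70) and the 82-nt rendered length are
    # fixed by the construct, so the order is a documented convention.
    "A70D": TailTemplate("A70D", (17, 18, 17, 18), ("CATTAC", "G", "CACAC")),
    "A30D": TailTemplate("A30D", (10, 10, 10), ("CT", "TAC")),
}


def builtin_template(name: str, definitions: Path | str | None = None) -> TailTemplate:
    """Return a built-in tail template by name, or one defined in a YAML file.

    Parameters
    ----------
    name
        Template label, e.g. ``"A70D"``.
    definitions
        Optional YAML file with user templates (see :func:`load_templates`);
        consulted before the builtins so entries may override them.
    """
    if definitions is not None:
        user = load_templates(definitions)
        if name in user:
            return user[name]
    try:
        return _BUILTINS[name]
    except KeyError:
        raise TemplateNotFoundError(name) from None


def load_templates(path: Path | str) -> dict[str, TailTemplate]:
    """Load tail templates from a YAML mapping::

        A30D:
          segments: [10, 10, 10]
          disruptions: [CT, TAC]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, TailTemplate] = {}
    for name, spec in raw.items():
        out[name] = TailTemplate(
            name=name,
            segments=tuple(spec["segments"]),
            disruptions=tuple(spec.get("disruptions", ())),
        )
    return out


# Synthetic stand-in for the tagged Alu body (element sequence 5' of the
# A-tail).  It is NOT a real Alu: a deterministic random sequence with the
# gross architecture the pipeline relies on -- two arms joined by a single
# internal A-rich linker (the only A-run >= 4), starting with a non-A base.
SYNTHETIC_ALU_BODY = (
    "GGCCGTCCGCAGCGAGCAGCTCGGACAGTAAGGAGCCGACGCGAACAACCTACTCCCTAA"
    "TCCACACTCAGACCCTGATTGTGCCCCTTCGCACCGAGTCTGAGCACGAGGTGGAGGGCA"
    "CCGCCCTCCAAAAAAATACACTCCGCGACGACTAAGGGTAGTCCGTGTACCGGGCCCATT"
    "CCCTCAATCTAGGGAATCAGATCCTATGCTGGAGGTGAGTCCCACTACGACCAGCGGAGT"
    "CCGCGCCAAACGGCGGAAGAGCGAAAGTCTGCGAC"
)


def _longest_internal_a_run(body: str, min_len: int = 6) -> tuple[int, int] | None:
    best: tuple[int, int] | None = None
    for m in re.finditer(r"A{%d,}" % min_len, body):
        if best is None or (m.end() - m.start()) > (best[1] - best[0]):
            best = (m.start(), m.end())
    return best


@dataclass(frozen=True)
class ConstructReference:
    """The tagged element: body sequence 5' of the A-tail, the tail template,
    an optional unique region 3' of the tail, and the A-rich middle interval
    masked in mismatch scans (defaults to the longest internal A-run >= 6)."""

    body: str
    tail: TailTemplate
    unique_3p: str | None = None
    a_rich_middle: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        body = self.body.upper()
        object.__setattr__(self, "body", body)
        if not body:
            raise ValueError("construct body must be non-empty")
        if self.a_rich_middle is None:
            object.__setattr__(self, "a_rich_middle", _longest_internal_a_run(body))
        if self.a_rich_middle is not None:
            s, e = self.a_rich_middle
            if not (0 <= s <= e <= len(body)):
                raise ValueError("a_rich_middle outside body bounds")

    @property
    def tail_seq(self) -> str:
        return self.tail.render()

    def insert_sequence(self, truncation_5p: int = 0, tail_seq: str | None = None) -> str:
        """Element sequence as integrated: optionally 5'-truncated body plus a
        (realized or parental) tail, plus the 3' unique region if present."""
        if not 0 <= truncation_5p <= len(self.body):
            raise ValueError("truncation outside body bounds")
        tail = self.tail_seq if tail_seq is None else tail_seq
        unique = self.unique_3p or ""
        return self.body[truncation_5p:] + tail + unique


def default_construct(tail: str | TailTemplate = "A70D") -> ConstructReference:
    """The bundled synthetic tagged-Alu construct with the requested tail."""
    template = tail if isinstance(tail, TailTemplate) else builtin_template(tail)
    return ConstructReference(body=SYNTHETIC_ALU_BODY, tail=template)
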