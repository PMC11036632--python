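"""Start/end boundary tagging of textual slot fillers.

Instead of IOB tagging, only the first and the last token of a filler are
labelled with the slot name (``start:Frequency`` / ``end:Frequency``); all
other tokens carry the no-slot label.  A single-token filler carries both its
start and its end label.  Predicted start and end tokens are joined
sentence-wise: each start token, processed left to right, consumes the
nearest unconsumed end token of the same label at a position >= its own;
unmatched boundary tokens are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .corpus import TokenizedDocument, span_from_tokens
from .schema import TextSpan

__all__ = ["NO_SLOT", "BoundaryTags", "spans_to_tags", "tags_to_spans", "to_iob"]

#: the no-slot label (rendered as None internally)
NO_SLOT: Optional[str] = None


@dataclass
class BoundaryTags:
    """Per-token start and end labels; ``None`` is the no-slot label."""

    start_labels: list[Optional[str]]
    end_labels: list[Optional[str]]

    def __post_init__(self) -> None:
        if len(self.start_labels) != len(self.end_labels):
            raise ValueError("start/end label sequences differ in length")

    def __len__(self) -> int:
        return len(self.start_labels)


def spans_to_tags(
    doc: TokenizedDocument, fillers: list[tuple[str, TextSpan]]
) -> BoundaryTags:
    """Convert (slot, span) fillers to boundary tags.

    Raises ``ValueError`` if two fillers share a start token or share an end
    token (one start and one end label per token).
    """
    n = doc.n_tokens
    start: list[Optional[str]] = [NO_SLOT] * n
    end: list[Optional[str]] = [NO_SLOT] * n
    for slot, span in fillers:
        if not (0 <= span.token_start <= span.token_end < n):
            raise ValueError(f"filler token span outside document: {span}")
        if start[span.token_start] is not NO_SLOT:
            raise ValueError(
                f"conflicting start labels at token {span.token_start}: "
                f"{start[span.token_start]} vs {slot}"
            )
        if end[span.token_end] is not NO_SLOT:
            raise ValueError(
                f"conflicting end labels at token {span.token_end}: "
                f"{end[span.token_end]} vs {slot}"
            )
        start[span.token_start] = slot
        end[span.token_end] = slot
    return BoundaryTags(start, end)


def tags_to_spans(
    doc: TokenizedDocument, tags: BoundaryTags
) -> list[tuple[str, TextSpan]]:
    """Join boundary tags into (slot, span) fillers, sentence by sentence.

    Matching is greedy left to right over start tokens; each consumes the
    nearest unconsumed same-label end token at position >= the start.  Starts
    and ends that find no partner within their sentence are discarded.
    """
    if len(tags) != doc.n_tokens:
        raise ValueError("tags do not cover the document")
    fillers: list[tuple[str, TextSpan]] = []
    for a, b in doc.sentence_spans:
        starts = [(i, tags.start_labels[i]) for i in range(a, b)
                  if tags.start_labels[i] is not NO_SLOT]
        ends = [(j, tags.end_labels[j]) for j in range(a, b)
                if tags.end_labels[j] is not NO_SLOT]
        consumed = [False] * len(ends)
        for i, label in starts:
            best = None
            for k, (j, elabel) in enumerate(ends):
                if consumed[k] or elabel != label or j < i:
                    continue
                if best is None or j < ends[best][0]:
                    best = k
            if best is not None:
                consumed[best] = True
                fillers.append((label, span_from_tokens(doc, i, ends[best][0])))
    fillers.sort(key=lambda sf: (sf[1].token_start, sf[1].token_end, sf[0]))
    return fillers


def to_iob(doc: TokenizedDocument, fillers: list[tuple[str, TextSpan]]) -> list[str]:
    """Render fillers in IOB-style labels for side-by-side comparison."""
    labels = ["O"] * doc.n_tokens
    for slot, span in fillers:
        for i in range(span.token_start, span.token_end + 1):
            labels[i] = f"I-{slot}"
    return labels
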