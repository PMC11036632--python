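"""Grammar-constrained greedy decoding.

At each step the decoding stack (a :class:`~picostruct.grammar.GrammarCursor`)
yields the set of tokens that keep the output derivable: the root's start
special at the beginning; inside a template frame, the start specials of that
template's slots plus the template's end special; inside a textual slot, the
token types of the input document plus the slot's end special; after a
template slot's start, the child template's start special.  Scores of all
other vocabulary entries are masked to minus infinity and the maximum-score
token is emitted greedily.  The output is therefore always derivable — or,
when the length budget is hit mid-structure, auto-closed in stack order and
flagged truncated.

Beam search and sampling are deliberately not provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .corpus import TokenizedDocument
from .grammar import Grammar, GrammarCursor, end_token, parse, start_token
from .schema import InstanceForest

__all__ = [
    "LogitProvider",
    "DecodeResult",
    "allowed_next_tokens",
    "constrained_decode",
    "decode_document",
]


class LogitProvider(Protocol):
    """Scoring contract: deterministic next-token scores given the input
    document and the generated prefix.

    ``vocabulary`` lists the scoreable tokens; ``next_scores`` returns one
    finite score per vocabulary entry."""

    @property
    def vocabulary(self) -> list[str]: ...

    def next_scores(
        self, doc: TokenizedDocument, prefix: Sequence[str]
    ) -> np.ndarray: ...


@dataclass
class DecodeResult:
    tokens: list[str]
    truncated: bool


def allowed_next_tokens(
    cursor: GrammarCursor, doc: TokenizedDocument
) -> set[str]:
    """The grammar-allowed next tokens, with the TEXT placeholder expanded to
    the distinct token types of the input document."""
    return cursor.allowed_surface(doc.surfaces())


def constrained_decode(
    provider: LogitProvider,
    grammar: Grammar,
    doc: TokenizedDocument,
    max_len: int | None = None,
) -> DecodeResult:
    """Greedy decoding under the vocabulary mask induced by the grammar.

    ``max_len`` defaults to four times the input length.  Ties between
    equally scored allowed tokens break toward the lowest vocabulary index.
    """
    if max_len is None:
        max_len = 4 * doc.n_tokens
    if max_len < 2:
        raise ValueError("max_len must be >= 2")

    vocab = provider.vocabulary
    index = {t: i for i, t in enumerate(vocab)}
    cursor = GrammarCursor(grammar)
    out: list[str] = []

    while not cursor.done and len(out) < max_len:
        allowed = allowed_next_tokens(cursor, doc)
        allowed_ids = [index[t] for t in allowed if t in index]
        # every grammar continuation must be scoreable; an empty allowed set
        # would be a grammar bug, not a model failure
        assert allowed_ids, (
            f"no scoreable allowed token at step {len(out)}; allowed={allowed!r}"
        )
        scores = np.asarray(provider.next_scores(doc, out), dtype=float)
        mask = np.full(len(vocab), -np.inf)
        mask[allowed_ids] = 0.0
        masked = scores + mask
        choice = vocab[int(np.argmax(masked))]
        out.append(choice)
        cursor.advance(choice, is_doc_token=not choice.startswith("["))

    truncated = not cursor.done
    if truncated:
        # auto-close open frames so downstream parsing never hard-fails; a
        # template slot still awaiting its child needs an empty child first
        while cursor.stack:
            top = cursor.stack[-1]
            if top.kind == "cslot" and not top.child_done:
                tok = start_token(top.spec.child_template)
            else:
                tok = end_token(top.name)
            out.append(tok)
            cursor.advance(tok)
    return DecodeResult(tokens=out, truncated=truncated)


def decode_document(
    provider: LogitProvider,
    grammar: Grammar,
    doc: TokenizedDocument,
    max_len: int | None = None,
) -> InstanceForest:
    """Decode and parse into an instance forest (best effort on truncation)."""
    result = constrained_decode(provider, grammar, doc, max_len=max_len)
    return parse(result.tokens, grammar, doc, allow_truncated=True)
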