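"""Document tokenization, character/token alignment and corpus (de)serialization.

Documents are plain-text RCT abstracts.  Tokenization is deterministic and
keeps an exact character alignment for every token, so gold character spans
can be projected to token spans (the boundary taggers operate on tokens) and
predicted token spans projected back.  Sentence boundaries come from a simple
deterministic rule: a ``.``/``?``/``!`` followed by whitespace and an
uppercase letter or digit ends a sentence.  Start/end token joining never
crosses these boundaries.

Corpora are JSONL files: one document per line with its text and, for gold
corpora, the instance forest (spans as 0-based half-open character offsets,
child instances as id references).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

from .schema import (
    FreeText,
    InstanceForest,
    SchemaConfig,
    TemplateInstance,
    TextSpan,
)

__all__ = [
    "Token",
    "TokenizedDocument",
    "tokenize_document",
    "align_span",
    "span_from_chars",
    "span_from_tokens",
    "read_corpus",
    "write_corpus",
    "write_predictions",
]


@dataclass(frozen=True)
class Token:
    surface: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class TokenizedDocument:
    doc_id: str
    text: str
    tokens: tuple[Token, ...]
    sentence_spans: tuple[tuple[int, int], ...]  # half-open token-index intervals
    tokenizer_id: str = "regex"

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def sentence_of(self, token_index: int) -> int:
        for k, (a, b) in enumerate(self.sentence_spans):
            if a <= token_index < b:
                return k
        raise IndexError(token_index)


_TOKENIZERS: dict[str, Callable[[str], list[tuple[int, int]]]] = {}


def _register(name):
    def deco(fn):
        _TOKENIZERS[name] = fn
        return fn

    return deco


@_register("whitespace")
def _whitespace_spans(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]


@_register("regex")
def _regex_spans(text: str) -> list[tuple[int, int]]:
    """Words, numbers (incl. decimals) and single punctuation marks."""
    pat = re.compile(r"\d+(?:\.\d+)?|\w+|[^\w\s]")
    return [(m.start(), m.end()) for m in pat.finditer(text)]


_SENT_BREAK = re.compile(r"[.?!](?=\s+[A-Z0-9])")


def tokenize_document(
    doc_id: str, text: str, tokenizer: str = "regex"
) -> TokenizedDocument:
    """Tokenize ``text`` with a registered deterministic tokenizer.

    Raises ``ValueError`` for empty (after stripping) text or an unknown
    tokenizer name.
    """
    if not text or not text.strip():
        raise ValueError("document text is empty")
    try:
        span_fn = _TOKENIZERS[tokenizer]
    except KeyError:
        raise ValueError(f"unknown tokenizer {tokenizer!r}") from None
    spans = span_fn(text)
    tokens = tuple(Token(text[a:b], a, b) for a, b in spans)
    if not tokens:
        raise ValueError("tokenizer produced no tokens")

    # sentence boundaries: token starting after a break character ends the
    # previous sentence
    break_positions = {m.start() for m in _SENT_BREAK.finditer(text)}
    sentence_spans: list[tuple[int, int]] = []
    start = 0
    for i, tok in enumerate(tokens[:-1]):
        # the break '.' is itself a token under the regex tokenizer; under the
        # whitespace tokenizer it is the tail of a word token
        if any(a in break_positions for a in range(tok.char_start, tok.char_end)):
            sentence_spans.append((start, i + 1))
            start = i + 1
    sentence_spans.append((start, len(tokens)))
    return TokenizedDocument(
        doc_id=doc_id,
        text=text,
        tokens=tokens,
        sentence_spans=tuple(sentence_spans),
        tokenizer_id=tokenizer,
    )


def align_span(
    doc: TokenizedDocument, char_start: int, char_end: int
) -> tuple[int, int]:
    """Minimal inclusive token interval covering [char_start, char_end).

    Raises ``ValueError`` if the interval lies outside the text or covers no
    token (e.g. pure whitespace).
    """
    if not (0 <= char_start < char_end <= len(doc.text)):
        raise ValueError(
            f"character interval [{char_start}, {char_end}) outside document "
            f"of length {len(doc.text)}"
        )
    first = last = None
    for i, tok in enumerate(doc.tokens):
        if tok.char_end > char_start and tok.char_start < char_end:
            if first is None:
                first = i
            last = i
    if first is None:
        raise ValueError(
            f"interval [{char_start}, {char_end}) covers no token"
        )
    return first, last


def span_from_chars(doc: TokenizedDocument, char_start: int, char_end: int) -> TextSpan:
    ts, te = align_span(doc, char_start, char_end)
    return TextSpan(
        doc_id=doc.doc_id,
        char_start=char_start,
        char_end=char_end,
        token_start=ts,
        token_end=te,
        text=doc.text[char_start:char_end],
    )


def span_from_tokens(doc: TokenizedDocument, token_start: int, token_end: int) -> TextSpan:
    """TextSpan covering the inclusive token range, with exact char offsets."""
    a = doc.tokens[token_start].char_start
    b = doc.tokens[token_end].char_end
    return TextSpan(
        doc_id=doc.doc_id,
        char_start=a,
        char_end=b,
        token_start=token_start,
        token_end=token_end,
        text=doc.text[a:b],
    )


# ---------------------------------------------------------------------------
# JSONL corpus format
# ---------------------------------------------------------------------------

def _forest_to_dict(forest: InstanceForest) -> dict:
    instances = []
    for inst in forest.instances:
        slots: dict[str, list] = {}
        for slot, fillers in inst.slots.items():
            out = []
            for f in fillers:
                if isinstance(f, TemplateInstance):
                    out.append({"ref": f.instance_id})
                elif isinstance(f, FreeText):
                    out.append({"text": f.text, "hallucinated": True})
                else:
                    out.append({"span": [f.char_start, f.char_end]})
            slots[slot] = out
        instances.append({"id": inst.instance_id, "type": inst.type, "slots": slots})
    return {"instances": instances, "root": forest.root}


def _forest_from_dict(data: dict, doc: TokenizedDocument) -> InstanceForest:
    insts = {
        d["id"]: TemplateInstance(instance_id=d["id"], type=d["type"])
        for d in data["instances"]
    }
    for d in data["instances"]:
        inst = insts[d["id"]]
        for slot, fillers in d.get("slots", {}).items():
            for f in fillers:
                if "ref" in f:
                    try:
                        inst.add(slot, insts[f["ref"]])
                    except KeyError:
                        raise ValueError(
                            f"{doc.doc_id}: unknown instance ref {f['ref']!r}"
                        ) from None
                elif "text" in f:
                    inst.add(slot, FreeText(doc_id=doc.doc_id, text=f["text"]))
                else:
                    cs, ce = f["span"]
                    inst.add(slot, span_from_chars(doc, cs, ce))
    return InstanceForest(
        doc_id=doc.doc_id, instances=list(insts.values()), root=data["root"]
    )


def write_corpus(
    path: Union[str, Path],
    items: Iterable[tuple[TokenizedDocument, Optional[InstanceForest]]],
) -> None:
    """Write (document, forest) pairs to a JSONL file; forest may be None."""
    with open(path, "w") as fh:
        for doc, forest in items:
            record: dict = {"doc_id": doc.doc_id, "text": doc.text,
                            "tokenizer": doc.tokenizer_id}
            if forest is not None:
                record.update(_forest_to_dict(forest))
            fh.write(json.dumps(record) + "\n")


def write_predictions(
    path: Union[str, Path],
    items: Iterable[tuple[TokenizedDocument, InstanceForest]],
) -> None:
    """Serialize predicted forests in the same JSONL format as gold corpora."""
    write_corpus(path, items)


def read_corpus(
    path: Union[str, Path],
    schema: Optional[SchemaConfig] = None,
) -> list[tuple[TokenizedDocument, Optional[InstanceForest]]]:
    """Read a JSONL corpus; re-tokenizes each document with its stored
    tokenizer and re-aligns annotation spans.

    If ``schema`` is given, templates and slots are checked against it and a
    ``ValueError`` is raised on unknown names.
    """
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{line_no}: malformed JSON: {exc}") from exc
            doc = tokenize_document(
                record["doc_id"], record["text"], record.get("tokenizer", "regex")
            )
            forest = None
            if "instances" in record:
                forest = _forest_from_dict(record, doc)
                if schema is not None:
                    _check_names(forest, schema, doc.doc_id)
            out.append((doc, forest))
    return out


def _check_names(forest: InstanceForest, schema: SchemaConfig, doc_id: str) -> None:
    for inst in forest.instances:
        if inst.type not in schema:
            raise ValueError(f"{doc_id}: unknown template {inst.type!r}")
        tspec = schema.template(inst.type)
        declared = {s.name for s in tspec.slots}
        for slot in inst.slots:
            if slot not in declared:
                raise ValueError(
                    f"{doc_id}: slot {slot!r} not declared for {inst.type}"
                )
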