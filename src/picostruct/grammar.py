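"""Linearization of instance forests and the schema-derived right-linear CFG.

A forest is serialized depth first: an instance of template ``T`` becomes
``[start:T] ... [end:T]``; inside, each filled slot emits every filler
wrapped in ``[start:SLOT] ... [end:SLOT]`` — verbatim document tokens for
textual fillers, a recursively linearized child instance for template slots.
Fillers within a slot are ordered by document position (template-valued
fillers by the position of their earliest textual descendant); slots within a
template by declaration order.

The same structure is described by a context-free grammar with, per template
type ``T``:

* a head rule        ``T_HEAD -> [start:T] T``
* a terminator rule  ``T -> [end:T]``
* per textual slot   ``T -> [start:SLOT] TEXT [end:SLOT] T``
* per template slot  ``T -> [start:SLOT] U_HEAD [end:SLOT] T``

where ``TEXT`` stands for any token sequence from the input document.  The
tail recursion into ``T`` permits any number of slot segments (including
repetitions) before the terminator.  Derivability is decided by an
equivalent stack machine (:class:`GrammarCursor`) that also powers the
constrained decoder: it yields the exact allowed-next-token set at every
prefix of a derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus import TokenizedDocument, span_from_tokens
from .schema import (
    FreeText,
    InstanceForest,
    SchemaConfig,
    SlotSpec,
    TemplateInstance,
    TextSpan,
)

__all__ = [
    "start_token",
    "end_token",
    "Rule",
    "Grammar",
    "build_grammar",
    "OrderingOperators",
    "default_orderings",
    "linearize",
    "GrammarCursor",
    "validate_sequence",
    "parse",
    "ParseError",
]


def start_token(name: str) -> str:
    return f"[start:{name}]"


def end_token(name: str) -> str:
    return f"[end:{name}]"


TEXT = "TEXT"  # placeholder terminal for "any token sequence from the document"


@dataclass(frozen=True)
class Rule:
    head: str
    rhs: tuple[str, ...]
    kind: str  # "head" | "terminator" | "textual_slot" | "template_slot"

    def __str__(self) -> str:  # pragma: no cover - debug aid
        return f"{self.head} := {' '.join(self.rhs)}"


@dataclass
class Grammar:
    """The right-linear CFG instantiated from a schema."""

    schema: SchemaConfig
    rules: list[Rule]
    start_symbol: str
    vocabulary: list[str] = field(default_factory=list)

    @property
    def special_tokens(self) -> list[str]:
        specials = []
        for t in self.schema.templates:
            specials.append(start_token(t.name))
            specials.append(end_token(t.name))
            for s in t.slots:
                specials.append(start_token(s.name))
                specials.append(end_token(s.name))
        return specials

    def rules_for(self, head: str) -> list[Rule]:
        return [r for r in self.rules if r.head == head]


def build_grammar(
    schema: SchemaConfig, vocabulary: Optional[Iterable[str]] = None
) -> Grammar:
    """Instantiate the four rule schemas for every template of ``schema``."""
    rules: list[Rule] = []
    for t in schema.templates:
        rules.append(
            Rule(f"{t.name}_HEAD", (start_token(t.name), t.name), "head")
        )
        rules.append(Rule(t.name, (end_token(t.name),), "terminator"))
        for s in t.slots:
            if s.kind == "textual":
                rules.append(
                    Rule(
                        t.name,
                        (start_token(s.name), TEXT, end_token(s.name), t.name),
                        "textual_slot",
                    )
                )
            else:
                rules.append(
                    Rule(
                        t.name,
                        (
                            start_token(s.name),
                            f"{s.child_template}_HEAD",
                            end_token(s.name),
                            t.name,
                        ),
                        "template_slot",
                    )
                )
    return Grammar(
        schema=schema,
        rules=rules,
        start_symbol=f"{schema.root}_HEAD",
        vocabulary=list(vocabulary) if vocabulary is not None else [],
    )


# ---------------------------------------------------------------------------
# Orderings and linearization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderingOperators:
    """Total orders used for the (otherwise ambiguous) set linearization.

    ``omega`` keys slot fillers within one slot; ``Omega`` keys slots within
    a template.  Both orders are arbitrary but must be fixed across training
    examples.
    """

    omega_key: "callable"
    Omega_key: "callable"


def _earliest_position(filler, creation_index: int) -> tuple:
    """Sort key: document position, template fillers by earliest textual
    descendant; fillers with no anchored text sort last, ties by creation
    order within the slot."""
    if isinstance(filler, TextSpan):
        return (0, filler.token_start, filler.token_end, creation_index)
    if isinstance(filler, FreeText):
        return (1, 0, 0, creation_index)
    best = None
    stack = [filler]
    seen = set()
    while stack:
        inst = stack.pop()
        if id(inst) in seen:
            continue
        seen.add(id(inst))
        for _, tf in inst.textual_fillers():
            if isinstance(tf, TextSpan):
                key = (tf.token_start, tf.token_end)
                if best is None or key < best:
                    best = key
        stack.extend(inst.children())
    if best is None:
        return (1, 0, 0, creation_index)
    return (0, best[0], best[1], creation_index)


def default_orderings(schema: SchemaConfig) -> OrderingOperators:
    slot_rank = {s: k for t in schema.templates for k, s in
                 enumerate(sp.name for sp in t.slots)}

    def omega(filler_with_index):
        filler, idx = filler_with_index
        return _earliest_position(filler, idx)

    def Omega(slot_name: str):
        return slot_rank[slot_name]

    return OrderingOperators(omega_key=omega, Omega_key=Omega)


def linearize(
    forest: InstanceForest,
    schema: SchemaConfig,
    ops: Optional[OrderingOperators] = None,
) -> list[str]:
    """Serialize a validated forest into a token sequence.

    Raises ``ValueError`` on forests the stack machine could not re-derive
    (cycles would not terminate; disconnected instances would be silently
    dropped, so both are rejected up front).
    """
    from .schema import validate_forest  # local import to avoid cycle at module load

    violations = validate_forest(forest, schema)
    if violations:
        raise ValueError(
            "forest is not linearizable: " + "; ".join(str(v) for v in violations)
        )
    if ops is None:
        ops = default_orderings(schema)

    out: list[str] = []

    def emit_instance(inst: TemplateInstance) -> None:
        tspec = schema.template(inst.type)
        out.append(start_token(inst.type))
        filled = sorted(inst.slots, key=ops.Omega_key)
        for slot_name in filled:
            fillers = inst.slots[slot_name]
            ordered = sorted(
                zip(fillers, range(len(fillers))), key=ops.omega_key
            )
            sspec = tspec.slot(slot_name)
            for filler, _ in ordered:
                out.append(start_token(slot_name))
                if isinstance(filler, TemplateInstance):
                    emit_instance(filler)
                elif isinstance(filler, TextSpan):
                    out.extend(
                        tok.surface
                        for tok in _doc_tokens_for(forest, filler, sspec)
                    )
                else:  # FreeText
                    out.extend(filler.text.split())
                out.append(end_token(slot_name))
        out.append(end_token(inst.type))

    emit_instance(forest.root_instance)
    return out


def _doc_tokens_for(forest: InstanceForest, span: TextSpan, sspec: SlotSpec):
    doc = getattr(forest, "_doc", None)
    if doc is not None:
        return doc.tokens[span.token_start: span.token_end + 1]

    # fall back to whitespace splitting of the covered string
    @dataclass
    class _Tok:
        surface: str

    return [_Tok(s) for s in span.text.split()]


def attach_document(forest: InstanceForest, doc: TokenizedDocument) -> InstanceForest:
    """Associate the source document so textual fillers emit exact tokens."""
    forest._doc = doc  # type: ignore[attr-defined]
    return forest


# ---------------------------------------------------------------------------
# Stack machine: allowed-next-token sets, recognition, parsing
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    def __init__(self, position: int, token, expected: set[str]):
        self.position = position
        self.token = token
        self.expected = expected
        shown = ", ".join(sorted(expected)[:8])
        super().__init__(
            f"position {position}: unexpected {token!r}; expected one of "
            f"{{{shown}{', ...' if len(expected) > 8 else ''}}}"
        )


@dataclass
class _Frame:
    kind: str  # "template" | "tslot" | "cslot"
    name: str
    child_done: bool = False  # cslot only
    spec: Optional[SlotSpec] = None


class GrammarCursor:
    """Incremental recognizer for the right-linear CFG.

    Tracks the decoding stack: ``[start:X]`` pushes a frame, the matching
    ``[end:X]`` pops it.  :meth:`allowed` returns the exact set of tokens
    that keep the prefix derivable (``TEXT`` standing for any document
    token); :meth:`advance` consumes one token.
    """

    def __init__(self, grammar: Grammar):
        self.grammar = grammar
        self.schema = grammar.schema
        self.stack: list[_Frame] = []
        self.started = False
        self.done = False

    @property
    def depth(self) -> int:
        return len(self.stack)

    def allowed(self) -> set[str]:
        """Allowed next tokens; ``TEXT`` denotes any input-document token."""
        if self.done:
            return set()
        if not self.started:
            return {start_token(self.schema.root)}
        top = self.stack[-1]
        if top.kind == "template":
            tspec = self.schema.template(top.name)
            return {start_token(s.name) for s in tspec.slots} | {end_token(top.name)}
        if top.kind == "tslot":
            return {TEXT, end_token(top.name)}
        # cslot
        if not top.child_done:
            return {start_token(top.spec.child_template)}
        return {end_token(top.name)}

    def allowed_surface(self, doc_tokens: Iterable[str]) -> set[str]:
        """Allowed set with ``TEXT`` expanded to the document's token types."""
        allowed = self.allowed()
        if TEXT in allowed:
            allowed = (allowed - {TEXT}) | set(doc_tokens)
        return allowed

    def advance(self, token: str, is_doc_token: bool = False) -> None:
        allowed = self.allowed()
        if token in allowed:
            self._apply_special_or_text(token)
            return
        if TEXT in allowed and (is_doc_token or not _is_special(token)):
            return  # document token inside an open textual slot: stay
        raise ParseError(-1, token, allowed)

    def _apply_special_or_text(self, token: str) -> None:
        if token == TEXT:
            return
        name = _special_name(token)
        if token.startswith("[start:"):
            if not self.started:
                self.started = True
                self.stack.append(_Frame("template", name))
                return
            top = self.stack[-1]
            if top.kind == "template":
                sspec = self.schema.template(top.name).slot(name)
                if sspec.kind == "textual":
                    self.stack.append(_Frame("tslot", name, spec=sspec))
                else:
                    self.stack.append(_Frame("cslot", name, spec=sspec))
            else:  # cslot awaiting its child template
                self.stack.append(_Frame("template", name))
        else:  # end token
            self.stack.pop()
            if not self.stack:
                self.done = True
            elif self.stack[-1].kind == "cslot" and not self.stack[-1].child_done:
                self.stack[-1].child_done = True


def _is_special(token: str) -> bool:
    return (token.startswith("[start:") or token.startswith("[end:")) and token.endswith("]")


def _special_name(token: str) -> str:
    return token[token.index(":") + 1: -1]


def validate_sequence(
    tokens: Sequence[str], grammar: Grammar, doc: Optional[TokenizedDocument] = None
) -> bool:
    """True iff ``tokens`` is derivable from the grammar's start symbol.

    If ``doc`` is given, tokens inside textual slots must additionally be
    token types occurring in the document.
    """
    doc_types = set(doc.surfaces()) if doc is not None else None
    cursor = GrammarCursor(grammar)
    for tok in tokens:
        allowed = cursor.allowed()
        if tok in allowed:
            cursor._apply_special_or_text(tok)
        elif TEXT in allowed and not _is_special(tok):
            if doc_types is not None and tok not in doc_types:
                return False
        else:
            return False
    return cursor.done


def parse(
    tokens: Sequence[str],
    grammar: Grammar,
    doc: TokenizedDocument,
    allow_truncated: bool = False,
) -> InstanceForest:
    """Parse a derivable token sequence back into an instance forest.

    Textual fillers are matched back to document spans by leftmost
    contiguous-surface match; unmatched text is kept as :class:`FreeText`
    with the hallucination flag set.  With ``allow_truncated``, a sequence
    that ends mid-derivation has its open frames auto-closed.
    """
    schema = grammar.schema
    cursor = GrammarCursor(grammar)
    instances: list[TemplateInstance] = []
    inst_stack: list[TemplateInstance] = []
    slot_stack: list[str] = []
    text_buf: list[str] = []
    counter = [0]

    def new_instance(type_name: str) -> TemplateInstance:
        counter[0] += 1
        inst = TemplateInstance(instance_id=f"{doc.doc_id}#{counter[0]}", type=type_name)
        instances.append(inst)
        return inst

    def close_textual(slot_name: str) -> None:
        surfaces = list(text_buf)
        text_buf.clear()
        if not surfaces:
            return
        filler = _match_back(doc, surfaces)
        inst_stack[-1].add(slot_name, filler)

    def step(tok: str, pos: int) -> None:
        allowed = cursor.allowed()
        if tok in allowed:
            top = cursor.stack[-1] if cursor.stack else None
            if tok.startswith("[start:"):
                name = _special_name(tok)
                if top is None or (top.kind == "cslot" and not top.child_done) or not cursor.started:
                    # template start (root or child)
                    inst = new_instance(name)
                    if inst_stack:
                        inst_stack[-1].add(slot_stack[-1], inst)
                    inst_stack.append(inst)
                elif top.kind == "template":
                    slot_stack.append(name)
            else:
                name = _special_name(tok)
                if top.kind == "tslot":
                    close_textual(name)
                    slot_stack.pop()
                elif top.kind == "cslot":
                    slot_stack.pop()
                else:  # template end
                    inst_stack.pop()
            cursor._apply_special_or_text(tok)
        elif TEXT in allowed and not _is_special(tok):
            text_buf.append(tok)
        else:
            raise ParseError(pos, tok, cursor.allowed())

    for pos, tok in enumerate(tokens):
        step(tok, pos)

    if not cursor.done:
        if not allow_truncated:
            raise ParseError(len(tokens), "<end-of-input>", cursor.allowed())
        while cursor.stack:
            step(end_token(cursor.stack[-1].name), len(tokens))

    if not instances:
        raise ParseError(0, "<empty>", {start_token(schema.root)})
    return InstanceForest(
        doc_id=doc.doc_id, instances=instances, root=instances[0].instance_id
    )


def _match_back(doc: TokenizedDocument, surfaces: list[str]):
    """Leftmost contiguous token-surface match; FreeText when absent."""
    n = len(surfaces)
    toks = doc.surfaces()
    for i in range(len(toks) - n + 1):
        if toks[i: i + n] == surfaces:
            return span_from_tokens(doc, i, i + n - 1)
    return FreeText(doc_id=doc.doc_id, text=" ".join(surfaces))
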