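"""Constrained decoding: allowed-token sets, masked greedy search, guarantees."""

import itertools

import numpy as np
import pytest

from picostruct.corpus import tokenize_document
from picostruct.decoding import (
    allowed_next_tokens,
    constrained_decode,
    decode_document,
)
from picostruct.grammar import GrammarCursor, build_grammar, linearize
from picostruct.schema import load_schema, validate_forest
from picostruct.synth import (
    FixtureConfig,
    TeacherProvider,
    UniformRandomProvider,
    generate_corpus,
)

TINY = load_schema({
    "root": "T",
    "templates": [
        {"name": "T", "slots": [{"name": "S", "kind": "textual"}]},
    ],
})


class TestAllowedNextTokens:
    def test_start_state_allows_only_root_start(self, grammar, small_corpus):
        doc, _ = small_corpus[0]
        cursor = GrammarCursor(grammar)
        assert allowed_next_tokens(cursor, doc) == {"[start:Publication]"}

    def test_open_textual_slot_allows_document_tokens_plus_end(self, grammar,
                                                               small_corpus):
        doc, _ = small_corpus[0]
        cursor = GrammarCursor(grammar)
        for tok in ["[start:Publication]", "[start:Title]"]:
            cursor.advance(tok)
        allowed = allowed_next_tokens(cursor, doc)
        assert allowed == set(doc.surfaces()) | {"[end:Title]"}

    def test_template_slot_start_forces_child_template(self, grammar,
                                                       small_corpus):
        doc, _ = small_corpus[0]
        cursor = GrammarCursor(grammar)
        for tok in ["[start:Publication]", "[start:describes]"]:
            cursor.advance(tok)
        assert allowed_next_tokens(cursor, doc) == {"[start:ClinicalTrial]"}

    def test_inside_template_frame_allows_slot_starts_and_end(self, grammar,
                                                              small_corpus):
        doc, _ = small_corpus[0]
        cursor = GrammarCursor(grammar)
        cursor.advance("[start:Publication]")
        allowed = allowed_next_tokens(cursor, doc)
        pub = grammar.schema.template("Publication")
        assert allowed == {f"[start:{s.name}]" for s in pub.slots} | {
            "[end:Publication]"
        }


def _enumerate_derivable(grammar, doc_types, max_len):
    """Independent brute-force enumeration of all derivable terminal
    sequences up to ``max_len``, by leftmost expansion of the production
    rules; TEXT expands to any sequence over the document token types."""
    rules_by_head = {}
    for r in grammar.rules:
        rules_by_head.setdefault(r.head, []).append(r)

    def is_nonterminal(sym):
        return sym == "TEXT" or sym in rules_by_head

    results = set()

    def expand(form):
        terminals = sum(1 for s in form if not is_nonterminal(s))
        if terminals > max_len:
            return
        idx = next((i for i, s in enumerate(form) if is_nonterminal(s)), None)
        if idx is None:
            results.add(form)
            return
        sym = form[idx]
        if sym == "TEXT":
            budget = max_len - terminals
            for k in range(budget + 1):
                for combo in itertools.product(doc_types, repeat=k):
                    expand(form[:idx] + combo + form[idx + 1:])
        else:
            for rule in rules_by_head[sym]:
                expand(form[:idx] + rule.rhs + form[idx + 1:])

    expand((grammar.start_symbol,))
    return results


class TestAllowedSetsMatchExhaustiveOracle:
    def test_tiny_schema_prefix_continuations(self):
        grammar = build_grammar(TINY)
        doc = tokenize_document("d", "aa bb")
        doc_types = tuple(sorted(set(doc.surfaces())))
        max_len = 8
        # enumerate a bit deeper so continuations at length-8 prefixes are
        # not clipped by the enumeration horizon (min completion length 2)
        sequences = _enumerate_derivable(grammar, doc_types, max_len + 4)
        continuations: dict[tuple, set] = {}
        for seq in sequences:
            for k in range(min(len(seq), max_len + 1)):
                continuations.setdefault(seq[:k], set()).add(seq[k])
        assert continuations  # oracle nonempty
        for prefix, allowed_oracle in continuations.items():
            cursor = GrammarCursor(grammar)
            for tok in prefix:
                cursor.advance(tok, is_doc_token=not tok.startswith("["))
            got = cursor.allowed_surface(doc_types)
            assert got == allowed_oracle, f"prefix {prefix}"


class TestConstrainedDecode:
    def test_teacher_provider_recovers_gold_sequence(self, schema, grammar,
                                                     small_corpus):
        for doc, forest in small_corpus[:5]:
            gold = linearize(forest, schema)
            provider = TeacherProvider(gold, grammar, doc, seed=3)
            result = constrained_decode(provider, grammar, doc)
            assert result.tokens == gold
            assert not result.truncated

    @pytest.mark.parametrize("seed", range(25))
    def test_adversarial_output_always_derivable(self, grammar, seed):
        from picostruct.grammar import validate_sequence

        corpus = generate_corpus(FixtureConfig(
            n_documents=1, seed=99,
            cardinalities={"Arm": (1, 1), "OutcomePerArm": (1, 1),
                           "DiffBetweenGroups": (1, 1),
                           "EvidenceQuality": (1, 1)},
        ))
        doc, _ = corpus[0]
        provider = UniformRandomProvider(grammar, doc, seed=seed)
        result = constrained_decode(provider, grammar, doc)
        assert validate_sequence(result.tokens, grammar, doc)

    def test_minimal_budget_truncates_with_flag(self, grammar, small_corpus):
        doc, _ = small_corpus[0]
        provider = UniformRandomProvider(grammar, doc, seed=0)
        result = constrained_decode(provider, grammar, doc, max_len=2)
        assert result.truncated
        assert result.tokens[0] == "[start:Publication]"

    def test_max_len_below_two_rejected(self, grammar, small_corpus):
        doc, _ = small_corpus[0]
        provider = UniformRandomProvider(grammar, doc, seed=0)
        with pytest.raises(ValueError):
            constrained_decode(provider, grammar, doc, max_len=1)

    def test_deterministic_given_provider_and_document(self, grammar,
                                                       small_corpus):
        doc, _ = small_corpus[1]
        a = constrained_decode(UniformRandomProvider(grammar, doc, seed=5),
                               grammar, doc)
        b = constrained_decode(UniformRandomProvider(grammar, doc, seed=5),
                               grammar, doc)
        assert a.tokens == b.tokens


class TestDecodeDocument:
    def test_teacher_decode_reproduces_gold_forest(self, schema, grammar,
                                                   small_corpus):
        from picostruct.evaluation import evaluate_corpus

        doc, forest = small_corpus[2]
        gold = linearize(forest, schema)
        provider = TeacherProvider(gold, grammar, doc, seed=1)
        decoded = decode_document(provider, grammar, doc)
        rep = evaluate_corpus([decoded], [forest], schema)
        assert rep.micro_f1 == 1.0
        assert all(v == 0.0 for v in rep.cardinality_mad.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_adversarial_decode_validates_against_schema(self, schema, grammar,
                                                         seed):
        corpus = generate_corpus(FixtureConfig(
            n_documents=1, seed=98,
            cardinalities={"Arm": (1, 1), "OutcomePerArm": (1, 1),
                           "DiffBetweenGroups": (1, 1),
                           "EvidenceQuality": (1, 1)},
        ))
        doc, _ = corpus[0]
        provider = UniformRandomProvider(grammar, doc, seed=seed)
        forest = decode_document(provider, grammar, doc)
        assert validate_forest(forest, schema) == []
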