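"""Linearization, the schema-derived CFG, parsing and derivability."""

import pytest

from picostruct.corpus import tokenize_document
from picostruct.grammar import (
    GrammarCursor,
    ParseError,
    attach_document,
    build_grammar,
    end_token,
    linearize,
    parse,
    start_token,
    validate_sequence,
)
from picostruct.schema import (
    InstanceForest,
    TemplateInstance,
    load_schema,
)
from picostruct.corpus import span_from_tokens


def _mini_schema(slots=("S",), template_slots=()):
    return load_schema({
        "root": "T",
        "templates": [
            {"name": "T", "slots": (
                [{"name": s, "kind": "textual"} for s in slots]
                + [{"name": n, "kind": "template", "child": c}
                   for n, c in template_slots]
            )},
        ] + [{"name": c, "slots": [{"name": f"{c}x", "kind": "textual"}]}
             for _, c in template_slots],
    })


class TestBuildGrammar:
    def test_one_template_one_textual_slot_instantiates_each_applicable_rule(self):
        g = build_grammar(_mini_schema())
        # head + terminator + one textual-slot rule; no template-valued
        # slots, so the fourth rule schema does not apply
        assert len(g.rules) == 3
        kinds = sorted(r.kind for r in g.rules)
        assert kinds == ["head", "terminator", "textual_slot"]

    def test_rule_count_formula_on_default_schema(self, schema, grammar):
        expected = sum(2 + len(t.slots) for t in schema.templates)
        assert len(grammar.rules) == expected

    def test_zero_slot_template_derives_only_empty_instance(self):
        schema = load_schema({
            "root": "T", "templates": [{"name": "T", "slots": []}]
        })
        g = build_grammar(schema)
        assert len(g.rules) == 2
        assert validate_sequence(["[start:T]", "[end:T]"], g)
        assert not validate_sequence(["[start:T]", "x", "[end:T]"], g)

    def test_start_symbol_is_root_head(self, grammar):
        assert grammar.start_symbol == "Publication_HEAD"


def _medication_forest():
    doc = tokenize_document("d", "patients received insulin daily")
    inst = TemplateInstance("m1", "Medication")
    inst.add("Drug", span_from_tokens(doc, 2, 2))
    forest = InstanceForest("d", [inst], "m1")
    return attach_document(forest, doc), doc


class TestLinearize:
    def test_single_drug_medication(self, schema):
        forest, _ = _medication_forest()
        # root type differs from schema root; use a medication-rooted schema
        med_schema = load_schema({
            "root": "Medication",
            "templates": [{
                "name": "Medication",
                "slots": [{"name": "Drug", "kind": "textual"},
                          {"name": "DoseValue", "kind": "textual"},
                          {"name": "DoseUnit", "kind": "textual"}],
            }],
        })
        toks = linearize(forest, med_schema)
        assert toks == ["[start:Medication]", "[start:Drug]", "insulin",
                        "[end:Drug]", "[end:Medication]"]

    def test_empty_instance(self):
        schema = load_schema({
            "root": "T", "templates": [{"name": "T", "slots": []}]
        })
        forest = InstanceForest("d", [TemplateInstance("a", "T")], "a")
        assert linearize(forest, schema) == ["[start:T]", "[end:T]"]

    def test_fillers_ordered_by_document_position(self):
        schema = _mini_schema()
        doc = tokenize_document("d", "alpha beta gamma delta")
        inst = TemplateInstance("a", "T")
        inst.add("S", span_from_tokens(doc, 2, 2))  # gamma (later position)
        inst.add("S", span_from_tokens(doc, 0, 0))  # alpha (earlier)
        forest = attach_document(InstanceForest("d", [inst], "a"), doc)
        toks = linearize(forest, schema)
        assert toks == ["[start:T]", "[start:S]", "alpha", "[end:S]",
                        "[start:S]", "gamma", "[end:S]", "[end:T]"]

    def test_invalid_forest_rejected(self, schema):
        a = TemplateInstance("a", "Publication")
        b = TemplateInstance("b", "Outcome")  # disconnected
        forest = InstanceForest("d", [a, b], "a")
        with pytest.raises(ValueError, match="not linearizable"):
            linearize(forest, schema)


class TestParse:
    def test_parse_inverts_linearize_on_fixtures(self, schema, grammar,
                                                 small_corpus):
        for doc, forest in small_corpus:
            toks = linearize(forest, schema)
            back = parse(toks, grammar, doc)
            assert linearize(back, schema) == toks

    def test_gold_spans_recovered_exactly(self, schema, grammar, small_corpus):
        doc, forest = small_corpus[0]
        back = parse(linearize(forest, schema), grammar, doc)
        gold = {(s, f.char_start, f.char_end)
                for s, f in forest.all_textual_fillers()}
        got = {(s, f.char_start, f.char_end)
               for s, f in back.all_textual_fillers()}
        assert got == gold

    def test_missing_end_token_is_a_parse_error(self, grammar, small_corpus):
        doc, forest = small_corpus[0]
        toks = linearize(forest, grammar.schema)[:-1]
        with pytest.raises(ParseError, match="end-of-input"):
            parse(toks, grammar, doc)

    def test_error_reports_position_and_expectations(self, grammar,
                                                     small_corpus):
        doc, _ = small_corpus[0]
        with pytest.raises(ParseError) as exc:
            parse(["[start:Outcome]"], grammar, doc)
        assert exc.value.position == 0
        assert "[start:Publication]" in exc.value.expected

    def test_hallucinated_text_kept_and_flagged(self):
        from picostruct.schema import FreeText

        schema = _mini_schema()
        g = build_grammar(schema)
        doc = tokenize_document("d", "alpha beta")
        toks = ["[start:T]", "[start:S]", "zebra", "[end:S]", "[end:T]"]
        forest = parse(toks, g, doc)
        fillers = forest.root_instance.fillers("S")
        assert len(fillers) == 1 and isinstance(fillers[0], FreeText)
        assert fillers[0].hallucinated and fillers[0].text == "zebra"


class TestValidateSequence:
    def test_empty_publication_is_derivable(self, grammar):
        assert validate_sequence(["[start:Publication]", "[end:Publication]"],
                                 grammar)

    def test_unbalanced_specials_rejected(self, grammar):
        assert not validate_sequence(["[start:Publication]"], grammar)
        assert not validate_sequence(
            ["[start:Publication]", "[end:Outcome]"], grammar
        )

    def test_document_restriction(self, grammar, small_corpus):
        doc, forest = small_corpus[0]
        toks = linearize(forest, grammar.schema)
        assert validate_sequence(toks, grammar, doc)
        other = tokenize_document("o", "completely different words")
        assert not validate_sequence(toks, grammar, other)


class TestStackDepth:
    def test_nesting_depth_bounded_by_containment_depth(self, schema, grammar,
                                                        small_corpus):
        bound = 2 * schema.containment_depth()
        for doc, forest in small_corpus:
            cursor = GrammarCursor(grammar)
            max_depth = 0
            for tok in linearize(forest, schema):
                cursor.advance(tok, is_doc_token=not tok.startswith("["))
                max_depth = max(max_depth, cursor.depth)
            assert max_depth <= bound


class TestSpecialTokens:
    def test_surface_forms(self):
        assert start_token("Drug") == "[start:Drug]"
        assert end_token("Drug") == "[end:Drug]"

    def test_special_inventory_covers_templates_and_slots(self, schema,
                                                          grammar):
        specials = set(grammar.special_tokens)
        for t in schema.templates:
            assert start_token(t.name) in specials
            assert end_token(t.name) in specials
            for s in t.slots:
                assert start_token(s.name) in specials
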