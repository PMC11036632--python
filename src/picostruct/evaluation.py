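"""Scoring predicted instance forests against gold.

Slot F1: each forest is reduced to its multiset of (slot, filler-string)
pairs, strings whitespace-normalized; predicted and gold fillers of one slot
are matched greedily one-to-one by exact string equality.  Micro F1 pools
TP/FP/FN over all slots; per-template mean F1 averages the per-slot F1 of the
template's textual slots.  An optional strict mode first aligns instances per
template (greedy, by filler overlap) and only scores fillers within aligned
instance pairs — stricter because a filler in the wrong instance then counts
as both a false positive and a false negative.

Template-cardinality error is the mean absolute deviation, over documents,
between the predicted and gold number of instances per template type;
templates whose cardinality is fixed at one per document (Publication,
ClinicalTrial, Population in the default schema) are excluded.

The absolute F1 numbers depend on the matching criterion; scores computed
under different criteria are not comparable, and reports carry the criterion
id for that reason.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .schema import InstanceForest, SchemaConfig, TemplateInstance

__all__ = [
    "SlotMatch",
    "EvalReport",
    "normalize",
    "match_fillers",
    "slot_f1",
    "evaluate_corpus",
    "cardinality_mad",
]


def normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


@dataclass(frozen=True)
class SlotMatch:
    slot: str
    gold: str | None  # normalized gold filler string, None for spurious pred
    pred: str | None  # None for missed gold filler
    criterion: str = "string"

    @property
    def is_tp(self) -> bool:
        return self.gold is not None and self.pred is not None


@dataclass
class EvalReport:
    criterion: str
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)  # slot -> (tp, fp, fn)
    micro_f1: float = 0.0
    micro_precision: float = 0.0
    micro_recall: float = 0.0
    per_slot_f1: dict[str, float] = field(default_factory=dict)
    per_template_f1: dict[str, float] = field(default_factory=dict)
    cardinality_mad: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "micro_f1": self.micro_f1,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "per_slot_f1": self.per_slot_f1,
            "per_template_f1": self.per_template_f1,
            "cardinality_mad": self.cardinality_mad,
            "counts": {k: list(v) for k, v in self.counts.items()},
        }


def _f1(tp: int, fp: int, fn: int) -> float:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def _slot_strings(forest: InstanceForest) -> dict[str, Counter]:
    """slot name -> multiset of normalized filler strings (textual only)."""
    out: dict[str, Counter] = {}
    for inst in forest.instances:
        for slot, f in inst.textual_fillers():
            out.setdefault(slot, Counter())[normalize(f.text)] += 1
    return out


def match_fillers(
    pred: InstanceForest, gold: InstanceForest, criterion: str = "string"
) -> list[SlotMatch]:
    """Greedy one-to-one matching of predicted against gold fillers per slot.

    ``criterion="string"`` (default) matches instance-agnostically on
    (slot, normalized string); ``criterion="strict"`` aligns instances per
    template first and matches only within aligned pairs.
    """
    if criterion == "string":
        return _match_string(pred, gold)
    if criterion == "strict":
        return _match_strict(pred, gold)
    raise ValueError(f"unknown matching criterion {criterion!r}")


def _match_counters(
    slot: str, pred: Counter, gold: Counter, criterion: str
) -> list[SlotMatch]:
    matches: list[SlotMatch] = []
    for text in sorted(set(pred) | set(gold)):
        tp = min(pred[text], gold[text])
        matches += [SlotMatch(slot, text, text, criterion)] * tp
        matches += [SlotMatch(slot, None, text, criterion)] * (pred[text] - tp)
        matches += [SlotMatch(slot, text, None, criterion)] * (gold[text] - tp)
    return matches


def _match_string(pred: InstanceForest, gold: InstanceForest) -> list[SlotMatch]:
    ps, gs = _slot_strings(pred), _slot_strings(gold)
    matches: list[SlotMatch] = []
    for slot in sorted(set(ps) | set(gs)):
        matches += _match_counters(
            slot, ps.get(slot, Counter()), gs.get(slot, Counter()), "string"
        )
    return matches


def _instance_strings(inst: TemplateInstance) -> dict[str, Counter]:
    out: dict[str, Counter] = {}
    for slot, f in inst.textual_fillers():
        out.setdefault(slot, Counter())[normalize(f.text)] += 1
    return out


def _match_strict(pred: InstanceForest, gold: InstanceForest) -> list[SlotMatch]:
    matches: list[SlotMatch] = []
    templates = {i.type for i in pred.instances} | {i.type for i in gold.instances}
    for template in sorted(templates):
        pinsts = [(_instance_strings(i), i) for i in pred.of_type(template)]
        ginsts = [(_instance_strings(i), i) for i in gold.of_type(template)]
        # greedy alignment by overlap count, largest first
        overlaps = []
        for pi, (pstr, _) in enumerate(pinsts):
            for gi, (gstr, _) in enumerate(ginsts):
                ov = sum(
                    (pstr.get(s, Counter()) & gstr.get(s, Counter())).total()
                    for s in set(pstr) | set(gstr)
                )
                overlaps.append((-ov, pi, gi))
        overlaps.sort()
        used_p: set[int] = set()
        used_g: set[int] = set()
        pairs: list[tuple[int, int]] = []
        for neg_ov, pi, gi in overlaps:
            if pi in used_p or gi in used_g:
                continue
            used_p.add(pi)
            used_g.add(gi)
            pairs.append((pi, gi))
        for pi, gi in pairs:
            pstr, gstr = pinsts[pi][0], ginsts[gi][0]
            for slot in sorted(set(pstr) | set(gstr)):
                matches += _match_counters(
                    slot, pstr.get(slot, Counter()), gstr.get(slot, Counter()),
                    "strict",
                )
        for pi, (pstr, _) in enumerate(pinsts):
            if pi not in used_p:
                for slot, ctr in pstr.items():
                    matches += [SlotMatch(slot, None, t, "strict")
                                for t, c in ctr.items() for _ in range(c)]
        for gi, (gstr, _) in enumerate(ginsts):
            if gi not in used_g:
                for slot, ctr in gstr.items():
                    matches += [SlotMatch(slot, t, None, "strict")
                                for t, c in ctr.items() for _ in range(c)]
    return matches


def slot_f1(
    matches: list[SlotMatch],
    schema: SchemaConfig | None = None,
    criterion: str = "string",
) -> EvalReport:
    """Aggregate matches into micro, per-slot and per-template-mean F1."""
    counts: dict[str, list[int]] = {}
    for m in matches:
        tp, fp, fn = counts.setdefault(m.slot, [0, 0, 0])
        if m.is_tp:
            counts[m.slot][0] += 1
        elif m.pred is not None:
            counts[m.slot][1] += 1
        else:
            counts[m.slot][2] += 1
    report = EvalReport(criterion=criterion)
    report.counts = {k: tuple(v) for k, v in counts.items()}
    TP = sum(v[0] for v in counts.values())
    FP = sum(v[1] for v in counts.values())
    FN = sum(v[2] for v in counts.values())
    report.micro_precision = TP / (TP + FP) if TP + FP else 0.0
    report.micro_recall = TP / (TP + FN) if TP + FN else 0.0
    report.micro_f1 = _f1(TP, FP, FN)
    report.per_slot_f1 = {s: _f1(*v) for s, v in counts.items()}
    if schema is not None:
        for t in schema.templates:
            slots = [s.name for s in t.textual_slots if s.name in counts]
            if slots:
                report.per_template_f1[t.name] = sum(
                    report.per_slot_f1[s] for s in slots
                ) / len(slots)
    return report


def evaluate_corpus(
    pred_forests: list[InstanceForest],
    gold_forests: list[InstanceForest],
    schema: SchemaConfig | None = None,
    criterion: str = "string",
) -> EvalReport:
    """Match and score aligned corpora (by document order; doc_ids checked)."""
    if len(pred_forests) != len(gold_forests):
        raise ValueError("pred/gold corpora differ in length")
    matches: list[SlotMatch] = []
    for p, g in zip(pred_forests, gold_forests):
        if p.doc_id != g.doc_id:
            raise ValueError(f"misaligned corpora: {p.doc_id} vs {g.doc_id}")
        matches += match_fillers(p, g, criterion)
    report = slot_f1(matches, schema, criterion)
    if schema is not None:
        excluded = {
            t.name for t in schema.templates if t.fixed_cardinality is not None
        }
        for t in schema.templates:
            if t.name in excluded:
                continue
            report.cardinality_mad[t.name] = cardinality_mad(
                pred_forests, gold_forests, t.name
            )
    return report


def cardinality_mad(
    pred_forests: list[InstanceForest],
    gold_forests: list[InstanceForest],
    template: str,
) -> float:
    """Mean over documents of |#predicted − #gold| instances of ``template``."""
    if len(pred_forests) != len(gold_forests):
        raise ValueError("pred/gold corpora differ in length")
    devs = []
    for p, g in zip(pred_forests, gold_forests):
        if p.doc_id != g.doc_id:
            raise ValueError(f"misaligned corpora: {p.doc_id} vs {g.doc_id}")
        devs.append(abs(len(p.of_type(template)) - len(g.of_type(template))))
    return sum(devs) / len(devs) if devs else 0.0
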