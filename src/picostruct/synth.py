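"""Seeded synthetic corpus of RCT-like abstracts with gold instance forests.

Each document is a short multi-sentence pseudo-abstract: slot fillers drawn
from per-slot vocabulary pools are embedded verbatim into templated sentences
(one sentence per template instance, so fillers of one instance are close
together while fillers of different instances sit in different sentences).
The gold forest is a single-Publication-rooted tree whose per-template
instance counts are drawn from configured cardinality ranges.

Pool construction guarantees: no token type is shared between the pools of
two different slots, scaffold words never collide with pool tokens, and
fillers are sampled without replacement per slot per document — so every
gold filler string occurs exactly once in its document, string-match
evaluation is unambiguous, and leftmost span matching on parse is exact.
These are fixture conveniences, not properties of real abstracts.

The module also provides the two test oracles: a gold-indicator
compatibility function (1 iff two fillers share a gold instance) and a
teacher logit provider that scores the gold linearization's next token
highest at every gold prefix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import TokenizedDocument, span_from_chars, tokenize_document
from .extractive import FillerRepr, QFunc
from .grammar import Grammar, attach_document
from .schema import (
    InstanceForest,
    SchemaConfig,
    TemplateInstance,
    TextSpan,
    default_schema,
)

__all__ = [
    "FixtureConfig",
    "generate_corpus",
    "oracle_similarity",
    "TeacherProvider",
    "UniformRandomProvider",
    "DEFAULT_POOLS",
]

# Per-slot filler pools.  Token-disjoint across slots by construction (checked
# at import time below).
DEFAULT_POOLS: dict[str, list[str]] = {
    "Title": [
        "Glycemora Outcomes Trial", "Ocustat Vision Study",
        "Renalta Protection Trial", "Cardiomet Prevention Study",
        "Glaucoril Progression Trial", "Pressura Control Study",
    ],
    "Authors": [
        "Smith et al", "Tanaka et al", "Mueller et al", "Garcia et al",
        "Olsen et al", "Kowalski et al",
    ],
    "Journal": ["Diabetologia", "Ophthalmology", "Lancet", "BMJ", "JAMA"],
    "PMID": [
        "31847265", "29453811", "33120947", "27586320", "30917442",
        "32594186", "28731900", "34205577",
    ],
    "PublicationYear": ["2014", "2015", "2016", "2017", "2018", "2019", "2020"],
    "NumberPatientsCT": ["412", "438", "451", "467", "483", "495"],
    "CTDesign": [
        "double blind", "open label", "placebo controlled",
        "crossover design", "parallel group",
    ],
    "CTDuration": [
        "sixteen weeks", "twenty weeks", "thirty weeks", "forty weeks",
        "fifty weeks",
    ],
    "Country": ["USA", "Australia", "Germany", "Japan", "Canada", "Brazil",
                "Norway", "India"],
    "Ethnicity": ["Caucasian", "Hispanic", "Asian", "African"],
    "Precondition": [
        "uncontrolled hyperglycemia", "refractory ocular hypertension",
        "insulin resistance", "prior laser treatment",
        "persistent macular edema",
    ],
    "FinalNumPatientsArm": ["201", "214", "226", "239", "247", "258"],
    "Frequency": [
        "once daily", "twice daily", "thrice daily", "every morning",
        "every evening", "weekly",
    ],
    "Drug": [
        "glargitol", "ocuvex", "latanoprost", "metforalin", "timogard",
        "insuletra", "brimozan", "dorzevia",
    ],
    "DoseValue": ["110", "120", "135", "150", "165", "180"],
    "DoseUnit": ["mg", "mcg", "IU", "mL"],
    "PercentageAffected": ["16", "19", "23", "26", "31", "34", "41", "47",
                           "52", "58"],
    "NumberAffected": ["61", "67", "73", "78", "84", "89", "92", "97"],
    "TimePoint": ["week twelve", "week twentyfour", "month six", "day ninety",
                  "year one"],
    "ObservedResult": [
        "improved significantly", "stable course", "worsened slightly",
        "marked reduction", "modest increase",
    ],
    "EndpointDescription": [
        "fasting plasma glucose", "intraocular pressure",
        "glycated hemoglobin", "visual acuity", "body mass",
    ],
    "AggregationMethod": ["adjusted mean", "median shift", "final average",
                          "normalised slope"],
    "MeasurementDevice": [
        "goldmann tonometer", "automated perimeter", "hplc assay",
        "digital scale",
    ],
    "DiffGroupAbsValue": ["0.42", "0.57", "0.63", "0.71", "0.88", "0.95"],
    "PValueChangeValue": ["0.013", "0.001", "0.024", "0.038", "0.045"],
    "Randomization": [
        "computer generated allocation", "sealed envelopes",
        "block randomisation", "stratified allocation",
    ],
    "Blinding": ["masked assessors", "unmasked", "partial masking",
                 "full masking"],
}


def _pool_tokens(pool: list[str]) -> set[str]:
    return {tok for entry in pool for tok in entry.split()}


def _check_disjoint(pools: dict[str, list[str]]) -> None:
    seen: dict[str, str] = {}
    for slot, pool in pools.items():
        for tok in _pool_tokens(pool):
            if tok in seen and seen[tok] != slot:
                raise ValueError(
                    f"token {tok!r} shared by slot pools {seen[tok]!r} and {slot!r}"
                )
            seen[tok] = slot


_check_disjoint(DEFAULT_POOLS)


@dataclass
class FixtureConfig:
    """Generator settings.

    Cardinality ranges are inclusive (lo, hi) per-document instance counts;
    fixed-cardinality templates are pinned to one.  ``endpoint_prob`` /
    ``optional_slot_prob`` control how often optional structure appears.
    """

    n_documents: int = 10
    seed: int = 0
    cardinalities: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "Arm": (2, 2),
            "OutcomePerArm": (1, 2),
            "DiffBetweenGroups": (1, 2),
            "EvidenceQuality": (1, 1),
        }
    )
    pools: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_POOLS))
    endpoint_prob: float = 0.7
    optional_slot_prob: float = 0.8
    tokenizer: str = "regex"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        _check_disjoint(self.pools)
        for name, (lo, hi) in self.cardinalities.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"bad cardinality range for {name}: ({lo}, {hi})")


class _DocSampler:
    """Samples pool entries without replacement within one document."""

    def __init__(self, pools: dict[str, list[str]], rng: np.random.Generator):
        self.rng = rng
        self.remaining = {slot: list(pool) for slot, pool in pools.items()}

    def take(self, slot: str) -> str:
        pool = self.remaining[slot]
        if not pool:
            raise ValueError(f"vocabulary pool for slot {slot!r} exhausted")
        idx = int(self.rng.integers(len(pool)))
        return pool.pop(idx)


def generate_corpus(
    config: FixtureConfig, schema: Optional[SchemaConfig] = None
) -> list[tuple[TokenizedDocument, InstanceForest]]:
    """Generate ``config.n_documents`` (document, gold forest) pairs.

    Deterministic given the seed.  Every gold textual filler occurs verbatim
    at its recorded character span; all forests are single-rooted trees that
    pass forest validation.
    """
    if schema is None:
        schema = default_schema()
    rng = np.random.default_rng(config.seed)
    return [
        _generate_document(f"synth{config.seed}-{k:04d}", config, schema, rng)
        for k in range(config.n_documents)
    ]


def _generate_document(
    doc_id: str,
    config: FixtureConfig,
    schema: SchemaConfig,
    rng: np.random.Generator,
) -> tuple[TokenizedDocument, InstanceForest]:
    sampler = _DocSampler(config.pools, rng)
    card = config.cardinalities
    counter = [0]
    instances: list[TemplateInstance] = []
    pieces: list[str] = []  # text built left to right
    pending: list[tuple[TemplateInstance, str, int, int]] = []  # char spans

    def make(type_name: str) -> TemplateInstance:
        counter[0] += 1
        inst = TemplateInstance(instance_id=f"{doc_id}#{counter[0]}", type=type_name)
        instances.append(inst)
        return inst

    cursor = [0]

    def emit(text: str) -> None:
        pieces.append(text)
        cursor[0] += len(text)

    def fill(inst: TemplateInstance, slot: str) -> None:
        value = sampler.take(slot)
        start = cursor[0]
        emit(value)
        pending.append((inst, slot, start, start + len(value)))

    def rand_in(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    def coin(p: float) -> bool:
        return bool(rng.random() < p)

    pub = make("Publication")
    trial = make("ClinicalTrial")
    pub.add("describes", trial)

    # sentence 1: publication
    fill(pub, "Title"); emit(" was reported by ")
    fill(pub, "Authors"); emit(" in ")
    fill(pub, "Journal"); emit(" ( pmid ")
    fill(pub, "PMID"); emit(" , ")
    fill(pub, "PublicationYear"); emit(" ) . ")

    # sentence 2: trial design
    emit("This "); fill(trial, "CTDesign"); emit(" trial enrolled ")
    fill(trial, "NumberPatientsCT"); emit(" patients and ran for ")
    fill(trial, "CTDuration"); emit(" . ")

    # sentence 3: population
    pop = make("Population")
    trial.add("hasPopulation", pop)
    emit("Participants were "); fill(pop, "Ethnicity"); emit(" adults from ")
    fill(pop, "Country")
    if coin(0.4):
        emit(" and "); fill(pop, "Country")
    emit(" with "); fill(pop, "Precondition")
    if coin(0.3):
        emit(" and "); fill(pop, "Precondition")
    emit(" . ")

    # arms with interventions, medications and outcomes
    n_arms = rand_in(*card.get("Arm", (2, 2)))
    force_endpoint = True  # at least one Endpoint instance per document
    for _ in range(n_arms):
        arm = make("Arm")
        trial.add("hasArm", arm)
        intervention = make("Intervention")
        arm.add("hasIntervention", intervention)
        medication = make("Medication")
        intervention.add("hasMedication", medication)
        emit("One group received ")
        fill(medication, "Drug"); emit(" ")
        fill(medication, "DoseValue"); emit(" ")
        fill(medication, "DoseUnit"); emit(" ")
        fill(intervention, "Frequency"); emit(" , comprising ")
        fill(arm, "FinalNumPatientsArm"); emit(" subjects . ")

        for _ in range(rand_in(*card.get("OutcomePerArm", (1, 2)))):
            outcome = make("Outcome")
            arm.add("hasOutcome", outcome)
            fill(outcome, "PercentageAffected")
            emit(" percent achieved the endpoint at ")
            fill(outcome, "TimePoint")
            if coin(config.optional_slot_prob):
                emit(" , with "); fill(outcome, "NumberAffected")
                emit(" responders showing "); fill(outcome, "ObservedResult")
            if force_endpoint or coin(config.endpoint_prob):
                force_endpoint = False
                endpoint = make("Endpoint")
                outcome.add("hasEndpoint", endpoint)
                emit(" , assessed on "); fill(endpoint, "EndpointDescription")
                if coin(config.optional_slot_prob):
                    emit(" measured as "); fill(endpoint, "AggregationMethod")
                if coin(config.optional_slot_prob):
                    emit(" using "); fill(endpoint, "MeasurementDevice")
            emit(" . ")

    # between-group differences
    for _ in range(rand_in(*card.get("DiffBetweenGroups", (1, 2)))):
        diff = make("DiffBetweenGroups")
        trial.add("hasDiffBetweenGroups", diff)
        emit("Between groups the gap was "); fill(diff, "DiffGroupAbsValue")
        emit(" with significance "); fill(diff, "PValueChangeValue"); emit(" . ")

    # evidence quality
    for _ in range(rand_in(*card.get("EvidenceQuality", (1, 1)))):
        ev = make("EvidenceQuality")
        trial.add("hasEvidenceQuality", ev)
        emit("Allocation used "); fill(ev, "Randomization")
        emit(" and "); fill(ev, "Blinding"); emit(" . ")

    text = "".join(pieces).rstrip()
    doc = tokenize_document(doc_id, text, tokenizer=config.tokenizer)
    for inst, slot, cs, ce in pending:
        inst.add(slot, span_from_chars(doc, cs, ce))
    forest = InstanceForest(doc_id=doc_id, instances=instances,
                            root=pub.instance_id)
    attach_document(forest, doc)
    return doc, forest


# ---------------------------------------------------------------------------
# Test oracles
# ---------------------------------------------------------------------------

def oracle_similarity(gold: InstanceForest) -> QFunc:
    """Gold-indicator compatibility: 1 iff two fillers share a gold instance.

    Fillers are identified by (slot, char_start, char_end); unknown fillers
    raise ``KeyError``.
    """
    owner: dict[tuple[str, int, int], str] = {}
    for inst in gold.instances:
        for slot, f in inst.textual_fillers():
            if isinstance(f, TextSpan):
                owner[(slot, f.char_start, f.char_end)] = inst.instance_id

    def key(f: FillerRepr) -> tuple[str, int, int]:
        return (f.slot, f.span.char_start, f.span.char_end)

    def q(a: FillerRepr, b: FillerRepr) -> float:
        return 1.0 if owner[key(a)] == owner[key(b)] else 0.0

    return q


def _prefix_rng(seed: int, doc_id: str, prefix: Sequence[str]) -> np.random.Generator:
    digest = hashlib.blake2b(
        ("\x1f".join([str(seed), doc_id, *prefix])).encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


class TeacherProvider:
    """Logit provider that scores the gold linearization's next token highest
    on every prefix of the gold sequence; seeded-random (but deterministic)
    scores in (0, 1) elsewhere."""

    def __init__(self, gold_tokens: Sequence[str], grammar: Grammar,
                 doc: TokenizedDocument, seed: int = 0):
        self.gold = list(gold_tokens)
        self.seed = seed
        vocab = sorted(set(self.gold) | set(grammar.special_tokens)
                       | set(doc.surfaces()))
        self.vocabulary = vocab
        self._index = {t: i for i, t in enumerate(vocab)}

    def next_scores(self, doc: TokenizedDocument, prefix: Sequence[str]) -> np.ndarray:
        rng = _prefix_rng(self.seed, doc.doc_id, prefix)
        scores = rng.random(len(self.vocabulary))  # in [0, 1)
        t = len(prefix)
        if t < len(self.gold) and list(prefix) == self.gold[:t]:
            scores[self._index[self.gold[t]]] = 2.0
        return scores


class UniformRandomProvider:
    """Adversarial provider: i.i.d. uniform scores, deterministic per
    (seed, document, prefix)."""

    def __init__(self, grammar: Grammar, doc: TokenizedDocument, seed: int = 0):
        self.seed = seed
        self.vocabulary = sorted(set(grammar.special_tokens) | set(doc.surfaces()))

    def next_scores(self, doc: TokenizedDocument, prefix: Sequence[str]) -> np.ndarray:
        rng = _prefix_rng(self.seed, doc.doc_id, prefix)
        return rng.random(len(self.vocabulary))
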