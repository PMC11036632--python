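"""Declarative data model for PICO template schemas and instance forests.

A schema declares a set of template types (Arm, Outcome, Medication, ...),
each with an ordered list of named slots.  A slot is either *textual* (filled
by verbatim text spans of the abstract) or *template-valued* (filled by child
template instances of a declared type).  Slot names are globally unique: every
slot belongs to exactly one template type.  The template-reference graph must
be acyclic and every template type reachable from a single root (Publication
in the default clinical-trial schema).

Extraction results are :class:`InstanceForest` objects: typed template
instances whose slots hold ordered lists of fillers.  The linearizer requires
the induced containment graph to be acyclic and connected, which
:func:`validate_forest` checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import yaml

__all__ = [
    "SlotSpec",
    "TemplateSpec",
    "SchemaConfig",
    "SchemaError",
    "TextSpan",
    "FreeText",
    "TemplateInstance",
    "InstanceForest",
    "Violation",
    "load_schema",
    "dump_schema",
    "default_schema",
    "validate_forest",
]

TEXTUAL = "textual"
TEMPLATE = "template"


class SchemaError(ValueError):
    """Raised when a schema configuration violates a structural invariant."""


@dataclass(frozen=True)
class SlotSpec:
    """One slot of a template type.

    ``kind`` is ``"textual"`` (text-span fillers) or ``"template"`` (child
    instance fillers, of type ``child_template``).  ``owner`` is the declaring
    template type.
    """

    name: str
    kind: str
    owner: str
    child_template: str | None = None
    max_multiplicity: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (TEXTUAL, TEMPLATE):
            raise SchemaError(f"slot {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == TEMPLATE and not self.child_template:
            raise SchemaError(f"slot {self.name!r}: template slot needs child_template")
        if self.kind == TEXTUAL and self.child_template:
            raise SchemaError(f"slot {self.name!r}: textual slot has child_template")


@dataclass(frozen=True)
class TemplateSpec:
    """A template type: its name and ordered slot list.

    The slot declaration order realizes the slot ordering operator used by the
    linearizer.  ``fixed_cardinality`` marks types that occur a fixed number
    of times per document (always 1 for Publication, ClinicalTrial and
    Population in the clinical-trial schema); the extractive engine pools all
    of their fillers into a single instance instead of clustering.
    """

    name: str
    slots: tuple[SlotSpec, ...]
    fixed_cardinality: int | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.slots]
        if len(names) != len(set(names)):
            raise SchemaError(f"template {self.name!r}: duplicate slot names")
        for s in self.slots:
            if s.owner != self.name:
                raise SchemaError(
                    f"slot {s.name!r} owned by {s.owner!r}, declared in {self.name!r}"
                )
        if self.fixed_cardinality is not None and self.fixed_cardinality < 1:
            raise SchemaError(f"template {self.name!r}: fixed_cardinality must be >= 1")

    def slot(self, name: str) -> SlotSpec:
        for s in self.slots:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def textual_slots(self) -> tuple[SlotSpec, ...]:
        return tuple(s for s in self.slots if s.kind == TEXTUAL)

    @property
    def template_slots(self) -> tuple[SlotSpec, ...]:
        return tuple(s for s in self.slots if s.kind == TEMPLATE)


class SchemaConfig:
    """A validated schema: template types, globally unique slots, one root."""

    def __init__(self, templates: Iterable[TemplateSpec], root: str):
        self.templates: tuple[TemplateSpec, ...] = tuple(templates)
        self.root = root
        self._by_name = {t.name: t for t in self.templates}
        self._validate()
        # slot name -> SlotSpec (global uniqueness established by _validate)
        self._slots = {s.name: s for t in self.templates for s in t.slots}

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if len(self._by_name) != len(self.templates):
            raise SchemaError("duplicate template type names")
        if self.root not in self._by_name:
            raise SchemaError(f"root template {self.root!r} not declared")
        seen_slots: dict[str, str] = {}
        for t in self.templates:
            for s in t.slots:
                if s.name in seen_slots:
                    raise SchemaError(
                        f"slot {s.name!r} owned by both {seen_slots[s.name]!r} "
                        f"and {t.name!r}; slot names must be globally unique"
                    )
                seen_slots[s.name] = t.name
                if s.kind == TEMPLATE and s.child_template not in self._by_name:
                    raise SchemaError(
                        f"slot {s.name!r} references unknown template "
                        f"{s.child_template!r}"
                    )
        self._check_acyclic()
        self._check_reachable()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(name: str, path: list[str]) -> None:
            if state.get(name) == 0:
                cycle = path[path.index(name):] + [name]
                raise SchemaError("cyclic template references: " + " -> ".join(cycle))
            if state.get(name) == 1:
                return
            state[name] = 0
            for s in self._by_name[name].template_slots:
                visit(s.child_template, path + [name])
            state[name] = 1

        for t in self.templates:
            visit(t.name, [])

    def _check_reachable(self) -> None:
        reached = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in reached:
                continue
            reached.add(name)
            for s in self._by_name[name].template_slots:
                stack.append(s.child_template)
        missing = {t.name for t in self.templates} - reached
        if missing:
            raise SchemaError(
                f"template types not reachable from root: {sorted(missing)}"
            )

    # -- lookups ----------------------------------------------------------
    def template(self, name: str) -> TemplateSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def template_names(self) -> list[str]:
        return [t.name for t in self.templates]

    def slot(self, name: str) -> SlotSpec:
        """Look up a slot by its globally unique name."""
        return self._slots[name]

    @property
    def slot_names(self) -> list[str]:
        return list(self._slots)

    @property
    def textual_slot_names(self) -> list[str]:
        return [n for n, s in self._slots.items() if s.kind == TEXTUAL]

    def parents_of(self, template_name: str) -> list[SlotSpec]:
        """Template slots (of other templates) whose child type is given."""
        return [
            s
            for t in self.templates
            for s in t.template_slots
            if s.child_template == template_name
        ]

    def containment_depth(self) -> int:
        """Maximum number of template types on a root-to-leaf containment path."""

        def depth(name: str) -> int:
            children = self._by_name[name].template_slots
            if not children:
                return 1
            return 1 + max(depth(s.child_template) for s in children)

        return depth(self.root)

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "templates": [
                {
                    "name": t.name,
                    **(
                        {"fixed_cardinality": t.fixed_cardinality}
                        if t.fixed_cardinality is not None
                        else {}
                    ),
                    "slots": [
                        {
                            "name": s.name,
                            "kind": s.kind,
                            **({"child": s.child_template} if s.child_template else {}),
                            **(
                                {"max_multiplicity": s.max_multiplicity}
                                if s.max_multiplicity is not None
                                else {}
                            ),
                        }
                        for s in t.slots
                    ],
                }
                for t in self.templates
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SchemaConfig":
        try:
            templates = []
            for td in data["templates"]:
                slots = tuple(
                    SlotSpec(
                        name=sd["name"],
                        kind=sd.get("kind", TEXTUAL),
                        owner=td["name"],
                        child_template=sd.get("child"),
                        max_multiplicity=sd.get("max_multiplicity"),
                    )
                    for sd in td.get("slots", [])
                )
                templates.append(
                    TemplateSpec(
                        name=td["name"],
                        slots=slots,
                        fixed_cardinality=td.get("fixed_cardinality"),
                    )
                )
            return cls(templates, root=data["root"])
        except KeyError as exc:
            raise SchemaError(f"missing schema key: {exc}") from exc

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SchemaConfig) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return f"SchemaConfig({len(self.templates)} templates, root={self.root!r})"


def load_schema(source: Union[str, Path, dict]) -> SchemaConfig:
    """Load and validate a schema from a YAML/JSON file or a parsed dict."""
    if isinstance(source, dict):
        return SchemaConfig.from_dict(source)
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SchemaConfig.from_dict(data)


def dump_schema(schema: SchemaConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(schema.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(schema.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Default clinical-trial schema
# ---------------------------------------------------------------------------

def _slots(owner: str, textual: list[str], template: list[tuple[str, str]] = ()):
    specs = [SlotSpec(name=n, kind=TEXTUAL, owner=owner) for n in textual]
    specs += [
        SlotSpec(name=n, kind=TEMPLATE, owner=owner, child_template=c)
        for n, c in template
    ]
    return tuple(specs)


def default_schema() -> SchemaConfig:
    """The shipped 10-template clinical-trial schema (C-TrO derived).

    Template names and the fixed-cardinality flags follow the published data
    model; the slot inventory covers the slot names appearing in the
    literature (Journal, PMID, Frequency, Drug, DoseUnit, PercentageAffected,
    TimePoint, ...) but is deliberately config-overridable: corpora annotated
    against the full 85-slot ontology can supply their own schema file.
    """
    templates = [
        TemplateSpec(
            "Publication",
            _slots(
                "Publication",
                ["Title", "Authors", "Journal", "PMID", "PublicationYear"],
                [("describes", "ClinicalTrial")],
            ),
            fixed_cardinality=1,
        ),
        TemplateSpec(
            "ClinicalTrial",
            _slots(
                "ClinicalTrial",
                ["CTDesign", "NumberPatientsCT", "CTDuration"],
                [
                    ("hasPopulation", "Population"),
                    ("hasArm", "Arm"),
                    ("hasDiffBetweenGroups", "DiffBetweenGroups"),
                    ("hasEvidenceQuality", "EvidenceQuality"),
                ],
            ),
            fixed_cardinality=1,
        ),
        TemplateSpec(
            "Population",
            _slots("Population", ["Ethnicity", "Country", "Precondition"]),
            fixed_cardinality=1,
        ),
        TemplateSpec(
            "Arm",
            _slots(
                "Arm",
                [],
                [("hasIntervention", "Intervention")],
            )
            + _slots("Arm", ["FinalNumPatientsArm"])
            + _slots("Arm", [], [("hasOutcome", "Outcome")]),
        ),
        TemplateSpec(
            "Intervention",
            _slots("Intervention", [], [("hasMedication", "Medication")])
            + _slots("Intervention", ["Frequency"]),
        ),
        TemplateSpec(
            "Medication",
            _slots("Medication", ["Drug", "DoseValue", "DoseUnit"]),
        ),
        TemplateSpec(
            "Outcome",
            _slots(
                "Outcome",
                ["PercentageAffected", "TimePoint", "NumberAffected", "ObservedResult"],
                [("hasEndpoint", "Endpoint")],
            ),
        ),
        TemplateSpec(
            "Endpoint",
            _slots(
                "Endpoint",
                ["EndpointDescription", "AggregationMethod", "MeasurementDevice"],
            ),
        ),
        TemplateSpec(
            "DiffBetweenGroups",
            _slots("DiffBetweenGroups", ["DiffGroupAbsValue", "PValueChangeValue"]),
        ),
        TemplateSpec(
            "EvidenceQuality",
            _slots("EvidenceQuality", ["Randomization", "Blinding"]),
        ),
    ]
    return SchemaConfig(templates, root="Publication")


# ---------------------------------------------------------------------------
# Instances and forests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextSpan:
    """A verbatim slot filler: a character span with its token alignment.

    Character offsets are 0-based half-open; token indices are inclusive.
    """

    doc_id: str
    char_start: int
    char_end: int
    token_start: int
    token_end: int
    text: str

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError("empty character span")
        if self.token_start > self.token_end:
            raise ValueError("token_start > token_end")


@dataclass(frozen=True)
class FreeText:
    """A textual filler produced by a generative model that does not occur
    verbatim in the source document.  Kept (not rejected) and flagged so that
    evaluation can count it as an ordinary — typically wrong — filler."""

    doc_id: str
    text: str
    hallucinated: bool = True


SlotFiller = Union[TextSpan, FreeText, "TemplateInstance"]


@dataclass
class TemplateInstance:
    """A typed node: slot name -> ordered list of fillers."""

    instance_id: str
    type: str
    slots: dict[str, list[SlotFiller]] = field(default_factory=dict)

    def add(self, slot: str, filler: SlotFiller) -> None:
        self.slots.setdefault(slot, []).append(filler)

    def fillers(self, slot: str) -> list[SlotFiller]:
        return self.slots.get(slot, [])

    def textual_fillers(self) -> list[tuple[str, SlotFiller]]:
        return [
            (slot, f)
            for slot, fl in self.slots.items()
            for f in fl
            if not isinstance(f, TemplateInstance)
        ]

    def children(self) -> list["TemplateInstance"]:
        return [
            f
            for fl in self.slots.values()
            for f in fl
            if isinstance(f, TemplateInstance)
        ]


@dataclass
class InstanceForest:
    """All template instances extracted from one document, plus the root id."""

    doc_id: str
    instances: list[TemplateInstance]
    root: str

    def by_id(self, instance_id: str) -> TemplateInstance:
        for inst in self.instances:
            if inst.instance_id == instance_id:
                return inst
        raise KeyError(instance_id)

    @property
    def root_instance(self) -> TemplateInstance:
        return self.by_id(self.root)

    def of_type(self, template_name: str) -> list[TemplateInstance]:
        return [i for i in self.instances if i.type == template_name]

    def all_textual_fillers(self) -> list[tuple[str, SlotFiller]]:
        return [tf for inst in self.instances for tf in inst.textual_fillers()]


@dataclass(frozen=True)
class Violation:
    kind: str  # "cycle" | "disconnected" | "type_mismatch" | "unknown" | ...
    message: str

    def __str__(self) -> str:  # pragma: no cover - debug aid
        return f"[{self.kind}] {self.message}"


def validate_forest(forest: InstanceForest, schema: SchemaConfig) -> list[Violation]:
    """Check the structural constraints the linearizer requires.

    Returns a list of violations; an empty list means the forest is
    linearizable: the containment graph is acyclic and connected (single
    root), and every filled slot respects the schema's typing.
    """
    violations: list[Violation] = []
    ids = {inst.instance_id for inst in forest.instances}
    if len(ids) != len(forest.instances):
        violations.append(Violation("duplicate_id", "duplicate instance ids"))
    if forest.root not in ids:
        violations.append(Violation("unknown", f"root {forest.root!r} not present"))

    for inst in forest.instances:
        if inst.type not in schema:
            violations.append(
                Violation("unknown", f"{inst.instance_id}: unknown template {inst.type!r}")
            )
            continue
        tspec = schema.template(inst.type)
        for slot_name, fillers in inst.slots.items():
            try:
                sspec = tspec.slot(slot_name)
            except KeyError:
                violations.append(
                    Violation(
                        "unknown",
                        f"{inst.instance_id}: slot {slot_name!r} not in {inst.type}",
                    )
                )
                continue
            for f in fillers:
                if isinstance(f, TemplateInstance):
                    if sspec.kind != TEMPLATE:
                        violations.append(
                            Violation(
                                "type_mismatch",
                                f"{inst.instance_id}.{slot_name}: instance filler "
                                "in textual slot",
                            )
                        )
                    elif f.type != sspec.child_template:
                        violations.append(
                            Violation(
                                "type_mismatch",
                                f"{inst.instance_id}.{slot_name}: child of type "
                                f"{f.type!r}, expected {sspec.child_template!r}",
                            )
                        )
                elif sspec.kind != TEXTUAL:
                    violations.append(
                        Violation(
                            "type_mismatch",
                            f"{inst.instance_id}.{slot_name}: text filler in "
                            "template slot",
                        )
                    )
            if (
                sspec.max_multiplicity is not None
                and len(fillers) > sspec.max_multiplicity
            ):
                violations.append(
                    Violation(
                        "multiplicity",
                        f"{inst.instance_id}.{slot_name}: {len(fillers)} fillers "
                        f"> max {sspec.max_multiplicity}",
                    )
                )

    # cycle / connectivity over the containment graph
    index = {id(inst): inst for inst in forest.instances}
    color: dict[int, int] = {}  # 0 visiting, 1 done
    reached: set[int] = set()

    def visit(inst: TemplateInstance, path: list[str]) -> None:
        key = id(inst)
        if color.get(key) == 0:
            violations.append(
                Violation(
                    "cycle",
                    "instance contains itself: " + " -> ".join(path + [inst.instance_id]),
                )
            )
            return
        if color.get(key) == 1:
            reached.add(key)
            return
        color[key] = 0
        reached.add(key)
        for child in inst.children():
            visit(child, path + [inst.instance_id])
        color[key] = 1

    if forest.root in ids:
        try:
            visit(forest.by_id(forest.root), [])
        except RecursionError:  # pathological depth; report as cycle
            violations.append(Violation("cycle", "containment recursion limit hit"))
    for inst in forest.instances:
        if id(inst) not in reached and id(inst) in index:
            violations.append(
                Violation(
                    "disconnected",
                    f"{inst.instance_id} not reachable from root {forest.root!r}",
                )
            )
    return violations
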