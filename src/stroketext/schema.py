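"""Attribute schema and report data model.

A report corpus is a set of free-text neuroimaging documents (head/neck CT,
CTA, CTP), each carrying optional gold labels for seven stroke attributes:

* five binary findings — proximal large vessel occlusion (``lvo``, an
  MCA-M1 or ACA-A1 occlusion with or without carotid terminus involvement),
  distal anterior-circulation occlusion (M2/A2 segments or beyond), basilar
  occlusion, established cerebral ischemia, and any intracranial hemorrhage;
* two categorical gradings — the ASPECTS early-ischemia score banded as
  ``<5`` vs ``>=5`` vs not reported, and qualitative collateral status
  (good / intermediate / poor / not reported).

Binary attributes use ``present``/``absent`` internally; corpus files may
spell gold labels as 1/0 or true/false and are normalised on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "AttributeSchema",
    "Report",
    "SchemaError",
    "LabelError",
    "STROKE_SCHEMA",
    "BINARY_ATTRIBUTES",
    "CATEGORICAL_ATTRIBUTES",
    "PRESENT",
    "ABSENT",
    "NOT_REPORTED",
    "validate_labels",
    "read_corpus",
    "write_corpus",
]

PRESENT = "present"
ABSENT = "absent"
NOT_REPORTED = "not_reported"


class SchemaError(ValueError):
    """An attribute name or schema definition is invalid."""


class LabelError(ValueError):
    """A gold label value is not a legal class for its attribute."""


@dataclass(frozen=True)
class AttributeSchema:
    """Definition of one extracted attribute.

    Parameters
    ----------
    name
        Attribute identifier, e.g. ``"lvo"``.
    kind
        ``"binary"`` or ``"categorical"``.
    classes
        Ordered class labels. Binary attributes must be exactly
        ``[present, absent]``.
    default_class
        Class predicted when no rule fires.
    priority
        Permutation of ``classes`` used to break score ties, worst
        (clinically most conservative) first.
    """

    name: str
    kind: str
    classes: tuple[str, ...]
    default_class: str
    priority: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical"):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")
        if self.default_class not in self.classes:
            raise SchemaError(
                f"{self.name}: default class {self.default_class!r} "
                f"not among classes {self.classes}"
            )
        if sorted(self.priority) != sorted(self.classes):
            raise SchemaError(f"{self.name}: priority must permute classes")
        if self.kind == "binary" and self.classes != (PRESENT, ABSENT):
            raise SchemaError(
                f"{self.name}: binary attributes must have classes "
                f"(present, absent), got {self.classes}"
            )

    @property
    def is_binary(self) -> bool:
        return self.kind == "binary"


def _binary(name: str) -> AttributeSchema:
    # absent-first priority: the default wins any tie at the threshold
    return AttributeSchema(
        name=name,
        kind="binary",
        classes=(PRESENT, ABSENT),
        default_class=ABSENT,
        priority=(ABSENT, PRESENT),
    )


#: The seven-attribute stroke schema shared by every stage of the pipeline.
STROKE_SCHEMA: dict[str, AttributeSchema] = {
    "lvo": _binary("lvo"),
    "distal_occlusion": _binary("distal_occlusion"),
    "basilar_occlusion": _binary("basilar_occlusion"),
    "ischemia": _binary("ischemia"),
    "hemorrhage": _binary("hemorrhage"),
    "aspects": AttributeSchema(
        name="aspects",
        kind="categorical",
        classes=(NOT_REPORTED, "lt5", "ge5"),
        default_class=NOT_REPORTED,
        priority=("lt5", "ge5", NOT_REPORTED),
    ),
    "collaterals": AttributeSchema(
        name="collaterals",
        kind="categorical",
        classes=(NOT_REPORTED, "poor", "intermediate", "good"),
        default_class=NOT_REPORTED,
        priority=("poor", "intermediate", "good", NOT_REPORTED),
    ),
}

BINARY_ATTRIBUTES = tuple(
    n for n, s in STROKE_SCHEMA.items() if s.is_binary
)
CATEGORICAL_ATTRIBUTES = tuple(
    n for n, s in STROKE_SCHEMA.items() if not s.is_binary
)

# Accepted spellings of binary labels in gold files.
_BINARY_ALIASES = {
    PRESENT: PRESENT,
    ABSENT: ABSENT,
    "1": PRESENT,
    "0": ABSENT,
    "true": PRESENT,
    "false": ABSENT,
    "yes": PRESENT,
    "no": ABSENT,
}


def _normalise_label(attr: AttributeSchema, value: object) -> str:
    if attr.is_binary:
        key = str(value).strip().lower()
        if key in _BINARY_ALIASES:
            return _BINARY_ALIASES[key]
        raise LabelError(
            f"{attr.name}: label {value!r} not in classes {attr.classes}"
        )
    if isinstance(value, str) and value in attr.classes:
        return value
    raise LabelError(
        f"{attr.name}: label {value!r} not in classes {attr.classes}"
    )


def validate_labels(
    labels: Mapping[str, object],
    schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
) -> dict[str, str]:
    """Normalise and complete a gold-label mapping.

    Every attribute of ``schema`` is present in the result; attributes
    missing from ``labels`` receive the schema default (``absent`` for
    binary findings, ``not_reported`` for gradings). Idempotent.

    Raises
    ------
    SchemaError
        If ``labels`` names an attribute not in the schema.
    LabelError
        If a value is not a legal class for its attribute.
    """
    unknown = set(labels) - set(schema)
    if unknown:
        raise SchemaError(f"unknown attribute(s): {sorted(unknown)}")
    out: dict[str, str] = {}
    for name, attr in schema.items():
        if name in labels:
            out[name] = _normalise_label(attr, labels[name])
        else:
            out[name] = attr.default_class
    return out


@dataclass
class Report:
    """One free-text radiology document.

    ``labels``, when present, is a complete validated attribute→class
    mapping (the manual chart abstraction serving as reference standard).
    ``hard_flags`` lists adversarial-case tags and only occurs in
    synthetic corpora.
    """

    id: str
    text: str
    labels: Optional[dict[str, str]] = None
    hard_flags: list[str] = field(default_factory=list)

    def to_json_obj(self) -> dict:
        obj: dict = {"id": self.id, "text": self.text}
        if self.labels is not None:
            obj["labels"] = dict(self.labels)
        if self.hard_flags:
            obj["hard_flags"] = list(self.hard_flags)
        return obj

    @classmethod
    def from_json_obj(
        cls,
        obj: Mapping[str, object],
        schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
    ) -> "Report":
        labels = obj.get("labels")
        return cls(
            id=str(obj["id"]),
            text=str(obj["text"]),
            labels=None if labels is None else validate_labels(labels, schema),
            hard_flags=list(obj.get("hard_flags", [])),
        )


def write_corpus(reports: Iterable[Report], path: str | Path) -> None:
    """Write a corpus as UTF-8 JSON-lines, one report object per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for report in reports:
            fh.write(json.dumps(report.to_json_obj(), ensure_ascii=False))
            fh.write("\n")


def read_corpus(
    path: str | Path,
    schema: Mapping[str, AttributeSchema] = STROKE_SCHEMA,
) -> list[Report]:
    """Read a JSON-lines corpus, validating labels and id uniqueness."""
    reports: list[Report] = []
    seen: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            report = Report.from_json_obj(obj, schema)
            if report.id in seen:
                raise ValueError(
                    f"duplicate report id {report.id!r} at line {lineno}"
                )
            seen.add(report.id)
            reports.append(report)
    return reports
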