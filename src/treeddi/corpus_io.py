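"""Corpus input/output for DDI-style XML and flat instance files.

The XML dialect mirrors the SemEval DDIExtraction challenge corpora:
``document`` elements contain ``sentence`` elements, which contain
``entity`` elements (with ``charOffset="a-b[;c-d]"``, 0-based inclusive
character intervals) and ``pair`` elements (``ddi="true|false"`` plus an
optional ``type`` attribute for positive pairs).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence
from xml.etree import ElementTree

__all__ = [
    "DDI_TYPES",
    "DETECTION_LABELS",
    "DRUG_ENTITY_TYPES",
    "EntityMention",
    "PairAnnotation",
    "SentenceRecord",
    "CandidateInstance",
    "CorpusValidationError",
    "read_ddi_xml",
    "write_ddi_xml",
    "write_instances",
    "read_instances",
]

#: Interaction types defined by the challenge annotation scheme.
DDI_TYPES = ("advice", "effect", "mechanism", "int")

DETECTION_LABELS = ("negative", "positive")

#: Entity classes that may form candidate drug pairs.  Other entity types
#: are kept as mentions but never paired.
DRUG_ENTITY_TYPES = frozenset({"drug", "brand", "group", "drug_n"})


class CorpusValidationError(ValueError):
    """Raised when an XML corpus violates the dialect's invariants."""


@dataclass(frozen=True)
class EntityMention:
    """A (possibly discontinuous) entity annotation within one sentence.

    ``spans`` holds half-open ``(start, end)`` character intervals in
    sentence coordinates, sorted and non-overlapping.  Discontinuous
    mentions ("two or more non-sequential words") carry more than one span.
    """

    id: str
    text: str
    spans: tuple[tuple[int, int], ...]
    etype: str = "drug"

    def __post_init__(self) -> None:
        if not self.spans:
            raise CorpusValidationError(f"entity {self.id}: empty span list")
        prev_end = -1
        for start, end in self.spans:
            if start >= end:
                raise CorpusValidationError(
                    f"entity {self.id}: empty or inverted span ({start},{end})"
                )
            if start < prev_end:
                raise CorpusValidationError(
                    f"entity {self.id}: spans overlap or are unsorted"
                )
            prev_end = end

    @property
    def is_drug(self) -> bool:
        return self.etype in DRUG_ENTITY_TYPES

    @property
    def first_start(self) -> int:
        return self.spans[0][0]


@dataclass(frozen=True)
class PairAnnotation:
    """Gold annotation for one candidate drug pair."""

    id: str
    e1: str
    e2: str
    ddi: bool
    type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type is not None and self.type not in DDI_TYPES:
            raise CorpusValidationError(
                f"pair {self.id}: unknown DDI type {self.type!r}"
            )
        if self.type is not None and not self.ddi:
            raise CorpusValidationError(
                f"pair {self.id}: type given on a non-interacting pair"
            )


@dataclass
class SentenceRecord:
    """One sentence with its entity and pair annotations."""

    id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    pairs: list[PairAnnotation] = field(default_factory=list)
    source: str = ""

    def entity(self, eid: str) -> EntityMention:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(eid)

    def validate(self) -> None:
        ids = {e.id for e in self.entities}
        if len(ids) != len(self.entities):
            raise CorpusValidationError(f"sentence {self.id}: duplicate entity ids")
        n = len(self.text)
        for ent in self.entities:
            for start, end in ent.spans:
                if not (0 <= start < end <= n):
                    raise CorpusValidationError(
                        f"sentence {self.id}: entity {ent.id} span ({start},{end}) "
                        f"outside sentence of length {n}"
                    )
        for pair in self.pairs:
            for eid in (pair.e1, pair.e2):
                if eid not in ids:
                    raise CorpusValidationError(
                        f"sentence {self.id}: pair {pair.id} references "
                        f"missing entity {eid}"
                    )


@dataclass
class CandidateInstance:
    """One (sentence, drug-pair) classification unit.

    ``tokens`` are the fully preprocessed tokens (drugs anonymized,
    numbers masked); ``target1``/``target2`` index the two ``Ddrug``
    placeholders.  Filtered gold positives from a test split are retained
    (``filtered=True``) so they can be charged as false negatives.
    """

    sentence_id: str
    e1_id: str
    e2_id: str
    tokens: list[str]
    target1: int
    target2: int
    label: str = "negative"
    ddi_type: Optional[str] = None
    e1_text: str = ""
    e2_text: str = ""
    filtered: bool = False
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.label not in DETECTION_LABELS:
            raise CorpusValidationError(f"unknown detection label {self.label!r}")
        if self.ddi_type is not None and self.ddi_type not in DDI_TYPES:
            raise CorpusValidationError(f"unknown DDI type {self.ddi_type!r}")
        n = len(self.tokens)
        for idx in (self.target1, self.target2):
            if not (0 <= idx < n):
                raise CorpusValidationError(
                    f"instance {self.key}: target index {idx} outside "
                    f"{n}-token sentence"
                )

    @property
    def key(self) -> str:
        return f"{self.sentence_id}:{self.e1_id}:{self.e2_id}"

    @property
    def five_class_label(self) -> str:
        return self.ddi_type if self.label == "positive" else "negative"


# ---------------------------------------------------------------------------
# XML corpus reading / writing


def _parse_char_offset(raw: str, eid: str) -> tuple[tuple[int, int], ...]:
    # Challenge dialect: 0-based inclusive "a-b", discontinuous "a-b;c-d".
    spans = []
    for part in raw.split(";"):
        try:
            a, b = part.split("-")
            start, end = int(a), int(b) + 1  # to half-open
        except ValueError as exc:
            raise CorpusValidationError(
                f"entity {eid}: malformed charOffset {raw!r}"
            ) from exc
        spans.append((start, end))
    return tuple(spans)


def read_ddi_xml(path) -> list[SentenceRecord]:
    """Read a DDI-style XML corpus into :class:`SentenceRecord` objects."""
    try:
        tree = ElementTree.parse(str(path))
    except ElementTree.ParseError as exc:
        raise CorpusValidationError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    docs = [root] if root.tag == "document" else root.iter("document")
    records: list[SentenceRecord] = []
    for doc in docs:
        source = doc.get("origin", doc.get("id", ""))
        for sent in doc.iter("sentence"):
            record = SentenceRecord(
                id=sent.get("id", ""), text=sent.get("text", ""), source=source
            )
            for ent in sent.iter("entity"):
                eid = ent.get("id", "")
                record.entities.append(
                    EntityMention(
                        id=eid,
                        text=ent.get("text", ""),
                        spans=_parse_char_offset(ent.get("charOffset", ""), eid),
                        etype=ent.get("type", "drug"),
                    )
                )
            for pair in sent.iter("pair"):
                ddi = pair.get("ddi", "false").lower() == "true"
                record.pairs.append(
                    PairAnnotation(
                        id=pair.get("id", ""),
                        e1=pair.get("e1", ""),
                        e2=pair.get("e2", ""),
                        ddi=ddi,
                        type=pair.get("type") if ddi else None,
                    )
                )
            record.validate()
            records.append(record)
    return records


def write_ddi_xml(records: Sequence[SentenceRecord], path) -> None:
    """Write SentenceRecords in the same XML dialect :func:`read_ddi_xml` reads."""
    root = ElementTree.Element("corpus")
    by_source: dict[str, ElementTree.Element] = {}
    for i, record in enumerate(records):
        source = record.source or f"d{i}"
        doc = by_source.get(source)
        if doc is None:
            doc = ElementTree.SubElement(root, "document", id=source)
            by_source[source] = doc
        sent = ElementTree.SubElement(doc, "sentence", id=record.id, text=record.text)
        for ent in record.entities:
            offset = ";".join(f"{s}-{e - 1}" for s, e in ent.spans)
            ElementTree.SubElement(
                sent,
                "entity",
                id=ent.id,
                charOffset=offset,
                type=ent.etype,
                text=ent.text,
            )
        for pair in record.pairs:
            attrs = {
                "id": pair.id,
                "e1": pair.e1,
                "e2": pair.e2,
                "ddi": "true" if pair.ddi else "false",
            }
            if pair.type is not None:
                attrs["type"] = pair.type
            ElementTree.SubElement(sent, "pair", **attrs)
    ElementTree.indent(root)
    ElementTree.ElementTree(root).write(str(path), encoding="unicode")


# ---------------------------------------------------------------------------
# Flat instance files (TSV)

_TSV_HEADER = [
    "sentence_id",
    "e1_id",
    "e2_id",
    "label",
    "ddi_type",
    "target1",
    "target2",
    "e1_text",
    "e2_text",
    "filtered",
    "tokens",
]


def write_instances(instances: Iterable[CandidateInstance], path) -> None:
    """Dump instances as a tab-separated file, one row per instance."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for inst in instances:
            writer.writerow(
                [
                    inst.sentence_id,
                    inst.e1_id,
                    inst.e2_id,
                    inst.label,
                    inst.ddi_type or "",
                    inst.target1,
                    inst.target2,
                    inst.e1_text,
                    inst.e2_text,
                    int(inst.filtered),
                    " ".join(inst.tokens),
                ]
            )


def read_instances(path) -> list[CandidateInstance]:
    """Read back a TSV written by :func:`write_instances`."""
    instances = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _TSV_HEADER:
            raise CorpusValidationError(f"unexpected instance header in {path}")
        for row in reader:
            instances.append(
                CandidateInstance(
                    sentence_id=row[0],
                    e1_id=row[1],
                    e2_id=row[2],
                    label=row[3],
                    ddi_type=row[4] or None,
                    target1=int(row[5]),
                    target2=int(row[6]),
                    e1_text=row[7],
                    e2_text=row[8],
                    filtered=bool(int(row[9])),
                    tokens=row[10].split(" "),
                )
            )
    return instances
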