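"""Sentence preprocessing: tokenization, drug anonymization, number
masking, candidate generation, negative-instance filtering and duplicate
removal.

The preprocessing contract is: every annotated drug mention in a sentence
is replaced by a placeholder token ``Ddrug{k}`` (``k`` assigned by order
of first span start), independent numbers become ``#``, and one
:class:`~treeddi.corpus_io.CandidateInstance` is produced per candidate
drug pair.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Optional, Sequence

from .corpus_io import (
    CandidateInstance,
    CorpusValidationError,
    EntityMention,
    SentenceRecord,
)

__all__ = [
    "FilterReport",
    "tokenize",
    "tokenize_with_offsets",
    "anonymize",
    "anonymize_text",
    "mask_numbers",
    "generate_candidates",
    "filter_negatives",
    "deduplicate",
    "preprocess_record",
    "preprocess_corpus",
    "placeholder",
    "is_placeholder",
]

PLACEHOLDER_RE = re.compile(r"^Ddrug\d+$")

# Tokens that may separate drug mentions inside one coordination run.
_COORD_SEPARATORS = frozenset({",", "and", "or", "/"})

# A whole-token integer or decimal literal, optionally signed.
NUMBER_RE = re.compile(r"^[+-]?\d+([.,]\d+)?$")

# Decimal literals stay single tokens so number masking sees them whole;
# any other non-word character becomes its own token.
_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)+|\w+|[^\w\s]")


def placeholder(k: int) -> str:
    return f"Ddrug{k}"


def is_placeholder(token: str) -> bool:
    return PLACEHOLDER_RE.match(token) is not None


@dataclass
class FilterReport:
    """Accounting of instances removed by filtering/deduplication.

    ``removed_positives`` is the ledger of gold-positive instances removed
    from a test split; evaluation charges each as a false negative.
    """

    same_drug: int = 0
    coordinate: int = 0
    duplicate: int = 0
    removed_positives: list[CandidateInstance] = field(default_factory=list)

    @property
    def total_removed(self) -> int:
        return self.same_drug + self.coordinate + self.duplicate

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            same_drug=self.same_drug + other.same_drug,
            coordinate=self.coordinate + other.coordinate,
            duplicate=self.duplicate + other.duplicate,
            removed_positives=self.removed_positives + other.removed_positives,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "same_drug": self.same_drug,
                "coordinate": self.coordinate,
                "duplicate": self.duplicate,
                "removed_positives": [
                    {
                        "sentence_id": inst.sentence_id,
                        "e1_id": inst.e1_id,
                        "e2_id": inst.e2_id,
                        "label": inst.label,
                        "ddi_type": inst.ddi_type,
                    }
                    for inst in self.removed_positives
                ],
            },
            indent=2,
        )


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Tokenize, returning ``(token, start, end)`` with half-open offsets."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def tokenize(text: str) -> list[str]:
    """Deterministic whitespace + punctuation tokenization.

    Punctuation is split into separate tokens; unsigned decimal literals
    (``2.5``) are kept whole so number masking can match them.
    """
    return [tok for tok, _, _ in tokenize_with_offsets(text)]


def mask_numbers(tokens: Sequence[str]) -> list[str]:
    """Replace every independent-number token with ``#``.

    Tokens merely containing digits (``CYP3A4``) are left unchanged.
    """
    return ["#" if NUMBER_RE.match(tok) else tok for tok in tokens]


def _check_replacement_overlap(entities: Sequence[EntityMention]) -> None:
    firsts = sorted((e.spans[0], e.id) for e in entities)
    for (span_a, id_a), (span_b, id_b) in zip(firsts, firsts[1:]):
        if span_b[0] < span_a[1]:
            raise CorpusValidationError(
                f"entities {id_a} and {id_b} have overlapping primary spans"
            )


def anonymize_text(record: SentenceRecord) -> str:
    """The sentence text with every drug mention replaced by its
    ``Ddrug{k}`` placeholder (whitespace normalized)."""
    text, _ = _anonymize(record)
    return text


def anonymize(
    record: SentenceRecord,
    name_normalizer: Optional[Callable[[str], str]] = None,
) -> tuple[list[str], dict[str, int]]:
    """Replace annotated drug mentions with ``Ddrug{k}`` placeholders.

    Returns the token list of the anonymized sentence and a map from
    entity id to the token index of its placeholder.  Placeholder numbers
    follow the order of each entity's first span start.  A discontinuous
    mention collapses to a single placeholder at its first span; its
    remaining spans are deleted (unless another entity's replacement
    already covers them, as with shared head nouns).

    ``name_normalizer`` is a hook for mapping surface forms to canonical
    names before downstream same-drug filtering; it defaults to identity
    and does not affect the emitted tokens.
    """
    anonymized, drugs = _anonymize(record)
    tokens = tokenize(anonymized)
    index_map: dict[str, int] = {}
    for k, ent in enumerate(drugs):
        token = placeholder(k)
        index_map[ent.id] = tokens.index(token)
    return tokens, index_map


def _anonymize(record: SentenceRecord) -> tuple[str, list[EntityMention]]:
    record.validate()
    drugs = sorted(
        (e for e in record.entities if e.is_drug), key=lambda e: e.first_start
    )
    _check_replacement_overlap(drugs)

    # Edit plan: (start, end, replacement-or-None) on the original text.
    edits: list[tuple[int, int, Optional[str]]] = []
    replaced_spans: list[tuple[int, int]] = []
    for k, ent in enumerate(drugs):
        start, end = ent.spans[0]
        edits.append((start, end, placeholder(k)))
        replaced_spans.append((start, end))
    for ent in drugs:
        for start, end in ent.spans[1:]:
            covered = any(s <= start and end <= e for s, e in replaced_spans)
            if not covered:
                edits.append((start, end, None))

    edits.sort()
    out: list[str] = []
    cursor = 0
    for start, end, repl in edits:
        out.append(record.text[cursor:start])
        if repl is not None:
            out.append(repl)
        cursor = end
    out.append(record.text[cursor:])
    anonymized = re.sub(r"\s+", " ", "".join(out)).strip()
    return anonymized, drugs


def generate_candidates(
    record: SentenceRecord,
    tokens: Sequence[str],
    index_map: dict[str, int],
) -> list[CandidateInstance]:
    """Build one CandidateInstance per candidate drug pair.

    Annotated pairs are used when present; otherwise every unordered pair
    of annotated drugs becomes an (unlabeled, negative) candidate.
    Sentences with fewer than two drugs yield no candidates.
    """
    if len(index_map) < 2:
        return []
    token_list = list(tokens)
    instances = []
    if record.pairs:
        for pair in record.pairs:
            if pair.e1 not in index_map or pair.e2 not in index_map:
                continue  # non-drug endpoint: never a candidate
            instances.append(
                CandidateInstance(
                    sentence_id=record.id,
                    e1_id=pair.e1,
                    e2_id=pair.e2,
                    tokens=token_list,
                    target1=index_map[pair.e1],
                    target2=index_map[pair.e2],
                    label="positive" if pair.ddi else "negative",
                    ddi_type=pair.type,
                    e1_text=record.entity(pair.e1).text,
                    e2_text=record.entity(pair.e2).text,
                )
            )
    else:
        ordered = sorted(index_map, key=index_map.get)
        for e1, e2 in combinations(ordered, 2):
            instances.append(
                CandidateInstance(
                    sentence_id=record.id,
                    e1_id=e1,
                    e2_id=e2,
                    tokens=token_list,
                    target1=index_map[e1],
                    target2=index_map[e2],
                    e1_text=record.entity(e1).text,
                    e2_text=record.entity(e2).text,
                )
            )
    return instances


def _coordination_runs(tokens: Sequence[str]) -> list[frozenset[int]]:
    """Maximal runs of >=3 drug placeholders separated only by
    commas/conjunctions; returns the placeholder token indices per run."""
    runs: list[list[int]] = []
    current: list[int] = []
    i = 0
    n = len(tokens)
    while i < n:
        if is_placeholder(tokens[i]):
            current.append(i)
            i += 1
            # consume separator gap leading to another placeholder
            j = i
            while j < n and tokens[j] in _COORD_SEPARATORS:
                j += 1
            if j < n and j > i and is_placeholder(tokens[j]):
                i = j
                continue
            runs.append(current)
            current = []
        else:
            i += 1
    if current:
        runs.append(current)
    return [frozenset(run) for run in runs if len(run) >= 3]


def filter_negatives(
    instances: Sequence[CandidateInstance],
    tokens: Sequence[str],
    split: str = "train",
    filter_train_positives: bool = False,
    synonym_map: Optional[dict[str, str]] = None,
) -> tuple[list[CandidateInstance], FilterReport]:
    """Apply the two negative-instance filtering rules.

    Rule 1 removes pairs whose surface forms are equal case-insensitively
    (optionally after a user-supplied synonym mapping).  Rule 2 removes
    pairs whose two targets lie in one coordination run of three or more
    drug placeholders.  Gold positives are only removed from a test split
    (or from train when ``filter_train_positives`` is set); removed gold
    positives are recorded in the report ledger for false-negative
    accounting.
    """
    if split not in ("train", "test"):
        raise ValueError(f"unknown split {split!r}")
    synonym_map = synonym_map or {}

    def canonical(name: str) -> str:
        name = name.strip().lower()
        return synonym_map.get(name, name)

    runs = _coordination_runs(tokens)
    kept: list[CandidateInstance] = []
    report = FilterReport()
    may_drop_positive = split == "test" or filter_train_positives
    for inst in instances:
        rule = None
        if canonical(inst.e1_text) == canonical(inst.e2_text):
            rule = "same_drug"
        elif any(inst.target1 in run and inst.target2 in run for run in runs):
            rule = "coordinate"
        if rule is None or (inst.label == "positive" and not may_drop_positive):
            kept.append(inst)
            continue
        setattr(report, rule, getattr(report, rule) + 1)
        if inst.label == "positive":
            inst.filtered = True
            report.removed_positives.append(inst)
    return kept, report


def deduplicate(
    instances: Sequence[CandidateInstance],
) -> tuple[list[CandidateInstance], FilterReport]:
    """Drop instances whose (token sequence, target indices) repeat an
    earlier instance; the first occurrence is kept."""
    seen: set[tuple] = set()
    kept: list[CandidateInstance] = []
    report = FilterReport()
    for inst in instances:
        key = (tuple(inst.tokens), inst.target1, inst.target2)
        if key in seen:
            inst.duplicate = True
            report.duplicate += 1
        else:
            seen.add(key)
            kept.append(inst)
    return kept, report


def preprocess_record(
    record: SentenceRecord,
    split: str = "train",
    filter_train_positives: bool = False,
    synonym_map: Optional[dict[str, str]] = None,
) -> tuple[list[CandidateInstance], FilterReport]:
    """Full per-sentence pipeline: anonymize, mask numbers, generate and
    filter candidates."""
    tokens, index_map = anonymize(record)
    tokens = mask_numbers(tokens)
    candidates = generate_candidates(record, tokens, index_map)
    return filter_negatives(
        candidates,
        tokens,
        split=split,
        filter_train_positives=filter_train_positives,
        synonym_map=synonym_map,
    )


def preprocess_corpus(
    records: Iterable[SentenceRecord],
    split: str = "train",
    filter_train_positives: bool = False,
    synonym_map: Optional[dict[str, str]] = None,
) -> tuple[list[CandidateInstance], FilterReport]:
    """Preprocess a corpus: per-sentence pipeline then corpus-wide
    duplicate removal."""
    all_instances: list[CandidateInstance] = []
    report = FilterReport()
    for record in records:
        kept, rec_report = preprocess_record(
            record,
            split=split,
            filter_train_positives=filter_train_positives,
            synonym_map=synonym_map,
        )
        all_instances.extend(kept)
        report = report.merge(rec_report)
    deduped, dup_report = deduplicate(all_instances)
    return deduped, report.merge(dup_report)
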