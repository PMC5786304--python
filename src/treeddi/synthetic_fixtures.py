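"""Self-contained toy corpus generator.

Emits sentences with entity/pair annotations plus aligned binary parse
trees, with planted lexical signals per interaction class, so the whole
pipeline (preprocessing, features, model, evaluation) is testable without
external corpora, parsers or embedding files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .corpus_io import EntityMention, PairAnnotation, SentenceRecord

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "TEMPLATES",
    "SEPARABLE_TEMPLATES",
    "TRIGGER_WORDS",
    "SYNONYM_MAP",
    "generate_corpus",
    "make_separable",
    "right_branching_tree",
]

CLASSES = ("negative", "advice", "effect", "mechanism", "int")

# Slot A / slot B mark the two target drugs of the labeled pair.
_A, _B, _C = "<A>", "<B>", "<C>"

#: Class-indicative templates.  Trigger vocabulary is disjoint between
#: classes so a planted lexical signal always exists.
TEMPLATES: dict[str, list[list[str]]] = {
    "advice": [
        [_A, "should", "not", "be", "combined", "with", _B, "."],
        ["caution", "is", "advised", "when", _A, "is", "given", "with", _B, "."],
    ],
    "effect": [
        [_A, "enhanced", "the", "toxicity", "of", _B, "."],
        [_A, "potentiated", "the", "sedative", "action", "of", _B, "."],
    ],
    "mechanism": [
        [_A, "raised", "the", "plasma", "concentration", "of", _B, "."],
        [_A, "reduced", "the", "clearance", "of", _B, "."],
    ],
    "int": [
        [_A, "interacts", "with", _B, "."],
        ["an", "interaction", "between", _A, "and", _B, "was", "reported", "."],
    ],
    "negative": [
        [_A, "was", "measured", "while", _B, "remained", "stable", "."],
        ["patients", "received", _A, "before", _B, "therapy", "began", "."],
        [_A, "dosing", "was", "unrelated", "to", _B, "exposure", "."],
    ],
}

#: One deterministic template per class for the separable variant.
SEPARABLE_TEMPLATES: dict[str, list[list[str]]] = {
    cls: [templates[0]] for cls, templates in TEMPLATES.items()
}

TRIGGER_WORDS: dict[str, frozenset[str]] = {
    "advice": frozenset({"should", "combined", "caution", "advised"}),
    "effect": frozenset({"enhanced", "toxicity", "potentiated", "sedative"}),
    "mechanism": frozenset({"raised", "concentration", "reduced", "clearance"}),
    "int": frozenset({"interacts", "interaction"}),
    "negative": frozenset(
        {"measured", "stable", "received", "therapy", "unrelated", "exposure"}
    ),
}

#: Tiny synonym list for exercising the same-drug filtering hook.
SYNONYM_MAP = {"asa": "aspirin"}

_COORDINATION_TEMPLATE = [_A, ",", _B, ",", "and", _C, "were", "coadministered", "."]
_SAME_DRUG_TEMPLATE = [_A, "therapy", "was", "compared", "with", _B, "therapy", "."]

# Neutral adverbial suffixes keep anonymized sentences distinct (the
# deduplication key is the post-preprocessing token string).  ``<W>`` is
# a vocabulary filler word.
_W = "<W>"
_SUFFIXES = [
    ["in", "the", _W, "study", "."],
    ["according", "to", _W, "."],
    ["during", _W, "treatment", "."],
    ["as", "noted", "by", _W, "."],
]


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Everything that determines a generated corpus; the seed fixes the
    output byte-for-byte."""

    n_sentences: int = 100
    mixture: dict[str, float] = field(
        default_factory=lambda: {
            "negative": 0.5,
            "advice": 0.125,
            "effect": 0.125,
            "mechanism": 0.125,
            "int": 0.125,
        }
    )
    distractor_rate: float = 0.0
    coordination_rate: float = 0.0
    same_drug_rate: float = 0.0
    vocab_size: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_sentences <= 0:
            raise ConfigError("n_sentences must be positive")
        unknown = set(self.mixture) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown classes in mixture: {sorted(unknown)}")
        if any(p < 0 for p in self.mixture.values()):
            raise ConfigError("mixture probabilities must be non-negative")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mixture must sum to 1, got {total}")
        for name in ("distractor_rate", "coordination_rate", "same_drug_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.coordination_rate > 0 and self.mixture.get("negative", 0.0) == 0:
            raise ConfigError(
                "coordination runs are negative sentences; mixture assigns "
                "them zero probability"
            )
        if self.same_drug_rate > 0 and self.mixture.get("negative", 0.0) == 0:
            raise ConfigError(
                "same-drug sentences are negative; mixture assigns them "
                "zero probability"
            )
        if self.vocab_size < 4:
            raise ConfigError("vocab_size must be at least 4")


def right_branching_tree(tokens: list[str]) -> str:
    """Exact binary tree over a token list: right-branching spine."""
    if not tokens:
        raise ValueError("cannot build a tree over zero tokens")

    def rec(toks: list[str], label: str) -> str:
        if len(toks) == 1:
            return toks[0]
        return f"({label} {toks[0]} {rec(toks[1:], 'X')})"

    return rec(tokens, "S") if len(tokens) > 1 else f"(S {tokens[0]})"


def _fill(template: list[str], slots: dict[str, str]) -> tuple[list[str], dict[str, int]]:
    tokens: list[str] = []
    positions: dict[str, int] = {}
    for tok in template:
        if tok in slots:
            positions[tok] = len(tokens)
            tokens.append(slots[tok])
        else:
            tokens.append(tok)
    return tokens, positions


def _sentence_record(
    sid: str,
    tokens: list[str],
    drug_positions: list[tuple[str, int]],
    gold: dict[frozenset[str], tuple[bool, Optional[str]]],
) -> SentenceRecord:
    text = " ".join(tokens)
    starts = []
    cursor = 0
    for tok in tokens:
        starts.append(cursor)
        cursor += len(tok) + 1
    entities = []
    for n, (name, pos) in enumerate(drug_positions):
        start = starts[pos]
        entities.append(
            EntityMention(
                id=f"{sid}.e{n}",
                text=name,
                spans=((start, start + len(name)),),
                etype="drug",
            )
        )
    pairs = []
    for a in range(len(entities)):
        for b in range(a + 1, len(entities)):
            key = frozenset({f"e{a}", f"e{b}"})
            ddi, ddi_type = gold.get(key, (False, None))
            pairs.append(
                PairAnnotation(
                    id=f"{sid}.p{len(pairs)}",
                    e1=entities[a].id,
                    e2=entities[b].id,
                    ddi=ddi,
                    type=ddi_type,
                )
            )
    record = SentenceRecord(id=sid, text=text, entities=entities, pairs=pairs)
    record.validate()
    return record


def generate_corpus(
    config: GeneratorConfig,
    templates: Optional[dict[str, list[list[str]]]] = None,
) -> tuple[list[SentenceRecord], list[str]]:
    """Generate a corpus and its aligned binary parse trees.

    Returns one SentenceRecord and one bracketed tree string per
    sentence (same order).  Trees come straight from the template
    derivation, so leaf count always equals token count.
    """
    config.validate()
    templates = templates if templates is not None else TEMPLATES
    rng = np.random.default_rng(config.seed)
    class_names = list(CLASSES)
    probs = np.array([config.mixture.get(c, 0.0) for c in class_names])

    def draw_drug(exclude: set[str] = frozenset()) -> str:
        while True:
            name = f"DRUG{rng.integers(config.vocab_size * 5)}"
            if name not in exclude:
                return name

    records: list[SentenceRecord] = []
    trees: list[str] = []
    for n in range(config.n_sentences):
        sid = f"synth.s{n}"
        cls = class_names[rng.choice(len(class_names), p=probs)]
        if cls == "negative" and rng.random() < config.coordination_rate:
            a = draw_drug()
            b = draw_drug({a})
            c = draw_drug({a, b})
            tokens, pos = _fill(_COORDINATION_TEMPLATE, {_A: a, _B: b, _C: c})
            drug_positions = [(a, pos[_A]), (b, pos[_B]), (c, pos[_C])]
            gold: dict[frozenset[str], tuple[bool, Optional[str]]] = {}
        elif cls == "negative" and rng.random() < config.same_drug_rate:
            a = draw_drug()
            variant = a.capitalize()  # same surface modulo case -> rule 1
            tokens, pos = _fill(_SAME_DRUG_TEMPLATE, {_A: a, _B: variant})
            drug_positions = [(a, pos[_A]), (variant, pos[_B])]
            gold = {}
        else:
            template = templates[cls][rng.integers(len(templates[cls]))]
            a = draw_drug()
            b = draw_drug({a})
            tokens, pos = _fill(template, {_A: a, _B: b})
            drug_positions = [(a, pos[_A]), (b, pos[_B])]
            gold = {}
            if cls != "negative":
                gold[frozenset({"e0", "e1"})] = (True, cls)
            if rng.random() < config.distractor_rate:
                d = draw_drug({a, b})
                tokens = tokens[:-1] + ["in", "patients", "receiving", d, "."]
                drug_positions.append((d, len(tokens) - 2))
        suffix = _SUFFIXES[rng.integers(len(_SUFFIXES))]
        filler = f"w{rng.integers(config.vocab_size)}"
        tokens = tokens[:-1] + [filler if t == _W else t for t in suffix]
        drug_positions.sort(key=lambda item: item[1])
        records.append(_sentence_record(sid, tokens, drug_positions, gold))
        trees.append(right_branching_tree(tokens))
    return records, trees


def make_separable(config: GeneratorConfig) -> tuple[list[SentenceRecord], list[str]]:
    """Corpus variant with unique, deterministic class triggers and no
    filtering noise — guaranteed learnable from the planted signal."""
    clean = replace(
        config, distractor_rate=0.0, coordination_rate=0.0, same_drug_rate=0.0
    )
    return generate_corpus(clean, templates=SEPARABLE_TEMPLATES)
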