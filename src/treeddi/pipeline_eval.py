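"""One-stage / two-stage orchestration and micro-averaged evaluation.

Detection scores the positive class only (binary-task convention); type
classification pools TP/FP/FN over the four interaction types.  Gold
positives removed from the test set by filtering are charged as false
negatives through the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus_io import DDI_TYPES, CandidateInstance, SentenceRecord
from .features import EmbeddingTable, PositionCodec
from .model import (
    CompiledTree,
    TreeLSTMParams,
    compile_tree,
    ensemble_logits,
    predict,
    predict_logits,
)
from .parse_trees import annotate, binarize, read_bracketed
from .preprocessing import FilterReport, preprocess_corpus

__all__ = [
    "DETECTION_CLASSES",
    "TYPE_CLASSES",
    "FIVE_CLASSES",
    "EvalCounts",
    "PreparedDataset",
    "prepare_dataset",
    "run_one_stage",
    "run_two_stage",
    "collapse_detection",
    "evaluate",
    "micro_f1",
    "evaluation_report",
]

DETECTION_CLASSES = ("negative", "positive")
TYPE_CLASSES = DDI_TYPES
FIVE_CLASSES = ("negative",) + DDI_TYPES


@dataclass
class PreparedDataset:
    """Preprocessed instances with their compiled, annotated trees."""

    instances: list[CandidateInstance]
    trees: list[CompiledTree]
    report: FilterReport

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def ledger(self) -> list[str]:
        """Gold classes of the filtered-out test positives."""
        return [
            inst.five_class_label for inst in self.report.removed_positives
        ]

    def gold_labels(self, task: str = "five") -> list[str]:
        if task == "detection":
            return [inst.label for inst in self.instances]
        return [inst.five_class_label for inst in self.instances]

    def label_indices(self, task: str) -> list[int]:
        """Integer training labels: ``detection`` (2-class),
        ``type4`` (4-class, positives only) or ``five`` (one-stage)."""
        if task == "detection":
            return [DETECTION_CLASSES.index(i.label) for i in self.instances]
        if task == "type4":
            labels = []
            for inst in self.instances:
                if inst.ddi_type is None:
                    raise ValueError(
                        f"instance {inst.key} has no type; select positives "
                        "before building type4 labels"
                    )
                labels.append(TYPE_CLASSES.index(inst.ddi_type))
            return labels
        if task == "five":
            return [FIVE_CLASSES.index(i.five_class_label) for i in self.instances]
        raise ValueError(f"unknown task {task!r}")

    def positives(self) -> "PreparedDataset":
        """Subset of gold-positive instances (typer training data)."""
        pairs = [
            (inst, tree)
            for inst, tree in zip(self.instances, self.trees)
            if inst.label == "positive"
        ]
        return PreparedDataset(
            instances=[p[0] for p in pairs],
            trees=[p[1] for p in pairs],
            report=FilterReport(),
        )


def prepare_dataset(
    records: Sequence[SentenceRecord],
    tree_strs: Sequence[str],
    table: EmbeddingTable,
    split: str = "train",
    codec: Optional[PositionCodec] = None,
    filter_train_positives: bool = False,
    synonym_map: Optional[dict[str, str]] = None,
) -> PreparedDataset:
    """Run preprocessing and build one compiled tree per instance.

    ``tree_strs`` holds one bracketed parse per sentence, aligned with
    ``records``; each candidate pair re-annotates the sentence tree with
    its own targets before input assembly.
    """
    if len(records) != len(tree_strs):
        raise ValueError("records and trees must align one-to-one")
    codec = codec or PositionCodec()
    tree_by_sentence = {rec.id: s for rec, s in zip(records, tree_strs)}
    instances, report = preprocess_corpus(
        records,
        split=split,
        filter_train_positives=filter_train_positives,
        synonym_map=synonym_map,
    )
    trees: list[CompiledTree] = []
    for inst in instances:
        root = binarize(read_bracketed(tree_by_sentence[inst.sentence_id]))
        annotate(root, inst.tokens, inst.target1, inst.target2, inst.sentence_id)
        trees.append(compile_tree(root, table, codec, tree_key=inst.key))
    return PreparedDataset(instances=instances, trees=trees, report=report)


def _models_logits(
    models: TreeLSTMParams | Sequence[TreeLSTMParams], tree: CompiledTree
) -> np.ndarray:
    if isinstance(models, TreeLSTMParams):
        return predict_logits(models, tree)
    return ensemble_logits(models, tree)


def run_one_stage(
    model5: TreeLSTMParams | Sequence[TreeLSTMParams],
    trees: Sequence[CompiledTree],
) -> list[str]:
    """Single five-class pass: each instance gets one of FIVE_CLASSES."""
    n_classes = (model5 if isinstance(model5, TreeLSTMParams) else model5[0]).n_classes
    if n_classes != len(FIVE_CLASSES):
        raise ValueError(f"one-stage model must have {len(FIVE_CLASSES)} classes")
    return [FIVE_CLASSES[predict(_models_logits(model5, tree))] for tree in trees]


def run_two_stage(
    detector: TreeLSTMParams | Sequence[TreeLSTMParams],
    typer: TreeLSTMParams | Sequence[TreeLSTMParams],
    trees: Sequence[CompiledTree],
) -> list[str]:
    """Detection first; only predicted positives are re-scored by the
    4-class typer.  Detection false negatives never reach the typer, so
    they surface as type-classification errors."""
    det_classes = (
        detector if isinstance(detector, TreeLSTMParams) else detector[0]
    ).n_classes
    typ_classes = (typer if isinstance(typer, TreeLSTMParams) else typer[0]).n_classes
    if det_classes != 2:
        raise ValueError("two-stage detector must be binary")
    if typ_classes != len(TYPE_CLASSES):
        raise ValueError(f"two-stage typer must have {len(TYPE_CLASSES)} classes")
    predictions = []
    for tree in trees:
        if predict(_models_logits(detector, tree)) == 0:
            predictions.append("negative")
        else:
            predictions.append(TYPE_CLASSES[predict(_models_logits(typer, tree))])
    return predictions


def collapse_detection(labels: Iterable[str]) -> list[str]:
    """Map 5-class / typed labels onto the binary detection task."""
    return ["negative" if lab == "negative" else "positive" for lab in labels]


@dataclass
class EvalCounts:
    """Pooled confusion tallies per scored class plus ledger-injected
    false negatives."""

    tp: dict[str, int] = field(default_factory=dict)
    fp: dict[str, int] = field(default_factory=dict)
    fn: dict[str, int] = field(default_factory=dict)
    ledger_fn: dict[str, int] = field(default_factory=dict)

    def classes(self) -> list[str]:
        keys = set(self.tp) | set(self.fp) | set(self.fn) | set(self.ledger_fn)
        return sorted(keys)

    @property
    def total_tp(self) -> int:
        return sum(self.tp.values())

    @property
    def total_fp(self) -> int:
        return sum(self.fp.values())

    @property
    def total_fn(self) -> int:
        return sum(self.fn.values()) + sum(self.ledger_fn.values())


def evaluate(
    predictions: Sequence[str],
    gold: Sequence[str],
    ledger: Sequence[str] = (),
    negative_label: str = "negative",
) -> EvalCounts:
    """Pool per-class confusion counts over aligned predictions and gold
    labels.

    ``ledger`` lists the gold class of every filtered-out test positive;
    each entry adds one false negative to its class.  The negative class
    is never scored.
    """
    if len(predictions) != len(gold):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(gold)} gold labels"
        )
    counts = EvalCounts()

    def bump(table: dict[str, int], key: str) -> None:
        table[key] = table.get(key, 0) + 1

    for pred, true in zip(predictions, gold):
        if pred == true:
            if pred != negative_label:
                bump(counts.tp, pred)
        else:
            if pred != negative_label:
                bump(counts.fp, pred)
            if true != negative_label:
                bump(counts.fn, true)
    for cls in ledger:
        if cls == negative_label:
            raise ValueError("ledger entries must be gold positives")
        bump(counts.ledger_fn, cls)
    return counts


def micro_f1(counts: EvalCounts) -> tuple[float, float, float]:
    """Micro-averaged precision, recall and F1 over the scored classes
    (0/0 -> 0 by convention); ledger entries count as false negatives."""
    tp, fp, fn = counts.total_tp, counts.total_fp, counts.total_fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluation_report(
    predictions: Sequence[str],
    gold: Sequence[str],
    ledger: Sequence[str] = (),
) -> dict:
    """Detection and type tables in one JSON-serializable report.

    Typed predictions are collapsed onto {negative, positive} for the
    detection table; the type table scores strict label match over the
    four interaction types.
    """
    det_counts = evaluate(
        collapse_detection(predictions),
        collapse_detection(gold),
        ledger=collapse_detection(ledger) if ledger else (),
    )
    det_p, det_r, det_f = micro_f1(det_counts)
    report = {
        "detection": {
            "precision": det_p,
            "recall": det_r,
            "f1": det_f,
            "tp": det_counts.total_tp,
            "fp": det_counts.total_fp,
            "fn": det_counts.total_fn,
        }
    }
    if any(lab in TYPE_CLASSES for lab in list(gold) + list(ledger)):
        type_counts = evaluate(predictions, gold, ledger=ledger)
        typ_p, typ_r, typ_f = micro_f1(type_counts)
        report["type"] = {
            "precision": typ_p,
            "recall": typ_r,
            "f1": typ_f,
            "per_class": {
                cls: {
                    "tp": type_counts.tp.get(cls, 0),
                    "fp": type_counts.fp.get(cls, 0),
                    "fn": type_counts.fn.get(cls, 0)
                    + type_counts.ledger_fn.get(cls, 0),
                }
                for cls in TYPE_CLASSES
            },
        }
    return report


def format_report(report: dict) -> str:
    lines = ["task       P        R        F1      TP    FP    FN"]
    for task in ("detection", "type"):
        if task not in report:
            continue
        r = report[task]
        lines.append(
            f"{task:<10} {r['precision']:<8.4f} {r['recall']:<8.4f} "
            f"{r['f1']:<8.4f} {r['tp']:<5} {r['fp']:<5} {r['fn']:<5}"
            if "tp" in r
            else f"{task:<10} {r['precision']:<8.4f} {r['recall']:<8.4f} {r['f1']:<8.4f}"
        )
    return "\n".join(lines)
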