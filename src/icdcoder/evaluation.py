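"""Multi-label evaluation: micro precision/recall/F1 and recall@K.

Micro scores pool true/false positives and false negatives over all
notes and labels before forming precision and recall, which keeps the
metric meaningful under the heavily imbalanced label frequencies of
ICD coding.  recall@K measures, over the corpus, what fraction of gold
codes appear among each note's K highest-ranked predictions — the
quantity that matters when the system shows a coder a short candidate
list (K defaults to 20).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    micro_precision: float
    micro_recall: float
    micro_f1: float
    tp: int
    fp: int
    fn: int
    recall_at_k: float | None = None
    k: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def table(self) -> str:
        rows = [
            ("micro precision", f"{self.micro_precision:.4f}"),
            ("micro recall", f"{self.micro_recall:.4f}"),
            ("micro F1", f"{self.micro_f1:.4f}"),
            ("TP / FP / FN", f"{self.tp} / {self.fp} / {self.fn}"),
        ]
        if self.recall_at_k is not None:
            rows.append((f"recall@{self.k}", f"{self.recall_at_k:.4f}"))
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val}" for name, val in rows)


def micro_scores(
    predicted: Sequence[set[str]], gold: Sequence[set[str]]
) -> EvalReport:
    """Pooled TP/FP/FN over all notes; P, R, F1 with the 0/0 -> 0 convention."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold lists differ in length")
    tp = fp = fn = 0
    for p, g in zip(predicted, gold):
        p, g = set(p), set(g)
        tp += len(p & g)
        fp += len(p - g)
        fn += len(g - p)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(precision, recall, f1, tp, fp, fn)


def recall_at_k(
    ranked: Sequence[Sequence[str]],
    gold: Sequence[set[str]],
    k: int = 20,
    aggregation: str = "micro",
) -> float:
    """Fraction of gold codes found in the top-K ranked predictions.

    ``micro`` (default) pools hits and gold counts over notes:
    sum_i |gold_i ∩ topK_i| / sum_i |gold_i|.  ``macro`` averages the
    per-note fraction instead.  Notes with an empty gold set carry no
    information and are excluded (with a warning).
    """
    if len(ranked) != len(gold):
        raise ValueError("ranked and gold lists differ in length")
    if k < 1:
        raise ValueError("k must be >= 1")
    if aggregation not in ("micro", "macro"):
        raise ValueError("aggregation must be 'micro' or 'macro'")
    hits = total = 0
    fractions: list[float] = []
    skipped = 0
    for r, g in zip(ranked, gold):
        g = set(g)
        if not g:
            skipped += 1
            continue
        h = len(g & set(r[:k]))
        hits += h
        total += len(g)
        fractions.append(h / len(g))
    if skipped:
        logger.warning("recall_at_k: excluded %d notes with empty gold sets", skipped)
    if total == 0:
        return 0.0
    if aggregation == "micro":
        return hits / total
    return sum(fractions) / len(fractions)


def evaluate_model(
    model, notes, k: int = 20, tau: float = 0.5, rules=None
) -> EvalReport:
    """Score a classifier on labeled notes.

    Composes forward -> threshold decode -> micro scores and
    forward -> top-K ranking -> recall@K into one report.  Optional
    postprocessing rules are applied to the decoded code sets before
    scoring.
    """
    from icdcoder.classifier import rank_top_k, threshold_decode
    from icdcoder.postprocess import apply_rules

    gold = [n.gold_codes for n in notes]
    probs = model.predict_proba(notes)
    decoded = [threshold_decode(p, model.label_space, tau) for p in probs]
    if rules:
        decoded = [apply_rules(c, rules) for c in decoded]
    ranked = [rank_top_k(p, model.label_space, k) for p in probs]
    report = micro_scores(decoded, gold)
    report.recall_at_k = recall_at_k(ranked, gold, k)
    report.k = k
    return report
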