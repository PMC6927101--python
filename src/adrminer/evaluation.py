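"""Mention-level and PT-level (micro/macro) precision, recall and F1.

Mention scoring uses exact matching: a prediction is a true positive iff
its section, full span set and type all equal those of a distinct gold
mention (one-to-one).  Normalization scoring compares per-label distinct
PT sets: micro pools (label, pt) pairs over all labels, macro averages
per-label scores arithmetically.

Degenerate conventions: precision is 0 with no predictions, recall is 0
with no gold, F1 is 0 when p + r = 0; a label with empty gold *and* empty
predicted PT sets scores (1, 1, 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from adrminer.label_io import Mention


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float

    def as_percent(self) -> tuple[float, float, float]:
        return (
            round(100 * self.precision, 1),
            round(100 * self.recall, 1),
            round(100 * self.f1, 1),
        )


def _prf(tp: int, n_pred: int, n_gold: int) -> PRF:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return PRF(p, r, f1)


def _mention_key(m: Mention) -> tuple:
    return (m.section_id, tuple(m.spans), m.type)


def score_mentions(gold: list[Mention], pred: list[Mention]) -> PRF:
    """Exact-match mention P/R/F1 with one-to-one matching."""
    gold_counts = Counter(_mention_key(m) for m in gold)
    pred_counts = Counter(_mention_key(m) for m in pred)
    tp = sum(min(gold_counts[k], pred_counts[k]) for k in gold_counts)
    return _prf(tp, len(pred), len(gold))


def score_normalization(
    gold_pt_sets: dict[str, set], pred_pt_sets: dict[str, set]
) -> tuple[PRF, PRF]:
    """(micro, macro) P/R/F1 over per-label PT sets."""
    if set(gold_pt_sets) != set(pred_pt_sets):
        missing = set(gold_pt_sets) ^ set(pred_pt_sets)
        raise ValueError(f"gold/pred label keys differ: {sorted(missing)!r}")
    tp = n_pred = n_gold = 0
    per_label: list[PRF] = []
    for key in gold_pt_sets:
        g, p = set(gold_pt_sets[key]), set(pred_pt_sets[key])
        tp += len(g & p)
        n_pred += len(p)
        n_gold += len(g)
        if not g and not p:
            per_label.append(PRF(1.0, 1.0, 1.0))
        else:
            per_label.append(_prf(len(g & p), len(p), len(g)))
    micro = _prf(tp, n_pred, n_gold)
    n = len(per_label)
    if n == 0:
        macro = PRF(1.0, 1.0, 1.0)
    else:
        macro = PRF(
            sum(x.precision for x in per_label) / n,
            sum(x.recall for x in per_label) / n,
            sum(x.f1 for x in per_label) / n,
        )
    return micro, macro


@dataclass
class EvalReport:
    """Aggregate report mirroring the mention / micro / macro layout."""

    mention: PRF
    norm_micro: PRF
    norm_macro: PRF
    per_label: dict[str, PRF] = field(default_factory=dict)

    def to_dict(self, percent: bool = True) -> dict:
        def fmt(prf: PRF) -> dict:
            p, r, f1 = prf.as_percent() if percent else (
                prf.precision,
                prf.recall,
                prf.f1,
            )
            return {"precision": p, "recall": r, "f1": f1}

        return {
            "identification": fmt(self.mention),
            "normalization": {
                "micro": fmt(self.norm_micro),
                "macro": fmt(self.norm_macro),
            },
            "per_label": {k: fmt(v) for k, v in sorted(self.per_label.items())},
        }


def evaluate_labels(
    gold_mentions: dict[str, list[Mention]],
    pred_mentions: dict[str, list[Mention]],
    gold_pt_sets: dict[str, set],
    pred_pt_sets: dict[str, set],
) -> EvalReport:
    """Full report: pooled mention scores plus micro/macro PT scores."""
    if set(gold_mentions) != set(pred_mentions):
        raise ValueError("gold/pred mention label keys differ")
    # keys must stay distinct across labels when pooling
    pooled_gold, pooled_pred = [], []
    for key in gold_mentions:
        for m in gold_mentions[key]:
            pooled_gold.append((key, _mention_key(m)))
        for m in pred_mentions[key]:
            pooled_pred.append((key, _mention_key(m)))
    gold_counts = Counter(pooled_gold)
    pred_counts = Counter(pooled_pred)
    tp = sum(min(gold_counts[k], pred_counts[k]) for k in gold_counts)
    mention = _prf(tp, len(pooled_pred), len(pooled_gold))
    micro, macro = score_normalization(gold_pt_sets, pred_pt_sets)
    per_label = {}
    for key in gold_pt_sets:
        g, p = set(gold_pt_sets[key]), set(pred_pt_sets[key])
        per_label[key] = (
            PRF(1.0, 1.0, 1.0) if not g and not p else _prf(len(g & p), len(p), len(g))
        )
    return EvalReport(mention=mention, norm_micro=micro, norm_macro=macro, per_label=per_label)
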