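"""Accuracy assessment for classification maps.

Confusion matrix over the nonzero-truth pixels, producer's per-class
accuracy (row-normalized), overall accuracy, and Cohen's kappa
``(p_o - p_e) / (1 - p_e)`` — the standard remote-sensing agreement
summary, chance-corrected by the row/column marginal product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_hsi import LabelMap


@dataclass
class ConfusionMatrix:
    """Truth-class x predicted-class counts over evaluated pixels."""

    counts: np.ndarray
    codes: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.codes):
            raise ValueError("one code per row/column required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        header = "truth\\pred," + ",".join(str(c) for c in self.codes)
        lines = [header]
        for code, row in zip(self.codes, self.counts):
            lines.append(f"{code}," + ",".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def confusion(truth: LabelMap, pred: LabelMap, codes: list[int] | None = None) -> ConfusionMatrix:
    """Count truth-vs-prediction agreement; truth code 0 is excluded."""
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape}, pred {pred.shape}")
    t = truth.labels.ravel()
    p = pred.labels.ravel()
    mask = t != 0
    t, p = t[mask], p[mask]
    if codes is None:
        # include a predicted 0 (fill/unclassified) column if one occurs on
        # evaluated pixels so the total stays exact
        codes = sorted({int(c) for c in np.unique(t)} | {int(c) for c in np.unique(p)})
    index = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((len(codes), len(codes)), dtype=np.int64)
    for ti, pi in zip(t, p):
        counts[index[int(ti)], index[int(pi)]] += 1
    return ConfusionMatrix(counts=counts, codes=list(codes))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of evaluated pixels on the diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def per_class_accuracy(cm: ConfusionMatrix) -> dict[int, float]:
    """Producer's accuracy per class: 100 * diagonal / row total."""
    row_totals = cm.counts.sum(axis=1)
    out: dict[int, float] = {}
    for i, code in enumerate(cm.codes):
        if row_totals[i] == 0:
            raise ValueError(f"class {code} has no truth pixels")
        out[code] = 100.0 * float(cm.counts[i, i]) / float(row_totals[i])
    return out


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa, (p_o - p_e)/(1 - p_e); 1 for a perfect single-cell map."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / total
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    p_e = float(rows @ cols) / total**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def metrics_report(cm: ConfusionMatrix) -> dict:
    """All Table-style metrics in one machine-readable dict."""
    return {
        "overall_accuracy_pct": overall_accuracy(cm),
        "kappa": kappa(cm),
        "per_class_accuracy_pct": {str(k): v for k, v in per_class_accuracy(cm).items()},
        "n_pixels": cm.total,
    }


def write_metrics_json(report: dict, path: str | Path) -> None:
    """Deterministic JSON (sorted keys) so identical runs are byte-identical."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


def summarize_repeats(reports: list[dict]) -> dict:
    """Mean and sample standard deviation over repeated runs.

    Emulates the "mean +/- std" presentation of repeated-draw experiments;
    std uses ddof=1 (0.0 reported for a single run).
    """
    if not reports:
        raise ValueError("no reports to summarize")
    oa = np.array([r["overall_accuracy_pct"] for r in reports], dtype=float)
    kap = np.array([r["kappa"] for r in reports], dtype=float)

    def _std(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    out = {
        "n_runs": len(reports),
        "overall_accuracy_pct_mean": float(oa.mean()),
        "overall_accuracy_pct_std": _std(oa),
        "kappa_mean": float(kap.mean()),
        "kappa_std": _std(kap),
    }
    class_keys = sorted(reports[0].get("per_class_accuracy_pct", {}))
    if class_keys:
        per_class = {}
        for key in class_keys:
            vals = np.array([r["per_class_accuracy_pct"][key] for r in reports])
            per_class[key] = {"mean": float(vals.mean()), "std": _std(vals)}
        out["per_class_accuracy_pct"] = per_class
    return out
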