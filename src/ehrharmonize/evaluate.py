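"""Metrics, ROC curves, and missingness-stratified method comparison.

AUC is the area under the ROC curve (trapezoidal integration, via
scikit-learn); F1, precision and recall are computed at a fixed probability
threshold (default 0.5).  For the stratified view, test patients are split
by the fraction of missing six-month intervals: under 50% versus 50% and
above (the boundary value K/2 is assigned to the "more missing" stratum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import train_test_split

from .models import ModelConfig, predict_proba, train
from .records import HarmonizedSequence


@dataclass
class MetricSet:
    auc: float
    f1: float
    precision: float
    recall: float
    n: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class EvalReport:
    method: str
    arch: str
    overall: MetricSet
    strata: dict[str, Optional[MetricSet]] = field(default_factory=dict)


def compute_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> MetricSet:
    """AUC (trapezoidal ROC) plus thresholded F1 / precision / recall."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute metrics")
    preds = (scores >= threshold).astype(int)
    fpr, tpr, _ = roc_curve(labels, scores)
    return MetricSet(
        auc=float(roc_auc_score(labels, scores)),
        f1=float(f1_score(labels, preds, zero_division=0)),
        precision=float(precision_score(labels, preds, zero_division=0)),
        recall=float(recall_score(labels, preds, zero_division=0)),
        n=len(labels),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )


def stratify_by_missingness(
    missing_fractions: Sequence[float], cutoff: float = 0.5
) -> dict[str, np.ndarray]:
    """Exhaustive, disjoint partition of indices by missingness fraction.

    ``lt50``: fraction < cutoff; ``ge50``: fraction >= cutoff (the exact
    boundary goes to the more-missing stratum).
    """
    fr = np.asarray(missing_fractions, dtype=float)
    return {
        "lt50": np.flatnonzero(fr < cutoff),
        "ge50": np.flatnonzero(fr >= cutoff),
    }


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    missing_fractions: Optional[Sequence[float]] = None,
    method: str = "",
    arch: str = "",
    threshold: float = 0.5,
) -> EvalReport:
    """Overall + per-stratum metrics; a one-class stratum reports None."""
    overall = compute_metrics(scores, labels, threshold)
    strata: dict[str, Optional[MetricSet]] = {}
    if missing_fractions is not None:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        for name, idx in stratify_by_missingness(missing_fractions).items():
            if len(idx) and len(np.unique(labels[idx])) == 2:
                strata[name] = compute_metrics(scores[idx], labels[idx], threshold)
            else:
                strata[name] = None
    return EvalReport(method, arch, overall, strata)


def compare_methods(
    sequences_by_method: dict[str, list[HarmonizedSequence]],
    labels: Sequence[int],
    archs: Sequence[str],
    split_seed: int = 0,
    test_size: float = 0.2,
    model_config: Optional[ModelConfig] = None,
    threshold: float = 0.5,
    missing_fractions: Optional[Sequence[float]] = None,
) -> tuple[list[EvalReport], pd.DataFrame]:
    """Train and evaluate every method x architecture cell.

    A single stratified train/test split (by label, seeded) is shared across
    all cells so the comparison is paired.  ``missing_fractions`` overrides
    the per-sequence missingness used for stratification (so all methods can
    be stratified by the same interval-grid missingness regardless of their
    sequence shape).  Returns the reports plus a tidy DataFrame with one row
    per cell.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    idx_train, idx_test = train_test_split(
        np.arange(n), test_size=test_size, random_state=split_seed,
        stratify=labels,
    )
    reports: list[EvalReport] = []
    rows = []
    for method, seqs in sequences_by_method.items():
        if len(seqs) != n:
            raise ValueError(f"method {method!r}: {len(seqs)} sequences for {n} labels")
        if missing_fractions is not None:
            fr_test = [missing_fractions[i] for i in idx_test]
        else:
            fr_test = [seqs[i].missing_fraction for i in idx_test]
        for arch in archs:
            base = model_config or ModelConfig(arch=arch, input_dim=seqs[0].vectors.shape[1])
            cfg = ModelConfig(**{**base.__dict__, "arch": arch,
                                 "input_dim": seqs[0].vectors.shape[1]})
            model = train([seqs[i] for i in idx_train], labels[idx_train], cfg)
            scores = predict_proba(model, [seqs[i] for i in idx_test])
            report = evaluate_scores(
                scores, labels[idx_test], fr_test, method, arch, threshold
            )
            reports.append(report)
            row = {
                "method": method, "arch": arch,
                "auc": report.overall.auc, "f1": report.overall.f1,
                "precision": report.overall.precision,
                "recall": report.overall.recall, "n_test": report.overall.n,
            }
            for name, ms in report.strata.items():
                row[f"auc_{name}"] = ms.auc if ms else np.nan
                row[f"f1_{name}"] = ms.f1 if ms else np.nan
                row[f"n_{name}"] = ms.n if ms else 0
            rows.append(row)
    return reports, pd.DataFrame(rows)


def plot_roc(reports: Sequence[EvalReport], path) -> None:
    """Render one ROC curve per method x architecture cell to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for r in reports:
        pts = np.asarray(r.overall.roc_points)
        ax.plot(pts[:, 0], pts[:, 1],
                label=f"{r.method} / {r.arch} (AUC {r.overall.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.6)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
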