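"""Diagnostic-accuracy metrics and report rendering.

All headline metrics derive from a per-patient 2×2 confusion matrix
with cancer as the positive class.  AUC is computed as the
Mann–Whitney concordance probability (ties counted ½), which equals
the trapezoidal area under the empirical ROC curve and is invariant
under strictly monotone transforms of the score.

Percentages are formatted by rounding half-up to one decimal, the
convention used when such studies print e.g. 83.3% / 87.0%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CANCER
from .errors import UsageError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Per-patient counts; cancer is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise UsageError("confusion-matrix counts must be ≥ 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(
        cls, truth: Sequence[str], predicted: Sequence[str], positive: str = CANCER
    ) -> "ConfusionMatrix":
        if len(truth) != len(predicted):
            raise UsageError("truth and predicted labels differ in length")
        t = np.asarray([x == positive for x in truth])
        p = np.asarray([x == positive for x in predicted])
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
            fn=int(np.sum(t & ~p)),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def sens_spec(cm: ConfusionMatrix) -> tuple[float | None, float | None]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) as proportions.

    A member whose denominator is zero is returned as ``None``
    (missing), never imputed as 0.
    """
    if cm.n == 0:
        raise UsageError("cannot compute metrics on an all-zero confusion matrix")
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return sens, spec


def format_percent(proportion: float, decimals: int = 1) -> str:
    """Half-up percentage formatting: 0.8696 → '87.0'."""
    q = Decimal(10) ** -decimals
    return str((Decimal(repr(proportion)) * 100).quantize(q, rounding=ROUND_HALF_UP))


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e).

    p_o is the observed accuracy; p_e the agreement expected from the
    marginal label frequencies.  When the margins are degenerate
    (p_e = 1, which forces p_o = 1), κ is defined as 1.
    """
    n = cm.n
    if n == 0:
        raise UsageError("cannot compute kappa on an empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = (
        (cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)
    ) / (n * n)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def roc_auc(
    scores: Sequence[float], labels: Sequence[str], positive: str = CANCER
) -> tuple[np.ndarray, float]:
    """Empirical ROC curve and Mann–Whitney AUC.

    Returns ``(points, auc)`` where ``points`` is an array of
    (false-positive rate, true-positive rate) pairs along decreasing
    score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    is_pos = np.asarray([l == positive for l in labels])
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UsageError("ROC requires both classes present")
    ranks = rankdata(scores)  # average ranks ⇒ ties count ½
    auc = (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(is_pos[order])
    fps = np.cumsum(~is_pos[order])
    # collapse threshold ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    points = np.column_stack(
        [np.r_[0.0, fps[distinct] / n_neg], np.r_[0.0, tps[distinct] / n_pos]]
    )
    return points, float(auc)


METRIC_NAMES = ("sensitivity", "specificity", "auc", "kappa")


@dataclass
class DiagnosticSummary:
    """Per-iteration metric vectors with their means and dispersions."""

    per_iteration: dict[str, list[float | None]]
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    n_iterations: int

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "per_iteration": self.per_iteration,
            "mean": self.mean,
            "sd": self.sd,
        }


def summarize_iterations(
    iteration_metrics: Sequence[dict[str, float | None]]
) -> DiagnosticSummary:
    """Aggregate per-iteration metric dicts into means and SDs.

    Missing (``None``) values are excluded from the aggregates for
    that metric but preserved in the per-iteration record.  SD uses
    ddof=1 (0 for a single iteration).
    """
    if not iteration_metrics:
        raise UsageError("summarize_iterations needs at least one iteration")
    per_iteration: dict[str, list[float | None]] = {m: [] for m in METRIC_NAMES}
    for it in iteration_metrics:
        for m in METRIC_NAMES:
            per_iteration[m].append(it.get(m))
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    for m, values in per_iteration.items():
        present = np.asarray([v for v in values if v is not None], dtype=float)
        if present.size == 0:
            mean[m], sd[m] = None, None
        else:
            mean[m] = float(present.mean())
            sd[m] = float(present.std(ddof=1)) if present.size > 1 else 0.0
    return DiagnosticSummary(
        per_iteration=per_iteration,
        mean=mean,
        sd=sd,
        n_iterations=len(iteration_metrics),
    )


def render_report(
    summary: DiagnosticSummary,
    confusion: ConfusionMatrix,
    out_dir: str | Path,
    *,
    roc_points: np.ndarray | None = None,
    auc: float | None = None,
    cohort: str = "cohort",
    n_cancer: int | None = None,
    n_patients: int | None = None,
) -> dict[str, Path]:
    """Write the report artifact set: confusion figure, ROC figure, metrics table.

    Returns a name → path mapping of everything written.  Figures use a
    non-interactive backend; numbers in the JSON/CSV equal the summary
    to full precision.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    fig, ax = plt.subplots(figsize=(4, 4))
    counts = np.array([[confusion.tp, confusion.fn], [confusion.fp, confusion.tn]])
    ax.imshow(counts, cmap="Blues")
    for (i, j), v in np.ndenumerate(counts):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["cancer", "non-cancer"])
    ax.set_yticks([0, 1], ["cancer", "non-cancer"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title("Per-patient confusion matrix")
    fig.tight_layout()
    written["confusion_figure"] = out_dir / "confusion_matrix.png"
    fig.savefig(written["confusion_figure"], dpi=150)
    plt.close(fig)

    if roc_points is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(roc_points[:, 0], roc_points[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        label = f"AUC = {auc:.3f}" if auc is not None else "ROC"
        ax.set_xlabel("1 − specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(label)
        fig.tight_layout()
        written["roc_figure"] = out_dir / "roc_curve.png"
        fig.savefig(written["roc_figure"], dpi=150)
        plt.close(fig)

    payload = {
        "cohort": cohort,
        "n_patients": n_patients if n_patients is not None else confusion.n,
        "n_cancer": n_cancer if n_cancer is not None else confusion.tp + confusion.fn,
        "confusion": {
            "tp": confusion.tp,
            "fp": confusion.fp,
            "tn": confusion.tn,
            "fn": confusion.fn,
        },
        **summary.to_dict(),
    }
    written["metrics_json"] = out_dir / "metrics.json"
    written["metrics_json"].write_text(json.dumps(payload, indent=2))
    rows = pd.DataFrame(summary.per_iteration)
    rows.insert(0, "iteration", np.arange(len(rows)))
    written["metrics_csv"] = out_dir / "metrics.csv"
    rows.to_csv(written["metrics_csv"], index=False)
    return written
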