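"""Model evaluation: ranking metrics, cutoff selection, grid and ablation.

ROC-AUC is the headline metric — the probability that a random active
outranks a random inactive, with ties counting one half.  Threshold
metrics (accuracy, precision, recall, F1, false-positive rate) use a
strict positive rule (score > cutoff), matching the tri-level call
convention.  The balanced-accuracy cutoff scan mirrors how screening
tools are compared: pick the ROC operating point maximizing
(sensitivity + specificity) / 2.

Two study-design utilities are included: the train-fraction ×
oversampling grid that maps how performance responds to training size
and augmentation, and the descriptor ablation (protein-only P,
ligand-only L, combined P+L) that shows the protein block only pays off
in combination with ligand features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .dataset import PCMExample, SplitSpec, features_labels, split
from .ligfeat import Compound, DescriptorManifest
from .model import (
    AugmentationConfig,
    MLPConfig,
    PCMModel,
    RFConfig,
    fit_mlp,
    fit_rf,
)
from .seqsim import AlignmentParams, DEFAULT_PARAMS, ProteinSequence, ReferencePanel


class EvaluationError(ValueError):
    pass


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise EvaluationError("labels and scores must be 1-D and equal length")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes must be present")
    return y, s


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (Mann–Whitney concordance, ties ½)."""
    y, s = _validate(labels, scores)
    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class MetricReport:
    """Threshold-based classification metrics at a fixed cutoff."""

    roc_auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    fpr: float
    cutoff_used: float
    n_pos: int
    n_neg: int
    degenerate: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "fpr": self.fpr,
            "cutoff_used": self.cutoff_used,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "degenerate": ",".join(self.degenerate),
        }


def classification_metrics(
    labels: Sequence[int], scores: Sequence[float], cutoff: float = 0.5
) -> MetricReport:
    """Confusion-matrix metrics with the strict positive rule score > cutoff.

    Ratios with a zero denominator (e.g. precision with no positive calls)
    are reported as 0 and flagged in ``degenerate``.
    """
    y, s = _validate(labels, scores)
    pred = (s > cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    degenerate: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    fpr = ratio(fp, fp + tn, "fpr")
    accuracy = (tp + tn) / len(y)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    if precision + recall == 0:
        degenerate.append("f1")
    return MetricReport(
        roc_auc=roc_auc(y, s),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        fpr=fpr,
        cutoff_used=cutoff,
        n_pos=int(np.sum(y == 1)),
        n_neg=int(np.sum(y == 0)),
        degenerate=tuple(degenerate),
    )


def best_balanced_accuracy_cutoff(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[float, float]:
    """Cutoff maximizing balanced accuracy (TPR + TNR) / 2.

    Candidates are the midpoints between consecutive distinct sorted
    scores plus the endpoints 0 and 1 — a finite, exhaustive scan of every
    distinct operating point.  Ties return the smallest qualifying cutoff.
    """
    y, s = _validate(labels, scores)
    distinct = np.unique(s)
    candidates = np.concatenate(([0.0], (distinct[:-1] + distinct[1:]) / 2, [1.0]))
    n_pos = np.sum(y == 1)
    n_neg = np.sum(y == 0)
    best_cut, best_ba = 0.0, -1.0
    for c in candidates:
        pred = s > c
        tpr = np.sum(pred & (y == 1)) / n_pos
        tnr = np.sum(~pred & (y == 0)) / n_neg
        ba = (tpr + tnr) / 2
        if ba > best_ba + 1e-12:
            best_cut, best_ba = float(c), float(ba)
    return best_cut, best_ba


def evaluate_model(
    model: PCMModel, examples: Sequence[PCMExample], cutoff: float = 0.5
) -> MetricReport:
    """Score held-out examples with a fitted model and report metrics."""
    X, y = features_labels(examples)
    return classification_metrics(y, model.score_matrix(X), cutoff)


AblationMode = Literal["P", "L", "P+L"]


def restrict_features(
    examples: Sequence[PCMExample], mode: AblationMode, panel_size: int
) -> list[PCMExample]:
    """Slice each feature vector to the requested descriptor block(s)."""
    if mode == "P+L":
        return list(examples)
    if mode not in ("P", "L"):
        raise EvaluationError(f"unknown ablation mode {mode!r}")
    out = []
    for e in examples:
        feat = e.feature[:panel_size] if mode == "P" else e.feature[panel_size:]
        out.append(PCMExample(feat, e.label, e.compound_id, e.target_id, e.origin))
    return out


def _fit(train, learner, learner_cfg, aug, panel, manifest, params):
    if learner == "rf":
        cfg = learner_cfg or RFConfig()
        return fit_rf(train, cfg, aug, panel, manifest, params)
    if learner == "mlp":
        cfg = learner_cfg or MLPConfig()
        return fit_mlp(train, cfg, aug, panel, manifest, params)
    raise EvaluationError(f"unknown learner {learner!r}")


def ablation(
    examples: Sequence[PCMExample],
    mode: AblationMode,
    panel: ReferencePanel,
    manifest: DescriptorManifest,
    split_spec: SplitSpec | None = None,
    aug: AugmentationConfig | None = None,
    learner: str = "rf",
    learner_cfg=None,
    params: AlignmentParams = DEFAULT_PARAMS,
    holdout: Sequence[PCMExample] | None = None,
) -> MetricReport:
    """Fit and evaluate with features restricted to one descriptor block.

    P keeps only the protein-similarity block (30-D), L only the ligand
    block (187-D), P+L both.  Evaluates on an internal split by default,
    or on ``holdout`` if given.
    """
    split_spec = split_spec or SplitSpec()
    aug = aug or AugmentationConfig()
    if holdout is None:
        train, val = split(examples, split_spec)
    else:
        train, val = list(examples), list(holdout)
    train_r = restrict_features(train, mode, len(panel))
    val_r = restrict_features(val, mode, len(panel))
    model = _fit(train_r, learner, learner_cfg, aug, panel, manifest, params)
    report = evaluate_model(model, val_r)
    return report


@dataclass
class GridResult:
    """Metric matrix over (train_fraction, n_per_target) with the best cell."""

    reports: dict[tuple[float, int], MetricReport]
    failures: dict[tuple[float, int], str]
    best: tuple[float, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (frac, n), rep in sorted(self.reports.items()):
            row = {"train_fraction": frac, "n_per_target": n}
            row.update(rep.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


DEFAULT_FRACTIONS = tuple(round(0.50 + 0.05 * i, 2) for i in range(9))  # 0.50..0.90
DEFAULT_N_VALUES = tuple(range(1000, 5001, 500))  # 1000..5000


def run_grid(
    examples: Sequence[PCMExample],
    panel: ReferencePanel,
    manifest: DescriptorManifest,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_values: Sequence[int] = DEFAULT_N_VALUES,
    learner: str = "rf",
    learner_cfg=None,
    sigma: float = 0.1,
    seed: int = 42,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> GridResult:
    """Sweep train fraction × oversampling count; one seeded split per cell.

    Each cell fits on its own stratified split and reports validation
    metrics; the best cell maximizes ROC-AUC, with ties broken toward the
    larger train fraction, then the larger oversampling count.  Cell
    failures are recorded and the sweep continues.
    """
    if not fractions or not n_values:
        raise EvaluationError("grid must contain at least one cell")
    reports: dict[tuple[float, int], MetricReport] = {}
    failures: dict[tuple[float, int], str] = {}
    for frac in fractions:
        for n in n_values:
            try:
                train, val = split(examples, SplitSpec(train_fraction=frac, seed=seed))
                aug = AugmentationConfig(n_per_target=n, sigma=sigma, seed=seed)
                model = _fit(train, learner, learner_cfg, aug, panel, manifest, params)
                reports[(frac, n)] = evaluate_model(model, val)
            except Exception as exc:  # record and continue
                failures[(frac, n)] = f"{type(exc).__name__}: {exc}"
    if not reports:
        raise EvaluationError("every grid cell failed")
    best = max(reports, key=lambda k: (reports[k].roc_auc, k[0], k[1]))
    return GridResult(reports=reports, failures=failures, best=best)


def score_file_metrics(
    df: pd.DataFrame, cutoff: float | None = None
) -> MetricReport:
    """Metrics for any predictor's score table (columns label, score).

    ``cutoff=None`` selects the best-balanced-accuracy cutoff first — the
    protocol used to compare external tools on a common footing.
    """
    if not {"label", "score"} <= set(df.columns):
        raise EvaluationError("score table needs 'label' and 'score' columns")
    y = df["label"].to_numpy(dtype=int)
    s = df["score"].to_numpy(dtype=float)
    if cutoff is None:
        cutoff, _ = best_balanced_accuracy_cutoff(y, s)
    return classification_metrics(y, s, cutoff)
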