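"""Stratified k-fold evaluation, the six-metric suite, ROC/AUC, ablation.

Folds are built per class: a seeded shuffle followed by round-robin
assignment, so per-class fold sizes differ by at most one and the multiset of
sizes is a deterministic function of the class counts alone.  For the
mass-patch class totals (1908 benign, 1810 malignant, k = 5) this reproduces
the published partition: every fold holds exactly 362 malignant samples,
benign folds split 382/382/382/381/381, and the largest fold totals 744.

Metrics treat malignant as the positive class.  AUC is computed from the
trapezoidal ROC over all distinct score thresholds, which equals the
Mann–Whitney concordance statistic (ties counted half).  Undefined ratios
(zero denominators) surface as NaN with a warning, never as silent zeros.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import fit_drvfl, fit_elm, fit_rvfln, predict
from .errors import ValidationError
from .features import CLASS_ORDER, POSITIVE_CLASS, FORMAT_VERSION, FeatureMatrix

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "ClassifierSpec",
    "stratified_kfold",
    "confusion_from_labels",
    "compute_metrics",
    "roc_auc",
    "cross_validate",
    "ablate",
    "report_to_json",
    "summary_to_csv",
    "METRIC_COLUMNS",
    "DEFAULT_GRIDS",
]

#: Column order of the published ablation tables.
METRIC_COLUMNS = ("sensitivity", "specificity", "precision", "f1", "accuracy", "auc")

#: Published ablation grids: hidden/enhancement nodes for the single-layer
#: models, per-layer width for the depth-3 deep RVFL.
DEFAULT_GRIDS = {
    "elm": (40, 80, 100, 200, 400, 800, 1000),
    "rvfln": (40, 80, 100, 200, 400, 800, 1000),
    "drvfl": (6, 12, 18, 24),
}


@dataclass(frozen=True)
class FoldPlan:
    """Per-sample fold assignment in 0..k−1."""

    k: int
    assignment: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassifierSpec:
    """Which randomized classifier to fit, and how.

    kind : 'elm' | 'rvfln' | 'drvfl'
    h : hidden/enhancement width for elm/rvfln
    widths : per-layer widths for drvfl
    """

    kind: str
    h: int | None = None
    widths: tuple[int, ...] | None = None
    activation: str = "sigmoid"
    eta: float = 0.0
    mode: str = "auto"

    def fit(self, train: FeatureMatrix, seed: int):
        from .linalg import SolverConfig

        cfg = SolverConfig(eta=self.eta, mode=self.mode)
        if self.kind == "elm":
            return fit_elm(train, self.h, self.activation, cfg, seed)
        if self.kind == "rvfln":
            return fit_rvfln(train, self.h, self.activation, cfg, seed)
        if self.kind == "drvfl":
            return fit_drvfl(train, list(self.widths), self.activation, cfg, seed)
        raise ValidationError(f"unknown classifier kind {self.kind!r}")


def stratified_kfold(labels, k: int, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment: per-class seeded shuffle + round-robin."""
    from .rng import substream

    labels = np.asarray(list(labels), dtype=object)
    if k < 2:
        raise ValidationError("k must be >= 2")
    assignment = np.full(len(labels), -1, dtype=int)
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValidationError(
                f"class {cls!r} has {len(idx)} samples, fewer than k={k}"
            )
        perm = substream(seed, "fold", cls).permutation(len(idx))
        assignment[idx[perm]] = np.arange(len(idx)) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def confusion_from_labels(true_labels, pred_labels) -> ConfusionCounts:
    t = np.asarray(list(true_labels), dtype=object) == POSITIVE_CLASS
    p = np.asarray(list(pred_labels), dtype=object) == POSITIVE_CLASS
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, precision, F1, accuracy from a confusion table."""
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(sens) or np.isnan(prec) or (prec + sens) == 0:
        if not (np.isnan(sens) or np.isnan(prec)):
            warnings.warn("f1 undefined (precision + sensitivity = 0); reporting NaN")
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    acc = _ratio(c.tp + c.tn, c.total, "accuracy")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
    }


def roc_auc(positive_scores, labels) -> tuple[float, np.ndarray]:
    """Trapezoidal ROC/AUC from raw positive-class scores.

    Returns (auc, points) with points an array of (fpr, tpr) rows running
    monotonically from (0, 0) to (1, 1).  Tied scores are grouped at one
    threshold, so the trapezoid over the tie segment counts each tied
    (positive, negative) pair half — the Mann–Whitney convention.
    """
    scores = np.asarray(positive_scores, dtype=float)
    y = np.asarray(list(labels), dtype=object) == POSITIVE_CLASS
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    tp = np.cumsum(yy)
    fp = np.cumsum(~yy)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def _summarize(per_fold: list[dict]) -> dict:
    out = {}
    for m in METRIC_COLUMNS:
        vals = np.array([f[m] for f in per_fold], dtype=float)
        ok = vals[np.isfinite(vals)]
        out[m] = {
            "mean": float(ok.mean()) if len(ok) else float("nan"),
            "std": float(ok.std(ddof=1)) if len(ok) > 1 else 0.0,
        }
    return out


def cross_validate(
    features: FeatureMatrix,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
    repeats: int = 1,
) -> dict:
    """Stratified k-fold cross-validation of one classifier configuration.

    Each repeat draws a fresh fold plan from its own substream.  Per-fold
    records hold the confusion table, the six metrics and the ROC points;
    the summary is the across-fold mean and sample standard deviation
    (k−1 divisor), matching the mean±std presentation convention.
    """
    from .rng import derive_seed

    per_fold = []
    for rep in range(repeats):
        plan = stratified_kfold(features.labels, k, seed=derive_seed(seed, "cv", rep))
        for fold in range(k):
            train = features.subset(plan.train_indices(fold))
            test = features.subset(plan.test_indices(fold))
            try:
                model = spec.fit(train, seed=derive_seed(seed, "fit", rep, fold))
            except Exception as exc:
                raise type(exc)(f"fold {fold}: {exc}") from exc
            pred = predict(model, test)
            c = confusion_from_labels(test.labels, pred.labels)
            metrics = compute_metrics(c)
            auc, points = roc_auc(pred.positive_score, test.labels)
            metrics["auc"] = auc
            # identity check: accuracy decomposes over the class counts
            p_n = c.tp + c.fn
            n_n = c.tn + c.fp
            if p_n and n_n:
                recon = (metrics["sensitivity"] * p_n + metrics["specificity"] * n_n) / (p_n + n_n)
                assert abs(recon - metrics["accuracy"]) < 1e-12
            per_fold.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
                    "roc_points": points.tolist(),
                    **metrics,
                }
            )
    return {
        "format_version": FORMAT_VERSION,
        "k": k,
        "seed": seed,
        "repeats": repeats,
        "classifier": {
            "kind": spec.kind,
            "h": spec.h,
            "widths": None if spec.widths is None else list(spec.widths),
            "activation": spec.activation,
            "eta": spec.eta,
            "mode": spec.mode,
        },
        "score_source": "raw positive-class output (no softmax)",
        "per_fold": per_fold,
        "summary": _summarize(per_fold),
    }


def ablate(
    features,
    kind: str,
    grid=None,
    k: int = 5,
    seed: int = 0,
    depth: int = 3,
) -> pd.DataFrame:
    """Width ablation: one cross-validation row per (feature level, width).

    ``features`` is a FeatureMatrix or a {level: FeatureMatrix} mapping.
    For 'drvfl' each grid value is replicated across ``depth`` equal layers
    (the published default keeps three equal-width layers).  The returned
    frame carries mean/std per metric plus a best-row flag per metric.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[kind]
    grid = list(grid)
    if not grid:
        raise ValidationError("ablation grid must be non-empty")
    if isinstance(features, FeatureMatrix):
        features = {features.level_tag: features}
    rows = []
    for level, fm in features.items():
        for width in grid:
            if kind == "drvfl":
                spec = ClassifierSpec(kind=kind, widths=(width,) * depth)
            else:
                spec = ClassifierSpec(kind=kind, h=width)
            report = cross_validate(fm, spec, k=k, seed=seed)
            row = {"level": level, "width": width}
            for m in METRIC_COLUMNS:
                row[f"{m}_mean"] = report["summary"][m]["mean"]
                row[f"{m}_std"] = report["summary"][m]["std"]
            rows.append(row)
    df = pd.DataFrame(rows)
    for m in METRIC_COLUMNS:
        df[f"best_{m}"] = df[f"{m}_mean"] == df[f"{m}_mean"].max()
    return df


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True)


def summary_to_csv(report_or_table, path) -> None:
    """Write a summary CSV whose columns mirror the published table order."""
    if isinstance(report_or_table, pd.DataFrame):
        report_or_table.to_csv(path, index=False)
        return
    summary = report_or_table["summary"]
    row = {}
    for m in METRIC_COLUMNS:
        row[f"{m}_mean"] = summary[m]["mean"]
        row[f"{m}_std"] = summary[m]["std"]
    pd.DataFrame([row]).to_csv(path, index=False)
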