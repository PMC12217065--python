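"""Evaluation: splits, confusion counts, derived metrics, significance tests.

The positive class is malignant (label 1) throughout. Accuracy is the
standard (TP+TN)/total ratio. ROC-AUC is computed from the tie-adjusted
rank statistic (Mann-Whitney), so it is invariant under strictly
monotone transforms of the scores.

Model comparison follows a normality-gated protocol: Shapiro-Wilk on
the paired differences chooses between the paired t test (p > 0.05)
and the Wilcoxon signed-rank test; constant differences fall back to
an exact sign test, flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from fswolf.preprocess import LabeledImageSet

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "MetricReport",
    "SignificanceReport",
    "split_indices",
    "split_dataset",
    "confusion",
    "metrics",
    "roc_auc",
    "compare_models",
    "grid_search",
]


@dataclass
class SplitSpec:
    train: float = 0.6
    validation: float = 0.2
    test: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train + self.validation + self.test
        if min(self.train, self.validation, self.test) <= 0 or abs(total - 1) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float
    roc_auc: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SignificanceReport:
    shapiro_p: float | None
    test_name: str
    statistic: float
    p_value: float
    mean_difference: float
    ci_low: float
    ci_high: float
    flags: list[str] = field(default_factory=list)


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, seeded train/validation/test index partition."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    groups = [np.where(labels == c)[0] for c in np.unique(labels)] if spec.stratified else [np.arange(labels.size)]
    for idx in groups:
        if idx.size < 3:
            raise ValueError("each class needs at least 3 samples to split")
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(spec.train * idx.size))
        n_val = int(round(spec.validation * idx.size))
        n_val = min(n_val, idx.size - n_train - 1)  # keep test nonempty
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


def split_dataset(
    dataset: LabeledImageSet, spec: SplitSpec
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Disjoint, exhaustive, stratified 60/20/20 split of an image set."""
    counts = dataset.class_counts()
    if min(counts.values()) < 5:
        raise ValueError("need at least 5 samples per class to split")
    tr, va, te = split_indices(dataset.labels, spec)
    return dataset.subset(tr), dataset.subset(va), dataset.subset(te)


def confusion(labels, predictions) -> ConfusionCounts:
    """Binary confusion counts with malignant (1) as the positive class."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (set(np.unique(y)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Precision, recall, F1 and accuracy from confusion counts.

    Undefined ratios (zero denominators) are reported as None with a
    flag rather than as 0.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    flags: list[str] = []
    precision = recall = f1 = None
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        flags.append("precision_undefined")
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        flags.append("recall_undefined")
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif "precision_undefined" not in flags and "recall_undefined" not in flags:
        flags.append("f1_undefined")
    accuracy = (counts.tp + counts.tn) / counts.total
    return MetricReport(precision=precision, recall=recall, f1=f1, accuracy=accuracy, flags=flags)


def roc_auc(scores, labels) -> float:
    """Tie-adjusted Mann-Whitney AUC of positive-class scores."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compare_models(a, b, alpha: float = 0.05) -> SignificanceReport:
    """Paired comparison of per-fold metric vectors A and B.

    Shapiro-Wilk on the paired differences gates the test: paired t if
    p > 0.05 (normality not rejected), else Wilcoxon signed-rank.
    Constant differences make both degenerate; an exact sign test is
    reported instead, flagged.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired vectors of equal length >= 5")
    diff = a - b
    mean_diff = float(diff.mean())
    n = diff.size
    se = diff.std(ddof=1) / np.sqrt(n)
    if se > 0:
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    else:
        ci = (mean_diff, mean_diff)
    flags: list[str] = []
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return SignificanceReport(
                shapiro_p=None,
                test_name="degenerate",
                statistic=0.0,
                p_value=1.0,
                mean_difference=mean_diff,
                ci_low=ci[0],
                ci_high=ci[1],
                flags=["constant_zero_differences"],
            )
        n_pos = int((diff > 0).sum())
        res = stats.binomtest(n_pos, n, 0.5)
        return SignificanceReport(
            shapiro_p=None,
            test_name="sign",
            statistic=float(n_pos),
            p_value=float(res.pvalue),
            mean_difference=mean_diff,
            ci_low=ci[0],
            ci_high=ci[1],
            flags=["constant_differences"],
        )
    shapiro_p = float(stats.shapiro(diff).pvalue)
    if shapiro_p > alpha:
        t_res = stats.ttest_rel(a, b)
        name, statistic, p_value = "paired_t", float(t_res.statistic), float(t_res.pvalue)
    else:
        w_res = stats.wilcoxon(a, b)
        name, statistic, p_value = "wilcoxon", float(w_res.statistic), float(w_res.pvalue)
    return SignificanceReport(
        shapiro_p=shapiro_p,
        test_name=name,
        statistic=statistic,
        p_value=p_value,
        mean_difference=mean_diff,
        ci_low=ci[0],
        ci_high=ci[1],
        flags=flags,
    )


def grid_search(
    labels: np.ndarray,
    configs: list[dict],
    trainer,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """Exhaustive configuration search by mean stratified k-fold accuracy.

    ``trainer(config, fit_idx, val_idx) -> accuracy`` evaluates one
    fold. Tie-break is deterministic: lower learning rate, then smaller
    batch size. Returns the winning config and the full grid table.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    if len(configs) == 0:
        raise ValueError("empty configuration grid")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    folds_idx = list(skf.split(np.zeros(labels.size), labels))
    for _, val_idx in folds_idx:
        if len(np.unique(labels[val_idx])) < 2:
            raise ValueError("a fold contains a single class; reduce folds")
    table = []
    for cfg in configs:
        accs = [float(trainer(cfg, fit, val)) for fit, val in folds_idx]
        table.append({**cfg, "fold_accuracies": accs, "mean_accuracy": float(np.mean(accs))})
    best = max(
        table,
        key=lambda row: (
            row["mean_accuracy"],
            -row.get("learning_rate", 0.0),
            -row.get("batch_size", 0),
        ),
    )
    winner = {k: v for k, v in best.items() if k not in ("fold_accuracies", "mean_accuracy")}
    return winner, table
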