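"""Confusion metrics, ROC/PR areas, repeated cross-validation, multi-label scoring.

Per-localization accuracy is summarized by sensitivity, specificity, F1,
Matthews correlation, and the areas under the ROC and precision-recall
curves, estimated by repeated stratified fivefold cross-validation: each
repeat draws a fresh stratified split, every fold refits the whole
preprocessing stack (PCA, SMOTE) on its training part only, and the report
carries the mean and standard error (sd / sqrt(repeats)) across repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from mirnaloc.princomp import fit_pca
from mirnaloc.psednc import PseDncConfig, encode_features
from mirnaloc.sequence_io import LabelTable, RnaSequence
from mirnaloc.smote import SmoteConfig, balance

logger = logging.getLogger(__name__)

METRICS = ("auc_roc", "auc_pr", "sensitivity", "specificity", "f1", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/tn/fp/fn of a binary evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def binary_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, precision, F1 and MCC from a confusion table.

    A metric whose denominator is zero is reported as NaN and listed under
    the ``"undefined"`` key rather than silently coerced to 0.
    """
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    if math.isnan(prec) or math.isnan(sens):
        undefined.append("f1")
        f1 = math.nan
    elif prec + sens == 0:
        f1 = 0.0  # both precision and recall are zero: no true positives
    else:
        f1 = 2 * prec * sens / (prec + sens)
    mcc_den = math.sqrt(
        float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = math.nan
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "mcc": mcc,
        "undefined": undefined,
    }


def auc_roc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Trapezoidal area under the ROC curve (ties grouped by equal score)."""
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC-ROC needs both classes present in the truth")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def auc_pr(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Step-wise area under the precision-recall curve.

    Uses the conservative sum of precision at each threshold times the
    recall increment (no linear interpolation between operating points).
    """
    truth = np.asarray(truth)
    if truth.sum() == 0:
        raise ValueError("AUC-PR needs at least one positive in the truth")
    return float(average_precision_score(truth, np.asarray(scores, dtype=float)))


# A fold function maps (X_train, y_train, X_test, seed) to (scores, predictions)
FoldFn = Callable[[pd.DataFrame, np.ndarray, pd.DataFrame, int], tuple[np.ndarray, np.ndarray]]


def svm_fold_pipeline(
    svm_gamma: float = 0.125,
    svm_cost: float = 2.0,
    smote_cfg: SmoteConfig | None = None,
    pca_on_all: bool = False,
) -> FoldFn:
    """Build the default leakage-free fold pipeline: PCA -> SMOTE -> RBF-SVM.

    PCA and SMOTE are fitted on the training part only (``pca_on_all`` exists
    for replication studies that fitted PCA globally; it is applied by the
    caller, not here).  Scores are SVM decision values — any monotone
    probability mapping yields the same ROC/PR areas.
    """
    base_smote = smote_cfg or SmoteConfig()

    def run(
        X_train: pd.DataFrame,
        y_train: np.ndarray,
        X_test: pd.DataFrame,
        seed: int,
    ) -> tuple[np.ndarray, np.ndarray]:
        pca = fit_pca(X_train)
        S_train = pca.transform(X_train)
        S_test = pca.transform(X_test)
        cfg = SmoteConfig(
            k_neighbors=base_smote.k_neighbors,
            target_ratio=base_smote.target_ratio,
            seed=seed % (2**31),
            skip_threshold=base_smote.skip_threshold,
        )
        Xb, yb = balance(S_train, y_train, cfg)
        clf = SVC(kernel="rbf", gamma=svm_gamma, C=svm_cost, cache_size=500)
        clf.fit(Xb.to_numpy(), yb)
        test_arr = S_test.to_numpy()
        return clf.decision_function(test_arr), clf.predict(test_arr)

    return run


def repeated_cv(
    seqs: Sequence[RnaSequence],
    labels: LabelTable,
    localization: str,
    fold_fn: FoldFn | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    features: pd.DataFrame | None = None,
    pse_cfg: PseDncConfig | None = None,
) -> dict:
    """Repeated stratified k-fold evaluation of one localization's classifier.

    Metrics are computed per fold, averaged within each repeat, then
    summarized as mean and standard error across repeats.  Pass `features`
    to reuse a precomputed encoding (the encoding itself carries no
    training-set statistics, so sharing it leaks nothing).
    """
    if fold_fn is None:
        fold_fn = svm_fold_pipeline()
    if features is None:
        features = encode_features(seqs, pse_cfg)
    pos = labels.positives(localization)
    y = np.array([1 if sid in pos else 0 for sid in features.index])
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"cannot stratify {k} folds with {n_pos} positives / {n_neg} negatives; "
            "use a smaller k"
        )

    per_repeat: list[dict[str, float]] = []
    for rep in range(repeats):
        rep_seed = (seed + rep) % (2**31)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        fold_vals: dict[str, list[float]] = {m: [] for m in METRICS}
        for f, (tr, te) in enumerate(skf.split(features, y)):
            scores, preds = fold_fn(
                features.iloc[tr], y[tr], features.iloc[te], rep_seed + 7919 * f
            )
            yt = y[te]
            fold_vals["auc_roc"].append(auc_roc(scores, yt))
            fold_vals["auc_pr"].append(auc_pr(scores, yt))
            conf = ConfusionCounts(
                tp=int(((preds == 1) & (yt == 1)).sum()),
                tn=int(((preds == 0) & (yt == 0)).sum()),
                fp=int(((preds == 1) & (yt == 0)).sum()),
                fn=int(((preds == 0) & (yt == 1)).sum()),
            )
            bm = binary_metrics(conf)
            fold_vals["sensitivity"].append(bm["sensitivity"])
            fold_vals["specificity"].append(bm["specificity"])
            fold_vals["f1"].append(bm["f1"])
            fold_vals["mcc"].append(bm["mcc"])
        rep_means = {}
        for m, v in fold_vals.items():
            defined = [x for x in v if not math.isnan(x)]
            rep_means[m] = float(np.mean(defined)) if defined else math.nan
        per_repeat.append(rep_means)

    report: dict = {
        "localization": localization,
        "repeats": repeats,
        "folds": k,
        "seed": seed,
    }
    for m in METRICS:
        vals = np.array([r[m] for r in per_repeat])
        report[f"{m}_mean"] = float(np.mean(vals))
        report[f"{m}_se"] = (
            float(np.std(vals, ddof=1) / math.sqrt(repeats)) if repeats > 1 else 0.0
        )
    return report


def multilabel_eval(
    predicted: Mapping[str, set[str]],
    truth: LabelTable,
) -> dict:
    """Score multi-label calls against the annotation table.

    A localization is correct for a sequence iff it appears in both the
    truth and the prediction.  The confusion matrix counts, for each number
    of true localizations r, how many sequences had exactly c of them
    correctly predicted (c = 0..r).
    """
    unknown = set(predicted) - set(truth.ids())
    if unknown:
        raise KeyError(f"predictions for unknown sequence id(s): {sorted(unknown)[:5]}")
    per_loc = {loc: 0 for loc in truth.localizations}
    total_correct = 0
    total_localizations = 0
    matrix: dict[int, dict[int, int]] = {}
    for sid in truth.ids():
        true_set = set(truth[sid])
        pred_set = set(predicted.get(sid, set()))
        correct = true_set & pred_set
        for loc in correct:
            per_loc[loc] += 1
        total_correct += len(correct)
        total_localizations += len(true_set)
        r, c = len(true_set), len(correct)
        matrix.setdefault(r, {})
        matrix[r][c] = matrix[r].get(c, 0) + 1
    return {
        "per_localization_correct": per_loc,
        "total_correct": total_correct,
        "total_localizations": total_localizations,
        "confusion": matrix,
    }
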