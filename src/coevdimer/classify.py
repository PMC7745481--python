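"""SVM discrimination of positive and negative dimers.

Protocol: hold out a stratified 30% of the dimers as a test set; on the
remaining 70%, tune an RBF-kernel SVM by ten-fold cross-validation
repeated over ten rotations of the fold assignment; refit the tuned
model on the full 70% and evaluate once on the held-out 30%.  Feature
standardization is fit inside the training data only (and inside each
CV training fold during tuning), so the test set never influences the
model.

The kernel is the standard radial basis function
k(a_i, a_j) = exp(-||a_i - a_j||^2 / (2 sigma^2)); the tuning grid puts
sigma on a log-spaced ladder around the median pairwise training
distance and the cost C on {0.1, 1, 10, 100}.

Evaluation reports the confusion counts and eight derived metrics:
accuracy, sensitivity, specificity, precision, FPR, NPV, FNR and
bookmaker informedness (BM = sensitivity + specificity - 1).  A metric
with a zero denominator is reported as NaN and listed in ``undefined``,
never silently zeroed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import NormFeatureTable


class ClassificationError(ValueError):
    """Raised for inputs the discrimination protocol cannot handle."""


def rbf_kernel(a_i: np.ndarray, a_j: np.ndarray, sigma: float) -> float:
    """exp(-||a_i - a_j||^2 / (2 sigma^2)); equals 1 iff a_i == a_j."""
    if sigma <= 0:
        raise ClassificationError(f"sigma must be > 0, got {sigma}")
    a_i = np.atleast_1d(np.asarray(a_i, dtype=float))
    a_j = np.atleast_1d(np.asarray(a_j, dtype=float))
    if a_i.shape != a_j.shape:
        raise ClassificationError("feature vectors have different lengths")
    d2 = float(np.sum((a_i - a_j) ** 2))
    return math.exp(-d2 / (2.0 * sigma * sigma))


@dataclass(frozen=True)
class SplitPlan:
    """Evaluation protocol parameters."""

    test_fraction: float = 0.30
    cv_folds: int = 10
    tuning_rotations: int = 10
    random_seed: int = 0
    cost_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    sigma_scale_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ClassificationError("test_fraction outside (0, 1)")
        if self.cv_folds < 2:
            raise ClassificationError("cv_folds must be >= 2")
        if self.tuning_rotations < 1:
            raise ClassificationError("tuning_rotations must be >= 1")


@dataclass
class EvaluationReport:
    """Confusion counts, the eight metrics, and protocol provenance."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    fpr: float
    npv: float
    fnr: float
    bm: float
    undefined: tuple[str, ...] = ()
    seed: Optional[int] = None
    grid: Optional[dict] = None
    best_params: Optional[dict] = None
    cv_accuracy: Optional[float] = None

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return json.dumps(d, default=float, **kwargs)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """All eight metrics from the confusion counts.

    Zero-denominator metrics come back as NaN with their names listed in
    ``undefined``; BM is undefined whenever sensitivity or specificity is.
    """
    counts = dict(tp=tp, tn=tn, fp=fp, fn=fn)
    if any(c < 0 for c in counts.values()):
        raise ClassificationError("confusion counts must be >= 0")
    total = tp + tn + fp + fn
    if total == 0:
        raise ClassificationError("all confusion counts are zero")

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = (tp + tn) / total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    fpr = ratio(fp, fp + tn, "fpr")
    npv = ratio(tn, tn + fn, "npv")
    fnr = ratio(fn, fn + tp, "fnr")
    if math.isnan(sensitivity) or math.isnan(specificity):
        undefined.append("bm")
        bm = float("nan")
    else:
        bm = sensitivity + specificity - 1.0
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        precision=precision, fpr=fpr, npv=npv, fnr=fnr, bm=bm,
        undefined=tuple(undefined),
    )


def _encode_labels(labels: pd.Series) -> np.ndarray:
    return (labels.to_numpy() == "positive").astype(int)


def _median_distance(x: np.ndarray) -> float:
    if len(x) < 2:
        return 1.0
    d = pdist(x)
    med = float(np.median(d))
    return med if med > 0 else 1.0


def _make_model(c: float, sigma: float, standardize: bool) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(C=c, kernel="rbf", gamma=1.0 / (2.0 * sigma * sigma))))
    return Pipeline(steps)


def train_eval_protocol(
    table: NormFeatureTable,
    plan: SplitPlan | None = None,
    return_model: bool = False,
):
    """Run the full discrimination protocol on a norm feature table.

    Stratified 70/30 split by the plan's seed; hyperparameters tuned by
    repeated stratified 10-fold cross-validation (``tuning_rotations``
    rotations) on the 70% only; the tuned model refit on the full 70%
    and evaluated once on the 30%.  Entirely deterministic given the
    seed.  Ties in CV accuracy resolve to the smallest cost, then the
    smallest sigma.
    """
    plan = plan or SplitPlan()
    if table.labels is None:
        raise ClassificationError("feature table carries no labels")
    x = table.features.to_numpy(dtype=float)
    y = _encode_labels(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ClassificationError("need both positive and negative dimers")
    if counts.min() < plan.cv_folds:
        raise ClassificationError(
            f"minority class has {counts.min()} dimers, fewer than "
            f"{plan.cv_folds} CV folds"
        )

    x_train, x_test, y_train, y_test = train_test_split(
        x, y,
        test_size=plan.test_fraction,
        random_state=plan.random_seed,
        stratify=y,
    )

    # sigma ladder around the median pairwise distance of the (scaled)
    # training features
    ref = StandardScaler().fit_transform(x_train) if plan.standardize else x_train
    d_med = _median_distance(ref)
    sigmas = tuple(s * d_med for s in plan.sigma_scale_grid)

    cv = RepeatedStratifiedKFold(
        n_splits=plan.cv_folds,
        n_repeats=plan.tuning_rotations,
        random_state=plan.random_seed,
    )
    best = None  # (score, -C_rank, -sigma_rank) comparisons done explicitly
    for c in plan.cost_grid:
        for sigma in sigmas:
            model = _make_model(c, sigma, plan.standardize)
            scores = cross_val_score(model, x_train, y_train, cv=cv, n_jobs=None)
            mean_score = float(scores.mean())
            if best is None or mean_score > best[0] + 1e-12:
                best = (mean_score, c, sigma)
    assert best is not None
    cv_accuracy, best_c, best_sigma = best

    final = _make_model(best_c, best_sigma, plan.standardize)
    final.fit(x_train, y_train)
    pred = final.predict(x_test)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    report = confusion_metrics(tp, tn, fp, fn)
    report.seed = plan.random_seed
    report.grid = {"cost": list(plan.cost_grid), "sigma": list(sigmas)}
    report.best_params = {"cost": best_c, "sigma": best_sigma}
    report.cv_accuracy = cv_accuracy
    if return_model:
        return report, final
    return report


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    significant: bool


def compare_norm_distributions(
    pos: Sequence[float], neg: Sequence[float], alpha: float = 0.05
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U rank-sum test between the norm values of
    positive and negative dimers, flagged at the 5% level by default."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ClassificationError("both norm lists must be nonempty")
    pooled = np.concatenate([pos, neg])
    if np.all(pooled == pooled[0]):
        # fully tied data: no evidence of separation by construction
        return MannWhitneyResult(
            u_statistic=pos.size * neg.size / 2.0, p_value=1.0, significant=False
        )
    res = mannwhitneyu(pos, neg, alternative="two-sided")
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue <= alpha),
    )
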