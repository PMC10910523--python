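"""Splitting, confusion-matrix metrics, ROC/AUC, confusion-matrix
reconstruction from rounded published metrics, and model explanation.

Metric definitions (binary, positives = lupus nephritis)::

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)
    F           = 2 * PPV * sensitivity / (PPV + sensitivity)

A ratio with a zero denominator is reported as absent (``None``), never as
0 or NaN. AUC is computed as the normalized Mann–Whitney U statistic
(ties count one half), which is exact and threshold-free.

:func:`reconstruct_confusion` inverts rounding: given cohort sizes and
sensitivity/specificity printed at two decimals, it enumerates every
integer confusion matrix consistent with them (round-half-up convention),
which lets published rows be audited for internal consistency.

Explanation is exact for a linear model: the Shapley value of feature
``j`` for patient ``i`` under the feature-independence convention is
``phi_ij = b_j * (x_ij - mean_background(x_j))``, and the local-accuracy
identity ``sum_j phi_ij + baseline = b0 + b . x_i`` holds to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .corpus import Corpus
from .features import FeatureMatrix
from .learn import PenalizedLogisticModel


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class EvaluationReport:
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f_measure: Optional[float]
    auc: Optional[float] = None
    threshold: Optional[float] = None
    n_pos: int = 0
    n_neg: int = 0


def split_train_test(
    corpus: Corpus,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive patient-id split; stratified by gold label.

    The test set takes ``ceil((1 - train_fraction) * n)`` patients and the
    training set the remaining floor (so 472 labeled patients at 0.75
    split 354/118). Deterministic per seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labeled = corpus.labeled()
    if stratified:
        if len(labeled) != len(corpus.patients):
            raise ValueError("stratified split requires every patient labeled")
        strata = [int(p.gold_label) for p in labeled]
    else:
        strata = None
        labeled = corpus.patients
    ids = [p.patient_id for p in labeled]
    train_ids, test_ids = train_test_split(
        ids, train_size=train_fraction, random_state=seed, shuffle=True,
        stratify=strata)
    return list(train_ids), list(test_ids)


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def f_measure(ppv: Optional[float], sensitivity: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision (PPV) and recall (sensitivity)."""
    if ppv is None or sensitivity is None:
        return None
    if ppv == 0 and sensitivity == 0:
        return None
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def metrics(cm: ConfusionMatrix, threshold: Optional[float] = None) -> EvaluationReport:
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    return EvaluationReport(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        f_measure=f_measure(ppv, sens), threshold=threshold,
        n_pos=cm.n_pos, n_neg=cm.n_neg)


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Threshold-free AUC = normalized Mann–Whitney U (ties count 1/2)."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present for AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    sensitivity_2dp: float,
    specificity_2dp: float,
) -> list[ConfusionMatrix]:
    """All integer confusion matrices consistent with rounded metrics.

    Exhaustive search over TP in [0, n_pos] and TN in [0, n_neg]; a matrix
    qualifies when its sensitivity and specificity round (half-up, 2 d.p.)
    to the given values. An empty result means no matrix is consistent.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be > 0")
    out = []
    for tp in range(n_pos + 1):
        if round_half_up(tp / n_pos) != round_half_up(sensitivity_2dp):
            continue
        for tn in range(n_neg + 1):
            if round_half_up(tn / n_neg) == round_half_up(specificity_2dp):
                out.append(ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn,
                                           fn=n_pos - tp))
    return out


def top_coefficients(model: PenalizedLogisticModel, k: int) -> list[tuple[str, float]]:
    """Features ordered by descending signed coefficient (ties by name)."""
    pairs = sorted(zip(model.feature_names, model.coef.tolist()),
                   key=lambda t: (-t[1], t[0]))
    return pairs[: max(k, 0)] if k < len(pairs) else pairs


@dataclass
class Attribution:
    feature_names: list[str]
    values: np.ndarray        # patients x features, phi_ij
    baseline: float           # expected margin over the background
    patient_ids: list[str] = field(default_factory=list)

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def ranking(self) -> list[tuple[str, float]]:
        pairs = zip(self.feature_names, self.mean_abs.tolist())
        return sorted(pairs, key=lambda t: (-t[1], t[0]))


def linear_shap(
    model: PenalizedLogisticModel,
    features: FeatureMatrix,
    background: FeatureMatrix,
) -> Attribution:
    """Exact Shapley attributions for the linear margin.

    ``phi_ij = b_j * (x_ij - xbar_j)`` with ``xbar`` the background mean;
    the per-patient attributions plus the baseline reproduce the linear
    margin exactly (local accuracy).
    """
    if not background.patient_ids:
        raise ValueError("background must be non-empty")
    if list(features.feature_names) != model.feature_names or \
            list(background.feature_names) != model.feature_names:
        raise ValueError("feature names must match the model")
    xbar = background.values.mean(axis=0)
    phi = (features.values - xbar) * model.coef
    baseline = float(model.intercept + xbar @ model.coef)
    return Attribution(feature_names=list(model.feature_names), values=phi,
                       baseline=baseline, patient_ids=list(features.patient_ids))
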