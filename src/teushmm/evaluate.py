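"""Leave-one-patient-out evaluation, metrics, ROC/AUC, grid search.

ROIs from the same patient are spatially correlated, so cross-validation
folds are whole patients: for each fold the held-out patient's ROIs are
scored by a model pair trained on all other patients (quantizer
included, so no held-out information leaks into preprocessing).

Per-patient metrics follow the usual confusion-matrix definitions with
malignant as the positive class.  Sensitivity and AUC are undefined
(reported as missing, never as zero) for patients contributing no
malignant ROIs; the cohort "average" row averages sensitivity and AUC
only over patients that have malignant ROIs, and the other measures over
all patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .classify import Prediction, classify_cohort, train_pair
from .errors import ValidationError
from .hmm import TrainConfig
from .preprocess import BENIGN, MALIGNANT
from .simulate import Cohort

DEFAULT_STATES = (2, 3, 4, 5, 6, 7, 8)
DEFAULT_ALPHABETS = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class FoldPlan:
    """Ordered leave-one-patient-out folds."""

    folds: tuple[tuple[str, tuple[str, ...]], ...]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


@dataclass(frozen=True)
class MetricsRecord:
    """Per-patient (or cohort-average) classification metrics.

    ``sensitivity``/``auc`` are ``None`` when the patient has no
    malignant ROIs; ``specificity`` is ``None`` when no benign ROIs.
    """

    patient_id: str
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass(eq=False)
class RocCurve:
    """ROC sweep (FPR, TPR per threshold) and its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(eq=False)
class GridResult:
    """Grid-search table with one row per (n_states, alphabet_size)."""

    table: "object"  # pandas.DataFrame with columns n_states, alphabet_size, mean_accuracy, sd_accuracy


def lopo_folds(cohort: Cohort) -> FoldPlan:
    """One fold per distinct patient, in sorted patient-id order."""
    pids = cohort.patient_ids()
    if len(pids) < 2:
        raise ValidationError("leave-one-patient-out requires >= 2 patients")
    folds = tuple(
        (held, tuple(p for p in pids if p != held)) for held in pids
    )
    return FoldPlan(folds)


def compute_metrics(
    truth: list[str], predicted: list[str], patient_id: str = ""
) -> MetricsRecord:
    """Confusion-matrix metrics with malignant as the positive class."""
    if len(truth) != len(predicted):
        raise ValidationError("truth and predicted must have equal length")
    if len(truth) == 0:
        raise ValidationError("at least one label is required")
    tp = sum(1 for t, p in zip(truth, predicted) if t == MALIGNANT and p == MALIGNANT)
    fn = sum(1 for t, p in zip(truth, predicted) if t == MALIGNANT and p == BENIGN)
    tn = sum(1 for t, p in zip(truth, predicted) if t == BENIGN and p == BENIGN)
    fp = sum(1 for t, p in zip(truth, predicted) if t == BENIGN and p == MALIGNANT)
    n_mal, n_ben = tp + fn, tn + fp
    accuracy = (tp + tn) / len(truth)
    sensitivity = tp / n_mal if n_mal else None
    specificity = tn / n_ben if n_ben else None
    return MetricsRecord(
        patient_id=patient_id,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=None,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
    )


def normalize_log_or(log_odds: np.ndarray) -> np.ndarray:
    """Map log-odds symmetrically into ``[0, 1]`` with 0 at 0.5.

    ``s(x) = 0.5 + x / (2 * max|x|)``; an all-zero vector maps to all
    0.5.  Thresholding the result at 0.5 is equivalent to thresholding
    the raw log-odds at 0.
    """
    x = np.asarray(log_odds, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot normalize an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("log-odds must be finite")
    scale = np.max(np.abs(x))
    if scale == 0:
        return np.full(x.shape, 0.5)
    return 0.5 + x / (2.0 * scale)


def roc_curve(malignancy_scores: np.ndarray, truth: list[str]) -> RocCurve:
    """ROC curve of malignancy scores (higher = more malignant).

    Sweeps all distinct score values plus sentinels; AUC by the
    trapezoidal rule, which on this sweep equals the pairwise rank
    statistic ``Pr(score_mal > score_ben) + 0.5 Pr(equal)``.
    """
    scores = np.asarray(malignancy_scores, dtype=float)
    y = np.asarray([t == MALIGNANT for t in truth], dtype=int)
    if scores.size != y.size:
        raise ValidationError("scores and truth must have equal length")
    if y.min() == y.max():
        raise ValidationError("ROC requires both classes present in truth")
    fpr, tpr, thr = _skm.roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def _malignancy_scores(predictions: list[Prediction]) -> np.ndarray:
    """Normalized malignancy score per prediction (higher = more malignant)."""
    return normalize_log_or(np.array([-p.log_odds for p in predictions]))


def _fold_seed(base_seed: int, n_states: int, alphabet: int, fold_index: int) -> int:
    """Deterministic per-fold seed; independent of evaluation order."""
    ss = np.random.SeedSequence(
        entropy=base_seed, spawn_key=(n_states, alphabet, fold_index)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _average_record(records: list[MetricsRecord]) -> MetricsRecord:
    sens = [r.sensitivity for r in records if r.sensitivity is not None]
    spec = [r.specificity for r in records if r.specificity is not None]
    aucs = [r.auc for r in records if r.auc is not None]
    return MetricsRecord(
        patient_id="average",
        accuracy=float(np.mean([r.accuracy for r in records])),
        sensitivity=float(np.mean(sens)) if sens else None,
        specificity=float(np.mean(spec)) if spec else None,
        auc=float(np.mean(aucs)) if aucs else None,
        tp=sum(r.tp for r in records),
        tn=sum(r.tn for r in records),
        fp=sum(r.fp for r in records),
        fn=sum(r.fn for r in records),
    )


def run_lopo(
    cohort: Cohort, config: TrainConfig
) -> tuple[list[MetricsRecord], list[Prediction]]:
    """Leave-one-patient-out evaluation of the two-HMM classifier.

    Trains a fresh model pair per fold on the retained patients only and
    scores the held-out patient.  Returns per-patient metrics followed by
    an ``"average"`` record, plus all held-out predictions.  Per-patient
    AUC uses the patient's own normalized log-odds and is missing for
    patients without malignant ROIs.
    """
    plan = lopo_folds(cohort)
    records: list[MetricsRecord] = []
    predictions: list[Prediction] = []
    for i, (held, train_ids) in enumerate(plan):
        fold_config = replace(
            config,
            seed=_fold_seed(config.seed, config.n_states, config.alphabet_size, i),
        )
        train = cohort.subset(train_ids)
        try:
            pair = train_pair(train, fold_config)
        except ValidationError as exc:
            raise ValidationError(f"fold holding out {held!r}: {exc}") from exc
        preds = classify_cohort(pair, cohort.subset([held]))
        predictions.extend(preds)
        truth = [p.true_label for p in preds]
        rec = compute_metrics(truth, [p.label for p in preds], patient_id=held)
        if rec.tp + rec.fn > 0 and rec.tn + rec.fp > 0:
            roc = roc_curve(_malignancy_scores(preds), truth)
            rec = replace(rec, auc=roc.auc)
        records.append(rec)
    records.append(_average_record(records))
    return records, predictions


def per_patient_rocs(predictions: list[Prediction]) -> dict[str, RocCurve]:
    """ROC per patient (own normalization), for patients with both classes."""
    out: dict[str, RocCurve] = {}
    for pid in sorted({p.patient_id for p in predictions}):
        preds = [p for p in predictions if p.patient_id == pid]
        truth = [p.true_label for p in preds]
        if MALIGNANT in truth and BENIGN in truth:
            out[pid] = roc_curve(_malignancy_scores(preds), truth)
    return out


def pooled_roc(predictions: list[Prediction]) -> RocCurve:
    """Overall ROC with log-odds normalized jointly over all predictions."""
    truth = [p.true_label for p in predictions]
    return roc_curve(_malignancy_scores(predictions), truth)


def grid_search(
    cohort: Cohort,
    states=DEFAULT_STATES,
    alphabets=DEFAULT_ALPHABETS,
    base_config: TrainConfig | None = None,
) -> GridResult:
    """LOPO accuracy over the cross product of model sizes.

    One row per ``(n_states, alphabet_size)`` with the mean and sample
    standard deviation of the per-patient accuracies; rows sorted by
    ``(alphabet_size, n_states)``.  Per-cell fold seeds derive from
    ``(base seed, N, M, fold)``, so results are independent of
    evaluation order.
    """
    import pandas as pd

    states = sorted(set(states))
    alphabets = sorted(set(alphabets))
    if not states or not alphabets:
        raise ValidationError("states and alphabets must be nonempty")
    if base_config is None:
        base_config = TrainConfig(n_states=states[0], alphabet_size=alphabets[0])
    rows = []
    for m in alphabets:
        for n in states:
            config = replace(base_config, n_states=n, alphabet_size=m)
            try:
                records, _ = run_lopo(cohort, config)
            except ValidationError as exc:
                raise ValidationError(f"grid cell (N={n}, M={m}): {exc}") from exc
            accs = [r.accuracy for r in records if r.patient_id != "average"]
            rows.append(
                {
                    "n_states": n,
                    "alphabet_size": m,
                    "mean_accuracy": float(np.mean(accs)),
                    "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                }
            )
    return GridResult(table=pd.DataFrame(rows))


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """One-tailed Mann–Whitney–Wilcoxon test that ``x`` exceeds ``y``.

    Uses midranks for ties.  The p-value is computed by exact enumeration
    of the rank-sum null distribution (dynamic program over all
    ``C(n+m, n)`` equally likely rank assignments) when
    ``len(x) * len(y) <= 400``, else by the normal approximation with tie
    and continuity corrections.  Returns ``(U, p)`` for the statistic of
    ``x`` over ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires nonempty inputs")
    if alternative != "greater":
        raise ValidationError("only alternative='greater' is supported")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    rank_sum_x = float(ranks[:nx].sum())
    u = rank_sum_x - nx * (nx + 1) / 2.0
    if nx * ny <= 400:
        p = _exact_rank_sum_p(ranks, nx, rank_sum_x)
    else:
        p = _normal_rank_sum_p(pooled, nx, ny, u)
    return u, p


def _exact_rank_sum_p(ranks: np.ndarray, nx: int, rank_sum_x: float) -> float:
    """Exact ``Pr(rank sum of x >= observed)`` over all equally likely
    subsets of the pooled (mid)ranks.

    Midranks are multiples of 1/2, so doubling them gives integers and
    the subset-sum distribution is computed by a generating-function
    dynamic program: ``dp[k, s]`` counts size-``k`` subsets with doubled
    rank sum ``s``.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    target = int(np.rint(2 * rank_sum_x))
    max_sum = int(np.sort(r2)[-nx:].sum())
    dp = np.zeros((nx + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        kmax = nx  # iterate k downward so each item is used at most once
        for k in range(kmax, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    total = dp[nx].sum()
    ge = dp[nx, target:].sum()
    return float(ge / total)


def _normal_rank_sum_p(
    pooled: np.ndarray, nx: int, ny: int, u: float
) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = nx + ny
    mean_u = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return 1.0 if u <= mean_u else 0.0
    z = (u - mean_u - 0.5) / math.sqrt(var_u)
    return float(stats.norm.sf(z))
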