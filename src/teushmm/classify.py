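"""Two-model likelihood-ratio tissue classification.

One HMM (``lambda_M``) is trained on malignant ROI sequences and one
(``lambda_B``) on benign sequences; a test ROI is assigned the label of
the model under which its symbol sequence is most likely.  The signed
log-odds ``log Pr(O | lambda_B) - log Pr(O | lambda_M)`` is the
confidence score used for ROC analysis and colormap rendering: positive
means benign-leaning, negative malignant-leaning.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .hmm import DiscreteHMM, FitResult, TrainConfig, baum_welch, forward_loglik, init_kmeans
from .preprocess import (
    BENIGN,
    MALIGNANT,
    Quantizer,
    RoiTimeSeries,
    first_difference,
    fit_quantizer,
    quantize,
)
from .simulate import Cohort


@dataclass(eq=False)
class ModelPair:
    """Trained malignant/benign HMM pair plus the shared quantizer.

    The quantizer travels with the models so test-time preprocessing is
    exactly the training fold's; both models share its alphabet so their
    log-likelihoods are comparable.
    """

    model_malignant: DiscreteHMM
    model_benign: DiscreteHMM
    quantizer: Quantizer
    config: TrainConfig
    provenance: str = ""
    fit_malignant: FitResult | None = None
    fit_benign: FitResult | None = None

    def __post_init__(self) -> None:
        m = self.quantizer.alphabet_size
        if self.model_malignant.n_symbols != m or self.model_benign.n_symbols != m:
            raise ValidationError(
                "both models must share n_symbols = quantizer.alphabet_size"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelPair):
            return NotImplemented
        return (
            self.model_malignant == other.model_malignant
            and self.model_benign == other.model_benign
            and self.quantizer == other.quantizer
            and self.config == other.config
            and self.provenance == other.provenance
        )


@dataclass(frozen=True)
class Prediction:
    """Per-ROI classification outcome.

    ``log_odds = loglik_benign - loglik_malignant``; the label is benign
    iff ``log_odds`` is strictly positive (ties resolve to malignant, the
    clinically conservative choice).
    """

    roi_id: str
    patient_id: str
    loglik_malignant: float
    loglik_benign: float
    log_odds: float
    label: str
    true_label: str = "unknown"


def train_pair(train: Cohort, config: TrainConfig) -> ModelPair:
    """Train ``lambda_M`` and ``lambda_B`` on a labeled training cohort.

    Pipeline: first differences -> one quantizer fitted on the pooled
    deltas of *both* classes (shared alphabet) -> per-class quantization
    -> per-class K-means initialization -> per-class Baum–Welch.
    Deterministic given ``config``.
    """
    by_class = {
        MALIGNANT: train.by_label(MALIGNANT),
        BENIGN: train.by_label(BENIGN),
    }
    for cls, rois in by_class.items():
        if not rois:
            raise ValidationError(f"training cohort has no {cls} ROIs")
    diffs = {
        cls: [first_difference(r) for r in rois] for cls, rois in by_class.items()
    }
    q = fit_quantizer(diffs[MALIGNANT] + diffs[BENIGN], config.alphabet_size)
    fits: dict[str, FitResult] = {}
    for cls in (MALIGNANT, BENIGN):
        seqs = [quantize(d, q) for d in diffs[cls]]
        init = init_kmeans(seqs, config.n_states, config.prob_floor, config.seed)
        fits[cls] = baum_welch(seqs, init, config)
    n_pat = len(train.patient_ids())
    provenance = (
        f"trained on {len(by_class[MALIGNANT])} malignant / "
        f"{len(by_class[BENIGN])} benign ROIs from {n_pat} patients "
        f"(N={config.n_states}, M={config.alphabet_size}, seed={config.seed})"
    )
    return ModelPair(
        model_malignant=fits[MALIGNANT].model,
        model_benign=fits[BENIGN].model,
        quantizer=q,
        config=config,
        provenance=provenance,
        fit_malignant=fits[MALIGNANT],
        fit_benign=fits[BENIGN],
    )


def score(pair: ModelPair, series: RoiTimeSeries) -> Prediction:
    """Score one ROI series under both models and assign a label."""
    seq = quantize(first_difference(series), pair.quantizer)
    ll_m = forward_loglik(pair.model_malignant, seq)
    ll_b = forward_loglik(pair.model_benign, seq)
    log_odds = ll_b - ll_m
    label = BENIGN if log_odds > 0 else MALIGNANT
    return Prediction(
        roi_id=series.roi_id,
        patient_id=series.patient_id,
        loglik_malignant=ll_m,
        loglik_benign=ll_b,
        log_odds=log_odds,
        label=label,
        true_label=series.label,
    )


def classify_cohort(pair: ModelPair, cohort: Cohort) -> list[Prediction]:
    """Score every record of a cohort, preserving input order."""
    out = []
    for r in cohort:
        try:
            out.append(score(pair, r))
        except Exception as exc:  # re-raise with ROI context
            raise type(exc)(f"while scoring ROI {r.roi_id!r}: {exc}") from exc
    return out
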