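"""File formats: cohort CSV, model-pair JSON, result CSVs, RF stacks.

All writers emit deterministic column/key order and contain no
wall-clock-dependent values, so reruns with identical inputs produce
byte-identical artifacts.  Probabilities serialize via Python's
shortest-round-trip ``repr`` (at most 17 significant digits), which
makes the model-pair JSON round-trip bit-exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ModelPair, Prediction
from .errors import IntegrityError, ParseError, SchemaError, ValidationError
from .evaluate import GridResult, MetricsRecord, RocCurve
from .hmm import DiscreteHMM, TrainConfig
from .preprocess import DEFAULT_FRAME_RATE, LABELS, Quantizer, RoiTimeSeries
from .simulate import Cohort

SCHEMA_VERSION = 1

_TIME_COL = re.compile(r"^t(\d+)$")


# ---------------------------------------------------------------------------
# cohort CSV


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as wide CSV: patient_id, roi_id, label, t000..tNNN."""
    if len(cohort) == 0:
        raise ValidationError("cannot write an empty cohort")
    n_t = len(cohort.records[0])
    width = max(3, len(str(n_t - 1)))
    cols = [f"t{i:0{width}d}" for i in range(n_t)]
    rows = []
    for r in cohort:
        row = {"patient_id": r.patient_id, "roi_id": r.roi_id, "label": r.label}
        row.update({c: v for c, v in zip(cols, r.values)})
        rows.append(row)
    pd.DataFrame(rows, columns=["patient_id", "roi_id", "label"] + cols).to_csv(
        path, index=False
    )


def read_cohort(path, frame_rate: float = DEFAULT_FRAME_RATE) -> Cohort:
    """Read a cohort CSV; lossless inverse of :func:`write_cohort`.

    The CSV stores no frame rate; pass ``frame_rate`` if the recording
    was not at the default 77 Hz.
    """
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "roi_id": str, "label": str},
        float_precision="round_trip",
    )
    for col in ("patient_id", "roi_id", "label"):
        if col not in df.columns:
            raise ParseError(f"cohort file {path} is missing column {col!r}")
    time_cols = sorted(
        (c for c in df.columns if _TIME_COL.match(c)),
        key=lambda c: int(_TIME_COL.match(c).group(1)),
    )
    if len(time_cols) < 2:
        raise ParseError(f"cohort file {path} has fewer than 2 time columns")
    seen: dict[tuple[str, str], int] = {}
    records = []
    for i, row in df.iterrows():
        key = (row["patient_id"], row["roi_id"])
        if key in seen:
            raise ParseError(
                f"duplicate (patient_id, roi_id) {key} at row {i + 2} "
                f"(first seen at row {seen[key] + 2})"
            )
        seen[key] = i
        if row["label"] not in LABELS:
            raise ParseError(f"row {i + 2}: label {row['label']!r} not in {LABELS}")
        values = pd.to_numeric(row[time_cols], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(values)):
            bad = time_cols[int(np.argmax(np.isnan(values)))]
            raise ParseError(f"row {i + 2}: non-numeric value in column {bad!r}")
        records.append(
            RoiTimeSeries(
                patient_id=row["patient_id"],
                roi_id=row["roi_id"],
                label=row["label"],
                values=values,
                frame_rate=frame_rate,
            )
        )
    return Cohort(records)


# ---------------------------------------------------------------------------
# model pair JSON


def _model_to_dict(model: DiscreteHMM) -> dict:
    return {
        "n_states": model.n_states,
        "n_symbols": model.n_symbols,
        "transition": model.transition.tolist(),
        "emission": model.emission.tolist(),
        "start": model.start.tolist(),
    }


def _model_from_dict(d: dict) -> DiscreteHMM:
    try:
        return DiscreteHMM(
            n_states=d["n_states"],
            n_symbols=d["n_symbols"],
            transition=np.array(d["transition"], dtype=float),
            emission=np.array(d["emission"], dtype=float),
            start=np.array(d["start"], dtype=float),
        )
    except ValidationError as exc:
        raise IntegrityError(f"model in file violates invariants: {exc}") from exc


def save_pair(pair: ModelPair, path) -> None:
    """Serialize a model pair to JSON with bit-exact probabilities."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "quantizer": {
            "alphabet_size": pair.quantizer.alphabet_size,
            "lo": pair.quantizer.lo,
            "hi": pair.quantizer.hi,
        },
        "config": asdict(pair.config),
        "model_malignant": _model_to_dict(pair.model_malignant),
        "model_benign": _model_to_dict(pair.model_benign),
        "provenance": pair.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_pair(path) -> ModelPair:
    """Load a model pair saved by :func:`save_pair`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse model file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    q = doc["quantizer"]
    cfg = doc["config"]
    config = TrainConfig(**{k: cfg[k] for k in (
        "n_states", "alphabet_size", "tol", "max_iter", "prob_floor", "seed"
    )})
    return ModelPair(
        model_malignant=_model_from_dict(doc["model_malignant"]),
        model_benign=_model_from_dict(doc["model_benign"]),
        quantizer=Quantizer(
            alphabet_size=q["alphabet_size"], lo=q["lo"], hi=q["hi"]
        ),
        config=config,
        provenance=doc.get("provenance", ""),
    )


# ---------------------------------------------------------------------------
# result CSVs


def write_predictions(predictions: list[Prediction], path) -> None:
    rows = [
        {
            "roi_id": p.roi_id,
            "patient_id": p.patient_id,
            "true_label": p.true_label,
            "loglik_malignant": p.loglik_malignant,
            "loglik_benign": p.loglik_benign,
            "log_odds": p.log_odds,
            "predicted_label": p.label,
        }
        for p in predictions
    ]
    pd.DataFrame(
        rows,
        columns=[
            "roi_id",
            "patient_id",
            "true_label",
            "loglik_malignant",
            "loglik_benign",
            "log_odds",
            "predicted_label",
        ],
    ).to_csv(path, index=False)


def read_predictions(path) -> list[Prediction]:
    df = pd.read_csv(path, dtype={"roi_id": str, "patient_id": str})
    return [
        Prediction(
            roi_id=r.roi_id,
            patient_id=r.patient_id,
            loglik_malignant=r.loglik_malignant,
            loglik_benign=r.loglik_benign,
            log_odds=r.log_odds,
            label=r.predicted_label,
            true_label=r.true_label,
        )
        for r in df.itertuples()
    ]


def write_metrics(records: list[MetricsRecord], path) -> None:
    """Metrics CSV, one row per patient plus the average row."""
    rows = [
        {
            "patient_id": r.patient_id,
            "accuracy": r.accuracy,
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "auc": r.auc,
            "tp": r.tp,
            "tn": r.tn,
            "fp": r.fp,
            "fn": r.fn,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "patient_id", "accuracy", "sensitivity", "specificity",
            "auc", "tp", "tn", "fp", "fn",
        ],
    ).to_csv(path, index=False)


def write_grid(result: GridResult, path) -> None:
    result.table.to_csv(path, index=False)


def write_roc(roc: RocCurve, path) -> None:
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# RF stacks


def load_rf_stack(path) -> np.ndarray:
    """Load a 3-D RF-frame stack (frames x axial x lateral) from a .npy file."""
    arr = np.load(path)
    if arr.ndim != 3:
        raise ValidationError(
            f"RF stack must be 3-D (frames, axial, lateral); got shape {arr.shape}"
        )
    return np.asarray(arr, dtype=float)
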