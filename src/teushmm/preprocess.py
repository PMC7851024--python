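"""Preprocessing of TeUS region-of-interest (ROI) signals.

A TeUS recording summarizes each ROI of the ultrasound frame grid as a
time series of mean echo intensities, one value per RF frame.  Before
HMM modeling each series is mapped to its first-order difference series
(the pattern of echo-intensity *change* carries the tissue-specific
information) and quantized into ``M`` equally spaced bins, producing a
discrete symbol sequence over the alphabet ``1..M``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

MALIGNANT = "malignant"
BENIGN = "benign"
UNKNOWN = "unknown"
LABELS = (MALIGNANT, BENIGN, UNKNOWN)

DEFAULT_FRAME_RATE = 77.0  # Hz


@dataclass(eq=False)
class RoiTimeSeries:
    """One ROI's labeled echo-intensity time series.

    Parameters
    ----------
    patient_id, roi_id
        Opaque identifiers; ``(patient_id, roi_id)`` is unique in a cohort.
    label
        One of ``"malignant"``, ``"benign"``, ``"unknown"``.
    values
        Mean echo intensity per frame, length ``T >= 2``, all finite.
    frame_rate
        Acquisition frame rate in Hz.
    """

    patient_id: str
    roi_id: str
    label: str
    values: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError(
                f"ROI {self.roi_id!r}: values must be a 1-D vector of length >= 2"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"ROI {self.roi_id!r}: values must be finite")
        if self.label not in LABELS:
            raise ValidationError(
                f"ROI {self.roi_id!r}: label {self.label!r} not in {LABELS}"
            )
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoiTimeSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.roi_id == other.roi_id
            and self.label == other.label
            and self.frame_rate == other.frame_rate
            and np.array_equal(self.values, other.values)
        )

    def __len__(self) -> int:
        return self.values.size


@dataclass(eq=False)
class DifferenceSeries:
    """First-order difference series of a :class:`RoiTimeSeries`."""

    deltas: np.ndarray
    patient_id: str = ""
    roi_id: str = ""
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.deltas.ndim != 1:
            raise ValidationError("deltas must be 1-D")

    def __len__(self) -> int:
        return self.deltas.size


@dataclass(frozen=True)
class Quantizer:
    """Equal-width quantizer over a fitted delta range.

    Bins are half-open ``[edge, next_edge)`` except the top bin, which is
    closed; values outside ``[lo, hi]`` clamp to the extreme bins so the
    mapping is total on test data.
    """

    alphabet_size: int
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ValidationError("alphabet_size must be >= 2")
        if not (self.lo < self.hi):
            raise ValidationError("quantizer requires lo < hi")

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.alphabet_size


@dataclass(eq=False)
class SymbolSequence:
    """Quantized observation sequence with symbols in ``1..M``."""

    symbols: np.ndarray
    alphabet_size: int
    patient_id: str = ""
    roi_id: str = ""
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1 or self.symbols.size < 1:
            raise ValidationError("symbols must be a nonempty 1-D integer vector")
        if self.symbols.min() < 1 or self.symbols.max() > self.alphabet_size:
            raise ValidationError(
                f"symbols must lie in 1..{self.alphabet_size} "
                f"(got range {self.symbols.min()}..{self.symbols.max()})"
            )

    def __len__(self) -> int:
        return self.symbols.size


@dataclass(frozen=True)
class GridSpec:
    """ROI grid geometry: RF samples averaged per ROI per frame.

    The default 44 axial samples x 2 lateral lines corresponds to a
    1.7 x 1.7 mm window (88 RF values) at typical transrectal-probe
    sampling.
    """

    axial_samples_per_roi: int = 44
    lateral_lines_per_roi: int = 2

    def __post_init__(self) -> None:
        if self.axial_samples_per_roi < 1 or self.lateral_lines_per_roi < 1:
            raise ValidationError("grid cell dimensions must be >= 1")


def average_rf_grid(
    frames: np.ndarray,
    grid: GridSpec = GridSpec(),
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> list[RoiTimeSeries]:
    """Summarize an RF-frame stack into per-ROI mean-intensity time series.

    ``frames`` is a 3-D array of shape ``(time, axial, lateral)``.  The
    frame is tiled with non-overlapping grid cells of
    ``axial_samples_per_roi x lateral_lines_per_roi`` RF values; the value
    of a ROI at time ``t`` is the arithmetic mean of its cell in frame
    ``t``.  Partial trailing cells are dropped.  Returned series are
    unlabeled; ``roi_id`` encodes the cell as ``"r{row}c{col}"``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValidationError("frames must be a 3-D array (time, axial, lateral)")
    if not np.all(np.isfinite(frames)):
        raise ValidationError("frames must be finite")
    n_t, n_ax, n_lat = frames.shape
    a, l = grid.axial_samples_per_roi, grid.lateral_lines_per_roi
    n_rows, n_cols = n_ax // a, n_lat // l
    if n_rows < 1 or n_cols < 1:
        raise ValidationError(
            f"array ({n_ax} axial x {n_lat} lateral) smaller than one "
            f"grid cell ({a} x {l})"
        )
    trimmed = frames[:, : n_rows * a, : n_cols * l]
    means = trimmed.reshape(n_t, n_rows, a, n_cols, l).mean(axis=(2, 4))
    return [
        RoiTimeSeries(
            patient_id="",
            roi_id=f"r{r}c{c}",
            label=UNKNOWN,
            values=means[:, r, c],
            frame_rate=frame_rate,
        )
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def first_difference(series: RoiTimeSeries) -> DifferenceSeries:
    """Map a length-``T`` series to its length-``T-1`` difference series,
    ``deltas[t] = values[t+1] - values[t]``."""
    if len(series) < 2:
        raise ValidationError("first_difference requires at least 2 time points")
    return DifferenceSeries(
        deltas=np.diff(series.values),
        patient_id=series.patient_id,
        roi_id=series.roi_id,
        label=series.label,
    )


def fit_quantizer(
    training: list[DifferenceSeries], alphabet_size: int
) -> Quantizer:
    """Fit equal-width bin edges to the pooled training deltas.

    ``lo``/``hi`` are the pooled minimum/maximum; a degenerate range
    (all deltas equal) is widened to ``[lo - 0.5, hi + 0.5]``.
    """
    if alphabet_size < 2:
        raise ValidationError("alphabet_size must be >= 2")
    pooled = [d.deltas for d in training if d.deltas.size > 0]
    if not pooled:
        raise ValidationError("fit_quantizer requires at least one nonempty series")
    allv = np.concatenate(pooled)
    lo, hi = float(allv.min()), float(allv.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return Quantizer(alphabet_size=alphabet_size, lo=lo, hi=hi)


def quantize(series: DifferenceSeries, q: Quantizer) -> SymbolSequence:
    """Quantize a difference series into symbols ``1..M``.

    ``symbol = clamp(floor((v - lo)/width) + 1, 1, M)``: half-open bins
    with a closed top bin; out-of-range values clamp to the extreme bins.
    """
    if series.deltas.size < 1:
        raise ValidationError("cannot quantize an empty difference series")
    raw = np.floor((series.deltas - q.lo) / q.bin_width).astype(np.int64) + 1
    symbols = np.clip(raw, 1, q.alphabet_size)
    return SymbolSequence(
        symbols=symbols,
        alphabet_size=q.alphabet_size,
        patient_id=series.patient_id,
        roi_id=series.roi_id,
        label=series.label,
    )
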