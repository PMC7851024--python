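"""Synthetic TeUS cohorts and HMM sequence sampling.

No public TeUS dataset exists, so this module generates patient-grouped,
labeled cohorts whose signals mimic the salient structure of real TeUS:
quasi-periodic echo-intensity oscillations in the 1–2 Hz band (tissue
micro-vibration driven by pulsation), sampled at 77 frames/s for 128
frames, with additive Gaussian noise and a lognormal per-patient
intensity scale.  Malignant and benign ROIs differ only in the
amplitudes of the two sinusoidal components, so the class signal lives
entirely in the *dynamics* — exactly what the difference-quantize-HMM
pipeline is designed to detect.

Each ROI draws from its own counter-based random substream keyed by
``(patient index, roi index)``, so adding patients or ROIs never
perturbs earlier draws, and swapping the class amplitude parameters
exactly swaps the malignant/benign series (class labels never influence
the noise draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .hmm import DiscreteHMM
from .preprocess import BENIGN, MALIGNANT, RoiTimeSeries, SymbolSequence

#: Default per-class sinusoid amplitude pairs. Malignant tissue is modeled
#: with larger micro-vibration amplitudes than benign; the 2.5x gap makes
#: the default classes separable by the HMM pipeline without being
#: trivially so at the default noise level (random per-ROI frequencies in
#: the 1-2 Hz band overlap the per-step delta scales of the two classes).
DEFAULT_AMP_MALIGNANT = (2.0, 1.0)
DEFAULT_AMP_BENIGN = (0.8, 0.4)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``amp_malignant``/``amp_benign`` are the amplitude pairs of the two
    sinusoidal components per class (intensity units); ``noise_sd`` is the
    per-frame Gaussian noise; ``patient_sd`` the lognormal sigma of the
    per-patient baseline multiplier; ``benign_only_patients`` makes the
    last patients contribute no malignant ROIs (as happens clinically when
    no significant malignant region is found).
    """

    n_patients: int = 12
    rois_per_patient_per_class: int = 12
    n_frames: int = 128
    frame_rate: float = 77.0
    baseline: float = 100.0
    amp_malignant: tuple[float, float] = DEFAULT_AMP_MALIGNANT
    amp_benign: tuple[float, float] = DEFAULT_AMP_BENIGN
    freq_band: tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 0.05
    patient_sd: float = 0.15
    benign_only_patients: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        if self.rois_per_patient_per_class < 1:
            raise ValidationError("rois_per_patient_per_class must be >= 1")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        lo, hi = self.freq_band
        if not (0 < lo <= hi < self.frame_rate / 2):
            raise ValidationError(
                "freq_band must lie within (0, frame_rate/2) with lo <= hi"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.patient_sd < 0:
            raise ValidationError("patient_sd must be >= 0")
        if not (0 <= self.benign_only_patients < self.n_patients):
            raise ValidationError(
                "benign_only_patients must be < n_patients and >= 0"
            )
        if len(self.amp_malignant) != 2 or len(self.amp_benign) != 2:
            raise ValidationError("amplitude parameters must be pairs")


@dataclass(eq=False)
class Cohort:
    """An ordered collection of labeled ROI time series."""

    records: list[RoiTimeSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValidationError("all cohort series must have the same length")
        for r in self.records:
            if not r.patient_id:
                raise ValidationError(f"ROI {r.roi_id!r} has an empty patient id")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patient_ids(self) -> list[str]:
        """Distinct patient ids in sorted order."""
        return sorted({r.patient_id for r in self.records})

    def subset(self, patient_ids) -> "Cohort":
        keep = set(patient_ids)
        return Cohort([r for r in self.records if r.patient_id in keep])

    def by_label(self, label: str) -> list[RoiTimeSeries]:
        return [r for r in self.records if r.label == label]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.records == other.records


def _roi_signal(
    spec: CohortSpec,
    rng: np.random.Generator,
    patient_gain: float,
    amps: tuple[float, float],
) -> np.ndarray:
    """One ROI series: DC baseline + two random-phase sinusoids + noise.

    Draw order (frequencies, phases, noise) is fixed so that the same
    substream produces identical stochastic components for either class.
    """
    lo, hi = spec.freq_band
    freqs = rng.uniform(lo, hi, size=2)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    eps = rng.standard_normal(spec.n_frames)
    t = np.arange(spec.n_frames)
    x = np.full(spec.n_frames, spec.baseline * patient_gain)
    for k in range(2):
        x = x + amps[k] * np.sin(2.0 * np.pi * freqs[k] * t / spec.frame_rate + phases[k])
    return x + spec.noise_sd * eps


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a patient-grouped labeled cohort, bit-reproducible per seed.

    Patient ``p`` receives ``rois_per_patient_per_class`` ROIs of each
    class, except the last ``benign_only_patients`` patients who receive
    benign ROIs only.  ROI ``(p, j)`` of either class shares the random
    substream keyed by ``(p, j)``, so class labels select amplitudes but
    never the noise realization.
    """
    records: list[RoiTimeSeries] = []
    n_benign_only = spec.benign_only_patients
    for p in range(spec.n_patients):
        gain_rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(p,))
        )
        gain = float(np.exp(gain_rng.normal(0.0, spec.patient_sd)))
        pid = f"P{p + 1:02d}"
        benign_only = p >= spec.n_patients - n_benign_only
        for label, amps in ((MALIGNANT, spec.amp_malignant), (BENIGN, spec.amp_benign)):
            if benign_only and label == MALIGNANT:
                continue
            for j in range(spec.rois_per_patient_per_class):
                rng = np.random.default_rng(
                    np.random.SeedSequence(spec.seed, spawn_key=(p, j))
                )
                values = _roi_signal(spec, rng, gain, amps)
                records.append(
                    RoiTimeSeries(
                        patient_id=pid,
                        roi_id=f"{pid}_{label[0]}{j:03d}",
                        label=label,
                        values=values,
                        frame_rate=spec.frame_rate,
                    )
                )
    return Cohort(records)


def generate_null_cohort(spec: CohortSpec) -> Cohort:
    """Calibration control: a cohort whose classes are identically distributed.

    Both classes are drawn with the *benign* amplitude pair, the
    "malignant"-labeled ROIs from the substreams of ``spec.seed`` and the
    benign ROIs from the independent substreams of ``spec.seed + 1``, so
    the labels carry no signal.  Any classifier evaluated on such a
    cohort should score at chance level.
    """
    from dataclasses import replace as _replace

    a = generate_cohort(_replace(spec, amp_malignant=spec.amp_benign))
    b = generate_cohort(
        _replace(spec, amp_malignant=spec.amp_benign, seed=spec.seed + 1)
    )
    records = [r for r in a if r.label == MALIGNANT]
    records += [r for r in b if r.label == BENIGN]
    return Cohort(records)


def sample_hmm(
    model: DiscreteHMM, length: int, n_sequences: int, seed: int
) -> list[SymbolSequence]:
    """Draw symbol sequences from an HMM's generative process.

    The chain starts in state 1 (the fixed start vector), then follows
    the transition matrix; each visited state emits one symbol from its
    emission row.  Deterministic given ``seed``.
    """
    model.validate()
    if length < 1:
        raise ValidationError("length must be >= 1")
    if n_sequences < 1:
        raise ValidationError("n_sequences must be >= 1")
    rng = np.random.default_rng(seed)
    N, M = model.n_states, model.n_symbols
    A_cdf = np.cumsum(model.transition, axis=1)
    B_cdf = np.cumsum(model.emission, axis=1)
    out = []
    for i in range(n_sequences):
        u_state = rng.random((length,))
        u_sym = rng.random((length,))
        states = np.empty(length, dtype=int)
        states[0] = 0
        for t in range(1, length):
            states[t] = np.searchsorted(A_cdf[states[t - 1]], u_state[t])
        symbols = np.empty(length, dtype=int)
        for t in range(length):
            symbols[t] = np.searchsorted(B_cdf[states[t]], u_sym[t])
        out.append(
            SymbolSequence(
                symbols=symbols + 1,
                alphabet_size=M,
                roi_id=f"sample_{i:04d}",
            )
        )
    return out


def make_toy_pair() -> tuple[DiscreteHMM, DiscreteHMM]:
    """The repository's canonical fixture: two fixed 3-state/10-symbol HMMs.

    The first model emits predominantly low symbols, the second high
    symbols, with distinct transition structure; their stationary emission
    mixtures are well separated (total-variation distance > 0.3), so
    likelihood-ratio classification between them is reliable at sequence
    length ~127.
    """
    a1 = [
        [0.70, 0.20, 0.10],
        [0.15, 0.70, 0.15],
        [0.10, 0.20, 0.70],
    ]
    b1 = [
        [0.45, 0.25, 0.10, 0.05, 0.04, 0.03, 0.03, 0.02, 0.02, 0.01],
        [0.02, 0.08, 0.30, 0.35, 0.15, 0.04, 0.02, 0.02, 0.01, 0.01],
        [0.01, 0.01, 0.03, 0.05, 0.15, 0.30, 0.25, 0.10, 0.06, 0.04],
    ]
    a2 = [
        [0.60, 0.30, 0.10],
        [0.10, 0.60, 0.30],
        [0.30, 0.10, 0.60],
    ]
    b2 = [
        [0.01, 0.02, 0.02, 0.03, 0.04, 0.08, 0.15, 0.30, 0.25, 0.10],
        [0.01, 0.01, 0.02, 0.02, 0.04, 0.10, 0.35, 0.30, 0.10, 0.05],
        [0.01, 0.01, 0.01, 0.02, 0.03, 0.05, 0.07, 0.15, 0.30, 0.35],
    ]
    m1 = DiscreteHMM(n_states=3, n_symbols=10, transition=a1, emission=b1)
    m2 = DiscreteHMM(n_states=3, n_symbols=10, transition=a2, emission=b2)
    return m1, m2


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary state distribution of a row-stochastic matrix.

    Computed as the left eigenvector of eigenvalue 1, normalized to sum 1.
    """
    A = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()
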