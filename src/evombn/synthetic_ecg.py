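"""Synthetic 12-lead ECG generator with lead-localized class signatures.

The generator produces two kinds of objects:

* continuous :class:`~evombn.data.EcgRecord` traces built from P/QRS/T bump
  templates repeated at a fixed beat rate, with optional baseline wander and
  white noise — input for the preprocessing chain; and
* labeled :class:`~evombn.data.BeatDataset` collections of 12 x 256 z-scored
  beats in which each MI subcategory perturbs the morphology *only on the
  leads facing its anatomical territory* (anterior V3/V4, septal V1/V2,
  lateral I/aVL/V5/V6, inferior II/III/aVF), so attention and localization
  behaviour can be verified against a known ground truth.

The model is deliberately minimal — Gaussian bumps for P and T, a narrow
biphasic spike for the QRS — not a dynamical heart simulator.  Its purpose is
a controllable, seeded signal whose class information lives on known leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BEAT_LENGTH, Beat, BeatDataset, EcgRecord
from .leads import CLASS_LEADS, CLASS_ORDER, LEAD_NAMES, lead_indices

#: Reference R-wave amplitude per lead (mV); sign encodes the dominant QRS
#: polarity (aVR and V1/V2 are predominantly negative).
R_AMP = np.array([0.9, 1.2, 0.6, -0.8, 0.4, 0.9, -0.5, -0.35, 0.6, 1.4, 1.3, 1.0])

#: (center s relative to R, width s, amplitude as multiple of R_AMP)
_COMPONENTS = {
    "P": (-0.18, 0.025, 0.12),
    "Q": (-0.028, 0.008, -0.12),
    "R": (0.0, 0.012, 1.0),
    "S": (0.028, 0.010, -0.30),
    "T": (0.25, 0.050, 0.30),
}

PERTURBATIONS = ("ST_elevation", "Q_deepening", "T_inversion")

#: Morphology change used by each MI subcategory.  The mapping is fixed so
#: overlapping lead territories (e.g. AMI vs ASMI) stay distinguishable.
CLASS_PERTURBATION = {
    "AMI": "ST_elevation",
    "ASMI": "Q_deepening",
    "ALMI": "T_inversion",
    "IMI": "ST_elevation",
    "ILMI": "T_inversion",
    "OMI": "ST_elevation",
}

DEFAULT_MAGNITUDE = 0.3  # fraction of the per-lead QRS amplitude


@dataclass(frozen=True)
class ClassSignature:
    """Which leads a diagnostic class affects and how."""

    class_label: str
    affected_leads: tuple[str, ...]
    perturbation: str | None
    magnitude: float = DEFAULT_MAGNITUDE

    def __post_init__(self):
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.perturbation is not None and self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if self.class_label == "HC" and self.affected_leads:
            raise ValueError("HC must have no affected leads")


def class_signature(label: str, rng: np.random.Generator | None = None,
                    magnitude: float = DEFAULT_MAGNITUDE) -> ClassSignature:
    """Build the signature for one class.

    OMI is a catch-all for infarct locations without enough records of their
    own, so its signature is a mild perturbation on a random 2-lead subset
    drawn from ``rng``; all other classes use their fixed anatomical leads.
    """
    if label == "HC":
        return ClassSignature("HC", (), None, 0.0)
    if label == "OMI":
        if rng is None:
            rng = np.random.default_rng(0)
        picks = rng.choice(12, size=2, replace=False)
        leads = tuple(LEAD_NAMES[i] for i in sorted(picks))
        return ClassSignature("OMI", leads, CLASS_PERTURBATION["OMI"], magnitude / 2)
    if label not in CLASS_LEADS:
        raise ValueError(f"unknown class label {label!r}")
    return ClassSignature(label, CLASS_LEADS[label], CLASS_PERTURBATION[label], magnitude)


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def cycle_waveform(t: np.ndarray) -> np.ndarray:
    """Clean 12-lead P-QRS-T cycle sampled at times ``t`` (s, R-wave at 0)."""
    wave = np.zeros((12, t.size))
    for center, width, rel_amp in _COMPONENTS.values():
        wave += (R_AMP * rel_amp)[:, None] * _gauss(t, center, width)[None, :]
    return wave


def perturbation_waveform(t: np.ndarray, kind: str, magnitude: float,
                          lead_idx: list[int]) -> np.ndarray:
    """Additive morphology change on the given leads, zero elsewhere.

    Amplitudes scale with each lead's QRS amplitude so the change survives
    per-lead z-scoring at a comparable relative size.
    """
    amp = magnitude * np.abs(R_AMP)
    shape = np.zeros((12, t.size))
    if kind == "ST_elevation":
        # raised plateau over the ST segment (~40-160 ms after the R-wave)
        bump = _gauss(t, 0.10, 0.045)
        shape[lead_idx] = amp[lead_idx, None] * bump[None, :]
    elif kind == "Q_deepening":
        bump = _gauss(t, -0.030, 0.009)
        shape[lead_idx] = -1.5 * amp[lead_idx, None] * bump[None, :]
    elif kind == "T_inversion":
        # cancel the upright T and push it below baseline
        _, width, rel = _COMPONENTS["T"]
        bump = _gauss(t, 0.25, width)
        t_amp = np.abs(R_AMP) * rel
        depth = (t_amp + amp)[lead_idx, None] * (magnitude / DEFAULT_MAGNITUDE)
        shape[lead_idx] = -depth * bump[None, :]
    else:
        raise ValueError(f"unknown perturbation {kind!r}")
    return shape


def generate_record(fs: float, duration: float, bpm: float, seed: int, *,
                    noise_sd: float = 0.01, baseline_amp: float = 0.05,
                    baseline_hz: float = 0.3, patient_id: str = "synthetic") -> EcgRecord:
    """Generate one continuous 12-lead record with planted R-peaks.

    Beats repeat every ``60/bpm`` seconds; ``rpeak_truth`` holds the exact QRS
    apex sample of every planted beat.  Baseline wander is a slow sinusoid and
    noise is white Gaussian, both per lead.
    """
    if duration <= 0 or bpm <= 0:
        raise ValueError("duration and bpm must be positive")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if duration * bpm / 60.0 < 1:
        raise ValueError("record must contain at least one beat")

    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    period = 60.0 / bpm
    # center the beat train so the first and last QRS complexes fit entirely
    r_indices = []
    r_time = 0.55 * period
    while r_time < duration - 0.3 * period:
        r_indices.append(int(round(r_time * fs)))
        r_time += period

    signal = np.zeros((12, n))
    for r in r_indices:
        signal += cycle_waveform(t - r / fs)
    if baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=12)
        signal += baseline_amp * np.sin(2 * np.pi * baseline_hz * t[None, :] + phase[:, None])
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=signal.shape)
    return EcgRecord(signal=signal, fs=fs, rpeak_truth=r_indices, patient_id=patient_id)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def generate_beat_dataset(n_per_class: int, classes=CLASS_ORDER, n_patients: int = 14,
                          noise_sd: float = 0.05, seed: int = 0, *,
                          magnitude: float = DEFAULT_MAGNITUDE,
                          fs: float = 250.0) -> BeatDataset:
    """Generate a labeled dataset of z-scored 12 x 256 beats.

    Each class contributes ``n_per_class`` beats built from the clean cycle
    template plus that class's perturbation on its signature leads, plus white
    noise.  Patients are dealt round-robin to classes and each patient carries
    exactly one class, so patient-wise splits are automatically class-pure.
    """
    classes = tuple(classes)
    if n_patients < len(classes):
        raise ValueError("need at least one patient per class")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    for c in classes:
        if c not in CLASS_ORDER:
            raise ValueError(f"unknown class label {c!r}")

    rng = np.random.default_rng(seed)
    t = (np.arange(BEAT_LENGTH) - 127) / fs
    base = cycle_waveform(t)

    # deal patients to classes round-robin: patient k carries classes[k % n_classes]
    patients_of = {c: [] for c in classes}
    for k in range(n_patients):
        patients_of[classes[k % len(classes)]].append(f"P{k:03d}")

    templates = {}
    for c in classes:
        sig = class_signature(c, rng=rng, magnitude=magnitude)
        wave = base.copy()
        if sig.perturbation is not None:
            wave += perturbation_waveform(
                t, sig.perturbation, sig.magnitude, lead_indices(sig.affected_leads))
        templates[c] = wave

    beats = []
    for c in classes:
        plist = patients_of[c]
        for j in range(n_per_class):
            x = templates[c] + (rng.normal(0.0, noise_sd, size=base.shape)
                                if noise_sd > 0 else 0.0)
            beats.append(Beat(_zscore_rows(x), label=c,
                              patient_id=plist[j % len(plist)], r_index=127))
    return BeatDataset(beats=beats, class_set=classes)
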