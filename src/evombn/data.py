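"""Core data containers: continuous records, segmented beats and beat datasets.

A :class:`Beat` is one P-QRS-T cycle as a 12 x 256 matrix (250 Hz, R-wave near
the center).  A :class:`BeatDataset` holds beats together with class labels and
patient identifiers so that train/test splits can partition *patients*, never
beats (the inter-patient paradigm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .leads import LEAD_NAMES

BEAT_LENGTH = 256
N_LEADS = 12


@dataclass
class EcgRecord:
    """A continuous multi-lead recording.

    Parameters
    ----------
    signal : ndarray, shape (12, T)
        Millivolt-scale samples, one row per lead.
    fs : float
        Sampling frequency in Hz.
    rpeak_truth : list of int, optional
        Sample indices of planted R-wave apices (synthetic records only).
    patient_id : str
        Opaque subject identifier.
    """

    signal: np.ndarray
    fs: float
    rpeak_truth: list[int] | None = None
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (leads x samples) array")
        if self.signal.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.rpeak_truth is not None:
            t = self.signal.shape[1]
            if any(not 0 <= r < t for r in self.rpeak_truth):
                raise ValueError("rpeak_truth indices must lie in [0, T)")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Beat:
    """One segmented, 12-lead, 256-sample heartbeat."""

    samples: np.ndarray
    label: str = "HC"
    patient_id: str = "unknown"
    r_index: int = -1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_LEADS, BEAT_LENGTH):
            raise ValueError(
                f"beat must be {N_LEADS} x {BEAT_LENGTH}, got {self.samples.shape}"
            )


@dataclass
class BeatDataset:
    """An ordered collection of beats with aligned labels and patient ids."""

    beats: list[Beat] = field(default_factory=list)
    class_set: tuple[str, ...] = ()
    lead_order: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        if len(self.lead_order) != N_LEADS:
            raise ValueError("lead_order must name exactly 12 leads")
        for b in self.beats:
            if self.class_set and b.label not in self.class_set:
                raise ValueError(f"beat label {b.label!r} not in class_set")

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def X(self) -> np.ndarray:
        """All beats stacked as an (n_beats, 12, 256) array."""
        return np.stack([b.samples for b in self.beats])

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.beats])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([b.patient_id for b in self.beats])

    def class_counts(self) -> dict[str, int]:
        labels = self.labels
        return {c: int(np.sum(labels == c)) for c in self.class_set}

    def subset(self, mask: np.ndarray) -> "BeatDataset":
        """Select beats by boolean mask or index array, keeping metadata."""
        idx = np.arange(len(self.beats))[mask]
        return BeatDataset(
            beats=[self.beats[i] for i in idx],
            class_set=self.class_set,
            lead_order=self.lead_order,
        )

    def relabel(self, mapping: dict[str, str], class_set: tuple[str, ...]) -> "BeatDataset":
        """Return a copy with labels mapped (e.g. collapsing MI subtypes to 'MI')."""
        beats = [
            Beat(b.samples, mapping.get(b.label, b.label), b.patient_id, b.r_index)
            for b in self.beats
        ]
        return BeatDataset(beats=beats, class_set=class_set, lead_order=self.lead_order)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write one row per beat: patient_id, class, 12*256 flattened samples."""
        n = len(self.beats)
        flat = np.stack([b.samples.ravel() for b in self.beats]) if n else np.empty((0, N_LEADS * BEAT_LENGTH))
        df = pd.DataFrame(flat, columns=[f"s{i}" for i in range(N_LEADS * BEAT_LENGTH)])
        df.insert(0, "class", self.labels if n else [])
        df.insert(0, "patient_id", self.patient_ids if n else [])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, class_set: tuple[str, ...] | None = None) -> "BeatDataset":
        df = pd.read_csv(path)
        sample_cols = [c for c in df.columns if c.startswith("s")]
        if len(sample_cols) != N_LEADS * BEAT_LENGTH:
            raise ValueError("CSV does not contain 12 x 256 sample columns")
        beats = [
            Beat(
                row[sample_cols].to_numpy(dtype=float).reshape(N_LEADS, BEAT_LENGTH),
                str(row["class"]),
                str(row["patient_id"]),
            )
            for _, row in df.iterrows()
        ]
        if class_set is None:
            seen = list(dict.fromkeys(b.label for b in beats))
            class_set = tuple(seen)
        return cls(beats=beats, class_set=class_set)
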