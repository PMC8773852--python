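"""Beat-level preprocessing: resampling, wavelet denoising, R-peak detection,
segmentation and z-score normalization.

The chain converts a raw multi-lead record into z-scored 256-sample beats:

1. downsample to 250 Hz;
2. Daubechies-6 wavelet filtering per lead — the approximation band (baseline
   wander) and the finest detail band (high-frequency noise) are zeroed before
   reconstruction;
3. R-wave detection on lead II (derivative -> squaring -> moving-window
   integration -> adaptive threshold, with apex refinement on the raw lead);
4. segmentation into windows of 127 samples left and 128 samples right of each
   R position (127 + 128 + 1 = 256), dropping windows that cross a record
   boundary;
5. per-lead z-scoring, z = (x - mu) / delta with the population standard
   deviation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .data import BEAT_LENGTH, Beat, BeatDataset, EcgRecord
from .leads import LEAD_INDEX

LEFT, RIGHT = 127, 128  # samples kept left/right of the R position
TARGET_FS = 250.0
ZSCORE_EPS = 1e-8


class DegenerateBeatError(ValueError):
    """Raised when a lead's standard deviation is too small to z-score."""


def resample_record(record: EcgRecord, target_fs: float = TARGET_FS) -> EcgRecord:
    """Downsample a record to ``target_fs`` (polyphase antialiasing filter).

    Only downsampling is supported; the output length is
    ``round(T * target_fs / fs)`` and planted R-peak indices are rescaled.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > record.fs:
        raise ValueError("upsampling is not supported; target_fs must be <= record fs")
    if target_fs == record.fs:
        return record

    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    out_len = int(round(record.n_samples * target_fs / record.fs))
    sig = sps.resample_poly(record.signal, frac.numerator, frac.denominator, axis=1)
    sig = sig[:, :out_len]
    if sig.shape[1] < out_len:  # polyphase length can undershoot by one
        sig = np.pad(sig, ((0, 0), (0, out_len - sig.shape[1])), mode="edge")
    rpeaks = None
    if record.rpeak_truth is not None:
        scale = target_fs / record.fs
        rpeaks = [min(int(round(r * scale)), out_len - 1) for r in record.rpeak_truth]
    return EcgRecord(signal=sig, fs=target_fs, rpeak_truth=rpeaks,
                     patient_id=record.patient_id)


def denoise(signal: np.ndarray, fs: float = TARGET_FS, *, wavelet: str = "db6",
            level: int = 8) -> np.ndarray:
    """Daubechies-6 wavelet filtering of one lead.

    Decompose to ``level`` scales, zero the approximation coefficients (slow
    baseline wander, incl. any DC offset) and the level-1 detail coefficients
    (the highest-frequency noise band), then reconstruct.  At 250 Hz with
    level 8 the zeroed approximation band lies below ~0.5 Hz and the zeroed
    detail band above ~62.5 Hz, bracketing the diagnostic ECG band.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("denoise operates on a single lead")
    w = pywt.Wavelet(wavelet)
    if x.size < w.dec_len:
        raise ValueError("signal shorter than the wavelet filter support")
    max_level = pywt.dwt_max_level(x.size, w.dec_len)
    eff_level = min(level, max_level) if max_level >= 1 else 1
    coeffs = pywt.wavedec(x, w, level=eff_level)
    coeffs[0] = np.zeros_like(coeffs[0])     # approximation: baseline wander
    coeffs[-1] = np.zeros_like(coeffs[-1])   # finest detail: HF noise
    rec = pywt.waverec(coeffs, w)
    return rec[: x.size]


def denoise_record(record: EcgRecord, *, wavelet: str = "db6", level: int = 8) -> EcgRecord:
    """Apply :func:`denoise` to every lead of a record."""
    sig = np.stack([denoise(row, record.fs, wavelet=wavelet, level=level)
                    for row in record.signal])
    return EcgRecord(signal=sig, fs=record.fs, rpeak_truth=record.rpeak_truth,
                     patient_id=record.patient_id)


def detect_rpeaks(signal: np.ndarray, fs: float) -> list[int]:
    """Locate R-wave apices in one lead.

    Built-in detector: band-pass (5-20 Hz) -> derivative -> squaring ->
    moving-window integration -> fixed-fraction adaptive threshold with a
    refractory distance, then apex refinement as the extremum of the band-
    passed lead within 100 ms of each integrated-energy peak.  Any external
    detector with the same ``(signal, fs) -> sorted indices`` contract can be
    substituted.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(signal, dtype=float)
    if x.size < 2 or np.allclose(x, x[0]):
        return []

    nyq = fs / 2.0
    b, a = sps.butter(2, [min(5.0, nyq * 0.2) / nyq, min(20.0, nyq * 0.8) / nyq],
                      btype="band")
    bp = sps.filtfilt(b, a, x)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(1, int(round(0.15 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")
    if mwi.max() <= 0:
        return []

    threshold = 0.3 * mwi.max()
    locs, _ = sps.find_peaks(mwi, height=threshold, distance=max(1, int(0.3 * fs)))
    half = max(1, int(round(0.10 * fs)))
    peaks: list[int] = []
    for p in locs:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        seg = bp[lo:hi]
        apex = lo + int(np.argmax(np.abs(seg)))
        if not peaks or apex - peaks[-1] >= int(0.25 * fs):
            peaks.append(apex)
    return sorted(set(peaks))


def segment_beats(record: EcgRecord, rpeaks, *, label: str = "HC") -> list[Beat]:
    """Cut the 12 x 256 window [r-127, r+128] (inclusive) around each R index.

    Peaks whose window would cross the record boundary are silently dropped.
    Beats are returned un-normalized; apply :func:`zscore` afterwards.
    """
    t = record.n_samples
    beats = []
    for r in rpeaks:
        if r - LEFT < 0 or r + RIGHT >= t:
            continue
        window = record.signal[:, r - LEFT: r + RIGHT + 1]
        beats.append(Beat(window.copy(), label=label,
                          patient_id=record.patient_id, r_index=int(r)))
    return beats


def zscore(beat: np.ndarray) -> np.ndarray:
    """Per-lead z-score z = (x - mu) / delta (population standard deviation).

    Raises :class:`DegenerateBeatError` naming the first offending lead if any
    lead is (numerically) constant.
    """
    x = np.asarray(beat, dtype=float)
    if x.ndim != 2 or x.shape[1] != BEAT_LENGTH:
        raise ValueError(f"beat must be leads x {BEAT_LENGTH}")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() <= ZSCORE_EPS)[0]
    if flat.size:
        raise DegenerateBeatError(
            f"lead index {flat[0]} has near-zero standard deviation; cannot z-score")
    return (x - mu) / sd


def preprocess_record(record: EcgRecord, *, target_fs: float = TARGET_FS,
                      detection_lead: str = "II", wavelet: str = "db6",
                      level: int = 8, label: str = "HC") -> list[Beat]:
    """Full chain: resample -> denoise -> detect (lead II) -> segment -> z-score."""
    rec = resample_record(record, target_fs) if record.fs != target_fs else record
    rec = denoise_record(rec, wavelet=wavelet, level=level)
    rpeaks = detect_rpeaks(rec.signal[LEAD_INDEX[detection_lead]], rec.fs)
    raw = segment_beats(rec, rpeaks, label=label)
    out = []
    for b in raw:
        try:
            out.append(Beat(zscore(b.samples), b.label, b.patient_id, b.r_index))
        except DegenerateBeatError:
            continue
    return out


def preprocess_records(records, **kwargs) -> BeatDataset:
    """Preprocess several records into one dataset (labels taken per record)."""
    beats = []
    labels = []
    for rec, lab in records:
        labels.append(lab)
        beats.extend(preprocess_record(rec, label=lab, **kwargs))
    class_set = tuple(dict.fromkeys(labels))
    return BeatDataset(beats=beats, class_set=class_set)
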