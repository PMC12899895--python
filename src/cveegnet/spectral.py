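"""Time-domain preprocessing and the complex spectral representation.

Pipeline order is fixed: sliding-window segmentation -> per-channel
z-scoring within the window -> full two-sided DFT.  Each 1 s window of a
C-channel recording becomes a C x F complex spectrum with F = T bins
(bin f covers f * fs / T Hz); no taper is applied and conjugate-symmetric
bins are kept, matching the width-T activations of the network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import List

import numpy as np

from .data import Recording

__all__ = [
    "EEGSegment", "ComplexSpectrum", "AmplitudePhase",
    "segment_recording", "segment_session", "zscore", "to_spectrum",
    "amplitude_phase", "preprocess_segments",
]

log = logging.getLogger(__name__)


@dataclass
class EEGSegment:
    """One analysis window of a trial: real (C, T) data plus provenance."""

    data: np.ndarray
    label: int
    subject_id: int = 0
    session_id: int = 0
    trial_id: int = 0
    fs: float = 200.0

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ComplexSpectrum:
    """Two-sided complex spectrum of one segment; F equals the window length."""

    real: np.ndarray  # (C, F)
    imag: np.ndarray  # (C, F)
    bin_hz: float

    @property
    def F(self) -> int:
        return self.real.shape[1]

    def numpy(self) -> np.ndarray:
        return self.real + 1j * self.imag


@dataclass
class AmplitudePhase:
    amplitude: np.ndarray  # (C, F), >= 0
    phase: np.ndarray      # (C, F), in (-pi, pi]


def segment_recording(recording: np.ndarray, fs: float, win_s: float = 1.0,
                      overlap_s: float = 0.5, *, label: int = 0, subject_id: int = 0,
                      session_id: int = 0, trial_id: int = 0) -> List[EEGSegment]:
    """Cut a (C, T_total) recording into overlapping windows.

    Windows of win_s seconds start every (win_s - overlap_s) seconds; a
    trailing partial window is dropped.  Every segment inherits the
    trial's label and identifiers.
    """
    if not 0 <= overlap_s < win_s:
        raise ValueError(f"need 0 <= overlap ({overlap_s}) < window ({win_s})")
    recording = np.asarray(recording)
    win = int(round(win_s * fs))
    hop = int(round((win_s - overlap_s) * fs))
    total = recording.shape[1]
    if win > total:
        warnings.warn(
            f"recording of {total} samples shorter than one {win}-sample window; "
            "no segments produced",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, total - win + 1, hop):
        out.append(EEGSegment(
            data=recording[:, start:start + win].copy(),
            label=label, subject_id=subject_id, session_id=session_id,
            trial_id=trial_id, fs=fs,
        ))
    return out


def segment_session(rec: Recording, win_s: float = 1.0, overlap_s: float = 0.5
                    ) -> List[EEGSegment]:
    """Segment every trial of a session; windows never cross trial bounds."""
    segments: List[EEGSegment] = []
    for trial in rec.trials:
        segments.extend(segment_recording(
            trial.data, rec.fs, win_s, overlap_s,
            label=trial.label, subject_id=rec.subject_id,
            session_id=rec.session_id, trial_id=trial.trial_id,
        ))
    return segments


def zscore(segment: EEGSegment) -> EEGSegment:
    """Standardize each channel to zero mean, unit variance within the window.

    A zero-variance channel carries no information inside the window; it is
    replaced by zeros and the event is logged.
    """
    data = segment.data
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    # a channel is flat when its spread is at rounding level relative to its mean
    flat = sd[:, 0] <= 1e-10 * (1.0 + np.abs(mean[:, 0]))
    if flat.any():
        log.warning(
            "zscore: %d zero-variance channel(s) in trial %d set to zeros",
            int(flat.sum()), segment.trial_id,
        )
    sd_safe = np.where(flat[:, None], 1.0, sd)
    z = (data - mean) / sd_safe
    z[flat] = 0.0
    return replace(segment, data=z)


def to_spectrum(segment: EEGSegment) -> ComplexSpectrum:
    """Full two-sided DFT per channel: x~(f) = sum_t x(t) e^{-j 2 pi f t / T}."""
    spec = np.fft.fft(segment.data, axis=1)
    return ComplexSpectrum(
        real=np.ascontiguousarray(spec.real),
        imag=np.ascontiguousarray(spec.imag),
        bin_hz=segment.fs / segment.n_samples,
    )


def amplitude_phase(spectrum: ComplexSpectrum) -> AmplitudePhase:
    """Polar view of a spectrum: A = |x~|, Phi = atan2(imag, real)."""
    return AmplitudePhase(
        amplitude=np.hypot(spectrum.real, spectrum.imag),
        phase=np.arctan2(spectrum.imag, spectrum.real),
    )


def preprocess_segments(segments: List[EEGSegment], dtype=np.float64):
    """segment -> zscore -> spectrum, stacked as network input.

    Returns (real, imag, labels): real/imag of shape (n, 1, C, F).
    """
    reals, imags, labels = [], [], []
    for seg in segments:
        spec = to_spectrum(zscore(seg))
        reals.append(spec.real)
        imags.append(spec.imag)
        labels.append(seg.label)
    xr = np.asarray(reals, dtype=dtype)[:, None, :, :]
    xi = np.asarray(imags, dtype=dtype)[:, None, :, :]
    return xr, xi, np.asarray(labels, dtype=np.int64)
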