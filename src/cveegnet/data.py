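"""Trial-structured EEG containers, HDF5 persistence, and a synthetic generator.

The generator emulates the statistical skeleton of emotion-elicitation EEG:
multiple trials per class, band-limited oscillations (1-50 Hz) riding on
1/f^alpha noise, with class information carried either by per-band
amplitude, by inter-channel phase offsets at matched power, or both.
Phase coding splits the montage into two equal channel groups; the second
group's oscillation is shifted by a class-specific phase, so single-channel
amplitude spectra are identical across classes and only the *relative*
phase between groups is informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "Trial", "Recording", "SynthSpec", "ContainerLayout",
    "generate_session", "save_recording", "load_recording", "DEFAULT_LAYOUT",
]


@dataclass
class Trial:
    data: np.ndarray          # (C, T) microvolt-scale samples
    label: int
    trial_id: int


@dataclass
class Recording:
    """One subject-session: a list of trials sharing montage and rate."""

    trials: List[Trial]
    fs: float
    channel_names: List[str]
    subject_id: int = 0
    session_id: int = 0

    def __post_init__(self):
        c = len(self.channel_names)
        for t in self.trials:
            if t.data.shape[0] != c:
                raise ValidationError(
                    f"trial {t.trial_id} has {t.data.shape[0]} channels, montage has {c}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def labels(self) -> List[int]:
        return [t.label for t in self.trials]


@dataclass
class SynthSpec:
    """Conditions for one synthetic subject-session.

    bands are (low_hz, high_hz, base_amplitude); each band contributes one
    sinusoid at its centre frequency snapped to an integer number of cycles
    per second, so 1 s analysis windows see it on the bin grid.  snr is the
    linear ratio of per-channel oscillation variance to noise variance.
    """

    K: int = 3
    C: int = 62
    fs: float = 200.0
    trial_seconds: float = 4.0
    trials_per_class: int = 20
    coding: str = "both"  # amplitude | phase | both
    bands: Sequence[Tuple[float, float, float]] = (
        (4.0, 7.0, 1.0),    # theta
        (8.0, 13.0, 1.0),   # alpha
        (14.0, 30.0, 1.0),  # beta
    )
    phase_offsets: Optional[Sequence[float]] = None  # per class, radians in (-pi, pi]
    amplitude_contrast: float = 2.0  # boost of a class's own band in amplitude coding
    snr: float = 5.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.coding not in ("amplitude", "phase", "both"):
            raise ConfigurationError(f"unknown coding {self.coding!r}")
        if self.snr <= 0:
            raise ConfigurationError("snr must be positive")
        if self.K < 2 or self.C < 2:
            raise ConfigurationError("need at least 2 classes and 2 channels")
        for lo, hi, amp in self.bands:
            if not (0 < lo <= hi < self.fs / 2):
                raise ConfigurationError(f"band ({lo},{hi}) outside (0, fs/2)")
            if amp <= 0:
                raise ConfigurationError("band amplitude must be positive")
        if self.phase_offsets is None:
            # evenly spaced class phases in (-pi, pi]
            self.phase_offsets = tuple(
                -math.pi + 2 * math.pi * (k + 1) / self.K for k in range(self.K)
            )
        if len(self.phase_offsets) != self.K:
            raise ConfigurationError("need one phase offset per class")
        for p in self.phase_offsets:
            if not (-math.pi < p <= math.pi + 1e-12):
                raise ConfigurationError("phase offsets must lie in (-pi, pi]")


def _pink_noise(rng: np.random.Generator, c: int, n: int, alpha: float) -> np.ndarray:
    """1/f^alpha noise via spectrally shaped random phases, unit variance rows."""
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    spec = (rng.standard_normal((c, f.size)) + 1j * rng.standard_normal((c, f.size))) * shape
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_session(spec: SynthSpec) -> Recording:
    """Deterministically synthesize one session of oscillatory trials."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.trial_seconds * spec.fs))
    t = np.arange(n) / spec.fs
    half = spec.C // 2
    group = (np.arange(spec.C) >= half).astype(float)  # 0 for group A, 1 for group B
    amp_code = spec.coding in ("amplitude", "both")
    phase_code = spec.coding in ("phase", "both")

    trials: List[Trial] = []
    n_trials = spec.K * spec.trials_per_class
    for trial_id in range(n_trials):
        label = trial_id % spec.K
        sig = np.zeros((spec.C, n))
        var_sig = 0.0
        for b, (lo, hi, base_amp) in enumerate(spec.bands):
            freq = float(round((lo + hi) / 2.0))
            amp = base_amp
            if amp_code and b == label % len(spec.bands):
                amp = base_amp * spec.amplitude_contrast
            offset = spec.phase_offsets[label] if phase_code else 0.0
            phase = group * offset  # group A at 0, group B shifted per class
            sig += amp * np.sin(2 * np.pi * freq * t[None, :] + phase[:, None])
            var_sig += amp * amp / 2.0
        noise = _pink_noise(rng, spec.C, n, spec.noise_exponent)
        noise *= np.sqrt(var_sig / spec.snr)
        trials.append(Trial(data=sig + noise, label=label, trial_id=trial_id))

    names = [f"CH{i + 1}" for i in range(spec.C)]
    return Recording(trials=trials, fs=spec.fs, channel_names=names,
                     subject_id=0, session_id=0)


# ---------------------------------------------------------------------------
# container I/O (hierarchical numeric-array file, one group per trial)
# ---------------------------------------------------------------------------

@dataclass
class ContainerLayout:
    """Maps container keys to trial arrays and metadata.

    Key names are configurable because trial-matrix containers from
    different dataset releases name their members differently.
    """

    trial_prefix: str = "trial_"
    data_key: str = "data"
    label_attr: str = "label"
    trial_id_attr: str = "trial_id"
    fs_attr: str = "fs"
    subject_attr: str = "subject_id"
    session_attr: str = "session_id"
    channels_attr: str = "channel_names"
    expected_channels: Optional[int] = None
    expected_fs: Optional[float] = None


DEFAULT_LAYOUT = ContainerLayout()


def save_recording(recording: Recording, path) -> None:
    """Write a Recording to an HDF5 container (lossless round-trip)."""
    if not recording.trials:
        raise ValueError("cannot save a recording with no trials")
    lay = DEFAULT_LAYOUT
    with h5py.File(path, "w") as f:
        f.attrs[lay.fs_attr] = recording.fs
        f.attrs[lay.subject_attr] = recording.subject_id
        f.attrs[lay.session_attr] = recording.session_id
        f.attrs[lay.channels_attr] = [str(c) for c in recording.channel_names]
        for tr in recording.trials:
            g = f.create_group(f"{lay.trial_prefix}{tr.trial_id:04d}")
            g.create_dataset(lay.data_key, data=tr.data)
            g.attrs[lay.label_attr] = tr.label
            g.attrs[lay.trial_id_attr] = tr.trial_id


def load_recording(path, layout: ContainerLayout = DEFAULT_LAYOUT) -> Recording:
    """Read a trial container back into a Recording, validating the layout."""
    with h5py.File(path, "r") as f:
        if layout.fs_attr not in f.attrs:
            raise FormatError(layout.fs_attr)
        fs = float(f.attrs[layout.fs_attr])
        subject = int(f.attrs.get(layout.subject_attr, 0))
        session = int(f.attrs.get(layout.session_attr, 0))
        names = [str(c) for c in f.attrs.get(layout.channels_attr, [])]
        trials = []
        groups = [k for k in f.keys() if k.startswith(layout.trial_prefix)]
        if not groups:
            raise FormatError(layout.trial_prefix)
        for key in groups:
            g = f[key]
            if layout.data_key not in g:
                raise FormatError(f"{key}/{layout.data_key}")
            if layout.label_attr not in g.attrs:
                raise FormatError(f"{key}@{layout.label_attr}")
            data = np.asarray(g[layout.data_key])
            trials.append(Trial(
                data=data,
                label=int(g.attrs[layout.label_attr]),
                trial_id=int(g.attrs.get(layout.trial_id_attr, len(trials))),
            ))
    trials.sort(key=lambda tr: tr.trial_id)
    if not names:
        names = [f"CH{i + 1}" for i in range(trials[0].data.shape[0])]
    if layout.expected_channels is not None:
        for tr in trials:
            if tr.data.shape[0] != layout.expected_channels:
                raise ValidationError(
                    f"trial {tr.trial_id}: expected {layout.expected_channels} channels, "
                    f"found {tr.data.shape[0]}"
                )
    if layout.expected_fs is not None and abs(fs - layout.expected_fs) > 1e-9:
        raise ValidationError(f"expected fs={layout.expected_fs}, container has {fs}")
    return Recording(trials=trials, fs=fs, channel_names=names,
                     subject_id=subject, session_id=session)
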