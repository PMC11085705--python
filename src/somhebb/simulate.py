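"""Synthetic 16-channel EEG with gesture-conditional band-power structure.

Real recordings of the facial gestures are not distributable, so the
package ships a generator that reproduces the statistical structure the
classifier consumes: each channel carries one random-frequency,
random-phase sinusoid per band (alpha, beta, theta) whose amplitude is
scaled by the gesture signature, clench gestures add band-passed white
noise (an EMG stand-in confined to the measured beta range), and white
Gaussian sensor noise is added everywhere.

A single sinusoid per band (rather than filtered noise) is a deliberate
choice: its band power has the closed form (amplitude)^2 / 2, which makes
every downstream stage checkable analytically.  The generator does not
attempt physiological realism (no 1/f background, no blink transients) —
only the class-conditional band-power geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import DEFAULT_BANDS
from .gestures import (
    N_BANDS,
    N_CHANNELS,
    GestureClass,
    GestureSignature,
    default_signatures,
)

DEFAULT_SAMPLE_RATE = 125.0  # Hz
DEFAULT_DURATION = 2.0  # seconds

#: Default per-segment noise levels; see docs/methods.md for rationale.
DEFAULT_NOISE_SD = 0.5
DEFAULT_AMPLITUDE_JITTER = 0.2
DEFAULT_BASE_AMPLITUDE = 1.0

_EMG_BAND = (14.0, 30.0)  # EMG stand-in stays inside the measured beta band


@dataclass
class EEGSegment:
    """A fixed-rate multichannel recording window.

    ``samples`` has shape (channels, time); default geometry is 16
    channels for 2 s at 125 Hz, i.e. 250 samples per channel.
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    channel_ids: tuple[int, ...] | None = None
    label: GestureClass | None = None
    seed: int | None = None  # generator seed, kept for provenance

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.sample_rate <= 0:
            raise ValueError("invalid geometry: sample_rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = tuple(range(1, self.samples.shape[0] + 1))
        elif len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def simulate_segment(
    gesture: GestureClass,
    signature_model: dict[GestureClass, GestureSignature] | None = None,
    duration: float = DEFAULT_DURATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    amplitude_jitter: float = DEFAULT_AMPLITUDE_JITTER,
    base_amplitude: float = DEFAULT_BASE_AMPLITUDE,
) -> EEGSegment:
    """Generate one labeled segment for a gesture.

    Each channel is the sum of three band-limited sinusoids (frequency
    uniform within the band, phase uniform), scaled by the signature
    multipliers and a per-sinusoid lognormal amplitude jitter, plus
    band-passed white noise on the EMG channels and white Gaussian noise
    of standard deviation ``noise_sd`` everywhere.  Identical inputs and
    seed give bit-identical output; the gesture id enters only through
    its signature.
    """
    try:
        gesture = GestureClass(gesture)
    except ValueError as exc:
        raise ValueError(f"unknown class: {gesture!r}") from exc
    if signature_model is None:
        signature_model = default_signatures()
    if gesture not in signature_model:
        raise ValueError(f"unknown class: {gesture!r} has no signature")
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("invalid geometry: duration and sample_rate must be positive")
    top = max(band.hi for band in DEFAULT_BANDS)
    if sample_rate <= 2 * top:
        raise ValueError(
            f"invalid geometry: sample_rate must exceed {2 * top} Hz"
        )
    n = int(round(duration * sample_rate))
    if abs(n - duration * sample_rate) > 1e-9:
        raise ValueError("invalid geometry: duration * sample_rate must be integral")

    sig = signature_model[gesture]
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sample_rate

    # Random draws happen in a fixed order, independent of the gesture id,
    # so that equal signatures give equal segments.
    freqs = np.empty((N_CHANNELS, N_BANDS))
    for b, band in enumerate(DEFAULT_BANDS):
        freqs[:, b] = rng.uniform(band.lo, band.hi, size=N_CHANNELS)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(N_CHANNELS, N_BANDS))
    jitter = rng.lognormal(mean=0.0, sigma=amplitude_jitter, size=(N_CHANNELS, N_BANDS))

    amp = base_amplitude * sig.multipliers * jitter  # (16, 3)
    # (16, 3, n) oscillations summed over bands
    osc = amp[:, :, None] * np.sin(
        2.0 * np.pi * freqs[:, :, None] * t[None, None, :] + phases[:, :, None]
    )
    samples = osc.sum(axis=1)

    if sig.emg_channels and sig.emg_gain > 0:
        white = rng.standard_normal((len(sig.emg_channels), n))
        nyq = sample_rate / 2.0
        b_, a_ = sps.butter(4, [_EMG_BAND[0] / nyq, _EMG_BAND[1] / nyq], btype="band")
        emg = sps.filtfilt(b_, a_, white, axis=-1) * sig.emg_gain
        for row, ch in enumerate(sig.emg_channels):
            samples[ch - 1] += emg[row]

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        samples += noise_sd * rng.standard_normal((N_CHANNELS, n))

    return EEGSegment(samples, sample_rate=sample_rate, label=gesture, seed=seed)


def generate_dataset(
    classes,
    n_per_class: int,
    seed: int = 0,
    **generator_params,
) -> list[EEGSegment]:
    """Labeled dataset: ``n_per_class`` segments for each class, in class order.

    Per-segment seeds derive deterministically from the master seed, so
    the same master seed reproduces the dataset exactly and each segment
    is statistically independent of the others.
    """
    classes = [GestureClass(c) for c in classes]
    if not classes:
        raise ValueError("classes must be non-empty")
    if len(set(classes)) != len(classes):
        raise ValueError("duplicate class in class list")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(classes) * n_per_class
    )
    segments = []
    i = 0
    for cls in classes:
        for _ in range(n_per_class):
            segments.append(
                simulate_segment(cls, seed=int(child_seeds[i]), **generator_params)
            )
            i += 1
    return segments


def expected_band_powers(
    sig: GestureSignature,
    base_amplitude: float = DEFAULT_BASE_AMPLITUDE,
    amplitude_jitter: float = DEFAULT_AMPLITUDE_JITTER,
) -> np.ndarray:
    """Noise-free expected band power per channel x band, analytically.

    A sinusoid of amplitude A has mean-square power A^2/2; the lognormal
    jitter J with log-sd s has E[J^2] = exp(2 s^2).  The EMG stand-in is
    band-passed unit white noise, whose expected power is approximately
    gain^2 times the fraction of the Nyquist range the pass band covers —
    all of it landing in the beta band.
    """
    amp2 = (base_amplitude * sig.multipliers) ** 2 / 2.0
    amp2 *= np.exp(2.0 * amplitude_jitter**2)
    out = amp2.copy()
    if sig.emg_channels and sig.emg_gain > 0:
        nyq = DEFAULT_SAMPLE_RATE / 2.0
        frac = (_EMG_BAND[1] - _EMG_BAND[0]) / nyq
        beta_idx = 1
        for ch in sig.emg_channels:
            out[ch - 1, beta_idx] += sig.emg_gain**2 * frac
    return out
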