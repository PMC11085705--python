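"""Band-power feature extraction.

An EEG segment is reduced to a 48-dimensional feature vector: the
absolute power in the alpha (8-13 Hz), beta (14-30 Hz) and theta
(4-7 Hz) bands of each of the 16 channels, laid out band-major
(alpha ch1..16, beta ch1..16, theta ch1..16).

The spectral estimator is a Welch averaged periodogram (Hann window,
1 s windows, 50% overlap, density scaling); band power is the
trapezoidal integral of the density over the frequency bins whose
centers fall inside the closed band interval.  Powers are absolute and
linear — no log transform and no relative normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import ALPHA, BETA, THETA, Band, DEFAULT_BANDS
from .simulate import EEGSegment

__all__ = [
    "Band", "ALPHA", "BETA", "THETA", "DEFAULT_BANDS", "FeatureVector",
    "power_spectrum", "band_power", "build_feature_vector",
    "features_from_segments", "zscore_features",
]

DEFAULT_WINDOW_LENGTH = 1.0  # seconds
DEFAULT_OVERLAP = 0.5


@dataclass(frozen=True)
class FeatureVector:
    """A band-major band-power vector with its (optional) source label."""

    values: np.ndarray
    source_label: object | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("feature values must be one-dimensional")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("feature values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def power_spectrum(
    segment: EEGSegment,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel power spectral density of a segment.

    Returns ``(freqs, psd)`` with ``psd`` of shape (channels, n_freqs) in
    units of power per Hz, so that the integral of a channel's density
    over the full grid approximates its mean squared amplitude.

    Raises
    ------
    ValueError
        If the segment is shorter than one window ("segment too short")
        or the overlap fraction is outside [0, 1).
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    fs = segment.sample_rate
    nperseg = int(round(window_length * fs))
    if nperseg <= 0 or nperseg > segment.n_samples:
        raise ValueError("segment too short for the requested window length")
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, psd = sps.welch(
        segment.samples,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: Band) -> np.ndarray:
    """Integrate a density over one band; returns one value per channel.

    Bins whose centers fall in the closed interval [lo, hi] are selected
    and integrated trapezoidally.  Raises ValueError if no bin falls in
    the band ("band unresolved at this resolution") or the band exceeds
    the Nyquist range of the grid.
    """
    if band.hi > freqs[-1] + 1e-9:
        raise ValueError(f"band {band.name} exceeds the Nyquist frequency")
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    if not np.any(mask):
        raise ValueError(f"band {band.name} unresolved at this resolution")
    sel = np.atleast_2d(psd)[:, mask]
    if mask.sum() == 1:
        # Degenerate single-bin band: use the bin's power content directly.
        df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
        return sel[:, 0] * df
    return np.trapezoid(sel, freqs[mask], axis=-1)


def build_feature_vector(
    segment: EEGSegment,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> FeatureVector:
    """Convert a segment to its band-major band-power feature vector.

    Length is ``len(bands) * n_channels`` — 48 for the default 16-channel
    headset and three bands.  Extraction is pure and deterministic.
    """
    freqs, psd = power_spectrum(segment, window_length, overlap_fraction)
    blocks = [band_power(freqs, psd, band) for band in bands]
    return FeatureVector(np.concatenate(blocks), source_label=segment.label)


def features_from_segments(
    segments,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> tuple[np.ndarray, list]:
    """Feature matrix (n_segments, D) and label list for a segment batch."""
    vecs = [
        build_feature_vector(s, bands, window_length, overlap_fraction)
        for s in segments
    ]
    X = np.stack([v.values for v in vecs])
    labels = [v.source_label for v in vecs]
    return X, labels


def zscore_features(X: np.ndarray) -> np.ndarray:
    """Optional per-dimension z-scoring (off by default in the pipeline)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd
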