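"""Facial gesture classes and their EEG/EMG signatures.

The recognizer deliberately exploits muscle (EMG) artifacts instead of
removing them: eye closure raises posterior alpha power, clenching the
teeth on one side injects broadband EMG power into the temporal electrode
on that side, and opening the eyes wide raises frontal power.  A gesture
is therefore characterised by a per-channel, per-band amplitude pattern
plus an optional EMG component on specific channels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

N_CHANNELS = 16
#: Band order used everywhere: alpha, beta, theta.
BAND_NAMES = ("alpha", "beta", "theta")
N_BANDS = len(BAND_NAMES)


class GestureClass(enum.IntEnum):
    """The seven facial gestures, ordered; experiment subsets are prefixes."""

    G1 = 1  # open eyes
    G2 = 2  # close eyes
    G3 = 3  # open eyes, clench right teeth
    G4 = 4  # open eyes, clench left teeth
    G5 = 5  # open eyes wide
    G6 = 6  # close eyes, clench right teeth
    G7 = 7  # close eyes, clench left teeth

    @property
    def description(self) -> str:
        return _DESCRIPTIONS[self]


_DESCRIPTIONS = {
    GestureClass.G1: "open eyes",
    GestureClass.G2: "close eyes",
    GestureClass.G3: "open eyes and clench right teeth",
    GestureClass.G4: "open eyes and clench left teeth",
    GestureClass.G5: "open eyes wide",
    GestureClass.G6: "close eyes and clench right teeth",
    GestureClass.G7: "close eyes and clench left teeth",
}

#: The four class subsets used in the recognition experiments.
CLASS_SUBSETS = {
    2: tuple(GestureClass)[:2],
    4: tuple(GestureClass)[:4],
    5: tuple(GestureClass)[:5],
    7: tuple(GestureClass)[:7],
}


@dataclass(frozen=True)
class ChannelRoles:
    """Which electrodes play which role (1-based channel ids).

    Only relative roles matter to the method, so the montage is
    configuration, not hard-coded: the defaults put the frontal pair on
    channels 1-2, the posterior pair on 7-8 and the temporal electrodes
    picking up left/right jaw EMG on 13 and 14.
    """

    frontal: tuple[int, ...] = (1, 2)
    posterior: tuple[int, ...] = (7, 8)
    left_temporal: int = 13
    right_temporal: int = 14


@dataclass(frozen=True)
class GestureSignature:
    """Per-channel x per-band amplitude multipliers plus an EMG component.

    ``multipliers`` has shape (16, 3) over bands (alpha, beta, theta); an
    all-ones matrix with ``emg_gain == 0`` reproduces the unmodulated
    background.  ``emg_channels`` lists 1-based channel ids that receive
    broadband EMG-like power scaled by ``emg_gain``.
    """

    multipliers: np.ndarray
    emg_channels: tuple[int, ...] = ()
    emg_gain: float = 0.0

    def __post_init__(self) -> None:
        mult = np.asarray(self.multipliers, dtype=float)
        if mult.shape != (N_CHANNELS, N_BANDS):
            raise ValueError(
                f"multipliers must have shape ({N_CHANNELS}, {N_BANDS}), "
                f"got {mult.shape}"
            )
        if not np.all(np.isfinite(mult)) or np.any(mult < 0):
            raise ValueError("multipliers must be finite and non-negative")
        if self.emg_gain < 0:
            raise ValueError("emg_gain must be non-negative")
        object.__setattr__(self, "multipliers", mult)
        object.__setattr__(self, "emg_channels", tuple(self.emg_channels))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GestureSignature):
            return NotImplemented
        return (
            np.array_equal(self.multipliers, other.multipliers)
            and self.emg_channels == other.emg_channels
            and self.emg_gain == other.emg_gain
        )


def baseline_signature() -> GestureSignature:
    """All-ones multipliers, no EMG: the unmodulated background."""
    return GestureSignature(np.ones((N_CHANNELS, N_BANDS)))


def default_signatures(
    roles: ChannelRoles | None = None,
    *,
    alpha_boost: float = 3.5,
    frontal_boost: float = 1.6,
    emg_gain: float = 3.5,
    wide_eyes_temporal_beta: float = 2.0,
) -> dict[GestureClass, GestureSignature]:
    """Build the default gesture -> signature map.

    ``alpha_boost`` multiplies posterior alpha amplitude for eyes-closed
    gestures, ``frontal_boost`` multiplies all bands on the frontal
    channels for eyes-wide-open, and ``emg_gain`` scales the broadband EMG
    injected into the clenching-side temporal channel.  Opening the eyes
    wide also activates scalp regions near the temporal electrodes, so the
    eyes-wide signature additionally raises beta amplitude on channels 13
    and 14 by ``wide_eyes_temporal_beta`` — weaker than, but of the same
    character as, the clench EMG, which makes the eyes-wide gesture partly
    confusable with the clench gestures.  The effect sizes are free
    parameters of the simulator (the underlying observations are
    qualitative); the defaults give well-separated but noisy classes.
    """
    roles = roles or ChannelRoles()
    a = BAND_NAMES.index("alpha")
    b = BAND_NAMES.index("beta")

    def base() -> np.ndarray:
        return np.ones((N_CHANNELS, N_BANDS))

    def closed_eyes(mult: np.ndarray) -> np.ndarray:
        for ch in roles.posterior:
            mult[ch - 1, a] *= alpha_boost
        return mult

    def wide_eyes(mult: np.ndarray) -> np.ndarray:
        for ch in roles.frontal:
            mult[ch - 1, :] *= frontal_boost
        for ch in (roles.left_temporal, roles.right_temporal):
            mult[ch - 1, b] *= wide_eyes_temporal_beta
        return mult

    left = (roles.left_temporal,)
    right = (roles.right_temporal,)
    return {
        GestureClass.G1: GestureSignature(base()),
        GestureClass.G2: GestureSignature(closed_eyes(base())),
        GestureClass.G3: GestureSignature(base(), right, emg_gain),
        GestureClass.G4: GestureSignature(base(), left, emg_gain),
        GestureClass.G5: GestureSignature(wide_eyes(base())),
        GestureClass.G6: GestureSignature(closed_eyes(base()), right, emg_gain),
        GestureClass.G7: GestureSignature(closed_eyes(base()), left, emg_gain),
    }
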