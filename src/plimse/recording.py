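"""Core containers: multichannel recordings, frequency bands, epoch sets.

A :class:`Recording` holds a channels x time matrix in arbitrary (microvolt-like)
units together with its sampling rate and ordered channel labels.  The default
montage is the 16-site subset of the international 10-20 system used for
resting-state clinical EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: 16-channel 10-20 montage (frontal to occipital order).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8", "C3",
    "C4", "P3", "Pz", "P4", "T5", "T6", "O1", "O2",
)


@dataclass(frozen=True)
class Band:
    """A frequency band delimited by half-power edges in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )

    def validate_against_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz is at or above "
                f"the Nyquist frequency {fs / 2.0} Hz"
            )


#: Canonical EEG band set; shared edges belong to both adjacent bands.
CANONICAL_BANDS: tuple[Band, ...] = (
    Band("delta", 2.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 60.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


def get_band(name: str) -> Band:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {BAND_NAMES}")


@dataclass
class Recording:
    """Multichannel time series.

    Parameters
    ----------
    samples
        Array of shape (n_channels, n_samples), microvolt-like units.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered unique labels, one per channel.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = field(default=DEFAULT_MONTAGE)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with replaced sample data."""
        return replace(self, samples=samples)


@dataclass
class EpochSet:
    """Fixed-length non-overlapping epochs cut from one recording.

    ``data`` has shape (n_epochs, n_channels, n_samples_per_epoch).
    """

    data: np.ndarray
    fs: float
    epoch_length_s: float
    channel_labels: tuple[str, ...]
    band: Band | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        n_per_epoch = self.epoch_length_s * self.fs
        if abs(n_per_epoch - round(n_per_epoch)) > 1e-9:
            raise ValueError("epoch_length_s x fs must be an integer sample count")
        if self.data.shape[2] != round(n_per_epoch):
            raise ValueError("epoch sample count does not match epoch_length_s x fs")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]
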