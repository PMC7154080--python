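"""Preprocessing: edge trimming, zero-phase band-pass decomposition, epoching.

The analysis convention is: start from a 60-s continuous segment, drop 1,000
samples at each end to discard filter transients (leaving a 50-s core), filter
the continuous core into canonical bands, and only then cut 5-s epochs — so no
epoch boundary ever sees a filter edge transient.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import Band, EpochSet, Recording

DEFAULT_TRIM_SAMPLES = 1000
DEFAULT_EPOCH_LENGTH_S = 5.0
DEFAULT_FILTER_ORDER = 4


def trim_edges(rec: Recording, n_edge: int = DEFAULT_TRIM_SAMPLES) -> Recording:
    """Remove ``n_edge`` samples from each end of the recording.

    The interior samples are returned unchanged; length shrinks by exactly
    ``2 * n_edge``.
    """
    if n_edge < 0:
        raise ValueError("n_edge must be non-negative")
    if n_edge == 0:
        return rec.with_samples(rec.samples.copy())
    if rec.n_samples <= 2 * n_edge:
        raise ValueError(
            f"recording of {rec.n_samples} samples is too short to trim "
            f"{n_edge} samples from each end"
        )
    return rec.with_samples(rec.samples[:, n_edge:-n_edge].copy())


def bandpass_sos(band: Band, fs: float, order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Butterworth band-pass in second-order sections, half-power at band edges."""
    band.validate_against_fs(fs)
    return signal.butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: Recording, band: Band, order: int = DEFAULT_FILTER_ORDER) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass of every channel.

    Zero phase is mandatory here: downstream phase-synchronization measures
    would be biased by any filter phase delay.
    """
    sos = bandpass_sos(band, rec.fs, order=order)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return rec.with_samples(np.ascontiguousarray(filtered))


def notch(rec: Recording, freq: float = 60.0, q: float = 30.0) -> Recording:
    """Optional line-noise notch for real acquisitions; synthetic data skips it."""
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    return rec.with_samples(signal.filtfilt(b, a, rec.samples, axis=-1))


def acquisition_bandpass(rec: Recording, f_lo: float = 1.5, f_hi: float = 60.0,
                         order: int = DEFAULT_FILTER_ORDER) -> Recording:
    """Optional acquisition-side broadband filter (1.5-60 Hz) for real data."""
    return bandpass(rec, Band("acquisition", f_lo, f_hi), order=order)


def segment_epochs(rec: Recording, epoch_length_s: float = DEFAULT_EPOCH_LENGTH_S,
                   band: Band | None = None) -> EpochSet:
    """Cut consecutive non-overlapping epochs from the start of the recording.

    The trailing remainder shorter than one epoch is dropped; the epoch count
    is ``floor(n_samples / (fs * epoch_length_s))``.
    """
    n_per_epoch_f = rec.fs * epoch_length_s
    if abs(n_per_epoch_f - round(n_per_epoch_f)) > 1e-9:
        raise ValueError("epoch_length_s x fs must be an integer sample count")
    n_per_epoch = int(round(n_per_epoch_f))
    if n_per_epoch < 1:
        raise ValueError("epoch length must be at least one sample")
    n_epochs = rec.n_samples // n_per_epoch
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{n_per_epoch}-sample epoch"
        )
    used = rec.samples[:, : n_epochs * n_per_epoch]
    data = used.reshape(rec.n_channels, n_epochs, n_per_epoch).swapaxes(0, 1)
    return EpochSet(
        data=np.ascontiguousarray(data),
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        channel_labels=rec.channel_labels,
        band=band,
    )
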