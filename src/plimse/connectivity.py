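"""Phase-synchronization connectivity: phase lag index and node degree.

The phase lag index (PLI) between channels a and b over T samples is

    PLI_ab = | (1/T) * sum_i sign(dphi(t_i)) |

where dphi is the instantaneous phase difference phi_a - phi_b wrapped into
(-pi, pi] and sign(0) = 0.  A consistently lagged pair scores near 1; random
phase relationships, and zero-lag relationships as produced by a common
(volume-conducted) source, score near 0.  The node degree of electrode a is
the mean PLI of a against all other electrodes.

Phases are extracted from the analytic signal of the *continuous* band-passed
recording and only then cut into epochs, so per-epoch Hilbert edge transients
never enter the phase estimates; PLI is computed per epoch and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .preprocess import segment_epochs
from .recording import Band, EpochSet, Recording


@dataclass
class PhaseEpochs:
    """Instantaneous phases (radians, (-pi, pi]) and amplitude envelopes.

    ``phases`` and ``amplitudes`` both have shape (epochs, channels, samples).
    The amplitude envelope is carried for completeness but not analysed
    further downstream.
    """

    phases: np.ndarray
    amplitudes: np.ndarray
    channel_labels: tuple[str, ...]
    fs: float
    band: Band | None = None

    @property
    def n_epochs(self) -> int:
        return self.phases.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phases.shape[1]


@dataclass
class PLIMatrix:
    """Symmetric, zero-diagonal matrix of pairwise PLI values in [0, 1]."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band: Band | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLI matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("PLI matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.channel_labels)
        return pd.DataFrame(self.values, index=labels, columns=labels)


def hilbert_phase(epochs_or_rec: EpochSet | Recording) -> PhaseEpochs:
    """Instantaneous phase and amplitude of every channel via the analytic signal.

    Accepts either a continuous band-limited :class:`Recording` (treated as a
    single epoch) or an :class:`EpochSet` whose epochs are contiguous slices of
    one continuous signal.  For an EpochSet the transform runs on the
    concatenated signal and the result is re-epoched, keeping epoch boundaries
    free of transform edge effects.
    """
    if isinstance(epochs_or_rec, Recording):
        rec = epochs_or_rec
        es = segment_epochs(rec, rec.n_samples / rec.fs)
    else:
        es = epochs_or_rec
    n_epochs, n_channels, n_per = es.data.shape
    if n_per < 2:
        raise ValueError("epochs too short for phase extraction")
    continuous = es.data.swapaxes(0, 1).reshape(n_channels, n_epochs * n_per)
    if np.any(np.all(continuous == 0.0, axis=1)):
        raise ValueError("all-zero channel has undefined phase")
    analytic = hilbert(continuous, axis=-1)
    phases = np.angle(analytic)
    amplitudes = np.abs(analytic)
    shape = (n_channels, n_epochs, n_per)
    return PhaseEpochs(
        phases=phases.reshape(shape).swapaxes(0, 1).copy(),
        amplitudes=amplitudes.reshape(shape).swapaxes(0, 1).copy(),
        channel_labels=es.channel_labels,
        fs=es.fs,
        band=es.band,
    )


def phase_difference(phi_a: np.ndarray, phi_b: np.ndarray) -> np.ndarray:
    """Pointwise phase difference wrapped into (-pi, pi]."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ValueError("phase series must have equal length")
    d = np.mod(phi_a - phi_b, 2.0 * np.pi)  # [0, 2*pi)
    d = np.where(d > np.pi, d - 2.0 * np.pi, d)  # (-pi, pi]
    return d


#: Differences smaller than this (radians) are treated as exactly zero lag.
#: Phases of scaled copies of one signal agree only to floating precision, so
#: a strict sign(0) = 0 would let ~1e-16 rounding dust masquerade as lag.
ZERO_LAG_TOL = 1e-8


def _signed(delta_phi: np.ndarray) -> np.ndarray:
    return np.where(np.abs(delta_phi) <= ZERO_LAG_TOL, 0.0, np.sign(delta_phi))


def pli(delta_phi: np.ndarray) -> float:
    """Phase lag index of a wrapped phase-difference series.

    ``|mean(sign(dphi))|`` with sign(0) = 0 — the zero-lag case therefore
    contributes nothing, which is what makes the index blind to common
    (volume-conducted) sources.  Differences within ``ZERO_LAG_TOL`` of zero
    count as zero lag.
    """
    delta_phi = np.asarray(delta_phi, dtype=float)
    if delta_phi.size == 0:
        raise ValueError("empty phase-difference series")
    return float(abs(np.mean(_signed(delta_phi))))


def pli_matrix(phase_epochs: PhaseEpochs) -> PLIMatrix:
    """Pairwise PLI per epoch, averaged over epochs, for all channel pairs."""
    ph = phase_epochs.phases
    n_epochs, n_channels, _ = ph.shape
    if n_channels < 2:
        raise ValueError("need at least two channels for pairwise PLI")
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    out = np.zeros((n_channels, n_channels))
    for a in range(n_channels):
        # vectorized over the partner channels b > a and over epochs
        d = np.mod(ph[:, a:a + 1, :] - ph[:, a + 1:, :], 2.0 * np.pi)
        d = np.where(d > np.pi, d - 2.0 * np.pi, d)
        per_epoch = np.abs(np.mean(_signed(d), axis=-1))  # (epochs, partners)
        out[a, a + 1:] = per_epoch.mean(axis=0)
    out = out + out.T
    return PLIMatrix(values=out, channel_labels=phase_epochs.channel_labels,
                     band=phase_epochs.band)


def node_degree(pli_mat: PLIMatrix) -> np.ndarray:
    """Per-electrode mean PLI to all other electrodes (the node degree)."""
    k = pli_mat.n_channels
    if k < 2:
        raise ValueError("node degree needs at least two channels")
    return pli_mat.values.sum(axis=1) / (k - 1)
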