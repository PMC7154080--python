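"""Synthetic EEG cohorts with tunable phase coupling and temporal complexity.

The generator emulates the structure assumed by the downstream analyses rather
than the biophysics of cortex: each channel is a sum over the five canonical
bands of *coupled* band-limited components plus broadband 1/f^beta noise.

Coupling mechanism.  For each band one shared band-limited oscillator s(t) is
drawn; channel i receives a copy phase-delayed by a per-channel lag and mixed
with an independent band-limited component::

    x_i = kappa * delay(s, lag_i) + sqrt(1 - kappa^2) * n_i

``kappa`` in [0, 1] is therefore an exact synchronization dial: kappa = 0
gives independent channels (phase lag index ~ 0), kappa = 1 gives perfectly
lag-coupled channels (PLI ~ 1).  Channel lags are drawn away from 0 and pi so
phase differences avoid the sign-cancellation boundaries of the PLI.

Complexity mechanism.  The broadband noise exponent beta is the complexity
dial: larger beta means a smoother fast component and hence lower sample
entropy at small coarse-graining scales.

Group defaults encode the qualitative disease contrast under study: the
AD-like group has reduced alpha/beta/gamma coupling and a steeper (smoother)
noise spectrum than the HC-like group; delta/theta coupling is left equal.
The sizes default to 18 HC-like and 16 AD-like subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, sosfiltfilt

from .preprocess import bandpass_sos
from .recording import BAND_NAMES, DEFAULT_MONTAGE, Band, Recording, get_band

HC = "HC"
AD = "AD"

#: Per-band coupling strength kappa for the two simulated groups.
DEFAULT_COUPLING: dict[str, dict[str, float]] = {
    HC: {"delta": 0.30, "theta": 0.30, "alpha": 0.60, "beta": 0.55, "gamma": 0.55},
    AD: {"delta": 0.30, "theta": 0.30, "alpha": 0.30, "beta": 0.25, "gamma": 0.25},
}

#: Broadband spectral exponent (power ~ 1/f^beta) per group; the AD-like
#: spectrum is steeper, i.e. the fast component is smoother.
DEFAULT_NOISE_EXPONENT: dict[str, float] = {HC: 1.0, AD: 1.7}

#: Relative amplitude of each band's oscillatory component (alpha-dominant
#: resting rhythm).
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 0.8, "theta": 0.7, "alpha": 1.0, "beta": 0.5, "gamma": 0.35,
}


@dataclass(frozen=True)
class SubjectLabel:
    group: str
    subject_id: str
    seed: int


@dataclass
class CohortConfig:
    """Parameters of a simulated two-group cohort."""

    n_hc: int = 18
    n_ad: int = 16
    n_channels: int = 16
    fs: float = 200.0
    duration_s: float = 60.0
    coupling: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COUPLING.items()})
    noise_exponent: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_EXPONENT))
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    noise_amplitude: float = 1.0
    lag_range: tuple[float, float] = (0.2, math.pi - 0.2)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_ad < 1:
            raise ValueError("both groups must have at least one subject")
        for group, bands in self.coupling.items():
            for band_name, kappa in bands.items():
                if not 0.0 <= kappa <= 1.0:
                    raise ValueError(
                        f"coupling[{group}][{band_name}] = {kappa} outside [0, 1]")
                band = get_band(band_name)
                if self.fs <= 2 * band.f_hi:
                    raise ValueError(
                        f"fs = {self.fs} Hz does not resolve band {band_name}: "
                        f"upper edge {band.f_hi} Hz is at or above the Nyquist "
                        f"frequency {self.fs / 2} Hz")
        for group, beta in self.noise_exponent.items():
            if beta < 0:
                raise ValueError(f"noise_exponent[{group}] = {beta} must be >= 0")
        lo, hi = self.lag_range
        if not 0.0 < lo < hi < math.pi:
            raise ValueError("lag_range must satisfy 0 < lo < hi < pi")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == len(DEFAULT_MONTAGE):
            return DEFAULT_MONTAGE
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))


# ---------------------------------------------------------------------------
# Primitive signal generators
# ---------------------------------------------------------------------------

def make_colored_noise(n: int, beta: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Zero-mean, unit-variance noise with power spectrum proportional to 1/f^beta.

    Implemented in the Fourier domain: white Gaussian coefficients are shaped
    by f^(-beta/2) (DC excluded) and transformed back.
    """
    if n < 2:
        raise ValueError("need at least 2 samples of noise")
    if beta < 0:
        raise ValueError("spectral exponent beta must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    x -= x.mean()
    sd = x.std()
    if sd == 0:  # degenerate draw; cannot happen for n >= 2 in practice
        raise ValueError("degenerate noise draw with zero variance")
    return x / sd


def make_band_limited_noise(n: int, fs: float, band: Band,
                            rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise confined to ``band`` by the analysis band-pass filter.

    Uses the identical zero-phase Butterworth as the preprocessing stage, so
    generated and analysed band definitions agree by construction.
    """
    sos = bandpass_sos(band, fs)
    x = sosfiltfilt(sos, rng.standard_normal(n))
    x -= x.mean()
    return x / x.std()


def phase_delay(x: np.ndarray, lag_rad: float) -> np.ndarray:
    """Delay a narrowband signal by a fixed phase angle via its analytic signal."""
    return np.real(hilbert(x) * np.exp(-1j * lag_rad))


def make_band_coupled_channels(n_channels: int, fs: float, duration_s: float,
                               band: Band, kappa: float, lags: np.ndarray,
                               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Channels sharing one band-limited oscillator with per-channel phase lags.

    Channel i is ``kappa * delay(source, lags[i]) + sqrt(1-kappa^2) * noise_i``
    with unit-variance components, so the output variance is kappa-invariant.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa = {kappa} outside [0, 1]")
    lags = np.asarray(lags, dtype=float)
    if lags.shape != (n_channels,):
        raise ValueError("need one lag per channel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    source = make_band_limited_noise(n, fs, band, rng)
    out = np.empty((n_channels, n))
    mix = math.sqrt(1.0 - kappa ** 2)
    for i in range(n_channels):
        independent = make_band_limited_noise(n, fs, band, rng)
        out[i] = kappa * phase_delay(source, lags[i]) + mix * independent
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_seed(master_seed: int, group: str, index: int) -> int:
    """Deterministic per-subject seed tied to (master seed, group, index).

    Because the seed depends only on the subject's identity, reordering the
    cohort never changes any subject's signal.
    """
    ss = np.random.SeedSequence([master_seed, {HC: 1, AD: 2}[group], index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def generate_subject(config: CohortConfig, label: SubjectLabel) -> Recording:
    """One subject's multichannel recording: coupled band components + 1/f noise."""
    if label.group not in config.coupling:
        raise ValueError(f"no coupling parameters for group {label.group!r}")
    rng = np.random.default_rng(label.seed)
    n = config.n_samples
    lo, hi = config.lag_range
    total = np.zeros((config.n_channels, n))
    for band_name in BAND_NAMES:
        band = get_band(band_name)
        kappa = config.coupling[label.group].get(band_name, 0.0)
        lags = rng.uniform(lo, hi, size=config.n_channels)
        channels = make_band_coupled_channels(
            config.n_channels, config.fs, config.duration_s, band, kappa, lags,
            seed=rng)
        total += config.band_amplitudes.get(band_name, 0.0) * channels
    beta = config.noise_exponent[label.group]
    for i in range(config.n_channels):
        total[i] += config.noise_amplitude * make_colored_noise(n, beta, seed=rng)
    return Recording(samples=total, fs=config.fs,
                     channel_labels=config.channel_labels())


def make_labels(config: CohortConfig) -> list[SubjectLabel]:
    labels = []
    for group, count in ((HC, config.n_hc), (AD, config.n_ad)):
        for i in range(count):
            labels.append(SubjectLabel(
                group=group,
                subject_id=f"{group}{i + 1:02d}",
                seed=_subject_seed(config.master_seed, group, i),
            ))
    return labels


def generate_cohort(config: CohortConfig) -> list[tuple[Recording, SubjectLabel]]:
    """All labeled recordings of the cohort, HC-like subjects first."""
    return [(generate_subject(config, lbl), lbl) for lbl in make_labels(config)]


# ---------------------------------------------------------------------------
# Single-purpose fixtures
# ---------------------------------------------------------------------------

def make_common_source_pair(n: int, fs: float, gain_a: float, gain_b: float,
                            noise_level: float = 0.0,
                            seed: int = 0,
                            band: Band | None = None) -> Recording:
    """Two channels observing one band-limited source at different gains.

    This is the volume-conduction fixture: with zero lag between the channels
    the phase difference is identically 0 (or pi for opposite-sign gains), so
    the phase lag index must vanish.  ``noise_level`` adds independent noise
    at that fraction of the source's amplitude.
    """
    if gain_a == 0.0 or gain_b == 0.0:
        raise ValueError("channel gains must be nonzero (degenerate channel)")
    rng = np.random.default_rng(seed)
    band = band or Band("carrier", 8.0, 13.0)
    source = make_band_limited_noise(n, fs, band, rng)
    a = gain_a * source
    b = gain_b * source
    if noise_level > 0.0:
        a = a + noise_level * abs(gain_a) * make_band_limited_noise(n, fs, band, rng)
        b = b + noise_level * abs(gain_b) * make_band_limited_noise(n, fs, band, rng)
    return Recording(samples=np.vstack([a, b]), fs=fs, channel_labels=("A", "B"))


def make_constant_lag_pair(freq: float, lag_rad: float, n: int, fs: float) -> Recording:
    """Two sinusoids at ``freq`` with an exact phase offset ``lag_rad``.

    Offsets of exactly 0 or +/-pi are rejected: those sit on the PLI sign
    boundary and are exercised by the common-source fixture instead.
    """
    if not 0.0 < abs(lag_rad) < math.pi:
        raise ValueError("lag_rad must satisfy 0 < |lag| < pi")
    t = np.arange(n) / fs
    a = np.cos(2 * math.pi * freq * t)
    b = np.cos(2 * math.pi * freq * t - lag_rad)
    return Recording(samples=np.vstack([a, b]), fs=fs, channel_labels=("A", "B"))
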