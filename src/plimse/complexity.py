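"""Multiscale entropy: coarse-graining and sample entropy over scales 1-20.

Sample entropy of a series x_1..x_T with template length m and tolerance r is

    SampEn = -ln(A / B)

where B counts template pairs (i != j) of length m whose Chebyshev distance is
<= r, A counts the same for length m+1, and both counts run over the common
index range i = 1..T-m (the standard convention: the last m-template is
dropped so every counted template has an (m+1)-point extension).  SampEn is 0
for a perfectly regular (pattern-repeating) series and grows with
irregularity; it is undefined when either count is zero, which is reported as
a flagged missing value rather than infinity.

Multiscale entropy evaluates SampEn on coarse-grained copies of the series
(non-overlapping block means of length tau), with the tolerance anchored to
the standard deviation of the *original* scale-1 series so the variance
reduction of coarse-graining is part of the measured effect.

Pair counting uses a KD-tree range count in the Chebyshev metric, which is
exactly equivalent to the O(T^2) double loop over template pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

from .recording import Recording

DEFAULT_SCALES: tuple[int, ...] = tuple(range(1, 21))


@dataclass
class MSEParams:
    """Parameters of the multiscale entropy computation.

    ``r_mode='relative'`` (the field convention) sets the tolerance to
    ``r_value * SD`` of each channel's original series; ``'absolute'`` uses
    ``r_value`` directly.
    """

    m: int = 2
    r_mode: str = "relative"
    r_value: float = 0.2
    scales: tuple[int, ...] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if self.r_mode not in ("relative", "absolute"):
            raise ValueError("r_mode must be 'relative' or 'absolute'")
        if self.r_value <= 0:
            raise ValueError("tolerance r_value must be positive")
        self.scales = tuple(int(s) for s in self.scales)
        if any(s < 1 for s in self.scales):
            raise ValueError("scales must be positive integers")


@dataclass
class MSECurve:
    """Per-channel SampEn as a function of coarse-graining scale.

    ``values`` has shape (channels, scales); entries where SampEn was
    undefined (no matching template pairs, or too-short coarse series) are NaN
    and flagged False in ``defined``.
    """

    values: np.ndarray
    scales: tuple[int, ...]
    channel_labels: tuple[str, ...]
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.defined is None:
            self.defined = ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channel_labels):
            for si, s in enumerate(self.scales):
                rows.append({"channel": ch, "scale": s,
                             "sampen": self.values[ci, si],
                             "defined": bool(self.defined[ci, si])})
        return pd.DataFrame(rows)


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; output length floor(T/tau)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("coarse_grain expects a 1-D series")
    if tau < 1:
        raise ValueError("scale factor tau must be >= 1")
    if tau > x.size:
        raise ValueError(f"tau = {tau} exceeds series length {x.size}")
    n_blocks = x.size // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def _template_pair_count(x: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Number of unordered template pairs (length m) within Chebyshev r."""
    templates = sliding_window_view(x, m)[:n_templates]
    tree = cKDTree(templates)
    ordered_with_self = tree.count_neighbors(tree, r, p=np.inf)
    return int(ordered_with_self - n_templates) // 2


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy of a 1-D series; NaN when no template pairs match.

    When ``r`` is None the tolerance defaults to 0.2 times the SD of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D series")
    if x.size <= m + 1:
        raise ValueError(f"series of length {x.size} too short for m = {m}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    n_templates = x.size - m  # common index range for both template lengths
    b = _template_pair_count(x, m, r, n_templates)
    if b == 0:
        return float("nan")
    a = _template_pair_count(x, m + 1, r, n_templates)
    if a == 0:
        return float("nan")
    return float(-np.log(a / b)) + 0.0  # normalise -0.0 from a == b


def mse_channel(x: np.ndarray, params: MSEParams) -> np.ndarray:
    """SampEn of one channel at every scale, tolerance fixed from scale 1."""
    x = np.asarray(x, dtype=float)
    if params.r_mode == "relative":
        sd = float(np.std(x))
        if sd == 0:
            # constant series: zero-tolerance would be degenerate; any positive
            # tolerance yields SampEn 0 at every scale
            return np.zeros(len(params.scales))
        r = params.r_value * sd
    else:
        r = params.r_value
    out = np.full(len(params.scales), np.nan)
    for si, tau in enumerate(params.scales):
        if x.size // tau <= params.m + 1:
            continue  # flagged undefined, not a global failure
        out[si] = sample_entropy(coarse_grain(x, tau), m=params.m, r=r)
    return out


def mse_curve(rec_or_channel: Recording | np.ndarray,
              params: MSEParams | None = None) -> MSECurve:
    """Multiscale entropy curve for a recording (per channel) or a single series."""
    params = params or MSEParams()
    if isinstance(rec_or_channel, Recording):
        data = rec_or_channel.samples
        labels = rec_or_channel.channel_labels
    else:
        data = np.atleast_2d(np.asarray(rec_or_channel, dtype=float))
        labels = tuple(f"ch{i:02d}" for i in range(data.shape[0]))
    values = np.vstack([mse_channel(ch, params) for ch in data])
    return MSECurve(values=values, scales=params.scales, channel_labels=labels)


def small_scale_mean(curve: MSECurve, scale_lo: int = 1, scale_hi: int = 5) -> np.ndarray:
    """Per-channel mean SampEn over scales ``scale_lo..scale_hi`` (inclusive).

    This is the summary complexity feature used for classification; an
    undefined SampEn anywhere in the range propagates NaN for that channel.
    """
    wanted = [s for s in range(scale_lo, scale_hi + 1)]
    idx = []
    for s in wanted:
        if s not in curve.scales:
            raise ValueError(f"scale {s} not present in curve")
        idx.append(curve.scales.index(s))
    return curve.values[:, idx].mean(axis=1)
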