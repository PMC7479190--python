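"""Stockwell time-frequency distribution and instantaneous frequency.

The S-transform combines the short-time Fourier transform's absolute phase
reference with the continuous wavelet transform's frequency-scaled window:
each frequency voice ``n`` is analyzed with a Gaussian window whose width is
inversely proportional to the frequency.  It is computed here in the
frequency domain: for voice ``n = 1..N//2``,

    S[tau, n] = IFFT_m( X[(m + n) mod N] * exp(-2 pi^2 m^2 / n^2) )(tau)

where ``X`` is the DFT of the mean-removed signal and the Gaussian is
evaluated at circularly wrapped (signed) frequency offsets ``m``, so that the
voice window is symmetric about its center frequency.

The instantaneous frequency (IF) reduces the TFD to one dimension: the first
conditional spectral moment, i.e. the power-weighted mean frequency at each
time point, in cycles/sample on [0, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import DerivedSeries, TimeSeries


@dataclass(frozen=True)
class TFDMatrix:
    """Amplitude of a time-frequency distribution.

    Rows are frequency voices (ascending, cycles/sample in [0, 0.5]); columns
    are the original time points.  Row 0 is the zero-frequency (mean) voice,
    held constant at the series mean magnitude.
    """

    amplitude: np.ndarray  # (n_freqs, n_times), nonnegative
    freqs: np.ndarray      # cycles per sample
    times: np.ndarray      # original time indices

    def __post_init__(self) -> None:
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude must be a 2-d matrix")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")
        if self.amplitude.shape != (self.freqs.size, self.times.size):
            raise ValueError("axes do not match amplitude shape")


def stockwell_transform(s: TimeSeries) -> TFDMatrix:
    """Discrete S-transform magnitude of a series (frequency-domain form)."""
    x = s.values
    n_pts = x.size
    if n_pts < 8:
        raise ValueError("S-transform needs at least 8 points")
    mean = float(np.mean(x))
    spec = np.fft.fft(x - mean)

    m = np.arange(n_pts)
    m_signed = np.where(m > n_pts // 2, m - n_pts, m).astype(float)
    voices = np.arange(1, n_pts // 2 + 1)

    amp = np.empty((voices.size + 1, n_pts))
    amp[0, :] = abs(mean)  # zero-frequency voice carries the mean
    for row, n in enumerate(voices, start=1):
        gauss = np.exp(-2.0 * np.pi**2 * m_signed**2 / float(n) ** 2)
        shifted = spec[(m + n) % n_pts]
        amp[row, :] = np.abs(np.fft.ifft(shifted * gauss))

    freqs = np.concatenate(([0.0], voices / n_pts))
    return TFDMatrix(amplitude=amp, freqs=freqs, times=s.times)


def instantaneous_frequency(tfd: TFDMatrix) -> DerivedSeries:
    """First conditional spectral moment of the TFD per time point.

    ``IF(tau) = sum_n f_n P(tau, n) / sum_n P(tau, n)`` with power
    ``P = amplitude**2``; the zero-frequency voice is excluded so the moment
    reflects oscillatory content only.  Columns with zero total power are
    undefined: they are trimmed at the edges (adjusting the offset) and kept
    as NaN in the interior, where downstream consumers drop them together
    with their time stamp.
    """
    power = tfd.amplitude[1:, :] ** 2
    freqs = tfd.freqs[1:]
    den = power.sum(axis=0)
    if not np.any(den > 0):
        raise ValueError("instantaneous frequency undefined: TFD has no power")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (freqs[:, None] * power).sum(axis=0) / den
    vals = np.where(den > 0, vals, np.nan)

    defined = np.flatnonzero(den > 0)
    start, stop = defined[0], defined[-1] + 1
    return DerivedSeries(vals[start:stop], window=1,
                         offset=int(tfd.times[start]))
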