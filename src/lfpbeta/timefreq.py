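"""Morlet wavelet time-frequency decomposition.

The transform is computed in the spectral domain: the FFT of the signal is
multiplied, per analysis frequency ``f``, by a Gaussian kernel centered on
``f`` and the product inverse-transformed.  Negative frequencies are zeroed,
so coefficients are complex analytic-signal-like values carrying amplitude
and phase.

Wavelet parameterization
------------------------
The dimensionless parameter ``sigma`` is the center angular frequency of the
mother wavelet ``psi(t) ~ exp(i*sigma*t) * exp(-t**2 / 2)``.  Scaled to
analysis frequency ``f`` this gives a Gaussian temporal envelope of standard
deviation ``sigma_t = sigma / (2*pi*f)`` seconds and a spectral standard
deviation ``sigma_f = f / sigma`` Hz.  With ``sigma = 5*pi`` the envelope
spans ``sigma / (2*pi) = 2.5`` carrier cycles per temporal SD (about 5.9
cycles at FWHM); ``sigma = 3*pi`` gives 1.5 cycles per SD.  Larger ``sigma``
therefore sharpens frequency resolution.

Normalization is "unit amplitude response": a unit-amplitude sinusoid at a
grid frequency yields coefficients of modulus 1 there, which makes
downstream ratio-to-baseline measures scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeFrequencyMap",
    "downsample",
    "morlet_tfmap",
    "morlet_kernel",
    "wavelet_time_sd",
]

#: default analysis parameter (2.5 carrier cycles per temporal SD)
SIGMA_ANALYSIS = 5.0 * np.pi
#: broader wavelet used for the high-frequency artifact band
SIGMA_ARTIFACT = 3.0 * np.pi


def wavelet_time_sd(freq: float, sigma: float) -> float:
    """Temporal standard deviation (s) of the wavelet envelope at ``freq``."""
    return sigma / (2.0 * np.pi * freq)


@dataclass
class TimeFrequencyMap:
    """Complex Morlet coefficients over a (time x frequency) grid.

    ``coeffs`` has shape ``(n_times, n_freqs)``.  ``times`` is a uniform
    grid at ``analysis_fs`` starting at ``t0`` (seconds); ``freqs`` is
    strictly increasing.
    """

    times: np.ndarray
    freqs: np.ndarray
    coeffs: np.ndarray
    sigma: float
    analysis_fs: float
    source: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be a strictly increasing 1-d grid")
        if self.coeffs.shape != (self.times.size, self.freqs.size):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} does not match "
                f"(n_times={self.times.size}, n_freqs={self.freqs.size})"
            )

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coeffs)

    @property
    def power(self) -> np.ndarray:
        c = self.coeffs
        return c.real**2 + c.imag**2

    def edge_valid_mask(self, n_sd: float = 3.0) -> np.ndarray:
        """Boolean (n_times, n_freqs) mask, False within ``n_sd`` wavelet
        temporal SDs of either signal edge (coefficients there are computed
        but contaminated by zero padding)."""
        margins = n_sd * self.sigma / (2.0 * np.pi * self.freqs)  # seconds
        t_rel = self.times - self.times[0]
        dur = t_rel[-1] if t_rel.size else 0.0
        return (t_rel[:, None] >= margins[None, :]) & (
            t_rel[:, None] <= dur - margins[None, :]
        )

    def index_of_time(self, t: float) -> int:
        """Nearest sample index for absolute time ``t`` (seconds)."""
        i = int(round((t - self.t0) * self.analysis_fs))
        return min(max(i, 0), self.times.size - 1)

    def sample_slice(self, t_start: float, t_stop: float) -> slice:
        """Half-open sample range covering [t_start, t_stop)."""
        eps = 1e-9
        i0 = int(np.ceil((t_start - self.t0) * self.analysis_fs - eps))
        i1 = int(np.ceil((t_stop - self.t0) * self.analysis_fs - eps))
        return slice(max(i0, 0), min(max(i1, 0), self.times.size))


def downsample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Anti-alias filtered resampling of ``x`` from ``fs`` to ``target_fs``.

    Uses polyphase resampling; non-integer ratios are handled through the
    rational approximation of ``target_fs / fs``.
    """
    if target_fs > fs:
        raise ValueError(f"target_fs={target_fs} exceeds fs={fs}")
    x = np.asarray(x, dtype=float)
    if target_fs == fs:
        return x.copy()
    ratio = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator, padtype="line")


def _spectral_kernel(fft_freqs: np.ndarray, f: float, sigma: float) -> np.ndarray:
    """Gaussian frequency response; factor 2 restores unit amplitude for a
    real unit sinusoid after negative frequencies are discarded."""
    sigma_f = f / sigma
    h = 2.0 * np.exp(-0.5 * ((fft_freqs - f) / sigma_f) ** 2)
    h[fft_freqs < 0] = 0.0
    return h


def morlet_kernel(f: float, sigma: float, fs: float, n_sd: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Time-domain wavelet matching the spectral path (test oracle).

    Returns ``(t, w)`` with ``w(t) = 2*sqrt(2*pi)*sigma_f *
    exp(i*2*pi*f*t) * exp(-t**2/(2*sigma_t**2))``; convolving the signal
    with ``w`` (times the sample period) reproduces the spectral-domain
    coefficients away from the edges.
    """
    sigma_t = wavelet_time_sd(f, sigma)
    sigma_f = f / sigma
    half = int(np.ceil(n_sd * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = (
        2.0
        * np.sqrt(2.0 * np.pi)
        * sigma_f
        * np.exp(2j * np.pi * f * t)
        * np.exp(-0.5 * (t / sigma_t) ** 2)
    )
    return t, w


def morlet_tfmap(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    sigma: float = SIGMA_ANALYSIS,
    source: str = "",
    t0: float = 0.0,
) -> TimeFrequencyMap:
    """Morlet wavelet transform of ``x`` on frequency grid ``freqs``.

    The signal is zero-padded to the next power of two (plus a wrap-around
    guard) before the FFT.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    nyq = fs / 2.0
    bad = freqs[freqs >= nyq]
    if bad.size:
        raise ValueError(f"frequency {bad[0]:g} Hz is at or above Nyquist ({nyq:g} Hz)")
    n = x.size
    guard = int(np.ceil(5.0 * wavelet_time_sd(freqs.min(), sigma) * fs))
    n_fft = 1 << int(np.ceil(np.log2(max(n + 2 * guard, 2))))
    xf = np.fft.fft(x, n_fft)
    fft_freqs = np.fft.fftfreq(n_fft, d=1.0 / fs)
    coeffs = np.empty((n, freqs.size), dtype=complex)
    for j, f in enumerate(freqs):
        h = _spectral_kernel(fft_freqs, f, sigma)
        coeffs[:, j] = np.fft.ifft(xf * h)[:n]
    times = t0 + np.arange(n) / fs
    return TimeFrequencyMap(
        times=times, freqs=freqs, coeffs=coeffs, sigma=sigma,
        analysis_fs=fs, source=source, t0=t0,
    )


def beta_freq_grid(f_lo: float = 17.0, f_hi: float = 28.0, step: float = 0.5) -> np.ndarray:
    """Default analysis grid: 17-28 Hz at 0.5 Hz resolution (23 points)."""
    n = int(round((f_hi - f_lo) / step)) + 1
    return f_lo + step * np.arange(n)
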