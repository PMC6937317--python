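"""High-frequency movement-artifact detection and trial exclusion.

Detection runs per channel at native sampling rate (no downsampling):

1. wavelet time-frequency map on 20 linearly spaced frequencies spanning
   90-250 Hz, with the broad wavelet (sigma = 3*pi);
2. power averaged across frequencies, then median and MAD of that series
   over time;
3. threshold = median + 25 * MAD (plain MAD, no consistency factor);
4. artifact epochs = maximal runs where mean power exceeds the threshold.

Trial-exclusion rules use half-open interval intersection throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import TrialTable
from .timefreq import SIGMA_ARTIFACT, morlet_tfmap

__all__ = [
    "ArtifactMask",
    "detect_artifacts",
    "excluded_trials_beta",
    "excluded_trials_connectivity",
]

ARTIFACT_BAND = (90.0, 250.0)
N_ARTIFACT_FREQS = 20
MAD_FACTOR = 25.0


def mad(x: np.ndarray) -> float:
    """Plain median absolute deviation (no 1.4826 consistency factor)."""
    x = np.asarray(x)
    return float(np.median(np.abs(x - np.median(x))))


@dataclass
class ArtifactMask:
    channel: str
    epochs: list[tuple[float, float]]
    threshold: float
    band: tuple[float, float] = ARTIFACT_BAND

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.epochs, self.epochs[1:]):
            if b0 < a1:
                raise ValueError("epochs must be disjoint and sorted")

    def intersects(self, start: float, stop: float) -> bool:
        """True if any epoch overlaps the half-open window [start, stop)."""
        return any(e0 < stop and start < e1 for e0, e1 in self.epochs)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``mask`` is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_artifacts(x: np.ndarray, fs: float, channel: str = "") -> ArtifactMask:
    """Run the 4-step MAD-threshold detector on one raw channel."""
    if fs <= 500.0:
        raise ValueError(
            f"fs={fs} Hz too low: the {ARTIFACT_BAND} Hz band requires fs > 500 Hz"
        )
    x = np.asarray(x, dtype=float)
    freqs = np.linspace(*ARTIFACT_BAND, N_ARTIFACT_FREQS)
    # accumulate mean power across frequencies one band at a time to keep
    # memory flat on long sessions
    n = x.size
    guard = int(np.ceil(5.0 * SIGMA_ARTIFACT / (2.0 * np.pi * freqs[0]) * fs))
    n_fft = 1 << int(np.ceil(np.log2(max(n + 2 * guard, 2))))
    xf = np.fft.fft(x, n_fft)
    fft_freqs = np.fft.fftfreq(n_fft, d=1.0 / fs)
    mean_power = np.zeros(n)
    for f in freqs:
        sigma_f = f / SIGMA_ARTIFACT
        h = 2.0 * np.exp(-0.5 * ((fft_freqs - f) / sigma_f) ** 2)
        h[fft_freqs < 0] = 0.0
        c = np.fft.ifft(xf * h)[:n]
        mean_power += c.real**2 + c.imag**2
    mean_power /= freqs.size

    med = float(np.median(mean_power))
    threshold = med + MAD_FACTOR * mad(mean_power)
    above = mean_power > threshold
    epochs = [(i0 / fs, i1 / fs) for i0, i1 in _runs_above(above)]
    return ArtifactMask(channel=channel, epochs=epochs, threshold=threshold)


def _excluded(trials: TrialTable, masks: dict[str, ArtifactMask],
              windows) -> set[int]:
    out: set[int] = set()
    for i in range(len(trials)):
        for w0, w1 in windows(trials.starts[i], trials.ends[i]):
            if any(m.intersects(w0, w1) for m in masks.values()):
                out.add(int(trials.df["trial"].iloc[i]))
                break
    return out


def excluded_trials_beta(trials: TrialTable, masks: dict[str, ArtifactMask]) -> set[int]:
    """Trials with any artifact in the 2.5 s window starting 1 s before
    nose-poke start, on any channel."""
    return _excluded(trials, masks, lambda s, e: [(s - 1.0, s + 1.5)])


def excluded_trials_connectivity(
    trials: TrialTable,
    masks: dict[str, ArtifactMask],
    half_window: float = 1.0,
) -> set[int]:
    """Trials with any artifact within ``half_window`` s of nose-poke start
    or end (2 s centered windows by default)."""
    return _excluded(
        trials, masks,
        lambda s, e: [(s - half_window, s + half_window),
                      (e - half_window, e + half_window)],
    )


def masks_to_frame(masks: dict[str, ArtifactMask]):
    """Flatten masks to a tidy table (channel, start, end, threshold)."""
    import pandas as pd

    rows = [
        {"channel": m.channel or name, "start": e0, "end": e1, "threshold": m.threshold}
        for name, m in masks.items()
        for e0, e1 in m.epochs
    ]
    return pd.DataFrame(rows, columns=["channel", "start", "end", "threshold"])
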