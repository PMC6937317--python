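"""Per-trial normalized beta amplitude and trial-block aggregation.

The per-trial measure is computed on the 17-28 Hz wavelet map of the
downsampled (200 Hz) signal: the raw amplitude is the time average, over
the window from 400 ms before nose-poke end until 100 ms after, of the
per-time-point maximum amplitude across the frequency grid.  It is
normalized by a baseline taken as the median of the same statistic over
non-overlapping 500 ms periods tiling a 240 s window centered on nose-poke
start (excluding other nose-pokes and licks extended by 200 ms and artifact
epochs extended by 2 s), and the natural logarithm of the ratio is the
final *beta amplitude*: 0 means no change from baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .artifacts import ArtifactMask, excluded_trials_beta, mad
from .simulate import NO_BURST_STRUCTURES, SessionRecording, TrialTable
from .timefreq import SIGMA_ANALYSIS, TimeFrequencyMap, beta_freq_grid, downsample, morlet_tfmap

__all__ = [
    "BetaMeasure",
    "TrialBlock",
    "trial_raw_beta",
    "trial_baseline",
    "compute_session_beta",
    "make_blocks",
    "time_of_max_beta",
]

log = logging.getLogger(__name__)

ANALYSIS_FS = 200.0
WINDOW_BEFORE_END = 0.4
WINDOW_AFTER_END = 0.1
BASELINE_HALF_WINDOW = 120.0
BASELINE_PERIOD = 0.5
EVENT_PAD = 0.2
ARTIFACT_PAD = 2.0


@dataclass
class BetaMeasure:
    trial: int
    structure: str
    raw_amplitude: float
    baseline: float
    beta_amplitude: float  # log(raw / baseline); nan if undefined
    n_baseline_periods: int
    excluded: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.beta_amplitude)


@dataclass
class TrialBlock:
    block: int
    trial_ids: list[int]
    performance: float
    median_beta: dict[str, float]


def _freq_max_series(tfmap: TimeFrequencyMap) -> np.ndarray:
    """Per-time-point maximum amplitude across the frequency grid.

    np.max on ties returns the first (lowest-frequency) occurrence, which
    fixes the tie-break deterministically.
    """
    return tfmap.amplitude.max(axis=1)


def _window_mean(series: np.ndarray, tfmap: TimeFrequencyMap,
                 t0: float, t1: float) -> float:
    sl = tfmap.sample_slice(t0, t1)
    if sl.stop <= sl.start:
        raise ValueError(f"window [{t0:g}, {t1:g}) s has no samples in the map")
    return float(series[sl].mean())


def trial_raw_beta(tfmap: TimeFrequencyMap, nose_poke_end: float) -> float:
    """Raw beta amplitude: time average over [end - 0.4, end + 0.1) s of the
    per-time-point frequency maximum."""
    t0 = nose_poke_end - WINDOW_BEFORE_END
    t1 = nose_poke_end + WINDOW_AFTER_END
    if t0 < tfmap.t0 or t1 > tfmap.t0 + tfmap.times.size / tfmap.analysis_fs:
        raise ValueError("trial window extends beyond the recording")
    return _window_mean(_freq_max_series(tfmap), tfmap, t0, t1)


def _overlaps(a0: float, a1: float, intervals) -> bool:
    return any(b0 < a1 and a0 < b1 for b0, b1 in intervals)


def trial_baseline(
    tfmap: TimeFrequencyMap,
    trial_index: int,
    trials: TrialTable,
    mask: ArtifactMask | None = None,
) -> tuple[float, int]:
    """Baseline amplitude for one trial: median over surviving 500 ms
    periods of a 240 s window centered on nose-poke start.

    Returns ``(baseline, n_periods)``; ``baseline`` is nan when no period
    survives the exclusions.
    """
    start = float(trials.starts[trial_index])
    rec_t0 = tfmap.t0
    rec_t1 = tfmap.t0 + tfmap.times.size / tfmap.analysis_fs
    w0 = max(start - BASELINE_HALF_WINDOW, rec_t0)
    w1 = min(start + BASELINE_HALF_WINDOW, rec_t1)

    excl: list[tuple[float, float]] = []
    for j in range(len(trials)):
        if j == trial_index:
            continue
        excl.append((trials.starts[j] - EVENT_PAD, trials.ends[j] + EVENT_PAD))
    for iv in trials.licks:
        excl.extend((a - EVENT_PAD, b + EVENT_PAD) for a, b in iv)
    if mask is not None:
        excl.extend((a - ARTIFACT_PAD, b + ARTIFACT_PAD) for a, b in mask.epochs)

    series = _freq_max_series(tfmap)
    values = []
    k = 0
    while True:
        p0 = w0 + k * BASELINE_PERIOD
        p1 = p0 + BASELINE_PERIOD
        if p1 > w1 + 1e-9:
            break
        k += 1
        if _overlaps(p0, p1, excl):
            continue
        values.append(_window_mean(series, tfmap, p0, p1))
    if not values:
        return float("nan"), 0
    return float(np.median(values)), len(values)


def compute_channel_tfmap(
    x: np.ndarray,
    fs: float,
    structure: str = "",
    freqs: np.ndarray | None = None,
) -> TimeFrequencyMap:
    """Downsample to the analysis rate and run the beta-band wavelet map."""
    if freqs is None:
        freqs = beta_freq_grid()
    y = downsample(x, fs, ANALYSIS_FS)
    return morlet_tfmap(y, ANALYSIS_FS, freqs, sigma=SIGMA_ANALYSIS, source=structure)


def compute_session_beta(
    recording: SessionRecording,
    masks: dict[str, ArtifactMask] | None = None,
    structures: list[str] | None = None,
    tfmaps: dict[str, TimeFrequencyMap] | None = None,
) -> list[BetaMeasure]:
    """Per-trial beta amplitude for every requested structure.

    Trials excluded by the beta artifact rule carry a flagged measure with
    nan amplitude.  Precomputed ``tfmaps`` may be passed to avoid repeating
    the wavelet transform.
    """
    masks = masks or {}
    trials = recording.events
    excluded = excluded_trials_beta(trials, masks) if masks else set()
    wanted = structures or list(recording.structures)
    out: list[BetaMeasure] = []
    for s in wanted:
        if s not in recording.channels:
            log.warning("structure %s missing from recording; skipped", s)
            continue
        tfm = (tfmaps or {}).get(s) or compute_channel_tfmap(
            recording.channels[s], recording.fs, s
        )
        mask = masks.get(s)
        for i in range(len(trials)):
            tid = int(trials.df["trial"].iloc[i])
            if tid in excluded:
                out.append(BetaMeasure(tid, s, float("nan"), float("nan"),
                                       float("nan"), 0, excluded=True))
                continue
            raw = trial_raw_beta(tfm, float(trials.ends[i]))
            base, n_periods = trial_baseline(tfm, i, trials, mask)
            amp = float(np.log(raw / base)) if (n_periods and base > 0) else float("nan")
            out.append(BetaMeasure(tid, s, raw, base, amp, n_periods))
    return out


def measures_to_frame(measures: list[BetaMeasure]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial": m.trial, "structure": m.structure,
                "raw": m.raw_amplitude, "baseline": m.baseline,
                "beta_amplitude": m.beta_amplitude,
                "n_baseline_periods": m.n_baseline_periods,
                "excluded": m.excluded,
            }
            for m in measures
        ]
    )


def make_blocks(trials: TrialTable, measures: list[BetaMeasure],
                per_odor: int = 10) -> list[TrialBlock]:
    """Greedy 20-trial blocks holding 10 presentations of each odor.

    Trials are scanned in order; a trial joins the current block unless its
    odor already has ``per_odor`` members, in which case it spills to the
    next block.  A block closes when both odors are full; the incomplete
    final block is dropped.
    """
    by_structure: dict[str, dict[int, float]] = {}
    for m in measures:
        if m.defined:
            by_structure.setdefault(m.structure, {})[m.trial] = m.beta_amplitude

    odors = trials.odors
    correct = trials.correct
    tids = trials.df["trial"].to_numpy(int)

    blocks: list[TrialBlock] = []
    pending: list[int] = list(range(len(trials)))
    current: list[int] = []
    counts = {"A": 0, "B": 0}
    spill: list[int] = []
    while pending:
        i = pending.pop(0)
        od = odors[i]
        if counts[od] < per_odor:
            current.append(i)
            counts[od] += 1
        else:
            spill.append(i)
        if all(c >= per_odor for c in counts.values()):
            ids = [int(tids[j]) for j in current]
            perf = float(np.mean([correct[j] for j in current]))
            med = {
                s: float(np.median([v[t] for t in ids if t in v]))
                if any(t in v for t in ids) else float("nan")
                for s, v in by_structure.items()
            }
            blocks.append(TrialBlock(len(blocks), ids, perf, med))
            current, counts = [], {"A": 0, "B": 0}
            pending = spill + pending
            spill = []
    return blocks


def time_of_max_beta(
    tfmaps: dict[str, TimeFrequencyMap],
    raw_signals: dict[str, np.ndarray],
    nose_poke_start: float,
    nose_poke_end: float,
    exclude: frozenset[str] = NO_BURST_STRUCTURES,
) -> float:
    """Time of maximal beta amplitude of the structure-average map.

    Each eligible map (everything except Hipp/Cereb by default) is divided
    by the MAD of its raw (downsampled) signal, maps are averaged across
    structures, and the returned time is the location of the global maximum
    over the beta grid in the window from 400 ms before nose-poke end (or
    trial start, for short trials) until 100 ms after.
    """
    eligible = [s for s in tfmaps if s not in exclude]
    if not eligible:
        raise ValueError("no eligible structures for time-of-max-beta")
    ref = tfmaps[eligible[0]]
    acc = np.zeros_like(ref.amplitude)
    for s in eligible:
        scale = mad(np.asarray(raw_signals[s], dtype=float))
        if scale == 0:
            raise ValueError(f"flat raw signal for structure {s}")
        acc += tfmaps[s].amplitude / scale
    acc /= len(eligible)

    t0 = max(nose_poke_end - WINDOW_BEFORE_END, nose_poke_start)
    t1 = nose_poke_end + WINDOW_AFTER_END
    sl = ref.sample_slice(t0, t1)
    window = acc[sl]
    if window.size == 0:
        raise ValueError("empty search window for time-of-max-beta")
    it, _ = np.unravel_index(int(np.argmax(window)), window.shape)
    return float(ref.times[sl.start + it])
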