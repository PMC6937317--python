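"""Behavioral scoring, learning-criterion detection and session labeling.

Session performance is the proportion of correct trials (no response counts
as incorrect).  Learning is achieved at 80% correct on two consecutive
30-trial blocks on three consecutive days; the session just before the
criterion run is labeled LC0, the run itself LC1-LC3, earlier days S1..Sn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TrialTable

__all__ = [
    "SessionLabel",
    "session_performance",
    "rolling_block_performance",
    "day_satisfies_criterion",
    "criterion_day",
    "label_sessions",
    "detect_pre_learning",
    "performer_split",
]

CRITERION_LEVEL = 0.80
CRITERION_BLOCK = 30
CRITERION_DAYS = 3


@dataclass(frozen=True)
class SessionLabel:
    phase: str  # P1, P2, P3, R1, T1, T2
    tag: str    # "S3" or "LC1"
    day: int    # raw index within phase (0-based)

    def __str__(self) -> str:
        return f"{self.phase}-{self.tag}" if self.phase else self.tag


def _correct_array(trials) -> np.ndarray:
    if isinstance(trials, TrialTable):
        return trials.correct
    return np.asarray(trials, dtype=bool)


def session_performance(trials) -> float:
    """Fraction of correct trials over the whole session."""
    c = _correct_array(trials)
    if c.size == 0:
        raise ValueError("session has no trials")
    return float(c.mean())


def rolling_block_performance(trials, block_size: int = CRITERION_BLOCK,
                              step: int = 1) -> np.ndarray:
    """Fraction correct in consecutive ``block_size``-trial blocks.

    ``step=1`` slides trial by trial; ``step=block_size`` partitions the
    session into non-overlapping blocks (partial trailing block dropped).
    """
    c = _correct_array(trials).astype(float)
    if c.size < block_size:
        return np.empty(0)
    cs = np.r_[0.0, np.cumsum(c)]
    starts = np.arange(0, c.size - block_size + 1, step)
    return (cs[starts + block_size] - cs[starts]) / block_size


def day_satisfies_criterion(trials, block_size: int = CRITERION_BLOCK,
                            level: float = CRITERION_LEVEL,
                            sliding: bool = False) -> bool:
    """True when some two consecutive blocks are both at/above ``level``.

    Blocks partition the session by default; ``sliding=True`` uses the
    trial-by-trial variant for sensitivity checks.
    """
    step = 1 if sliding else block_size
    perf = rolling_block_performance(trials, block_size, step=step)
    if perf.size < 2:
        return False
    return bool(np.any((perf[:-1] >= level) & (perf[1:] >= level)))


def criterion_day(day_flags) -> int | None:
    """0-based index of the first day ending a run of three consecutive
    satisfying days, or None."""
    flags = np.asarray(day_flags, dtype=bool)
    for d in range(CRITERION_DAYS - 1, flags.size):
        if flags[d - CRITERION_DAYS + 1:d + 1].all():
            return d
    return None


def label_sessions(day_flags, phase: str = "") -> list[SessionLabel]:
    """Map day-wise criterion flags to S/LC labels.

    With the criterion run starting on day k: days before k-1 are S1..Sn,
    day k-1 is LC0, days k..k+2 are LC1..LC3, and later days continue LC4,
    LC5, ...  Without a criterion run every day is S_n.
    """
    flags = np.asarray(day_flags, dtype=bool)
    end = criterion_day(flags)
    labels: list[SessionLabel] = []
    if end is None:
        return [SessionLabel(phase, f"S{d + 1}", d) for d in range(flags.size)]
    run_start = end - CRITERION_DAYS + 1
    lc0_day = run_start - 1  # absent when the run starts on day 0
    for d in range(flags.size):
        if lc0_day >= 0 and d < lc0_day:
            labels.append(SessionLabel(phase, f"S{d + 1}", d))
        elif d == lc0_day:
            labels.append(SessionLabel(phase, "LC0", d))
        else:
            labels.append(SessionLabel(phase, f"LC{d - run_start + 1}", d))
    return labels


def detect_pre_learning(performances, threshold: float = 0.60) -> int:
    """Index (0-based) of the last session with performance below the
    threshold (the reversal 'pre-learning' session)."""
    p = np.asarray(performances, dtype=float)
    below = np.flatnonzero(p < threshold)
    if below.size == 0:
        raise ValueError(f"no session with performance below {threshold:g}")
    return int(below[-1])


def performer_split(trials, first: int = 11, last: int = 20,
                    level: float = CRITERION_LEVEL) -> bool:
    """Recall-test performer flag: fraction correct over trials ``first``
    to ``last`` (1-based, inclusive) at or above ``level``."""
    c = _correct_array(trials)
    if c.size < last:
        raise ValueError(f"need at least {last} trials, have {c.size}")
    return bool(c[first - 1:last].mean() >= level)
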