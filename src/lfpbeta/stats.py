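"""Group-level aggregation: bootstrap CIs, rank correlations, tidy exports.

Per-rat aggregation (medians) always precedes across-rat aggregation
(means); pooling trials across rats is deliberately avoided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sct

__all__ = ["GroupSummary", "bootstrap_ci", "hub_amplitude_correlation", "export_tidy"]


@dataclass
class GroupSummary:
    keys: dict
    per_rat: dict[str, float]
    mean: float
    ci_low: float
    ci_high: float
    n_rats: int


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed: int | np.random.Generator = 0) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean, resampling rats with replacement.

    Returns ``(mean, low, high)``; deterministic given the seed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("bootstrap_ci requires at least 2 values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    q = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [q, 1.0 - q])
    return float(v.mean()), float(lo), float(hi)


def summarize_by_rat(df: pd.DataFrame, value: str, rat: str = "rat",
                     n_boot: int = 1000, seed: int = 0, **keys) -> GroupSummary:
    """Median per rat, then bootstrap CI of the across-rat mean."""
    sub = df
    for k, v in keys.items():
        sub = sub[sub[k] == v]
    per_rat = sub.groupby(rat)[value].median().to_dict()
    vals = np.asarray(list(per_rat.values()), dtype=float)
    mean, lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=seed)
    return GroupSummary(keys=keys, per_rat=per_rat, mean=mean,
                        ci_low=lo, ci_high=hi, n_rats=vals.size)


def hub_amplitude_correlation(hub_index, median_beta) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) between per-session hub
    index and median beta amplitude; returns (rho, p)."""
    hub = np.asarray(hub_index, dtype=float)
    amp = np.asarray(median_beta, dtype=float)
    if hub.size != amp.size:
        raise ValueError("inputs must have equal length")
    if hub.size < 4:
        raise ValueError("need at least 4 sessions")
    rho, p = sct.spearmanr(hub, amp)
    return float(rho), float(p)


def export_tidy(df: pd.DataFrame, path) -> None:
    """Write a long-format table so that read-back round-trips losslessly."""
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_tidy(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
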