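"""Task-structured multichannel LFP simulator with ground truth.

Generates sessions that mimic the statistical structure the analysis
pipeline assumes: 1/f background noise, a slow respiration-locked component
on olfactory channels, beta bursts with Gaussian envelopes ending near
nose-poke end whose gain follows a per-trial schedule, controllable
cross-channel phase coupling of those bursts, and optional brief broadband
movement artifacts.  Every injected quantity is recorded in a
:class:`GroundTruth` so downstream stages have a parameter-recovery test
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SimConfig",
    "TrialTable",
    "SessionRecording",
    "GroundTruth",
    "generate_session",
    "generate_learning_sequence",
    "inject_artifacts",
    "SCENARIOS",
]

KNOWN_STRUCTURES = ("OB", "AP", "PP", "OT", "Stri", "Hipp", "Cereb")
#: channels that receive the respiration-locked slow component
OLFACTORY_STRUCTURES = frozenset({"OB", "AP", "PP", "OT"})
#: channels that never carry task-related beta bursts
NO_BURST_STRUCTURES = frozenset({"Hipp", "Cereb"})


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session.

    ``burst_gain`` is a dimensionless per-trial multiplier of the burst
    peak amplitude expressed in units of the background RMS; a scalar is
    broadcast over trials.  ``coupled_pairs`` maps ``(structure_a,
    structure_b)`` to ``(phase_offset_rad, phase_jitter_sd_rad)`` where the
    offset is the phase lead of ``structure_a`` over ``structure_b``.
    """

    structures: tuple[str, ...] = ("OB", "AP", "PP", "OT")
    fs: float = 1000.0
    n_trials: int = 80
    trial_duration_range: tuple[float, float] = (0.8, 1.8)
    inter_trial_interval_min: float = 7.0
    noise_exponent: float = 1.0
    respiration_freq: float = 2.0
    respiration_amplitude: float = 0.5
    beta_freq: float = 25.0
    burst_envelope_sd: float = 0.12
    burst_center_before_end: float = 0.15
    burst_gain: float | tuple[float, ...] = 1.0
    coupled_pairs: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    artifact_rate: float = 0.0
    artifact_amplitude: float = 20.0
    performance: float | tuple[float, ...] = 0.5
    warmup: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 200.0:
            raise ConfigError(f"fs={self.fs} Hz is below the minimum 200 Hz")
        if self.beta_freq >= self.fs / 2.0:
            raise ConfigError(f"beta_freq={self.beta_freq} Hz is at or above Nyquist")
        if not 17.0 <= self.beta_freq <= 28.0:
            raise ConfigError(f"beta_freq={self.beta_freq} Hz outside the 17-28 Hz band")
        if len(set(self.structures)) != len(self.structures):
            raise ConfigError("structures must be unique labels")
        lo, hi = self.trial_duration_range
        if not (0.0 < lo <= hi < 2.0):
            raise ConfigError("trial_duration_range must satisfy 0 < min <= max < 2 s")
        if self.inter_trial_interval_min < 7.0:
            raise ConfigError("inter_trial_interval_min must be >= 7 s")
        if np.any(np.asarray(self.gain_schedule()) < 0):
            raise ConfigError("burst_gain must be >= 0")
        if self.artifact_rate > 0 and self.fs <= 500.0:
            raise ConfigError("fs must exceed 500 Hz when artifacts are simulated")
        if self.artifact_rate > 0 and self.artifact_amplitude <= 0:
            raise ConfigError("artifact_amplitude must be positive")
        for pair in self.coupled_pairs:
            for s in pair:
                if s not in self.structures:
                    raise ConfigError(f"coupled pair references unknown structure {s!r}")

    def gain_schedule(self) -> np.ndarray:
        g = self.burst_gain
        if np.isscalar(g):
            return np.full(self.n_trials, float(g))
        g = np.asarray(g, dtype=float)
        if g.size != self.n_trials:
            raise ConfigError(
                f"burst_gain schedule length {g.size} != n_trials {self.n_trials}"
            )
        return g

    def performance_schedule(self) -> np.ndarray:
        p = self.performance
        if np.isscalar(p):
            return np.full(self.n_trials, float(p))
        p = np.asarray(p, dtype=float)
        if p.size != self.n_trials:
            raise ConfigError(
                f"performance schedule length {p.size} != n_trials {self.n_trials}"
            )
        return p


class TrialTable:
    """Per-trial event table: nose-poke interval, odor, choice, licks.

    Wraps a :class:`pandas.DataFrame` with columns ``trial``,
    ``nose_poke_start``, ``nose_poke_end``, ``odor``, ``side``, ``correct``
    and a parallel list of lick intervals (``[start, end)`` seconds).
    """

    COLUMNS = ("trial", "nose_poke_start", "nose_poke_end", "odor", "side", "correct")

    def __init__(self, df: pd.DataFrame, licks: list[list[tuple[float, float]]] | None = None):
        df = df.reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table missing columns {missing}")
        starts = df["nose_poke_start"].to_numpy(float)
        ends = df["nose_poke_end"].to_numpy(float)
        if np.any(ends <= starts):
            raise ValueError("nose_poke_end must exceed nose_poke_start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("trials must be ordered and non-overlapping")
        self.df = df
        self.licks = licks if licks is not None else [[] for _ in range(len(df))]
        if len(self.licks) != len(df):
            raise ValueError("licks list length must match trial count")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def starts(self) -> np.ndarray:
        return self.df["nose_poke_start"].to_numpy(float)

    @property
    def ends(self) -> np.ndarray:
        return self.df["nose_poke_end"].to_numpy(float)

    @property
    def correct(self) -> np.ndarray:
        return self.df["correct"].to_numpy(bool)

    @property
    def odors(self) -> np.ndarray:
        return self.df["odor"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["licks"] = [
            ";".join(f"{a:.6f}-{b:.6f}" for a, b in iv) for iv in self.licks
        ]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialTable":
        df = pd.read_csv(path)
        licks: list[list[tuple[float, float]]] = []
        raw = df.pop("licks") if "licks" in df.columns else pd.Series([""] * len(df))
        for cell in raw.fillna(""):
            iv = []
            for tok in str(cell).split(";"):
                if tok and "-" in tok:
                    a, b = tok.split("-")
                    iv.append((float(a), float(b)))
            licks.append(iv)
        df["correct"] = df["correct"].astype(bool)
        return cls(df, licks)


@dataclass
class SessionRecording:
    """Multichannel voltage series + events + metadata for one session."""

    channels: dict[str, np.ndarray]
    fs: float
    events: TrialTable
    rat_id: str = "sim"
    session_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GroundTruth:
    """Simulator-side record of everything injected."""

    burst_gains: dict[str, np.ndarray]
    burst_peak_times: np.ndarray
    burst_phases: dict[str, np.ndarray]
    pair_offsets: dict[tuple[str, str], tuple[float, float]]
    artifact_intervals: dict[str, list[tuple[float, float]]]
    latent_performance: np.ndarray
    intended_label: str = ""


def _pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise by spectral shaping of white noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    gain = np.ones_like(f)
    gain[1:] = f[1:] ** (-alpha / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n)
    return x / np.std(x)


def _balanced_odor_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random A/B sequence with balanced counts (block shuffling)."""
    seq = []
    while len(seq) < n:
        block = ["A", "A", "B", "B"]
        rng.shuffle(block)
        seq.extend(block)
    return np.asarray(seq[:n])


def _make_trials(config: SimConfig, rng: np.random.Generator) -> tuple[TrialTable, np.ndarray]:
    lo, hi = config.trial_duration_range
    durations = rng.uniform(lo, hi, config.n_trials)
    itis = config.inter_trial_interval_min + rng.uniform(0.0, 2.0, config.n_trials)
    starts = np.empty(config.n_trials)
    t = config.warmup
    for i in range(config.n_trials):
        starts[i] = t
        t = starts[i] + durations[i] + itis[i]
    ends = starts + durations
    odors = _balanced_odor_sequence(config.n_trials, rng)
    perf = config.performance_schedule()
    correct = rng.random(config.n_trials) < perf
    odor_side = {"A": "L", "B": "R"}
    sides, licks = [], []
    for i in range(config.n_trials):
        good = odor_side[odors[i]]
        if correct[i]:
            sides.append(good)
            lick_on = ends[i] + rng.uniform(0.5, 1.5)
            licks.append([(lick_on, lick_on + 2.0)])
        else:
            # mostly wrong-side pokes, occasionally no response
            sides.append("none" if rng.random() < 0.1 else ("R" if good == "L" else "L"))
            licks.append([])
    df = pd.DataFrame(
        {
            "trial": np.arange(config.n_trials),
            "nose_poke_start": starts,
            "nose_poke_end": ends,
            "odor": odors,
            "side": sides,
            "correct": correct,
        }
    )
    return TrialTable(df, licks), perf


def _coupling_components(
    structures: tuple[str, ...],
    pairs: dict[tuple[str, str], tuple[float, float]],
) -> list[dict[str, tuple[float, float]]]:
    """Resolve pair constraints into per-component phase assignments.

    Each component is rooted at its first structure (offset 0, jitter 0);
    every other member gets (cumulative offset, jitter) relative to the
    root by breadth-first traversal.  Pair offset = phase(a) - phase(b).
    """
    adj: dict[str, list[tuple[str, float, float]]] = {s: [] for s in structures}
    for (a, b), (off, jit) in pairs.items():
        adj[a].append((b, -off, jit))   # phase(b) = phase(a) - off
        adj[b].append((a, off, jit))
    seen: set[str] = set()
    components = []
    for root in structures:
        if root in seen:
            continue
        comp = {root: (0.0, 0.0)}
        seen.add(root)
        queue = [root]
        while queue:
            cur = queue.pop()
            cur_off, _ = comp[cur]
            for nxt, delta, jit in adj[cur]:
                if nxt not in comp:
                    comp[nxt] = (cur_off + delta, jit)
                    seen.add(nxt)
                    queue.append(nxt)
        components.append(comp)
    return components


def generate_session(
    config: SimConfig,
    gain_schedule: np.ndarray | None = None,
    rat_id: str = "sim",
    session_label: str = "S1",
) -> tuple[SessionRecording, GroundTruth]:
    """Simulate one session; deterministic given ``config.seed``.

    ``gain_schedule`` overrides ``config.burst_gain`` (must have length
    ``n_trials``).
    """
    config.validate()
    if gain_schedule is not None:
        gain_schedule = np.asarray(gain_schedule, dtype=float)
        if gain_schedule.size != config.n_trials:
            raise ConfigError(
                f"gain schedule length {gain_schedule.size} != n_trials {config.n_trials}"
            )
        if np.any(gain_schedule < 0):
            raise ConfigError("burst_gain must be >= 0")
    else:
        gain_schedule = config.gain_schedule()

    rng = np.random.default_rng(config.seed)
    trials, perf = _make_trials(config, rng)
    duration = trials.ends[-1] + config.inter_trial_interval_min + 2.0
    n = int(round(duration * config.fs))
    t = np.arange(n) / config.fs

    peak_times = trials.ends - config.burst_center_before_end
    components = _coupling_components(config.structures, config.coupled_pairs)

    # per-trial, per-structure burst carrier phases honoring the coupling graph
    phases = {s: np.zeros(config.n_trials) for s in config.structures}
    for comp in components:
        root_phase = rng.uniform(0.0, 2.0 * np.pi, config.n_trials)
        for s, (off, jit) in comp.items():
            jitter = rng.normal(0.0, jit, config.n_trials) if jit > 0 else 0.0
            phases[s] = root_phase + off + jitter

    channels: dict[str, np.ndarray] = {}
    burst_gains: dict[str, np.ndarray] = {}
    for s in config.structures:
        x = _pink_noise(n, config.noise_exponent, rng)
        if s in OLFACTORY_STRUCTURES and config.respiration_amplitude > 0:
            freq_walk = np.cumsum(rng.normal(0.0, 0.002, n))
            phase = 2.0 * np.pi * np.cumsum(
                (config.respiration_freq + freq_walk) / config.fs
            )
            x = x + config.respiration_amplitude * np.sin(phase + rng.uniform(0, 2 * np.pi))
        gains = np.zeros(config.n_trials) if s in NO_BURST_STRUCTURES else gain_schedule.copy()
        for i in range(config.n_trials):
            if gains[i] <= 0:
                continue
            tc = peak_times[i]
            lo = max(0, int((tc - 5 * config.burst_envelope_sd) * config.fs))
            hi = min(n, int((tc + 5 * config.burst_envelope_sd) * config.fs))
            tt = t[lo:hi]
            env = gains[i] * np.exp(-0.5 * ((tt - tc) / config.burst_envelope_sd) ** 2)
            x[lo:hi] += env * np.cos(
                2.0 * np.pi * config.beta_freq * (tt - tc) + phases[s][i]
            )
        channels[s] = x
        burst_gains[s] = gains

    recording = SessionRecording(
        channels=channels, fs=config.fs, events=trials,
        rat_id=rat_id, session_label=session_label, seed=config.seed,
    )
    truth = GroundTruth(
        burst_gains=burst_gains,
        burst_peak_times=peak_times,
        burst_phases=phases,
        pair_offsets=dict(config.coupled_pairs),
        artifact_intervals={s: [] for s in config.structures},
        latent_performance=perf,
        intended_label=session_label,
    )
    if config.artifact_rate > 0:
        recording, truth = inject_artifacts(recording, config, truth)
    return recording, truth


def inject_artifacts(
    recording: SessionRecording,
    config: SimConfig,
    truth: GroundTruth | None = None,
) -> tuple[SessionRecording, GroundTruth]:
    """Add brief broadband (>90 Hz) transients at ``config.artifact_rate``
    events per minute and ``config.artifact_amplitude`` times the background
    RMS; intervals are appended to the ground truth."""
    if recording.fs <= 500.0:
        raise ConfigError("fs must exceed 500 Hz to place 90-250 Hz artifacts")
    if config.artifact_amplitude <= 0:
        raise ConfigError("artifact_amplitude must be positive")
    if truth is None:
        truth = GroundTruth(
            burst_gains={s: np.zeros(len(recording.events)) for s in recording.structures},
            burst_peak_times=recording.events.ends - config.burst_center_before_end,
            burst_phases={s: np.zeros(len(recording.events)) for s in recording.structures},
            pair_offsets={},
            artifact_intervals={s: [] for s in recording.structures},
            latent_performance=np.full(len(recording.events), 0.5),
        )
    if config.artifact_rate == 0:
        return recording, truth

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA21FAC]))
    fs = recording.fs
    n = recording.n_samples
    duration_min = recording.duration / 60.0
    sos = sps.butter(4, [90.0, min(250.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    channels = {s: v.copy() for s, v in recording.channels.items()}
    intervals = {s: list(truth.artifact_intervals.get(s, [])) for s in recording.structures}
    for s in recording.structures:
        n_events = rng.poisson(config.artifact_rate * duration_min)
        rms = np.std(recording.channels[s])
        for _ in range(n_events):
            width = rng.uniform(0.02, 0.2)
            start = rng.uniform(0.0, recording.duration - width)
            i0, i1 = int(start * fs), int((start + width) * fs)
            if i1 <= i0 + 8:
                continue
            burst = sps.sosfiltfilt(sos, rng.standard_normal(i1 - i0 + 200))[100:-100]
            burst = burst / np.std(burst) * config.artifact_amplitude * rms
            burst *= sps.windows.tukey(i1 - i0, alpha=0.5)
            channels[s][i0:i1] += burst
            intervals[s].append((i0 / fs, i1 / fs))
        intervals[s].sort()
    new_rec = replace(recording, channels=channels)
    new_truth = replace(truth, artifact_intervals=intervals)
    return new_rec, new_truth


# --------------------------------------------------------------------------
# learning-sequence scenarios

def _session_gain_profile(n_trials: int, g_max: float, ramp_trials: int = 15,
                          g_start_frac: float = 0.3) -> np.ndarray:
    """Within-session gain ramp over the first ``ramp_trials`` trials."""
    idx = np.arange(n_trials, dtype=float)
    ramp = np.minimum(1.0, idx / max(ramp_trials - 1, 1))
    return g_max * (g_start_frac + (1.0 - g_start_frac) * ramp)


def _scenario_acquisition(n_sessions: int) -> list[tuple[float, float, float]]:
    """(session perf, session max gain, coupling jitter) per session."""
    perf = np.linspace(0.5, 0.92, n_sessions)
    gain = np.linspace(0.4, 3.0, n_sessions)
    jitter = np.linspace(2.5, 0.2, n_sessions)
    return list(zip(perf, gain, jitter))

def _scenario_transfer(n_sessions: int) -> list[tuple[float, float, float]]:
    perf = np.linspace(0.6, 0.92, n_sessions)
    gain = np.linspace(1.0, 3.0, n_sessions)
    jitter = np.linspace(1.5, 0.2, n_sessions)
    return list(zip(perf, gain, jitter))

def _scenario_recall(n_sessions: int) -> list[tuple[float, float, float]]:
    return [(0.9, 3.0, 0.2)] * n_sessions

def _scenario_reversal(n_sessions: int) -> list[tuple[float, float, float]]:
    # below-chance start (old association), gain initially high, dips, recovers
    perf = np.concatenate([[0.2], np.linspace(0.35, 0.9, max(n_sessions - 1, 1))])[:n_sessions]
    gain = np.concatenate([[3.0], np.linspace(1.0, 3.0, max(n_sessions - 1, 1))])[:n_sessions]
    jitter = np.concatenate([[0.3], np.linspace(1.5, 0.2, max(n_sessions - 1, 1))])[:n_sessions]
    return list(zip(perf, gain, jitter))


SCENARIOS = {
    "acquisition": _scenario_acquisition,
    "transfer": _scenario_transfer,
    "recall": _scenario_recall,
    "reversal": _scenario_reversal,
}


def generate_learning_sequence(
    config: SimConfig,
    scenario: str,
    n_sessions: int = 8,
    rat_id: str = "sim",
) -> list[tuple[SessionRecording, GroundTruth]]:
    """Generate a multi-session sequence following a named phase plan.

    Session-wise latent performance and burst-gain trajectories follow the
    scenario; within each session the gain ramps over the first ~15 trials.
    Coupling jitter of the pairs in ``config.coupled_pairs`` follows the
    scenario trajectory (tightening as learning progresses).
    """
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; valid names: {sorted(SCENARIOS)}"
        )
    plan = SCENARIOS[scenario](n_sessions)
    out = []
    for k, (perf, g_max, jitter) in enumerate(plan):
        pairs = {
            pair: (off, jitter)
            for pair, (off, _) in config.coupled_pairs.items()
        }
        cfg = replace(
            config,
            performance=perf,
            coupled_pairs=pairs,
            seed=int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0]),
        )
        gains = _session_gain_profile(config.n_trials, g_max)
        label = f"{scenario[:3].upper()}-{k + 1}"
        out.append(generate_session(cfg, gain_schedule=gains, rat_id=rat_id,
                                    session_label=label))
    return out
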