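"""Synthetic session generators for the three behavioral tasks.

Three tasks are simulated, matching the parameterization used for the rat
experiments the models are built around:

* **Pavlovian conditioning** — three auditory cues (pip trains, 2.6 s total,
  followed by a 0.5 s trace period) predict a food-hopper reward click with
  probabilities 75%, 25% and 0%; a fourth trial type delivers the click with
  no preceding cue. Trial types are interleaved in pseudorandom order with a
  uniform 15-30 s intertrial interval, 60 trials of each type per session.
* **Multiple-delay conditioning** — cues are pip trains of 1, 17 or 76 pips
  (150 ms pip period), each followed by a fixed 0.5 s trace and a 75%-probable
  reward click, giving cue-to-outcome delays of 0.6 s, 3.0 s and ~11.9 s,
  plus uncued (zero-delay) reward deliveries.
* **Instrumental probabilistic reward** — self-paced trials with a 0.5-1.5 s
  hold before a Go cue; left/right reward probabilities drawn independently
  from {10%, 50%, 90%} in blocks of 35-45 trials. Choices come from a simple
  softmax policy over leaky-integrated per-side reward history (the point is
  plausible outcome sequences for downstream fitting, not a behavioral model).

"Pseudorandom order" is implemented as a shuffled concatenation of the exact
per-type trial counts, so per-session counts are exact rather than binomial.
All times are seconds from the first event; same seed gives a bit-identical
session.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventStream",
    "TaskConfig",
    "generate_pavlovian_session",
    "generate_delay_session",
    "generate_instrumental_session",
    "trials_per_window",
]

EVENT_LABELS = (
    "cue_onset",
    "cue_offset",
    "reward_click",
    "pellet",
    "poke_in",
    "poke_out",
    "go_cue",
)

TRIAL_COLUMNS = [
    "trial_index",
    "trial_type",
    "cue_prob",
    "delay",
    "rewarded",
    "cue_onset_time",
    "outcome_time",
    "iti_before",
]


@dataclass(frozen=True)
class EventStream:
    """Timestamped task events: (time s, label, optional cue id).

    Times are nondecreasing; every cue_onset is paired with a later
    cue_offset carrying the same cue id.
    """

    times: np.ndarray
    labels: np.ndarray
    cue_ids: np.ndarray  # float array; NaN where no cue id applies

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("times must be 1-D")
        if len(t) != len(self.labels) or len(t) != len(self.cue_ids):
            raise ValueError("times, labels, cue_ids must have equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("event times must be nondecreasing")
        bad = set(np.unique(self.labels)) - set(EVENT_LABELS)
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.times)

    def select(self, label: str) -> np.ndarray:
        """Times of all events with the given label."""
        return self.times[self.labels == label]

    def events_of(self, label: str) -> pd.DataFrame:
        m = self.labels == label
        return pd.DataFrame(
            {"time": self.times[m], "cue_id": self.cue_ids[m]}
        )

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "label": self.labels, "cue_id": self.cue_ids}
        )

    def to_tsv(self, path_or_buf) -> None:
        """Serialize as tab-delimited text (time, label, cue_id); the
        shortest-repr float formatting round-trips exactly."""
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "EventStream":
        df = pd.read_csv(path_or_buf, sep="\t",
                         float_precision="round_trip")
        return cls(
            times=df["time"].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=object),
            cue_ids=df["cue_id"].to_numpy(dtype=float),
        )

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "EventStream":
        """Build from (time, label, cue_id-or-None) tuples, sorting by time."""
        if len(records) == 0:
            return cls(np.empty(0), np.empty(0, dtype=object), np.empty(0))
        rec = sorted(records, key=lambda r: r[0])
        times = np.array([r[0] for r in rec], dtype=float)
        labels = np.array([r[1] for r in rec], dtype=object)
        cue_ids = np.array(
            [np.nan if r[2] is None else float(r[2]) for r in rec], dtype=float
        )
        return cls(times, labels, cue_ids)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of a simulated session.

    Defaults follow the rat task design: 100 ms pips with 50 ms gaps,
    uniform 15-30 s ITI, 0.5 s trace period between cue end and outcome.
    """

    task_kind: str = "pavlovian"
    probs: tuple = (0.75, 0.25, 0.0)
    delays_pips: tuple = (1, 17, 76)
    delay_reward_prob: float = 0.75
    n_per_type: int = 60
    iti_range: tuple = (15.0, 30.0)
    pip_on: float = 0.1
    pip_off: float = 0.05
    cue_duration: float = 2.6
    trace: float = 0.5
    # instrumental-only
    n_trials: int = 300
    block_len_range: tuple = (35, 45)
    block_probs: tuple = (0.1, 0.5, 0.9)
    hold_range: tuple = (0.5, 1.5)
    move_time_range: tuple = (0.3, 1.5)
    instr_iti_range: tuple = (3.0, 10.0)
    policy_beta: float = 3.0
    policy_tau: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.task_kind not in ("pavlovian", "delay", "instrumental"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.n_per_type < 0 or self.n_trials < 0:
            raise ValueError("trial counts must be nonnegative")
        if any(not (0.0 <= p <= 1.0) for p in self.probs):
            raise ValueError("cue probabilities must lie in [0, 1]")
        if not (0.0 <= self.delay_reward_prob <= 1.0):
            raise ValueError("delay_reward_prob must lie in [0, 1]")
        if any(k < 1 for k in self.delays_pips):
            raise ValueError("pip counts must be >= 1")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range inverted")
        if self.block_len_range[0] > self.block_len_range[1]:
            raise ValueError("block_len_range inverted")
        if self.hold_range[0] > self.hold_range[1]:
            raise ValueError("hold_range inverted")

    @property
    def pip_period(self) -> float:
        return self.pip_on + self.pip_off


def _shuffled_types(labels: list, counts: list, rng: np.random.Generator):
    order = np.repeat(np.arange(len(labels)), counts)
    rng.shuffle(order)
    return order


def generate_pavlovian_session(config: TaskConfig):
    """Simulate one Pavlovian session.

    Returns (EventStream, TrialTable). Four trial types (three cues plus
    uncued reward) are shuffled with exact per-type counts; each cued trial is
    a ``cue_duration`` pip train, a ``trace`` period, then a reward click with
    the cue's probability. Uncued trials are a bare reward click.
    """
    if config.task_kind != "pavlovian":
        raise ValueError("config.task_kind must be 'pavlovian'")
    if len(config.probs) != 3:
        raise ValueError("pavlovian task uses exactly 3 cue probabilities")
    rng = np.random.default_rng(config.seed)
    n_types = 4  # 3 cues + uncued
    order = _shuffled_types(
        list(range(n_types)), [config.n_per_type] * n_types, rng
    )
    events: list[tuple] = []
    rows = []
    t = 0.0
    trial_dur = config.cue_duration + config.trace
    for i, typ in enumerate(order):
        iti = rng.uniform(*config.iti_range)
        t += iti
        if typ < 3:  # cued
            p = config.probs[typ]
            rewarded = bool(rng.random() < p)
            onset = t
            events.append((onset, "cue_onset", typ))
            events.append((onset + config.cue_duration, "cue_offset", typ))
            outcome = onset + trial_dur
            if rewarded:
                events.append((outcome, "reward_click", typ))
            rows.append(
                (i, f"cue{int(round(p * 100))}", p, np.nan, rewarded,
                 onset, outcome, iti)
            )
            t = outcome
        else:  # uncued reward
            outcome = t
            events.append((outcome, "reward_click", None))
            rows.append(
                (i, "uncued", np.nan, np.nan, True, np.nan, outcome, iti)
            )
    stream = EventStream.from_records(events)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return stream, trials


def generate_delay_session(config: TaskConfig):
    """Simulate one multiple-delay session.

    Cues are pip trains of k pips at a 150 ms period; the outcome click (75%
    probable) follows the end of the last pip plus the 0.5 s trace, so the
    single-pip cue has a 0.6 s cue-to-outcome delay and the 17-pip cue 3.0 s.
    Uncued (zero-delay) reward trials are interleaved.
    """
    if config.task_kind != "delay":
        raise ValueError("config.task_kind must be 'delay'")
    rng = np.random.default_rng(config.seed)
    k_list = list(config.delays_pips)
    n_types = len(k_list) + 1
    order = _shuffled_types(
        list(range(n_types)), [config.n_per_type] * n_types, rng
    )
    events: list[tuple] = []
    rows = []
    t = 0.0
    for i, typ in enumerate(order):
        iti = rng.uniform(*config.iti_range)
        t += iti
        if typ < len(k_list):
            k = k_list[typ]
            onset = t
            delay = (k - 1) * config.pip_period + config.pip_on + config.trace
            train_end_on = onset + (delay - config.trace)
            rewarded = bool(rng.random() < config.delay_reward_prob)
            events.append((onset, "cue_onset", typ))
            events.append((train_end_on, "cue_offset", typ))
            outcome = onset + delay
            if rewarded:
                events.append((outcome, "reward_click", typ))
            rows.append(
                (i, f"delay_{k}pip", config.delay_reward_prob, delay,
                 rewarded, onset, outcome, iti)
            )
            t = outcome
        else:
            outcome = t
            events.append((outcome, "reward_click", None))
            rows.append(
                (i, "uncued", np.nan, 0.0, True, np.nan, outcome, iti)
            )
    stream = EventStream.from_records(events)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return stream, trials


def _softmax2(q_left: float, q_right: float, beta: float, rng) -> int:
    z = beta * (q_right - q_left)
    p_right = 1.0 / (1.0 + np.exp(-z))
    return int(rng.random() < p_right)


def generate_instrumental_session(config: TaskConfig):
    """Simulate one instrumental session.

    Left/right reward probabilities are piecewise-constant in blocks of
    35-45 trials, drawn independently from ``block_probs``. Each trial:
    center poke-in, uniform 0.5-1.5 s hold, Go cue, poke-out, side poke
    (the choice, from a softmax over leaky-integrated per-side reward
    history), and a reward click on rewarded trials at the side poke.
    """
    if config.task_kind != "instrumental":
        raise ValueError("config.task_kind must be 'instrumental'")
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    lo, hi = config.block_len_range
    # independent left/right block schedules
    def schedule():
        probs = np.empty(n)
        i = 0
        while i < n:
            ln = int(rng.integers(lo, hi + 1))
            probs[i: i + ln] = rng.choice(config.block_probs)
            i += ln
        return probs

    p_left, p_right = schedule(), schedule()
    events: list[tuple] = []
    rows = []
    t = 0.0
    q = np.zeros(2)  # leaky per-side reward history
    last_t = 0.0
    for i in range(n):
        iti = rng.uniform(*config.instr_iti_range)
        t += iti
        # decay history to current time
        q *= np.exp(-(t - last_t) / config.policy_tau)
        last_t = t
        poke_in = t
        hold = rng.uniform(*config.hold_range)
        go = poke_in + hold
        move = rng.uniform(*config.move_time_range)
        side_poke = go + move
        choice = _softmax2(q[0], q[1], config.policy_beta, rng)  # 1 = right
        p = p_right[i] if choice else p_left[i]
        rewarded = bool(rng.random() < p)
        events.append((poke_in, "poke_in", None))
        events.append((go, "go_cue", None))
        events.append((go + 0.05, "poke_out", None))
        events.append((side_poke, "poke_in", None))
        if rewarded:
            events.append((side_poke, "reward_click", None))
            q[choice] += 1.0
        rows.append(
            (i, "right" if choice else "left", p, np.nan, rewarded,
             np.nan, side_poke, iti)
        )
        t = side_poke
    stream = EventStream.from_records(events)
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    trials["block_p_left"] = p_left
    trials["block_p_right"] = p_right
    return stream, trials


def trial_onset_times(stream: EventStream) -> np.ndarray:
    """Trial-start times: cue onsets plus uncued reward clicks.

    An uncued click is a reward_click with no cue id (NaN).
    """
    onsets = stream.select("cue_onset")
    m = (stream.labels == "reward_click") & np.isnan(stream.cue_ids)
    uncued = stream.times[m]
    return np.sort(np.concatenate([onsets, uncued]))


def trials_per_window(stream: EventStream, window: float):
    """Mean and SD of trial-onset counts in consecutive windows.

    Windows tile [t0, t_end) with the given length; the trailing partial
    window is dropped. Returns a dict with mean, sd, counts, n_windows.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    onsets = trial_onset_times(stream)
    if len(onsets) == 0:
        raise ValueError("stream contains no trials")
    t0, t_end = stream.times[0], stream.times[-1]
    n_win = int(np.floor((t_end - t0) / window))
    if n_win < 1:
        counts = np.array([len(onsets)])
    else:
        edges = t0 + window * np.arange(n_win + 1)
        counts, _ = np.histogram(onsets, bins=edges)
    return {
        "mean": float(np.mean(counts)),
        "sd": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
        "counts": counts,
        "n_windows": int(len(counts)),
    }
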