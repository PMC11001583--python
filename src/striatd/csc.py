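"""Complete-serial-compound TD(λ) model of Pavlovian conditioning.

The cue-reward interval is divided into fixed-width sub-states (200 ms by
default). Each cue activates its own one-hot serial chain — feature (cue, k)
is active k steps after that cue's onset — plus a *shared* serial chain that
is active during any cue's pip train, which lets learning generalize between
cues early in training. Values are linear in the features, V(x) = w·x, and
weights follow TD(λ) with accumulating eligibility traces:

    δ_t = r_t + γ V(x_t) − V(x_{t−1})
    e_t = γλ e_{t−1} + x_{t−1}
    w  += α δ_t e_t

Both value terms use the pre-update weights. Intertrial intervals are not
represented by sub-states: traces reset at trial start, and weights persist
across trials. For a deterministic cue with reward D steps after onset the
converged cue-onset prediction error is γ^D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CSCConfig", "CSCRun", "build_features", "run_csc",
           "csc_cue_summary", "gamma_from_tau_step"]

TRIAL_TYPES = ("cue75", "cue25", "cue0", "uncued")


def gamma_from_tau_step(tau: float, dt: float) -> float:
    """Per-step discount equivalent to a continuous time constant τ."""
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    return float(np.exp(-dt / tau))


@dataclass(frozen=True)
class CSCConfig:
    """Sub-state model parameters.

    ``n_substates`` sub-states of width ``dt`` cover the trial from cue onset
    through ~1 s past reward; the reward click lands at step
    ``reward_step`` (cue 2.6 s + trace 0.5 s at dt = 0.2 s → step 15).
    """

    gamma: float = 0.9
    alpha: float = 0.01
    lam: float = 0.98
    dt: float = 0.2
    n_substates: int = 21
    cue_duration: float = 2.6
    trace: float = 0.5
    reward_probs: tuple = (0.75, 0.25, 0.0)
    reward_magnitude: float = 1.0
    shared_gain: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.n_substates * self.dt < self.cue_duration + self.trace:
            raise ValueError("sub-states do not cover the cue-reward interval")

    @property
    def reward_step(self) -> int:
        return int(np.round((self.cue_duration + self.trace) / self.dt))

    @property
    def cue_steps(self) -> int:
        """Sub-states during the pip train (shared feature active)."""
        return int(np.round(self.cue_duration / self.dt))

    @property
    def n_features(self) -> int:
        return 4 * self.n_substates  # 3 cue chains + 1 shared chain

    @property
    def tau_equivalent(self) -> float:
        """Time constant (s) with the same per-step discount."""
        return float(-self.dt / np.log(self.gamma)) if self.gamma < 1 \
            else np.inf


def build_features(trial_type: str, config: CSCConfig) -> np.ndarray:
    """Per-step feature matrix (n_substates, n_features) for one trial.

    Cue trials activate the cue's serial one-hot chain for every step and the
    shared chain during the pip train only; uncued trials activate nothing.
    """
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial type {trial_type!r}")
    n, m = config.n_substates, config.n_features
    X = np.zeros((n, m))
    if trial_type == "uncued":
        return X
    cue_idx = TRIAL_TYPES.index(trial_type)
    for k in range(n):
        X[k, cue_idx * config.n_substates + k] = 1.0
        if k < config.cue_steps:
            X[k, 3 * config.n_substates + k] = config.shared_gain
    return X


@dataclass
class CSCRun:
    config: CSCConfig
    w: np.ndarray
    rpe: np.ndarray  # (n_trials, n_substates) per-step delta
    trial_types: np.ndarray
    rewarded: np.ndarray
    w_snapshots: np.ndarray | None = None

    @property
    def onset_rpe(self) -> np.ndarray:
        return self.rpe[:, 0]

    @property
    def outcome_rpe(self) -> np.ndarray:
        return self.rpe[:, self.config.reward_step]


def _trial_type_of_row(row) -> str:
    tt = row["trial_type"]
    return tt if tt in TRIAL_TYPES else "uncued"


def run_csc(config: CSCConfig, trial_sequence, seed: int = 0,
            snapshot_every: int = 0) -> CSCRun:
    """Run the model over a trial sequence.

    ``trial_sequence`` is a Pavlovian trial table (DataFrame with trial_type
    and rewarded columns) or a list of (trial_type, rewarded) pairs. Traces
    reset at trial start; weights persist. Returns per-trial, per-step
    prediction errors.
    """
    if isinstance(trial_sequence, pd.DataFrame):
        trials = [(_trial_type_of_row(r), bool(r["rewarded"]))
                  for _, r in trial_sequence.iterrows()]
    else:
        trials = [(tt, bool(rw)) for tt, rw in trial_sequence]
    n_steps, n_feat = config.n_substates, config.n_features
    feats = {tt: build_features(tt, config) for tt in TRIAL_TYPES}
    w = np.zeros(n_feat)
    rpe = np.zeros((len(trials), n_steps))
    snaps = []
    g, lam, a = config.gamma, config.lam, config.alpha
    for i, (tt, rewarded) in enumerate(trials):
        X = feats[tt]
        e = np.zeros(n_feat)
        x_prev = np.zeros(n_feat)
        # uncued reward clicks arrive unsignaled at the trial frame origin
        click_step = 0 if tt == "uncued" else config.reward_step
        for t in range(n_steps):
            x_t = X[t]
            r_t = config.reward_magnitude \
                if (rewarded and t == click_step) else 0.0
            delta = r_t + g * (w @ x_t) - (w @ x_prev)
            w = w + a * delta * e
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(
                    f"divergent weights at trial {i} step {t}; "
                    f"config={config}"
                )
            rpe[i, t] = delta
            e = g * lam * e + x_t
            x_prev = x_t
        if snapshot_every and (i + 1) % snapshot_every == 0:
            snaps.append(w.copy())
    return CSCRun(
        config=config,
        w=w,
        rpe=rpe,
        trial_types=np.array([tt for tt, _ in trials]),
        rewarded=np.array([rw for _, rw in trials]),
        w_snapshots=np.array(snaps) if snaps else None,
    )


def csc_cue_summary(run: CSCRun, n_blocks: int = 5) -> pd.DataFrame:
    """Block-averaged onset and outcome prediction errors per trial type.

    Splits the run into ``n_blocks`` consecutive equal blocks of trials and
    averages the cue-onset δ (all trials) and the reward-time δ (rewarded
    trials) per type. Outcome δ for uncued trials is the δ at the click step
    (step 0 for uncued trials, reward_step for cued).
    """
    n = len(run.trial_types)
    if n_blocks < 1 or n < n_blocks:
        raise ValueError("invalid block count")
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    rows = []
    present = [tt for tt in TRIAL_TYPES if (run.trial_types == tt).any()]
    # uncued clicks arrive with no preceding cue: the click step is 0 in the
    # uncued trial's sub-state frame (no features precede it)
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        for tt in present:
            m = (run.trial_types[lo:hi] == tt)
            if not m.any():
                raise ValueError(f"empty block {b} for type {tt}")
            seg_rpe = run.rpe[lo:hi][m]
            seg_rw = run.rewarded[lo:hi][m]
            onset = np.nan if tt == "uncued" else float(seg_rpe[:, 0].mean())
            click_step = 0 if tt == "uncued" else run.config.reward_step
            if seg_rw.any():
                outcome = float(seg_rpe[seg_rw][:, click_step].mean())
            else:
                outcome = np.nan
            rows.append({"block": b, "trial_type": tt,
                         "onset_rpe": onset, "outcome_rpe": outcome,
                         "n_trials": int(m.sum())})
    return pd.DataFrame(rows)
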