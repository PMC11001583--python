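"""Two-channel synthetic fiber-photometry traces with a known ground truth.

The simulator stands in for dLight dopamine recordings: each task event
(reward click, cue onset) injects an impulse whose amplitude is given by a
configurable ground-truth prediction-error model, convolved with a
single-exponential impulse response whose decay constant differs by striatal
subregion (fast in DLS, slow in VS). On top of the event-driven transients the
signal channel carries additive white noise and a slow drift; the control
channel carries the same drift (scaled) plus independent noise but no event
response, which is what the control-channel regression in ``signal_ops`` is
meant to remove.

Everything about the truth (model kind, parameters, per-event amplitudes) is
returned alongside the trace so that downstream fits can be scored as
parameter recovery. The kernel parameters are free parameters of the
simulator, not measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .task_sim import EventStream

__all__ = [
    "RegionParams",
    "PhotometryTrace",
    "GroundTruth",
    "REGION_DEFAULTS",
    "rpe_amplitudes_from_truth",
    "synthesize_trace",
    "raw_channels",
]


@dataclass(frozen=True)
class RegionParams:
    """Region-specific trace kinetics; defaults ordered DLS < DMS < VS."""

    region: str = "VS"
    kernel_tau: float = 0.4  # s, impulse-response decay
    noise_sd: float = 0.02  # dF/F units
    slow_drift_sd: float = 0.005  # dF/F units, kept small vs transients
    control_gain: float = 1.0

    def __post_init__(self):
        if self.kernel_tau <= 0:
            raise ValueError("kernel_tau must be positive")
        if self.noise_sd < 0 or self.slow_drift_sd < 0:
            raise ValueError("noise magnitudes must be nonnegative")


REGION_DEFAULTS = {
    "DLS": RegionParams(region="DLS", kernel_tau=0.1),
    "DMS": RegionParams(region="DMS", kernel_tau=0.2),
    "VS": RegionParams(region="VS", kernel_tau=0.4),
}


@dataclass(frozen=True)
class PhotometryTrace:
    """Uniformly sampled signal + control channel pair."""

    fs: float
    signal: np.ndarray
    control: np.ndarray
    region: str = ""
    t0: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.signal) != len(self.control):
            raise ValueError("signal and control must have equal length")

    def __len__(self) -> int:
        return len(self.signal)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.signal)) / self.fs

    def save(self, path) -> None:
        """Flat binary (.npz) with a JSON sidecar holding the metadata."""
        path = str(path)
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 signal=self.signal, control=self.control)
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json", "w") as fh:
            json.dump({"fs": self.fs, "region": self.region,
                       "t0": self.t0}, fh)

    def to_csv(self, path_or_buf) -> None:
        """Plain-text export (t, signal, control) for small fixtures."""
        import pandas as pd

        pd.DataFrame({"t": self.times, "signal": self.signal,
                      "control": self.control}).to_csv(path_or_buf,
                                                       index=False)

    @classmethod
    def load(cls, path) -> "PhotometryTrace":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        arrays = np.load(base + ".npz")
        with open(base + ".json") as fh:
            meta = json.load(fh)
        return cls(fs=meta["fs"], signal=arrays["signal"],
                   control=arrays["control"], region=meta["region"],
                   t0=meta["t0"])


@dataclass(frozen=True)
class GroundTruth:
    """The prediction-error model driving a synthetic trace.

    model_kind:
      * ``leaky_integrator`` — click amplitude a − b·rate(t⁻), rate from a
        leaky integrator of past reward clicks with time constant τ
        (params: a, b, tau).
      * ``delta_rule`` — click amplitude a − b·V(trial), V from a per-trial
        delta rule with learning rate α (params: a, b, alpha; trial outcomes
        taken from the stream's rewarded clicks).
      * ``discount_curve`` — cue-onset amplitude b + A·e^(−delay/τ)
        (params: b, A, tau); clicks get unit amplitude.
    """

    model_kind: str = "leaky_integrator"
    params: dict = field(default_factory=lambda: {"a": 1.0, "b": 0.02,
                                                  "tau": 60.0})
    amplitudes: Optional[dict] = None  # filled in by synthesize_trace

    def __post_init__(self):
        if self.model_kind not in (
            "leaky_integrator", "delta_rule", "discount_curve"
        ):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


def _cue_delays(stream: EventStream) -> dict:
    """Map cue_onset time -> delay to that trial's outcome (click time).

    Uses the next reward_click with the same cue id; unrewarded cue onsets
    get the cue-to-scheduled-outcome delay inferred from cue_offset + trace
    where available, else NaN.
    """
    onsets = stream.events_of("cue_onset")
    clicks = stream.events_of("reward_click")
    delays = {}
    for _, row in onsets.iterrows():
        t, cid = row["time"], row["cue_id"]
        later = clicks[(clicks["time"] > t) & (clicks["cue_id"] == cid)]
        delays[t] = float(later["time"].iloc[0] - t) if len(later) else np.nan
    return delays


def rpe_amplitudes_from_truth(stream: EventStream, truth: GroundTruth):
    """Per-event impulse amplitudes implied by the ground-truth model.

    Returns (event_times, amplitudes) covering reward clicks and, for the
    discount_curve model, cue onsets as well. Rates/values are evaluated at
    the left limit (the event itself excluded).
    """
    p = truth.params
    clicks = stream.select("reward_click")
    if truth.model_kind == "leaky_integrator":
        from .history_fit import leaky_rate

        rate = leaky_rate(clicks, p["tau"], clicks)  # left limit by contract
        amps = p["a"] - p["b"] * rate
        return clicks.copy(), amps
    if truth.model_kind == "delta_rule":
        from .history_fit import delta_rule_values

        # Full trial outcome sequence may be supplied via params["outcomes"]
        # (0/1 per trial, rewarded trials in click order); otherwise every
        # click is treated as a rewarded trial with no interleaved misses.
        outcomes = np.asarray(p.get("outcomes", np.ones(len(clicks), int)))
        v = delta_rule_values(outcomes, p["alpha"], p.get("v0", 0.0))
        v_click = v[outcomes == 1]
        if len(v_click) != len(clicks):
            raise ValueError(
                "params['outcomes'] rewarded count must match click count"
            )
        amps = p["a"] - p["b"] * v_click
        return clicks.copy(), amps
    if truth.model_kind == "discount_curve":
        delays = _cue_delays(stream)
        cue_t = np.array(sorted(delays))
        cue_amp = np.array(
            [p["b"] + p["A"] * np.exp(-delays[t] / p["tau"])
             if np.isfinite(delays[t]) else p["b"] for t in cue_t]
        )
        times = np.concatenate([cue_t, clicks])
        amps = np.concatenate([cue_amp, np.ones(len(clicks))])
        order = np.argsort(times, kind="stable")
        return times[order], amps[order]
    raise ValueError(f"unknown model_kind {truth.model_kind!r}")


def _slow_drift(n: int, fs: float, sd: float, rng) -> np.ndarray:
    """Random walk low-passed at ~0.1 Hz, scaled to the requested SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    steps = rng.standard_normal(n)
    walk = np.cumsum(steps)
    # single-pole low-pass at 0.1 Hz
    fc = 0.1
    a = np.exp(-2.0 * np.pi * fc / fs)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = a * acc + (1 - a) * walk[i]
        out[i] = acc
    s = out.std()
    return out * (sd / s) if s > 0 else out


def synthesize_trace(
    stream: EventStream,
    truth: GroundTruth,
    rp: RegionParams,
    seed: int = 0,
    fs: float = 100.0,
    pad: float = 5.0,
):
    """Render a two-channel trace from an event stream and a truth model.

    Each driven event injects ``amplitude × exp(−t/kernel_tau)`` starting at
    the event sample. The signal channel adds white noise and slow drift; the
    control channel carries ``control_gain × drift`` plus independent noise
    and no event response. Returns (PhotometryTrace, GroundTruth) with the
    per-event amplitudes recorded in the truth.
    """
    if len(stream) == 0:
        raise ValueError("empty event stream")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    t0 = float(stream.times[0]) - pad
    t_end = float(stream.times[-1]) + pad
    n = int(np.ceil((t_end - t0) * fs)) + 1
    ev_times, ev_amps = rpe_amplitudes_from_truth(stream, truth)

    signal = np.zeros(n)
    idx = np.round((ev_times - t0) * fs).astype(int)
    ok = (idx >= 0) & (idx < n)
    np.add.at(signal, idx[ok], ev_amps[ok])
    # causal exponential kernel via recursive filter: peak = impulse amplitude
    decay = np.exp(-1.0 / (fs * rp.kernel_tau))
    from scipy.signal import lfilter

    signal = lfilter([1.0], [1.0, -decay], signal)

    drift = _slow_drift(n, fs, rp.slow_drift_sd, rng)
    sig_noise = rng.standard_normal(n) * rp.noise_sd
    ctl_noise = rng.standard_normal(n) * rp.noise_sd
    trace = PhotometryTrace(
        fs=fs,
        signal=signal + drift + sig_noise,
        control=rp.control_gain * drift + ctl_noise,
        region=rp.region,
        t0=t0,
    )
    truth_out = GroundTruth(
        model_kind=truth.model_kind,
        params=dict(truth.params),
        amplitudes={"times": ev_times, "amps": ev_amps},
    )
    return trace, truth_out


def raw_channels(trace: PhotometryTrace, f0_signal: float = 100.0,
                 f0_control: float = 80.0):
    """Convert dF/F-scale channels to raw-fluorescence-like channels.

    Useful for exercising the control-fit dF/F computation: returns
    (signal_raw, control_raw) = (f0_s·(1+signal), f0_c·(1+control)).
    """
    return (f0_signal * (1.0 + trace.signal),
            f0_control * (1.0 + trace.control))
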