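"""Photometry signal conventions: dF/F, normalization, response extraction.

Implements the standard dual-channel processing chain for dLight-style
recordings: the control channel is least-squares rescaled onto the signal
channel (affine: gain plus offset) and the fractional fluorescence is
(signal − control_fit)/control_fit. Responses are normalized to the mean peak
response within 1 s of unpredictable reward delivery, cue responses are the
extremum of larger absolute value within 0.5 s of cue onset, autocorrelation
tempo is quantified as the best-fit exponential decay over 40-200 ms lags,
and transient duration as the width at half maximum.

Peak windows are half-open (0, w] after the event: the sample at exactly the
event time is excluded, because event-driven transients begin after the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .photometry_sim import PhotometryTrace
from .task_sim import EventStream

__all__ = [
    "AlignedResponse",
    "compute_dff",
    "align_to_events",
    "peak_in_window",
    "uncued_click_times",
    "normalize_to_uncued",
    "cue_response",
    "autocorr",
    "autocorr_decay",
    "half_width",
]


@dataclass(frozen=True)
class AlignedResponse:
    """Per-event signal snippets on a common window around time zero."""

    window: tuple  # (pre, post) seconds relative to the event, pre <= 0
    snippets: np.ndarray  # (n_events, n_samples)
    fs: float

    def __post_init__(self):
        if not (self.window[0] <= 0.0 <= self.window[1]):
            raise ValueError("window must contain 0")
        if self.snippets.ndim != 2:
            raise ValueError("snippets must be 2-D (events x samples)")

    @property
    def lags(self) -> np.ndarray:
        n = self.snippets.shape[1]
        return self.window[0] + np.arange(n) / self.fs

    def mean(self) -> np.ndarray:
        return self.snippets.mean(axis=0)


def compute_dff(signal_raw, control_raw) -> np.ndarray:
    """Fractional fluorescence from a signal/control channel pair.

    The control is affinely rescaled onto the signal by least squares
    (control_fit = a·control + c) and dff = (signal − control_fit)/control_fit.
    Invariant to multiplying both channels by a positive constant.
    """
    s = np.asarray(signal_raw, dtype=float)
    c = np.asarray(control_raw, dtype=float)
    if s.shape != c.shape or s.ndim != 1:
        raise ValueError("channels must be equal-length 1-D arrays")
    if np.ptp(c) == 0:
        raise ValueError("degenerate control channel (zero variance)")
    A = np.column_stack([c, np.ones_like(c)])
    coef, *_ = np.linalg.lstsq(A, s, rcond=None)
    fit = A @ coef
    if np.any(fit == 0):
        raise ValueError("control fit crosses zero; dF/F undefined")
    return (s - fit) / fit


def _sample_index(t: float, t0: float, fs: float) -> int:
    return int(np.round((t - t0) * fs))


def peak_in_window(dff, fs: float, t0: float, event_time: float,
                   window: float = 1.0, mode: str = "max") -> float:
    """Extremum of dff on the half-open window (event, event + window].

    ``mode`` is 'max', 'min', or 'absmax' (larger absolute value, ties to
    the maximum).
    """
    i0 = _sample_index(event_time, t0, fs)
    i1 = i0 + int(np.round(window * fs))
    if i0 + 1 < 0 or i1 + 1 > len(dff):
        raise ValueError("window extends outside the trace")
    seg = np.asarray(dff)[i0 + 1: i1 + 1]
    if len(seg) == 0:
        raise ValueError("empty response window")
    if mode == "max":
        return float(np.max(seg))
    if mode == "min":
        return float(np.min(seg))
    if mode == "absmax":
        hi, lo = float(np.max(seg)), float(np.min(seg))
        return hi if abs(hi) >= abs(lo) else lo
    raise ValueError(f"unknown mode {mode!r}")


def align_to_events(dff, fs: float, t0: float, event_times,
                    window=(-1.0, 2.0)) -> AlignedResponse:
    """Cut equal-length snippets of dff around each event time."""
    dff = np.asarray(dff)
    pre, post = window
    n_pre = int(np.round(-pre * fs))
    n_post = int(np.round(post * fs))
    rows = []
    for t in np.atleast_1d(event_times):
        i = _sample_index(t, t0, fs)
        if i - n_pre < 0 or i + n_post + 1 > len(dff):
            raise ValueError(f"event at t={t} outside trace for window")
        rows.append(dff[i - n_pre: i + n_post + 1])
    return AlignedResponse(window=(pre, post), snippets=np.array(rows), fs=fs)


def uncued_click_times(stream: EventStream) -> np.ndarray:
    m = (stream.labels == "reward_click") & np.isnan(stream.cue_ids)
    return stream.times[m]


def normalize_to_uncued(dff, stream: EventStream, fs: float, t0: float,
                        window: float = 1.0) -> np.ndarray:
    """Divide dff by the mean peak response to unpredictable reward.

    The divisor is the mean over uncued reward clicks of the maximum dff in
    the 1 s following each click.
    """
    clicks = uncued_click_times(stream)
    if len(clicks) == 0:
        raise ValueError("stream contains no uncued reward clicks")
    peaks = [peak_in_window(dff, fs, t0, t, window, mode="max")
             for t in clicks]
    divisor = float(np.mean(peaks))
    if divisor <= 0:
        raise ValueError(f"nonpositive normalization divisor ({divisor})")
    return np.asarray(dff) / divisor


def cue_response(dff, fs: float, t0: float, onset: float,
                 window: float = 0.5) -> float:
    """Cue-evoked response amplitude.

    The maximum or minimum of dff within ``window`` seconds after cue onset,
    whichever has the larger absolute value; ties go to the maximum.
    """
    return peak_in_window(dff, fs, t0, onset, window, mode="absmax")


def autocorr(x, max_lag: int) -> np.ndarray:
    """Biased autocorrelation of the mean-subtracted series, acf[0] = 1."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1] / n
    if acov[0] <= 0 or not np.all(np.isfinite(acov)):
        raise ValueError("degenerate series: non-finite or zero-variance ACF")
    return acov / acov[0]


def autocorr_decay(dff, fs: float, fit_range=(0.04, 0.2)):
    """Exponential decay constant of the autocorrelation function.

    Fits a·e^(−lag/τ) to the ACF over the given lag range (default
    40-200 ms) by least squares. Returns a dict with tau, amplitude a,
    r_squared of the fit over the range, and a poor_fit flag (r² < 0.8).
    """
    lo, hi = fit_range
    if hi <= lo or lo < 0:
        raise ValueError("invalid fit_range")
    n_hi = int(np.round(hi * fs))
    if len(dff) < 10 * n_hi:
        raise ValueError("trace too short for the requested fit range")
    acf = autocorr(dff, n_hi)
    lags = np.arange(n_hi + 1) / fs
    m = (lags >= lo) & (lags <= hi)
    y = acf[m]
    t = lags[m]

    def model(t, a, tau):
        return a * np.exp(-t / tau)

    # log-linear start where possible
    tau0 = 0.1
    if np.all(y > 0):
        slope = np.polyfit(t, np.log(y), 1)[0]
        if slope < 0:
            tau0 = min(max(-1.0 / slope, 1e-3), 10.0)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[max(y[0], 1e-3), tau0],
            bounds=([0.0, 1e-4], [10.0, 100.0]), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise ValueError(f"autocorrelation decay fit failed: {exc}") from exc
    resid = y - model(t, *popt)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return {
        "tau": float(popt[1]),
        "a": float(popt[0]),
        "r_squared": float(r2),
        "poor_fit": bool(r2 < 0.8),
    }


def half_width(mean_response, fs: float) -> float:
    """Duration at half maximum of a response, seconds.

    Width of the interval around the (positive) peak where the response stays
    at or above half its maximum, with linear interpolation at the crossings.
    If the response never falls below half maximum on a side, the width is
    censored at the trace edge.
    """
    y = np.asarray(mean_response, dtype=float)
    if len(y) < 2:
        raise ValueError("response too short")
    peak = np.max(y)
    if peak <= 0:
        raise ValueError("nonpositive peak; half-width undefined")
    half = peak / 2.0
    i_pk = int(np.argmax(y))

    # walk left
    i = i_pk
    while i > 0 and y[i - 1] >= half:
        i -= 1
    if i == 0:
        left = 0.0
    else:
        frac = (y[i] - half) / (y[i] - y[i - 1])  # in (0, 1]
        left = i - frac
    # walk right
    j = i_pk
    n = len(y)
    while j < n - 1 and y[j + 1] >= half:
        j += 1
    if j == n - 1:
        right = float(n - 1)
    else:
        frac = (y[j] - half) / (y[j] - y[j + 1])
        right = j + frac
    return float((right - left) / fs)
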