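"""Temporal-discounting curve fits to cue responses in the delay task.

Peak dopamine responses to cues predicting reward at different delays t are
fit with either an exponential, f = b + A·e^(−t/τ), or a hyperbolic,
f = b + A/(1 + t/τ), discounting curve. The design has only four delays
(0, 0.6, 3.0 and ~11.9 s — zero delay being the uncued reward itself), so a
three-parameter fit is near-saturated: residual sum of squares and an
identifiability flag are always reported.

Two stated variants are available: fixing the baseline b to zero, and scaling
cue amplitudes by the cued reward probability before fitting (the default
ignores the shared 75% probability, since a common factor only rescales A).
Optimization is multi-start nonlinear least squares with τ initialized
log-uniform on [0.1, 100] s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "DiscountFitResult",
    "fit_discount",
    "discount_value",
    "DiscountCurveFit",
]

TAU_BOUNDS = (0.05, 1000.0)


@dataclass(frozen=True)
class DiscountFitResult:
    kind: str
    b: float
    A: float
    tau: float
    rss: float
    n: int
    non_identifiable: bool = False

    def __post_init__(self):
        if self.kind not in ("exponential", "hyperbolic"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _curve(kind: str, t, b, A, tau):
    t = np.asarray(t, dtype=float)
    if kind == "exponential":
        return b + A * np.exp(-t / tau)
    if kind == "hyperbolic":
        return b + A / (1.0 + t / tau)
    raise ValueError(f"unknown kind {kind!r}")


def discount_value(t, params: DiscountFitResult):
    """Evaluate a fitted discount curve at delay(s) t >= 0."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("delays must be nonnegative")
    return _curve(params.kind, t, params.b, params.A, params.tau)


def fit_discount(delays, amplitudes, kind: str = "exponential",
                 fix_b: bool = False, reward_probs=None,
                 n_starts: int = 20, seed: int = 0) -> DiscountFitResult:
    """Fit a discounting curve to cue response amplitude vs delay.

    Parameters
    ----------
    delays, amplitudes : array-like
        Cue-to-reward delays (s) and the matching normalized peak responses.
    kind : 'exponential' or 'hyperbolic'
    fix_b : bool
        Omit the baseline term (b = 0).
    reward_probs : array-like or None
        Per-point reward probabilities; when given, amplitudes are divided by
        them before fitting (the probability-adjusted variant).
    n_starts : int
        Multi-start count; τ starts log-uniform on [0.1, 100] s.

    Notes
    -----
    τ is constrained to [0.05, 1000] s; a best fit with τ at either bound is
    flagged ``non_identifiable``, as is a degenerate amplitude (|A| ~ 0),
    since τ is then unconstrained by the data.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("delays and amplitudes must be equal-length 1-D")
    if np.any(t < 0):
        raise ValueError("delays must be nonnegative")
    if reward_probs is not None:
        pr = np.asarray(reward_probs, dtype=float)
        if np.any(pr <= 0):
            raise ValueError("reward probabilities must be positive")
        y = y / pr
    n_par = 2 if fix_b else 3
    if len(np.unique(t)) < n_par:
        raise ValueError(
            f"need at least {n_par} distinct delays for {n_par} parameters"
        )
    rng = np.random.default_rng(seed)
    lo_t, hi_t = TAU_BOUNDS

    def resid(theta):
        if fix_b:
            A, ltau = theta
            b = 0.0
        else:
            b, A, ltau = theta
        return _curve(kind, t, b, A, np.exp(ltau)) - y

    best = None
    tau_starts = np.exp(rng.uniform(np.log(0.1), np.log(100.0), n_starts))
    span = y.max() - y.min()
    for tau0 in tau_starts:
        A0 = span if span > 0 else 1.0
        b0 = y.min()
        x0 = [A0, np.log(tau0)] if fix_b else [b0, A0, np.log(tau0)]
        lb = ([-np.inf, np.log(lo_t)] if fix_b
              else [-np.inf, -np.inf, np.log(lo_t)])
        ub = ([np.inf, np.log(hi_t)] if fix_b
              else [np.inf, np.inf, np.log(hi_t)])
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            ftol=1e-15, xtol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    if fix_b:
        b, (A, ltau) = 0.0, best.x
    else:
        b, A, ltau = best.x
    tau = float(np.exp(ltau))
    rss = float(2.0 * best.cost)
    at_bound = (tau <= lo_t * (1 + 1e-6)) or (tau >= hi_t * (1 - 1e-6))
    degenerate = abs(A) < 1e-8 * max(1.0, np.abs(y).max())
    return DiscountFitResult(
        kind=kind, b=float(b), A=float(A), tau=tau, rss=rss, n=len(t),
        non_identifiable=bool(at_bound or degenerate),
    )


class DiscountCurveFit(BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_discount`.

    fit(X, y) takes delays X (s) and amplitudes y; fitted attributes are
    ``b_``, ``A_``, ``tau_``, ``rss_``, ``non_identifiable_``, ``result_``.
    """

    def __init__(self, kind="exponential", fix_b=False, n_starts=20, seed=0):
        self.kind = kind
        self.fix_b = fix_b
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X, y, reward_probs=None):
        res = fit_discount(np.ravel(X), y, kind=self.kind, fix_b=self.fix_b,
                           reward_probs=reward_probs,
                           n_starts=self.n_starts, seed=self.seed)
        self.result_ = res
        self.b_ = res.b
        self.A_ = res.A
        self.tau_ = res.tau
        self.rss_ = res.rss
        self.non_identifiable_ = res.non_identifiable
        return self

    def predict(self, X):
        return discount_value(np.ravel(X), self.result_)
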