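"""Trial-level reward-history models and timescale grid scans.

Two single-parameter models of reward expectation are fit to per-trial
dopamine reward responses:

* a time-based **leaky integrator**: the reward-rate estimate jumps by 1 at
  every reward and decays exponentially, dV/dt = −V/τ + Σ δ(t − t_reward).
  (A published form of this model prints the decay term as "−τ", which is
  dimensionally inconsistent with an exponential decay of time constant τ;
  the verbal description is implemented.)
* a trial-based **delta rule**: V ← V + α(r − V) once per trial, with binary
  outcomes r ∈ {0, 1}; small α integrates a longer history.

The timescale (τ or α) is chosen on a grid to maximize the *negative*
correlation between the model's expectation immediately before each reward
click and the dopamine peak response to that click — the signature of
positive reward-prediction-error coding. Fit significance is assessed by a
seeded permutation test of the trial order, since a grid-maximized
correlation has no closed-form null.

``LeakyIntegratorScan`` and ``DeltaRuleScan`` wrap the scans as scikit-learn
style estimators (fit / fitted attributes with trailing underscores);
``scan_tau`` / ``scan_alpha`` are functional shortcuts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .signal_ops import AlignedResponse

__all__ = [
    "FitResult",
    "leaky_rate",
    "delta_rule_values",
    "default_tau_grid",
    "default_alpha_grid",
    "scan_tau",
    "scan_alpha",
    "LeakyIntegratorScan",
    "DeltaRuleScan",
    "tercile_labels",
    "rpe_coding_fraction",
]


@dataclass(frozen=True)
class FitResult:
    """Grid scan outcome: objective curve and the extremal grid point."""

    param_grid: np.ndarray
    objective: np.ndarray  # signed correlation per grid point
    best_param: float
    best_objective: float
    p_value: float = np.nan  # permutation p for the best correlation

    def __post_init__(self):
        if len(self.param_grid) != len(self.objective):
            raise ValueError("grid and objective lengths differ")


def leaky_rate(reward_times, tau: float, eval_times) -> np.ndarray:
    """Leaky-integrated reward rate at given times (left limit).

    V(t) = Σ_{r < t} e^{−(t − r)/τ}: each past reward contributes a unit
    impulse decayed by the elapsed time; a reward exactly at an evaluation
    time is excluded (the value "immediately before" the event).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    r = np.asarray(reward_times, dtype=float)
    t = np.asarray(eval_times, dtype=float)
    if np.any(np.diff(r) < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    out = np.empty(len(t))
    v = 0.0
    last = -np.inf
    j = 0
    for i, ti in enumerate(t):
        while j < len(r) and r[j] < ti:
            if np.isfinite(last):
                v *= np.exp(-(r[j] - last) / tau)
            v += 1.0
            last = r[j]
            j += 1
        out[i] = v * np.exp(-(ti - last) / tau) if np.isfinite(last) else 0.0
    return out


def delta_rule_values(outcomes, alpha: float, v0: float = 0.0) -> np.ndarray:
    """Pre-outcome value on each trial under the delta rule.

    V(t) = V(t−1) + α (r_{t−1} − V(t−1)); the returned V[t] is the value held
    *before* trial t's outcome, so V[0] = v0. Equivalent to the closed-form
    exponential average V_t = (1−α)^t v0 + α Σ_k (1−α)^k r_{t−1−k}.
    """
    r = np.asarray(outcomes)
    if not np.all(np.isin(r, (0, 1))):
        raise ValueError("outcomes must be binary {0, 1}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    v = np.empty(len(r))
    cur = float(v0)
    for i in range(len(r)):
        v[i] = cur
        cur = cur + alpha * (r[i] - cur)
    return v


def default_tau_grid(n: int = 50, lo: float = 1.0, hi: float = 2500.0):
    """Log-spaced τ grid over the scanned range [1, 2500] s."""
    return np.geomspace(lo, hi, n)


def default_alpha_grid(step: float = 0.01):
    """α grid 0.01..1 in the scanned step (α=0 gives a constant regressor)."""
    return np.round(np.arange(step, 1.0 + step / 2, step), 10)


def _pearson(x, y) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _scan(regressors: np.ndarray, responses: np.ndarray, grid: np.ndarray,
          n_perm: int, seed: int, method: str) -> FitResult:
    """Shared scan core: regressors is (n_grid, n_trials)."""
    if method == "pearson":
        corr = _pearson
    elif method == "spearman":
        def corr(x, y):
            if np.std(x) == 0 or np.std(y) == 0:
                return np.nan
            return float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    obj = np.array([corr(reg, responses) for reg in regressors])
    if np.all(np.isnan(obj)):
        raise ValueError("all grid points give degenerate correlations "
                         "(zero-variance regressor or responses)")
    best_i = int(np.nanargmin(obj))  # most negative; ties -> smaller param
    best = obj[best_i]
    p_value = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(responses))
            null = np.nanmin(
                [corr(reg, responses[perm]) for reg in regressors]
            )
            if null <= best:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return FitResult(
        param_grid=np.asarray(grid, dtype=float),
        objective=obj,
        best_param=float(grid[best_i]),
        best_objective=float(best),
        p_value=float(p_value),
    )


def scan_tau(da_click_responses, reward_times, response_times, tau_grid=None,
             n_perm: int = 0, seed: int = 0,
             method: str = "pearson") -> FitResult:
    """Choose the leaky-integrator τ maximizing negative DA-rate correlation.

    For each τ on the grid, correlates the leaky reward rate evaluated at the
    click times (left limit) with the per-click DA peak response; returns the
    τ minimizing the signed correlation (ties to the smaller τ). Responses
    with zero variance raise. ``n_perm > 0`` adds a permutation p-value for
    the scan-minimized correlation.
    """
    y = np.asarray(da_click_responses, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant DA responses (zero variance)")
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.sort(np.asarray(tau_grid, dtype=float))
    regressors = np.array(
        [leaky_rate(reward_times, tau, response_times) for tau in tau_grid]
    )
    return _scan(regressors, y, tau_grid, n_perm, seed, method)


def scan_alpha(da_click_responses, outcomes, alpha_grid=None,
               n_perm: int = 0, seed: int = 0, method: str = "pearson",
               response_trials=None, v0: float = 0.0) -> FitResult:
    """Choose the delta-rule α maximizing negative DA-value correlation.

    ``outcomes`` is the full binary trial sequence; ``response_trials``
    optionally gives the trial indices the responses belong to (default: the
    rewarded trials, in order, matching click-aligned responses).
    """
    y = np.asarray(da_click_responses, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant DA responses (zero variance)")
    outcomes = np.asarray(outcomes)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.sort(np.asarray(alpha_grid, dtype=float))
    if response_trials is None:
        response_trials = np.flatnonzero(outcomes == 1)
    response_trials = np.asarray(response_trials, dtype=int)
    if len(response_trials) != len(y):
        raise ValueError("responses and response_trials length mismatch")
    regressors = np.array(
        [delta_rule_values(outcomes, a, v0)[response_trials]
         for a in alpha_grid]
    )
    return _scan(regressors, y, alpha_grid, n_perm, seed, method)


class LeakyIntegratorScan(BaseEstimator):
    """Grid-scan estimator for the leaky-integrator timescale τ.

    Parameters
    ----------
    tau_grid : array-like or None
        Candidate τ values (s); default 50 log-spaced points on [1, 2500].
    n_perm : int
        Permutation draws for the significance of the best correlation.
    method : str
        'pearson' (default) or 'spearman'.

    Attributes (after fit)
    ----------------------
    best_tau_, best_objective_, objective_curve_, tau_grid_, p_value_
    """

    def __init__(self, tau_grid=None, n_perm=0, seed=0, method="pearson"):
        self.tau_grid = tau_grid
        self.n_perm = n_perm
        self.seed = seed
        self.method = method

    def fit(self, X, y):
        """X: (reward_times, response_times) tuple; y: per-click responses."""
        reward_times, response_times = X
        res = scan_tau(y, reward_times, response_times, self.tau_grid,
                       self.n_perm, self.seed, self.method)
        self.result_ = res
        self.tau_grid_ = res.param_grid
        self.objective_curve_ = res.objective
        self.best_tau_ = res.best_param
        self.best_objective_ = res.best_objective
        self.p_value_ = res.p_value
        return self

    def predict(self, eval_times):
        """Leaky reward rate at the fitted τ (requires fit's reward_times
        to be passed again via a (reward_times, eval_times) tuple)."""
        reward_times, t = eval_times
        return leaky_rate(reward_times, self.best_tau_, t)


class DeltaRuleScan(BaseEstimator):
    """Grid-scan estimator for the delta-rule learning rate α."""

    def __init__(self, alpha_grid=None, n_perm=0, seed=0, method="pearson",
                 v0=0.0):
        self.alpha_grid = alpha_grid
        self.n_perm = n_perm
        self.seed = seed
        self.method = method
        self.v0 = v0

    def fit(self, X, y):
        """X: binary outcome sequence (or (outcomes, response_trials));
        y: per-response DA amplitudes."""
        if isinstance(X, tuple):
            outcomes, response_trials = X
        else:
            outcomes, response_trials = X, None
        res = scan_alpha(y, outcomes, self.alpha_grid, self.n_perm,
                         self.seed, self.method, response_trials, self.v0)
        self.result_ = res
        self.alpha_grid_ = res.param_grid
        self.objective_curve_ = res.objective
        self.best_alpha_ = res.best_param
        self.best_objective_ = res.best_objective
        self.p_value_ = res.p_value
        return self


def tercile_labels(values) -> np.ndarray:
    """Empirical tercile split into 'low' / 'mid' / 'high'.

    Boundaries are the 1/3 and 2/3 empirical quantiles; values tied with a
    boundary are assigned to the lower tercile. All-equal input is degenerate
    and raises.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 values for terciles")
    if np.ptp(v) == 0:
        raise ValueError("all values equal; no tercile split possible")
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(v <= q1, "low", np.where(v <= q2, "mid", "high"))
    return labels


def rpe_coding_fraction(sessions, p_thresh: float = 0.01):
    """Fraction of sessions with significant rate dependence, per time bin.

    ``sessions`` is a list of (AlignedResponse, rate_values) pairs, one rate
    value per snippet. For each session and time bin, dff is regressed on the
    reward rate by OLS; a bin counts as significant when the slope's two-sided
    p-value is below ``p_thresh``. Returns a dict with the per-bin fraction,
    the per-bin mean slope sign, and the lag axis.
    """
    if isinstance(sessions, tuple):
        sessions = [sessions]
    if len(sessions) == 0:
        raise ValueError("no sessions")
    n_bins = sessions[0][0].snippets.shape[1]
    sig = np.zeros(n_bins)
    slope_sum = np.zeros(n_bins)
    for aligned, rates in sessions:
        Y = aligned.snippets  # (n_events, n_bins)
        x = np.asarray(rates, dtype=float)
        if Y.shape[0] != len(x):
            raise ValueError("one rate value per snippet required")
        n = len(x)
        if n < 3:
            raise ValueError("need at least 3 snippets per session")
        if Y.shape[1] != n_bins:
            raise ValueError("sessions have inconsistent window lengths")
        xc = x - x.mean()
        sxx = np.sum(xc ** 2)
        if sxx == 0:
            raise ValueError("zero-variance rate regressor")
        Yc = Y - Y.mean(axis=0)
        slope = (xc @ Yc) / sxx
        resid = Yc - np.outer(xc, slope)
        dof = n - 2
        s2 = np.sum(resid ** 2, axis=0) / dof
        se = np.sqrt(s2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, slope / se, np.inf * np.sign(slope))
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        sig += (p < p_thresh).astype(float)
        slope_sum += np.sign(slope)
    n_sessions = len(sessions)
    lags = sessions[0][0].lags
    return {
        "fraction": sig / n_sessions,
        "mean_slope_sign": slope_sum / n_sessions,
        "lags": lags,
        "n_sessions": n_sessions,
    }
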