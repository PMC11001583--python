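"""Three-subnetwork recurrent actor-critic with distinct discount factors.

The agent models value computation in three striatal subregions as three
pools of LSTM units ("DLS", "DMS", "VS"; 32 units each) that receive the same
sensory inputs but have no connections between pools. Each pool has its own
linear value head with its own discount factor, γ_i = e^(−dt/τ_i) with
τ = (2, 10, 1000) s at dt = 50 ms, so "DLS" looks a couple of seconds ahead
while "VS" integrates across many trials. All pools feed a shared softmax
policy over two actions, poke / no-poke.

Training minimizes a PPO objective: a clipped policy-ratio term whose
advantage is the *sum* of per-pool generalized advantage estimates, a value
loss summing squared errors of the three pools against discounted returns
bootstrapped at the sequence end, and an entropy bonus. Sequences are
T = 10,000 steps (~20 trials); hidden state carries across consecutive
sequences (detached), and weights update with Adam.

Everything is plain numpy: the LSTM forward/backward passes are written out
analytically and checked against numerical gradients in the test suite. The
per-pool prediction error reported for comparison with dopamine is
RPE_i(t) = r_t + γ_i·V_i(t) − V_i(t−1).

Environment contract: a reward click is delivered on the task's schedule
regardless of behavior; the unit reward is collected by the first poke at or
after an uncollected click. Poking costs −0.003, reduced to 10% of that for
pokes continuing a consecutive run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .task_sim import EventStream

__all__ = [
    "AgentConfig",
    "EnvState",
    "Agent",
    "gamma_from_tau",
    "encode_inputs",
    "click_schedule",
    "env_step",
    "compute_gae",
    "ppo_policy_loss",
    "value_targets",
    "train_agent",
    "extract_rpe",
    "cue_rpe_summary",
]

POKE, NO_POKE = 1, 0
SUBNET_NAMES = ("DLS", "DMS", "VS")


def gamma_from_tau(tau: float, dt: float) -> float:
    """Discount per step for a continuous time constant: γ = e^(−dt/τ)."""
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    return float(np.exp(-dt / tau))


@dataclass(frozen=True)
class AgentConfig:
    tau_list: tuple = (2.0, 10.0, 1000.0)
    dt: float = 0.05
    units_per_subnet: int = 32
    T: int = 10_000
    beta_v: float = 0.8
    beta_e: float = 0.001
    lam_gae: float = 0.98
    eps_clip: float = 0.2
    learning_rate: float = 0.0005
    poke_cost: float = -0.003
    repeat_cost_fraction: float = 0.1
    click_input_value: float = 5.0
    n_background: int = 3
    n_cues: int = 3
    n_shared_cue_dims: int = 17
    ppo_epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if any(tau <= 0 for tau in self.tau_list):
            raise ValueError("time constants must be positive")
        if self.T < 2:
            raise ValueError("sequence length too short")

    @property
    def n_subnets(self) -> int:
        return len(self.tau_list)

    @property
    def gammas(self) -> np.ndarray:
        return np.array([gamma_from_tau(t, self.dt) for t in self.tau_list])

    @property
    def input_dim(self) -> int:
        # click + (one-hot + shared) cue dims + background
        return 1 + self.n_cues + self.n_shared_cue_dims + self.n_background


def encode_inputs(stream: EventStream, config: AgentConfig,
                  t0: float | None = None, n_steps: int | None = None):
    """Per-step input vectors for an event stream on the dt grid.

    Layout: [click (0 or 5, one step per click) | 3 one-hot cue dims |
    17 shared cue dims (1 during any cue presentation) | 3 background dims
    (constantly 1)]. Returns (X, t0) with X of shape (n_steps, input_dim).
    """
    dt = config.dt
    if t0 is None:
        t0 = float(stream.times[0]) - 1.0
    if n_steps is None:
        n_steps = int(np.ceil((stream.times[-1] - t0) / dt)) + 20
    X = np.zeros((n_steps, config.input_dim))
    X[:, -config.n_background:] = 1.0
    step_of = lambda t: int(np.floor((t - t0) / dt))
    # clicks: one step each
    for t in stream.select("reward_click"):
        s = step_of(t)
        if 0 <= s < n_steps:
            X[s, 0] = config.click_input_value
    # cues: active for the full presentation
    onsets = stream.events_of("cue_onset")
    offsets = stream.events_of("cue_offset")
    shared = slice(1 + config.n_cues, 1 + config.n_cues
                   + config.n_shared_cue_dims)
    for _, row in onsets.iterrows():
        t_on, cid = row["time"], row["cue_id"]
        later = offsets[(offsets["time"] > t_on)
                        & (offsets["cue_id"] == cid)]
        if len(later) == 0:
            raise ValueError(f"cue_onset at {t_on} has no matching offset")
        t_off = float(later["time"].iloc[0])
        s0, s1 = max(step_of(t_on), 0), min(step_of(t_off), n_steps)
        if s0 >= n_steps or s1 <= 0:
            continue
        seg = X[s0:s1]
        if np.any(seg[:, 1: 1 + config.n_cues] != 0):
            raise ValueError("overlapping cue presentations")
        seg[:, 1 + int(cid)] = 1.0
        seg[:, shared] = 1.0
    return X, t0


def click_schedule(stream: EventStream, config: AgentConfig, t0: float,
                   n_steps: int) -> np.ndarray:
    """Boolean per-step array: a reward click lands at this step."""
    out = np.zeros(n_steps, dtype=bool)
    for t in stream.select("reward_click"):
        s = int(np.floor((t - t0) / config.dt))
        if 0 <= s < n_steps:
            out[s] = True
    return out


@dataclass
class EnvState:
    pending_reward: bool = False
    prev_action: int = NO_POKE


def env_step(state: EnvState, action: int, click_now: bool = False,
             poke_cost: float = -0.003,
             repeat_cost_fraction: float = 0.1):
    """One environment transition; returns (reward, new state).

    A click arriving now makes a unit reward pending; the first poke at or
    after the click collects it (once). Poking costs ``poke_cost``, reduced
    to ``repeat_cost_fraction`` of that when continuing a consecutive run of
    pokes.
    """
    pending = state.pending_reward or click_now
    reward = 0.0
    if action == POKE:
        reward += poke_cost * (repeat_cost_fraction
                               if state.prev_action == POKE else 1.0)
        if pending:
            reward += 1.0
            pending = False
    return reward, EnvState(pending_reward=pending, prev_action=action)


def compute_gae(delta_series, gamma: float, lam: float) -> np.ndarray:
    """Generalized advantage: A_t = δ_t + (γλ)δ_{t+1} + … + (γλ)^{T−t}δ_T."""
    d = np.asarray(delta_series, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta series")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite deltas")
    A = np.empty_like(d)
    acc = 0.0
    gl = gamma * lam
    for t in range(len(d) - 1, -1, -1):
        acc = d[t] + gl * acc
        A[t] = acc
    return A


def value_targets(reward_series, bootstrap_value: float,
                  gamma: float) -> np.ndarray:
    """Discounted returns with a terminal bootstrap.

    target_t = r_{t+1} + γ r_{t+2} + … + γ^{T−1−t} r_T + γ^{T−t} V_boot,
    with ``reward_series[t]`` holding the reward for the action at step t.
    """
    r = np.asarray(reward_series, dtype=float)
    if r.size == 0:
        raise ValueError("empty reward series")
    out = np.empty_like(r)
    acc = float(bootstrap_value)
    for t in range(len(r) - 1, -1, -1):
        acc = r[t] + gamma * acc
        out[t] = acc
    return out


def ppo_policy_loss(rho_series, advantage_series,
                    eps_clip: float = 0.2) -> float:
    """Mean clipped surrogate objective (to be maximized).

    mean_t min(ρ_t A_t, clip(ρ_t, 1−ε, 1+ε) A_t). Training minimizes the
    negative of this quantity.
    """
    rho = np.asarray(rho_series, dtype=float)
    A = np.asarray(advantage_series, dtype=float)
    if not np.all(np.isfinite(rho)) or np.any(rho <= 0):
        raise ValueError("probability ratios must be finite and positive")
    clipped = np.clip(rho, 1.0 - eps_clip, 1.0 + eps_clip)
    return float(np.mean(np.minimum(rho * A, clipped * A)))


# ---------------------------------------------------------------------------
# network


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class Agent:
    """Numpy LSTM actor-critic; parameters in a flat dict.

    Per pool p: Wx[p] (4H, D), Wh[p] (4H, H), b[p] (4H) with gate order
    (input, forget, cell, output) and forget bias initialized to 1;
    vw[p] (H), vb[p] — the value head. Shared policy head: Pw (2, n_pools·H),
    Pb (2).
    """

    def __init__(self, config: AgentConfig, rng=None):
        self.config = config
        rng = np.random.default_rng(config.seed) if rng is None else rng
        H, D, P = config.units_per_subnet, config.input_dim, config.n_subnets
        s_x, s_h = 1.0 / np.sqrt(D), 1.0 / np.sqrt(H)
        self.params = {
            "Wx": rng.standard_normal((P, 4 * H, D)) * s_x,
            "Wh": rng.standard_normal((P, 4 * H, H)) * s_h,
            "b": np.zeros((P, 4 * H)),
            "vw": rng.standard_normal((P, H)) * s_h,
            "vb": np.zeros(P),
            "Pw": rng.standard_normal((2, P * H)) * (1.0 / np.sqrt(P * H)),
            "Pb": np.zeros(2),
        }
        self.params["b"][:, H: 2 * H] = 1.0  # forget-gate bias
        self.h = np.zeros((P, H))
        self.c = np.zeros((P, H))
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def step(self, x, h, c):
        """One LSTM step for all pools. Returns (h, c, cache)."""
        p = self.params
        H = self.config.units_per_subnet
        z = (p["Wx"] @ x) + np.matmul(p["Wh"], h[:, :, None])[:, :, 0] + p["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H: 2 * H])
        g = np.tanh(z[:, 2 * H: 3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        return h_new, c_new, (x, h, c, i, f, g, o, c_new, tanh_c)

    def heads(self, h):
        """Values (one per pool) and policy logits from pooled hidden state."""
        p = self.params
        values = np.sum(p["vw"] * h, axis=1) + p["vb"]
        logits = p["Pw"] @ h.reshape(-1) + p["Pb"]
        return values, logits

    def policy(self, logits):
        z = logits - logits.max()
        e = np.exp(z)
        return e / e.sum()

    def forward_sequence(self, X, actions=None, rng=None, h0=None, c0=None):
        """Run T steps; sample actions unless given (teacher forcing).

        Returns dict with per-step hidden caches, values (T, P), probs (T, 2),
        actions (T,), log-probs of taken actions, final (h, c).
        """
        T = len(X)
        P = self.config.n_subnets
        h = self.h.copy() if h0 is None else h0.copy()
        c = self.c.copy() if c0 is None else c0.copy()
        caches = []
        values = np.empty((T, P))
        probs = np.empty((T, 2))
        acts = np.empty(T, dtype=int)
        for t in range(T):
            h, c, cache = self.step(X[t], h, c)
            v, logits = self.heads(h)
            pi = self.policy(logits)
            if actions is None:
                a = int(rng.random() < pi[POKE])
            else:
                a = int(actions[t])
            caches.append(cache)
            values[t] = v
            probs[t] = pi
            acts[t] = a
        return {
            "caches": caches, "values": values, "probs": probs,
            "actions": acts, "h": h, "c": c,
        }

    # -- backward ----------------------------------------------------------

    def backward_sequence(self, X, fwd, dvalues, dlogits):
        """Analytic BPTT. dvalues (T, P) and dlogits (T, 2) are the loss
        gradients at the value and policy outputs; returns parameter grads."""
        p = self.params
        cfg = self.config
        H, P = cfg.units_per_subnet, cfg.n_subnets
        T = len(X)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh_next = np.zeros((P, H))
        dc_next = np.zeros((P, H))
        WhT = p["Wh"].transpose(0, 2, 1)
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new, tanh_c = fwd["caches"][t]
            h_t = o * tanh_c
            # head gradients into dh
            dh = dh_next.copy()
            dh += dvalues[t][:, None] * p["vw"]
            grads["vw"] += dvalues[t][:, None] * h_t
            grads["vb"] += dvalues[t]
            hcat = h_t.reshape(-1)
            grads["Pw"] += np.outer(dlogits[t], hcat)
            grads["Pb"] += dlogits[t]
            dh += (p["Pw"].T @ dlogits[t]).reshape(P, H)
            # LSTM cell backward
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1
            )
            grads["Wx"] += dz[:, :, None] * x[None, None, :]
            grads["Wh"] += dz[:, :, None] * h_prev[:, None, :]
            grads["b"] += dz
            dh_next = np.matmul(WhT, dz[:, :, None])[:, :, 0]
        return grads

    def adam_step(self, grads, lr=None, beta1=0.9, beta2=0.999, eps=1e-8):
        lr = self.config.learning_rate if lr is None else lr
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def _loss_and_output_grads(config, values, probs, actions, old_logp,
                           advantages, targets):
    """Per-step gradients at the network outputs for the PPO loss.

    Returns (loss components dict, dvalues (T, P), dlogits (T, 2)). The
    minimized loss is −L^P + β_V L^V − β_e L^e, each term averaged over the
    sequence.
    """
    T = len(actions)
    eps = config.eps_clip
    logp = np.log(probs[np.arange(T), actions])
    rho = np.exp(logp - old_logp)
    clipped = np.clip(rho, 1.0 - eps, 1.0 + eps)
    surr = np.minimum(rho * advantages, clipped * advantages)
    policy_term = surr.mean()
    verr = values - targets  # (T, P)
    value_term = np.sum(verr ** 2, axis=1).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        logpi = np.where(probs > 0, np.log(probs), 0.0)
    entropy = -(probs * logpi).sum(axis=1)
    loss = (-policy_term + config.beta_v * value_term
            - config.beta_e * entropy.mean())

    # gradients
    dvalues = config.beta_v * 2.0 * verr / T
    dlogits = np.zeros((T, 2))
    unclipped_active = ~(
        ((advantages > 0) & (rho > 1.0 + eps))
        | ((advantages < 0) & (rho < 1.0 - eps))
    )
    coef = np.where(unclipped_active, advantages * rho, 0.0) / T
    onehot = np.zeros((T, 2))
    onehot[np.arange(T), actions] = 1.0
    dlogits -= coef[:, None] * (onehot - probs)  # −∂L^P/∂z
    dlogits += (config.beta_e / T) * probs * (logpi + entropy[:, None])
    comps = {"loss": float(loss), "policy": float(policy_term),
             "value": float(value_term), "entropy": float(entropy.mean())}
    return comps, dvalues, dlogits


def train_agent(config: AgentConfig, stream: EventStream,
                n_updates: int, agent: Agent | None = None,
                log_rpe: bool = False, start_update: int = 0):
    """Train the agent on a Pavlovian event stream.

    The stream is laid out on the dt grid and consumed in consecutive
    ``T``-step sequences, one Adam update per sequence (``ppo_epochs`` passes
    each); hidden state carries across sequences. Raises if the stream is
    shorter than ``(start_update + n_updates) × T`` steps; ``start_update``
    lets a continued run consume the next chunk of the same stream.
    Returns (agent, log DataFrame).
    """
    X_all, t0 = encode_inputs(stream, config)
    n_steps = len(X_all)
    clicks = click_schedule(stream, config, t0, n_steps)
    if n_steps < (start_update + n_updates) * config.T:
        raise ValueError(
            f"stream provides {n_steps} steps < "
            f"{(start_update + n_updates) * config.T} needed"
        )
    if agent is None:
        agent = Agent(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1, start_update]))
    env = EnvState()
    gammas = config.gammas
    rows = []
    for u in range(start_update, start_update + n_updates):
        sl = slice(u * config.T, (u + 1) * config.T)
        X = X_all[sl]
        clk = clicks[sl]
        h0, c0 = agent.h.copy(), agent.c.copy()
        fwd = agent.forward_sequence(X, rng=rng, h0=h0, c0=c0)
        T = config.T
        rewards = np.empty(T)
        for t in range(T):
            rewards[t], env = env_step(
                env, fwd["actions"][t], click_now=bool(clk[t]),
                poke_cost=config.poke_cost,
                repeat_cost_fraction=config.repeat_cost_fraction,
            )
        # bootstrap values one step past the sequence
        if sl.stop < n_steps:
            h_b, c_b, _ = agent.step(X_all[sl.stop], fwd["h"], fwd["c"])
            v_boot, _ = agent.heads(h_b)
        else:
            v_boot = np.zeros(config.n_subnets)
        values = fwd["values"]
        v_next = np.vstack([values[1:], v_boot[None, :]])
        deltas = rewards[:, None] + gammas[None, :] * v_next - values
        adv = np.zeros(T)
        targets = np.empty((T, config.n_subnets))
        for pidx in range(config.n_subnets):
            adv += compute_gae(deltas[:, pidx], gammas[pidx], config.lam_gae)
            targets[:, pidx] = value_targets(rewards, v_boot[pidx],
                                             gammas[pidx])
        old_logp = np.log(fwd["probs"][np.arange(T), fwd["actions"]])
        comps = None
        for epoch in range(config.ppo_epochs):
            if epoch > 0:
                fwd_e = agent.forward_sequence(X, actions=fwd["actions"],
                                               h0=h0, c0=c0)
            else:
                fwd_e = fwd
            comps, dvalues, dlogits = _loss_and_output_grads(
                config, fwd_e["values"], fwd_e["probs"], fwd_e["actions"],
                old_logp, adv, targets,
            )
            grads = agent.backward_sequence(X, fwd_e, dvalues, dlogits)
            agent.adam_step(grads)
        # carry hidden state (detached) into the next sequence
        agent.h, agent.c = fwd["h"], fwd["c"]
        row = {
            "update": u,
            "loss": comps["loss"],
            "policy_term": comps["policy"],
            "value_loss": comps["value"],
            "entropy": comps["entropy"],
            "mean_p_poke": float(fwd["probs"][:, POKE].mean()),
            "total_reward": float(rewards.sum()),
            "n_clicks": int(clk.sum()),
        }
        if log_rpe:
            rpe = rewards[:, None] + gammas[None, :] * v_next - values
            for pidx, name in enumerate(SUBNET_NAMES):
                row[f"mean_abs_rpe_{name}"] = float(
                    np.abs(rpe[:, pidx]).mean())
        rows.append(row)
    return agent, pd.DataFrame(rows)


def extract_rpe(agent: Agent, stream: EventStream, seed: int = 0,
                greedy: bool = False, carry_state: bool = False):
    """Run the agent over a stream and report per-pool prediction errors.

    RPE_i(t) = r_t + γ_i V_i(t) − V_i(t−1), where r_t is the reward received
    *at* step t (the reward for the action taken at t−1). Returns a dict with
    the dt-grid times, rewards, values (T, P), rpe (T, P; first step NaN),
    actions and poke probabilities.
    """
    config = agent.config
    X, t0 = encode_inputs(stream, config)
    clicks = click_schedule(stream, config, t0, len(X))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    h = agent.h.copy() if carry_state else np.zeros_like(agent.h)
    c = agent.c.copy() if carry_state else np.zeros_like(agent.c)
    T = len(X)
    P = config.n_subnets
    values = np.empty((T, P))
    probs = np.empty((T, 2))
    actions = np.empty(T, dtype=int)
    rewards_after = np.empty(T)  # reward for the action at step t
    env = EnvState()
    for t in range(T):
        h, c, _ = agent.step(X[t], h, c)
        v, logits = agent.heads(h)
        pi = agent.policy(logits)
        if greedy:
            a = int(pi[POKE] >= 0.5)
        else:
            a = int(rng.random() < pi[POKE])
        rewards_after[t], env = env_step(
            env, a, click_now=bool(clicks[t]),
            poke_cost=config.poke_cost,
            repeat_cost_fraction=config.repeat_cost_fraction,
        )
        values[t] = v
        probs[t] = pi
        actions[t] = a
    r_at = np.concatenate([[0.0], rewards_after[:-1]])
    gammas = config.gammas
    rpe = np.full((T, P), np.nan)
    rpe[1:] = (r_at[1:, None] + gammas[None, :] * values[1:]
               - values[:-1])
    return {
        "t": t0 + np.arange(T) * config.dt,
        "t0": t0,
        "rewards_at": r_at,
        "values": values,
        "rpe": rpe,
        "actions": actions,
        "p_poke": probs[:, POKE],
        "clicks": clicks,
    }


def cue_rpe_summary(rpe_out, stream: EventStream, config: AgentConfig,
                    window: float = 0.5) -> pd.DataFrame:
    """Event-aligned RPE summary per pool.

    For each cue onset and each reward click, takes the per-pool RPE of
    largest absolute value within ``window`` seconds after the event
    (half-open, the event step included since the input arrives on it).
    Returns a tidy DataFrame: event kind, cue_id, pool, response.
    """
    t_grid = rpe_out["t"]
    dt = config.dt
    n = len(t_grid)
    w = int(np.round(window / dt))
    rows = []

    def peak(i0, pidx):
        seg = rpe_out["rpe"][i0: min(i0 + w + 1, n), pidx]
        seg = seg[np.isfinite(seg)]
        if len(seg) == 0:
            return np.nan
        hi, lo = seg.max(), seg.min()
        return hi if abs(hi) >= abs(lo) else lo

    onsets = stream.events_of("cue_onset")
    for _, r in onsets.iterrows():
        i0 = int(np.floor((r["time"] - rpe_out["t0"]) / dt))
        if not (0 <= i0 < n):
            continue
        for pidx, name in enumerate(SUBNET_NAMES):
            rows.append({"event": "cue_onset", "cue_id": int(r["cue_id"]),
                         "time": r["time"], "pool": name,
                         "response": peak(i0, pidx)})
    clicks = stream.events_of("reward_click")
    for _, r in clicks.iterrows():
        i0 = int(np.floor((r["time"] - rpe_out["t0"]) / dt))
        if not (0 <= i0 < n):
            continue
        cid = r["cue_id"]
        for pidx, name in enumerate(SUBNET_NAMES):
            rows.append({"event": "reward_click",
                         "cue_id": -1 if np.isnan(cid) else int(cid),
                         "time": r["time"], "pool": name,
                         "response": peak(i0, pidx)})
    return pd.DataFrame(rows)
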