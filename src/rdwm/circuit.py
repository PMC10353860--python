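"""Spiking winner-take-all circuit realizing the optimal memory channel.

Each stored item is coded by a subpopulation of ``N`` Poisson neurons
with cosine input tuning.  Neuron ``i`` of subpopulation ``m`` receives
excitatory drive

    u_im = -beta * pi_m * d(theta_m, phi_im) + w_im

(stimulus drive scaled by the shared gain ``beta`` and the probing
probability ``pi_m``, plus an intrinsic excitability ``w_im``), and
fires with divisively normalized rate ``r_i = exp(u_i) / sum_j
exp(u_j)``.  Whenever neuron ``i`` spikes, the momentary channel output
is its preferred stimulus ``phi_i``, so the population implements the
Blahut-Arimoto channel of :mod:`rdwm.channel` when ``w`` equals the log
marginal winner probability.  Two slow processes keep it there:

* intrinsic plasticity  ``dw_i = eta * (c * exp(-w_i) * z_i - 1)``
  drives ``exp(w_i)`` toward ``c * E[z_i]``, i.e. ``w`` toward the log
  marginal (the source of serial dependence and frequency biases);
* homeostatic gain adaptation  ``dbeta = alpha * (C_eff - R)`` holds the
  information rate at the effective capacity, where ``C_eff`` rescales
  the capacity by the duty cycle (RI + ITI) / RI.

Learning rates are pre-scaled by the simulation step ``dt`` so results
are insensitive to the step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channel import StimulusGrid, effective_capacity, wrap_angle

__all__ = [
    "CircuitParams",
    "CircuitState",
    "VARIANTS",
    "excitatory_input",
    "firing_rates",
    "sample_spikes",
    "update_excitability",
    "information_rate",
    "update_gain",
    "decode_ml",
    "run_trial",
    "run_session",
]

#: Model variants: the full model, a fixed-gain model (alpha = 0), and a
#: no-plasticity model (eta = 0, excitability frozen at its initial value).
VARIANTS = ("full", "fixed_gain", "no_plasticity")


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the circuit simulation.

    Defaults follow the standard simulation settings: N=100 neurons per
    subpopulation, omega=1, eta=1e-3, alpha=1e-1, dt=0.05 s, beta0=15,
    beta clipped to [0, 1000], w clipped to [-12, 0], decode window
    Td=0.1 s.  The capacity ``C`` (nats), population rate scale
    ``r_bar`` (spikes/s) and plasticity gain ``c`` are subject-level
    parameters; ``c`` defaults to 1/(r_bar*dt), the value at which the
    plasticity fixed point exp(w*) = c*E[z] equals the marginal winner
    probability.
    """

    N: int = 100
    omega: float = 1.0
    eta: float = 1e-3
    alpha: float = 1e-1
    C: float = 1.0
    r_bar: float = 50.0
    c: float | None = None
    dt: float = 5e-2
    beta0: float = 15.0
    beta_clip: tuple[float, float] = (0.0, 1000.0)
    w_clip: tuple[float, float] = (-12.0, 0.0)
    Td: float = 0.1
    #: If True, the ML decoder scores spikes against the full rates
    #: (including the excitability w); by default it uses the
    #: stimulus-driven tuning curves only, the population-coding
    #: convention.  A w-aware decoder compensates the marginal-rate bias
    #: and thereby removes serial dependence and frequency biases.
    decode_uses_w: bool = False

    def __post_init__(self):
        for name in ("N", "omega", "eta", "alpha", "C", "r_bar", "dt", "Td"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.N < 2 or self.dt <= 0 or self.Td <= 0 or self.r_bar < 0:
            raise ValueError("invalid circuit parameters")
        if self.c is None:
            object.__setattr__(self, "c", 1.0 / max(self.r_bar * self.dt, 1e-12))
        elif self.c <= 0:
            raise ValueError("c must be positive")

    @property
    def phi(self) -> np.ndarray:
        """Preferred stimuli, one grid bin per neuron."""
        return StimulusGrid(self.N).centers


@dataclass
class CircuitState:
    """Mutable state carried across trials of a session.

    ``w`` has one row per subpopulation (stimulus slot); ``beta`` is
    shared across subpopulations.
    """

    beta: float
    w: np.ndarray  # (M, N)
    phi: np.ndarray  # (N,)
    grid: StimulusGrid
    cosmat: np.ndarray = field(repr=False, default=None)  # (K, N)

    @classmethod
    def init(cls, params: CircuitParams, n_subpops: int = 1,
             w0: float | None = None, grid_K: int | None = None) -> "CircuitState":
        phi = params.phi
        if w0 is None:
            w0 = float(np.log(1.0 / params.N))
        w = np.full((n_subpops, params.N), np.clip(w0, *params.w_clip))
        grid = StimulusGrid(grid_K if grid_K is not None else params.N)
        cosmat = np.cos(grid.centers[:, None] - phi[None, :])
        return cls(beta=params.beta0, w=w, phi=phi, grid=grid, cosmat=cosmat)

    @property
    def n_subpops(self) -> int:
        return self.w.shape[0]


def excitatory_input(state: CircuitState, stimuli, params: CircuitParams,
                     probe_probs=None) -> np.ndarray:
    """Per-neuron drive u_im = -beta*pi_m*d(theta_m, phi_i) + w_im.

    With cosine distortion the stimulus term is
    beta*pi_m*omega*cos(theta_m - phi_i).  ``stimuli`` must have one
    angle per subpopulation; ``probe_probs`` defaults to uniform.
    """
    theta = np.atleast_1d(np.asarray(stimuli, dtype=float))
    M = theta.shape[0]
    if M != state.n_subpops:
        raise ValueError("stimulus count must match number of subpopulations")
    pi = np.full(M, 1.0 / M) if probe_probs is None else np.asarray(probe_probs, float)
    drive = state.beta * pi[:, None] * params.omega * np.cos(theta[:, None] - state.phi[None, :])
    return drive + state.w


def firing_rates(u: np.ndarray) -> np.ndarray:
    """Divisively normalized rates r_i = exp(u_i)/sum_j exp(u_j) (last axis)."""
    u = np.asarray(u, dtype=float)
    e = np.exp(u - u.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def sample_spikes(r: np.ndarray, params: CircuitParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson spike counts with per-neuron mean r_bar * r_i * dt."""
    return rng.poisson(params.r_bar * np.asarray(r) * params.dt)


def update_excitability(w: np.ndarray, z: np.ndarray, params: CircuitParams) -> np.ndarray:
    """Spike-triggered intrinsic-plasticity update, clipped to w_clip.

    w <- clip(w + eta*dt*(c*exp(-w)*z - 1)); the learning rate is
    pre-scaled by dt.
    """
    w_new = w + params.eta * params.dt * (params.c * np.exp(-w) * z - 1.0)
    return np.clip(w_new, *params.w_clip)


def _log_softmax_last(U: np.ndarray) -> np.ndarray:
    U = U - U.max(axis=-1, keepdims=True)
    return U - np.log(np.exp(U).sum(axis=-1, keepdims=True))


def _winner_mi_numpy(bop: np.ndarray, cosmat: np.ndarray, w: np.ndarray,
                     prior: np.ndarray) -> float:
    """Mutual information of the winner-take-all channel, summed over
    subpopulations.

    ``bop[m] = beta * omega * pi_m``; rows of the channel are softmax
    over neurons of bop[m]*cosmat[k] + w[m].  Uses the decomposition
    R_m = sum_k p_k sum_i r_ki log r_ki - sum_i rbar_i log rbar_i.
    """
    U = bop[:, None, None] * cosmat[None, :, :] + w[:, None, :]
    logr = _log_softmax_last(U)
    r = np.exp(logr)
    rbar = np.einsum("k,mki->mi", prior, r)
    t1 = float(np.einsum("k,mki,mki->", prior, r, logr))
    t2 = float(np.sum(rbar * np.log(rbar)))
    return max(t1 - t2, 0.0)


try:  # optional compiled kernel for the per-step hot path
    from numba import njit as _njit

    @_njit(cache=False, fastmath=True)
    def _winner_mi_nb(bop, cosmat, w, prior):  # pragma: no cover - numerics
        M = bop.shape[0]
        K, N = cosmat.shape
        R = 0.0
        u = np.empty(N)
        e = np.empty(N)
        rbar = np.empty(N)
        for m in range(M):
            for i in range(N):
                rbar[i] = 0.0
            t1 = 0.0
            for k in range(K):
                mx = -1e300
                for i in range(N):
                    ui = bop[m] * cosmat[k, i] + w[m, i]
                    u[i] = ui
                    if ui > mx:
                        mx = ui
                s = 0.0
                su = 0.0
                for i in range(N):
                    ei = np.exp(u[i] - mx)
                    e[i] = ei
                    s += ei
                    su += ei * (u[i] - mx)
                t1 += prior[k] * (su / s - np.log(s))
                pks = prior[k] / s
                for i in range(N):
                    rbar[i] += pks * e[i]
            t2 = 0.0
            for i in range(N):
                if rbar[i] > 0.0:
                    t2 += rbar[i] * np.log(rbar[i])
            R += t1 - t2
        return R if R > 0.0 else 0.0

    @_njit(cache=False, fastmath=True)
    def _winner_mi_circ_nb(bop, w, cosg, prior):  # pragma: no cover - numerics
        """Same quantity as _winner_mi_nb for the aligned case K == N,
        exploiting that exp(bop*cos(theta_k - phi_i)) is circulant:
        only O(N) exponentials and O(N^2) multiply-adds per subpopulation.
        ``cosg[j] = cos(2*pi*j/N)``."""
        M, N = w.shape
        g = np.empty(N)
        ht = np.empty(N)
        ew = np.empty(N)
        wew = np.empty(N)
        ps = np.empty(N)
        R = 0.0
        for m in range(M):
            b = bop[m]
            for j in range(N):
                gj = np.exp(b * (cosg[j] - 1.0))
                g[j] = gj
                ht[j] = gj * b * (cosg[j] - 1.0)
            for i in range(N):
                e = np.exp(w[m, i])
                ew[i] = e
                wew[i] = w[m, i] * e
            t1 = 0.0
            for k in range(N):
                sk = 0.0
                suk = 0.0
                for i in range(k + 1):
                    j = k - i
                    sk += g[j] * ew[i]
                    suk += ht[j] * ew[i] + g[j] * wew[i]
                for i in range(k + 1, N):
                    j = k - i + N
                    sk += g[j] * ew[i]
                    suk += ht[j] * ew[i] + g[j] * wew[i]
                ps[k] = prior[k] / sk
                t1 += prior[k] * (suk / sk - np.log(sk))
            t2 = 0.0
            for i in range(N):
                acc = 0.0
                for k in range(i):
                    acc += ps[k] * g[k - i + N]
                for k in range(i, N):
                    acc += ps[k] * g[k - i]
                rb = ew[i] * acc
                if rb > 0.0:
                    t2 += rb * np.log(rb)
            R += t1 - t2
        return R if R > 0.0 else 0.0

    @_njit(cache=False)
    def _trial_loop_nb(seed, n_steps, td_steps, stim_cos, pi, w, beta0,
                       omega, eta_dt, alpha_dt, c, lam_scale, C_eff,
                       lo_w, hi_w, lo_b, hi_b, cosmat, prior, cosg, circulant,
                       plastic, adapt, probe_index, decode_counts,
                       beta_trace, R_trace):  # pragma: no cover - numerics
        np.random.seed(seed)
        M, N = stim_cos.shape
        u = np.empty(N)
        bop = np.empty(M)
        beta = beta0
        R = np.nan
        for step in range(n_steps):
            for m in range(M):
                mx = -1e300
                for i in range(N):
                    ui = beta * omega * pi[m] * stim_cos[m, i] + w[m, i]
                    u[i] = ui
                    if ui > mx:
                        mx = ui
                s = 0.0
                for i in range(N):
                    e = np.exp(u[i] - mx)
                    u[i] = e
                    s += e
                for i in range(N):
                    z = np.random.poisson(lam_scale * u[i] / s)
                    if z > 0 and m == probe_index and step >= n_steps - td_steps:
                        decode_counts[i] += z
                    if plastic:
                        wi = w[m, i] + eta_dt * (c * np.exp(-w[m, i]) * z - 1.0)
                        w[m, i] = min(max(wi, lo_w), hi_w)
            if adapt:
                for m in range(M):
                    bop[m] = beta * omega * pi[m]
                if circulant:
                    R = _winner_mi_circ_nb(bop, w, cosg, prior)
                else:
                    R = _winner_mi_nb(bop, cosmat, w, prior)
                beta = min(max(beta + alpha_dt * (C_eff - R), lo_b), hi_b)
            beta_trace[step] = beta
            R_trace[step] = R
        return beta

except Exception:  # pragma: no cover - numba absent
    _winner_mi_nb = None
    _trial_loop_nb = None


def information_rate(state: CircuitState, params: CircuitParams,
                     probe_probs=None, prior: np.ndarray | None = None,
                     fast: bool = False) -> float:
    """Information rate R of the circuit in nats under the current (beta, w).

    Resolved as the exact mutual information between grid stimuli and
    winner identity of the winner-take-all channel implied by the
    deterministic rates, summed over subpopulations:

        R_m = sum_theta P(theta) sum_i r_i(theta) log[r_i(theta)/rbar_i]

    with rbar_i the prior-weighted marginal rate.  P(theta) defaults to
    uniform over the grid.
    """
    M = state.n_subpops
    pi = np.full(M, 1.0 / M) if probe_probs is None else np.asarray(probe_probs, float)
    bop = state.beta * params.omega * pi
    p = np.full(state.grid.K, 1.0 / state.grid.K) if prior is None \
        else np.asarray(prior, float)
    if fast and _winner_mi_nb is not None:
        return float(_winner_mi_nb(bop, state.cosmat, state.w, p))
    return _winner_mi_numpy(bop, state.cosmat, state.w, p)


def update_gain(beta: float, R: float, params: CircuitParams,
                T_active: float, T_silent: float) -> float:
    """Homeostatic gain update beta <- clip(beta + alpha*dt*(C_eff - R))."""
    C_eff = effective_capacity(params.C, T_active, T_silent)
    return float(np.clip(beta + params.alpha * params.dt * (C_eff - R), *params.beta_clip))


def decode_ml(counts: np.ndarray, state: CircuitState, params: CircuitParams,
              subpop: int, probe_prob: float, rng: np.random.Generator) -> tuple[float, bool]:
    """Maximum-likelihood decode of accumulated spike counts over the grid.

    Scores each candidate stimulus by sum_i n_i * log r_i(theta) (the
    total-rate term is constant because rates are normalized); ties break
    toward the lowest grid index.  Zero total spikes yield a uniformly
    random grid angle, flagged.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        return float(state.grid.centers[rng.integers(state.grid.K)]), True
    U = state.beta * params.omega * probe_prob * state.cosmat
    if params.decode_uses_w:
        U = U + state.w[subpop][None, :]
    logr = _log_softmax_last(U)
    scores = logr @ counts
    return float(state.grid.centers[int(np.argmax(scores))]), False


def _trial_probe_probs(set_size: int, cued_index: int, priority: float) -> np.ndarray:
    a = np.ones(set_size)
    if 0 <= cued_index < set_size:
        a[cued_index] = priority
    return a / a.sum()


def run_trial(stimuli, probe_index: int, ri: float, iti: float,
              state: CircuitState, params: CircuitParams,
              rng: np.random.Generator, variant: str = "full",
              cued_index: int = -1, priority: float = 1.0,
              prior: np.ndarray | None = None,
              trace: list | None = None, trace_every: int = 0) -> dict:
    """Simulate one trial, mutating ``state``; returns a trial record.

    The retention interval is simulated in steps of dt with the stimulus
    drive clamped; the active time is max(ri, Td) so the decode window
    always fits (ri = 0 means an immediate report).  The intertrial
    interval is not simulated step-by-step: it enters only through the
    effective capacity; w and beta persist unchanged across it.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if ri < 0 or iti < 0:
        raise ValueError("ri and iti must be non-negative")
    theta = np.atleast_1d(np.asarray(stimuli, dtype=float))
    M = theta.shape[0]
    if M != state.n_subpops:
        raise ValueError("trial set size must match state subpopulations")
    if not 0 <= probe_index < M:
        raise ValueError("probe_index out of range")
    pi = _trial_probe_probs(M, cued_index, priority)

    T_active = max(ri, params.Td)
    n_steps = max(int(round(T_active / params.dt)), 1)
    td_steps = min(max(int(round(params.Td / params.dt)), 1), n_steps)
    C_eff = effective_capacity(params.C, T_active, iti)

    stim_cos = np.cos(theta[:, None] - state.phi[None, :])  # (M, N)
    decode_counts = np.zeros(params.N, dtype=np.int64)
    plastic = variant != "no_plasticity"
    adapt = variant != "fixed_gain"
    eta_dt = params.eta * params.dt
    alpha_dt = params.alpha * params.dt
    lo_w, hi_w = params.w_clip
    lo_b, hi_b = params.beta_clip
    lam_scale = params.r_bar * params.dt

    grid_prior = np.full(state.grid.K, 1.0 / state.grid.K) if prior is None \
        else np.asarray(prior, float)
    beta = state.beta
    w = state.w
    if _trial_loop_nb is not None:
        # compiled step loop; spikes drawn from numba's seeded global stream
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        beta_trace = np.empty(n_steps)
        R_trace = np.empty(n_steps)
        w_c = np.ascontiguousarray(w)
        K = state.grid.K
        circulant = K == params.N and np.allclose(state.phi, state.grid.centers)
        cosg = np.cos(2.0 * np.pi * np.arange(K) / K)
        beta = float(_trial_loop_nb(
            kernel_seed, n_steps, td_steps, np.ascontiguousarray(stim_cos), pi,
            w_c, beta, params.omega, eta_dt, alpha_dt, params.c, lam_scale,
            C_eff, lo_w, hi_w, lo_b, hi_b, state.cosmat, grid_prior, cosg,
            circulant, plastic, adapt, probe_index, decode_counts,
            beta_trace, R_trace))
        w[...] = w_c
        if trace is not None and trace_every:
            for step in range(0, n_steps, trace_every):
                trace.append((step, float(beta_trace[step]), float(R_trace[step])))
    else:
        for step in range(n_steps):
            u = beta * params.omega * pi[:, None] * stim_cos + w
            u -= u.max(axis=1, keepdims=True)
            e = np.exp(u)
            r = e / e.sum(axis=1, keepdims=True)
            z = rng.poisson(lam_scale * r)
            if plastic:
                w += eta_dt * (params.c * np.exp(-w) * z - 1.0)
                np.clip(w, lo_w, hi_w, out=w)
            if adapt:
                R = _winner_mi_numpy(beta * params.omega * pi, state.cosmat, w,
                                     grid_prior)
                beta = min(max(beta + alpha_dt * (C_eff - R), lo_b), hi_b)
            if step >= n_steps - td_steps:
                decode_counts += z[probe_index]
            if trace is not None and trace_every and step % trace_every == 0:
                trace.append((step, beta, R if adapt else np.nan))
    state.beta = beta

    response, zero_flag = decode_ml(decode_counts, state, params, probe_index,
                                    float(pi[probe_index]), rng)
    target = float(theta[probe_index])
    return {
        "set_size": M,
        "stimuli": theta,
        "probe_index": probe_index,
        "cued": int(probe_index == cued_index),
        "ri_s": float(ri),
        "iti_s": float(iti),
        "target": target,
        "response": response,
        "error": float(wrap_angle(response - target)),
        "zero_spike_flag": int(zero_flag),
        "beta": float(beta),
    }


def run_session(session, params: CircuitParams, variant: str = "full",
                seed: int | np.random.SeedSequence = 0,
                session_label: str | int = 0,
                trace: list | None = None, trace_every: int = 0,
                return_state: bool = False):
    """Simulate all trials of a session, carrying (w, beta) across trials.

    ``session`` is a :class:`rdwm.paradigms.SessionSpec`.  One master
    seed stream per session is split into per-trial substreams, so the
    noise of one trial does not perturb later trials when trial counts
    change.  Returns a pandas TrialTable (one row per trial).
    """
    import pandas as pd

    n = session.n_trials
    if n == 0:
        empty = _empty_trial_table(0)
        return (empty, None) if return_state else empty
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(n)
    m_max = int(session.stimuli.shape[1])
    state = CircuitState.init(params, n_subpops=m_max)

    records = []
    for t in range(n):
        rng = np.random.default_rng(trial_seeds[t])
        m = int(session.set_size[t])
        theta = session.stimuli[t, :m]
        # only the first m slots hold items this trial; idle slots keep their state
        sub = CircuitState(beta=state.beta, w=state.w[:m], phi=state.phi,
                           grid=state.grid, cosmat=state.cosmat)
        rec = run_trial(
            theta, int(session.probe_index[t]), float(session.ri[t]),
            float(session.iti[t]), sub, params, rng, variant=variant,
            cued_index=int(session.cued_index[t]), priority=float(session.priority),
            trace=trace, trace_every=trace_every,
        )
        state.beta = sub.beta
        rec["session"] = session_label
        rec["trial"] = t
        records.append(rec)

    rows = []
    for rec in records:
        row = {k: rec[k] for k in ("session", "trial", "set_size", "probe_index",
                                   "cued", "ri_s", "iti_s", "target", "response",
                                   "error", "zero_spike_flag", "beta")}
        for j in range(m_max):
            row[f"stim_{j + 1}"] = rec["stimuli"][j] if j < rec["set_size"] else np.nan
        rows.append(row)
    cols = (["session", "trial", "set_size"] + [f"stim_{j + 1}" for j in range(m_max)]
            + ["probe_index", "cued", "ri_s", "iti_s", "target", "response", "error",
               "zero_spike_flag", "beta"])
    table = pd.DataFrame(rows, columns=cols)
    return (table, state) if return_state else table


def _empty_trial_table(m_max: int):
    import pandas as pd

    cols = (["session", "trial", "set_size"] + [f"stim_{j + 1}" for j in range(m_max)]
            + ["probe_index", "cued", "ri_s", "iti_s", "target", "response", "error",
               "zero_spike_flag", "beta"])
    return pd.DataFrame(columns=cols)
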