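"""Rate-distortion machinery for discrete circular channels.

A memory system that stores a circular feature (color, orientation,
location) and reproduces it with error can be described as a noisy
channel ``Q(theta_hat | theta)``.  Rate-distortion theory asks for the
channel that minimizes the expected cost of errors, ``D = E[d(theta,
theta_hat)]``, subject to a bound ``C`` on the information rate ``R =
I(theta; theta_hat)``.  The Lagrangian form ``min_Q R + beta*D`` is
solved by the Blahut-Arimoto alternating iteration, whose fixed point is

    Q(theta_hat | theta)  ∝  exp[-beta * d(theta, theta_hat) + log Qbar(theta_hat)]

with ``Qbar`` the output marginal under the source prior.  The Lagrange
multiplier ``beta`` is the (negative) slope of the rate-distortion curve
and doubles as the stimulus gain of the spiking circuit in
:mod:`rdwm.circuit`.

All information quantities are in nats.  Stimulus spaces are discretized
into ``K`` equally spaced bins on the circle ``[-pi, pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusGrid",
    "Source",
    "DistortionMatrix",
    "Channel",
    "RDPoint",
    "wrap_angle",
    "cosine_distortion",
    "pooled_distortion",
    "probe_probabilities",
    "blahut_arimoto",
    "mutual_information",
    "expected_distortion",
    "rd_curve",
    "beta_for_capacity",
    "effective_capacity",
    "BETA_MAX",
]

#: Upper end of the admissible gain range (the circuit clips beta here too).
BETA_MAX = 1000.0


def wrap_angle(theta):
    """Wrap angles to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class StimulusGrid:
    """Discretization of the circular stimulus space into K equal bins.

    Bin centers are equally spaced in [-pi, pi), starting at -pi.
    """

    K: int

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("StimulusGrid requires K >= 2")

    @property
    def centers(self) -> np.ndarray:
        return -np.pi + 2.0 * np.pi * np.arange(self.K) / self.K

    @property
    def spacing(self) -> float:
        return 2.0 * np.pi / self.K

    def nearest(self, theta) -> np.ndarray:
        """Index of the grid bin nearest to ``theta`` (circular distance)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        idx = np.round((theta + np.pi) / self.spacing).astype(int) % self.K
        return idx


@dataclass(frozen=True)
class Source:
    """A stimulus grid together with a prior P(theta) over its bins."""

    grid: StimulusGrid
    prior: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        prior = self.prior
        if prior is None:
            prior = np.full(self.grid.K, 1.0 / self.grid.K)
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (self.grid.K,):
            raise ValueError("prior length must equal grid.K")
        if np.any(prior < 0):
            raise ValueError("prior must be non-negative")
        if abs(prior.sum() - 1.0) > 1e-12:
            raise ValueError("prior must sum to 1 within 1e-12")
        object.__setattr__(self, "prior", prior)


def cosine_distortion(theta, theta_hat, omega: float = 1.0):
    """Cosine distortion d(theta, theta_hat) = -omega * cos(theta - theta_hat).

    Minimal (-omega) at zero error, maximal (+omega) for antipodal
    errors, and 2*pi-periodic in both arguments.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    theta = np.asarray(theta, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    d = -omega * np.cos(theta - theta_hat)
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class DistortionMatrix:
    """Pairwise distortion d(center_i, center_j) on a stimulus grid."""

    grid: StimulusGrid
    omega: float = 1.0
    values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.values is None:
            c = self.grid.centers
            vals = cosine_distortion(c[:, None], c[None, :], self.omega)
            object.__setattr__(self, "values", vals)
        else:
            vals = np.asarray(self.values, dtype=float)
            if vals.shape != (self.grid.K, self.grid.K):
                raise ValueError("values must be K x K")
            object.__setattr__(self, "values", vals)


def probe_probabilities(priorities) -> np.ndarray:
    """Probing probabilities pi_m from attentional priority weights.

    ``pi_m = alpha_m / sum(alpha)``; a 3:1 cue priority with M=4 gives
    (1/2, 1/6, 1/6, 1/6).
    """
    a = np.asarray(priorities, dtype=float)
    if np.any(a < 0) or a.sum() <= 0:
        raise ValueError("priorities must be non-negative with positive sum")
    return a / a.sum()


def pooled_distortion(stimuli, reconstructions, probe_probs, omega: float = 1.0) -> float:
    """Distortion for M simultaneously stored items, marginalized over the probe.

    Returns sum_m pi_m * d(theta_m, theta_hat_m) with cosine distortion.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    reconstructions = np.asarray(reconstructions, dtype=float)
    pi = np.asarray(probe_probs, dtype=float)
    if not (stimuli.shape == reconstructions.shape == pi.shape):
        raise ValueError("stimuli, reconstructions and probe_probs must have equal length")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("probe probabilities must sum to 1")
    return float(np.sum(pi * cosine_distortion(stimuli, reconstructions, omega)))


@dataclass(frozen=True)
class Channel:
    """Conditional distribution Q(theta_hat | theta) over a stimulus grid.

    ``Q`` is row-stochastic (rows indexed by the true stimulus) and
    ``marginal`` is the output distribution prior @ Q.
    """

    source: Source
    Q: np.ndarray
    converged: bool = True
    residual: float = 0.0
    n_iter: int = 0

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        K = self.source.grid.K
        if Q.shape != (K, K):
            raise ValueError("Q must be K x K")
        rows = Q.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-10:
            raise ValueError("channel rows must sum to 1 within 1e-10")
        object.__setattr__(self, "Q", Q)

    @property
    def marginal(self) -> np.ndarray:
        return self.source.prior @ self.Q


def blahut_arimoto(
    source: Source,
    D: DistortionMatrix,
    beta: float,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> Channel:
    """Optimal channel at gain ``beta`` by Blahut-Arimoto alternating iteration.

    Starting from uniform Q and marginal, alternates

        Q(.|theta) ∝ Qbar * exp(-beta * d(theta, .));   Qbar = prior @ Q

    until the maximum elementwise change of Q between sweeps is <= tol.
    Non-convergence within ``max_iter`` is flagged on the returned
    Channel rather than raised.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    K = source.grid.K
    p = source.prior
    # exp(-beta*d) rescaled by the row max for numerical range
    logW = -beta * D.values
    logW = logW - logW.max(axis=1, keepdims=True)
    W = np.exp(logW)
    qbar = np.full(K, 1.0 / K)
    Q = np.full((K, K), 1.0 / K)
    residual = np.inf
    for it in range(1, max_iter + 1):
        A = W * qbar[None, :]
        Q_new = A / A.sum(axis=1, keepdims=True)
        residual = float(np.max(np.abs(Q_new - Q)))
        Q = Q_new
        qbar = p @ Q
        if residual <= tol:
            return Channel(source, Q, converged=True, residual=residual, n_iter=it)
    return Channel(source, Q, converged=False, residual=residual, n_iter=max_iter)


def mutual_information(channel: Channel) -> float:
    """I(theta; theta_hat) of a channel in nats, with 0*log(0) := 0."""
    p = channel.source.prior
    Q = channel.Q
    qbar = channel.marginal
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Q > 0, Q / np.where(qbar[None, :] > 0, qbar[None, :], 1.0), 1.0)
        terms = np.where(Q > 0, Q * np.log(ratio), 0.0)
    return max(float(p @ terms.sum(axis=1)), 0.0)


def expected_distortion(channel: Channel, D: DistortionMatrix) -> float:
    """E[d(theta, theta_hat)] under the source prior and channel."""
    if D.grid.K != channel.source.grid.K:
        raise ValueError("distortion matrix grid does not match channel grid")
    p = channel.source.prior
    return float(p @ (channel.Q * D.values).sum(axis=1))


@dataclass(frozen=True)
class RDPoint:
    """One point (beta, rate, distortion) on a rate-distortion curve."""

    beta: float
    rate: float
    distortion: float


def rd_curve(source: Source, D: DistortionMatrix, betas, tol: float = 1e-10,
             max_iter: int = 100_000) -> list[RDPoint]:
    """Rate-distortion points for an ascending grid of beta values."""
    betas = np.asarray(betas, dtype=float)
    if np.any(np.diff(betas) < 0):
        raise ValueError("betas must be sorted ascending")
    points = []
    for b in betas:
        ch = blahut_arimoto(source, D, float(b), tol=tol, max_iter=max_iter)
        points.append(RDPoint(float(b), mutual_information(ch), expected_distortion(ch, D)))
    return points


def beta_for_capacity(
    source: Source,
    D: DistortionMatrix,
    C: float,
    beta_bounds: tuple[float, float] = (0.0, BETA_MAX),
    tol_rate: float = 1e-6,
    tol_beta: float = 1e-6,
    ba_tol: float = 1e-10,
) -> tuple[float, bool]:
    """Gain beta* with information rate closest to capacity C.

    Exploits monotonicity of R(beta) and bisects until |R - C| <= tol_rate
    or the beta interval is shorter than tol_beta.  Returns ``(beta,
    saturated)``; ``saturated`` is True when C exceeds the rate achievable
    at the upper bound, in which case the upper bound is returned.
    """
    if C < 0:
        raise ValueError("capacity must be non-negative")
    lo, hi = beta_bounds
    if lo < 0 or hi > BETA_MAX or lo >= hi:
        raise ValueError(f"beta_bounds must lie within [0, {BETA_MAX}]")

    def rate(b):
        return mutual_information(blahut_arimoto(source, D, b, tol=ba_tol))

    if C == 0.0:
        return 0.0, False
    if rate(hi) < C - tol_rate:
        return hi, True
    while hi - lo > tol_beta:
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - C) <= tol_rate:
            return mid, False
        if r < C:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), False


def effective_capacity(C: float, T_active: float, T_silent: float) -> float:
    """Duty-cycle rescaled capacity C * (T_active + T_silent) / T_active.

    During silent periods (the intertrial interval) no information is
    transmitted, so the sustainable rate during active periods (the
    retention interval) exceeds the long-run capacity by the duty-cycle
    factor.
    """
    if T_active <= 0:
        raise ValueError("T_active must be positive")
    if T_silent < 0:
        raise ValueError("T_silent must be non-negative")
    return C * (T_active + T_silent) / T_active
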