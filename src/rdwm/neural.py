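"""Neural-gain analysis of delay-period spike counts.

Estimates each neuron's preferred stimulus with a bell-shaped (von
Mises-like) tuning curve, then recovers the gain ``beta`` by Poisson
regression of trial spike counts on the cosine distortion between the
trial stimulus and the preferred stimulus, with an exponential moving
average of the neuron's spike history as a nuisance regressor:

    log E[s_j] = a0 + coef_D * D_j + coef_h * ema_j,

with D_j = -cos(theta_j - phi).  Since the circuit drive is -beta * D,
the reported gain is beta = -coef_D (positive for stimulus-driven
firing).  Neurons with negative fitted beta, or beta more than 5 SD
above the mean, are excluded, mirroring standard outlier rules for this
analysis.  Session-level associations between gain and behavioral
precision close the loop with the homeostatic model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .channel import wrap_angle

__all__ = [
    "TuningFit",
    "fit_tuning_curve",
    "spike_history_ema",
    "NeuronGainFit",
    "fit_poisson_gain",
    "exclude_neurons",
    "QuantileEffect",
    "error_quantile_analysis",
    "gain_precision_correlation",
]

#: Width above which a tuning fit is considered uninformative (flat).
_FLAT_WIDTH = 50.0


@dataclass(frozen=True)
class TuningFit:
    """Bell-shaped tuning curve f(theta) = A*exp(w^-1*(cos(theta-phi)-1))."""

    A: float
    w: float
    phi: float
    rss: float
    flag: str | None = None

    def predict(self, theta):
        return self.A * np.exp((np.cos(np.asarray(theta, float) - self.phi) - 1.0) / self.w)


def fit_tuning_curve(stimuli, mean_counts, w_bounds=(0.05, 1e3)) -> TuningFit:
    """Least-squares tuning fit with multi-start over the preferred angle.

    ``stimuli`` are the distinct presented angles and ``mean_counts``
    the mean spike count at each.  Requires >= 4 distinct angles and a
    non-zero response.  Flat profiles produce a large fitted width and
    are flagged 'flat'.
    """
    theta = np.asarray(stimuli, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if np.unique(np.round(theta, 9)).size < 4:
        raise ValueError("need at least 4 distinct stimulus angles")
    if np.all(y == 0):
        raise ValueError("all mean counts are zero")

    def resid(p):
        A, w, phi = p
        return A * np.exp((np.cos(theta - phi) - 1.0) / w) - y

    best = None
    A0 = max(float(y.max()), 1e-6)
    for phi0 in theta:
        for w0 in (0.3, 1.0, 3.0):
            sol = least_squares(
                resid, x0=[A0, w0, float(phi0)],
                bounds=([1e-9, w_bounds[0], -2 * np.pi], [np.inf, w_bounds[1], 2 * np.pi]))
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[1]:
                best = (sol.x, rss)
    (A, w, phi), rss = best
    flag = "flat" if w > _FLAT_WIDTH else None
    return TuningFit(float(A), float(w), float(wrap_angle(phi)), rss, flag)


def spike_history_ema(counts, decay: float = 0.8) -> np.ndarray:
    """Exponential moving average of past spike counts (current trial excluded).

    ema_1 = 0;  ema_j = decay * ema_{j-1} + (1 - decay) * s_{j-1}.
    """
    s = np.asarray(counts, dtype=float)
    ema = np.zeros_like(s)
    for j in range(1, s.size):
        ema[j] = decay * ema[j - 1] + (1.0 - decay) * s[j - 1]
    return ema


@dataclass(frozen=True)
class NeuronGainFit:
    """Per-neuron Poisson regression estimates (gain sign convention:
    beta = -coefficient on the distortion regressor)."""

    neuron_id: object
    intercept: float
    beta: float
    beta_se: float
    history_coef: float
    history_se: float
    n: int
    log_lik: float
    excluded: bool = False
    reason: str | None = None

    def beta_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 * (1 + level))
        return self.beta - z * self.beta_se, self.beta + z * self.beta_se


def fit_poisson_gain(spikes: pd.DataFrame, tuning: TuningFit,
                     decay: float = 0.8, include_history: bool = True) -> NeuronGainFit:
    """Poisson GLM of one neuron's trial spike counts on distortion and history.

    ``spikes`` must contain columns ``trial``, ``stimulus`` and
    ``spike_count`` for a single neuron (>= 30 trials).  D_j is the
    cosine distortion (omega = 1) between the trial stimulus and the
    neuron's fitted preferred angle; omega is absorbed into beta.
    """
    g = spikes.sort_values("trial")
    if len(g) < 30:
        raise ValueError("need at least 30 trials per neuron")
    neuron_id = g["neuron_id"].iloc[0] if "neuron_id" in g else None
    counts = g["spike_count"].to_numpy(float)
    D = -np.cos(g["stimulus"].to_numpy(float) - tuning.phi)
    X = [np.ones_like(D), D]
    if include_history:
        X.append(spike_history_ema(counts, decay))
    X = np.column_stack(X)
    try:
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite estimates")
    except Exception as exc:  # separation / non-convergence
        return NeuronGainFit(neuron_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                             len(g), -np.inf, excluded=True, reason=f"fit-failed: {exc}")
    hist_coef = float(res.params[2]) if include_history else 0.0
    hist_se = float(res.bse[2]) if include_history else np.nan
    return NeuronGainFit(neuron_id, float(res.params[0]), -float(res.params[1]),
                         float(res.bse[1]), hist_coef, hist_se, len(g),
                         float(res.llf))


def exclude_neurons(fits) -> tuple[list, list]:
    """Apply the neuron exclusion rules; returns (kept, exclusion_log).

    Neurons with negative fitted beta are removed first; among the
    remainder, any beta more than 5 SD above the mean is removed.
    """
    fits = list(fits)
    log = []
    kept = []
    for f in fits:
        if f.excluded:
            log.append((f.neuron_id, f.reason or "pre-excluded"))
        elif f.beta < 0:
            log.append((f.neuron_id, "negative"))
        else:
            kept.append(f)
    if len(kept) >= 2:
        betas = np.array([f.beta for f in kept])
        thresh = betas.mean() + 5.0 * betas.std(ddof=1)
        final = []
        for f in kept:
            if f.beta > thresh:
                log.append((f.neuron_id, "outlier>5sd"))
            else:
                final.append(f)
        kept = final
    return kept, log


@dataclass(frozen=True)
class QuantileEffect:
    """Previous-error effect on current squared error."""

    coef: float
    se: float
    pvalue: float
    quantile_means: np.ndarray
    mean_sq_error: float
    method: str


def error_quantile_analysis(table: pd.DataFrame, n_quantiles: int = 6) -> QuantileEffect:
    """Does squared error on trial t decrease after a bad trial t-1?

    Builds the indicator i_t = +1 if the previous trial's squared error
    exceeded the (pooled) mean squared error, else -1, and fits
    e_t^2 ~ 1 + i_t with a per-session random intercept (falling back to
    session-demeaned OLS when the mixed fit is degenerate or only one
    session is present).  Also returns the mean current squared error in
    ``n_quantiles`` equal-frequency bins of the previous squared error.
    A negative coefficient means performance improves after poor trials,
    the signature of homeostatic gain adaptation.
    """
    rows = []
    for sess, g in table.groupby("session", sort=False):
        g = g.sort_values("trial")
        e2 = g["error"].to_numpy(float) ** 2
        rows.append(pd.DataFrame({"session": sess, "e2": e2[1:], "prev_e2": e2[:-1]}))
    d = pd.concat(rows, ignore_index=True)
    if len(d) < n_quantiles + 2:
        raise ValueError("not enough trials")
    mean_e2 = float(d["e2"].mean())
    d["i"] = np.where(d["prev_e2"].to_numpy() > mean_e2, 1.0, -1.0)

    # equal-frequency quantile profile of the previous squared error (pooled)
    if d["prev_e2"].nunique() > 1:
        q = pd.qcut(d["prev_e2"], n_quantiles, labels=False, duplicates="drop")
        profile = d.groupby(q)["e2"].mean().to_numpy()
    else:
        profile = np.full(n_quantiles, mean_e2)
    if d["i"].nunique() < 2:  # degenerate indicator: no contrast to estimate
        return QuantileEffect(0.0, np.nan, 1.0, profile, mean_e2, "degenerate")

    n_sessions = d["session"].nunique()
    if n_sessions >= 2:
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = sm.MixedLM(d["e2"], sm.add_constant(d["i"]),
                               groups=d["session"]).fit(reml=True)
            if np.isfinite(m.bse_fe.iloc[1]):
                return QuantileEffect(float(m.fe_params.iloc[1]), float(m.bse_fe.iloc[1]),
                                      float(m.pvalues.iloc[1]), profile, mean_e2, "mixed")
        except Exception:
            pass
    # fallback: demean within session, then OLS
    d["e2_dm"] = d["e2"] - d.groupby("session")["e2"].transform("mean") + mean_e2
    ols = sm.OLS(d["e2_dm"], sm.add_constant(d["i"])).fit()
    return QuantileEffect(float(ols.params.iloc[1]), float(ols.bse.iloc[1]),
                          float(ols.pvalues.iloc[1]), profile, mean_e2, "demeaned-ols")


def gain_precision_correlation(mean_beta, mean_sq_error) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between per-session mean
    fitted gain and mean squared behavioral error."""
    b = np.asarray(mean_beta, float)
    e = np.asarray(mean_sq_error, float)
    if b.size != e.size or b.size < 3:
        raise ValueError("need >= 3 paired sessions")
    r, p = pearsonr(b, e)
    return float(r), float(p)
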