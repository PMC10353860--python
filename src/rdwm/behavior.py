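"""Circular behavioral statistics for delayed-estimation data.

Implements the error analyses used throughout the package: circular
variance and kurtosis from trigonometric moments, derivative-of-Gaussian
(DoG) fits of serial dependence, folded error, sliding-window bias
curves, the set-size permutation test, and the standard 31-bin error
histogram.

Conventions.  Errors are the wrapped circular distance response - target
in (-pi, pi].  Serial dependence is measured against the offset of the
previous trial's target (or report) from the current target; positive
folded error means attraction toward the previous stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .channel import wrap_angle

__all__ = [
    "circular_error",
    "trig_moment",
    "circ_variance",
    "circ_kurtosis",
    "DOG_C",
    "dog_curve",
    "DoGFit",
    "fit_dog",
    "folded_error",
    "BiasCurve",
    "sliding_bias",
    "serial_dependence_xy",
    "permutation_setsize_test",
    "error_histogram",
]

#: Normalizing constant of the DoG curve.  Chosen so the peak-to-peak
#: amplitude of ``x * a * w * c * exp(-(w*x)^2)`` is exactly ``2a``
#: (analytically, the extrema are at x = +-1/(w*sqrt(2)) with value
#: +-a*c/sqrt(2e), forcing c = sqrt(2e)).
DOG_C = math.sqrt(2.0 * math.e)


def circular_error(response, target):
    """Signed circular distance response - target, wrapped to (-pi, pi]."""
    return wrap_angle(np.asarray(response, float) - np.asarray(target, float))


def trig_moment(angles, n: int = 1) -> complex:
    """n-th uncentered trigonometric moment (1/L) * sum(exp(i*n*theta))."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    return complex(np.mean(np.exp(1j * n * a)))


def circ_variance(angles) -> float:
    """Circular variance sigma^2 = -2*log|m1|; +inf for |m1| = 0."""
    r = abs(trig_moment(angles, 1))
    if r < 1e-15:  # numerically vanishing resultant
        return float("inf")
    return -2.0 * math.log(r)


def circ_kurtosis(angles) -> float:
    """Circular (excess) kurtosis from the first two trigonometric moments.

    k = (|m2| * cos(Arg(m2) - 2*Arg(m1)) - |m1|^4) / (1 - |m1|)^2.

    Near zero for wrapped-normal samples; positive for heavier-than-
    normal tails.  A degenerate point mass (|m1| = 1) returns 0 by
    convention.
    """
    m1 = trig_moment(angles, 1)
    m2 = trig_moment(angles, 2)
    r1 = abs(m1)
    if abs(1.0 - r1) < 1e-12:
        return 0.0
    num = abs(m2) * math.cos(np.angle(m2) - 2.0 * np.angle(m1)) - r1 ** 4
    return num / (1.0 - r1) ** 2


def dog_curve(x, a: float, w: float, c: float = DOG_C):
    """DoG serial-dependence curve y = x * a * w * c * exp(-(w*x)^2)."""
    x = np.asarray(x, dtype=float)
    y = x * a * w * c * np.exp(-((w * x) ** 2))
    return y if y.ndim else float(y)


@dataclass(frozen=True)
class DoGFit:
    """Least-squares DoG fit; ``peak_to_peak`` is 2a by construction."""

    a: float
    w: float
    rss: float
    c: float = DOG_C

    @property
    def peak_to_peak(self) -> float:
        return 2.0 * self.a

    def predict(self, x):
        return dog_curve(x, self.a, self.w, self.c)


def _dog_grid_fit(x, y, w_grid, c):
    """For each candidate width, the amplitude is linear: solve in closed form."""
    best = (0.0, w_grid[0], np.inf)
    for w in w_grid:
        b = x * w * c * np.exp(-((w * x) ** 2))
        denom = float(b @ b)
        if denom <= 0:
            continue
        a = float(b @ y) / denom
        rss = float(np.sum((y - a * b) ** 2))
        if rss < best[2]:
            best = (a, w, rss)
    return best


def fit_dog(x, y, w_bounds=(0.1, 20.0), n_starts: int = 16,
            c: float = DOG_C, refine: bool = True) -> DoGFit:
    """Fit the DoG curve to (x, y) by bounded multi-start least squares.

    The width is scanned on a log-spaced grid over ``w_bounds`` (the
    amplitude is profiled out in closed form at each width), then the
    best grid point is refined with bounded nonlinear least squares.
    ``refine=False`` keeps the fast grid-only fit, used inside
    permutation loops.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 10:
        raise ValueError("fit_dog requires at least 10 points")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: all x equal")
    w_grid = np.geomspace(w_bounds[0], w_bounds[1], n_starts)
    a0, w0, rss0 = _dog_grid_fit(x, y, w_grid, c)
    if not refine:
        return DoGFit(a0, w0, rss0, c)

    def resid(p):
        return dog_curve(x, p[0], p[1], c) - y

    sol = least_squares(resid, x0=[a0, w0],
                        bounds=([-np.inf, w_bounds[0]], [np.inf, w_bounds[1]]))
    rss = float(np.sum(sol.fun ** 2))
    if rss <= rss0:
        return DoGFit(float(sol.x[0]), float(sol.x[1]), rss, c)
    return DoGFit(a0, w0, rss0, c)


def folded_error(error, prev_distance):
    """Folded error err * sign(prev_distance); sign(0) yields 0.

    Positive values indicate attraction toward the previous stimulus.
    """
    e = np.asarray(error, dtype=float)
    d = np.asarray(prev_distance, dtype=float)
    out = e * np.sign(d)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BiasCurve:
    """Sliding-window mean of y over x; empty windows hold NaN."""

    centers: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    width: float
    step: float


def sliding_bias(x, y, width: float, step: float,
                 domain=(-math.pi, math.pi), circular: bool = True) -> BiasCurve:
    """Mean of ``y`` in sliding windows of ``x``.

    Window membership is wrap-aware when ``circular`` (the natural
    choice for angular predictors); windows with no members are flagged
    with NaN mean and n = 0.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    centers = np.arange(domain[0], domain[1] + 1e-12, step)
    means = np.full(centers.size, np.nan)
    ns = np.zeros(centers.size, dtype=int)
    for i, ctr in enumerate(centers):
        d = np.abs(wrap_angle(x - ctr)) if circular else np.abs(x - ctr)
        inside = d <= width / 2.0
        ns[i] = int(inside.sum())
        if ns[i]:
            means[i] = float(y[inside].mean())
    return BiasCurve(centers, means, ns, width, step)


def serial_dependence_xy(table, ref: str = "target", error_cap: float | None = None):
    """Extract (x, y) pairs for serial-dependence analysis from a TrialTable.

    x is the circular offset of the previous trial's probed ``target``
    (or ``response``, per ``ref``) from the current target; y is the
    current signed error.  The first trial of each session is dropped;
    ``error_cap`` optionally excludes |error| above a threshold
    (pi/4 in the folded-error analyses).
    """
    xs, ys = [], []
    for _, g in table.groupby("session", sort=False):
        g = g.sort_values("trial")
        prev = g[ref].to_numpy()[:-1]
        cur_t = g["target"].to_numpy()[1:]
        err = g["error"].to_numpy()[1:]
        xs.append(wrap_angle(prev - cur_t))
        ys.append(err)
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if error_cap is not None:
        keep = np.abs(y) <= error_cap
        x, y = x[keep], y[keep]
    return x, y


def permutation_setsize_test(xy_a, xy_b, n_perm: int = 20_000, seed: int = 0,
                             w_bounds=(0.1, 20.0), n_starts: int = 16):
    """Permutation test for a difference in DoG amplitude between groups.

    The observed statistic is amp(b) - amp(a) of grid-profiled DoG fits
    (the same fitting rule and width bounds are applied to every
    permutation).  Labels are shuffled preserving group sizes; the
    one-sided p-value is the proportion of shuffles whose amplitude
    difference is >= the observed one.  Returns ``(p, observed_diff)``.
    """
    xa, ya = (np.asarray(v, float) for v in xy_a)
    xb, yb = (np.asarray(v, float) for v in xy_b)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both groups must be non-empty")
    w_grid = np.geomspace(w_bounds[0], w_bounds[1], n_starts)

    def amp(x, y):
        a, _, _ = _dog_grid_fit(x, y, w_grid, DOG_C)
        return a

    observed = amp(xb, yb) - amp(xa, ya)
    x_all = np.concatenate([xa, xb])
    y_all = np.concatenate([ya, yb])
    na = xa.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    failures = 0
    for i in range(n_perm):
        perm = rng.permutation(x_all.size)
        try:
            null[i] = amp(x_all[perm[na:]], y_all[perm[na:]]) - \
                amp(x_all[perm[:na]], y_all[perm[:na]])
        except Exception:
            null[i] = np.nan
            failures += 1
    if failures > 0.01 * n_perm:
        raise RuntimeError(f"DoG fit failed in {failures}/{n_perm} permutations")
    p = float(np.nanmean(null >= observed))
    return p, float(observed)


def error_histogram(errors, n_bins: int = 31):
    """Histogram of errors over (-pi, pi] with the standard 31 bins.

    Returns ``(counts, edges)``.
    """
    errors = np.asarray(errors, dtype=float)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(errors, bins=edges)
    return counts, edges
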