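"""Synthetic session generators for the delayed-estimation paradigms.

Each generator emits a :class:`SessionSpec` — the per-trial schedule of
set size, stimulus angles, probe, cue, retention interval (RI) and
intertrial interval (ITI) — emulating one of the experimental designs
the model addresses:

* set-size / prioritization: M in {1,2,4,8}, one cued location probed
  3x as often as the others;
* timing: M=6 color stimuli with factorial RI {1, 3} s x ITI {1, 7.5} s;
* serial dependence: single item, RI in {0,1,3,6,10} s and ITI in
  {1,3,6,10} s varied over blocks;
* biased colors: two items drawn from four equally spaced bumps of
  width pi/9, RI 0.5 or 4 s;
* oculomotor delayed response: single item at one of 8 locations.

Also provides model-free synthetic behavior and spike-count tables with
known ground truth, used to validate the analysis modules in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import dog_curve
from .channel import wrap_angle

__all__ = [
    "SessionSpec",
    "SyntheticBehaviorSpec",
    "gen_setsize_session",
    "gen_timing_session",
    "gen_serialdep_session",
    "gen_biased_color_session",
    "gen_odr_session",
    "sample_bump_mixture",
    "gen_synthetic_behavior",
    "gen_synthetic_spikes",
]


@dataclass
class SessionSpec:
    """Per-trial schedule of one synthetic session.

    ``stimuli`` is (n_trials, M_max) with NaN in unused slots;
    ``cued_index`` is -1 on trials without a cue.  ``priority`` is the
    relative probing weight of the cued item (1 = no prioritization).
    """

    n_trials: int
    set_size: np.ndarray
    stimuli: np.ndarray
    probe_index: np.ndarray
    cued_index: np.ndarray
    ri: np.ndarray
    iti: np.ndarray
    priority: float = 1.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.n_trials
        for name in ("set_size", "probe_index", "cued_index", "ri", "iti"):
            arr = np.asarray(getattr(self, name))
            if arr.shape == ():
                arr = np.full(n, arr.item())
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length n_trials (or be scalar)")
            setattr(self, name, arr)
        self.stimuli = np.atleast_2d(np.asarray(self.stimuli, dtype=float))
        if self.stimuli.shape[0] != n:
            raise ValueError("stimuli must have n_trials rows")


def _uniform_angles(rng, size):
    return rng.uniform(-np.pi, np.pi, size=size)


def gen_setsize_session(n_trials: int, set_sizes=(1, 2, 4, 8), priority: float = 3.0,
                        seed: int = 0) -> SessionSpec:
    """Set-size/prioritization design: random M per trial, one cued item.

    The cued location is ``priority`` times as likely to be probed as
    each uncued location (probe probabilities pi_m proportional to the
    priority weights).  Stimuli are i.i.d. uniform on [-pi, pi).
    """
    rng = np.random.default_rng(seed)
    set_sizes = np.asarray(set_sizes, dtype=int)
    m_max = int(set_sizes.max())
    M = rng.choice(set_sizes, size=n_trials)
    stimuli = np.full((n_trials, m_max), np.nan)
    probe = np.zeros(n_trials, dtype=int)
    cued = np.full(n_trials, -1, dtype=int)
    for t in range(n_trials):
        m = M[t]
        stimuli[t, :m] = _uniform_angles(rng, m)
        cued[t] = rng.integers(m)
        weights = np.ones(m)
        weights[cued[t]] = priority
        probe[t] = rng.choice(m, p=weights / weights.sum())
    return SessionSpec(n_trials, M, stimuli, probe, cued,
                       ri=np.full(n_trials, 1.0), iti=np.full(n_trials, 1.0),
                       priority=priority, seed=seed,
                       meta={"design": "setsize"})


def _balanced_cells(n_trials: int, cells: list, blocked: bool) -> np.ndarray:
    """Assign each trial a condition cell, counts balanced within 1."""
    base = n_trials // len(cells)
    counts = np.full(len(cells), base)
    counts[: n_trials - base * len(cells)] += 1
    idx = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    if not blocked:
        idx = np.sort(idx)  # already sorted; kept for clarity
    return idx


def gen_timing_session(n_trials: int, ri_levels=(1.0, 3.0), iti_levels=(1.0, 7.5),
                       M: int = 6, seed: int = 0) -> SessionSpec:
    """Timing design: M simultaneous items, factorial RI x ITI in blocks.

    The four timing cells get per-cell trial counts balanced within one
    trial and are run as contiguous blocks (the intervals were varied
    across sessions in the source design, so gain adaptation sees each
    cell as a stable regime).
    """
    rng = np.random.default_rng(seed)
    cells = [(ri, iti) for ri in ri_levels for iti in iti_levels]
    cell_of = _balanced_cells(n_trials, cells, blocked=True)
    ri = np.array([cells[i][0] for i in cell_of])
    iti = np.array([cells[i][1] for i in cell_of])
    stimuli = _uniform_angles(rng, (n_trials, M))
    probe = rng.integers(M, size=n_trials)
    return SessionSpec(n_trials, np.full(n_trials, M), stimuli, probe,
                       np.full(n_trials, -1), ri, iti, priority=1.0, seed=seed,
                       meta={"design": "timing", "cells": cells})


def gen_serialdep_session(n_trials: int, ri_levels=(0.0, 1.0, 3.0, 6.0, 10.0),
                          iti_levels=(1.0,), M: int = 1, seed: int = 0) -> SessionSpec:
    """Serial-dependence design: single item, intervals varied over blocks."""
    rng = np.random.default_rng(seed)
    cells = [(ri, iti) for ri in ri_levels for iti in iti_levels]
    cell_of = _balanced_cells(n_trials, cells, blocked=True)
    ri = np.array([cells[i][0] for i in cell_of])
    iti = np.array([cells[i][1] for i in cell_of])
    stimuli = _uniform_angles(rng, (n_trials, M))
    probe = rng.integers(M, size=n_trials)
    return SessionSpec(n_trials, np.full(n_trials, M), stimuli, probe,
                       np.full(n_trials, -1), ri, iti, priority=1.0, seed=seed,
                       meta={"design": "serialdep", "cells": cells})


def bump_centers(n_bumps: int = 4, offset: float = 0.0) -> np.ndarray:
    return wrap_angle(-np.pi + 2.0 * np.pi * np.arange(n_bumps) / n_bumps + offset)


def sample_bump_mixture(rng, size, centers, width: float = math.pi / 9) -> np.ndarray:
    """Sample from an equal mixture of uniform arcs of the given width."""
    if width <= 0:
        raise ValueError("bump width must be positive")
    centers = np.asarray(centers, dtype=float)
    which = rng.integers(len(centers), size=size)
    return wrap_angle(centers[which] + rng.uniform(-width / 2, width / 2, size=size))


def gen_biased_color_session(n_trials: int, n_bumps: int = 4, width: float = math.pi / 9,
                             M: int = 2, ri_levels=(0.5, 4.0), iti: float = 1.0,
                             bump_offset: float = 0.0, seed: int = 0) -> SessionSpec:
    """Biased-distribution design: stimuli from four equally spaced bumps.

    Bump centers are constant within the session; the RI is drawn per
    trial from ``ri_levels``.  The probe is uniform over the M items.
    """
    rng = np.random.default_rng(seed)
    centers = bump_centers(n_bumps, bump_offset)
    stimuli = sample_bump_mixture(rng, (n_trials, M), centers, width)
    ri = rng.choice(np.asarray(ri_levels, float), size=n_trials)
    probe = rng.integers(M, size=n_trials)
    return SessionSpec(n_trials, np.full(n_trials, M), stimuli, probe,
                       np.full(n_trials, -1), ri, np.full(n_trials, float(iti)),
                       priority=1.0, seed=seed,
                       meta={"design": "bias", "bump_centers": centers, "bump_width": width})


def gen_odr_session(n_trials: int, n_locations: int = 8, ri: float = 3.0,
                    iti: float = 3.0, seed: int = 0) -> SessionSpec:
    """Oculomotor delayed response: one item at one of 8 fixed locations."""
    rng = np.random.default_rng(seed)
    locations = wrap_angle(-np.pi + 2.0 * np.pi * np.arange(n_locations) / n_locations)
    stimuli = rng.choice(locations, size=(n_trials, 1))
    complete = len(np.unique(stimuli)) == n_locations
    return SessionSpec(n_trials, np.ones(n_trials, dtype=int), stimuli,
                       np.zeros(n_trials, dtype=int), np.full(n_trials, -1),
                       np.full(n_trials, float(ri)), np.full(n_trials, float(iti)),
                       priority=1.0, seed=seed,
                       meta={"design": "odr", "locations": locations,
                             "all_locations_shown": complete})


@dataclass(frozen=True)
class SyntheticBehaviorSpec:
    """Ground-truth response model for model-free behavioral fixtures.

    Responses are target + von Mises noise (concentration ``kappa``) +
    a DoG-shaped attraction of amplitude ``dog_a`` and width ``dog_w``
    toward the previous trial's target, plus an optional static bias
    field (callable angle -> bias).
    """

    kappa: float = 8.0
    dog_a: float = 0.0
    dog_w: float = 1.5
    bias_fn: object = None
    n_subjects: int = 1
    n_trials: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("concentration must be positive")


def gen_synthetic_behavior(spec: SyntheticBehaviorSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a behavioral TrialTable from a known response model.

    Returns ``(table, truth)`` where ``truth`` records the generating
    parameters for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for s in range(spec.n_subjects):
        targets = _uniform_angles(rng, spec.n_trials)
        noise = rng.vonmises(0.0, spec.kappa, size=spec.n_trials)
        resp = targets + noise
        prev_offset = np.full(spec.n_trials, np.nan)
        prev_offset[1:] = wrap_angle(targets[:-1] - targets[1:])
        if spec.dog_a != 0.0:
            pull = np.where(np.isnan(prev_offset), 0.0,
                            dog_curve(np.nan_to_num(prev_offset), spec.dog_a, spec.dog_w))
            resp = resp + pull
        if spec.bias_fn is not None:
            resp = resp + np.asarray(spec.bias_fn(targets), dtype=float)
        resp = wrap_angle(resp)
        for t in range(spec.n_trials):
            rows.append({
                "session": s, "trial": t, "set_size": 1, "stim_1": targets[t],
                "probe_index": 0, "cued": 0, "ri_s": 1.0, "iti_s": 1.0,
                "target": targets[t], "response": resp[t],
                "error": float(wrap_angle(resp[t] - targets[t])),
                "zero_spike_flag": 0, "beta": np.nan,
            })
    truth = {"kappa": spec.kappa, "dog_a": spec.dog_a, "dog_w": spec.dog_w}
    return pd.DataFrame(rows), truth


def gen_synthetic_spikes(n_neurons: int = 20, n_trials: int = 500,
                         n_locations: int = 8, amp_range=(5.0, 15.0),
                         width_range=(0.5, 2.0), beta_range=(0.5, 2.5),
                         history_coef: float = 0.0, history_decay: float = 0.8,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic spike counts from a known tuning/gain generative model.

    Per neuron, counts on trial j are Poisson with

        log lambda_j = a0 + beta * (-D_j) + h * ema_j,

    where D_j = -cos(theta_j - phi) is the cosine distortion between the
    trial stimulus and the neuron's preferred angle and ema_j is the
    exponential moving average of its past counts (decay
    ``history_decay``, excluding the current trial).  Returns ``(spikes,
    truth)`` long tables; ``truth`` holds the planted parameters.
    """
    rng = np.random.default_rng(seed)
    locations = wrap_angle(-np.pi + 2.0 * np.pi * np.arange(n_locations) / n_locations)
    stimuli = rng.choice(locations, size=n_trials)
    rows, truth_rows = [], []
    for i in range(n_neurons):
        phi = float(rng.uniform(-np.pi, np.pi))
        amp = float(rng.uniform(*amp_range))
        width = float(rng.uniform(*width_range))
        beta = float(rng.uniform(*beta_range))
        a0 = float(np.log(amp))
        ema = 0.0
        for j in range(n_trials):
            D = -np.cos(stimuli[j] - phi)
            # rate guard: the count -> ema -> rate loop is a positive
            # feedback for history_coef > 0; cap keeps it bounded
            lam = min(np.exp(a0 - beta * D + history_coef * ema), 1e3)
            count = int(rng.poisson(lam))
            rows.append({"neuron_id": i, "session": 0, "trial": j,
                         "stimulus": float(stimuli[j]), "spike_count": count})
            ema = history_decay * ema + (1.0 - history_decay) * count
        truth_rows.append({"neuron_id": i, "phi": phi, "amp": amp, "width": width,
                           "beta": beta, "history_coef": history_coef,
                           "intercept": a0})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
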