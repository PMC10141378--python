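"""Independent brute-force oracles used by the test suite.

Everything here is written against the mathematical definitions only —
plain Python loops, itertools enumeration and scipy densities — and never
calls the implementation paths it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm


def round_half_away_scalar(v: float) -> int:
    """Nearest integer, ties away from zero (pure-Python reference)."""
    if v < 0:
        return -int(math.floor(-v + 0.5))
    return int(math.floor(v + 0.5))


def unique_cells(xs, ys, cell_size: float) -> set[tuple[int, int]]:
    """Per-sample grid cells as a set, via the scalar rounding reference."""
    return {
        (round_half_away_scalar(x / cell_size), round_half_away_scalar(y / cell_size))
        for x, y in zip(xs, ys)
    }


def path_length(xs, ys) -> float:
    return sum(
        math.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])
        for i in range(len(xs) - 1)
    )


def wandering_style(xs, ys, cell_size: float) -> float:
    length = path_length(xs, ys)
    if length == 0.0:
        return 0.0
    return len(unique_cells(xs, ys, cell_size)) / length


def cell_dwell_tally(ts, xs, ys, cell_size: float) -> dict[tuple[int, int], float]:
    """Dwell per cell by a per-sample loop (interval charged to its start)."""
    dwell: dict[tuple[int, int], float] = {}
    for i in range(len(ts) - 1):
        cell = (
            round_half_away_scalar(xs[i] / cell_size),
            round_half_away_scalar(ys[i] / cell_size),
        )
        dwell[cell] = dwell.get(cell, 0.0) + (ts[i + 1] - ts[i])
    return dwell


def hmm_path_logprob(startprob, transmat, means, variances, obs, path) -> float:
    """Log joint probability of one hidden path and the observations."""
    lp = math.log(startprob[path[0]])
    for t in range(1, len(path)):
        lp += math.log(transmat[path[t - 1], path[t]])
    for t, state in enumerate(path):
        lp += float(
            norm.logpdf(obs[t], means[state], np.sqrt(variances[state])).sum()
        )
    return lp


def enumerate_paths(n_states: int, T: int):
    return itertools.product(range(n_states), repeat=T)


def _emission_logprobs(means, variances, obs) -> np.ndarray:
    """Per-(window, state) Gaussian log-density table, shape (T, K)."""
    return norm.logpdf(
        obs[:, None, :], means[None, :, :], np.sqrt(variances)[None, :, :]
    ).sum(axis=-1)


def _path_logprob_from_table(startprob, transmat, E, path) -> float:
    lp = math.log(startprob[path[0]]) + E[0, path[0]]
    for t in range(1, len(path)):
        lp += math.log(transmat[path[t - 1], path[t]]) + E[t, path[t]]
    return lp


def brute_force_forward(startprob, transmat, means, variances, obs) -> float:
    """Log-likelihood by summing over every hidden path."""
    E = _emission_logprobs(means, variances, obs)
    lps = [
        _path_logprob_from_table(startprob, transmat, E, path)
        for path in enumerate_paths(len(startprob), obs.shape[0])
    ]
    return float(logsumexp(lps))


def brute_force_viterbi(startprob, transmat, means, variances, obs):
    """Most probable hidden path by exhaustive argmax."""
    E = _emission_logprobs(means, variances, obs)
    best_lp, best_path = -math.inf, None
    for path in enumerate_paths(len(startprob), obs.shape[0]):
        lp = _path_logprob_from_table(startprob, transmat, E, path)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return list(best_path), best_lp
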