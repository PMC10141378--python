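"""Six-level behavioural stress decoding with a Gaussian HMM.

Windowed feature vectors (moving time, track spread, wandering style,
hotspot spread) are modelled as emissions of a hidden Markov chain with six
states, interpreted as ordered stress levels 0 (very low) to 5 (very
high).  The model is fit unsupervised by Baum–Welch on z-scored features
(diagonal Gaussian emissions, several random restarts, best log-likelihood
kept), then the states are relabelled so that level increases with
movement: ascending moving-time mean first (rounded to 0.1 s, since moving
time saturates at the window length once a regime's speed clears the
threshold), ties broken by ascending track-spread mean, which grows
strictly with movement speed.

Decoded levels map onto a [0, 1] stress score via ``level / 5``, averaged
over windows; the per-subject default uses the posterior-expected level,
giving a continuous score rather than a multiple of 1/5.

The heavy lifting (EM, Viterbi, forward–backward) is delegated to
hmmlearn's ``GaussianHMM``; this module owns standardisation, restarts,
state ordering, serialization and the score mapping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .errors import ValidationError
from .features import FEATURE_NAMES, FeatureVector

logger = logging.getLogger(__name__)

N_STATES = 6
_VAR_FLOOR = 1e-6
_SELECTION_VAR_FLOOR = 1e-4  # z-space, used when ranking restarts
_SERIAL_VERSION = 1


def as_feature_array(sequence) -> np.ndarray:
    """Coerce a window sequence (FeatureVectors or array) to ``(T, 4)`` floats."""
    if isinstance(sequence, np.ndarray):
        arr = np.asarray(sequence, dtype=float)
    else:
        seq = list(sequence)
        if seq and isinstance(seq[0], FeatureVector):
            arr = np.array([fv.as_array() for fv in seq])
        else:
            arr = np.asarray(seq, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise ValidationError(
            f"expected a (T, {len(FEATURE_NAMES)}) feature sequence, got shape {arr.shape}"
        )
    return arr


@dataclass
class StressHMM:
    """A fitted 6-state stress model, states already in level order.

    Parameters are stored in z-scored feature space together with the
    scaler (``feature_mean``, ``feature_scale``), so the model is
    self-contained.  ``state_order`` records the permutation applied to the
    raw fitted states (``state_order[level] = raw state``), for provenance.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    means_z: np.ndarray
    vars_z: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    state_order: np.ndarray
    log_likelihood: float = float("nan")
    n_states: int = N_STATES

    def __post_init__(self) -> None:
        rows = self.transmat.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValidationError("StressHMM: transition rows must sum to 1")
        if not np.all(self.vars_z > 0):
            raise ValidationError("StressHMM: emission variances must be positive")
        if sorted(self.state_order.tolist()) != list(range(self.n_states)):
            raise ValidationError("StressHMM: state_order must be a permutation")

    @property
    def emission_means(self) -> np.ndarray:
        """Per-level emission means in original feature units, ``(6, 4)``."""
        return self.means_z * self.feature_scale + self.feature_mean

    def _hmm(self) -> GaussianHMM:
        m = GaussianHMM(n_components=self.n_states, covariance_type="diag")
        m.n_features = self.means_z.shape[1]
        m.startprob_ = self.startprob.copy()
        m.transmat_ = self.transmat.copy()
        m.means_ = self.means_z.copy()
        m.covars_ = self.vars_z.copy()
        return m

    def standardize(self, sequence) -> np.ndarray:
        x = as_feature_array(sequence)
        return (x - self.feature_mean) / self.feature_scale

    def to_json(self, path) -> None:
        payload = {
            "format_version": _SERIAL_VERSION,
            "model": "stress-hmm-gaussian-diag",
            "n_states": self.n_states,
            "feature_names": list(FEATURE_NAMES),
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means_z": self.means_z.tolist(),
            "vars_z": self.vars_z.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "state_order": self.state_order.tolist(),
            "log_likelihood": self.log_likelihood,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StressHMM":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != _SERIAL_VERSION:
            raise ValidationError(
                f"{path}: unsupported model format version "
                f"{payload.get('format_version')!r}"
            )
        return cls(
            startprob=np.array(payload["startprob"]),
            transmat=np.array(payload["transmat"]),
            means_z=np.array(payload["means_z"]),
            vars_z=np.array(payload["vars_z"]),
            feature_mean=np.array(payload["feature_mean"]),
            feature_scale=np.array(payload["feature_scale"]),
            state_order=np.array(payload["state_order"], dtype=int),
            log_likelihood=float(payload["log_likelihood"]),
            n_states=int(payload["n_states"]),
        )


@dataclass
class StressTrace:
    """Decoded stress for one window sequence.

    ``levels`` holds the per-window level (Viterbi path in ``viterbi``
    mode, posterior argmax in ``posterior`` mode); ``posteriors`` the
    forward–backward state probabilities, one row per window, columns in
    level order.
    """

    levels: np.ndarray
    posteriors: np.ndarray
    mode: str
    log_likelihood: float = float("nan")

    @property
    def expected_levels(self) -> np.ndarray:
        """Posterior mean level per window, a float in [0, 5]."""
        return self.posteriors @ np.arange(self.posteriors.shape[1])


def _order_states(means_orig: np.ndarray) -> np.ndarray:
    """Permutation putting states in ascending stress order.

    Key: moving-time mean rounded to 0.1 s, then track-spread mean.
    """
    key = [(round(m[0], 1), m[1]) for m in means_orig]
    return np.array(sorted(range(len(key)), key=lambda s: key[s]), dtype=int)


def fit_hmm(
    sequences: Iterable,
    seed: int = 0,
    n_init: int = 10,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> StressHMM:
    """Baum–Welch fit of the 6-state model over one or more sequences.

    Features are z-scored over the pooled training windows (a feature with
    zero variance gets unit scale and its emission variance floored, with a
    logged warning).  The likelihood surface is multimodal, so the search
    runs ``max(4 * n_init, 24)`` short EM runs from diverse initialisations
    and then full EM from the eight most promising; all randomness flows
    from ``seed``, so refitting with the same seed reproduces the same
    parameters bit for bit.
    """
    seqs = [as_feature_array(s) for s in sequences]
    seqs = [s for s in seqs if s.shape[0] > 0]
    if not seqs or max(s.shape[0] for s in seqs) < 2:
        raise ValidationError("fit_hmm: need at least one sequence with >=2 windows")
    X = np.vstack(seqs)
    lengths = [s.shape[0] for s in seqs]

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale < 1e-12
    if degenerate.any():
        names = [FEATURE_NAMES[i] for i in np.flatnonzero(degenerate)]
        logger.warning(
            "fit_hmm: zero variance in feature(s) %s; scale set to 1 and "
            "emission variance floored at %g", names, _VAR_FLOOR,
        )
        scale = np.where(degenerate, 1.0, scale)
    Z = (X - mean) / scale

    # Baum-Welch is multimodal here, so the search runs in two stages:
    # many diverse short EM runs, then full EM from the most promising
    # starts.  Restarts are ranked by log-likelihood with every variance
    # floored equally — Gaussian likelihoods are unbounded as a state's
    # variance collapses onto a few points, and the floor caps such
    # degenerate spikes without penalising genuinely tight states.
    rng = np.random.default_rng(seed)
    n_short = max(4 * n_init, 24)

    def make_model(restart: int, iters: int) -> GaussianHMM:
        rs = int(rng.integers(0, 2**31 - 1))
        m = GaussianHMM(
            n_components=N_STATES,
            covariance_type="diag",
            n_iter=iters,
            tol=tol,
            random_state=rs,
            min_covar=1e-3,
        )
        if restart == 1:
            # ordered-level init: cluster the 1-D movement index (z-scored
            # moving time + track spread) into 6 intervals and start each
            # state at its interval's 4-D centroid
            m.init_params = "stc"
            m.means_ = _ordered_index_means(Z, rs)
        elif restart > 1:
            # hmmlearn's own k-means init is nearly seed-independent, so
            # the remaining restarts draw well-spread means via kmeans++
            from sklearn.cluster import kmeans_plusplus

            centers, _ = kmeans_plusplus(Z, N_STATES, random_state=rs)
            m.init_params = "stc"
            m.means_ = centers
        return m

    def floored_ll(m: GaussianHMM) -> float:
        m.covars_ = np.maximum(_diag_covars(m), _SELECTION_VAR_FLOOR)
        return float(m.score(Z, lengths))

    candidates: list[tuple[float, GaussianHMM]] = []
    for restart in range(n_short):
        m = make_model(restart, iters=15)
        try:
            m.fit(Z, lengths)
            candidates.append((floored_ll(m), m))
        except (ValueError, np.linalg.LinAlgError) as exc:  # degenerate restart
            logger.warning("fit_hmm: short restart failed (%s); continuing", exc)
    if not candidates:
        raise ValidationError("fit_hmm: all restarts failed")
    candidates.sort(key=lambda c: -c[0])

    best: GaussianHMM | None = None
    best_ll = -np.inf
    for _, warm in candidates[:8]:
        m = GaussianHMM(
            n_components=N_STATES,
            covariance_type="diag",
            n_iter=n_iter,
            tol=tol,
            init_params="",
            min_covar=1e-3,
        )
        m.startprob_ = warm.startprob_
        m.transmat_ = warm.transmat_
        m.means_ = warm.means_
        m.covars_ = np.maximum(_diag_covars(warm), _VAR_FLOOR)
        try:
            m.fit(Z, lengths)
            ll = floored_ll(m)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("fit_hmm: refinement failed (%s); continuing", exc)
            continue
        if ll > best_ll:
            best, best_ll = m, ll
    if best is None:
        raise ValidationError("fit_hmm: all refinement runs failed")

    vars_z = np.maximum(_diag_covars(best), _VAR_FLOOR)
    means_orig = best.means_ * scale + mean
    order = _order_states(means_orig)
    return StressHMM(
        startprob=best.startprob_[order],
        transmat=best.transmat_[np.ix_(order, order)],
        means_z=best.means_[order],
        vars_z=vars_z[order],
        feature_mean=mean,
        feature_scale=scale,
        state_order=order,
        log_likelihood=float(best_ll),
    )


def _ordered_index_means(Z: np.ndarray, random_state: int) -> np.ndarray:
    """State means from 1-D k-means on the movement index ``z_mt + z_ts``."""
    from sklearn.cluster import KMeans

    index = (Z[:, 0] + Z[:, 1]).reshape(-1, 1)
    km = KMeans(N_STATES, n_init=10, random_state=random_state).fit(index)
    order = np.argsort(km.cluster_centers_[:, 0])
    return np.array([Z[km.labels_ == k].mean(axis=0) for k in order])


def _diag_covars(model: GaussianHMM) -> np.ndarray:
    # hmmlearn's covars_ getter expands diag models to full matrices
    c = np.asarray(model.covars_)
    if c.ndim == 3:
        c = np.diagonal(c, axis1=1, axis2=2)
    return np.array(c, dtype=float)


def decode_stress(
    model: StressHMM,
    sequence,
    mode: Literal["viterbi", "posterior"] = "viterbi",
) -> StressTrace:
    """Decode a window sequence into per-window stress levels.

    ``viterbi`` returns the jointly most probable level path; ``posterior``
    returns per-window forward–backward posteriors with the argmax level.
    Posteriors are computed in both modes.
    """
    if mode not in ("viterbi", "posterior"):
        raise ValidationError(f"decode_stress: unknown mode {mode!r}")
    if not isinstance(model, StressHMM):
        raise ValidationError("decode_stress: model is not a fitted StressHMM")
    Z = model.standardize(sequence)
    if Z.shape[0] == 0:
        raise ValidationError("decode_stress: empty sequence")
    hmm = model._hmm()
    post = hmm.predict_proba(Z)
    ll = float(hmm.score(Z))
    if mode == "viterbi":
        levels = hmm.predict(Z)
    else:
        levels = post.argmax(axis=1)
    return StressTrace(
        levels=np.asarray(levels, dtype=int),
        posteriors=post,
        mode=mode,
        log_likelihood=ll,
    )


def forward_log_likelihood(model: StressHMM, sequence) -> float:
    """Log-likelihood of a sequence under the model (forward algorithm)."""
    Z = model.standardize(sequence)
    return float(model._hmm().score(Z))


def stress_score(
    trace: StressTrace,
    mode: Literal["expected_level", "mode_level"] = "expected_level",
) -> float:
    """Collapse a decoded trace to one stress score in [0, 1].

    Level ``k`` maps to ``k / 5``.  ``mode_level`` averages the mapped
    discrete levels over windows; ``expected_level`` (default) averages the
    posterior-expected level divided by 5, giving a continuous score.
    """
    if trace.levels.size == 0:
        raise ValidationError("stress_score: empty trace")
    top = trace.posteriors.shape[1] - 1
    if mode == "mode_level":
        return float(trace.levels.mean() / top)
    if mode == "expected_level":
        return float(trace.expected_levels.mean() / top)
    raise ValidationError(f"stress_score: unknown mode {mode!r}")
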