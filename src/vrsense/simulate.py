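"""Seed-controlled synthetic VR sessions: trajectories and labels.

Movement is a regime-switching correlated random walk.  Each of six
regimes represents one stress level and sets a mean walking speed, a speed
SD, and a heading persistence (1 = perfectly straight, 0 = near-uniform
random turning).  Higher levels walk strictly faster and turn more
erratically — calm subjects amble smoothly, stressed subjects rush about —
which is the behavioural contrast the feature extractor and stress HMM are
designed to pick up.  The regime switches between tumbling feature windows
according to a sticky Markov chain, so the ground-truth level is constant
within each window and can be compared with the decoded level one-to-one.

Sentiment labels are drawn per hotspot and viewing direction from
configurable 3-class distributions (valence uniform by default; arousal
biased towards calm, mirroring a quiet exploratory session).

All randomness derives from the single session seed through documented
``numpy`` seed-sequence streams — ``[seed, 1, subject_index]`` for each
trajectory, ``[seed, 2]`` for labels — so any subset of a session is
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import VRSenseError, ValidationError
from .features import window_features
from .sentiment import (
    Arousal,
    ScreenshotLabel,
    SentimentClass,
    Valence,
    write_labels,
)
from .trajectory import Trajectory, write_trajectories

logger = logging.getLogger(__name__)

_STREAM_TRAJ = 1
_STREAM_LABELS = 2


@dataclass(frozen=True)
class RegimeSpec:
    """Movement statistics of one stress level."""

    level: int
    mean_speed: float  # m/s
    speed_sd: float  # m/s
    heading_persistence: float  # 1 = straight, 0 = uniform random turns
    dwell_bias: tuple[int, int] | None = None  # optional attractor cell

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValidationError("RegimeSpec: speeds must be non-negative")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise ValidationError("RegimeSpec: heading_persistence must be in [0, 1]")


#: Default six-level ladder.  Speeds rise strictly with level; the speed
#: SDs keep adjacent levels at least 3 SDs apart, and persistence falls so
#: higher levels are both faster and more erratic.
DEFAULT_REGIMES: tuple[RegimeSpec, ...] = (
    RegimeSpec(0, 0.05, 0.015, 0.99),
    RegimeSpec(1, 0.13, 0.012, 0.98),
    RegimeSpec(2, 0.35, 0.030, 0.97),
    RegimeSpec(3, 0.50, 0.050, 0.96),
    RegimeSpec(4, 0.75, 0.080, 0.95),
    RegimeSpec(5, 1.00, 0.080, 0.94),
)


@dataclass
class SessionSpec:
    """Everything needed to generate one synthetic session."""

    n_subjects: int = 10
    duration_s: float = 300.0
    sample_rate_hz: float = 10.0
    regimes: tuple[RegimeSpec, ...] = DEFAULT_REGIMES
    regime_stay_prob: float = 0.9  # per window; remainder split uniformly
    dt_jitter: float = 0.15  # frame jitter, fraction of the nominal period
    window_s: float = 5.0
    n_hotspots: int = 5
    n_directions: int = 4
    valence_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    arousal_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("SessionSpec: duration must be positive")
        if self.n_subjects < 1 or self.sample_rate_hz <= 0:
            raise ValidationError("SessionSpec: need >=1 subject and a positive rate")
        for probs in (self.valence_probs, self.arousal_probs):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValidationError(f"SessionSpec: class probs {probs!r} must sum to 1")
        if not 0.0 < self.regime_stay_prob <= 1.0:
            raise ValidationError("SessionSpec: regime_stay_prob must be in (0, 1]")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _regime_chain(
    rng: np.random.Generator, n_windows: int, n_regimes: int, stay: float
) -> np.ndarray:
    probs = np.full((n_regimes, n_regimes), (1.0 - stay) / max(n_regimes - 1, 1))
    np.fill_diagonal(probs, stay if n_regimes > 1 else 1.0)
    out = np.empty(n_windows, dtype=int)
    out[0] = rng.integers(n_regimes)
    for w in range(1, n_windows):
        out[w] = rng.choice(n_regimes, p=probs[out[w - 1]])
    return out


def simulate_trajectory(
    spec: SessionSpec, subject_index: int
) -> tuple[Trajectory, np.ndarray]:
    """One subject's correlated-random-walk trajectory plus ground truth.

    Sample times carry frame jitter (gaps uniform within ±``dt_jitter`` of
    the nominal period), as real headset telemetry never ticks perfectly;
    downstream code must cope with irregular sampling, and the jitter also
    keeps windowed features continuous rather than lattice-valued.  The
    regime is constant within each feature window by construction, and the
    true level per window is returned alongside the trajectory.
    """
    rng = _rng(spec.seed, _STREAM_TRAJ, subject_index)
    dt = 1.0 / spec.sample_rate_hz
    n_windows = int(np.floor(spec.duration_s / spec.window_s))
    if n_windows == 0 or spec.window_s * spec.sample_rate_hz < 2:
        raise ValidationError(
            "simulate_trajectory: duration shorter than one window, or rate too low"
        )
    regimes = _regime_chain(rng, n_windows, len(spec.regimes), spec.regime_stay_prob)

    # jittered sample times covering all complete windows
    total = n_windows * spec.window_s
    n_gaps = int(np.ceil(total / (dt * (1.0 - spec.dt_jitter)))) + 2
    gaps = rng.uniform(dt * (1.0 - spec.dt_jitter), dt * (1.0 + spec.dt_jitter), n_gaps)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    t = t[: int(np.searchsorted(t, total, side="left")) + 1]  # first sample >= total

    # per-sample regime = regime of the window the sample falls in
    w = np.minimum((t / spec.window_s).astype(int), n_windows - 1)
    r = regimes[w]
    mu = np.array([g.mean_speed for g in spec.regimes])[r]
    sd = np.array([g.speed_sd for g in spec.regimes])[r]
    turn_sd = np.array(
        [(1.0 - g.heading_persistence) * np.pi for g in spec.regimes]
    )[r]

    n = t.size
    turns = rng.normal(0.0, 1.0, n - 1) * turn_sd[:-1]
    headings = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(turns)
    speeds = np.clip(rng.normal(mu[:-1], sd[:-1]), 0.0, None)
    steps = (speeds * np.diff(t))[:, None] * np.column_stack(
        [np.cos(headings), np.sin(headings)]
    )
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

    # optional attractor: re-aim the heading at each window entry
    biased = [g.dwell_bias is not None for g in spec.regimes]
    if any(biased):
        xy = _apply_dwell_bias(spec, regimes, t, xy, speeds, rng)

    traj = Trajectory(f"Subject_{subject_index + 1}", t, xy[:, 0], xy[:, 1])
    return traj, regimes


def _apply_dwell_bias(spec, regimes, t, xy, speeds, rng) -> np.ndarray:
    """Rebuild positions window-by-window, aiming biased regimes at their
    attractor cell on window entry (slow path, only when a bias is set)."""
    out = np.zeros_like(xy)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pos = np.zeros(2)
    bounds = np.searchsorted(t, np.arange(len(regimes) + 1) * spec.window_s, "left")
    for k, r in enumerate(regimes):
        reg = spec.regimes[r]
        lo, hi = bounds[k], min(bounds[k + 1], len(t) - 1)
        if hi <= lo:
            continue
        if reg.dwell_bias is not None:
            target = np.array(reg.dwell_bias, dtype=float) * 0.1
            heading = float(np.arctan2(*(target - pos)[::-1]))
        turn_sd = (1.0 - reg.heading_persistence) * np.pi
        headings = heading + np.cumsum(rng.normal(0.0, turn_sd, hi - lo))
        steps = (speeds[lo:hi] * np.diff(t[lo : hi + 1]))[:, None] * np.column_stack(
            [np.cos(headings), np.sin(headings)]
        )
        out[lo + 1 : hi + 1] = pos + np.cumsum(steps, axis=0)
        pos = out[hi]
        heading = float(headings[-1])
    return out


def simulate_labels(spec: SessionSpec) -> list[ScreenshotLabel]:
    """Random per-hotspot, per-direction sentiment labels for the session."""
    rng = _rng(spec.seed, _STREAM_LABELS)
    val_ladder = (Valence.NEGATIVE, Valence.NEUTRAL, Valence.POSITIVE)
    aro_ladder = (Arousal.CALM, Arousal.NEUTRAL, Arousal.EXCITED)
    out = []
    for s in range(spec.n_subjects):
        for rank in range(1, spec.n_hotspots + 1):
            for d in range(spec.n_directions):
                v = val_ladder[rng.choice(3, p=spec.valence_probs)]
                a = aro_ladder[rng.choice(3, p=spec.arousal_probs)]
                out.append(
                    ScreenshotLabel(f"Subject_{s + 1}", rank, d, SentimentClass(v, a))
                )
    return out


@dataclass
class SessionData:
    """A fully generated session with its ground truth."""

    spec: SessionSpec
    trajectories: dict[str, Trajectory]
    true_regimes: dict[str, np.ndarray]
    labels: list[ScreenshotLabel]


def simulate_session(spec: SessionSpec) -> SessionData:
    trajectories: dict[str, Trajectory] = {}
    true_regimes: dict[str, np.ndarray] = {}
    for i in range(spec.n_subjects):
        traj, regimes = simulate_trajectory(spec, i)
        trajectories[traj.subject_id] = traj
        true_regimes[traj.subject_id] = regimes
    return SessionData(spec, trajectories, true_regimes, simulate_labels(spec))


PRESETS: dict[str, SessionSpec] = {
    "tiny": SessionSpec(n_subjects=1, duration_s=30.0),
    "paperlike": SessionSpec(n_subjects=10, duration_s=300.0),
}


def make_fixture_session(
    preset: str, out_dir, seed: int | None = None
) -> dict[str, Path]:
    """Write a preset session's trajectory and labels CSVs to ``out_dir``.

    Presets: ``tiny`` (1 subject, 30 s — end-to-end smoke) and
    ``paperlike`` (10 subjects, 5 hotspots, 300 s — the published session
    shape).  Regenerating with the same seed is byte-identical.
    """
    if preset not in PRESETS:
        raise VRSenseError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    spec = PRESETS[preset]
    if seed is not None:
        spec = replace(spec, seed=seed)
    session = simulate_session(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj_csv = out_dir / "trajectories.csv"
    labels_csv = out_dir / "labels.csv"
    write_trajectories(session.trajectories, traj_csv)
    write_labels(session.labels, labels_csv)
    logger.info("wrote %s preset to %s", preset, out_dir)
    return {"trajectories": traj_csv, "labels": labels_csv}


def regime_recovery_benchmark(
    n_windows: int = 5000,
    seed: int = 0,
    n_sequences: int = 10,
    spec: SessionSpec | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], SessionSpec]:
    """Feature sequences with ground-truth regimes for recovery studies.

    Generates ``n_sequences`` subjects whose windows total ``n_windows``,
    extracts the behavioural features per window, and returns the feature
    sequences, the true per-window regimes, and the spec used.
    """
    per_seq = int(np.ceil(n_windows / n_sequences))
    base = spec or SessionSpec()
    spec = replace(
        base,
        n_subjects=n_sequences,
        duration_s=per_seq * base.window_s,
        seed=seed,
    )
    sequences, truths = [], []
    for i in range(n_sequences):
        traj, regimes = simulate_trajectory(spec, i)
        fvs = window_features(traj, window=spec.window_s)
        if len(fvs) != regimes.size:
            raise VRSenseError(
                "regime_recovery_benchmark: window/truth misalignment "
                f"({len(fvs)} vs {regimes.size})"
            )
        sequences.append(np.array([fv.as_array() for fv in fvs]))
        truths.append(regimes)
    return sequences, truths, spec


def regime_emission_moments(
    seed: int = 0, n_windows: int = 1000, spec: SessionSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level mean and SD of the windowed features under the generator.

    Measured empirically by simulating trajectories and grouping the
    extracted feature windows by their true regime; this is the "known
    model" used by :func:`sample_hmm_benchmark`.
    """
    seqs, truths, used = regime_recovery_benchmark(n_windows, seed, spec=spec)
    X = np.vstack(seqs)
    t = np.concatenate(truths)
    n_levels = len(used.regimes)
    means = np.array([X[t == k].mean(axis=0) for k in range(n_levels)])
    sds = np.array([X[t == k].std(axis=0) for k in range(n_levels)])
    return means, np.maximum(sds, 1e-3)


def sample_hmm_benchmark(
    n_windows: int = 5000,
    seed: int = 0,
    n_sequences: int = 10,
    stay_prob: float = 0.9,
    moments: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Feature sequences sampled from a known 6-state Gaussian HMM.

    The emission moments default to the movement generator's per-level
    windowed-feature moments (:func:`regime_emission_moments`), and the
    hidden chain uses the same sticky transitions as the session schedule.
    Because the data really are conditionally Gaussian, this is the clean
    parameter-recovery setting for Baum–Welch; the trajectory-derived
    features themselves are *not* Gaussian per regime (moving time has
    atoms at 0 and at the window span, the cell count is lattice-valued),
    which is why end-to-end recovery is checked separately at session
    scale.  Returns sequences, true state paths, and the emission means.
    """
    if moments is None:
        moments = regime_emission_moments(seed=seed)
    means, sds = moments
    # floor each state SD at 2% of the across-level spread so every state
    # of the known model is well-conditioned (no quasi-degenerate peaks)
    # without washing out the separation between adjacent levels
    sds = np.maximum(sds, 0.02 * means.std(axis=0))
    n_levels = means.shape[0]
    rng = _rng(seed, 3)
    per_seq = int(np.ceil(n_windows / n_sequences))
    sequences, truths = [], []
    for _ in range(n_sequences):
        states = _regime_chain(rng, per_seq, n_levels, stay_prob)
        obs = rng.normal(means[states], sds[states])
        sequences.append(obs)
        truths.append(states)
    return sequences, truths, means
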