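import numpy as np
import pytest

import _oracles
from vrsense.errors import ValidationError
from vrsense.simulate import SessionSpec, regime_recovery_benchmark
from vrsense.stress import (
    StressHMM,
    StressTrace,
    decode_stress,
    fit_hmm,
    forward_log_likelihood,
    stress_score,
)


def random_model(rng, separation=2.0):
    """A valid 6-state model with random parameters (identity scaler)."""
    startprob = rng.dirichlet(np.ones(6))
    transmat = rng.dirichlet(np.ones(6), size=6)
    means = rng.normal(0.0, separation, size=(6, 4))
    variances = rng.uniform(0.2, 1.5, size=(6, 4))
    return StressHMM(
        startprob=startprob,
        transmat=transmat,
        means_z=means,
        vars_z=variances,
        feature_mean=np.zeros(4),
        feature_scale=np.ones(4),
        state_order=np.arange(6),
    )


class TestOracleEquivalence:
    @pytest.mark.parametrize("T", [2, 3, 5])
    def test_forward_matches_path_sum(self, rng, T):
        model = random_model(rng)
        obs = rng.normal(0, 2, size=(T, 4))
        ll = forward_log_likelihood(model, obs)
        oracle = _oracles.brute_force_forward(
            model.startprob, model.transmat, model.means_z, model.vars_z, obs
        )
        assert ll == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("T", [2, 4, 6])
    def test_viterbi_matches_exhaustive_argmax(self, rng, T):
        model = random_model(rng)
        obs = rng.normal(0, 2, size=(T, 4))
        trace = decode_stress(model, obs, mode="viterbi")
        path, _ = _oracles.brute_force_viterbi(
            model.startprob, model.transmat, model.means_z, model.vars_z, obs
        )
        assert trace.levels.tolist() == path


class TestDecode:
    def test_posteriors_normalised(self, rng):
        model = random_model(rng)
        trace = decode_stress(model, rng.normal(size=(12, 4)), mode="posterior")
        np.testing.assert_allclose(trace.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_separated_single_state_decodes_constant(self, rng):
        # emissions 5 SD apart: a one-state sequence decodes to that level
        model = random_model(rng)
        model.means_z = np.arange(6)[:, None] * np.ones(4) * 5.0
        model.vars_z = np.ones((6, 4))
        obs = rng.normal(model.means_z[3], 1.0, size=(20, 4))
        trace = decode_stress(model, obs, mode="viterbi")
        assert set(trace.levels.tolist()) == {3}

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValidationError):
            decode_stress(random_model(rng), np.empty((0, 4)))

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValidationError, match="not a fitted"):
            decode_stress(object(), np.zeros((3, 4)))


@pytest.fixture(scope="module")
def small_sequences():
    seqs, _, _ = regime_recovery_benchmark(
        n_windows=120, seed=5, n_sequences=2, spec=SessionSpec()
    )
    return seqs


class TestFit:
    def test_refit_same_seed_identical(self, small_sequences):
        a = fit_hmm(small_sequences, seed=3, n_init=2)
        b = fit_hmm(small_sequences, seed=3, n_init=2)
        np.testing.assert_array_equal(a.means_z, b.means_z)
        np.testing.assert_array_equal(a.transmat, b.transmat)
        np.testing.assert_array_equal(a.state_order, b.state_order)

    def test_fitted_model_is_valid(self, small_sequences):
        m = fit_hmm(small_sequences, seed=3, n_init=2)
        np.testing.assert_allclose(m.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m.vars_z > 0)
        assert sorted(m.state_order.tolist()) == list(range(6))
        # levels ordered by movement: moving-time mean non-decreasing
        mt_means = m.emission_means[:, 0]
        assert np.all(np.round(np.diff(mt_means), 6) >= -0.1)

    def test_degenerate_feature_floored(self, rng):
        # constant hotspot-spread column: variance floored, fit still valid
        seqs = [np.column_stack([
            rng.normal(2, 1, 40), rng.normal(1, 0.5, 40),
            rng.normal(10, 2, 40), np.zeros(40),
        ])]
        m = fit_hmm(seqs, seed=0, n_init=2)
        assert np.all(m.vars_z > 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            fit_hmm([np.zeros((1, 4))], seed=0)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        model = random_model(rng)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = StressHMM.from_json(path)
        np.testing.assert_array_equal(back.means_z, model.means_z)
        np.testing.assert_array_equal(back.transmat, model.transmat)
        obs = rng.normal(size=(8, 4))
        assert forward_log_likelihood(back, obs) == pytest.approx(
            forward_log_likelihood(model, obs)
        )

    def test_unknown_version_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValidationError, match="version"):
            StressHMM.from_json(path)


class TestStressScore:
    def trace(self, levels, posteriors=None):
        levels = np.asarray(levels, dtype=int)
        if posteriors is None:
            posteriors = np.zeros((levels.size, 6))
            posteriors[np.arange(levels.size), levels] = 1.0
        return StressTrace(levels=levels, posteriors=posteriors, mode="viterbi")

    def test_bounds(self):
        assert stress_score(self.trace([0, 0, 0]), "mode_level") == 0.0
        assert stress_score(self.trace([5, 5]), "mode_level") == 1.0

    def test_uniform_posterior_is_half(self):
        tr = self.trace([0, 0], posteriors=np.full((2, 6), 1 / 6))
        assert stress_score(tr, "expected_level") == pytest.approx(0.5)

    def test_level_mapping_is_fifths(self):
        assert stress_score(self.trace([2]), "mode_level") == pytest.approx(2 / 5)

    def test_monotone_in_levels(self, rng):
        levels = rng.integers(0, 5, size=10)  # headroom to raise by one
        lo = stress_score(self.trace(levels), "mode_level")
        hi = stress_score(self.trace(levels + 1), "mode_level")
        assert hi > lo

    def test_empty_trace_rejected(self):
        with pytest.raises(ValidationError):
            stress_score(self.trace([]))
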