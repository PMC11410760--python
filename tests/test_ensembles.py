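import numpy as np
import pytest

from pretextnet.ensembles import (
    AFEnsembleModel,
    EnsembleWeights,
    PredictionSet,
    apply_weights,
    build_af_ensemble,
    fit_slsqp_weights,
    log_loss,
    simple_average,
    train_af_ensemble,
)
from pretextnet.sharp_unet import build_restorer
from pretextnet.transfer import (
    ClassifierTrainConfig,
    build_classifier,
    fine_tune,
    truncate_encoder,
)


def _pred_set(probs, labels, names=None):
    probs = np.asarray(probs, dtype=np.float64)
    logits = np.log(np.clip(probs, 1e-9, None))
    names = names or [f"m{i}" for i in range(probs.shape[0])]
    return PredictionSet(names, probs, logits, np.asarray(labels))


class TestSimpleAverage:
    def test_arithmetic_mean(self):
        ps = _pred_set(
            [[[0.8, 0.2]], [[0.6, 0.4]]],
            [0],
        )
        assert np.allclose(simple_average(ps), [[0.7, 0.3]])

    def test_identical_members_unchanged(self, rng):
        p = rng.dirichlet((1, 1), size=10)
        ps = _pred_set(np.stack([p, p]), np.zeros(10, int))
        assert np.allclose(simple_average(ps), p)

    def test_rows_sum_to_one(self, rng):
        p1, p2 = rng.dirichlet((1, 1), 20), rng.dirichlet((1, 1), 20)
        ps = _pred_set(np.stack([p1, p2]), np.zeros(20, int))
        assert np.allclose(simple_average(ps).sum(axis=1), 1.0)

    def test_single_member_rejected(self, rng):
        ps = _pred_set(rng.dirichlet((1, 1), 5)[None], np.zeros(5, int))
        with pytest.raises(ValueError):
            simple_average(ps)


class TestApplyWeights:
    def _ps(self, rng, n=12):
        return _pred_set(
            np.stack([rng.dirichlet((1, 1), n), rng.dirichlet((1, 1), n)]),
            np.zeros(n, int),
        )

    def test_one_hot_selects_member(self, rng):
        ps = self._ps(rng)
        out = apply_weights(ps, EnsembleWeights(np.array([1.0, 0.0])))
        assert np.allclose(out, ps.probs[0])

    def test_uniform_equals_simple_average(self, rng):
        ps = self._ps(rng)
        out = apply_weights(ps, EnsembleWeights(np.array([0.5, 0.5])))
        assert np.allclose(out, simple_average(ps))

    def test_convexity(self, rng):
        ps = self._ps(rng)
        out = apply_weights(ps, EnsembleWeights(np.array([0.3, 0.7])))
        assert np.all(out >= ps.probs.min(axis=0) - 1e-12)
        assert np.all(out <= ps.probs.max(axis=0) + 1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_weights(self._ps(rng), EnsembleWeights(np.array([0.5, 0.3, 0.2])))


class TestSlsqpWeights:
    def _synthetic(self, rng, n=200):
        labels = rng.integers(0, 2, n)
        perfect = np.zeros((n, 2))
        perfect[np.arange(n), labels] = 0.98
        perfect[np.arange(n), 1 - labels] = 0.02
        uniform = np.full((n, 2), 0.5)
        return _pred_set(np.stack([perfect, uniform]), labels)

    def test_perfect_member_dominates(self, rng):
        w = fit_slsqp_weights(self._synthetic(rng))
        assert w.w[0] > 0.9

    def test_matches_grid_search_oracle(self, rng):
        ps = self._synthetic(rng)
        w = fit_slsqp_weights(ps)
        slsqp_loss = log_loss(apply_weights(ps, w), ps.labels)
        grid_losses = [
            log_loss(
                apply_weights(ps, EnsembleWeights(np.array([a, 1 - a]))), ps.labels
            )
            for a in np.round(np.arange(0.0, 1.0001, 0.01), 2)
        ]
        assert slsqp_loss <= min(grid_losses) + 1e-6

    def test_identical_members_feasible_flat_objective(self, rng):
        p = rng.dirichlet((2, 2), 50)
        labels = rng.integers(0, 2, 50)
        ps = _pred_set(np.stack([p, p]), labels)
        w = fit_slsqp_weights(ps)
        assert w.w.sum() == pytest.approx(1.0)
        assert log_loss(apply_weights(ps, w), ps.labels) == pytest.approx(
            log_loss(p, labels)
        )

    def test_never_worse_than_uniform(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            p1, p2 = r.dirichlet((1, 1), 40), r.dirichlet((1, 1), 40)
            labels = r.integers(0, 2, 40)
            ps = _pred_set(np.stack([p1, p2]), labels)
            w = fit_slsqp_weights(ps)
            uniform = EnsembleWeights(np.full(2, 0.5))
            assert (
                log_loss(apply_weights(ps, w), labels)
                <= log_loss(apply_weights(ps, uniform), labels) + 1e-9
            )


@pytest.fixture(scope="module")
def two_members():
    members = []
    for seed in (0, 1):
        restorer = build_restorer((32, 32), width_multiplier=0.0625, seed=seed)
        members.append(build_classifier(truncate_encoder(restorer), seed=seed))
    return members


class TestAFEnsemble:
    def test_attention_weights_sum_to_one(self, two_members, rng):
        af = build_af_ensemble(two_members, seed=0)
        x = rng.random((4, 1, 32, 32)).astype(np.float32)
        alphas = af.attention_weights(x)
        assert np.allclose(alphas.sum(axis=1), 1.0, atol=1e-9)

    def test_gamma_to_zero_flattens_output(self, two_members, rng):
        af = build_af_ensemble(two_members, seed=0)
        af.gamma.value = np.float32(1e-8)
        probs = af.forward(rng.random((4, 1, 32, 32)).astype(np.float32))
        assert np.allclose(probs, 0.5, atol=1e-6)

    def test_gamma_scaling_preserves_argmax(self, two_members, rng):
        af = build_af_ensemble(two_members, seed=0)
        x = rng.random((8, 1, 32, 32)).astype(np.float32)
        af.gamma.value = np.float32(1.0)
        arg1 = np.argmax(af.forward(x), axis=1)
        af.gamma.value = np.float32(5.0)
        arg5 = np.argmax(af.forward(x), axis=1)
        assert np.array_equal(arg1, arg5)

    def test_output_rows_valid(self, two_members, rng):
        af = build_af_ensemble(two_members, seed=1)
        probs = af.forward(rng.random((6, 1, 32, 32)).astype(np.float32))
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_single_member_rejected(self, two_members):
        with pytest.raises(ValueError):
            build_af_ensemble(two_members[:1])


class TestTrainAF:
    def test_backbones_frozen_and_gamma_trains(self, two_members, tiny_cohort):
        from pretextnet.ensembles import _encoder_checksum

        af = build_af_ensemble(two_members, seed=2)
        before = [_encoder_checksum(m) for m in af.members]
        gamma0 = float(af.gamma.value)
        cfg = ClassifierTrainConfig(max_epochs=2, batch_size=8, seed=2)
        best, history = train_af_ensemble(af, tiny_cohort, cfg)
        assert [_encoder_checksum(m) for m in af.members] == before
        assert float(af.gamma.value) != gamma0
        assert len(history) == 2
        assert set(best) == set(af.state_dict())

    def test_unfrozen_members_rejected(self, two_members, tiny_cohort):
        af = build_af_ensemble(two_members, seed=0)
        af.frozen = False
        with pytest.raises(RuntimeError):
            train_af_ensemble(af, tiny_cohort, ClassifierTrainConfig(max_epochs=1))

    def test_beats_best_member_with_anti_informative_partner(self, tiny_cohort):
        # member A: briefly fine-tuned (informative); member B: A with a
        # negated head (anti-informative). The trained ensemble should match
        # or beat the best single member in >= 7 of 10 paired seeds.
        restorer = build_restorer((32, 32), width_multiplier=0.0625, seed=11)
        member_a = build_classifier(truncate_encoder(restorer), seed=11)
        fine_tune(member_a, tiny_cohort, ClassifierTrainConfig(max_epochs=6, seed=11))
        member_b = build_classifier(truncate_encoder(restorer), seed=12)
        member_b.load_state_dict(member_a.state_dict())
        member_b.head.W.value = -member_b.head.W.value
        member_b.head.b.value = -member_b.head.b.value

        from pretextnet.transfer import _cohort_arrays

        x_val, y_val, _ = _cohort_arrays(tiny_cohort, "val")

        def accuracy(probs):
            return float(np.mean(np.argmax(probs, axis=1) == y_val))

        acc_members = max(
            accuracy(member_a.predict_proba(x_val)),
            accuracy(member_b.predict_proba(x_val)),
        )
        wins = 0
        for seed in range(10):
            af = build_af_ensemble([member_a, member_b], seed=seed)
            cfg = ClassifierTrainConfig(max_epochs=30, batch_size=8, seed=seed)
            best, _ = train_af_ensemble(af, tiny_cohort, cfg)
            af.load_state_dict(best)
            if accuracy(af.forward(x_val)) >= acc_members:
                wins += 1
        assert wins >= 7
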