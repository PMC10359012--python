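"""Network correctness: analytic gradients vs finite differences,
seeded determinism, softmax normalization, training-loop contracts."""

import numpy as np
import pytest

from mousemime.errors import ConstructionError, TrainingError
from mousemime.nn import (
    Model,
    ModelSpec,
    Softmax,
    TrainConfig,
    build_model,
    cross_entropy,
    images_to_batch,
    train,
)

MICRO = ModelSpec(variant="tiny", in_side=8, stem_channels=4,
                  fire_blocks=((2, 4, 4),), pools_after=(0,))


def _micro_data(n=6, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n, 3, 8, 8))
    y = rng.integers(0, 3, n)
    return x, y


def test_analytic_gradients_match_finite_differences():
    model = build_model(MICRO, seed=1, dtype=np.float64)
    x, y = _micro_data()
    model.set_training(True)
    loss, d = cross_entropy(model.forward(x), y)
    model.backward(d)
    rng = np.random.default_rng(7)
    for _, _, arr, grad in model.parameters():
        for _ in range(4):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            eps, orig = 1e-6, arr[idx]
            arr[idx] = orig + eps
            l1, _ = cross_entropy(model.forward(x), y)
            arr[idx] = orig - eps
            l2, _ = cross_entropy(model.forward(x), y)
            arr[idx] = orig
            fd = (l1 - l2) / (2 * eps)
            if max(abs(fd), abs(grad[idx])) < 1e-7:
                continue  # below the finite-difference noise floor
            denom = max(abs(fd), abs(grad[idx]))
            assert abs(fd - grad[idx]) / denom < 1e-4


def test_softmax_outputs_are_normalized():
    model = build_model(MICRO, seed=0)
    x, _ = _micro_data(4)
    p = model.predict_proba(x.astype(np.float32))
    assert p.shape == (4, 3)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()


def test_same_seed_same_initial_outputs():
    x, _ = _micro_data(3)
    a = build_model(MICRO, seed=5).predict_proba(x.astype(np.float32))
    b = build_model(MICRO, seed=5).predict_proba(x.astype(np.float32))
    np.testing.assert_array_equal(a, b)
    c = build_model(MICRO, seed=6).predict_proba(x.astype(np.float32))
    assert not np.array_equal(a, c)


def test_fresh_model_is_class_agnostic_on_gray_input():
    """Symmetric random init: uniform gray input scores near (1/3,1/3,1/3)
    averaged over seeds."""
    gray = np.zeros((1, 3, 16, 16), dtype=np.float32)
    spec = ModelSpec(variant="tiny", in_side=16, stem_channels=4,
                     fire_blocks=((2, 4, 4),), pools_after=(0,))
    probs = [build_model(spec, seed=s).predict_proba(gray)[0]
             for s in range(100)]
    np.testing.assert_allclose(np.mean(probs, axis=0), 1 / 3, atol=0.05)


def test_batched_prediction_matches_single(experiment):
    model = experiment.model
    recs = experiment.test_records()[:4]
    x = images_to_batch(recs)
    batched = model.predict_proba(x)
    singles = np.concatenate([model.predict_proba(x[i:i + 1])
                              for i in range(4)])
    np.testing.assert_allclose(batched, singles, atol=1e-5)


def test_zero_learning_rate_freezes_weights():
    model = build_model(MICRO, seed=2)
    x, y = _micro_data(8, seed=3)
    before = [arr.copy() for _, _, arr, _ in model.parameters()]
    cfg = TrainConfig(batch_size=4, learning_rate=0.0, iterations=20, seed=0)
    hist = train(model, x.astype(np.float32), y, cfg=cfg)
    for (_, _, arr, _), b in zip(model.parameters(), before):
        np.testing.assert_array_equal(arr, b)
    assert len(hist.train_loss) == 20


def test_training_descends_on_separable_data(small_records):
    """On linearly separable synthetic classes the final training loss
    must undercut the initial one."""
    x = np.stack([r.image for r in small_records])
    y = np.array([{"neutral": 0, "tail_pinch": 1, "brushing": 2}[r.label]
                  for r in small_records])
    model = build_model(ModelSpec.tiny(), seed=0)
    cfg = TrainConfig(batch_size=30, learning_rate=0.1, iterations=30, seed=1)
    hist = train(model, x, y, cfg=cfg,
                 augment_fn=lambda b, r: images_to_batch(b))
    assert hist.train_loss[-1] < hist.train_loss[0]


def test_divergence_reports_iteration():
    model = build_model(MICRO, seed=4, dtype=np.float32)
    x, y = _micro_data(8, seed=1)
    cfg = TrainConfig(batch_size=8, learning_rate=1e12, iterations=50, seed=0)
    with pytest.raises(TrainingError) as exc:
        train(model, (x * 1e3).astype(np.float32), y, cfg=cfg)
    assert exc.value.iteration is not None


def test_validation_history_cadence():
    model = build_model(MICRO, seed=0)
    x, y = _micro_data(10)
    xf = x.astype(np.float32)
    cfg = TrainConfig(batch_size=5, learning_rate=0.01, iterations=25,
                      val_period=10, seed=0)
    hist = train(model, xf, y, xf, y, cfg=cfg)
    assert hist.val_iterations == [10, 20, 25]


def test_malformed_fire_spec_rejected():
    with pytest.raises(ConstructionError):
        build_model(ModelSpec(fire_blocks=((64, 4, 4),)), seed=0)
    with pytest.raises(ConstructionError):
        build_model(ModelSpec(fire_blocks=((2, 4, 8),)), seed=0)


def test_weight_archive_roundtrip(tmp_path):
    a = build_model(MICRO, seed=9)
    x, _ = _micro_data(2)
    xf = x.astype(np.float32)
    a.save(tmp_path / "w")
    b = build_model(MICRO, seed=13)
    b.load(tmp_path / "w")
    np.testing.assert_array_equal(a.predict_proba(xf), b.predict_proba(xf))
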