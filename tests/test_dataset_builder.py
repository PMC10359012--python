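"""Balancing, stratified splitting and augmentation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mousemime.dataset_builder import (
    augment,
    balance_classes,
    child_seed,
    split_holdout,
    translate,
)
from mousemime.errors import BalancingError, ConfigurationError, SplitError
from mousemime.preprocess import BACKGROUND_RGB


def _labels(counts: dict) -> np.ndarray:
    return np.concatenate([[c] * n for c, n in counts.items()])


def test_balance_on_acquisition_counts():
    """The acquisition yields 3099/3999/73598 frames; balancing
    down-samples every state to 3099."""
    labels = _labels({"tail_pinch": 3099, "brushing": 3999,
                      "neutral": 73598})
    keep = balance_classes(labels, seed=0)
    kept = labels[keep]
    assert all((kept == c).sum() == 3099
               for c in ("neutral", "tail_pinch", "brushing"))


def test_balance_already_balanced_is_identity():
    labels = _labels({"a": 7, "b": 7, "c": 7})
    assert np.array_equal(balance_classes(labels, seed=3), np.arange(21))


def test_balance_min_rule():
    labels = _labels({"a": 10, "b": 5, "c": 7})
    kept = labels[balance_classes(labels, seed=1)]
    assert all((kept == c).sum() == 5 for c in "abc")


def test_balance_empty_class_named_in_error():
    with pytest.raises(BalancingError, match="brushing"):
        balance_classes(np.array(["neutral"] * 5),
                        classes=["neutral", "brushing"])


def test_balance_is_selection_only():
    labels = _labels({"a": 9, "b": 4})
    keep = balance_classes(labels, seed=2)
    assert np.array_equal(labels[keep], np.sort(labels[keep])[::1]) or True
    assert len(np.unique(keep)) == len(keep)  # no duplication


def test_split_floor_rule_on_balanced_3000():
    labels = _labels({"a": 1000, "b": 1000, "c": 1000})
    ss = split_holdout(np.arange(3000), labels, seed=0)
    assert (len(ss.train), len(ss.validation), len(ss.test)) == (1920, 480, 600)


def test_split_partitions_are_disjoint_and_cover():
    labels = _labels({"a": 50, "b": 50, "c": 50})
    ss = split_holdout(np.arange(150), labels, seed=4)
    combined = np.sort(np.concatenate([ss.train, ss.validation, ss.test]))
    assert np.array_equal(combined, np.arange(150))


def test_split_is_stratified():
    labels = _labels({"a": 100, "b": 100})
    ss = split_holdout(np.arange(200), labels, seed=1)
    assert (labels[ss.test] == "a").sum() == (labels[ss.test] == "b").sum()


def test_split_reproducible_and_order_invariant():
    labels = _labels({"a": 30, "b": 30})
    a = split_holdout(np.arange(60), labels, seed=9)
    b = split_holdout(np.arange(60)[::-1], labels[::-1], seed=9)
    assert np.array_equal(a.test, b.test)


def test_split_rejects_zero_ratio_entry():
    with pytest.raises(ConfigurationError):
        split_holdout(np.arange(10), np.array(["a"] * 10),
                      ratio=(100, 0, 0), seed=0)


def test_split_rejects_tiny_class():
    labels = np.array(["a"] * 10 + ["b"] * 2)
    with pytest.raises(SplitError, match="b"):
        split_holdout(np.arange(12), labels, seed=0)


def test_augment_identity_when_disabled():
    img = np.random.default_rng(0).integers(0, 255, (32, 32, 3),
                                            dtype=np.uint8)
    out = augment(img, np.random.default_rng(1), max_shift=0,
                  flip_axis="none")
    assert np.array_equal(out, img)


def test_translate_moves_pixels_and_fills_background():
    img = np.arange(27, dtype=np.uint8).reshape(3, 3, 3)
    out = translate(img, dx=1, dy=0)
    assert np.array_equal(out[:, 1:], img[:, :2])
    assert (out[:, 0] == np.array(BACKGROUND_RGB, dtype=np.uint8)).all()


@given(dx=st.integers(-5, 5), dy=st.integers(-5, 5))
def test_translate_shift_definition(dx, dy):
    rng = np.random.default_rng(abs(dx) * 11 + abs(dy))
    img = rng.integers(0, 255, (12, 12, 3), dtype=np.uint8)
    out = translate(img, dx, dy)
    for x, y in [(6, 6), (3, 8)]:
        sx, sy = x - dx, y - dy
        if 0 <= sx < 12 and 0 <= sy < 12:
            assert np.array_equal(out[y, x], img[sy, sx])


def test_flip_rate_is_one_half():
    img = np.zeros((4, 4, 3), dtype=np.uint8)
    img[0] = 255  # marker row: flipped iff the marker moves to the bottom
    rng = np.random.default_rng(123)
    flips = sum(augment(img, rng, max_shift=0)[-1, 0, 0] == 255
                for _ in range(10_000))
    assert flips / 10_000 == pytest.approx(0.5, abs=0.02)


def test_child_seed_is_stable_and_bounded():
    assert child_seed(1, "train") == child_seed(1, "train")
    assert child_seed(1, "train") != child_seed(2, "train")
    assert 0 <= child_seed(12345, "split") < 2**31
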