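"""Class balancing, stratified hold-out splitting and training-time
augmentation.

The corpus being emulated is heavily imbalanced (the neutral state is
recorded continuously while stimuli last 5 s), so classes are first
down-sampled without replacement to the minimum class count, then split
64:16:20 into train/validation/test stratified by class. Augmentation —
random up–down flip and random translation — is applied online to
training images only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mousemime.errors import BalancingError, ConfigurationError, SplitError
from mousemime.preprocess import BACKGROUND_RGB
from mousemime.synthetic_faces import ImageRecord

DEFAULT_RATIO = (64, 16, 20)
MAX_SHIFT = 30  # px, at the 227-px network scale


@dataclass
class SplitSet:
    """Disjoint train/validation/test index lists covering a dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self):
        parts = [np.asarray(p, dtype=int) for p in
                 (self.train, self.validation, self.test)]
        self.train, self.validation, self.test = parts
        combined = np.concatenate(parts)
        if len(np.unique(combined)) != len(combined):
            raise SplitError("split partitions overlap")

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def balance_classes(labels, seed: int = 0, classes=None) -> np.ndarray:
    """Down-sample every class to the minimum class count.

    Selection is uniform without replacement within each class; returned
    indices are sorted ascending, so retained records keep their original
    relative order and an already-balanced input returns the identity
    permutation. Raises :class:`BalancingError` naming any empty class.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise BalancingError("no samples to balance")
    classes = np.asarray(classes) if classes is not None else np.unique(labels)
    counts = {c: int((labels == c).sum()) for c in classes}
    for c, n in counts.items():
        if n == 0:
            raise BalancingError(f"class '{c}' has no samples")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) > m:
            idx = rng.choice(idx, size=m, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def split_holdout(indices, labels, ratio=DEFAULT_RATIO,
                  seed: int = 0) -> SplitSet:
    """Stratified random hold-out split at ``ratio`` (percent triple).

    Per class, the train and validation counts are floors of the exact
    shares; the remainder goes to test, so test is never under-sized.
    A class smaller than 3 cannot populate all partitions and raises
    :class:`SplitError`.
    """
    ratio = tuple(ratio)
    if len(ratio) != 3 or any(r <= 0 for r in ratio) or sum(ratio) != 100:
        raise ConfigurationError(
            f"ratio must be three positive percentages summing to 100, "
            f"got {ratio}")
    indices = np.asarray(indices, dtype=int)
    labels = np.asarray(labels)
    if len(indices) != len(labels):
        raise ConfigurationError("indices and labels must have equal length")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(labels):
        cls_idx = np.sort(indices[labels == c])  # canonical order, then shuffle
        n = len(cls_idx)
        if n < 3:
            raise SplitError(f"class '{c}' has {n} samples; need >= 3")
        perm = rng.permutation(cls_idx)
        n_tr = int(np.floor(n * ratio[0] / 100))
        n_val = int(np.floor(n * ratio[1] / 100))
        train.append(perm[:n_tr])
        val.append(perm[n_tr:n_tr + n_val])
        test.append(perm[n_tr + n_val:])
    return SplitSet(train=np.sort(np.concatenate(train)),
                    validation=np.sort(np.concatenate(val)),
                    test=np.sort(np.concatenate(test)),
                    seed=seed)


def translate(img: np.ndarray, dx: int, dy: int,
              fill=BACKGROUND_RGB) -> np.ndarray:
    """Integer-shift an image; vacated pixels take the background color."""
    h, w = img.shape[:2]
    out = np.empty_like(img)
    out[:] = np.asarray(fill, dtype=img.dtype)
    xs0, xs1 = max(0, dx), min(w, w + dx)
    ys0, ys1 = max(0, dy), min(h, h + dy)
    if xs1 > xs0 and ys1 > ys0:
        out[ys0:ys1, xs0:xs1] = img[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
    return out


def augment(image: ImageRecord | np.ndarray, rng: np.random.Generator,
            max_shift: int = MAX_SHIFT, flip_axis: str = "horizontal",
            flip_prob: float = 0.5, fill=BACKGROUND_RGB) -> np.ndarray:
    """Random flip + random translation for one training image.

    ``flip_axis='horizontal'`` flips up–down (about the horizontal
    axis); ``'vertical'`` mirrors left–right; ``'none'`` disables
    flipping. The translation Δx, Δy is drawn uniformly from
    [-max_shift, max_shift] and vacated pixels are filled with the
    uniform background color so augmentation cannot leak border
    artifacts. Returns the augmented pixel array.
    """
    if flip_axis not in ("horizontal", "vertical", "none"):
        raise ConfigurationError(f"unknown flip axis {flip_axis!r}")
    img = image.image if isinstance(image, ImageRecord) else image
    if flip_axis != "none" and rng.random() < flip_prob:
        img = img[::-1] if flip_axis == "horizontal" else img[:, ::-1]
    dx = int(rng.integers(-max_shift, max_shift + 1))
    dy = int(rng.integers(-max_shift, max_shift + 1))
    if dx == 0 and dy == 0:
        return np.ascontiguousarray(img)
    return translate(img, dx, dy, fill=fill)


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31 (FNV-style hash of
    the stage name folded into the global seed)."""
    h = seed & 0xFFFFFFFFFFFFFFFF
    for ch in stage:
        h = ((h * 1000003) ^ ord(ch)) & 0xFFFFFFFFFFFFFFFF
    return h % (2**31 - 1)
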