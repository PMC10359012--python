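"""Gradient-weighted Class Activation Mapping (Grad-CAM).

For a chosen convolutional feature layer, the channel weights are the
spatial averages of the class-score gradient with respect to the feature
maps; the saliency map is the rectified, weighted channel sum, upsampled
bilinearly to the input size and max-normalized to [0, 1]. The class
score is the pre-softmax logit.

A finite-difference route (:func:`gradcam_finite_difference`) computes
the same map by numerically differentiating the score against each
feature-map element; it serves as an independent oracle for the
backprop-based implementation.

:func:`top_k_overlays` reproduces the reporting convention of keeping,
per class, the k test images with the highest posterior among images
predicted as that class, alpha-blended with a colormap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform

from mousemime.errors import LayerLookupError
from mousemime.nn import Model, Softmax


@dataclass
class Heatmap:
    """Per-pixel relevance in [0, 1] at the input-image size."""

    values: np.ndarray
    image_id: str
    target_class: int
    layer: str

    def mass_fraction_in(self, mask: np.ndarray,
                         threshold: float = 0.5) -> float:
        """Fraction of above-threshold heatmap mass inside a mask."""
        v = np.where(self.values >= threshold, self.values, 0.0)
        total = v.sum()
        if total == 0:
            return 0.0
        return float(v[mask.astype(bool)].sum() / total)


def _raw_cam(activation: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Rectified weighted channel sum for one sample (C, h, w)."""
    weights = grad.mean(axis=(1, 2))
    cam = np.tensordot(weights, activation, axes=1)
    return np.maximum(cam, 0.0)


def _finish(cam: np.ndarray, out_side: int, image_id: str,
            target_class: int, layer: str) -> Heatmap:
    m = cam.max()
    if m > 0:
        cam = cam / m
    up = transform.resize(cam, (out_side, out_side), order=1,
                          anti_aliasing=False, preserve_range=True)
    up = np.clip(up, 0.0, 1.0)
    return Heatmap(values=up, image_id=image_id, target_class=target_class,
                   layer=layer)


def gradcam(model: Model, image_nchw: np.ndarray, target_class: int,
            layer: str | None = None, image_id: str = "") -> Heatmap:
    """Grad-CAM heatmap of one image (1, 3, H, W) for a class logit.

    ``layer`` defaults to the model's last convolutional feature layer.
    Raises :class:`LayerLookupError` for unknown layer names.
    """
    layer = layer or model.last_feature_layer()
    if layer not in model.layer_names():
        raise LayerLookupError(f"no layer named {layer!r}")
    x = np.asarray(image_nchw)
    if x.ndim == 3:
        x = x[None]
    logits, act = model.forward(x, capture=layer)
    dlogits = np.zeros_like(logits)
    dlogits[:, target_class] = 1.0
    dact = model.backward(dlogits, stop_at=layer)
    cam = _raw_cam(act[0], dact[0])
    return _finish(cam, x.shape[-1], image_id, target_class, layer)


def gradcam_finite_difference(model: Model, image_nchw: np.ndarray,
                              target_class: int, layer: str | None = None,
                              eps: float = 1e-3,
                              image_id: str = "") -> Heatmap:
    """Finite-difference Grad-CAM oracle.

    The gradient of the class logit w.r.t. every element of the target
    layer's activation is estimated by central differences, re-running
    only the network tail. Intended for small models/feature maps.
    """
    layer = layer or model.last_feature_layer()
    x = np.asarray(image_nchw)
    if x.ndim == 3:
        x = x[None]
    _, act = model.forward(x, capture=layer)
    act = act.astype(np.float64)
    grad = np.zeros_like(act)
    it = np.nditer(act, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        for sign in (+1, -1):
            pert = act.copy()
            pert[idx] += sign * eps
            logit = model.forward_from(layer, pert)[0, target_class]
            grad[idx] += sign * logit
        grad[idx] /= 2 * eps
        it.iternext()
    cam = _raw_cam(act[0], grad[0])
    return _finish(cam, x.shape[-1], image_id, target_class, layer)


# ------------------------------------------------------------------- overlays

def overlay(image_rgb: np.ndarray, heatmap: Heatmap,
            alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend a jet-style colormap of the heatmap onto the image."""
    from matplotlib import cm

    colored = cm.jet(heatmap.values)[..., :3]
    base = image_rgb.astype(float) / 255.0
    out = (1 - alpha) * base + alpha * colored
    return np.clip(np.round(out * 255), 0, 255).astype(np.uint8)


def top_k_selection(image_ids, true_labels, probs: np.ndarray,
                    classes, k: int = 5) -> dict[str, list[int]]:
    """Per class, indices of the k highest-posterior images among those
    *predicted* as that class; ties broken by image id (stable).

    Returns fewer than k (with a warning) when not enough qualify.
    """
    import warnings

    probs = np.asarray(probs)
    pred = probs.argmax(axis=1)
    ids = np.asarray(image_ids)
    out: dict[str, list[int]] = {}
    for ci, cname in enumerate(classes):
        cand = np.flatnonzero(pred == ci)
        # stable sort by (-score, id)
        order = sorted(cand, key=lambda i: (-probs[i, ci], str(ids[i])))
        if len(order) < k:
            warnings.warn(f"class '{cname}': only {len(order)} qualifying "
                          f"images for top-{k}", stacklevel=2)
        out[cname] = [int(i) for i in order[:k]]
    return out


def top_k_overlays(model: Model, images_nchw: np.ndarray,
                   images_rgb: np.ndarray, image_ids, classes,
                   k: int = 5, layer: str | None = None,
                   outdir: str | Path | None = None) -> dict[str, list]:
    """Grad-CAM overlays for the top-k scored images of each class.

    Returns {class: [(image_id, overlay_rgb, Heatmap), ...]}; also
    writes PNGs (overlay + single-channel heatmap) when ``outdir`` is
    given.
    """
    probs = model.predict_proba(images_nchw)
    selection = top_k_selection(image_ids, None, probs, classes, k=k)
    results: dict[str, list] = {}
    for ci, cname in enumerate(classes):
        items = []
        for i in selection[cname]:
            hm = gradcam(model, images_nchw[i], ci, layer=layer,
                         image_id=str(image_ids[i]))
            ov = overlay(images_rgb[i], hm)
            items.append((str(image_ids[i]), ov, hm))
        results[cname] = items
    if outdir is not None:
        from PIL import Image

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cname, items in results.items():
            for image_id, ov, hm in items:
                Image.fromarray(ov).save(outdir / f"{cname}_{image_id}_overlay.png")
                Image.fromarray(
                    (hm.values * 255).astype(np.uint8)).save(
                    outdir / f"{cname}_{image_id}_heatmap.png")
    return results
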