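"""Subject masking, background compositing and network resizing.

The preprocessing contract: detect the subject silhouette, replace every
background pixel with the uniform reference color RGB [200, 167, 122],
and resize to the square network input (227 px by default).

Subject detection here is a self-contained background-model segmenter —
color distance to the median border color, morphological closing, then
the largest connected component. Any external detector can be plugged in
by passing its binary mask straight to :func:`composite`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology, transform

from mousemime.errors import AlignmentError, ConfigurationError, DetectionError
from mousemime.synthetic_faces import ImageRecord

#: uniform background color composited behind the subject
BACKGROUND_RGB = (200, 167, 122)

#: default network input side, px
NET_SIDE = 227


@dataclass
class SubjectMask:
    """Binary foreground map aligned to its source image."""

    mask: np.ndarray  # bool (H, W)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def detect_subject(image: ImageRecord | np.ndarray,
                   color_threshold: float = 70.0,
                   min_area_fraction: float = 0.005) -> SubjectMask:
    """Segment the subject from a frame by background-color distance.

    The background model is the median color of the 2-px image border;
    pixels further than ``color_threshold`` (Euclidean RGB distance) are
    foreground. Holes are closed morphologically and only the largest
    connected component is kept.

    Raises :class:`DetectionError` when the largest component covers
    less than ``min_area_fraction`` of the frame (e.g. a background-only
    frame); such frames are meant to be excluded, mirroring how unusable
    sequences are dropped from the analysis.
    """
    img = image.image if isinstance(image, ImageRecord) else image
    if img.ndim != 3 or img.shape[2] != 3:
        raise ConfigurationError("detect_subject expects an RGB image")
    f = img.astype(float)
    border = np.concatenate([
        f[:2].reshape(-1, 3), f[-2:].reshape(-1, 3),
        f[:, :2].reshape(-1, 3), f[:, -2:].reshape(-1, 3),
    ])
    bg = np.median(border, axis=0)
    dist = np.sqrt(((f - bg) ** 2).sum(axis=2))
    fg = dist > color_threshold
    fg = morphology.closing(fg, morphology.disk(3))
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise DetectionError("no foreground found in frame")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    if mask.sum() < min_area_fraction * mask.size:
        raise DetectionError(
            f"largest component ({int(mask.sum())} px) below the "
            f"minimum plausible subject area")
    return SubjectMask(mask=mask)


def composite(image: ImageRecord, mask: SubjectMask,
              bg: tuple[int, int, int] = BACKGROUND_RGB) -> ImageRecord:
    """Copy foreground pixels verbatim onto the uniform background color.

    Every pixel outside the mask equals ``bg`` exactly in the output.
    Raises :class:`AlignmentError` on shape mismatch.
    """
    if mask.shape != image.image.shape[:2]:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match image "
            f"{image.image.shape[:2]}")
    out = np.empty_like(image.image)
    out[:] = np.asarray(bg, dtype=np.uint8)
    out[mask.mask] = image.image[mask.mask]
    return ImageRecord(id=image.id, label=image.label, image=out,
                       provenance="masked", masks=image.masks,
                       params=image.params)


def resize_for_net(image: ImageRecord, side: int = NET_SIDE) -> ImageRecord:
    """Resize (stretch, no padding) to ``side`` x ``side`` x 3.

    Bilinear with anti-aliasing; an input already at the target size is
    passed through bit-identically.
    """
    if side < 8:
        raise ConfigurationError(f"resize side must be >= 8, got {side}")
    if image.image.shape[:2] == (side, side):
        return ImageRecord(id=image.id, label=image.label,
                           image=image.image.copy(), provenance="resized",
                           masks=image.masks, params=image.params)
    out = transform.resize(image.image, (side, side), order=1,
                           anti_aliasing=True, preserve_range=True)
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return ImageRecord(id=image.id, label=image.label, image=out,
                       provenance="resized", masks=image.masks,
                       params=image.params)
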