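"""The ten geometric facial parameters.

Replaces the manual measurement workflow: from per-part masks (ground
truth on synthetic data, annotation polygons/landmarks on real images)
compute

    mouth_opening, jaw_angle, ear_angle, ear_eccentricity,
    ear_perimeter, eye_angle, eye_eccentricity, eye_perimeter,
    ear_to_eye_angle, ear_to_eye_distance.

Ellipses are fitted by matching second central moments of the mask (the
inertia-equivalent ellipse, the behaviour of the common "fit ellipse"
image-analysis tools); perimeters use Ramanujan's second approximation.

Angle convention: degrees in [0, 180), measured against the horizontal
in image coordinates (y increases downward). A measurement that cannot
be computed is reported as NaN, never as a silent zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from mousemime.errors import (
    FitError,
    GeometryError,
    UndefinedOrientationError,
)

PARAMETER_NAMES = (
    "mouth_opening", "jaw_angle", "ear_angle", "ear_eccentricity",
    "ear_perimeter", "eye_angle", "eye_eccentricity", "eye_perimeter",
    "ear_to_eye_angle", "ear_to_eye_distance",
)

#: mouth-open decision threshold, px at the 256-px raw scale
MOUTH_OPEN_TAU = 2.0
#: rendered closed-lip band thickness assumed when measuring gap from a mask
MOUTH_CLOSED_THICKNESS = 3.0


@dataclass
class EllipseFit:
    """Moment-matched ellipse: center, semi-axes (a >= b), orientation
    of the major axis vs the horizontal in [0, 180) degrees."""

    center: tuple[float, float]
    a: float
    b: float
    angle: float

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise FitError("ellipse requires a >= b > 0")
        self.angle = float(self.angle % 180.0)


@dataclass
class MorphometryVector:
    """The ten facial parameters of one image. NaN marks a missing part."""

    mouth_opening: float
    jaw_angle: float
    ear_angle: float
    ear_eccentricity: float
    ear_perimeter: float
    eye_angle: float
    eye_eccentricity: float
    eye_perimeter: float
    ear_to_eye_angle: float
    ear_to_eye_distance: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_ellipse(part_mask: np.ndarray) -> EllipseFit:
    """Fit the second-central-moment ellipse of a binary mask.

    The fitted semi-axes are ``2*sqrt(eigenvalue)`` of the pixel
    coordinate covariance, which reproduces the axes of an ideal filled
    ellipse. Raises :class:`FitError` for empty, single-pixel or
    degenerate (collinear) masks.
    """
    mask = np.asarray(part_mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if len(xs) < 5:
        raise FitError(f"mask has only {len(xs)} pixels; cannot fit ellipse")
    pts = np.stack([xs, ys]).astype(float)
    center = pts.mean(axis=1)
    cov = np.cov(pts)  # 2x2, sample covariance over pixels
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-9:
        raise FitError("degenerate (collinear) mask; no ellipse fit")
    a = 2.0 * np.sqrt(evals[1])
    b = 2.0 * np.sqrt(evals[0])
    major = evecs[:, 1]
    angle = np.degrees(np.arctan2(major[1], major[0])) % 180.0
    return EllipseFit(center=(float(center[0]), float(center[1])),
                      a=float(a), b=float(b), angle=float(angle))


def eccentricity(e: EllipseFit) -> float:
    """sqrt(1 - (b/a)^2): 0 for a circle, toward 1 as it flattens."""
    return float(np.sqrt(1.0 - (e.b / e.a) ** 2))


def perimeter(e: EllipseFit) -> float:
    """Ellipse perimeter via Ramanujan's second approximation
    (relative error < 1e-6 for mild eccentricities)."""
    a, b = e.a, e.b
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def part_angle(e: EllipseFit, min_axis_ratio: float = 1e-3) -> float:
    """Major-axis angle vs horizontal, degrees in [0, 180).

    Raises :class:`UndefinedOrientationError` when a == b (a circle has
    no major axis); callers report the angle as missing.
    """
    if (e.a - e.b) / e.a < min_axis_ratio:
        raise UndefinedOrientationError(
            "near-circular fit: major-axis orientation undefined")
    return float(e.angle)


def jaw_angle(jaw, mouth, nose) -> float:
    """Interior angle at the mouth between jaw-mouth and mouth-nose
    lines, degrees in [0, 180]. 180 means a straight jawline."""
    jaw = np.asarray(jaw, dtype=float)
    mouth = np.asarray(mouth, dtype=float)
    nose = np.asarray(nose, dtype=float)
    v1 = jaw - mouth
    v2 = nose - mouth
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("coincident landmark points; jaw angle undefined")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def ear_eye_relation(ear: EllipseFit, eye: EllipseFit) -> tuple[float, float]:
    """(angle of the centroid-connecting line vs horizontal in [0, 180),
    centroid-to-centroid distance in px)."""
    d = np.asarray(eye.center, dtype=float) - np.asarray(ear.center, dtype=float)
    dist = float(np.linalg.norm(d))
    if dist == 0:
        raise GeometryError("coincident centroids; ear-eye angle undefined")
    ang = float(np.degrees(np.arctan2(d[1], d[0])) % 180.0)
    return ang, dist


def mouth_open(mouth_gap: float | None = None,
               mouth_mask: np.ndarray | None = None,
               tau: float = MOUTH_OPEN_TAU,
               closed_thickness: float = MOUTH_CLOSED_THICKNESS) -> float:
    """Binary mouth state: 1 open, 0 closed.

    Given a gap in px directly, compares it with the threshold ``tau``.
    Given a mouth mask, the gap is estimated as the mask's extent along
    its minor axis minus the closed-lip band thickness. Returns NaN when
    no evidence is available.
    """
    if mouth_gap is None and mouth_mask is None:
        return float("nan")
    if mouth_gap is None:
        mask = np.asarray(mouth_mask).astype(bool)
        ys, xs = np.nonzero(mask)
        if len(xs) == 0:
            return float("nan")
        pts = np.stack([xs, ys]).astype(float)
        pts -= pts.mean(axis=1, keepdims=True)
        cov = np.cov(pts) if pts.shape[1] > 1 else np.eye(2)
        _, evecs = np.linalg.eigh(cov)
        minor = evecs[:, 0]
        proj = minor @ pts
        extent = proj.max() - proj.min() + 1.0
        mouth_gap = max(0.0, float(extent) - closed_thickness)
    return 1.0 if mouth_gap > tau else 0.0


def measure_all(masks: dict[str, np.ndarray] | None,
                landmarks: dict | None = None,
                tau: float = MOUTH_OPEN_TAU) -> MorphometryVector:
    """Compute the full ten-parameter vector for one image.

    ``masks`` holds boolean part masks keyed ``ear``/``eye``/``mouth``;
    ``landmarks`` holds the ``jaw_point``/``mouth_point``/``nose_point``
    2-D coordinates. Any unmeasurable parameter is NaN.
    """
    masks = masks or {}
    landmarks = landmarks or {}
    nan = float("nan")

    def safe_fit(name):
        try:
            return fit_ellipse(masks[name]) if name in masks else None
        except FitError:
            return None

    ear = safe_fit("ear")
    eye = safe_fit("eye")

    def angle_of(fit):
        if fit is None:
            return nan
        try:
            return part_angle(fit)
        except UndefinedOrientationError:
            return nan

    ear_ecc = eccentricity(ear) if ear else nan
    ear_per = perimeter(ear) if ear else nan
    eye_ecc = eccentricity(eye) if eye else nan
    eye_per = perimeter(eye) if eye else nan

    if ear and eye:
        try:
            e2e_ang, e2e_dist = ear_eye_relation(ear, eye)
        except GeometryError:
            e2e_ang, e2e_dist = nan, 0.0
    else:
        e2e_ang, e2e_dist = nan, nan

    if all(k in landmarks for k in ("jaw_point", "mouth_point", "nose_point")):
        try:
            jaw = jaw_angle(landmarks["jaw_point"], landmarks["mouth_point"],
                            landmarks["nose_point"])
        except GeometryError:
            jaw = nan
    else:
        jaw = nan

    mouth = mouth_open(mouth_mask=masks.get("mouth"), tau=tau) \
        if "mouth" in masks else nan

    return MorphometryVector(
        mouth_opening=mouth,
        jaw_angle=jaw,
        ear_angle=angle_of(ear),
        ear_eccentricity=ear_ecc,
        ear_perimeter=ear_per,
        eye_angle=angle_of(eye),
        eye_eccentricity=eye_ecc,
        eye_perimeter=eye_per,
        ear_to_eye_angle=e2e_ang,
        ear_to_eye_distance=e2e_dist,
    )


def measure_record(record) -> MorphometryVector:
    """Measure a synthetic :class:`ImageRecord` from its ground-truth
    masks and landmark points."""
    params = record.params
    landmarks = None
    if params is not None:
        landmarks = {"jaw_point": params.jaw_point,
                     "mouth_point": params.mouth_point,
                     "nose_point": params.nose_point}
    return measure_all(record.masks, landmarks)


def measurement_table(records) -> "pandas.DataFrame":
    """Ten-parameter table (one row per record) plus label column."""
    import pandas as pd

    rows = []
    for rec in records:
        d = measure_record(rec).to_dict()
        d["label"] = rec.label
        d["image"] = rec.id
        rows.append(d)
    return pd.DataFrame(rows).set_index("image")
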