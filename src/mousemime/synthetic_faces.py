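"""Synthetic lateral mouse-face benchmark with per-part ground truth.

Real facial videos of head-fixed mice are not publicly deposited, so this
module is the canonical test input of the pipeline: it renders a lateral
head silhouette carrying an ear ellipse, an eye ellipse, a mouth
(closed line or open cavity), a jaw line (jaw–mouth–nose polyline) and a
nose landmark over a distractor background, with state-dependent
deformations:

* ``neutral`` — near-circular ear, closed mouth, near-straight jawline;
* ``tail_pinch`` — crumpled (eccentric, rotated) ear and an open mouth;
* ``brushing`` — crumpled ear, bent jawline and a deformed, rotated eye.

Per-state parameter distributions are truncated normals whose supports
deliberately overlap feature-by-feature (no single facial parameter
separates the states cleanly) while the joint deformation pattern does.
Nuisance factors — head position and size, global brightness, background
style — are drawn i.i.d. across states so a classifier cannot exploit
non-facial shortcuts.

Every record carries the generative parameters (:class:`FaceParams`) and
boolean per-part masks, giving downstream saliency and morphometry
stages exact ground truth. Rendering is fully deterministic given
(seed, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mousemime.errors import InvalidLabelError, RenderError

STATES = ("neutral", "tail_pinch", "brushing")

#: reference scale (px) at which all geometric constants below are stated
REF_SIZE = 256

# layout constants at REF_SIZE, (x, y) with y increasing downward
_HEAD_CENTER = (128.0, 140.0)
_EAR_OFFSET = (-28.0, -52.0)
_EYE_OFFSET = (22.0, -20.0)
_MOUTH_OFFSET = (52.0, 25.0)
_NOSE_OFFSET = (72.0, 5.0)

# truncated-normal presets: field -> state -> (mean, sd, lo, hi).
# Supports overlap between states on purpose; only the joint pattern of
# ear eccentricity/angle, mouth state, jaw bend and eye shape separates them.
_STATE_PRESETS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "ear_ecc": {
        "neutral": (0.45, 0.11, 0.05, 0.80),
        "tail_pinch": (0.72, 0.09, 0.30, 0.93),
        "brushing": (0.70, 0.09, 0.30, 0.93),
    },
    "ear_angle": {
        "neutral": (30.0, 14.0, 4.0, 176.0),
        "tail_pinch": (62.0, 16.0, 4.0, 176.0),
        "brushing": (95.0, 16.0, 4.0, 176.0),
    },
    "eye_ecc": {
        "neutral": (0.55, 0.08, 0.20, 0.85),
        "tail_pinch": (0.55, 0.08, 0.20, 0.85),
        "brushing": (0.72, 0.08, 0.30, 0.93),
    },
    "eye_angle": {
        "neutral": (20.0, 10.0, 4.0, 176.0),
        "tail_pinch": (20.0, 10.0, 4.0, 176.0),
        "brushing": (50.0, 18.0, 4.0, 176.0),
    },
    "jaw_angle": {
        "neutral": (170.0, 5.0, 150.0, 179.5),
        "tail_pinch": (153.0, 8.0, 120.0, 178.0),
        "brushing": (140.0, 8.0, 110.0, 172.0),
    },
}

#: probability the mouth is rendered open, per state
_MOUTH_OPEN_PROB = {"neutral": 0.03, "tail_pinch": 0.92, "brushing": 0.25}
#: mouth-gap distribution (mean, sd, lo, hi) at REF_SIZE, used when open
_MOUTH_GAP = {
    "neutral": (4.0, 0.7, 3.0, 5.0),
    "tail_pinch": (9.0, 2.0, 4.0, 14.0),
    "brushing": (5.0, 1.5, 3.0, 9.0),
}

_PART_NAMES = ("ear", "eye", "mouth", "jaw", "head")


@dataclass
class SceneConfig:
    """Rendering configuration.

    ``size`` is the square image side in pixels; all geometry scales
    linearly from the 256-px reference. ``bg_style`` is either a uniform
    random gray-ish background or a low-contrast textured distractor.
    ``spread_scale`` multiplies every per-state SD, controlling how much
    the single-feature distributions overlap. ``frame_rate_hz`` and
    ``window_s`` document the acquisition cadence being emulated
    (5 Hz over 5 s stimulation windows); they do not affect rendering.
    """

    size: int = 256
    bg_style: str = "textured"  # "uniform" | "textured"
    spread_scale: float = 1.0
    frame_rate_hz: float = 5.0
    window_s: float = 5.0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("image size must be >= 32 px")
        if self.bg_style not in ("uniform", "textured"):
            raise ValueError(f"unknown background style {self.bg_style!r}")
        if self.spread_scale < 0:
            raise ValueError("spread_scale must be >= 0")

    @property
    def scale(self) -> float:
        return self.size / REF_SIZE

    def frames_per_window(self) -> int:
        """Number of frames in one emulated stimulation window."""
        return int(round(self.frame_rate_hz * self.window_s))


def tiny_profile() -> SceneConfig:
    """64-px profile used by fast tests and the desk-scale classifier."""
    return SceneConfig(size=64)


@dataclass
class FaceParams:
    """Ground-truth generative parameters of one synthetic face.

    All coordinates/lengths are pixels at the rendered size, ``(x, y)``
    with y downward; angles are degrees of the major axis against the
    horizontal, in [0, 180).
    """

    state: str
    ear_center: tuple[float, float]
    ear_a: float
    ear_b: float
    ear_angle: float
    eye_center: tuple[float, float]
    eye_a: float
    eye_b: float
    eye_angle: float
    mouth_gap: float
    jaw_point: tuple[float, float]
    mouth_point: tuple[float, float]
    nose_point: tuple[float, float]
    seed: int
    # nuisance scene factors, i.i.d. across states
    head_center: tuple[float, float] = (128.0, 140.0)
    head_a: float = 85.0
    head_b: float = 72.0
    brightness: float = 1.0
    bg_color: tuple[int, int, int] = (185, 185, 190)
    bg_seed: int = 0

    def validate(self) -> None:
        if self.state not in STATES:
            raise InvalidLabelError(f"unknown state {self.state!r}")
        for name, a, b in (("ear", self.ear_a, self.ear_b),
                           ("eye", self.eye_a, self.eye_b)):
            if not (a >= b > 0):
                raise ValueError(f"{name} semi-axes must satisfy a >= b > 0")
        if self.mouth_gap < 0:
            raise ValueError("mouth_gap must be >= 0")
        for name, pt in self._anchor_points().items():
            if not self._inside_head(pt):
                raise ValueError(f"{name} lies outside the head silhouette")

    def _anchor_points(self) -> dict[str, tuple[float, float]]:
        return {
            "ear_center": self.ear_center,
            "eye_center": self.eye_center,
            "jaw_point": self.jaw_point,
            "mouth_point": self.mouth_point,
            "nose_point": self.nose_point,
        }

    def _inside_head(self, pt: tuple[float, float], margin: float = 1.0) -> bool:
        dx = (pt[0] - self.head_center[0]) / (self.head_a * margin)
        dy = (pt[1] - self.head_center[1]) / (self.head_b * margin)
        return dx * dx + dy * dy <= 1.0

    @property
    def ear_eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.ear_b / self.ear_a) ** 2))

    @property
    def eye_eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.eye_b / self.eye_a) ** 2))

    @property
    def mouth_is_open(self) -> bool:
        return self.mouth_gap > 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class ImageRecord:
    """One frame: RGB image, label, provenance and optional ground truth."""

    id: str
    label: str
    image: np.ndarray  # uint8 (H, W, 3)
    provenance: str = "raw"  # raw | masked | resized
    masks: dict[str, np.ndarray] | None = None
    params: FaceParams | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.image.shape


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    """Truncated normal by resampling; falls back to clipping."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(50):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _rot(vec: np.ndarray, deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def sample_params(state: str, rng_seed: int,
                  cfg: SceneConfig | None = None) -> FaceParams:
    """Draw ground-truth parameters for one face of the given state.

    Identical ``(state, rng_seed, cfg)`` always returns identical
    parameters. Raises :class:`InvalidLabelError` for unknown states.
    """
    if state not in STATES:
        raise InvalidLabelError(
            f"unknown state {state!r}; expected one of {STATES}")
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(rng_seed)
    # redraw until all anchor points land inside the head silhouette;
    # the rng stream continues, so the result stays seed-deterministic
    last_err = None
    for _ in range(50):
        try:
            return _sample_once(state, rng, cfg, rng_seed)
        except ValueError as err:
            last_err = err
    raise ValueError(
        f"could not sample valid geometry for state '{state}': {last_err}")


def _sample_once(state: str, rng: np.random.Generator, cfg: SceneConfig,
                 rng_seed: int) -> FaceParams:
    ss = cfg.spread_scale

    def draw(fieldname: str) -> float:
        mean, sd, lo, hi = _STATE_PRESETS[fieldname][state]
        return _trunc_normal(rng, mean, sd * ss, lo, hi)

    # nuisance scene geometry, independent of state
    hc = np.array(_HEAD_CENTER) + rng.normal(0, 4.0 * ss, 2)
    head_a = _trunc_normal(rng, 85.0, 3.0 * ss, 78.0, 92.0)
    head_b = _trunc_normal(rng, 72.0, 2.5 * ss, 66.0, 78.0)
    brightness = float(rng.uniform(0.85, 1.15))
    bg_color = tuple(int(v) for v in rng.integers(150, 215, 3))
    bg_seed = int(rng.integers(0, 2**31 - 1))

    ear_center = hc + np.array(_EAR_OFFSET) + rng.normal(0, 4.0 * ss, 2)
    ear_a = _trunc_normal(rng, 36.0, 2.5 * ss, 30.0, 42.0)
    ear_ecc = draw("ear_ecc")
    ear_b = ear_a * np.sqrt(1.0 - ear_ecc**2)
    ear_angle = draw("ear_angle")

    eye_center = hc + np.array(_EYE_OFFSET) + rng.normal(0, 3.0 * ss, 2)
    eye_a = _trunc_normal(rng, 13.0, 1.0 * ss, 10.0, 16.0)
    eye_ecc = draw("eye_ecc")
    eye_b = eye_a * np.sqrt(1.0 - eye_ecc**2)
    eye_angle = draw("eye_angle")

    mouth_point = hc + np.array(_MOUTH_OFFSET) + rng.normal(0, 3.0 * ss, 2)
    nose_point = hc + np.array(_NOSE_OFFSET) + rng.normal(0, 3.0 * ss, 2)

    if rng.random() < _MOUTH_OPEN_PROB[state]:
        mouth_gap = _trunc_normal(rng, *_MOUTH_GAP[state])
    else:
        mouth_gap = 0.0

    # jaw point: the jaw-mouth segment makes the configured interior
    # angle with the mouth-nose segment at the mouth vertex
    jaw_interior = draw("jaw_angle")
    jaw_len = _trunc_normal(rng, 40.0, 4.0 * ss, 30.0, 50.0)
    u = nose_point - mouth_point
    u = u / np.linalg.norm(u)
    jaw_dir = _rot(-u, 180.0 - jaw_interior)
    jaw_point = mouth_point + jaw_len * jaw_dir

    s = cfg.scale

    def pt(v) -> tuple[float, float]:
        return (float(v[0] * s), float(v[1] * s))

    params = FaceParams(
        state=state,
        ear_center=pt(ear_center), ear_a=ear_a * s, ear_b=ear_b * s,
        ear_angle=float(ear_angle),
        eye_center=pt(eye_center), eye_a=eye_a * s, eye_b=eye_b * s,
        eye_angle=float(eye_angle),
        mouth_gap=mouth_gap * s,
        jaw_point=pt(jaw_point), mouth_point=pt(mouth_point),
        nose_point=pt(nose_point),
        seed=int(rng_seed),
        head_center=pt(hc), head_a=head_a * s, head_b=head_b * s,
        brightness=brightness, bg_color=bg_color, bg_seed=bg_seed,
    )
    params.validate()
    return params


# ----------------------------------------------------------------- rendering

_HEAD_COLOR = np.array([125.0, 101.0, 82.0])
_EAR_COLOR = np.array([98.0, 78.0, 62.0])
_EAR_RIM_COLOR = np.array([72.0, 56.0, 44.0])
_EYE_COLOR = np.array([32.0, 28.0, 26.0])
_JAW_COLOR = np.array([70.0, 55.0, 45.0])
_MOUTH_COLOR = np.array([52.0, 30.0, 28.0])

_MOUTH_HALF_LEN = 12.0   # at REF_SIZE, along the mouth->nose direction
_MOUTH_THICKNESS = 2.5   # closed-lip band thickness at REF_SIZE
_MOUTH_CAVITY_PAD = 2.0  # parted-lip margin added to the open cavity
_JAW_THICKNESS = 3.0


def _ellipse_mask(shape: tuple[int, int], center, a: float, b: float,
                  angle_deg: float) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - center[0]
    dy = ys - center[1]
    r = np.deg2rad(angle_deg)
    xr = dx * np.cos(r) + dy * np.sin(r)
    yr = -dx * np.sin(r) + dy * np.cos(r)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _band_mask(shape: tuple[int, int], p0, p1, thickness: float) -> np.ndarray:
    """Pixels within thickness/2 of the segment p0-p1."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    L2 = float(d @ d)
    t = ((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / max(L2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    px = p0[0] + t * d[0]
    py = p0[1] + t * d[1]
    dist2 = (xs - px) ** 2 + (ys - py) ** 2
    return dist2 <= (thickness / 2.0) ** 2


def _check_in_frame(name: str, size: int, xmin, xmax, ymin, ymax) -> None:
    if xmin < 0 or ymin < 0 or xmax > size - 1 or ymax > size - 1:
        raise RenderError(
            f"part '{name}' extends outside the {size}x{size} frame")


def _background(size: int, style: str, color, bg_seed: int) -> np.ndarray:
    img = np.ones((size, size, 3)) * np.asarray(color, dtype=float)
    if style == "textured":
        rng = np.random.default_rng(bg_seed)
        ys, xs = np.mgrid[0:size, 0:size].astype(float)
        for _ in range(2):
            fx, fy = rng.uniform(1.0, 6.0, 2)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(4.0, 10.0)
            wave = amp * np.sin(2 * np.pi * (fx * xs + fy * ys) / size + phase)
            img += wave[..., None] * rng.uniform(0.5, 1.0, 3)
    return img


def render(params: FaceParams, cfg: SceneConfig | None = None) -> ImageRecord:
    """Render one face deterministically from its parameters.

    Returns an :class:`ImageRecord` whose ``masks`` dict holds boolean
    ground-truth masks for ``head``, ``ear``, ``eye``, ``mouth``, ``jaw``
    and the full ``subject`` silhouette. Raises :class:`RenderError`
    naming the first part that would leave the frame.
    """
    cfg = cfg or SceneConfig()
    params.validate()
    size = cfg.size
    s = cfg.scale
    shape = (size, size)

    # analytic extent checks before touching any pixels
    for name, c, a in (("ear", params.ear_center, params.ear_a),
                       ("eye", params.eye_center, params.eye_a)):
        _check_in_frame(name, size, c[0] - a, c[0] + a, c[1] - a, c[1] + a)
    jm = np.array([params.jaw_point, params.mouth_point, params.nose_point])
    pad = _JAW_THICKNESS * s
    _check_in_frame("jaw", size, jm[:, 0].min() - pad, jm[:, 0].max() + pad,
                    jm[:, 1].min() - pad, jm[:, 1].max() + pad)

    img = _background(size, cfg.bg_style, params.bg_color, params.bg_seed)

    head = _ellipse_mask(shape, params.head_center, params.head_a,
                         params.head_b, 0.0)
    img[head] = _HEAD_COLOR * params.brightness

    ear = _ellipse_mask(shape, params.ear_center, params.ear_a,
                        params.ear_b, params.ear_angle)
    rim = _ellipse_mask(shape, params.ear_center, params.ear_a + 1.5 * s,
                        params.ear_b + 1.5 * s, params.ear_angle) & ~ear
    img[rim] = _EAR_RIM_COLOR * params.brightness
    img[ear] = _EAR_COLOR * params.brightness

    jaw = (_band_mask(shape, params.jaw_point, params.mouth_point,
                      _JAW_THICKNESS * s)
           | _band_mask(shape, params.mouth_point, params.nose_point,
                        _JAW_THICKNESS * s))
    img[jaw] = _JAW_COLOR * params.brightness

    u = np.array(params.nose_point) - np.array(params.mouth_point)
    u = u / np.linalg.norm(u)
    half = _MOUTH_HALF_LEN * s
    mp = np.array(params.mouth_point)
    mouth = _band_mask(shape, mp - half * u, mp + half * u,
                       _MOUTH_THICKNESS * s)
    if params.mouth_gap > 0:
        cavity_b = params.mouth_gap / 2.0 + _MOUTH_CAVITY_PAD * s
        mouth_angle = float(np.degrees(np.arctan2(u[1], u[0]))) % 180.0
        cavity = _ellipse_mask(shape, mp, half, cavity_b, mouth_angle)
        mouth = mouth | cavity
    img[mouth] = _MOUTH_COLOR

    eye = _ellipse_mask(shape, params.eye_center, params.eye_a,
                        params.eye_b, params.eye_angle)
    img[eye] = _EYE_COLOR

    subject = head | rim | ear | jaw | mouth | eye
    masks = {"head": head, "ear": ear, "eye": eye, "mouth": mouth,
             "jaw": jaw, "subject": subject}
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    rec_id = f"{params.state}_{params.seed}"
    return ImageRecord(id=rec_id, label=params.state, image=image,
                       provenance="raw", masks=masks, params=params)


def generate_dataset(n_per_state: int, cfg: SceneConfig | None = None,
                     seed: int = 0) -> list[ImageRecord]:
    """Generate an exactly balanced labeled dataset.

    Per-record seeds are derived from ``seed`` so the whole dataset is
    reproducible from a single integer; records are ordered
    neutral → tail_pinch → brushing, then by index.
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    cfg = cfg or SceneConfig()
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=3 * n_per_state)
    records: list[ImageRecord] = []
    k = 0
    for state in STATES:
        for i in range(n_per_state):
            params = sample_params(state, int(child_seeds[k]), cfg)
            rec = render(params, cfg)
            rec.id = f"{state}_{i:04d}"
            records.append(rec)
            k += 1
    return records


# -------------------------------------------------------------- serialization

def save_dataset(records: list[ImageRecord], outdir: str | Path,
                 save_masks: bool = False) -> None:
    """Write PNG frames plus ground truth (JSON keyed by filename, and a
    flat CSV of FaceParams)."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: dict[str, dict] = {}
    rows = []
    for rec in records:
        fname = f"{rec.id}.png"
        Image.fromarray(rec.image).save(outdir / fname)
        if rec.params is not None:
            d = rec.params.to_dict()
            truth[fname] = d
            flat = {"image": fname, "label": rec.label}
            for key, val in d.items():
                if isinstance(val, list) and len(val) == 2:
                    flat[f"{key}_x"], flat[f"{key}_y"] = val
                elif isinstance(val, list):
                    flat[key] = ",".join(str(x) for x in val)
                else:
                    flat[key] = val
            rows.append(flat)
        if save_masks and rec.masks is not None:
            for part, m in rec.masks.items():
                Image.fromarray((m * 255).astype(np.uint8)).save(
                    outdir / f"{rec.id}_{part}_mask.png")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    if rows:
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "face_params.csv", index=False)
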