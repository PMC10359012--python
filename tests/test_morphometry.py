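"""The ten facial parameters: moment-fit oracle checks, angle
conventions, rigid-motion invariance, recovery of generator truth."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import special
from skimage.measure import regionprops

from mousemime.errors import (
    FitError,
    GeometryError,
    UndefinedOrientationError,
)
from mousemime.morphometry import (
    PARAMETER_NAMES,
    EllipseFit,
    eccentricity,
    ear_eye_relation,
    fit_ellipse,
    jaw_angle,
    measure_record,
    mouth_open,
    part_angle,
    perimeter,
)
from mousemime.synthetic_faces import _ellipse_mask


def _raster_ellipse(a, b, angle, size=128):
    return _ellipse_mask((size, size), (size / 2, size / 2), a, b, angle)


def test_fit_recovers_disk():
    fit = fit_ellipse(_raster_ellipse(20, 20, 0))
    assert fit.a == pytest.approx(20, rel=0.01)
    assert fit.b == pytest.approx(20, rel=0.01)


def test_fit_recovers_rotated_ellipse():
    fit = fit_ellipse(_raster_ellipse(30, 15, 40))
    assert fit.a == pytest.approx(30, rel=0.02)
    assert fit.b == pytest.approx(15, rel=0.02)
    assert fit.angle == pytest.approx(40, abs=1.0)


def test_fit_agrees_with_regionprops_oracle():
    mask = _raster_ellipse(25, 12, 117)
    fit = fit_ellipse(mask)
    props = regionprops(mask.astype(int))[0]
    assert fit.a == pytest.approx(props.axis_major_length / 2, rel=2e-3)
    assert fit.b == pytest.approx(props.axis_minor_length / 2, rel=2e-3)
    rp_angle = (90 - np.degrees(props.orientation)) % 180
    assert fit.angle == pytest.approx(rp_angle, abs=0.1)
    assert fit.center[0] == pytest.approx(props.centroid[1], abs=0.1)


def test_fit_rejects_degenerate_masks():
    with pytest.raises(FitError):
        fit_ellipse(np.zeros((10, 10), dtype=bool))
    single = np.zeros((10, 10), dtype=bool)
    single[5, 5] = True
    with pytest.raises(FitError):
        fit_ellipse(single)
    line = np.zeros((20, 20), dtype=bool)
    line[10, 2:18] = True
    with pytest.raises(FitError):
        fit_ellipse(line)


def test_eccentricity_values():
    assert eccentricity(EllipseFit((0, 0), 5, 5, 0)) == 0.0
    assert eccentricity(EllipseFit((0, 0), 5, 3, 0)) == pytest.approx(0.8)
    assert 0 <= eccentricity(EllipseFit((0, 0), 1e6, 1, 0)) < 1


def test_perimeter_circle_and_quadrature_oracle():
    assert perimeter(EllipseFit((0, 0), 10, 10, 0)) == \
        pytest.approx(2 * np.pi * 10, abs=1e-3)
    # exact perimeter via the complete elliptic integral of the 2nd kind
    a, b = 5.0, 3.0
    exact = 4 * a * special.ellipe(1 - (b / a) ** 2)
    assert perimeter(EllipseFit((0, 0), a, b, 0)) == \
        pytest.approx(exact, rel=1e-4)


@given(a=st.floats(2.0, 50.0), b=st.floats(1.0, 2.0))
def test_perimeter_monotone_in_major_axis(a, b):
    p1 = perimeter(EllipseFit((0, 0), a, b, 0))
    p2 = perimeter(EllipseFit((0, 0), a + 1.0, b, 0))
    assert p2 > p1


def test_part_angle_conventions():
    assert part_angle(fit_ellipse(_raster_ellipse(30, 10, 0))) == \
        pytest.approx(0, abs=0.5)
    assert part_angle(fit_ellipse(_raster_ellipse(30, 10, 90))) == \
        pytest.approx(90, abs=0.5)


def test_part_angle_equivariant_under_rotation():
    base = part_angle(fit_ellipse(_raster_ellipse(30, 12, 20)))
    rotated = part_angle(fit_ellipse(_raster_ellipse(30, 12, 45)))
    assert (rotated - base) % 180 == pytest.approx(25, abs=1.0)


def test_part_angle_undefined_for_circle():
    square = np.zeros((20, 20), dtype=bool)
    square[5:15, 5:15] = True  # equal second moments: no major axis
    with pytest.raises(UndefinedOrientationError):
        part_angle(fit_ellipse(square))


def test_jaw_angle_cases():
    assert jaw_angle((0, 0), (1, 0), (2, 0)) == pytest.approx(180)
    assert jaw_angle((0, 1), (0, 0), (1, 0)) == pytest.approx(90)
    with pytest.raises(GeometryError):
        jaw_angle((1, 1), (1, 1), (2, 2))


@given(theta=st.floats(0, 2 * np.pi), tx=st.floats(-50, 50),
       ty=st.floats(-50, 50))
def test_jaw_angle_rigid_motion_invariant(theta, tx, ty):
    pts = np.array([[0.0, 2.0], [1.0, 0.0], [3.0, 1.0]])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + [tx, ty]
    assert jaw_angle(*moved) == pytest.approx(jaw_angle(*pts), abs=1e-6)


def test_ear_eye_relation_geometry():
    e1 = EllipseFit((0, 0), 5, 3, 0)
    assert ear_eye_relation(e1, EllipseFit((10, 0), 5, 3, 0)) == \
        pytest.approx((0.0, 10.0))
    assert ear_eye_relation(e1, EllipseFit((0, 10), 5, 3, 0)) == \
        pytest.approx((90.0, 10.0))
    with pytest.raises(GeometryError):
        ear_eye_relation(e1, EllipseFit((0, 0), 4, 2, 0))


def test_mouth_open_thresholding():
    assert mouth_open(mouth_gap=0.0) == 0.0
    assert mouth_open(mouth_gap=50.0) == 1.0
    assert np.isnan(mouth_open())


def test_measure_record_populates_all_ten(frames256):
    for rec in frames256:
        vec = measure_record(rec).as_array()
        assert vec.shape == (10,)
        assert not np.isnan(vec).any()
        assert len(PARAMETER_NAMES) == 10


def test_measure_missing_part_is_nan(frames256):
    rec = frames256[0]
    masks = {k: v for k, v in rec.masks.items() if k != "eye"}
    from mousemime.morphometry import measure_all

    vec = measure_all(masks, {"jaw_point": rec.params.jaw_point,
                              "mouth_point": rec.params.mouth_point,
                              "nose_point": rec.params.nose_point})
    assert np.isnan(vec.eye_eccentricity)
    assert np.isnan(vec.ear_to_eye_distance)
    assert not np.isnan(vec.ear_eccentricity)


def test_parameter_recovery_on_corpus(morpho_corpus, morpho_analysis):
    """Every continuous parameter measured from rendered masks correlates
    with generator ground truth at r >= 0.9; the binary mouth state
    agrees >= 99%."""
    from mousemime.morphometry import jaw_angle as jaw

    tab = morpho_analysis["table"]
    recs = morpho_corpus
    p = [r.params for r in recs]
    truth = {
        "jaw_angle": [jaw(q.jaw_point, q.mouth_point, q.nose_point) for q in p],
        "ear_angle": [q.ear_angle for q in p],
        "ear_eccentricity": [q.ear_eccentricity for q in p],
        "eye_angle": [q.eye_angle for q in p],
        "eye_eccentricity": [q.eye_eccentricity for q in p],
        "ear_to_eye_distance": [float(np.hypot(
            q.eye_center[0] - q.ear_center[0],
            q.eye_center[1] - q.ear_center[1])) for q in p],
    }
    for name, t in truth.items():
        r = np.corrcoef(tab[name].to_numpy(), t)[0, 1]
        assert r >= 0.9, name
    agree = (tab["mouth_opening"].to_numpy()
             == [float(q.mouth_is_open) for q in p]).mean()
    assert agree >= 0.99
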