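"""Daily metric set, shift sensitivity, collimator pair, linearity, summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidqa import (ConsistencyError, InputError, NumericError, PortalImage,
                    analyze_acquisition, collimator_pair_center, depth_dose_bq,
                    linearity_fit, long_term_summary, mean_central_roi,
                    shift_sensitivity, wedge_factor)
from epidqa.errors import GeometryError
from epidqa.metrics import _roi_mask, sensitivity_frame
from epidqa.synthetic import (SYNERGY_MU_LADDER, TRUEBEAM_MU_LADDER,
                              SyntheticBeamSpec, WedgeSpec,
                              generate_linearity_series, generate_portal_image)


# -- mean_central_roi -----------------------------------------------------

def test_roi_mean_of_constant_image():
    img = PortalImage(np.full((128, 128), 3.5), 0.4, 1600.0)
    assert mean_central_roi(img, (0.0, 0.0)) == 3.5


def test_roi_covers_40x40_pixels_at_quarter_mm():
    """A 10 mm ROI on a 0.25 mm isocenter grid selects exactly 40 x 40 pixels."""
    img = PortalImage(np.ones((128, 128)), 0.4, 1600.0)
    assert _roi_mask(img, (0.0, 0.0), 10.0).sum() == 40 * 40


def test_roi_linearity_in_mu(default_spec):
    a = generate_portal_image(dataclasses.replace(default_spec, mu=100.0, offset=0.0))
    b = generate_portal_image(dataclasses.replace(default_spec, mu=200.0, offset=0.0))
    assert mean_central_roi(b, (0.0, 0.0)) == pytest.approx(
        2.0 * mean_central_roi(a, (0.0, 0.0)), rel=1e-12)


def test_roi_outside_grid_rejected(open_image):
    with pytest.raises(GeometryError):
        mean_central_roi(open_image, (100.0, 0.0))


# -- wedge factor, depth-dose BQ ------------------------------------------

def test_wedge_factor_arithmetic():
    assert wedge_factor(100.0, 100.0) == 1.0
    assert wedge_factor(60.0, 100.0) == pytest.approx(0.6)
    with pytest.raises(NumericError):
        wedge_factor(-1.0, 100.0)


@given(c=st.floats(1e-3, 1e6))
@settings(max_examples=25, deadline=None)
def test_wedge_factor_scale_invariance(c):
    assert wedge_factor(60.0 * c, 100.0 * c) == pytest.approx(0.6, rel=1e-12)


def test_depth_dose_bq():
    assert depth_dose_bq(50.0, 50.0) == 1.0
    assert depth_dose_bq(30.0, 60.0) == pytest.approx(0.5)
    assert depth_dose_bq(30.0 * 7, 60.0 * 7) == pytest.approx(0.5)
    with pytest.raises(NumericError):
        depth_dose_bq(0.0, 60.0)


# -- analyze_acquisition --------------------------------------------------

def test_acquisition_wedge_factor_matches_generator(open_image, wedge_image):
    m = analyze_acquisition(open_image, wedge_image)
    truth = wedge_image.ground_truth.expected_wedge_factor
    assert m.wedge_factor == pytest.approx(truth, rel=0.002)
    assert m.mu_open == pytest.approx(open_image.ground_truth.expected_mu, rel=0.001)


def test_acquisition_fff_has_no_flatness(fff_image):
    m = analyze_acquisition(fff_image, is_fff=True)
    assert m.flatness_x is None and m.flatness_y is None
    assert m.symmetry_x >= 0 and m.fff


def test_acquisition_open_only_has_no_wedge_factor(open_image):
    m = analyze_acquisition(open_image)
    assert m.mu_wedge is None and m.wedge_factor is None


def test_acquisition_rejects_mismatched_wedge_field(open_image, default_spec):
    small = generate_portal_image(dataclasses.replace(
        default_spec, field_x=92.0, field_y=92.0, wedge=WedgeSpec()))
    with pytest.raises(ConsistencyError):
        analyze_acquisition(open_image, small)


def test_wedge_factor_gain_invariance(open_image, wedge_image):
    """A global detector gain applied to both images cancels in W."""
    w0 = analyze_acquisition(open_image, wedge_image).wedge_factor
    gain = 1.37
    scaled_open = PortalImage(open_image.pixels * gain, open_image.pixel_spacing_detector,
                              open_image.sdd, sad=open_image.sad)
    scaled_wedge = PortalImage(wedge_image.pixels * gain, wedge_image.pixel_spacing_detector,
                               wedge_image.sdd, sad=wedge_image.sad,
                               modifier="wedge60")
    assert analyze_acquisition(scaled_open, scaled_wedge).wedge_factor == pytest.approx(
        w0, rel=1e-12)


# -- shift_sensitivity ----------------------------------------------------

def test_zero_offset_deviations_are_zero(open_image, wedge_image):
    recs = shift_sensitivity(open_image, wedge_image, offsets=[0.0])
    for r in recs:
        assert r.output_deviation == pytest.approx(0.0, abs=1e-12)
        assert r.bq_deviation == pytest.approx(0.0, abs=1e-12)


def test_left_right_symmetry_of_symmetric_beam(open_image):
    recs = shift_sensitivity(open_image, offsets=[1, 5, 10])
    devs = {(r.direction, r.offset): r.output_deviation for r in recs}
    for off in (1, 5, 10):
        assert devs[("left", off)] == pytest.approx(devs[("right", off)], abs=1e-9)
        assert devs[("gantry", off)] == pytest.approx(devs[("target", off)], abs=1e-9)


@pytest.mark.parametrize("beam", ["ff", "fff"])
def test_deviation_grows_past_ten_mm(beam, default_spec):
    """|output deviation| at 15 mm exceeds every deviation at <= 10 mm."""
    spec = dataclasses.replace(default_spec, beam_type=beam)
    recs = shift_sensitivity(generate_portal_image(spec))
    devs = {(r.direction, r.offset): abs(r.output_deviation) for r in recs}
    for direction in ("left", "right", "gantry", "target"):
        d15 = devs[(direction, 15.0)]
        assert all(devs[(direction, float(o))] < d15 for o in range(1, 11))


def test_roi_leaving_grid_is_flagged_not_fatal(open_image):
    recs = shift_sensitivity(open_image, offsets=[200.0])
    assert all(not r.ok and r.output_deviation is None for r in recs)


def test_sensitivity_frame_columns(open_image):
    df = sensitivity_frame(shift_sensitivity(open_image, offsets=[1, 2]))
    assert list(df.columns[:4]) == ["direction", "offset_mm", "output_dev_pct", "bq_dev_pct"]
    assert len(df) == 8


# -- collimator_pair_center -----------------------------------------------

def test_pair_center_of_identical_images(open_image):
    geom_center = collimator_pair_center(open_image, open_image)
    assert geom_center == pytest.approx((0.0, 0.0), abs=0.125)


def test_pair_center_is_mean(default_spec):
    a = generate_portal_image(dataclasses.replace(default_spec, shift_x=1.0))
    b = generate_portal_image(dataclasses.replace(default_spec, shift_x=-1.0))
    cx, cy = collimator_pair_center(a, b)
    assert cx == pytest.approx(0.0, abs=1e-6)
    assert cy == pytest.approx(0.0, abs=1e-6)


def test_pair_center_recovers_beam_center(default_spec):
    """Collimator-asymmetric offsets +-d about (2, -1) mm average out."""
    a = generate_portal_image(dataclasses.replace(default_spec, shift_x=2.8, shift_y=-1.5,
                                                  collimator_angle=90.0))
    b = generate_portal_image(dataclasses.replace(default_spec, shift_x=1.2, shift_y=-0.5,
                                                  collimator_angle=270.0))
    cx, cy = collimator_pair_center(a, b)
    assert cx == pytest.approx(2.0, abs=0.125)
    assert cy == pytest.approx(-1.0, abs=0.125)


# -- linearity ------------------------------------------------------------

def test_linearity_exact_line():
    series = [(mu, 2.0 * mu + 1.0) for mu in (1, 5, 10, 50)]
    slope, intercept, r2 = linearity_fit(series)
    assert slope == pytest.approx(2.0)
    assert intercept == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)


def test_linearity_requires_three_distinct_mu():
    with pytest.raises(InputError):
        linearity_fit([(1, 1), (2, 2)])
    with pytest.raises(InputError):
        linearity_fit([(1, 1), (1, 2), (1, 3)])


def test_linearity_permutation_invariance():
    rng = np.random.default_rng(0)
    series = [(mu, 3 * mu + rng.normal()) for mu in range(1, 20)]
    shuffled = [series[i] for i in rng.permutation(len(series))]
    assert linearity_fit(series) == pytest.approx(linearity_fit(shuffled))


@pytest.mark.parametrize("ladder", [SYNERGY_MU_LADDER, TRUEBEAM_MU_LADDER],
                         ids=["fine27", "high8"])
def test_noiseless_ladder_r2_and_slope(ladder, default_spec):
    """Noiseless MU ladders: R^2 = 1 to 1e-12 and slope recovered to 3 s.f."""
    images = generate_linearity_series(ladder, default_spec)
    series = []
    for img in images:
        series.append((img.mu, mean_central_roi(img, (0.0, 0.0))))
    slope, intercept, r2 = linearity_fit(series)
    assert 1.0 - r2 < 1e-12
    true_slope = (images[0].ground_truth.expected_mu - default_spec.offset) / images[0].mu
    assert slope == pytest.approx(true_slope, rel=5e-4)
    assert intercept == pytest.approx(default_spec.offset, rel=1e-6)


def test_noiseless_series_strictly_increasing(default_spec):
    images = generate_linearity_series((1, 10, 100, 300), default_spec)
    mus = [mean_central_roi(img, (0.0, 0.0)) for img in images]
    assert np.all(np.diff(mus) > 0)


# -- long_term_summary ----------------------------------------------------

def test_summary_constant_series_has_zero_sd():
    mean, sd = long_term_summary([1.0, 1.0, 1.0])
    assert mean[0] == 1.0 and sd[0] == 0.0


def test_summary_hand_example():
    mean, sd = long_term_summary([-1.0, 1.0])
    assert mean[0] == pytest.approx(0.0)
    assert sd[0] == pytest.approx(np.sqrt(2.0))


def test_summary_componentwise_and_translation_equivariant():
    centers = [(0.0, 1.0), (2.0, 3.0)]
    mean, sd = long_term_summary(centers)
    mean2, sd2 = long_term_summary([(x + 5, y + 5) for x, y in centers])
    assert np.allclose(mean2, mean + 5)
    assert np.allclose(sd2, sd)
    with pytest.raises(InputError):
        long_term_summary([(1.0, 2.0)])
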