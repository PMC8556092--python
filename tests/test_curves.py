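"""Curve I/O, peak finding and effective-point shift extraction."""

import io

import numpy as np
import pytest

from peffkit import synthbeam
from peffkit.curves import (
    BeamSetup,
    CurvePair,
    CurveParseError,
    DepthIonizationCurve,
    corrected_peak_depth,
    find_peak_depth,
    normalize_to_peak,
    peff_shift,
    read_curve,
    resample_monotone,
    shift_table,
    write_curve,
)


def _gaussian_curve(center=174.9, sigma=2.0, step=0.1, half=15.0, pedestal=0.0):
    d = np.arange(center - half, center + half + step / 2, step)
    return DepthIonizationCurve(d, pedestal + np.exp(-0.5 * ((d - center) / sigma) ** 2))


# ---------------------------------------------------------------------------
# I/O


def test_read_curve_roundtrip_bit_identical(pristine_330):
    buf = io.StringIO()
    write_curve(pristine_330, buf)
    back = read_curve(io.StringIO(buf.getvalue()))
    assert np.array_equal(back.depth_mm, pristine_330.depth_mm)
    assert np.array_equal(back.reading, pristine_330.reading)
    assert back.metadata["energy_mev_u"] == 330.0


def test_read_curve_parses_metadata_and_header():
    text = "# chamber=ptw_30013\n# energy_mev_u=330\ndepth_mm,reading\n" + "\n".join(
        f"{d},{v}" for d, v in zip(range(5), [1, 2, 5, 2, 1])
    )
    curve = read_curve(io.StringIO(text))
    assert curve.metadata == {"chamber": "ptw_30013", "energy_mev_u": 330}
    assert len(curve) == 5


def test_read_curve_tab_separated():
    text = "\n".join(f"{d}\t{v}" for d, v in zip(range(6), [1, 2, 5, 4, 2, 1]))
    assert len(read_curve(io.StringIO(text))) == 6


@pytest.mark.parametrize(
    "rows, message",
    [
        (["0,1", "1,2", "1,3", "2,1", "3,1"], "repeated depth"),
        (["0,1", "1,2", "2,-3", "3,1", "4,1"], "negative reading"),
        (["0,1", "1,2", "2,3"], ">= 5"),
    ],
)
def test_read_curve_validation_errors(rows, message):
    with pytest.raises(CurveParseError, match=message):
        read_curve(io.StringIO("\n".join(rows)))


def test_curve_invariants_direct_construction():
    with pytest.raises(CurveParseError, match="row 3"):
        DepthIonizationCurve([0, 1, 1, 2, 3], [1, 1, 1, 1, 1])
    with pytest.raises(CurveParseError):
        DepthIonizationCurve([0, 1, 2, 3], [1, 1, 1, 1])


# ---------------------------------------------------------------------------
# normalization


def test_normalize_to_peak_idempotent():
    curve = _gaussian_curve()
    scaled = DepthIonizationCurve(curve.depth_mm, 5.0 * curve.reading)
    once = normalize_to_peak(scaled)
    assert once.reading.max() == pytest.approx(1.0)
    twice = normalize_to_peak(once)
    assert np.array_equal(once.reading, twice.reading)
    assert once.metadata["normalized"] is True


def test_normalize_preserves_area_ratio():
    a = _gaussian_curve(sigma=1.5)
    b = _gaussian_curve(sigma=3.0)
    ratio_before = np.trapezoid(a.reading, a.depth_mm) / np.trapezoid(
        b.reading, b.depth_mm
    )
    na, nb = normalize_to_peak(a), normalize_to_peak(b)
    ratio_after = np.trapezoid(na.reading, na.depth_mm) / np.trapezoid(
        nb.reading, nb.depth_mm
    )
    # both peaks were already 1.0, so normalization is a no-op scale
    assert ratio_after == pytest.approx(ratio_before, rel=1e-12)


def test_normalize_all_zero_errors():
    with pytest.raises(ValueError):
        normalize_to_peak(DepthIonizationCurve(np.arange(5.0), np.zeros(5)))


# ---------------------------------------------------------------------------
# peak finding


def test_peak_exact_on_symmetric_gaussian():
    assert find_peak_depth(_gaussian_curve(center=174.9)) == pytest.approx(
        174.9, abs=1e-9
    )


def test_peak_exact_on_symmetric_peak_with_pedestal():
    assert find_peak_depth(_gaussian_curve(center=164.65, pedestal=0.3)) == (
        pytest.approx(164.65, abs=1e-9)
    )


def test_peak_matches_dense_grid_argmax(pristine_330):
    """Parabola vertex on a 0.1 mm grid vs argmax on a 1 um oracle grid."""
    model = synthbeam.BeamModel(energy=330.0)
    oracle = synthbeam.generate_pristine(model, 0.001)
    dense_argmax = oracle.depth_mm[np.argmax(oracle.reading)]
    assert abs(find_peak_depth(pristine_330) - dense_argmax) <= 0.05


def test_peak_tie_broken_toward_smaller_depth():
    d = np.arange(0.0, 10.5, 1.0)
    v = np.zeros_like(d)
    v[4] = v[6] = 1.0  # two equal maxima; windowing anchors on the first
    curve = DepthIonizationCurve(d, v)
    assert find_peak_depth(curve, window_mm=1.0) <= 5.0


def test_peak_at_boundary_raises():
    d = np.arange(0.0, 5.0)
    v = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    with pytest.raises(ValueError, match="extend"):
        find_peak_depth(DepthIonizationCurve(d, v))


# ---------------------------------------------------------------------------
# WET chains and shift bookkeeping


def _setup(total_wet: float) -> BeamSetup:
    return BeamSetup(
        chain=(
            ("tank wall", 5.0, total_wet - 10.0),
            ("clearance", 7.0, 7.0),
            ("window", 2.0, 3.0),
        )
    )


def test_corrected_peak_depth_adds_chain():
    curve = _gaussian_curve(center=174.9)
    assert corrected_peak_depth(curve, _setup(20.882)) == pytest.approx(195.782)
    farmer_curve = _gaussian_curve(center=164.65)
    assert corrected_peak_depth(farmer_curve, _setup(33.41)) == pytest.approx(198.06)
    assert corrected_peak_depth(curve, BeamSetup()) == pytest.approx(174.9)


def test_beam_setup_rejects_negative_wet():
    with pytest.raises(ValueError):
        BeamSetup(chain=(("bad", 1.0, -0.5),))


def test_peff_shift_printed_bookkeeping():
    shift, ratio = peff_shift(195.782, 198.06, 3.05)
    assert shift == pytest.approx(2.278)
    assert round(ratio, 4) == 0.7469
    shift, ratio = peff_shift(100.0, 102.269, 3.05)
    assert round(ratio, 3) == 0.744
    assert round(shift, 1) == 2.3
    assert peff_shift(50.0, 50.0, 3.05) == (0.0, 0.0)
    with pytest.raises(ValueError):
        peff_shift(1.0, 2.0, 0.0)


def test_shift_translation_invariance():
    curve_a = _gaussian_curve(center=174.9)
    curve_b = _gaussian_curve(center=164.65)
    base_a, base_b = _setup(20.882), _setup(33.41)
    shifted_a = BeamSetup(chain=base_a.chain + (("extra", 4.0, 4.0),))
    shifted_b = BeamSetup(chain=base_b.chain + (("extra", 4.0, 4.0),))
    _, r1 = peff_shift(
        corrected_peak_depth(curve_a, base_a),
        corrected_peak_depth(curve_b, base_b),
        3.05,
    )
    _, r2 = peff_shift(
        corrected_peak_depth(curve_a, shifted_a),
        corrected_peak_depth(curve_b, shifted_b),
        3.05,
    )
    assert r2 == pytest.approx(r1, abs=1e-12)


# ---------------------------------------------------------------------------
# shift table


def test_shift_table_summary(farmer):
    ref = _gaussian_curve(center=100.0)
    pairs = [
        CurvePair(330, 10, ref, _gaussian_curve(center=100.0 + 0.74 * 3.05)),
        CurvePair(330, 10, ref, _gaussian_curve(center=100.0 + 0.75 * 3.05)),
    ]
    table = shift_table(pairs, farmer)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["n"] == 2
    assert row["ratio_mean"] == pytest.approx(0.745, abs=1e-6)
    assert row["ratio_sd"] == pytest.approx(np.std([0.74, 0.75], ddof=1), abs=1e-6)


def test_shift_table_single_replicate_has_nan_sd(farmer):
    ref = _gaussian_curve(center=100.0)
    pairs = [CurvePair(120, 3, ref, _gaussian_curve(center=102.4))]
    table = shift_table(pairs, farmer)
    assert np.isnan(table.iloc[0]["ratio_sd"])


def test_shift_table_empty(farmer):
    assert shift_table([], farmer).empty


def test_shift_table_recovers_synthetic_ground_truth(farmer, pristine_330):
    cavity = synthbeam.CavityResponse(3.05, 0.744)
    pairs = [CurvePair(330, 10, pristine_330, synthbeam.apply_cavity(pristine_330, cavity))]
    table = shift_table(pairs, farmer)
    assert table.iloc[0]["ratio_mean"] == pytest.approx(0.744, abs=0.02)


def test_shift_table_requires_cylindrical_chamber():
    from peffkit.chambers import load_chamber

    with pytest.raises(ValueError):
        shift_table([], load_chamber("ptw_34080"))


def test_resample_monotone_is_for_plotting_only():
    curve = _gaussian_curve()
    res = resample_monotone(curve, np.linspace(165, 185, 401))
    assert res.metadata["resampled"] is True
    assert res.reading.min() >= 0
    # PCHIP does not overshoot the data range
    assert res.reading.max() <= curve.reading.max() + 1e-12
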