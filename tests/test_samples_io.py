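"""Unit and property tests for table reading, units, haloclines, labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from karstmix import (
    ReaderConfig,
    SondeProfile,
    ValidationError,
    WaterSample,
    chloride_to_salinity,
    classify_water_mass,
    detect_haloclines,
    read_sample_table,
    salinity_to_chloride,
)
from karstmix.synthetic import SondeConfig, generate_sonde_profile


# ---------------------------------------------------------------------------
# chloride → salinity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "chloride_mm, expected_psu",
    [
        (0.0, 0.0),
        (1.0, 35.453 * 0.0018066),       # 0.06405
        (546.0, 546 * 35.453 * 0.0018066),  # 34.97
    ],
)
def test_chloride_to_salinity_values(chloride_mm, expected_psu):
    assert chloride_to_salinity(chloride_mm) == pytest.approx(expected_psu, rel=1e-12)


def test_chloride_to_salinity_seawater_magnitude():
    # a sea-water chloride level must land near sea-water salinity
    assert chloride_to_salinity(546.0) == pytest.approx(34.97, abs=0.01)


def test_negative_chloride_rejected():
    with pytest.raises(ValidationError):
        chloride_to_salinity(-1.0)


@given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
def test_chloride_salinity_round_trip(cl):
    s = chloride_to_salinity(cl)
    assert s >= 0
    assert salinity_to_chloride(s) == pytest.approx(cl, rel=1e-9, abs=1e-9)


@given(
    st.floats(min_value=0.0, max_value=1e4),
    st.floats(min_value=1e-6, max_value=100.0),
)
def test_chloride_to_salinity_strictly_increasing(cl, dcl):
    assert chloride_to_salinity(cl + dcl) > chloride_to_salinity(cl)


# ---------------------------------------------------------------------------
# sample table reading
# ---------------------------------------------------------------------------

def _write(tmp_path, text, name="samples.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_well_formed_table(tmp_path):
    path = _write(
        tmp_path,
        "sample_id,salinity,ch4,doc\n"
        + "".join(f"s{i},0.3,{6000 + i},600\n" for i in range(5)),
    )
    result = read_sample_table(path)
    assert len(result.samples) == 5
    assert result.errors == []
    assert result.samples[0].ch4 == 6000


def test_invalid_row_flagged_not_dropped_silently(tmp_path):
    path = _write(
        tmp_path,
        "sample_id,salinity,ch4\n"
        "ok1,0.3,6000\nbad,-1,100\nok2,1.8,150\nok3,33,110\nok4,0.5,7000\n",
    )
    result = read_sample_table(path)
    assert len(result.samples) == 4
    assert len(result.errors) == 1
    assert result.errors[0].line == 3  # header is line 1
    assert "salinity" in result.errors[0].message


def test_unparseable_numeric_reported_with_line(tmp_path):
    path = _write(tmp_path, "sample_id,salinity,ch4\na,0.3,oops\nb,0.4,10\n")
    result = read_sample_table(path)
    assert len(result.samples) == 1
    assert result.errors[0].line == 2
    assert "oops" in result.errors[0].message


def test_missing_tracer_columns_is_an_error(tmp_path):
    path = _write(tmp_path, "sample_id,ch4\na,100\n")
    with pytest.raises(ValidationError):
        read_sample_table(path)


def test_salinity_derived_from_chloride(tmp_path):
    path = _write(tmp_path, "sample_id,chloride\na,546\n")
    result = read_sample_table(path)
    assert result.samples[0].salinity == pytest.approx(34.97, abs=0.01)


def test_chloride_mg_per_l_unit_flag(tmp_path):
    path = _write(tmp_path, "sample_id,chloride\na,19357.3\n")
    cfg = ReaderConfig(chloride_unit="mg/L")
    result = read_sample_table(path, cfg)
    assert result.samples[0].salinity == pytest.approx(34.97, abs=0.01)


def test_empty_cells_become_absent_fields_not_zero(tmp_path):
    path = _write(tmp_path, "sample_id,salinity,ch4,doc\na,0.3,6000,\n")
    result = read_sample_table(path)
    assert result.samples[0].doc is None


def test_table1_means_file_round_trips(table1_means_csv):
    result = read_sample_table(table1_means_csv)
    assert len(result.samples) == 3 and not result.errors
    mfw = next(s for s in result.samples if s.water_mass == "MFW")
    assert mfw.ch4 == pytest.approx(6466)
    assert mfw.doc == pytest.approx(661)
    assert mfw.d13c_ch4 == pytest.approx(-66.3)


def test_water_sample_requires_a_tracer():
    with pytest.raises(ValidationError):
        WaterSample(sample_id="x", ch4=100.0)


def test_delta_sanity_band_enforced():
    with pytest.raises(ValidationError):
        WaterSample(sample_id="x", salinity=0.3, d13c_ch4=-200.0)


def test_chloride_wins_over_salinity_column():
    # chloride is authoritative: the mismatching salinity column is replaced
    s = WaterSample(sample_id="x", salinity=10.0, chloride=546.0)
    assert s.salinity == pytest.approx(34.97, abs=0.01)


# ---------------------------------------------------------------------------
# sonde profiles and halocline detection
# ---------------------------------------------------------------------------

def test_profile_depth_must_increase():
    with pytest.raises(ValidationError):
        SondeProfile(depth=[0, 1, 1], salinity=[0.3, 0.3, 0.3])


def test_profile_salinity_inversion_rejected():
    with pytest.raises(ValidationError):
        SondeProfile(depth=[0, 1, 2], salinity=[2.0, 0.3, 2.0])


def test_detect_haloclines_on_generated_three_layer_column():
    profile, truth = generate_sonde_profile()
    found = detect_haloclines(profile)
    assert len(found) == 2
    assert [h.label for h in found] == ["H1", "H2"]
    for h, z_true in zip(found, truth["step_depths"]):
        assert abs(h.midpoint - z_true) <= truth["resolution"] / 2
    # steps recovered with the right amplitude ordering
    assert found[1].salinity_step > found[0].salinity_step > 0


@pytest.mark.parametrize("thickness", [0.2, 0.4, 0.6])
def test_halocline_thickness_recovered(thickness):
    cfg = SondeConfig(step_thickness=(thickness, thickness))
    profile, truth = generate_sonde_profile(cfg)
    found = detect_haloclines(profile)
    for h in found:
        assert h.thickness == pytest.approx(thickness, abs=2 * cfg.resolution)


def test_constant_profile_has_no_haloclines():
    profile = SondeProfile(
        depth=np.linspace(0, 10, 50), salinity=np.full(50, 0.5)
    )
    assert detect_haloclines(profile) == []


def test_single_step_profile_yields_one_labeled_h1():
    depth = np.linspace(0, 10, 101)
    sal = np.where(depth < 5, 0.5, 0.5 + np.clip((depth - 5) / 0.4, 0, 1) * 30)
    profile = SondeProfile(depth=depth, salinity=sal)
    found = detect_haloclines(profile)
    assert len(found) == 1
    assert found[0].label == "H1"


def test_profile_too_short_is_an_error():
    profile = SondeProfile(depth=[0.0, 0.2, 0.4], salinity=[0.3, 0.3, 0.3])
    with pytest.raises(ValidationError):
        detect_haloclines(profile)


# ---------------------------------------------------------------------------
# water-mass classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "salinity, label",
    [
        (0.26, "MFW"),
        (1.81, "MBW"),
        (32.87, "SGW"),
        (1.0, "MFW"),       # boundary belongs to the fresher mass
        (10.0, "MBW"),
        (20.0, "UNASSIGNED"),  # mixing interface band
        (30.0, "UNASSIGNED"),
    ],
)
def test_classify_water_mass(salinity, label):
    assert classify_water_mass(salinity) == label


@given(st.floats(min_value=0.0, max_value=45.0, allow_nan=False))
def test_classification_is_total_and_single_valued(s):
    label = classify_water_mass(s)
    assert label in ("MFW", "MBW", "SGW", "UNASSIGNED")
    # piecewise-constant: the same salinity always maps to the same label
    assert classify_water_mass(s) == label


def test_negative_salinity_rejected():
    with pytest.raises(ValidationError):
        classify_water_mass(-0.1)
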