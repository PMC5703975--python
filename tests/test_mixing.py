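"""Tests for mixing fractions, mixing lines, envelopes, and consumption."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from karstmix import (
    EndMemberPair,
    ValidationError,
    build_mixing_envelope,
    classify_deviation,
    conservative_concentration,
    conservative_delta,
    mixing_fraction,
    organic_carbon_partition,
    percent_consumed,
)

# water-mass mean salinities and concentrations used throughout
S_MFW, S_MBW, S_SGW = 0.26, 1.81, 32.87
F_MBW = (S_SGW - S_MBW) / (S_SGW - S_MFW)   # 0.95247


# ---------------------------------------------------------------------------
# mixing fraction
# ---------------------------------------------------------------------------

def test_fraction_endpoints():
    assert mixing_fraction(S_MFW, S_MFW, S_SGW).value == pytest.approx(1.0)
    assert mixing_fraction(S_SGW, S_MFW, S_SGW).value == pytest.approx(0.0)


def test_fraction_at_brackish_salinity():
    res = mixing_fraction(S_MBW, S_MFW, S_SGW)
    assert res.value == pytest.approx(0.9525, abs=1e-4)
    assert not res.out_of_bracket


def test_fraction_out_of_bracket_flagged_not_clamped():
    res = mixing_fraction(40.0, S_MFW, S_SGW)
    assert res.value < 0
    assert res.out_of_bracket


def test_degenerate_end_members_rejected():
    with pytest.raises(ValidationError):
        mixing_fraction(1.0, 2.0, 2.0)


# ---------------------------------------------------------------------------
# conservative concentration and δ
# ---------------------------------------------------------------------------

def test_concentration_end_member_identity():
    assert conservative_concentration(1.0, 6466, 110) == pytest.approx(6466)
    assert conservative_concentration(0.0, 6466, 110) == pytest.approx(110)


@pytest.mark.parametrize(
    "c_mfw, c_sgw, expected",
    [(6466.0, 110.0, 6163.9), (661.0, 41.0, 631.5)],
)
def test_concentration_at_brackish_fraction(c_mfw, c_sgw, expected):
    assert conservative_concentration(F_MBW, c_mfw, c_sgw) == pytest.approx(
        expected, abs=0.1
    )


def test_extrapolation_requires_opt_in():
    with pytest.raises(ValidationError):
        conservative_concentration(1.2, 100, 10)
    assert conservative_concentration(1.2, 100, 10, allow_extrapolation=True) == (
        pytest.approx(118.0)
    )


def test_delta_end_member_identity():
    assert conservative_delta(1.0, 6466, -66.3, 110, -56.3) == pytest.approx(-66.3)
    assert conservative_delta(0.0, 6466, -66.3, 110, -56.3) == pytest.approx(-56.3)


def test_delta_equal_concentrations_is_plain_average():
    assert conservative_delta(0.5, 100, -60.0, 100, -20.0) == pytest.approx(-40.0)


def test_delta_at_brackish_fraction_weighted_oracle():
    # independent weighted-average arithmetic
    c_mix = F_MBW * 6466 + (1 - F_MBW) * 110
    expected = (F_MBW * 6466 * -66.3 + (1 - F_MBW) * 110 * -56.3) / c_mix
    got = conservative_delta(F_MBW, 6466, -66.3, 110, -56.3)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(-66.29, abs=0.01)


def test_delta_of_two_empty_pools_undefined():
    with pytest.raises(ValidationError):
        conservative_delta(0.5, 0.0, -66.3, 0.0, -56.3)


@given(
    f=st.floats(min_value=0, max_value=1),
    c_mfw=st.floats(min_value=1e-3, max_value=1e4),
    c_sgw=st.floats(min_value=1e-3, max_value=1e4),
    d_mfw=st.floats(min_value=-100, max_value=0),
    d_sgw=st.floats(min_value=-100, max_value=0),
)
def test_isotope_mass_balance_property(f, c_mfw, c_sgw, d_mfw, d_sgw):
    """C_MIX·δ_MIX must equal the sum of the end-member isotope loads."""
    c_mix = conservative_concentration(f, c_mfw, c_sgw)
    d_mix = conservative_delta(f, c_mfw, d_mfw, c_sgw, d_sgw)
    lhs = c_mix * d_mix
    rhs = f * c_mfw * d_mfw + (1 - f) * c_sgw * d_sgw
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)
    assert min(d_mfw, d_sgw) - 1e-9 <= d_mix <= max(d_mfw, d_sgw) + 1e-9


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def _pair(c_mfw, c_sgw, d=None, event="e"):
    return EndMemberPair(
        constituent="CH4", tracer_mfw=S_MFW, tracer_sgw=S_SGW,
        c_mfw=c_mfw, c_sgw=c_sgw,
        d_mfw=d[0] if d else None, d_sgw=d[1] if d else None, event=event,
    )


def test_single_event_envelope_collapses_to_one_line():
    env = build_mixing_envelope([_pair(6466, 110, d=(-66.3, -56.3))], n_grid=50)
    assert np.allclose(env.lower_line, env.upper_line)
    assert np.allclose(env.lower_delta, env.upper_delta)


def test_nested_end_members_envelope_equals_outer_event():
    outer, inner = _pair(8000, 200, event="outer"), _pair(5000, 120, event="inner")
    env = build_mixing_envelope([outer, inner], n_grid=50)
    assert np.allclose(env.upper_line, outer.concentration_line(env.tracer_grid))
    assert np.allclose(env.lower_line, inner.concentration_line(env.tracer_grid))


def test_envelope_passes_through_extreme_end_members():
    env = build_mixing_envelope([_pair(5000, 100), _pair(8000, 300)], n_grid=50)
    assert env.lower_line[0] == pytest.approx(5000)
    assert env.upper_line[0] == pytest.approx(8000)
    assert env.lower_line[-1] == pytest.approx(100)
    assert env.upper_line[-1] == pytest.approx(300)


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=1.0, max_value=1e4),
            st.floats(min_value=1.0, max_value=1e4),
        ),
        min_size=1,
        max_size=5,
    )
)
def test_envelope_equals_brute_force_enumeration(concs):
    """Pointwise min/max over explicitly enumerated event lines."""
    pairs = [_pair(cm, cs, event=f"e{i}") for i, (cm, cs) in enumerate(concs)]
    grid = np.linspace(S_MFW, S_SGW, 50)
    env = build_mixing_envelope(pairs, tracer_grid=grid)
    for j, t in enumerate(grid):
        values = []
        for cm, cs in concs:
            f = (S_SGW - t) / (S_SGW - S_MFW)
            values.append(f * cm + (1 - f) * cs)
        assert env.lower_line[j] == pytest.approx(min(values), rel=1e-12)
        assert env.upper_line[j] == pytest.approx(max(values), rel=1e-12)
    # containment: every event line lies inside the envelope
    for p in pairs:
        line = p.concentration_line(grid)
        assert np.all(line >= env.lower_line - 1e-9)
        assert np.all(line <= env.upper_line + 1e-9)


def test_empty_pair_list_rejected():
    with pytest.raises(ValidationError):
        build_mixing_envelope([])


# ---------------------------------------------------------------------------
# deviation classification
# ---------------------------------------------------------------------------

def test_brackish_methane_classified_as_consumption():
    env = build_mixing_envelope([_pair(6466, 110)])
    assert classify_deviation(S_MBW, 157.0, env) == "consumption"


def test_sample_on_the_line_is_conservative():
    env = build_mixing_envelope([_pair(6466, 110)])
    on_line = conservative_concentration(F_MBW, 6466, 110)
    assert classify_deviation(S_MBW, on_line, env) == "conservative"


def test_sulfate_within_uncertainty_is_conservative():
    so4 = EndMemberPair(
        constituent="SO4", tracer_mfw=S_MFW, tracer_sgw=S_SGW,
        c_mfw=0.3, c_sgw=26.4,
    )
    env = build_mixing_envelope([so4])
    # measured brackish sulfate 1.6 mM vs mixing-line 1.54 mM: inside 1σ
    assert classify_deviation(S_MBW, 1.6, env, sigma=0.1) == "conservative"
    # without the uncertainty pad the same point reads as production
    assert classify_deviation(S_MBW, 1.6, env, sigma=0.0) == "production"


def test_tracer_outside_grid_span_is_an_error():
    env = build_mixing_envelope([_pair(6466, 110)])
    with pytest.raises(ValidationError):
        classify_deviation(40.0, 100.0, env)


# ---------------------------------------------------------------------------
# consumption statistic and organic-carbon partition
# ---------------------------------------------------------------------------

def test_no_removal_gives_zero_percent():
    res = percent_consumed(6164.0, 6164.0, 6466.0)
    assert res.percent_consumed == 0.0
    assert res.absolute_reduction == 0.0
    assert not res.net_production


@pytest.mark.parametrize(
    "c_mix, c_mbw, c_mfw, expected_pct, expected_rounded",
    [
        (6163.9, 157.0, 6466.0, 92.9, 93),
        (631.5, 131.0, 661.0, 75.7, 76),
    ],
)
def test_percent_consumed_reproduces_study_values(
    c_mix, c_mbw, c_mfw, expected_pct, expected_rounded
):
    res = percent_consumed(c_mix, c_mbw, c_mfw)
    assert res.percent_consumed == pytest.approx(expected_pct, abs=0.05)
    assert round(res.percent_consumed) == expected_rounded
    assert res.absolute_reduction == pytest.approx(c_mix - c_mbw, rel=1e-12)


def test_net_production_flagged_not_clipped():
    res = percent_consumed(100.0, 150.0, 500.0)
    assert res.percent_consumed == pytest.approx(-10.0)
    assert res.net_production


def test_percent_consumed_requires_positive_source():
    with pytest.raises(ValidationError):
        percent_consumed(100.0, 50.0, 0.0)


def test_full_chain_from_salinities_to_percent():
    """Mixing fraction → conservative blend → consumption, in one chain."""
    f = mixing_fraction(S_MBW, S_MFW, S_SGW).value
    c_mix = conservative_concentration(f, 6466.0, 110.0)
    res = percent_consumed(c_mix, 157.0, 6466.0)
    assert round(res.percent_consumed) == 93


def test_organic_carbon_partition_study_values():
    part = organic_carbon_partition(661.0, 10.9)
    assert part.ratio == pytest.approx(60.6, abs=0.1)
    assert part.poc_percent_of_doc == pytest.approx(1.6, abs=0.1)


def test_partition_identity_case():
    part = organic_carbon_partition(100.0, 100.0)
    assert part.ratio == pytest.approx(1.0)
    assert part.poc_percent_of_doc == pytest.approx(100.0)


def test_partition_requires_positive_poc():
    with pytest.raises(ValidationError):
        organic_carbon_partition(100.0, 0.0)
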