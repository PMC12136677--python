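"""Formula-level tests: impedance decomposition, phase angle, Kotler TBW,
specific indexes, and their algebraic identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biaindex import (
    derive_all,
    impedance_magnitude,
    phase_angle_deg,
    specific_indexes,
    tbw_kotler,
)
from biaindex.bioparams import DomainError
from biaindex.schema import COHORT_COLUMNS


# --- scalar examples -------------------------------------------------------

@pytest.mark.parametrize(
    "r, xc, expected",
    [
        (3.0, 4.0, 5.0),                      # right triangle
        (250.0, 0.0, 250.0),                  # purely resistive limit
        (867.0, 132.0, math.hypot(867, 132)),  # arithmetic oracle
    ],
)
def test_impedance_magnitude(r, xc, expected):
    assert impedance_magnitude(r, xc) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "r, xc, expected",
    [
        (100.0, 0.0, 0.0),
        (1.0, 1.0, 45.0),
        (867.0, 132.0, math.degrees(math.atan(132 / 867))),  # ≈ 8.657°
    ],
)
def test_phase_angle(r, xc, expected):
    theta = phase_angle_deg(r, xc)
    assert theta == pytest.approx(expected, rel=1e-12, abs=1e-12)
    assert 0.0 <= theta < 90.0


def test_phase_angle_derived_value():
    assert phase_angle_deg(867, 132) == pytest.approx(8.6568, abs=1e-4)


@pytest.mark.parametrize(
    "sex, h, w, z, expected",
    [
        # frozen from independent log-space evaluation of the Kotler equations
        ("male", 140.0, 35.0, 600.0, 22.165669912967964),
        ("female", 140.0, 32.0, 650.0, 21.135684245508674),
    ],
)
def test_tbw_kotler_examples(sex, h, w, z, expected):
    assert tbw_kotler(sex, h, w, z) == pytest.approx(expected, rel=1e-12)


def test_tbw_kotler_weight_linearity():
    """The weight term of the male equation is exactly +0.32 L per kg."""
    base = tbw_kotler("male", 150.0, 40.0, 700.0)
    bumped = tbw_kotler("male", 150.0, 41.0, 700.0)
    assert bumped - base == pytest.approx(0.32, abs=1e-12)


def test_specific_indexes_example():
    i_r, i_xc = specific_indexes(20.0, 800.0, 0.0, 140.0)
    assert i_r == pytest.approx(0.020 * 800 / 1.96, rel=1e-12)  # ≈ 8.163 Ω·m
    assert i_xc == 0.0
    assert specific_indexes(0.0, 800.0, 50.0, 140.0) == (0.0, 0.0)


@pytest.mark.parametrize(
    "func, args",
    [
        (impedance_magnitude, (0.0, 10.0)),
        (impedance_magnitude, (-5.0, 10.0)),
        (phase_angle_deg, (-1.0, 10.0)),
        (phase_angle_deg, (100.0, -1.0)),
        (tbw_kotler, ("male", 140.0, 35.0, 0.0)),
        (tbw_kotler, ("male", 0.0, 35.0, 600.0)),
        (specific_indexes, (20.0, 800.0, 100.0, 0.0)),
    ],
)
def test_domain_errors(func, args):
    with pytest.raises(DomainError):
        func(*args)


def test_domain_error_names_offending_field():
    with pytest.raises(DomainError, match="Z_ohm"):
        tbw_kotler("female", 140.0, 35.0, -2.0)


def test_unknown_sex_level_rejected():
    with pytest.raises(DomainError, match="sex"):
        tbw_kotler("F", 140.0, 35.0, 600.0)


# --- property tests --------------------------------------------------------

_heights = st.floats(70.0, 200.0)
_weights = st.floats(8.0, 120.0)
_zs = st.floats(200.0, 1500.0)
_sexes = st.sampled_from(["female", "male"])


@settings(max_examples=200, derandomize=True)
@given(sex=_sexes, h=_heights, w=_weights, z=_zs)
def test_tbw_log_space_oracle(sex, h, w, z):
    """Power terms agree with an independent log-space re-expression."""
    if sex == "male":
        expected = 0.58 * math.exp(1.62 * math.log(h) - 0.70 * math.log(z)) / 1.35
        expected += 0.32 * w - 3.66
    else:
        expected = 0.76 * math.exp(1.99 * math.log(h) - 0.58 * math.log(z)) / 18.91
        expected += 0.14 * w - 0.86
    assert tbw_kotler(sex, h, w, z) == pytest.approx(expected, rel=1e-9)


@settings(max_examples=100, derandomize=True)
@given(sex=_sexes, h=_heights, w=_weights, z=_zs)
def test_tbw_monotonicity(sex, h, w, z):
    """TBW strictly decreases in Z and increases in height and weight."""
    base = tbw_kotler(sex, h, w, z)
    assert tbw_kotler(sex, h, w, z * 1.05) < base
    assert tbw_kotler(sex, h * 1.05, w, z) > base
    assert tbw_kotler(sex, h, w + 1.0, z) > base


@settings(max_examples=200, derandomize=True)
@given(
    tbw=st.floats(1.0, 60.0),
    r=st.floats(100.0, 1200.0),
    xc=st.floats(0.1, 200.0),
    h=_heights,
)
def test_index_ratio_and_norm_identities(tbw, r, xc, h):
    """I_Xc/I_r = Xc/R exactly; the index norm equals TBW·Z/h² (SI units)."""
    i_r, i_xc = specific_indexes(tbw, r, xc, h)
    assert i_xc / i_r == pytest.approx(xc / r, rel=1e-12)
    z = impedance_magnitude(r, xc)
    norm = math.hypot(i_r, i_xc)
    assert norm == pytest.approx((tbw / 1000) * z / (h / 100) ** 2, rel=1e-9)
    theta_raw = phase_angle_deg(r, xc)
    assert i_xc / i_r == pytest.approx(math.tan(math.radians(theta_raw)), rel=1e-12)


# --- derive_all ------------------------------------------------------------

def test_derive_all_empty_cohort():
    empty = pd.DataFrame(columns=COHORT_COLUMNS)
    result = derive_all(empty)
    assert len(result.table) == 0
    assert len(result.rejections) == 0
    assert "I_r" in result.table.columns


def _single_record(**overrides):
    row = {
        "subject_id": "S1",
        "sex": "male",
        "age": 10.0,
        "height_cm": 140.0,
        "weight_kg": 35.0,
        "weight_status": "normal",
        "Z_ohm": math.hypot(600.0, 60.0),
        "R_ohm": 600.0,
        "Xc_ohm": 60.0,
        "Xcc_ohm": 48.0,
        "ECM_kg": 14.0,
        "TBW_L": 21.0,
        "ICW_L": 11.55,
        "ECW_L": 9.45,
    }
    row.update(overrides)
    return pd.DataFrame([row])


def test_derive_all_matches_scalar_operations():
    result = derive_all(_single_record())
    assert len(result.table) == 1
    row = result.table.iloc[0]
    z = math.hypot(600.0, 60.0)
    tbw = tbw_kotler("male", 140.0, 35.0, z)
    assert row["tbw_kotler_L"] == pytest.approx(tbw, rel=1e-12)
    assert row["theta_deg"] == pytest.approx(phase_angle_deg(600.0, 60.0), rel=1e-12)
    assert row["theta_dataset_deg"] == pytest.approx(phase_angle_deg(600.0, 48.0), rel=1e-12)
    i_r, i_xc = specific_indexes(tbw, 600.0, 60.0, 140.0)
    assert row["I_r"] == pytest.approx(i_r, rel=1e-12)
    assert row["I_Xc"] == pytest.approx(i_xc, rel=1e-12)


def test_derive_all_recovers_missing_resistance():
    frame = _single_record(R_ohm=np.nan)
    result = derive_all(frame)
    assert result.warnings["r_recovered"] == 1
    assert result.table.iloc[0]["theta_deg"] == pytest.approx(
        phase_angle_deg(600.0, 60.0), rel=1e-9
    )


def test_derive_all_rejects_implausible_tbw():
    """A huge Z drives Kotler TBW negative: excluded with a logged reason."""
    frame = pd.concat(
        [
            _single_record(),
            _single_record(
                subject_id="S2", weight_kg=9.0, Z_ohm=50000.0,
                R_ohm=49990.0, Xc_ohm=math.sqrt(50000.0**2 - 49990.0**2),
            ),
        ],
        ignore_index=True,
    )
    result = derive_all(frame)
    assert len(result.table) == 1
    assert result.warnings["tbw_nonpositive"] == 1
    assert "TBW" in result.rejections.iloc[0]["reason"]


def test_derive_all_preserves_row_order_and_input(derived, cohort):
    assert list(derived.table["subject_id"]) == list(cohort.table["subject_id"])
    assert "I_r" not in cohort.table.columns  # input not modified
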