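"""Agreement statistics against brute-force formula oracles and pingouin."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renovol.agreement import (
    AgreementReport,
    agreement_report,
    dsc,
    icc_absolute,
    lins_ccc,
    mean_difference_index,
)
from renovol.errors import ParameterError

SERIES_X = np.array([31.2, 45.8, 12.4, 60.1, 38.7, 25.3])
SERIES_Y = np.array([29.9, 47.2, 14.0, 57.5, 40.2, 24.1])


# --- DSC ------------------------------------------------------------------

def test_dsc_identical_and_disjoint_masks():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[1:3, 1:3, 1:3] = True
    assert dsc(a, a) == 1.0
    b = np.zeros_like(a)
    b[0, 0, 0] = True
    assert dsc(a, b) == 0.0


def test_dsc_matches_tp_fp_fn_count():
    """TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 2/3."""
    a = np.array([1, 1, 1, 0], dtype=bool).reshape(2, 2, 1)
    b = np.array([1, 1, 0, 1], dtype=bool).reshape(2, 2, 1)
    assert dsc(a, b) == pytest.approx(4.0 / 6.0, abs=1e-15)


def test_dsc_both_empty_convention():
    empty = np.zeros((3, 3, 3), dtype=bool)
    assert dsc(empty, empty) == 1.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_dsc_symmetry(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((5, 5, 5)) < 0.4
    b = rng.random((5, 5, 5)) < 0.4
    assert dsc(a, b) == dsc(b, a)


# --- Lin's CCC ------------------------------------------------------------

def test_ccc_perfect_concordance():
    value, ci = lins_ccc(SERIES_X, SERIES_X)
    assert value == 1.0
    assert ci == (1.0, 1.0)


def test_ccc_penalizes_constant_shift():
    y = SERIES_X + 5.0
    value, _ = lins_ccc(SERIES_X, y)
    assert value < 1.0  # pearson r is exactly 1 here


def test_ccc_matches_direct_formula_oracle():
    x, y = SERIES_X, SERIES_Y
    n = x.size
    mx, my = x.sum() / n, y.sum() / n
    sx2 = ((x - mx) ** 2).sum() / n
    sy2 = ((y - my) ** 2).sum() / n
    sxy = ((x - mx) * (y - my)).sum() / n
    expected = 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    value, ci = lins_ccc(x, y)
    assert value == pytest.approx(expected, abs=1e-12)
    assert ci[0] < value < ci[1]


def test_ccc_undefined_for_identical_constants():
    with pytest.raises(ParameterError):
        lins_ccc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_ccc_never_exceeds_absolute_pearson(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(10, 3, size=12)
    y = 0.5 * x + rng.normal(0, 2, size=12)
    value, _ = lins_ccc(x, y)
    r = np.corrcoef(x, y)[0, 1]
    assert value <= abs(r) + 1e-12


def test_ccc_ci_tightens_with_sample_size(rng):
    x = rng.normal(30, 8, size=400)
    y = x + rng.normal(0, 3, size=400)
    _, ci_big = lins_ccc(x, y)
    _, ci_small = lins_ccc(x[:20], y[:20])
    assert (ci_big[1] - ci_big[0]) < (ci_small[1] - ci_small[0])


# --- ICC(2,1) -------------------------------------------------------------

def test_icc_identical_series_is_one():
    value, ci = icc_absolute(SERIES_X, SERIES_X)
    assert value == pytest.approx(1.0)


def test_icc_matches_hand_computed_mean_squares():
    """4x2 table pushed through the two-way ANOVA decomposition by hand."""
    x = np.array([9.0, 6.0, 8.0, 7.0])
    y = np.array([2.0, 1.0, 4.0, 1.0])
    data = np.column_stack([x, y])
    n, k = 4, 2
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((data - grand) ** 2).sum()
        - (n - 1) * msr
        - (k - 1) * msc
    ) / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    value, _ = icc_absolute(x, y)
    assert value == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin_icc2():
    import pandas as pd
    import pingouin as pg

    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(SERIES_X.size), 2),
            "raters": ["a", "b"] * SERIES_X.size,
            "score": np.column_stack([SERIES_X, SERIES_Y]).ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
    row = ref[ref["Type"] == "ICC(A,1)"]  # absolute agreement, single rater
    ref_icc = float(row["ICC"].iloc[0])
    ref_ci = row["CI95"].iloc[0]  # reported rounded to 2 decimals
    value, ci = icc_absolute(SERIES_X, SERIES_Y)
    assert value == pytest.approx(ref_icc, abs=1e-10)
    assert ci[0] == pytest.approx(ref_ci[0], abs=0.006)
    assert ci[1] == pytest.approx(ref_ci[1], abs=0.006)


def test_icc_near_zero_for_independent_series(rng):
    x = rng.normal(size=200)
    y = rng.normal(size=200)
    value, _ = icc_absolute(x, y)
    assert abs(value) < 0.2


def test_icc_and_ccc_agree_on_equal_moment_bivariate_normal(rng):
    cov = [[1.0, 0.8], [0.8, 1.0]]
    data = rng.multivariate_normal([10, 10], cov, size=500)
    ccc, _ = lins_ccc(data[:, 0], data[:, 1])
    icc, _ = icc_absolute(data[:, 0], data[:, 1])
    assert abs(ccc - icc) < 0.02


# --- mean difference index ------------------------------------------------

def test_mean_difference_index_examples():
    assert mean_difference_index([10.0, 20.0], [10.0, 20.0]) == 0.0
    assert mean_difference_index([10.0, 20.0], [9.0, 22.0]) == pytest.approx(0.1, abs=1e-15)
    assert mean_difference_index([20.0, 40.0], [18.0, 44.0]) == pytest.approx(0.1, abs=1e-15)


def test_mean_difference_index_requires_positive_gt():
    with pytest.raises(ParameterError):
        mean_difference_index([10.0, 0.0], [9.0, 1.0])


# --- report ---------------------------------------------------------------

def test_report_perfect_agreement():
    rep = agreement_report(SERIES_X, SERIES_X)
    assert rep.lins_ccc == 1.0
    assert rep.icc == pytest.approx(1.0)
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.mean_difference_index == 0.0


def test_report_round_trips_through_json():
    masks = [(SERIES_X > 30, SERIES_Y > 30)]
    rep = agreement_report(SERIES_X, SERIES_Y, mask_pairs=masks)
    back = AgreementReport.from_json(rep.to_json())
    assert back == rep
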