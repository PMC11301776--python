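"""Calibration fitting, lower limits, acceptance rules and method comparison."""

import itertools
import math
import random

import numpy as np
import pytest

from surroquant import (
    CalibrationPoint,
    CalibrationStudy,
    assess_calibrators,
    assess_qc,
    back_calculate,
    compare_methods,
    fit_calibration,
    lower_limits,
)
from surroquant.validation import (
    DegenerateDesignError,
    InsufficientReplicationError,
    read_area_table,
)


def _points(analysis, level_ratios, reps=1):
    return [
        CalibrationPoint(analysis, level, tuple(ratios) if isinstance(ratios, (list, tuple)) else (ratios,) * reps)
        for level, ratios in level_ratios
    ]


# ---------------------------------------------------------------------------
# fit_calibration
# ---------------------------------------------------------------------------

def test_exact_line_recovered():
    pts = _points("a1", [(x, 2.0 * x + 0.5) for x in (1, 2, 4, 8)])
    fit = fit_calibration(pts)
    assert fit.slope == pytest.approx(2.0, abs=1e-12)
    assert fit.intercept == pytest.approx(0.5, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_single_level_is_degenerate():
    pts = _points("a1", [(5.0, 1.0), (5.0, 1.1)])
    with pytest.raises(DegenerateDesignError):
        fit_calibration(pts)


def test_mixed_analyses_rejected():
    pts = _points("a1", [(1, 1.0)]) + _points("a2", [(2, 2.0)])
    with pytest.raises(ValueError, match="multiple analyses"):
        fit_calibration(pts)


def _normal_equations(x, y, w):
    """Independent weighted least-squares oracle via explicit 2x2 solve."""
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return slope, intercept


@pytest.mark.parametrize("weighting", ["none", "1/x", "1/x2"])
def test_weighted_fit_matches_normal_equations(weighting):
    rng = np.random.default_rng(2024)
    levels = np.array([0.5, 1, 2, 5, 10, 50, 100.0])
    x = np.repeat(levels, 3)
    y = 0.02 * x + 0.1 + rng.normal(0, 0.01 * (1 + x), size=x.size)  # heteroscedastic
    pts = [
        CalibrationPoint("a1", lvl, tuple(y[x == lvl]))
        for lvl in levels
    ]
    fit = fit_calibration(pts, weighting=weighting)
    w = {"none": np.ones_like(x), "1/x": 1 / x, "1/x2": 1 / x**2}[weighting]
    slope, intercept = _normal_equations(x, y, w)
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)


def test_replicate_means_mode():
    pts = _points("a1", [(1, (1.0, 3.0)), (2, (4.0, 6.0))])
    fit = fit_calibration(pts, use_replicate_means=True)
    # means are 2 and 5 -> slope 3, intercept -1
    assert fit.slope == pytest.approx(3.0)
    assert fit.intercept == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# lower_limits
# ---------------------------------------------------------------------------

def _fit(analysis, slope, intercept):
    pts = _points(analysis, [(x, slope * x + intercept) for x in (1, 2, 4, 8, 16, 32)])
    return fit_calibration(pts)


def test_zero_variance_gives_zero_limits():
    fits = [_fit(f"a{i}", 2.0, 0.1) for i in range(3)]
    limits = lower_limits(fits)
    assert limits.sigma == pytest.approx(0.0, abs=1e-12)
    assert limits.llod == pytest.approx(0.0, abs=1e-12)
    assert limits.lloq == pytest.approx(0.0, abs=1e-12)


def test_direct_substitution_into_formula():
    # intercepts with SD 0.03 and slopes averaging 0.1
    intercepts = [0.07, 0.10, 0.13]
    sigma = float(np.std(intercepts, ddof=1))
    fits = [_fit(f"a{i}", 0.1, b) for i, b in enumerate(intercepts)]
    limits = lower_limits(fits)
    assert limits.sigma == pytest.approx(sigma, rel=1e-12)
    assert limits.llod == pytest.approx(3.3 * sigma / 0.1, rel=1e-9)
    assert limits.lloq == pytest.approx(10 * sigma / 0.1, rel=1e-9)


def test_lloq_llod_ratio_invariant():
    rng = random.Random(8)
    for _ in range(20):
        fits = [
            _fit(f"a{i}", rng.uniform(0.01, 5), rng.uniform(0, 1)) for i in range(4)
        ]
        limits = lower_limits(fits)
        if limits.llod > 0:
            assert limits.lloq / limits.llod == pytest.approx(10 / 3.3, rel=1e-12)


def test_insufficient_replication_rejected():
    fits = [_fit("a1", 1, 0), _fit("a2", 1, 0.1)]
    with pytest.raises(InsufficientReplicationError):
        lower_limits(fits)


# ---------------------------------------------------------------------------
# back_calculate
# ---------------------------------------------------------------------------

def test_back_calculation_inverts_fit():
    fit = _fit("a1", 2.0, 0.5)
    assert back_calculate(4.5, fit) == pytest.approx(2.0)
    assert back_calculate(fit.intercept, fit) == pytest.approx(0.0)


def test_back_calculation_roundtrip_property():
    rng = random.Random(4)
    for _ in range(50):
        fit = _fit("a1", rng.uniform(0.001, 10), rng.uniform(0, 2))
        c = rng.uniform(0, 1000)
        assert back_calculate(fit.predict(c), fit) == pytest.approx(c, abs=1e-9)


# ---------------------------------------------------------------------------
# calibrator / QC acceptance
# ---------------------------------------------------------------------------

LEVELS9 = (0.49, 0.98, 1.95, 3.91, 15.63, 62.50, 250.0, 500.0, 1000.0)


def test_perfect_line_passes_everywhere():
    fit = _fit("a1", 0.005, 0.01)
    pts = _points("a1", [(x, fit.predict(x)) for x in LEVELS9], reps=3)
    verdicts, overall = assess_calibrators(fit, pts)
    assert overall
    assert all(v.passed for v in verdicts)
    assert all(v.mean_recovery_pct == pytest.approx(100.0) for v in verdicts)
    # tolerance is 20% only at the LLOQ-level (lowest) calibrator
    assert verdicts[0].tolerance_pct == 20.0
    assert all(v.tolerance_pct == 15.0 for v in verdicts[1:])


def test_eighty_percent_recovery_fails_non_lloq_level():
    fit = _fit("a1", 1.0, 0.0)
    pts = _points("a1", [(1.0, 1.0), (10.0, 8.0), (100.0, 100.0)])
    verdicts, _ = assess_calibrators(fit, pts, lloq_level=1.0)
    by_level = {v.level: v for v in verdicts}
    assert by_level[10.0].mean_recovery_pct == pytest.approx(80.0)
    assert not by_level[10.0].passed
    assert by_level[100.0].passed


def test_overall_requires_six_passing_levels():
    fit = _fit("a1", 1.0, 0.0)
    good = [(float(x), float(x)) for x in (1, 2, 4, 8, 16)]
    bad = [(32.0, 16.0)]  # 50% recovery
    _, overall = assess_calibrators(fit, _points("a1", good + bad))
    assert not overall  # only five passing levels
    more_good = good + [(64.0, 64.0)]
    _, overall2 = assess_calibrators(fit, _points("a1", more_good + bad))
    assert overall2


def test_verdicts_match_spreadsheet_style_oracle():
    rng = np.random.default_rng(77)
    fit = _fit("a1", 0.01, 0.002)
    pts = []
    for level in LEVELS9:
        ratios = tuple(fit.predict(level) * np.exp(rng.normal(0, 0.05, 3)))
        pts.append(CalibrationPoint("a1", level, ratios))
    verdicts, _ = assess_calibrators(fit, pts)
    for v, p in zip(verdicts, sorted(pts, key=lambda q: q.nominal)):
        back = [(r - fit.intercept) / fit.slope for r in p.replicate_ratios]
        mean = sum(back) / len(back)
        sd = math.sqrt(sum((b - mean) ** 2 for b in back) / (len(back) - 1))
        assert v.mean_recovery_pct == pytest.approx(100 * mean / p.nominal)
        assert v.re_pct == pytest.approx(100 * (mean - p.nominal) / p.nominal)
        assert v.cv_pct == pytest.approx(100 * sd / mean)
        tol = 20.0 if p.nominal == min(LEVELS9) else 15.0
        expect_pass = (
            abs(v.mean_recovery_pct - 100) <= tol
            and v.cv_pct <= tol
            and abs(v.re_pct) <= tol
        )
        assert v.passed == expect_pass


def test_qc_uses_fifteen_percent_everywhere():
    fit = _fit("a1", 1.0, 0.0)
    verdicts = assess_qc([(125.0, (125.0, 125.0, 125.0)), (32.0, (37.1, 37.1, 37.1))], fit)
    assert verdicts[0].passed and verdicts[0].mean_recovery_pct == pytest.approx(100.0)
    # 116% recovery breaches the 115% bound even at the lowest QC level
    assert verdicts[1].mean_recovery_pct == pytest.approx(115.9375)
    assert not verdicts[1].passed
    assert all(v.tolerance_pct == 15.0 for v in verdicts)


def test_verdicts_invariant_to_common_area_rescaling():
    import pandas as pd

    rng = np.random.default_rng(5)
    rows = []
    for analysis in ("a1", "a2", "a3"):
        for level in LEVELS9:
            for rep in range(3):
                ratio = (0.005 * level + 0.01) * math.exp(rng.normal(0, 0.05))
                rows.append(
                    dict(
                        analysis_id=analysis,
                        sample_type="calibrator",
                        level_or_id=f"c{level}",
                        nominal=level,
                        replicate=rep,
                        area_analyte=ratio * 1e5,
                        area_is=1e5,
                    )
                )
    frame = pd.DataFrame(rows)
    scaled = frame.copy()
    scaled[["area_analyte", "area_is"]] *= 3.7
    res1 = CalibrationStudy(frame).fit()
    res2 = CalibrationStudy(scaled).fit()
    assert res1.verdict_frame()["pass"].tolist() == res2.verdict_frame()["pass"].tolist()
    assert res1.limits.llod == pytest.approx(res2.limits.llod)


# ---------------------------------------------------------------------------
# compare_methods (Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def _exact_two_sided_p(x, y):
    """Brute-force permutation oracle for the rank-sum test (no ties)."""
    combined = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    t_obs = sum(ranks[v] for v in x)
    m = len(x)
    stats_all = [
        sum(combined.index(v) + 1 for v in subset)
        for subset in itertools.combinations(combined, m)
    ]
    lo = sum(1 for t in stats_all if t <= t_obs) / len(stats_all)
    hi = sum(1 for t in stats_all if t >= t_obs) / len(stats_all)
    return min(1.0, 2 * min(lo, hi))


def test_identical_sets_not_significant():
    res = compare_methods({"s": [1.0, 2.0, 3.0]}, {"s": [1.0, 2.0, 3.0]})
    assert res[0].p_value == pytest.approx(1.0)
    assert not res[0].significant_05


def test_separated_triplets_exact_p():
    res = compare_methods({"s": [1.0, 2.0, 3.0]}, {"s": [10.0, 11.0, 12.0]})
    # one-sided tail is 1/20 over the 20 rank assignments -> two-sided 0.1
    assert res[0].p_value == pytest.approx(0.1)
    assert not res[0].significant_05


def test_exact_p_matches_permutation_enumeration():
    rng = random.Random(31)
    for _ in range(30):
        m = rng.randint(2, 5)
        n = rng.randint(2, min(5, 10 - m))
        vals = rng.sample(range(1000), m + n)
        x = [float(v) for v in vals[:m]]
        y = [float(v) for v in vals[m:]]
        res = compare_methods({"s": x}, {"s": y})
        assert res[0].p_value == pytest.approx(_exact_two_sided_p(x, y), abs=1e-12)


def test_p_values_symmetric_in_argument_order():
    x = [1.0, 5.0, 7.0]
    y = [2.0, 9.0, 11.0]
    a = compare_methods({"s": x}, {"s": y})[0].p_value
    b = compare_methods({"s": y}, {"s": x})[0].p_value
    assert a == pytest.approx(b)


def test_insufficient_replicates_flagged_not_raised():
    res = compare_methods({"s": [1.0]}, {"s": [2.0, 3.0]})
    assert math.isnan(res[0].p_value)
    assert "insufficient" in res[0].note


def test_paired_mode_uses_signed_rank():
    x = [10.0, 12.0, 14.0, 16.0, 18.0, 20.0]
    y = [v + 1 for v in x]
    res = compare_methods({"s": x}, {"s": y}, paired=True)
    from scipy import stats

    expected = float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    assert res[0].p_value == pytest.approx(expected)


# ---------------------------------------------------------------------------
# area-table reader
# ---------------------------------------------------------------------------

def test_reader_rejects_bad_sample_type(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(
        "analysis_id,sample_type,level_or_id,nominal,replicate,area_analyte,area_is\n"
        "a1,calibrator,c1,1.0,1,100,50\n"
        "a1,unknown,c1,1.0,2,100,50\n"
    )
    with pytest.raises(ValueError, match="row 3.*sample_type"):
        read_area_table(path)


def test_reader_rejects_nonpositive_area(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(
        "analysis_id,sample_type,level_or_id,nominal,replicate,area_analyte,area_is\n"
        "a1,calibrator,c1,1.0,1,0,50\n"
    )
    with pytest.raises(ValueError, match="area_analyte"):
        read_area_table(path)
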