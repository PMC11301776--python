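"""Calibration-curve fitting and bioanalytical method validation.

Quantitation rests on a linear calibration of the peak-area ratio
(analyte area / internal-standard area) on nominal concentration.  From
replicate calibration analyses the lower assay limits follow the ICH Q2
intercept-dispersion construction

    LLOD = 3.3 * sigma / S        LLOQ = 10 * sigma / S

where sigma is the standard deviation of the regression y-intercepts
across analyses and S is the slope.  Calibrators and QC samples are
judged by the FDA/ICH bioanalytical rules: mean back-calculated recovery,
%CV and %RE within +/-15% (+/-20% at the LLOQ-level calibrator), with at
least six nonzero calibrators passing per analysis.

The module is organised around a :class:`CalibrationStudy` model object
built from a tidy area table; its :meth:`~CalibrationStudy.fit` returns a
:class:`ValidationResults` carrying the per-analysis fits, the lower
limits, acceptance verdicts and a ``summary()`` table.  The underlying
operations (``fit_calibration``, ``lower_limits``, ``back_calculate``,
``assess_calibrators``, ``assess_qc``, ``compare_methods``) are plain
functions usable on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AcceptanceVerdict",
    "CalibrationFit",
    "CalibrationPoint",
    "CalibrationStudy",
    "DegenerateDesignError",
    "LowerLimits",
    "MethodComparison",
    "ValidationResults",
    "assess_calibrators",
    "assess_qc",
    "back_calculate",
    "compare_methods",
    "fit_calibration",
    "lower_limits",
    "read_area_table",
]

LLOD_FACTOR = 3.3
LLOQ_FACTOR = 10.0
DEFAULT_TOLERANCE_PCT = 15.0
LLOQ_TOLERANCE_PCT = 20.0
MIN_PASSING_CALIBRATORS = 6


class DegenerateDesignError(ValueError):
    """The calibration design cannot identify a slope (a single level)."""


class InsufficientReplicationError(ValueError):
    """Too few replicate analyses to estimate intercept dispersion."""


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate peak-area ratios measured at one nominal concentration."""

    analysis_id: str
    nominal: float
    replicate_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.nominal < 0:
            raise ValueError(f"nominal concentration must be >= 0, got {self.nominal}")
        if not self.replicate_ratios:
            raise ValueError("at least one replicate ratio is required")
        if any(r < 0 for r in self.replicate_ratios):
            raise ValueError("peak-area ratios must be >= 0")


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted calibration line: ratio = slope * nominal + intercept."""

    analysis_id: str
    slope: float
    intercept: float
    r_squared: float
    weighting: str  # "none" | "1/x" | "1/x2"
    n_points: int

    def predict(self, nominal: float) -> float:
        return self.slope * nominal + self.intercept


_WEIGHT_FUNCS = {
    "none": lambda x: np.ones_like(x),
    "1/x": lambda x: 1.0 / x,
    "1/x2": lambda x: 1.0 / x**2,
}


def fit_calibration(
    points: Sequence[CalibrationPoint],
    weighting: str = "none",
    use_replicate_means: bool = False,
) -> CalibrationFit:
    """Least-squares calibration line of ratio on nominal concentration.

    Replicates enter as individual observations by default (so the
    intercept dispersion feeding the LLOD has the correct degrees of
    freedom); ``use_replicate_means`` reproduces the mean-per-level fit
    seen on published calibration plots.  Weighting by 1/x or 1/x2 in
    nominal is available for heteroscedastic data.
    """
    if weighting not in _WEIGHT_FUNCS:
        raise ValueError(f"unknown weighting {weighting!r}; choose none, 1/x or 1/x2")
    if not points:
        raise ValueError("no calibration points supplied")
    ids = {p.analysis_id for p in points}
    if len(ids) > 1:
        raise ValueError(f"points span multiple analyses: {sorted(ids)}")
    if use_replicate_means:
        x = np.array([p.nominal for p in points], dtype=float)
        y = np.array([float(np.mean(p.replicate_ratios)) for p in points], dtype=float)
    else:
        x = np.array([p.nominal for p in points for _ in p.replicate_ratios], dtype=float)
        y = np.array([r for p in points for r in p.replicate_ratios], dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateDesignError(
            "all calibrators share one nominal level; the slope is unidentifiable"
        )
    if weighting != "none" and np.any(x <= 0):
        raise ValueError(f"{weighting} weighting requires strictly positive nominals")
    w = _WEIGHT_FUNCS[weighting](x)
    sw = np.sqrt(w)
    design = np.column_stack([x * sw, sw])
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * resid**2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(
        analysis_id=points[0].analysis_id,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        weighting=weighting,
        n_points=len(y),
    )


@dataclass(frozen=True)
class LowerLimits:
    """Lower assay limits from intercept dispersion across analyses."""

    sigma: float  # SD (n-1) of the per-analysis y-intercepts
    S: float  # pooled slope (mean of per-analysis slopes)
    llod: float
    lloq: float
    n_analyses: int


def lower_limits(fits: Sequence[CalibrationFit], min_fits: int = 3) -> LowerLimits:
    """LLOD = 3.3*sigma/S and LLOQ = 10*sigma/S across replicate analyses.

    sigma is the sample SD (n-1 denominator) of the y-intercepts of the
    per-analysis regression lines; S is the mean of their slopes.
    """
    if len(fits) < min_fits:
        raise InsufficientReplicationError(
            f"need at least {min_fits} replicate analyses, got {len(fits)}"
        )
    intercepts = np.array([f.intercept for f in fits], dtype=float)
    slopes = np.array([f.slope for f in fits], dtype=float)
    sigma = float(np.std(intercepts, ddof=1))
    S = float(np.mean(slopes))
    if S == 0:
        raise ValueError("pooled slope is zero; limits are undefined")
    llod = LLOD_FACTOR * sigma / S
    return LowerLimits(
        sigma=sigma,
        S=S,
        llod=llod,
        lloq=llod * (LLOQ_FACTOR / LLOD_FACTOR),
        n_analyses=len(fits),
    )


def back_calculate(ratio: float, fit: CalibrationFit) -> float:
    """Invert the calibration line: concentration = (ratio - intercept)/slope.

    The value may be negative for ratios below the fitted blank level; it
    is reported as-is so the caller can flag it against the LLOD.
    """
    if fit.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot back-calculate")
    return (ratio - fit.intercept) / fit.slope


@dataclass(frozen=True)
class AcceptanceVerdict:
    """FDA/ICH accuracy-precision verdict at one concentration level."""

    level: float
    mean_recovery_pct: float
    cv_pct: float
    re_pct: float
    tolerance_pct: float
    passed: bool


def _level_verdict(
    level: float, back_calcs: Sequence[float], tolerance_pct: float
) -> AcceptanceVerdict:
    arr = np.asarray(back_calcs, dtype=float)
    mean = float(arr.mean())
    recovery = 100.0 * mean / level
    re_pct = 100.0 * (mean - level) / level
    cv = 0.0 if len(arr) < 2 or mean == 0 else 100.0 * float(arr.std(ddof=1)) / abs(mean)
    passed = (
        abs(recovery - 100.0) <= tolerance_pct
        and cv <= tolerance_pct
        and abs(re_pct) <= tolerance_pct
    )
    return AcceptanceVerdict(level, recovery, cv, re_pct, tolerance_pct, passed)


def assess_calibrators(
    fit: CalibrationFit,
    points: Sequence[CalibrationPoint],
    lloq_level: float | None = None,
    min_passing: int = MIN_PASSING_CALIBRATORS,
) -> tuple[list[AcceptanceVerdict], bool]:
    """Per-level calibrator verdicts and the overall analysis verdict.

    Recovery tolerance is +/-20% at the LLOQ-level calibrator (by default
    the lowest nonzero level) and +/-15% elsewhere; the analysis passes
    iff at least ``min_passing`` nonzero levels pass.  Zero calibrators
    are excluded (recovery against a zero nominal is undefined).
    """
    nonzero = [p for p in points if p.nominal > 0]
    if lloq_level is None and nonzero:
        lloq_level = min(p.nominal for p in nonzero)
    verdicts = []
    for p in sorted(nonzero, key=lambda q: q.nominal):
        tol = LLOQ_TOLERANCE_PCT if p.nominal == lloq_level else DEFAULT_TOLERANCE_PCT
        back = [back_calculate(r, fit) for r in p.replicate_ratios]
        verdicts.append(_level_verdict(p.nominal, back, tol))
    overall = sum(v.passed for v in verdicts) >= min_passing
    return verdicts, overall


def assess_qc(
    qc_replicates: Sequence[tuple[float, Sequence[float]]],
    fit: CalibrationFit,
) -> list[AcceptanceVerdict]:
    """QC verdicts at +/-15% for all levels (QCs sit above the LLOQ)."""
    verdicts = []
    for level, ratios in qc_replicates:
        back = [back_calculate(r, fit) for r in ratios]
        verdicts.append(_level_verdict(level, back, DEFAULT_TOLERANCE_PCT))
    return verdicts


@dataclass(frozen=True)
class MethodComparison:
    """Wilcoxon rank-sum comparison of two IS methods on one sample."""

    sample_id: str
    mean_conc_method_a: float
    mean_conc_method_b: float
    p_value: float
    significant_05: bool
    significant_01: bool
    note: str = ""


def _rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact distribution when the combined sample is small (n <= 20) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    combined = list(x) + list(y)
    has_ties = len(set(combined)) < len(combined)
    if not has_ties and len(combined) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_methods(
    a: Mapping[str, Sequence[float]],
    b: Mapping[str, Sequence[float]],
    paired: bool = False,
) -> list[MethodComparison]:
    """Per-sample comparison of back-calculated concentrations.

    ``a`` and ``b`` map sample ids to replicate concentrations for the
    two IS methods.  The default test is the two-sided Wilcoxon rank-sum
    (independent replicate groups); ``paired=True`` switches to the
    signed-rank test on replicate-wise differences.
    """
    out: list[MethodComparison] = []
    for sample_id in a:
        if sample_id not in b:
            continue
        xa, xb = list(a[sample_id]), list(b[sample_id])
        mean_a, mean_b = float(np.mean(xa)), float(np.mean(xb))
        if len(xa) < 2 or len(xb) < 2 or (paired and len(xa) != len(xb)):
            out.append(
                MethodComparison(
                    sample_id, mean_a, mean_b, math.nan, False, False,
                    note="insufficient replicates for a test",
                )
            )
            continue
        if paired:
            diffs = np.subtract(xa, xb)
            if np.all(diffs == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(xa, xb, alternative="two-sided").pvalue)
        else:
            p = _rank_sum_p(xa, xb)
        out.append(
            MethodComparison(sample_id, mean_a, mean_b, p, p < 0.05, p < 0.01)
        )
    return out


# ---------------------------------------------------------------------------
# Tidy area-table dialect and the model/results objects
# ---------------------------------------------------------------------------

AREA_COLUMNS = [
    "analysis_id",
    "sample_type",
    "level_or_id",
    "nominal",
    "replicate",
    "area_analyte",
    "area_is",
]
SAMPLE_TYPES = {"calibrator", "qc", "sample", "blank"}


def read_area_table(path: str | Path) -> pd.DataFrame:
    """Read the delimited area table, validating columns and values."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in AREA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_types = set(frame["sample_type"]) - SAMPLE_TYPES
    if bad_types:
        row = frame.index[~frame["sample_type"].isin(SAMPLE_TYPES)][0]
        raise ValueError(
            f"{path}: row {row + 2}, column sample_type: "
            f"unknown value(s) {sorted(bad_types)}"
        )
    for col in ("area_analyte", "area_is"):
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            row = frame.index[values.isna()][0]
            raise ValueError(f"{path}: row {row + 2}, column {col}: non-numeric value")
        if (values <= 0).any():
            row = frame.index[values <= 0][0]
            raise ValueError(f"{path}: row {row + 2}, column {col}: area must be > 0")
        frame[col] = values
    return frame


def _points_from_frame(frame: pd.DataFrame, sample_type: str) -> dict[str, list[CalibrationPoint]]:
    """Group rows into CalibrationPoints per analysis."""
    sub = frame[frame["sample_type"] == sample_type]
    points: dict[str, list[CalibrationPoint]] = {}
    for (analysis, nominal), grp in sub.groupby(["analysis_id", "nominal"], sort=True):
        ratios = tuple(grp["area_analyte"] / grp["area_is"])
        points.setdefault(str(analysis), []).append(
            CalibrationPoint(str(analysis), float(nominal), ratios)
        )
    return points


@dataclass
class CalibrationStudy:
    """Model object: a multi-analysis calibration study with optional QCs.

    Construct from a tidy DataFrame in the documented dialect or from a
    delimited file, then call :meth:`fit`.
    """

    data: pd.DataFrame
    weighting: str = "none"
    min_fits_for_limits: int = 3

    def __post_init__(self) -> None:
        missing = [c for c in AREA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"area table is missing columns {missing}")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CalibrationStudy":
        return cls(read_area_table(path), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "CalibrationStudy":
        return cls(frame.copy(), **kwargs)

    def fit(
        self,
        weighting: str | None = None,
        lloq_level: float | None = None,
    ) -> "ValidationResults":
        """Fit per-analysis calibration lines and evaluate acceptance."""
        weighting = weighting or self.weighting
        cal_points = _points_from_frame(self.data, "calibrator")
        if not cal_points:
            raise ValueError("area table contains no calibrator rows")
        fits: dict[str, CalibrationFit] = {}
        calibrator_verdicts: dict[str, list[AcceptanceVerdict]] = {}
        analysis_pass: dict[str, bool] = {}
        for analysis, points in sorted(cal_points.items()):
            fit = fit_calibration(points, weighting=weighting)
            fits[analysis] = fit
            verdicts, ok = assess_calibrators(fit, points, lloq_level=lloq_level)
            calibrator_verdicts[analysis] = verdicts
            analysis_pass[analysis] = ok
        limits = None
        if len(fits) >= self.min_fits_for_limits:
            limits = lower_limits(list(fits.values()), min_fits=self.min_fits_for_limits)
        qc_points = _points_from_frame(self.data, "qc")
        qc_verdicts = {
            analysis: assess_qc([(p.nominal, p.replicate_ratios) for p in pts], fits[analysis])
            for analysis, pts in sorted(qc_points.items())
            if analysis in fits
        }
        samples = self._sample_concentrations(fits)
        return ValidationResults(
            study=self,
            weighting=weighting,
            fits=fits,
            limits=limits,
            calibrator_verdicts=calibrator_verdicts,
            analysis_pass=analysis_pass,
            qc_verdicts=qc_verdicts,
            sample_concentrations=samples,
        )

    def _sample_concentrations(
        self, fits: Mapping[str, CalibrationFit]
    ) -> dict[str, list[float]]:
        """Back-calculate study-sample replicate concentrations.

        Samples are quantified against the calibration fit of their own
        analysis when available, else against the last analysis (the
        external-curve convention for study samples).
        """
        sub = self.data[self.data["sample_type"] == "sample"]
        out: dict[str, list[float]] = {}
        if sub.empty:
            return out
        last = sorted(fits)[-1]
        for (analysis, sample_id), grp in sub.groupby(["analysis_id", "level_or_id"], sort=True):
            fit = fits.get(str(analysis), fits[last])
            concs = [back_calculate(r, fit) for r in grp["area_analyte"] / grp["area_is"]]
            out.setdefault(str(sample_id), []).extend(concs)
        return out


@dataclass
class ValidationResults:
    """Results object carrying fits, limits, verdicts and sample estimates."""

    study: CalibrationStudy
    weighting: str
    fits: dict[str, CalibrationFit]
    limits: LowerLimits | None
    calibrator_verdicts: dict[str, list[AcceptanceVerdict]]
    analysis_pass: dict[str, bool]
    qc_verdicts: dict[str, list[AcceptanceVerdict]] = field(default_factory=dict)
    sample_concentrations: dict[str, list[float]] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        """True iff every analysis meets the >=6-passing-calibrator rule."""
        return all(self.analysis_pass.values())

    def verdict_frame(self) -> pd.DataFrame:
        """Calibrator and QC verdicts as one tidy DataFrame."""
        rows = []
        for kind, table in (("calibrator", self.calibrator_verdicts), ("qc", self.qc_verdicts)):
            for analysis, verdicts in table.items():
                for v in verdicts:
                    rows.append(
                        {
                            "analysis_id": analysis,
                            "kind": kind,
                            "level": v.level,
                            "mean_recovery_pct": v.mean_recovery_pct,
                            "cv_pct": v.cv_pct,
                            "re_pct": v.re_pct,
                            "tolerance_pct": v.tolerance_pct,
                            "pass": v.passed,
                        }
                    )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """Machine-readable report."""
        return {
            "weighting": self.weighting,
            "fits": {
                a: {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                    "n_points": f.n_points,
                }
                for a, f in self.fits.items()
            },
            "limits": None
            if self.limits is None
            else {
                "sigma": self.limits.sigma,
                "S": self.limits.S,
                "llod": self.limits.llod,
                "lloq": self.limits.lloq,
                "n_analyses": self.limits.n_analyses,
            },
            "analysis_pass": self.analysis_pass,
            "overall_pass": self.overall_pass,
            "verdicts": self.verdict_frame().to_dict(orient="records"),
            "sample_concentrations": self.sample_concentrations,
        }

    def summary(self) -> str:
        """Human-readable validation summary."""
        lines = ["Calibration study validation", "=" * 28, ""]
        lines.append(f"Weighting: {self.weighting}")
        lines.append("")
        lines.append(f"{'analysis':<12}{'slope':>12}{'intercept':>12}{'R^2':>10}{'n':>5}  verdict")
        for a, f in self.fits.items():
            verdict = "pass" if self.analysis_pass[a] else "FAIL"
            lines.append(
                f"{a:<12}{f.slope:>12.6g}{f.intercept:>12.6g}{f.r_squared:>10.5f}"
                f"{f.n_points:>5}  {verdict}"
            )
        if self.limits is not None:
            lines.append("")
            lines.append(
                f"Lower limits over {self.limits.n_analyses} analyses: "
                f"sigma = {self.limits.sigma:.6g}, S = {self.limits.S:.6g}, "
                f"LLOD = {self.limits.llod:.4g}, LLOQ = {self.limits.lloq:.4g}"
            )
        frame = self.verdict_frame()
        if not frame.empty:
            lines.append("")
            lines.append("Per-level verdicts (recovery %, CV %, RE %):")
            lines.append(frame.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        if self.sample_concentrations:
            lines.append("")
            lines.append("Study-sample mean concentrations:")
            for sid, concs in self.sample_concentrations.items():
                lines.append(f"  {sid}: {np.mean(concs):.4g} (n={len(concs)})")
        return "\n".join(lines)


def compare_is_modes(
    frame: pd.DataFrame, mode_column: str = "is_mode", **study_kwargs
) -> list[MethodComparison]:
    """Fit one study per IS mode in a combined table and compare samples.

    The table must carry a ``mode_column`` with exactly two values (e.g.
    ``sil`` and ``matrix``); back-calculated study-sample concentrations
    are compared per sample with the Wilcoxon rank-sum test.
    """
    if mode_column not in frame.columns:
        raise ValueError(f"table has no {mode_column!r} column")
    modes = sorted(frame[mode_column].unique())
    if len(modes) != 2:
        raise ValueError(f"expected exactly two IS modes, found {modes}")
    results = {
        mode: CalibrationStudy(frame[frame[mode_column] == mode].copy(), **study_kwargs).fit()
        for mode in modes
    }
    return compare_methods(
        results[modes[0]].sample_concentrations,
        results[modes[1]].sample_concentrations,
    )
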