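"""Assay-validation statistics for allele-specific qPCR.

Covers the validation stages of a quantitative molecular assay:

* amplification-efficiency estimation from serial-dilution standard
  curves, with slope-equality testing (the efficiency premise of the
  comparative-Cq method);
* limit of detection by probit regression on replicate detection data;
* limit of quantification by observed-vs-expected one-sample t tests
  down a dilution series;
* precision as within-run / between-day / total CVs from a balanced
  day-by-replicate design (one-way random-effects variance components,
  CLSI EP05 style);
* trueness and specimen agreement: Pearson correlation, ordinary least
  squares, Bland-Altman bias with limits of agreement, and qualitative
  2x2 agreement.

Model fits go through scipy/statsmodels; the surrounding estimators and
decision rules are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DetectionTable",
    "ProbitFit",
    "ProbitConvergenceError",
    "probit_lod",
    "fit_standard_curve",
    "efficiency_from_slope",
    "SlopeComparison",
    "compare_slopes",
    "one_sample_t_from_summary",
    "LoqLevel",
    "LoqResult",
    "loq_assessment",
    "PrecisionResult",
    "precision_analysis",
    "MethodComparisonResult",
    "method_comparison",
    "method_comparison_subgroups",
    "AgreementResult",
    "qualitative_agreement",
]


# --------------------------------------------------------------------------
# detection panel and probit LOD

@dataclass(frozen=True)
class DetectionTable:
    """Replicate detection counts per mutant-allele level (strictly
    decreasing levels, percent scale)."""

    levels_percent: tuple[float, ...]
    n_tested: tuple[int, ...]
    n_detected: tuple[int, ...]

    def __init__(self, levels_percent, n_tested, n_detected):
        levels = tuple(float(x) for x in levels_percent)
        tested = tuple(int(x) for x in n_tested)
        detected = tuple(int(x) for x in n_detected)
        if not (len(levels) == len(tested) == len(detected)):
            raise ValueError("columns must have equal length")
        if any(x <= 0 for x in levels):
            raise ValueError("levels must be positive percents")
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly decreasing")
        if any(not 0 <= d <= n for d, n in zip(detected, tested)):
            raise ValueError("need 0 <= n_detected <= n_tested")
        object.__setattr__(self, "levels_percent", levels)
        object.__setattr__(self, "n_tested", tested)
        object.__setattr__(self, "n_detected", detected)

    def detection_rate(self) -> np.ndarray:
        return np.asarray(self.n_detected) / np.asarray(self.n_tested)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_percent": self.levels_percent,
                "n_tested": self.n_tested,
                "n_detected": self.n_detected,
                "detection_rate": self.detection_rate(),
            }
        )


class ProbitConvergenceError(RuntimeError):
    """Probit MLE did not converge (e.g. complete separation: all-hit
    levels strictly above all-miss levels with no partial level)."""


@dataclass(frozen=True)
class ProbitFit:
    """Fitted detection model P(detect) = Phi(intercept + slope * dose).

    ``dose_scale`` is "linear" (dose = percent) or "log10"
    (dose = log10 percent).  ``lod`` is the level at which the fitted
    detection probability equals ``target_probability``, with a
    delta-method Wald CI computed on the dose scale.
    """

    intercept: float
    slope: float
    lod: float
    lod_ci: tuple[float, float]
    target_probability: float
    dose_scale: str
    fitted_probabilities: tuple[float, ...]
    levels_percent: tuple[float, ...]
    converged: bool

    def _dose(self, level_percent) -> np.ndarray:
        x = np.asarray(level_percent, dtype=float)
        return np.log10(x) if self.dose_scale == "log10" else x

    def predict(self, level_percent):
        """Fitted detection probability at the given percent level(s)."""
        return stats.norm.cdf(self.intercept + self.slope * self._dose(level_percent))


def probit_lod(
    table: DetectionTable,
    target_probability: float = 0.95,
    dose_scale: str = "linear",
) -> ProbitFit:
    """Limit of detection by maximum-likelihood probit regression.

    Fits Phi(a + b*dose) to detected/tested counts, with the dose either
    the percent level itself (default) or its log10.  The LOD is the
    level at the target detection probability,
    ``dose* = (Phi^-1(target) - a) / b``, with a 95% Wald interval from
    the delta method on the dose scale.

    Raises :class:`ProbitConvergenceError` when the MLE diverges
    (complete separation) instead of returning a silent estimate.
    """
    if dose_scale not in ("linear", "log10"):
        raise ValueError("dose_scale must be 'linear' or 'log10'")
    if not 0 < target_probability < 1:
        raise ValueError("target_probability must lie in (0, 1)")
    levels = np.asarray(table.levels_percent)
    dose = np.log10(levels) if dose_scale == "log10" else levels
    detected = np.asarray(table.n_detected)
    tested = np.asarray(table.n_tested)

    exog = sm.add_constant(dose)
    model = sm.GLM(
        np.column_stack([detected, tested - detected]),
        exog,
        family=sm.families.Binomial(link=sm.families.links.Probit()),
    )
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(maxiter=200)
    except PerfectSeparationWarning as exc:
        raise ProbitConvergenceError(
            "probit MLE diverged: the detection levels are completely "
            "separated (no partially detected level); add informative "
            "levels between the all-miss and all-hit regions"
        ) from exc
    except Exception as exc:  # perfect separation can break IRLS outright
        raise ProbitConvergenceError(f"probit MLE failed: {exc}") from exc
    a, b = res.params
    cov = np.asarray(res.cov_params())
    if (
        not res.converged
        or not np.all(np.isfinite(cov))
        or max(abs(a), abs(b)) > 1e4
        or b <= 0
    ):
        raise ProbitConvergenceError(
            "probit MLE diverged (likely complete separation between "
            f"all-miss and all-hit levels); params a={a:.3g}, b={b:.3g}"
        )

    z = stats.norm.ppf(target_probability)
    dose_star = (z - a) / b
    grad = np.array([-1.0 / b, -(z - a) / b**2])
    se = float(np.sqrt(grad @ cov @ grad))
    lo, hi = dose_star - 1.96 * se, dose_star + 1.96 * se
    if dose_scale == "log10":
        lod, ci = 10.0**dose_star, (10.0**lo, 10.0**hi)
    else:
        lod, ci = float(dose_star), (float(lo), float(hi))

    fitted = stats.norm.cdf(a + b * dose)
    return ProbitFit(
        intercept=float(a),
        slope=float(b),
        lod=lod,
        lod_ci=ci,
        target_probability=target_probability,
        dose_scale=dose_scale,
        fitted_probabilities=tuple(float(p) for p in fitted),
        levels_percent=table.levels_percent,
        converged=True,
    )


# --------------------------------------------------------------------------
# standard curves and efficiency

def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(-1/slope) - 1 from a
    Cq-vs-log10(concentration) slope (must be negative)."""
    if slope >= 0:
        raise ValueError("slope must be negative for an amplifying assay")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    min_points: int = 3,
    min_log10_span: float = 1.0,
):
    """Ordinary least squares of Cq on log10(relative concentration).

    ``points`` are (log10 concentration, Cq) pairs; at least
    ``min_points`` spanning at least ``min_log10_span`` decades are
    required (a 2-fold series needs >= 5 points to span one decade;
    relax ``min_log10_span`` for shorter designs).  Returns a
    :class:`asqpcr.core.StandardCurveModel` whose ``efficiency``
    property is 10^(-1/slope) - 1.
    """
    from .core import StandardCurveModel

    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < min_points:
        raise ValueError(f"need >= {min_points} points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    span = x.max() - x.min()
    if span < min_log10_span:
        raise ValueError(
            f"concentration span {span:.3g} log10 below required {min_log10_span}"
        )
    fit = stats.linregress(x, y)
    return StandardCurveModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


@dataclass(frozen=True)
class SlopeComparison:
    """Slope-equality tests across dilution series.

    ``global_p`` is the extra-sum-of-squares F test of one common slope
    (separate intercepts) against separate slopes; ``pairwise_p`` holds
    two-sided t tests on each slope difference with pooled residual
    variance."""

    global_f: float
    global_p: float
    df_num: int
    df_den: int
    slopes: tuple[float, ...]
    pairwise_p: dict[tuple[int, int], float]


def _series_arrays(series):
    out = []
    for pts in series:
        pts = [(float(a), float(b)) for a, b in pts]
        if len(pts) < 3:
            raise ValueError("each series needs >= 3 points")
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.ptp(x) == 0:
            raise ValueError("degenerate series: no concentration spread")
        out.append((x, y))
    return out


def compare_slopes(series: Sequence[Sequence[tuple[float, float]]]) -> SlopeComparison:
    """Test whether several dilution-series regressions share a slope.

    The global test compares the common-slope model (one slope, one
    intercept per series) with the separate-slopes model by an
    extra-sum-of-squares F test.  Per-pair t statistics use the pooled
    residual variance of the two series, the classical ANCOVA
    comparison of two regression lines.
    """
    arrays = _series_arrays(series)
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two series")

    slopes, residuals, sxx, dfs = [], [], [], []
    rss_sep = 0.0
    for x, y in arrays:
        fit = stats.linregress(x, y)
        slopes.append(float(fit.slope))
        resid = y - (fit.intercept + fit.slope * x)
        rss_sep += float(resid @ resid)
        residuals.append(float(resid @ resid))
        sxx.append(float(((x - x.mean()) ** 2).sum()))
        dfs.append(len(x) - 2)

    # common-slope model: y_ij = a_i + b * x_ij
    n_total = sum(len(x) for x, _ in arrays)
    b_common_num = sum(
        ((x - x.mean()) * (y - y.mean())).sum() for x, y in arrays
    )
    b_common_den = sum(((x - x.mean()) ** 2).sum() for x, y in arrays)
    b_common = b_common_num / b_common_den
    rss_common = 0.0
    for x, y in arrays:
        a_i = y.mean() - b_common * x.mean()
        resid = y - (a_i + b_common * x)
        rss_common += float(resid @ resid)

    df_num = k - 1
    df_den = n_total - 2 * k
    if df_den <= 0:
        raise ValueError("not enough points for the separate-slopes model")
    if rss_sep <= 0:
        # all series fit exactly: slopes differ iff the fitted slopes differ
        identical = max(slopes) - min(slopes) < 1e-12
        f_stat, p_global = (0.0, 1.0) if identical else (math.inf, 0.0)
    else:
        f_stat = ((rss_common - rss_sep) / df_num) / (rss_sep / df_den)
        f_stat = max(f_stat, 0.0)
        p_global = float(stats.f.sf(f_stat, df_num, df_den))

    pairwise: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            df = dfs[i] + dfs[j]
            pooled = (residuals[i] + residuals[j]) / df if df > 0 else 0.0
            se = math.sqrt(pooled * (1.0 / sxx[i] + 1.0 / sxx[j]))
            diff = slopes[i] - slopes[j]
            if se == 0:
                pairwise[(i, j)] = 1.0 if abs(diff) < 1e-12 else 0.0
            else:
                t = diff / se
                pairwise[(i, j)] = float(2.0 * stats.t.sf(abs(t), df))

    return SlopeComparison(
        global_f=float(f_stat),
        global_p=float(p_global),
        df_num=df_num,
        df_den=df_den,
        slopes=tuple(slopes),
        pairwise_p=pairwise,
    )


# --------------------------------------------------------------------------
# LOQ

def one_sample_t_from_summary(
    mean: float, sd: float, n: int, expected: float
) -> tuple[float, float]:
    """One-sample t test from summary statistics.

    t = (mean - expected) / (sd / sqrt(n)), two-sided p on n-1 df.
    A degenerate sd = 0 gives p = 1 when the mean equals the expected
    value exactly and p = 0 otherwise.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        if mean == expected:
            return 0.0, 1.0
        return math.copysign(math.inf, mean - expected), 0.0
    t = (mean - expected) / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return float(t), p


@dataclass(frozen=True)
class LoqLevel:
    """One dilution level of an LOQ experiment, as replicate observations
    or as (mean, sd, n) summaries."""

    level_percent: float
    observations: tuple[float, ...] | None = None
    mean: float | None = None
    sd: float | None = None
    n: int | None = None
    n_detected: int | None = None
    n_tested: int | None = None

    def summary(self) -> tuple[float, float, int]:
        if self.observations is not None:
            obs = np.asarray(self.observations, dtype=float)
            if obs.size < 2:
                raise ValueError("need >= 2 replicate observations per level")
            return float(obs.mean()), float(obs.std(ddof=1)), int(obs.size)
        if self.mean is None or self.sd is None or self.n is None:
            raise ValueError("level needs observations or (mean, sd, n)")
        return self.mean, self.sd, self.n

    def detection(self) -> tuple[int, int]:
        if self.n_detected is not None and self.n_tested is not None:
            return self.n_detected, self.n_tested
        if self.observations is not None:
            n = len(self.observations)
            return n, n  # every recorded observation was a detection
        _, _, n = self.summary()
        return n, n


@dataclass(frozen=True)
class LoqResult:
    loq_percent: float | None
    table: pd.DataFrame
    min_detected_fraction: float

    @property
    def defined(self) -> bool:
        return self.loq_percent is not None


def loq_assessment(
    levels: Sequence[LoqLevel],
    alpha: float = 0.05,
    min_detected_fraction: float = 8.0 / 9.0,
) -> LoqResult:
    """Limit of quantification by observed-vs-expected t tests.

    A level is quantifiable when (a) it was detected in at least
    ``ceil(min_detected_fraction * n_tested)`` replicates and (b) the
    one-sample t test of the observed results against the expected
    (nominal) level is non-significant at ``alpha`` — i.e. the assay is
    still unbiased there.  The LOQ is the lowest quantifiable level all
    of whose lower tested levels fail; if no level qualifies the result
    is explicitly undefined.
    """
    lv = list(levels)
    if any(b.level_percent >= a.level_percent for a, b in zip(lv, lv[1:])):
        raise ValueError("levels must be strictly decreasing")

    rows = []
    passes = []
    for level in lv:
        mean, sd, n = level.summary()
        n_det, n_tot = level.detection()
        detected_ok = n_det >= math.ceil(min_detected_fraction * n_tot)
        t, p = one_sample_t_from_summary(mean, sd, n, level.level_percent)
        ok = bool(detected_ok and p > alpha)
        passes.append(ok)
        rows.append(
            {
                "level_percent": level.level_percent,
                "mean": mean,
                "sd": sd,
                "n": n,
                "n_detected": n_det,
                "n_tested": n_tot,
                "detection_ok": detected_ok,
                "t": t,
                "p_value": p,
                "quantifiable": ok,
            }
        )
    table = pd.DataFrame(rows)

    loq = None
    # lowest passing level below which nothing passes
    for i in range(len(lv) - 1, -1, -1):
        if passes[i] and not any(passes[i + 1:]):
            loq = lv[i].level_percent
            break
    return LoqResult(
        loq_percent=loq, table=table, min_detected_fraction=min_detected_fraction
    )


# --------------------------------------------------------------------------
# precision

@dataclass(frozen=True)
class PrecisionResult:
    """Variance-component precision summary of a day x replicate design."""

    mean: float
    cv_total: float
    cv_between_day: float
    cv_within_run: float
    var_within: float
    var_between: float
    n_days: int
    n_replicates: int

    @property
    def var_total(self) -> float:
        return self.var_within + self.var_between


def precision_analysis(design) -> PrecisionResult:
    """Within-run / between-day / total CVs from a balanced design.

    ``design`` is a days-by-replicates array of measured percents.
    One-way random-effects ANOVA with day as the random factor:
    within-run variance is the within-day mean square, the between-day
    component is ``max(0, (MS_between - MS_within) / n_rep)``, and the
    total is their sum.  CVs are 100 * sqrt(variance) / grand mean.
    """
    data = np.asarray(design, dtype=float)
    if data.ndim != 2:
        raise ValueError("design must be a 2-D days x replicates array (balanced)")
    n_days, n_rep = data.shape
    if n_days < 2 or n_rep < 2:
        raise ValueError("need >= 2 days and >= 2 replicates per day")
    if not np.all(np.isfinite(data)):
        raise ValueError("design contains non-finite values")

    grand = data.mean()
    day_means = data.mean(axis=1)
    ss_within = float(((data - day_means[:, None]) ** 2).sum())
    ss_between = float(n_rep * ((day_means - grand) ** 2).sum())
    ms_within = ss_within / (n_days * (n_rep - 1))
    ms_between = ss_between / (n_days - 1)

    var_within = ms_within
    var_between = max(0.0, (ms_between - ms_within) / n_rep)
    var_total = var_within + var_between
    if grand == 0:
        raise ValueError("grand mean is zero; CV undefined")

    cv = lambda v: 100.0 * math.sqrt(v) / abs(grand)
    return PrecisionResult(
        mean=float(grand),
        cv_total=cv(var_total),
        cv_between_day=cv(var_between),
        cv_within_run=cv(var_within),
        var_within=var_within,
        var_between=var_between,
        n_days=n_days,
        n_replicates=n_rep,
    )


# --------------------------------------------------------------------------
# method comparison and agreement

@dataclass(frozen=True)
class MethodComparisonResult:
    """Quantitative agreement between a test and a reference method.

    ``bias`` is mean(test - reference); ``loa`` the Bland-Altman limits
    of agreement bias +/- 1.96*SD(differences); ``bias_ci`` the t-based
    95% CI of the mean difference.  ``pearson_r`` is NaN (with
    ``correlation_defined`` False) when either vector has no variance.
    """

    n: int
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    r_squared: float
    bias: float
    sd_diff: float
    loa: tuple[float, float]
    bias_ci: tuple[float, float]
    correlation_defined: bool = True


def method_comparison(
    reference: Sequence[float], test: Sequence[float]
) -> MethodComparisonResult:
    """Pearson / OLS / Bland-Altman comparison of paired measurements.

    The regression is of test on reference; differences are
    test - reference, so a positive bias means the test method (or
    specimen) reads higher.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test must be equal-length 1-D sequences")
    n = ref.size
    if n < 3:
        raise ValueError("need >= 3 pairs")

    d = tst - ref
    bias = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd_diff, bias + 1.96 * sd_diff)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    half = tcrit * sd_diff / math.sqrt(n)
    bias_ci = (bias - half, bias + half)

    if ref.std() == 0 or tst.std() == 0:
        return MethodComparisonResult(
            n=n,
            pearson_r=float("nan"),
            pearson_p=float("nan"),
            slope=float("nan"),
            intercept=float("nan"),
            r_squared=float("nan"),
            bias=bias,
            sd_diff=sd_diff,
            loa=loa,
            bias_ci=bias_ci,
            correlation_defined=False,
        )

    r, p = stats.pearsonr(ref, tst)
    fit = stats.linregress(ref, tst)
    return MethodComparisonResult(
        n=n,
        pearson_r=float(r),
        pearson_p=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        bias=bias,
        sd_diff=sd_diff,
        loa=loa,
        bias_ci=bias_ci,
    )


def method_comparison_subgroups(
    reference: Sequence[float],
    test: Sequence[float],
    threshold: float = 20.0,
) -> dict[str, MethodComparisonResult]:
    """Overall comparison plus a split at a reference-value threshold
    (default 20% mutant allele), mirroring low- vs high-burden
    subgroup analyses."""
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    out = {"all": method_comparison(ref, tst)}
    below = ref < threshold
    if below.sum() >= 3:
        out["below"] = method_comparison(ref[below], tst[below])
    if (~below).sum() >= 3:
        out["above"] = method_comparison(ref[~below], tst[~below])
    return out


@dataclass(frozen=True)
class AgreementResult:
    """Qualitative 2x2 agreement between test and reference calls.

    Percent agreements are None when the corresponding reference stratum
    is empty."""

    concordant_positive: int
    reference_pos_test_neg: int
    reference_neg_test_pos: int
    concordant_negative: int
    total_agreement: float | None
    positive_agreement: float | None
    negative_agreement: float | None

    @property
    def n(self) -> int:
        return (
            self.concordant_positive
            + self.reference_pos_test_neg
            + self.reference_neg_test_pos
            + self.concordant_negative
        )


def qualitative_agreement(calls: Sequence[tuple[bool, bool]]) -> AgreementResult:
    """Total / positive / negative percent agreement from paired binary
    (reference, test) calls."""
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one pair of calls")
    a = sum(1 for r, t in calls if r and t)
    b = sum(1 for r, t in calls if r and not t)
    c = sum(1 for r, t in calls if not r and t)
    d = sum(1 for r, t in calls if not r and not t)
    n = a + b + c + d
    total = 100.0 * (a + d) / n
    ppa = 100.0 * a / (a + b) if (a + b) else None
    npa = 100.0 * d / (c + d) if (c + d) else None
    return AgreementResult(
        concordant_positive=a,
        reference_pos_test_neg=b,
        reference_neg_test_pos=c,
        concordant_negative=d,
        total_agreement=total,
        positive_agreement=ppa,
        negative_agreement=npa,
    )
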