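"""Method-qualification statistics: linearity, LOD/LOQ, recovery,
precision, paired method comparison, specificity and the uncertainty budget.

Conventions follow ICH Q2 / GUM practice: detection and quantification
limits are 3 and 10 residual standard deviations over the slope of the
linearity line; the combined uncertainty is the root sum of squares of the
relative standard uncertainties and the expanded uncertainty applies a
coverage factor (default k = 2, ~95% coverage).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .qnmr import QuantSetup, Spectrum, fit_and_integrate


class ValidationError(ValueError):
    """Invalid qualification-statistics input."""


@dataclass
class LinearityResult:
    slope: float
    intercept: float
    r2: float
    residual_sd: float
    lod: float                   # 3 sigma / slope, mmol/L
    loq: float                   # 10 sigma / slope, mmol/L


def linearity(prepared, measured) -> LinearityResult:
    """Regress prepared concentration (y) on measured concentration (x)."""
    y = np.asarray(prepared, dtype=float)
    x = np.asarray(measured, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need at least 3 paired concentrations")
    if np.ptp(x) == 0:
        raise ValidationError("measured concentrations are constant; no line defined")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sigma = math.sqrt(float(resid @ resid) / (len(x) - 2))
    return LinearityResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        residual_sd=sigma,
        lod=3.0 * sigma / res.slope,
        loq=10.0 * sigma / res.slope,
    )


def lod_loq(residual_sd: float, slope: float) -> tuple[float, float]:
    """Detection / quantification limits from residual SD and slope."""
    if slope == 0:
        raise ValidationError("zero slope")
    return 3.0 * residual_sd / slope, 10.0 * residual_sd / slope


def recovery(measured_spiked: float, measured_base: float, added: float) -> float:
    """Spike recovery in percent."""
    if added <= 0:
        raise ValidationError("added amount must be positive")
    return 100.0 * (measured_spiked - measured_base) / added


def rsd(values) -> float:
    """Relative standard deviation (sample SD over mean) in percent."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValidationError("RSD needs at least 2 values")
    if v.mean() == 0:
        raise ValidationError("RSD undefined for zero mean")
    return 100.0 * v.std(ddof=1) / v.mean()


@dataclass
class ComparisonResult:
    """Paired comparison of two methods over the same samples."""

    differences: np.ndarray
    mean_difference: float
    conf_int: tuple[float, float]
    t_statistic: float
    df: int
    p_value: float
    relative_deviation: np.ndarray   # per pair, % of method B
    mean_relative_deviation: float   # from column means, %


def paired_comparison(method_a, method_b, confidence: float = 0.95) -> ComparisonResult:
    """Paired t test of method A against method B (differences a - b).

    Per-pair relative deviation uses method B as the denominator; the mean
    relative deviation compares the column means.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("need two equal-length series with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0 and d.mean() != 0:
        raise ValidationError("zero variance of differences with nonzero mean")
    se = sd / math.sqrt(n)
    tq = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    if sd == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = d.mean() / se
        p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    return ComparisonResult(
        differences=d,
        mean_difference=float(d.mean()),
        conf_int=(float(d.mean() - tq * se), float(d.mean() + tq * se)),
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p),
        relative_deviation=100.0 * d / b,
        mean_relative_deviation=float(100.0 * (a.mean() - b.mean()) / b.mean()),
    )


@dataclass
class UncertaintyBudget:
    """GUM-style budget of relative standard uncertainties (percent)."""

    components: dict[str, float]
    k: float
    cu: float                    # combined uncertainty, %
    eu: float                    # expanded uncertainty = k * CU, %

    @property
    def contribution_fractions(self) -> dict[str, float]:
        """u_i^2 / CU^2 per component; sums to 1."""
        return {name: (u / self.cu) ** 2 for name, u in self.components.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"components_pct": self.components, "k": self.k,
                       "CU_pct": self.cu, "EU_pct": self.eu,
                       "contribution_fractions": self.contribution_fractions},
                      fh, indent=2)


def uncertainty_budget(components: dict[str, float], k: float = 2.0) -> UncertaintyBudget:
    """Root-sum-of-squares combination with coverage factor ``k``."""
    if not components:
        raise ValidationError("budget needs at least one component")
    if any(u < 0 for u in components.values()):
        raise ValidationError("relative uncertainties must be non-negative")
    cu = math.sqrt(sum(u**2 for u in components.values()))
    return UncertaintyBudget(dict(components), k, cu, k * cu)


def specificity_check(
    negative_control: Spectrum,
    sample: Spectrum,
    setup: QuantSetup = QuantSetup(),
    reportable_fraction: float = 0.01,
) -> bool:
    """True when the quantitative window of a negative control is silent.

    The control's integrated area over the analyte window must stay below
    ``reportable_fraction`` of the sample's area — the quantitative-signal
    specificity criterion used when transferring the method to a new matrix.
    """
    n_peaks = len(setup.ts_ppm)
    _, area_control, _ = fit_and_integrate(negative_control, setup.ts_window,
                                           n_peaks, centers=list(setup.ts_ppm))
    _, area_sample, _ = fit_and_integrate(sample, setup.ts_window,
                                          n_peaks, centers=list(setup.ts_ppm))
    if area_sample <= 0:
        raise ValidationError("sample shows no quantitative signal")
    return area_control < reportable_fraction * area_sample
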