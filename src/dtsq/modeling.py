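"""Screening and response-surface regression on coded designs.

Screening fits are first-order least-squares models

    y = a0 + sum_i a_i x_i

on the coded two-level factors; a factor is a critical parameter when the
95% t confidence interval of its coefficient excludes zero.  Optimization
fits are quadratic-subset models

    Y = b0 + sum b_i X_i + sum b_ii X_i^2 + sum b_ij X_i X_j

on the coded central-composite factors.  Coefficients are reported both in
raw coded units and standardized per one sample standard deviation of the
model column — the scale on which chemometrics packages print their
"scaled and centered" coefficient tables and plots.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .doe import DesignMatrix


class ModelError(ValueError):
    """Underdetermined or rank-deficient fit request."""


@dataclass(frozen=True)
class ModelTerm:
    """One model term: intercept, linear, square or two-factor interaction."""

    kind: str
    factors: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        expect = {"intercept": 0, "linear": 1, "square": 1, "interaction": 2}
        if self.kind not in expect:
            raise ModelError(f"unknown term kind {self.kind!r}")
        if len(self.factors) != expect[self.kind]:
            raise ModelError(f"{self.kind} term takes {expect[self.kind]} factor index(es)")
        if self.kind == "interaction" and self.factors[0] == self.factors[1]:
            raise ModelError("interaction terms need two distinct factors")

    def label(self, names: Sequence[str]) -> str:
        if self.kind == "intercept":
            return "b0"
        if self.kind == "linear":
            return names[self.factors[0]]
        if self.kind == "square":
            return f"{names[self.factors[0]]}^2"
        return f"{names[self.factors[0]]}*{names[self.factors[1]]}"

    def evaluate(self, coded: np.ndarray) -> np.ndarray:
        if self.kind == "intercept":
            return np.ones(len(coded))
        if self.kind == "linear":
            return coded[:, self.factors[0]]
        if self.kind == "square":
            return coded[:, self.factors[0]] ** 2
        return coded[:, self.factors[0]] * coded[:, self.factors[1]]


def parse_term(spec: str, names: Sequence[str]) -> ModelTerm:
    """Parse 'b0', 'NS', 'NS^2' or 'NS*Tl' against the factor names."""
    spec = spec.strip()
    if spec in ("b0", "1", "intercept"):
        return ModelTerm("intercept")
    m = re.fullmatch(r"(\w+)\^2", spec)
    if m:
        return ModelTerm("square", (list(names).index(m.group(1)),))
    m = re.fullmatch(r"(\w+)\*(\w+)", spec)
    if m:
        return ModelTerm("interaction", (list(names).index(m.group(1)),
                                         list(names).index(m.group(2))))
    return ModelTerm("linear", (list(names).index(spec),))


def linear_terms(k: int) -> list[ModelTerm]:
    return [ModelTerm("intercept")] + [ModelTerm("linear", (i,)) for i in range(k)]


def full_quadratic(k: int) -> list[ModelTerm]:
    terms = linear_terms(k)
    terms += [ModelTerm("square", (i,)) for i in range(k)]
    terms += [ModelTerm("interaction", (i, j)) for i in range(k) for j in range(i + 1, k)]
    return terms


@dataclass
class FittedModel:
    """A least-squares fit with its full uncertainty description."""

    response: str
    terms: list[ModelTerm]
    factor_names: list[str]
    coefficients: np.ndarray
    cov: np.ndarray              # coefficient covariance
    resid_var: float             # residual variance s^2
    df_resid: int
    r2: float
    r2_adj: float
    conf_int: np.ndarray         # (p, 2) two-sided 95% bounds
    column_sd: np.ndarray        # sample SD of each model column
    factor_sd: np.ndarray        # sample SD of each coded factor column

    @property
    def labels(self) -> list[str]:
        return [t.label(self.factor_names) for t in self.terms]

    @property
    def significant(self) -> np.ndarray:
        """True where the 95% CI excludes zero (intercept included)."""
        return (self.conf_int[:, 0] > 0) | (self.conf_int[:, 1] < 0)

    @property
    def significant_factors(self) -> set[str]:
        return {
            lab for lab, t, s in zip(self.labels, self.terms, self.significant)
            if s and t.kind != "intercept"
        }

    @property
    def term_scale(self) -> np.ndarray:
        """Per-term standardization factor: the product of the sample SDs of
        the coded factor columns entering the term (1 for the intercept).

        A linear term scales by sd(X_i), an interaction by sd(X_i)*sd(X_j)
        and a square by sd(X_i)^2 — the unit-variance factor scaling on
        which chemometrics packages print coefficient tables.
        """
        return np.array([
            float(np.prod([self.factor_sd[i] for i in t.factors])) or 1.0
            for t in self.terms
        ])

    @property
    def standardized(self) -> np.ndarray:
        """Coefficients per one sample SD of each factor (intercept as-is)."""
        return self.coefficients * self.term_scale

    def basis(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        return np.column_stack([t.evaluate(coded) for t in self.terms])

    def predict(self, point, with_interval: bool = False):
        """Mean prediction at coded coordinates.

        With ``with_interval`` also returns the prediction standard
        deviation sqrt(x' Sigma x + s^2) and the 95% prediction interval.
        """
        X = self.basis(point)
        mean = X @ self.coefficients
        mean_out = mean if np.ndim(point) > 1 else float(mean[0])
        if not with_interval:
            return mean_out
        var = np.einsum("ij,jk,ik->i", X, self.cov, X) + self.resid_var
        sd = np.sqrt(var)
        t = stats.t.ppf(0.975, self.df_resid)
        if np.ndim(point) > 1:
            return mean, sd, np.column_stack([mean - t * sd, mean + t * sd])
        return mean_out, float(sd[0]), (float(mean[0] - t * sd[0]), float(mean[0] + t * sd[0]))

    def to_report(self) -> dict:
        return {
            "response": self.response,
            "terms": self.labels,
            "coefficients": [float(c) for c in self.coefficients],
            "standardized_coefficients": [float(c) for c in self.standardized],
            "conf_int": [[float(a), float(b)] for a, b in self.conf_int],
            "significant": [bool(s) for s in self.significant],
            "r2": float(self.r2),
            "r2_adj": float(self.r2_adj),
            "resid_var": float(self.resid_var),
            "df_resid": int(self.df_resid),
        }


def _fit(design: DesignMatrix, response: str, terms: list[ModelTerm]) -> FittedModel:
    if design.responses is None or response not in design.responses:
        raise ModelError(f"design carries no response named {response!r}")
    coded = design.coded.to_numpy()
    names = [f.name for f in design.factors]
    X = np.column_stack([t.evaluate(coded) for t in terms])
    y = design.responses[response].to_numpy(dtype=float)
    if len(y) < X.shape[1]:
        raise ModelError(
            f"underdetermined fit: {len(y)} runs for {X.shape[1]} terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns for the error message
        labels = [t.label(names) for t in terms]
        _, r = np.linalg.qr(X)
        bad = [labels[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10 * len(y)]
        raise ModelError(f"rank-deficient model matrix; aliased columns: {bad}")
    res = sm.OLS(y, X).fit()
    p = X.shape[1]
    r2 = float(res.rsquared)
    r2_adj = float(res.rsquared_adj) if len(y) > p else r2
    return FittedModel(
        response=response,
        terms=list(terms),
        factor_names=names,
        coefficients=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        resid_var=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        df_resid=int(res.df_resid),
        r2=r2,
        r2_adj=r2_adj,
        conf_int=np.asarray(res.conf_int(0.05), dtype=float),
        column_sd=X.std(axis=0, ddof=1),
        factor_sd=coded.std(axis=0, ddof=1),
    )


def fit_screening(design: DesignMatrix, response: str) -> FittedModel:
    """First-order fit of a response on all coded factors (all runs)."""
    return _fit(design, response, linear_terms(len(design.factors)))


def fit_rsm(
    design: DesignMatrix,
    response: str,
    terms: Sequence[ModelTerm | str],
) -> FittedModel:
    """Quadratic-subset response-surface fit on the coded design.

    ``terms`` may mix :class:`ModelTerm` objects and shorthand strings such
    as ``"NS"``, ``"NS^2"`` or ``"NS*Tl"``; the intercept is always included.
    """
    names = [f.name for f in design.factors]
    parsed = [t if isinstance(t, ModelTerm) else parse_term(t, names) for t in terms]
    if not any(t.kind == "intercept" for t in parsed):
        parsed = [ModelTerm("intercept")] + parsed
    return _fit(design, response, parsed)


def write_model_report(path, models: Sequence[FittedModel]) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_report() for m in models], fh, indent=2)


def coefficient_plot_table(model: FittedModel) -> pd.DataFrame:
    """Standardized coefficients with CI half-widths, one row per term."""
    t = stats.t.ppf(0.975, model.df_resid)
    se = np.sqrt(np.diag(model.cov))
    scale = model.term_scale
    return pd.DataFrame(
        {
            "term": model.labels,
            "standardized_coefficient": model.standardized,
            "ci_half_width": t * se * scale,
            "significant": model.significant,
        }
    ).set_index("term")
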