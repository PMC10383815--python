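"""FMECA risk ranking for analytical-procedure development.

Each candidate failure factor of the qNMR procedure is scored for severity
(S), probability of occurrence (O) and ease of detection (D) on a 1..5
scale; the risk priority number RPN = S*O*D then ranks the factors.  A
two-sided t confidence interval of the mean RPN partitions the register into
low / medium / high risk: factors whose RPN exceeds the upper bound are the
high-risk parameters carried forward into screening experiments.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

CATEGORIES = (
    "sample preparation",
    "spectra acquisition",
    "data processing",
    "environment",
    "instrument",
)

#: default score scale; RPN then spans 1..125
MAX_SCORE = 5


class FmecaError(ValueError):
    """Invalid risk-register input."""


@dataclass(frozen=True)
class RiskFactor:
    """One failure factor with its S/O/D scores."""

    name: str
    category: str
    S: int
    O: int
    D: int
    max_score: int = MAX_SCORE

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise FmecaError(
                f"category {self.category!r} for factor {self.name!r} is not one of {CATEGORIES}"
            )
        for fieldname in ("S", "O", "D"):
            score = getattr(self, fieldname)
            if not (isinstance(score, (int, np.integer)) and 1 <= score <= self.max_score):
                raise FmecaError(
                    f"score {fieldname}={score!r} for factor {self.name!r} "
                    f"must be an integer in [1, {self.max_score}]"
                )

    @property
    def rpn(self) -> int:
        return int(self.S) * int(self.O) * int(self.D)


def compute_rpn(factor: RiskFactor) -> int:
    """Risk priority number: severity x occurrence x detectability."""
    return factor.rpn


@dataclass
class RiskRegister:
    """Ordered collection of scored risk factors."""

    factors: list[RiskFactor]

    def __len__(self) -> int:
        return len(self.factors)

    @property
    def rpn(self) -> np.ndarray:
        return np.array([f.rpn for f in self.factors], dtype=int)

    def summary(self) -> dict[str, float]:
        r = self.rpn.astype(float)
        return {
            "n": len(r),
            "mean": float(r.mean()),
            "sd": float(r.std(ddof=1)) if len(r) > 1 else 0.0,
            "min": float(r.min()),
            "max": float(r.max()),
        }


def rpn_confidence_interval(
    mean: float, sd: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided t interval for the mean RPN (n-1 degrees of freedom)."""
    if n < 3:
        raise FmecaError(f"need at least 3 factors for a confidence interval, got n={n}")
    half = stats.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / math.sqrt(n)
    return mean - half, mean + half


@dataclass
class Classification:
    """Risk levels with the interval that produced them."""

    levels: list[str]
    lower: float
    upper: float
    mean: float
    sd: float
    confidence: float

    def factors_at(self, level: str) -> list[int]:
        return [i for i, lv in enumerate(self.levels) if lv == level]


def classify_register(register: RiskRegister, confidence: float = 0.95) -> Classification:
    """Partition a register into low / medium / high risk.

    The mean-RPN confidence interval is the medium band; RPN strictly above
    the upper bound is high, strictly below the lower bound is low.  Ties on
    a bound classify as medium.
    """
    if len(register) < 3:
        raise FmecaError(
            f"register has {len(register)} factors; classification needs n >= 3"
        )
    s = register.summary()
    lower, upper = rpn_confidence_interval(s["mean"], s["sd"], int(s["n"]), confidence)
    levels = [
        "high" if r > upper else "low" if r < lower else "medium"
        for r in register.rpn
    ]
    return Classification(levels, lower, upper, s["mean"], s["sd"], confidence)


def read_register_csv(path) -> RiskRegister:
    """Read a register from CSV with columns category,name,S,O,D."""
    factors = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                factors.append(
                    RiskFactor(
                        name=row["name"],
                        category=row["category"],
                        S=int(row["S"]),
                        O=int(row["O"]),
                        D=int(row["D"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FmecaError(f"{path} line {i}: {exc}") from exc
    return RiskRegister(factors)


def write_classification_csv(path, register: RiskRegister, cls: Classification) -> None:
    """Write the ranked register with a summary header block."""
    s = register.summary()
    with open(path, "w", newline="") as fh:
        fh.write(f"# n,{s['n']:.0f}\n")
        fh.write(f"# mean_rpn,{s['mean']:.6g}\n")
        fh.write(f"# sd_rpn,{s['sd']:.6g}\n")
        fh.write(f"# ci_lower,{cls.lower:.6g}\n")
        fh.write(f"# ci_upper,{cls.upper:.6g}\n")
        writer = csv.writer(fh)
        writer.writerow(["category", "name", "S", "O", "D", "rpn", "level"])
        order = np.argsort(-register.rpn, kind="stable")
        for i in order:
            f = register.factors[i]
            writer.writerow([f.category, f.name, f.S, f.O, f.D, f.rpn, cls.levels[i]])
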