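"""Experimental designs and acquisition-time arithmetic.

Plackett-Burman (two-level screening) and central-composite (five-level
response-surface) designs over NMR acquisition parameters, the piecewise
coding map between engineering units and coded levels, and the closed-form
timing model of a 1D acquisition:

    AQ  = TD / (2 * SW_Hz)          acquisition time per scan
    T_l = AQ + D1                   time lag between excitations
    T_q = (NS + DS) * (T_l + D8 + overhead) / 60   total time, minutes
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_FREQUENCY_MHZ = 500.13  # 500 MHz instrument
#: per-scan housekeeping time (s) calibrated once against the packaged CCD
#: run table; reproduces all printed total times to within 0.05 min
PER_SCAN_OVERHEAD_S = 2.75


class DesignError(ValueError):
    """Invalid factor definition or unsupported design request."""


@dataclass(frozen=True)
class FactorDef:
    """A design factor with explicit low / center / high settings.

    The center need not be the arithmetic midpoint (e.g. sample
    concentration 0.5 / 2 / 5 mmol/L); coding is the piecewise-linear map
    fixed by the three anchors, so low -> -1, center -> 0, high -> +1.
    ``allowed_values`` restricts settings to a hardware grid (powers of two
    for the FID size, receiver-gain steps) and is used to snap axial points.
    """

    name: str
    symbol: str
    low: float
    high: float
    center: float
    axial_low: float | None = None
    axial_high: float | None = None
    units: str = ""
    allowed_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise DesignError(f"{self.name}: low must be < high")
        if not (self.low < self.center < self.high):
            raise DesignError(f"{self.name}: center must lie strictly between low and high")
        if self.axial_low is not None and self.axial_low >= self.low:
            raise DesignError(f"{self.name}: axial_low must be < low")
        if self.axial_high is not None and self.axial_high <= self.high:
            raise DesignError(f"{self.name}: axial_high must be > high")

    @property
    def step(self) -> float:
        """Half-range (high - low) / 2, the CCD coding step."""
        return (self.high - self.low) / 2.0


def code(value, factor: FactorDef):
    """Map engineering units to coded level (low -> -1, center -> 0, high -> +1).

    Piecewise linear about the explicit center; extrapolates beyond the
    anchors (axial points land at their |coded| > 1 values).
    """
    v = np.asarray(value, dtype=float)
    up = factor.high - factor.center
    down = factor.center - factor.low
    out = np.where(v >= factor.center, (v - factor.center) / up, (v - factor.center) / down)
    return out.item() if np.isscalar(value) else out


def decode(coded, factor: FactorDef):
    """Inverse of :func:`code`."""
    c = np.asarray(coded, dtype=float)
    up = factor.high - factor.center
    down = factor.center - factor.low
    out = np.where(c >= 0, factor.center + c * up, factor.center + c * down)
    return out.item() if np.isscalar(coded) else out


@dataclass
class DesignMatrix:
    """Runs of a design in coded and engineering units, plus responses."""

    factors: list[FactorDef]
    actual: pd.DataFrame
    responses: pd.DataFrame | None = None

    @property
    def coded(self) -> pd.DataFrame:
        cols = {f.name: code(self.actual[f.name].to_numpy(), f) for f in self.factors}
        return pd.DataFrame(cols, index=self.actual.index)

    @property
    def n_runs(self) -> int:
        return len(self.actual)

    def with_responses(self, responses: pd.DataFrame) -> "DesignMatrix":
        if len(responses) != self.n_runs:
            raise DesignError("responses must have one row per run")
        return DesignMatrix(self.factors, self.actual, responses.set_index(self.actual.index))

    def to_csv(self, path) -> None:
        coded = self.coded.add_suffix(" (coded)")
        out = pd.concat(
            [self.actual, coded] + ([self.responses] if self.responses is not None else []),
            axis=1,
        )
        out.index.name = "run"
        out.to_csv(path, float_format="%.6g")


# first row of the 12-run Plackett-Burman design (Paley construction);
# subsequent rows are cyclic right-shifts, the 12th row is all -1
_PB12_ROW = np.array([1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1])


def pbd_base_matrix(n_factors: int) -> np.ndarray:
    """12-run Plackett-Burman +-1 matrix for up to 11 factors."""
    if not 1 <= n_factors <= 11:
        raise DesignError(
            f"the 12-run Plackett-Burman base supports at most 11 factors, got {n_factors}"
        )
    rows = [np.roll(_PB12_ROW, i) for i in range(11)]
    mat = np.vstack(rows + [-np.ones(11, dtype=int)])
    return mat[:, :n_factors]


def generate_pbd(factors: Sequence[FactorDef], n_center: int = 3) -> DesignMatrix:
    """12-run Plackett-Burman screening design plus center replicates."""
    factors = list(factors)
    base = pbd_base_matrix(len(factors))
    coded = np.vstack([base, np.zeros((n_center, len(factors)))])
    actual = pd.DataFrame(
        {f.name: decode(coded[:, j], f) for j, f in enumerate(factors)},
        index=pd.RangeIndex(1, len(coded) + 1, name="run"),
    )
    design = DesignMatrix(factors, actual)
    validate_two_level(design)
    return design


def validate_two_level(design: DesignMatrix, atol: float = 1e-9) -> None:
    """Check balance and orthogonality of the +-1 block of a screening design.

    Raises :class:`DesignError` if any non-center column is unbalanced or any
    pair of columns has a nonzero inner product over the two-level runs.
    """
    coded = design.coded.to_numpy()
    two_level = coded[np.abs(coded).max(axis=1) > atol]
    names = [f.name for f in design.factors]
    for j, name in enumerate(names):
        col = two_level[:, j]
        if abs(col.sum()) > atol:
            raise DesignError(f"column {name} is unbalanced (sum {col.sum():g})")
    gram = two_level.T @ two_level
    off = gram - np.diag(np.diag(gram))
    if np.abs(off).max() > atol:
        i, j = np.unravel_index(np.abs(off).argmax(), off.shape)
        raise DesignError(f"columns {names[i]} and {names[j]} are not orthogonal")


def _snap(value: float, allowed: Iterable[float]) -> float:
    allowed = list(allowed)
    if not allowed:
        raise DesignError("empty allowed_values grid")
    return min(allowed, key=lambda a: abs(a - value))


def generate_ccd(
    factors: Sequence[FactorDef],
    alpha: float | Mapping[str, float] = 1.682,
    n_center: int = 3,
) -> DesignMatrix:
    """Central composite design: 2^k factorial + 2k axial + center runs.

    ``alpha`` may be a scalar or a per-factor mapping.  Axial settings are
    center +- alpha*step, snapped to the factor's ``allowed_values`` grid
    when one is given (the snapped point must stay outside the factorial
    range, otherwise the design degenerates and an error is raised unless
    alpha <= 1 was requested explicitly).
    """
    factors = list(factors)
    k = len(factors)

    def alpha_of(f: FactorDef) -> float:
        a = alpha[f.name] if isinstance(alpha, Mapping) else alpha
        if a <= 0:
            raise DesignError(f"alpha for {f.name} must be positive, got {a}")
        return float(a)

    rows = []
    # factorial block
    for signs in np.ndindex(*(2,) * k):
        rows.append([f.low if s == 0 else f.high for s, f in zip(signs, factors)])
    # axial block
    for j, f in enumerate(factors):
        a = alpha_of(f)
        lo = f.center - a * f.step
        hi = f.center + a * f.step
        if f.allowed_values is not None:
            lo, hi = _snap(lo, f.allowed_values), _snap(hi, f.allowed_values)
            if a > 1 and not (lo < f.low and hi > f.high):
                raise DesignError(
                    f"{f.name}: snapped axial points ({lo:g}, {hi:g}) do not extend "
                    f"beyond the factorial range [{f.low:g}, {f.high:g}]"
                )
        for v in (lo, hi):
            row = [g.center for g in factors]
            row[j] = v
            rows.append(row)
    rows += [[f.center for f in factors] for _ in range(n_center)]
    actual = pd.DataFrame(
        rows, columns=[f.name for f in factors], index=pd.RangeIndex(1, len(rows) + 1, name="run")
    )
    return DesignMatrix(factors, actual)


# ---------------------------------------------------------------- timing ---


def acquisition_time(
    td: float, sw_ppm: float, frequency_mhz: float = DEFAULT_FREQUENCY_MHZ
) -> float:
    """Acquisition time per scan AQ = TD / (2 * SW) with SW in Hz, in seconds."""
    if td <= 0 or sw_ppm <= 0 or frequency_mhz <= 0:
        raise DesignError("td, sw_ppm and frequency_mhz must all be positive")
    return td / (2.0 * sw_ppm * frequency_mhz)


@dataclass(frozen=True)
class AcquisitionSettings:
    """One set of 1D acquisition parameters.

    Defaults are the method's chosen operating point: 32 scans, 4 dummy
    scans, 64k FID points, 18.73 s relaxation delay, 12.016 ppm spectral
    width on a 500.13 MHz instrument at 298 K.
    """

    NS: int = 32
    DS: int = 4
    TD: int = 65536
    D1: float = 18.73
    D8: float = 0.05
    SW: float = 12.016
    frequency_mhz: float = DEFAULT_FREQUENCY_MHZ
    O1: float = 2428.67
    P1: float = 14.75
    RG: float = 71.8
    temperature: float = 298.0
    per_scan_overhead: float = PER_SCAN_OVERHEAD_S

    def __post_init__(self) -> None:
        for name in ("NS", "DS", "TD"):
            v = getattr(self, name)
            if not (float(v).is_integer() and v >= (1 if name != "DS" else 0)):
                raise DesignError(f"{name} must be a non-negative integer, got {v!r}")
        if self.D1 < 0 or self.D8 < 0:
            raise DesignError("delays must be non-negative")
        if self.SW <= 0:
            raise DesignError("spectral width must be positive")

    @property
    def aq(self) -> float:
        return acquisition_time(self.TD, self.SW, self.frequency_mhz)

    @property
    def time_lag(self) -> float:
        """T_l = AQ + D1, the interval governing relaxation between scans."""
        return self.aq + self.D1


def total_time(settings: AcquisitionSettings) -> float:
    """Total acquisition time T_q in minutes."""
    per_scan = settings.time_lag + settings.D8 + settings.per_scan_overhead
    return (settings.NS + settings.DS) * per_scan / 60.0


def total_time_from(
    ns: float,
    tl: float,
    ds: float = 4,
    d8: float = 0.05,
    per_scan_overhead: float = PER_SCAN_OVERHEAD_S,
) -> float:
    """T_q in minutes directly from NS and the time lag T_l (seconds)."""
    return (ns + ds) * (tl + d8 + per_scan_overhead) / 60.0
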