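"""Monte-Carlo probability-based design space and MODR verification.

For every candidate operating point the three fitted response surfaces
(accuracy, SNR, total time) are simulated by drawing coefficient vectors
from the multivariate normal defined by each fit's estimate and covariance
and adding an independent residual draw per simulated observation.  A draw
fails when accuracy exceeds its upper limit, SNR falls below its lower
limit, or the total time exceeds its upper limit; the per-point failure
probability is the failing fraction.  The design space is the region whose
combined failure probability stays at or below the chosen threshold
(default 1%), and the method operable design region (MODR) is the
practically convenient box selected inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doe import FactorDef, acquisition_time, code
from .modeling import FittedModel

DEFAULT_SEED = 20230629

#: the six robustness-verification settings (NS, TD, D1 seconds) selected
#: inside the MODR, plus the routine operating point of the method
VERIFICATION_POINTS: tuple[tuple[int, int, float], ...] = (
    (32, 98304, 19.0),
    (48, 98304, 16.0),
    (40, 98304, 17.0),
    (48, 65536, 20.0),
    (32, 65536, 18.0),
    (40, 65536, 19.0),
)
OPERATING_POINT: tuple[int, int, float] = (32, 65536, 18.73)


class DesignSpaceError(ValueError):
    """Invalid design-space request."""


@dataclass(frozen=True)
class SpecLimits:
    """Performance limits from the analytical target profile."""

    accuracy_max: float = 3.0    # % relative deviation, upper limit
    snr_min: float = 1000.0      # signal-to-noise, lower limit
    time_max: float = 25.0       # total acquisition time, minutes

    def __post_init__(self) -> None:
        if min(self.accuracy_max, self.snr_min, self.time_max) <= 0:
            raise DesignSpaceError("all specification limits must be positive")

    #: (response, side) pairs; side "upper" fails above the limit
    def checks(self) -> list[tuple[str, float, str]]:
        return [
            ("accuracy", self.accuracy_max, "upper"),
            ("snr", self.snr_min, "lower"),
            ("tq", self.time_max, "upper"),
        ]


@dataclass(frozen=True)
class MCSettings:
    grid_resolution: int = 64
    n_sim: int = 10_000
    failure_threshold: float = 0.01
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.grid_resolution < 2:
            raise DesignSpaceError("grid_resolution must be >= 2")
        if self.n_sim < 100:
            raise DesignSpaceError("n_sim must be >= 100")
        if not 0 < self.failure_threshold < 1:
            raise DesignSpaceError("failure_threshold must lie in (0, 1)")


@dataclass
class DesignSpaceGrid:
    """Per-point failure probabilities over (NS, T_l) at each TD slice."""

    ns_axis: np.ndarray          # actual scans
    tl_axis: np.ndarray          # actual seconds
    td_values: tuple[int, ...]
    per_response: dict[str, np.ndarray]   # each (n_td, n_tl, n_ns)
    combined: np.ndarray
    settings: MCSettings

    def to_frame(self) -> pd.DataFrame:
        td, tl, ns = np.meshgrid(self.td_values, self.tl_axis, self.ns_axis, indexing="ij")
        out = pd.DataFrame(
            {"TD": td.ravel(), "Tl": tl.ravel(), "NS": ns.ravel(),
             "combined": self.combined.ravel()}
        )
        for name, arr in self.per_response.items():
            out[f"p_fail_{name}"] = arr.ravel()
        out.index.name = "point_id"
        return out


def _require_cov(models: Mapping[str, FittedModel]) -> None:
    for name, m in models.items():
        if m.cov is None or m.resid_var is None:
            raise DesignSpaceError(
                f"model {name!r} carries no covariance; refit with the modeling module"
            )


def failure_probability_map(
    models: Mapping[str, FittedModel],
    limits: SpecLimits,
    mc: MCSettings,
    factors: Sequence[FactorDef],
    td_values: Sequence[int] = (32768, 65536, 98304),
    ns_range: tuple[float, float] | None = None,
    tl_range: tuple[float, float] | None = None,
) -> DesignSpaceGrid:
    """Failure probabilities on a (NS, T_l) grid at each TD slice.

    ``factors`` are the CCD factor definitions (NS, TD, Tl) used to code the
    grid; the axes default to the modelled (axial-inclusive) ranges.
    """
    _require_cov(models)
    ns_f, td_f, tl_f = factors
    ns_range = ns_range or (ns_f.axial_low or ns_f.low, ns_f.axial_high or ns_f.high)
    tl_range = tl_range or (tl_f.axial_low or tl_f.low, tl_f.axial_high or tl_f.high)
    ns_axis = np.linspace(*ns_range, mc.grid_resolution)
    tl_axis = np.linspace(*tl_range, mc.grid_resolution)

    rng = np.random.default_rng(mc.seed)
    # one MVN coefficient sample per response, shared across grid points;
    # residual draws are independent per point
    coef_draws = {
        name: rng.multivariate_normal(m.coefficients, m.cov, size=mc.n_sim,
                                      method="svd")  # tolerates singular covariances
        for name, m in models.items()
    }

    shape = (len(td_values), mc.grid_resolution, mc.grid_resolution)
    per_response = {name: np.empty(shape) for name in models}
    combined = np.empty(shape)

    tl_grid, ns_grid = np.meshgrid(tl_axis, ns_axis, indexing="ij")
    coded_pts = np.column_stack([
        code(ns_grid.ravel(), ns_f),
        np.zeros(ns_grid.size),
        code(tl_grid.ravel(), tl_f),
    ])
    n_pts = len(coded_pts)
    chunk = max(1, int(2e7) // mc.n_sim)

    for it, td in enumerate(td_values):
        coded_pts[:, 1] = code(float(td), td_f)
        fails = {name: np.empty(n_pts) for name in models}
        combined_p = np.empty(n_pts)
        for start in range(0, n_pts, chunk):
            sl = slice(start, min(start + chunk, n_pts))
            any_fail = np.zeros((sl.stop - sl.start, mc.n_sim), dtype=bool)
            for (name, limit, side) in limits.checks():
                m = models[name]
                X = m.basis(coded_pts[sl])
                sims = X @ coef_draws[name].T
                sims += rng.normal(0.0, np.sqrt(m.resid_var), size=sims.shape)
                f = sims > limit if side == "upper" else sims < limit
                fails[name][sl] = f.mean(axis=1)
                any_fail |= f
            combined_p[sl] = any_fail.mean(axis=1)
        for name in models:
            per_response[name][it] = fails[name].reshape(mc.grid_resolution,
                                                         mc.grid_resolution)
        combined[it] = combined_p.reshape(mc.grid_resolution, mc.grid_resolution)

    return DesignSpaceGrid(ns_axis, tl_axis, tuple(int(t) for t in td_values),
                           per_response, combined, mc)


def extract_design_space(
    grid: DesignSpaceGrid,
    threshold: float | None = None,
    contour_levels: Sequence[float] = (0.005, 0.01, 0.05, 0.1),
) -> tuple[np.ndarray, dict[tuple[int, float], list[np.ndarray]]]:
    """Boolean acceptance mask plus contour polylines of the combined map.

    Returns ``(mask, contours)`` where ``mask[i]`` is True where the
    combined failure probability at TD slice ``i`` is <= threshold, and
    ``contours`` maps (TD, level) to polylines in actual (T_l, NS) units.
    """
    from skimage import measure

    threshold = grid.settings.failure_threshold if threshold is None else threshold
    mask = grid.combined <= threshold
    contours: dict[tuple[int, float], list[np.ndarray]] = {}
    for it, td in enumerate(grid.td_values):
        for level in contour_levels:
            lines = measure.find_contours(grid.combined[it], level)
            out = []
            for line in lines:
                tl = np.interp(line[:, 0], np.arange(len(grid.tl_axis)), grid.tl_axis)
                ns = np.interp(line[:, 1], np.arange(len(grid.ns_axis)), grid.ns_axis)
                out.append(np.column_stack([tl, ns]))
            contours[(td, level)] = out
    return mask, contours


@dataclass(frozen=True)
class MODRBox:
    """The selected method operable design region."""

    td_values: tuple[int, ...] = (65536, 98304)
    ns_values: tuple[int, ...] = (32, 40, 48)
    tl_range: tuple[float, float] = (20.0, 25.0)

    def corner_points(self, sw_ppm: float = 12.016,
                      frequency_mhz: float = 500.13) -> list[tuple[int, int, float]]:
        """(NS, TD, D1) settings at every box vertex, D1 = T_l - AQ."""
        pts = []
        for td in self.td_values:
            aq = acquisition_time(td, sw_ppm, frequency_mhz)
            for ns in self.ns_values:
                for tl in self.tl_range:
                    pts.append((ns, td, tl - aq))
        return pts

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"TD": list(self.td_values), "NS": list(self.ns_values),
                 "Tl_s": list(self.tl_range)}, fh, indent=2)


def verify_points(
    models: Mapping[str, FittedModel],
    limits: SpecLimits,
    points: Sequence[tuple[float, float, float]],
    factors: Sequence[FactorDef],
    sw_ppm: float = 12.016,
    frequency_mhz: float = 500.13,
) -> pd.DataFrame:
    """Mean-model predictions and limit flags at (NS, TD, D1) settings.

    The time lag is derived as T_l = AQ(TD) + D1 before coding, so the
    TD - D1 interaction stays out of the model space.
    """
    ns_f, td_f, tl_f = factors
    rows = []
    for ns, td, d1 in points:
        tl = acquisition_time(td, sw_ppm, frequency_mhz) + d1
        x = [code(float(ns), ns_f), code(float(td), td_f), code(tl, tl_f)]
        row = {"NS": ns, "TD": td, "D1": d1, "Tl": tl}
        ok = True
        for name, limit, side in limits.checks():
            pred = models[name].predict(x)
            passed = pred <= limit if side == "upper" else pred >= limit
            row[f"pred_{name}"] = pred
            row[f"pass_{name}"] = passed
            ok &= passed
        row["pass_all"] = ok
        rows.append(row)
    return pd.DataFrame(rows)
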