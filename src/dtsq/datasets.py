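"""Packaged study tables and factor definitions.

The screening and optimization run tables of the published total-saponin
qNMR method development are shipped as small CSV fixtures so every fit and
design-space computation can be reproduced offline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .doe import DesignMatrix, FactorDef

_TD_GRID = (16384, 32768, 49152, 65536, 98304, 131072)


def pbd_factors() -> list[FactorDef]:
    """The seven screened acquisition parameters (two-level + center)."""
    return [
        FactorDef("M", "x1", 0.5, 5, 2, units="mmol/L"),
        FactorDef("DS", "x2", 0, 8, 4, units="scans"),
        FactorDef("NS", "x3", 16, 128, 64, units="scans"),
        FactorDef("TD", "x4", 16384, 65536, 32768, units="points",
                  allowed_values=_TD_GRID),
        FactorDef("RG", "x5", 40.3, 161, 90.5),
        FactorDef("D1", "x6", 2, 30, 10, units="s"),
        FactorDef("Temp", "x7", 296, 300, 298, units="K"),
    ]


def ccd_factors() -> list[FactorDef]:
    """The three optimized parameters: scans, FID size, time lag."""
    return [
        FactorDef("NS", "X1", 32, 80, 56, axial_low=16, axial_high=96,
                  units="scans", allowed_values=tuple(range(8, 136, 8))),
        FactorDef("TD", "X2", 32768, 98304, 65536, axial_low=16384,
                  axial_high=131072, units="points", allowed_values=_TD_GRID),
        FactorDef("Tl", "X3", 20, 30, 25, axial_low=16.59, axial_high=33.41,
                  units="s"),
    ]


def _read(name: str) -> pd.DataFrame:
    with resources.files("dtsq.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_pbd() -> DesignMatrix:
    """Screening design with its accuracy / SNR / resolution responses."""
    design = _read("pbd_design.csv").set_index("run")
    responses = _read("pbd_responses.csv").set_index("run")
    return DesignMatrix(pbd_factors(), design, responses)


def load_ccd() -> DesignMatrix:
    """Optimization design with accuracy / SNR / total-time responses."""
    runs = _read("ccd_runs.csv").set_index("run")
    factors = ccd_factors()
    names = [f.name for f in factors]
    return DesignMatrix(factors, runs[names], runs.drop(columns=names))


def load_rsm_reference() -> pd.DataFrame:
    """Published response-surface coefficients (unit-variance factor scale)."""
    return _read("rsm_reference.csv").set_index("term")


def load_method_comparison() -> pd.DataFrame:
    """UV colorimetry vs qNMR totals for six production batches (mmol/L)."""
    return _read("method_comparison.csv").set_index("batch")
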