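"""Sedimentary covariates: grain-size fractionation and table validation.

Grain-size spectra (particle size in micrometres vs mass fraction) are folded
into clay (<4 um), silt (4-63 um) and sand (>63 um) percentages plus the
silt/clay ratio. Point spectra are classified directly; explicit [lo, hi)
bins straddling a cut point are split pro-rata on log particle size (the
instrument's native bin edges are not standardized). A convenience textural
class labels the dominant fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLAY_SILT_CUT_UM = 4.0
SILT_SAND_CUT_UM = 63.0

ABIOTIC_VARIABLES = ["protein", "carbohydrate", "silt_clay_ratio",
                     "sand_percent", "oxygen", "depth_m", "horizon_cm"]

#: default vertical slicing scheme (cm thickness per slice, surface down)
HORIZON_SCHEME = (1, 2, 2, 2, 3, 3, 4)


def horizon_boundaries(scheme=HORIZON_SCHEME) -> list[tuple[float, float]]:
    if any(t <= 0 for t in scheme):
        raise ValueError("slice thicknesses must be positive")
    edges = np.concatenate([[0.0], np.cumsum(scheme)])
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def horizon_midpoint(top: float, bottom: float) -> float:
    return (top + bottom) / 2.0


@dataclass
class GrainSizeFractions:
    clay_percent: float
    silt_percent: float
    sand_percent: float
    silt_clay_ratio: float | None   # None when clay fraction is zero

    @property
    def shepard_class(self) -> str:
        best = max(
            [("clay", self.clay_percent), ("silt", self.silt_percent),
             ("sand", self.sand_percent)],
            key=lambda t: t[1],
        )
        return best[0]


def _split_bin(lo: float, hi: float, frac: float) -> tuple[float, float, float]:
    """Apportion one [lo, hi) mass fraction to (clay, silt, sand), log pro-rata."""
    if lo <= 0 or hi <= lo:
        raise ValueError(f"bad grain-size bin [{lo}, {hi})")
    cuts = [CLAY_SILT_CUT_UM, SILT_SAND_CUT_UM]
    span = math.log(hi) - math.log(lo)
    parts = [0.0, 0.0, 0.0]
    edges = [lo] + [c for c in cuts if lo < c < hi] + [hi]
    for a, b in zip(edges[:-1], edges[1:]):
        mid = math.sqrt(a * b)
        if mid < CLAY_SILT_CUT_UM:
            k = 0
        elif mid < SILT_SAND_CUT_UM:
            k = 1
        else:
            k = 2
        parts[k] += frac * (math.log(b) - math.log(a)) / span
    return tuple(parts)  # type: ignore[return-value]


def fractionate(spectrum) -> GrainSizeFractions:
    """Clay/silt/sand percentages and silt/clay ratio from one spectrum.

    `spectrum` is either a list of (size_um, mass_fraction) point masses or
    a DataFrame with columns size_lo_um, size_hi_um, fraction. Fractions
    must sum to 1 (+/- 1e-6).
    """
    clay = silt = sand = 0.0
    if isinstance(spectrum, pd.DataFrame):
        total = float(spectrum["fraction"].sum())
        rows = spectrum.itertuples()
        items = [("bin", r.size_lo_um, r.size_hi_um, r.fraction) for r in rows]
    else:
        items = [("point", size, None, frac) for size, frac in spectrum]
        total = float(sum(frac for _, frac in spectrum))
    if any(it[3] < 0 for it in items):
        raise ValueError("mass fractions must be non-negative")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mass fractions sum to {total}, expected 1")
    for kind, a, b, frac in items:
        if kind == "point":
            if a < CLAY_SILT_CUT_UM:
                clay += frac
            elif a <= SILT_SAND_CUT_UM:
                silt += frac
            else:
                sand += frac
        else:
            dc, ds, dd = _split_bin(a, b, frac)
            clay += dc
            silt += ds
            sand += dd
    ratio = silt / clay if clay > 0 else None
    if ratio is None:
        log.warning("clay fraction is zero; silt/clay ratio undefined")
    return GrainSizeFractions(100 * clay, 100 * silt, 100 * sand, ratio)


def validate_abiotic_table(
    table: pd.DataFrame,
    scheme=HORIZON_SCHEME,
    variables=None,
) -> pd.DataFrame:
    """Check, midpoint-annotate and z-score an abiotic table.

    Requires `horizon_top_cm` / `horizon_bottom_cm` columns conforming to the
    slicing scheme, plus the numeric covariate columns. Appends
    `horizon_cm` (interval midpoint) and a z-scored copy `<var>_z` of every
    covariate.
    """
    if table.empty:
        raise ValueError("empty abiotic table")
    variables = list(variables) if variables is not None else [
        v for v in ABIOTIC_VARIABLES if v in table.columns and v != "horizon_cm"
    ]
    for col in ("horizon_top_cm", "horizon_bottom_cm"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing abiotic columns: {missing}")
    out = table.copy()
    valid = set(horizon_boundaries(scheme))
    for _, row in out.iterrows():
        iv = (float(row["horizon_top_cm"]), float(row["horizon_bottom_cm"]))
        if iv not in valid:
            raise ValueError(f"horizon interval {iv} not in slicing scheme {list(scheme)}")
    out["horizon_cm"] = [
        horizon_midpoint(t, b)
        for t, b in zip(out["horizon_top_cm"], out["horizon_bottom_cm"])
    ]
    for v in variables + ["horizon_cm"]:
        col = pd.to_numeric(out[v], errors="coerce")
        if col.isna().any():
            bad = out.index[col.isna()].tolist()
            raise ValueError(f"non-numeric values in column {v!r} at rows {bad}")
        sd = col.std(ddof=1)
        out[v + "_z"] = (col - col.mean()) / sd if sd > 0 else 0.0
    return out
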