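"""Read-count normalization by counted specimens and background zeroing.

Mapped meiofaunal read numbers per ASV-3 are converted to estimated specimen
counts by proportional allocation of the slice's sorted-specimen total. Part
of the reads come from sources that were never counted (soft-bodied taxa, gut
contents, adsorbed DNA), which drags the per-slice counts/ASV-3 index below 1;
a single global threshold is raised over the matrix cell values until the
index exceeds 1 in every slice, zeroing low-count cells (the planted
background signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import SliceProfile

TAXON_GROUPS = ("Nematoda", "Copepoda", "Polychaeta", "Isopoda",
                "Ostracoda", "Cumacea", "Mollusca")

CORE_DIAMETER_CM = 9.4
CORE_AREA_M2 = math.pi * (CORE_DIAMETER_CM / 200.0) ** 2   # ~6.94e-3 m^2

COUNT_COLUMNS = ["site", "core", "horizon_top_cm", "horizon_bottom_cm",
                 "taxon_group", "count"]


@dataclass
class ZeroingResult:
    matrix: pd.DataFrame          # ASV-3 x slice, zeroed estimated counts
    tau: float                    # minimal admissible global threshold
    index: pd.Series              # per-slice counts / nnz after zeroing
    flagged_slices: list[str]     # totals <= 1 (zeroed entirely) or emptied


def normalize_profile(profile: SliceProfile | dict[str, int], total_count: int) -> dict[str, float]:
    """Estimated specimen counts per ASV-3 for one slice.

    estimate(c) = reads(c) / sum(meiofaunal reads) * total_count, so the
    estimates sum exactly (in real arithmetic) to the counted total.
    """
    reads = profile.reads_per_cluster if isinstance(profile, SliceProfile) else profile
    if total_count < 0:
        raise ValueError("total_count must be non-negative")
    total_reads = sum(reads.values())
    if total_count == 0 or total_reads == 0:
        if total_count > 0:
            raise ValueError(
                "slice has counted specimens but zero mapped meiofaunal reads")
        return {c: 0.0 for c in reads}
    return {c: r / total_reads * total_count for c, r in reads.items()}


def build_abundance_matrix(
    profiles: dict[str, SliceProfile], totals: pd.Series | dict[str, int]
) -> pd.DataFrame:
    """ASV-3 x slice matrix of estimated counts (columns ordered by slice id)."""
    import logging

    totals = pd.Series(totals)
    cols = {}
    for sid in sorted(profiles):
        try:
            cols[sid] = normalize_profile(profiles[sid], int(totals.get(sid, 0)))
        except ValueError:
            # counted specimens but no mapped reads: no estimate possible
            logging.getLogger(__name__).warning(
                "slice %s has counts but no mapped meiofaunal reads; zeroed", sid)
            cols[sid] = {}
    df = pd.DataFrame(cols).fillna(0.0)
    return df.sort_index()


def _slice_indices(matrix: pd.DataFrame, totals: pd.Series) -> pd.Series:
    nnz = (matrix > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = totals.reindex(matrix.columns).astype(float) / nnz.replace(0, np.nan)
    return idx


def background_zero(
    matrix: pd.DataFrame,
    totals: pd.Series | dict[str, int],
    renormalize: bool = False,
    per_slice: bool = False,
) -> ZeroingResult:
    """Zero low-count cells until counts/ASV-3 exceeds 1 in every slice.

    tau is the smallest value from {0} + sorted multiset of positive cell
    values such that zeroing every cell strictly below tau makes
    total_counts / nnz > 1 for every slice with total > 1. Slices whose
    total is <= 1 can never satisfy the strict index and are zeroed entirely
    and flagged. With `per_slice=True` the threshold is found independently
    per column (sensitivity variant). `renormalize=True` rescales the
    surviving cells of each slice back to its counted total.
    """
    totals = pd.Series(totals, dtype=float).reindex(matrix.columns).fillna(0.0)
    m = matrix.copy().astype(float)

    flagged = [c for c in m.columns if 0 < totals[c] <= 1]
    m.loc[:, flagged] = 0.0

    def find_tau(mat: pd.DataFrame) -> tuple[pd.DataFrame, float]:
        V = mat.to_numpy(dtype=float)
        t = totals.reindex(mat.columns).to_numpy(dtype=float)
        need = t > 1

        def admissible(tau: float) -> bool:
            nnz = ((V >= tau) & (V > 0)).sum(axis=0)
            ok = (nnz == 0) | (nnz < t)   # t/nnz > 1  <=>  nnz < t
            return bool(ok[need].all())

        # Raising tau never decreases any slice's index while nnz > 0, so
        # admissibility is monotone in tau and the minimum is found by
        # binary search over the sorted multiset of cell values.
        candidates = [0.0] + sorted(set(V[V > 0].tolist()))
        lo, hi = 0, len(candidates) - 1
        if not admissible(candidates[hi]):
            # only possible when top cells tie in an unsatisfiable slice
            return mat.where(mat > np.inf, 0.0), float("inf")
        if admissible(candidates[0]):
            return mat.copy(), 0.0
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if admissible(candidates[mid]):
                hi = mid
            else:
                lo = mid
        tau = candidates[hi]
        return mat.where(~((mat > 0) & (mat < tau)), 0.0), tau

    if per_slice:
        taus = {}
        for c in m.columns:
            zc, taus[c] = find_tau(m[[c]])
            m[c] = zc[c]
        tau = max(taus.values()) if taus else 0.0
    else:
        m, tau = find_tau(m)

    emptied = [c for c in m.columns
               if totals[c] > 1 and (m[c] > 0).sum() == 0 and c not in flagged]
    if renormalize:
        for c in m.columns:
            s = m[c].sum()
            if s > 0:
                m[c] *= totals[c] / s
    return ZeroingResult(matrix=m, tau=tau,
                         index=_slice_indices(m, totals),
                         flagged_slices=flagged + emptied)


# ---------------------------------------------------------------------------
# Sorted-specimen count tables


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def validate_count_table(df: pd.DataFrame, max_depth_cm: float = 17.0) -> pd.DataFrame:
    if (df["count"] < 0).any():
        bad = df[df["count"] < 0].index.tolist()
        raise ValueError(f"negative counts at rows {bad}")
    if ((df["horizon_top_cm"] < 0) | (df["horizon_bottom_cm"] > max_depth_cm)).any():
        raise ValueError(f"horizon intervals outside [0, {max_depth_cm}] cm")
    return df


def sum_count_table(df: pd.DataFrame):
    """Grand total plus per-site and per-taxon margins (exact integers)."""
    validate_count_table(df, max_depth_cm=np.inf)
    grand = int(df["count"].sum())
    per_site = df.groupby("site")["count"].sum().astype(int)
    per_taxon = df.groupby("taxon_group")["count"].sum().astype(int)
    return grand, per_site, per_taxon


def slice_totals(df: pd.DataFrame) -> pd.Series:
    """Counted specimens per slice, keyed 'site:core:top-bottom'."""
    key = (df["site"].astype(str) + ":" + df["core"].astype(str) + ":"
           + df["horizon_top_cm"].map("{:g}".format) + "-"
           + df["horizon_bottom_cm"].map("{:g}".format))
    return df.assign(_k=key).groupby("_k")["count"].sum()


def areal_abundance(df: pd.DataFrame, n_cores: int) -> pd.DataFrame:
    """Individuals per m^2 normalized to 1 cm horizon thickness.

    value(site, horizon) = sum(counts) / (n_cores * core_area * thickness).
    """
    if n_cores < 1:
        raise ValueError("n_cores must be >= 1")
    validate_count_table(df, max_depth_cm=np.inf)
    thickness = df["horizon_bottom_cm"] - df["horizon_top_cm"]
    if (thickness <= 0).any():
        row = df[thickness <= 0].iloc[0]
        raise ValueError(f"bad horizon interval in row {row.to_dict()}")
    g = df.assign(thickness=thickness).groupby(
        ["site", "horizon_top_cm", "horizon_bottom_cm", "thickness"], as_index=False
    )["count"].sum()
    g["individuals_per_m2_per_cm"] = g["count"] / (n_cores * CORE_AREA_M2 * g["thickness"])
    return g.drop(columns="thickness")
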