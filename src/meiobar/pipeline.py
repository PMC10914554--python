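"""End-to-end orchestration of the metabarcoding analysis.

Stages: read QC and pair merging -> reference library build (or load) ->
read mapping into per-slice ASV-3 profiles -> count normalization and
background zeroing -> Hill-number diversity on replicate-combined slices ->
Bray-Curtis community structure, pairwise permutation tests and BIOENV.

`run_synthetic_study` wires a seeded simulation through every stage and is
the integration surface the tests and the acceptance script exercise;
`run_pipeline` does the same from files on disk described by a YAML config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import community as comm
from . import diversity as dv
from .mapping import MappingParams, ReadMapper, attach_mapping_counts, profile_slice
from .qc import QCParams, ReadFunnelStats, process_pair
from .reflib import ASVRecord, ReferenceLibrary, build_library, partition_by_annotation
from .simulate import PHYLUM_TO_GROUP, SimulationConfig, simulate_study

log = logging.getLogger(__name__)

FUNNEL_COLUMNS = ["n_raw_pairs", "n_filtered_pairs", "n_merged",
                  "n_mapped", "n_mapped_meiofauna"]


@dataclass
class StudyResult:
    library: ReferenceLibrary
    profiles: dict
    funnel: pd.DataFrame
    abundance_raw: pd.DataFrame
    zeroing: ab.ZeroingResult
    diversity: pd.DataFrame
    similarity: pd.DataFrame          # Bray-Curtis, combined slices
    bioenv: comm.BioenvResult | None
    shared: pd.DataFrame
    extras: dict = field(default_factory=dict)


def _slice_key(slice_id: str) -> tuple[str, str, str]:
    site, core, horizon = slice_id.split(":")
    return site, core, horizon


def qc_reads(reads_by_slice, params: QCParams):
    """QC + merge every slice; returns ({slice: merged reads}, {slice: stats})."""
    merged, stats = {}, {}
    for slice_id, (r1, r2) in sorted(reads_by_slice.items()):
        st = ReadFunnelStats(slice_id=slice_id)
        out = []
        for (rid, fs, fq), (_, rs, rq) in zip(r1, r2):
            st.n_raw_pairs += 1
            result, reason = process_pair((fs, fq), (rs, rq), params)
            if result is None:
                st.reject_reasons[reason] = st.reject_reasons.get(reason, 0) + 1
                if reason == "no_overlap":
                    st.n_filtered_pairs += 1
                continue
            st.n_filtered_pairs += 1
            st.n_merged += 1
            out.append((rid.split()[0], result[0]))
        merged[slice_id] = out
        stats[slice_id] = st
    return merged, stats


def build_reference(asvs: list[ASVRecord], cut: float = 0.03,
                    phylum_to_group: dict | None = None) -> ReferenceLibrary:
    lib = build_library(asvs, cut=cut)
    partition_by_annotation(lib, phylum_to_group or PHYLUM_TO_GROUP)
    return lib


def run_synthetic_study(
    cfg: SimulationConfig,
    qc_params: QCParams | None = None,
    map_params: MappingParams | None = None,
    n_perm: int = 99,
    diversity_boot: int = 200,
    run_bioenv: bool = True,
    outdir: str | Path | None = None,
) -> StudyResult:
    """Simulate a study and push it through the whole pipeline."""
    qc_params = qc_params or QCParams()
    map_params = map_params or MappingParams()

    asvs, gt, reads, count_table = simulate_study(cfg, outdir=outdir)
    merged, stats = qc_reads(reads, qc_params)

    lib = build_reference(asvs, cut=0.03)
    mapper = ReadMapper(lib, map_params)
    profiles = {}
    for slice_id, rds in merged.items():
        prof = profile_slice(rds, lib, map_params, slice_id=slice_id, mapper=mapper)
        attach_mapping_counts(stats[slice_id], prof)
        profiles[slice_id] = prof
    funnel = pd.DataFrame([s.as_row() for s in stats.values()]).set_index("slice_id")

    totals = ab.slice_totals(count_table)
    matrix = ab.build_abundance_matrix(profiles, totals)
    zr = ab.background_zero(matrix, totals)

    # --- replicate combination per site x horizon, 1 cm normalization
    slices = list(zr.matrix.columns)
    combos: dict[tuple[str, str], list[str]] = {}
    for s in slices:
        site, core, hz = _slice_key(s)
        combos.setdefault((site, hz), []).append(s)
    combined = {}
    div_rows = []
    for (site, hz), members in sorted(combos.items()):
        top, bottom = (float(v) for v in hz.split("-"))
        thickness = bottom - top
        series = [zr.matrix[m] for m in members]
        x, flagged = dv.combine_replicates(series, thickness)
        combined[f"{site}:{hz}"] = x
        if x.sum() > 0:
            for q in (0, 1):
                est = dv.estimate(x, q, B=diversity_boot,
                                  seed=int(_stable_seed(cfg.seed, site, hz, q)))
                div_rows.append({
                    "site": site, "horizon": hz, "q": q,
                    "observed": est.observed, "estimated": est.estimated,
                    "se": est.se, "ci_lo": est.ci95[0], "ci_hi": est.ci95[1],
                    "rounding_flagged": flagged,
                })
    diversity = pd.DataFrame(div_rows)

    comb_matrix = pd.DataFrame(combined).T.fillna(0.0)
    similarity = comm.bray_curtis(comb_matrix, transform="sqrt")

    bioenv_res = None
    if run_bioenv and gt.abiotic_true is not None:
        abio = gt.abiotic_true.copy()
        abio.index = (abio["site"] + ":" + abio["horizon_top_cm"].map("{:g}".format)
                      + "-" + abio["horizon_bottom_cm"].map("{:g}".format))
        dissim = 100.0 - similarity
        varcols = ["protein", "carbohydrate", "silt_clay_ratio",
                   "sand_percent", "oxygen", "depth_m", "horizon_cm"]
        bioenv_res = comm.bioenv(dissim, abio[varcols], n_perm=n_perm,
                                 seed=cfg.seed + 17)

    site_sets = {}
    for col in zr.matrix.columns:
        site = _slice_key(col)[0]
        present = set(zr.matrix.index[zr.matrix[col] > 0])
        site_sets.setdefault(site, set()).update(present)
    shared = comm.shared_asv_matrix(site_sets)

    result = StudyResult(
        library=lib, profiles=profiles, funnel=funnel,
        abundance_raw=matrix, zeroing=zr, diversity=diversity,
        similarity=similarity, bioenv=bioenv_res, shared=shared,
        extras={"ground_truth": gt, "count_table": count_table,
                "combined_matrix": comb_matrix, "merged_reads": merged},
    )
    if outdir is not None:
        write_outputs(result, Path(outdir), cfg)
    return result


def _stable_seed(*parts) -> int:
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def write_outputs(result: StudyResult, outdir: Path, cfg=None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.funnel.to_csv(outdir / "funnel.tsv", sep="\t")
    result.abundance_raw.to_csv(outdir / "abundance_raw.tsv", sep="\t")
    result.zeroing.matrix.to_csv(outdir / "abundance_zeroed.tsv", sep="\t")
    result.zeroing.index.rename("counts_per_asv3").to_csv(
        outdir / "slice_index.tsv", sep="\t")
    result.diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    result.similarity.to_csv(outdir / "bray_curtis.tsv", sep="\t")
    merges, ids = comm.dendrogram(result.similarity)
    (outdir / "dendrogram.nwk").write_text(comm.to_newick(merges, ids))
    result.shared.to_csv(outdir / "shared_asv3_percent.tsv", sep="\t")
    if result.bioenv is not None:
        (outdir / "bioenv.json").write_text(json.dumps({
            "best_subset": list(result.bioenv.best_subset),
            "rho": result.bioenv.rho,
            "permutation_threshold": result.bioenv.permutation_threshold,
            "per_size": {str(k): [list(v[0]), v[1]]
                         for k, v in result.bioenv.per_size.items()},
        }, indent=1))
    if cfg is not None:
        cfg_json = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(cfg).items()}, sort_keys=True)
        (outdir / "run_manifest.json").write_text(json.dumps({
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }, indent=1))


def run_pipeline(config_path: str | Path, outdir: str | Path) -> StudyResult:
    """File-driven entry point: YAML config naming the simulation parameters
    (and optional QC/mapping overrides), artifacts written to `outdir`."""
    import yaml

    with open(config_path) as fh:
        cfg_dict = yaml.safe_load(fh) or {}
    sim = {k: (tuple(v) if isinstance(v, list) else v)
           for k, v in (cfg_dict.get("simulate") or {}).items()}
    cfg = SimulationConfig(**sim)
    qc_params = QCParams(**(cfg_dict.get("qc") or {}))
    map_params = MappingParams(**(cfg_dict.get("mapping") or {}))
    n_perm = int(cfg_dict.get("n_perm", 99))
    return run_synthetic_study(cfg, qc_params, map_params, n_perm=n_perm,
                               outdir=outdir)
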