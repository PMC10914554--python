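"""Seeded synthetic studies with the statistical structure the pipeline assumes.

A study consists of: a reference pool of barcode variants (several ASVs per
species, pairwise divergence below the species-proxy threshold within a
species and well above it between species, flanked by realized primer-binding
motifs); site-and-horizon-structured communities whose expected abundance
decays exponentially with bottom depth and sub-bottom horizon midpoint;
paired amplicon reads per slice, including a configurable fraction of
background reads from soft-bodied species absent from the sorted-specimen
counts; count tables for hard-bodied species only; and abiotic covariates
with tunable coupling to the planted depth/horizon gradient.

All randomness flows from `SimulationConfig.seed`; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .abiotics import HORIZON_SCHEME, horizon_boundaries, horizon_midpoint
from .abundance import COUNT_COLUMNS, TAXON_GROUPS
from .qc import write_fastq
from .reflib import ASVRecord, p_distance
from .seqs import (FORWARD_PRIMER, REVERSE_PRIMER, mutate, random_sequence,
                   realize_degenerate, reverse_complement)


class InfeasibleConfigError(ValueError):
    """Requested divergence structure cannot be realized at this length."""


#: taxonomy labels for hard-bodied species (the 7 counted groups), the
#: soft-bodied background pool, and non-meiofaunal off-target taxa
SOFT_BODIED_PHYLA = ("Platyhelminthes", "Gastrotricha", "Gnathostomulida",
                     "Xenacoelomorpha")
OTHER_PHYLA = ("Fungi", "Alveolata")

#: phylum -> functional group annotation table used by the pipeline
PHYLUM_TO_GROUP = {p: "meiofauna" for p in TAXON_GROUPS + SOFT_BODIED_PHYLA}
PHYLUM_TO_GROUP.update({p: "other" for p in OTHER_PHYLA})

#: sampling weights of the counted groups (nematode-dominated meiofauna)
GROUP_WEIGHTS = (0.60, 0.20, 0.08, 0.03, 0.03, 0.03, 0.03)


@dataclass
class SimulationConfig:
    """Study design and generative parameters (defaults mirror the survey
    setting: six slope-to-basin sites, three replicate cores, seven slices
    down to 17 cm, 8.9% background reads)."""

    n_sites: int = 6
    depths_m: tuple[float, ...] = (54, 122, 394, 771, 1134, 1418)
    horizon_scheme: tuple[float, ...] = HORIZON_SCHEME
    n_cores_per_site: int = 3
    n_species: int = 40
    n_background_species: int = 6
    n_other_species: int = 2
    n_asvs_per_species: int = 3
    barcode_length_range: tuple[int, int] = (325, 445)
    within_cluster_divergence: float = 0.015
    between_cluster_divergence: float = 0.05
    abundance_decay_depth: float = 0.003     # per metre
    abundance_decay_horizon: float = 0.2     # per cm
    decay_heterogeneity: float = 0.6         # log-sd of per-species decay rates
    baseline_log_mean: float = 3.0           # lognormal per-species baseline counts
    baseline_log_sd: float = 1.2
    background_read_fraction: float = 0.089
    reads_per_slice: int = 400
    read_length: int = 250
    seq_error_rate: float = 0.001
    read_allocation: str = "proportional"    # or "multinomial"
    indels: bool = False
    degrading_quality: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.depths_m) != self.n_sites:
            raise ValueError("depths_m must have one entry per site")
        if any(d <= 0 for d in self.depths_m):
            raise ValueError("depths must be positive")
        if any(t <= 0 for t in self.horizon_scheme):
            raise ValueError("horizon thicknesses must be positive")
        if not (self.within_cluster_divergence < 0.03 < self.between_cluster_divergence):
            raise ValueError(
                "need within_cluster_divergence < 0.03 < between_cluster_divergence")
        for p in (self.background_read_fraction, self.seq_error_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.read_allocation not in ("proportional", "multinomial"):
            raise ValueError("read_allocation must be 'proportional' or 'multinomial'")
        lo, hi = self.barcode_length_range
        if lo < len(FORWARD_PRIMER) + len(REVERSE_PRIMER) + 50 or hi < lo:
            raise ValueError("barcode length range too short for the primer pair")

    def noiseless(self) -> "SimulationConfig":
        """Copy with sequencing noise and background reads switched off."""
        d = asdict(self)
        d.update(background_read_fraction=0.0, seq_error_rate=0.0,
                 read_allocation="proportional")
        return SimulationConfig(**d)


@dataclass
class GroundTruth:
    species_sequences: dict[str, list[str]] = field(default_factory=dict)  # sp -> ASV ids
    asv_sequences: dict[str, str] = field(default_factory=dict)
    true_membership: dict[str, str] = field(default_factory=dict)          # ASV -> sp
    species_group: dict[str, str] = field(default_factory=dict)            # sp -> phylum/group
    species_kind: dict[str, str] = field(default_factory=dict)             # hard|background|other
    true_counts: pd.DataFrame | None = None   # columns: species,site,core,slice_idx,count
    abiotic_true: pd.DataFrame | None = None
    coupling: dict[str, float] = field(default_factory=dict)
    read_truth: dict[str, dict[str, int]] = field(default_factory=dict)  # slice -> sp -> reads


def _species_labels(cfg: SimulationConfig, rng: np.random.Generator):
    labels = {}
    kind = {}
    counters: dict[str, int] = {}

    def take(phylum):
        counters[phylum] = counters.get(phylum, 0) + 1
        return f"{phylum}_{counters[phylum]}"

    hard_groups = rng.choice(len(TAXON_GROUPS), size=cfg.n_species, p=GROUP_WEIGHTS)
    for s in range(cfg.n_species):
        sp = f"sp{s:03d}"
        labels[sp] = take(TAXON_GROUPS[hard_groups[s]])
        kind[sp] = "hard"
    for s in range(cfg.n_background_species):
        sp = f"bg{s:03d}"
        labels[sp] = take(SOFT_BODIED_PHYLA[s % len(SOFT_BODIED_PHYLA)])
        kind[sp] = "background"
    for s in range(cfg.n_other_species):
        sp = f"ot{s:03d}"
        labels[sp] = take(OTHER_PHYLA[s % len(OTHER_PHYLA)])
        kind[sp] = "other"
    return labels, kind


def simulate_reference_sequences(
    cfg: SimulationConfig, margin: float | None = None
) -> tuple[list[ASVRecord], GroundTruth]:
    """Generate the reference ASV pool and its planted species membership.

    Every ASV is a full amplicon: realized forward primer + species core +
    reverse complement of the realized reverse primer. Within a species,
    pairwise p-distance stays below `within_cluster_divergence`; across
    species it must exceed `between_cluster_divergence` (checked; an
    InfeasibleConfigError is raised when the draw cannot satisfy it, e.g.
    at very short lengths or absurd species numbers).
    """
    rng = np.random.default_rng(cfg.seed)
    margin = cfg.between_cluster_divergence if margin is None else margin
    labels, kinds = _species_labels(cfg, rng)
    gt = GroundTruth(species_group=labels, species_kind=kinds)

    lo, hi = cfg.barcode_length_range
    primer_len = len(FORWARD_PRIMER) + len(REVERSE_PRIMER)
    ancestors: dict[str, str] = {}
    for sp in labels:
        length = int(rng.integers(lo, hi + 1))
        fwd = realize_degenerate(FORWARD_PRIMER, rng)
        rev = realize_degenerate(REVERSE_PRIMER, rng)
        core = random_sequence(length - primer_len, rng)
        ancestors[sp] = fwd + core + reverse_complement(rev)

    asvs: list[ASVRecord] = []
    for sp, anc in ancestors.items():
        L = len(anc)
        core_positions = np.arange(len(FORWARD_PRIMER), L - len(REVERSE_PRIMER))
        n_sub = int(np.floor(cfg.within_cluster_divergence * L / 2))
        n_variants = cfg.n_asvs_per_species if kinds[sp] == "hard" else 1
        gt.species_sequences[sp] = []
        for v in range(n_variants):
            asv_id = f"{sp}.v{v}"
            if v == 0:
                seq = anc
            else:
                pos = rng.choice(core_positions, size=n_sub, replace=False)
                seq = mutate(anc, pos, rng)
                if cfg.indels and n_sub > 0:
                    # optional single 1-3 bp indel to exercise the gap rule
                    cutpos = int(rng.choice(core_positions[:-3]))
                    glen = int(rng.integers(1, 4))
                    seq = seq[:cutpos] + seq[cutpos + glen:]
            gt.species_sequences[sp].append(asv_id)
            gt.asv_sequences[asv_id] = seq
            gt.true_membership[asv_id] = sp
            asvs.append(ASVRecord(asv_id, seq, labels[sp], "meiofauna"
                                  if kinds[sp] != "other" else "other"))

    _check_divergences(cfg, gt, margin)
    return asvs, gt


def _check_divergences(cfg: SimulationConfig, gt: GroundTruth, margin: float) -> None:
    sps = list(gt.species_sequences)
    # within-species diameters
    for sp in sps:
        ids = gt.species_sequences[sp]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = p_distance(gt.asv_sequences[ids[i]], gt.asv_sequences[ids[j]])
                if d >= 0.03:
                    raise InfeasibleConfigError(
                        f"within-species distance {d:.3f} >= 0.03 in {sp}")
    # between-species separation: compare ancestors (v0 representatives)
    for i in range(len(sps)):
        for j in range(i + 1, len(sps)):
            a = gt.asv_sequences[gt.species_sequences[sps[i]][0]]
            b = gt.asv_sequences[gt.species_sequences[sps[j]][0]]
            d = p_distance(a, b)
            if d < margin:
                raise InfeasibleConfigError(
                    f"between-species distance {d:.3f} < required {margin} "
                    f"({sps[i]} vs {sps[j]}); configuration infeasible")


def simulate_community(cfg: SimulationConfig, gt: GroundTruth) -> pd.DataFrame:
    """Poisson specimen counts per species x site x core x slice.

    Expected count = baseline_s * exp(-k_d,s * depth) * exp(-k_h,s * horizon
    midpoint); per-species rates scatter lognormally around the configured
    decay rates, which is what creates compositional turnover along the
    depth and horizon gradients.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sps = [sp for sp in gt.species_sequences]
    base = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, len(sps)))
    het = cfg.decay_heterogeneity
    kd = cfg.abundance_decay_depth * np.exp(rng.normal(0, het, len(sps)))
    kh = cfg.abundance_decay_horizon * np.exp(rng.normal(0, het, len(sps)))
    bounds = horizon_boundaries(cfg.horizon_scheme)
    rows = []
    for si, depth in enumerate(cfg.depths_m):
        site = f"S{si}"
        for core in range(cfg.n_cores_per_site):
            for hzi, (top, bottom) in enumerate(bounds):
                mid = horizon_midpoint(top, bottom)
                lam = base * np.exp(-kd * depth) * np.exp(-kh * mid)
                counts = rng.poisson(lam)
                for sp, c in zip(sps, counts):
                    rows.append((sp, site, f"C{core}", hzi, int(c)))
    gt.true_counts = pd.DataFrame(
        rows, columns=["species", "site", "core", "slice_idx", "count"])
    gt.coupling = {"kd": kd.tolist(), "kh": kh.tolist(), "baseline": base.tolist()}
    return gt.true_counts


def simulate_abiotics(
    cfg: SimulationConfig,
    gt: GroundTruth,
    couplings: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Abiotic covariates per site x horizon with known gradient coupling.

    The community gradient g = k_d*depth + k_h*horizon (the log-scale
    abundance decay) is z-scored; each non-spatial variable is generated as
    rho * z(g) + sqrt(1-rho^2) * noise, then shifted/scaled to plausible
    units. Depth and horizon themselves are exact, making them the planted
    drivers a BIOENV search should recover.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    couplings = couplings if couplings is not None else {
        "protein": -0.2, "carbohydrate": 0.0, "silt_clay_ratio": 0.1,
        "sand_percent": -0.1, "oxygen": -0.2,
    }
    bounds = horizon_boundaries(cfg.horizon_scheme)
    rows = []
    for si, depth in enumerate(cfg.depths_m):
        for (top, bottom) in bounds:
            mid = horizon_midpoint(top, bottom)
            rows.append({"site": f"S{si}", "horizon_top_cm": top,
                         "horizon_bottom_cm": bottom, "depth_m": depth,
                         "horizon_cm": mid})
    df = pd.DataFrame(rows)
    g = cfg.abundance_decay_depth * df["depth_m"] + cfg.abundance_decay_horizon * df["horizon_cm"]
    zg = (g - g.mean()) / g.std(ddof=1)
    scales = {"protein": (2.0, 0.6), "carbohydrate": (300.0, 80.0),
              "silt_clay_ratio": (1.2, 0.3), "sand_percent": (8.0, 4.0),
              "oxygen": (150.0, 60.0)}
    for var, rho in couplings.items():
        noise = rng.normal(size=len(df))
        zvar = rho * zg + np.sqrt(max(1 - rho ** 2, 0)) * noise
        mu, sd = scales[var]
        df[var] = np.maximum(mu + sd * zvar, 0.01)
    gt.abiotic_true = df
    gt.coupling.update({f"rho_{k}": v for k, v in couplings.items()})
    return df


def _phred_qualities(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> list[int]:
    if not cfg.degrading_quality:
        return [38] * n
    # linear decay over the 3' half, down to well below the trimming cutoff
    qs = np.full(n, 38.0)
    tail = n // 2
    qs[-tail:] = np.linspace(38, 8, tail)
    return [int(q) for q in qs]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    return mutate(seq, pos, rng)


def _allocate(weights: np.ndarray, total: int, mode: str, rng) -> np.ndarray:
    """Integer allocation of `total` reads proportional to weights."""
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    p = weights / weights.sum()
    if mode == "multinomial":
        return rng.multinomial(total, p)
    # deterministic largest-remainder
    raw = p * total
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    out[order[:rem]] += 1
    return out


def simulate_reads(
    cfg: SimulationConfig, gt: GroundTruth
) -> tuple[dict[str, tuple[list, list]], pd.DataFrame]:
    """Paired reads per slice plus the hard-bodied count table.

    Default allocation gives each counted specimen a fixed number of reads
    (so downstream count recovery is exact in the noiseless setting);
    background/off-target reads are appended so that their expected share of
    the slice's reads equals the configured fractions. Returns
    ({slice_id: (R1 records, R2 records)}, count table).
    """
    if gt.true_counts is None:
        raise ValueError("simulate_community must run first")
    rng = np.random.default_rng(cfg.seed + 3)
    sps = list(gt.species_sequences)
    hard = [s for s in sps if gt.species_kind[s] == "hard"]
    bg = [s for s in sps if gt.species_kind[s] == "background"]
    other = [s for s in sps if gt.species_kind[s] == "other"]
    bounds = horizon_boundaries(cfg.horizon_scheme)

    counts = gt.true_counts
    reads_by_slice: dict[str, tuple[list, list]] = {}
    count_rows = []
    other_frac = 0.02 if other else 0.0

    for (site, core, hzi), grp in counts.groupby(["site", "core", "slice_idx"]):
        top, bottom = bounds[int(hzi)]
        slice_id = f"{site}:{core}:{top:g}-{bottom:g}"
        per_sp = grp.set_index("species")["count"]
        total_hard = int(per_sp.loc[hard].sum())
        # count table rows (hard-bodied only, by sorted group)
        by_group = {}
        for sp in hard:
            gname = gt.species_group[sp].rsplit("_", 1)[0]
            by_group[gname] = by_group.get(gname, 0) + int(per_sp[sp])
        for gname, c in sorted(by_group.items()):
            count_rows.append((site, core, top, bottom, gname, c))

        # hard-bodied reads: fixed reads per specimen
        budget_hard = cfg.reads_per_slice * (1 - cfg.background_read_fraction - other_frac)
        rps = max(1, int(round(budget_hard / total_hard))) if total_hard else 0
        r1, r2 = [], []
        serial = 0

        def emit(sp, n_reads):
            nonlocal serial
            if n_reads:
                truth = gt.read_truth.setdefault(slice_id, {})
                truth[sp] = truth.get(sp, 0) + int(n_reads)
            ids = gt.species_sequences[sp]
            alloc = _allocate(np.ones(len(ids)), n_reads, "proportional", rng) \
                if cfg.read_allocation == "proportional" else \
                rng.multinomial(n_reads, np.ones(len(ids)) / len(ids))
            for asv_id, k in zip(ids, alloc):
                amp = gt.asv_sequences[asv_id]
                for _ in range(k):
                    serial += 1
                    fwd = amp[: cfg.read_length]
                    rev = reverse_complement(amp)[: cfg.read_length]
                    fwd = _apply_errors(fwd, cfg.seq_error_rate, rng)
                    rev = _apply_errors(rev, cfg.seq_error_rate, rng)
                    rid = f"SIM:{site}:{core}:{top:g}-{bottom:g}:{serial}"
                    r1.append((rid + " 1", fwd, _phred_qualities(cfg, len(fwd), rng)))
                    r2.append((rid + " 2", rev, _phred_qualities(cfg, len(rev), rng)))

        if cfg.read_allocation == "proportional":
            for sp in hard:
                emit(sp, int(per_sp[sp]) * rps)
        else:
            w = per_sp.loc[hard].to_numpy(dtype=float)
            for sp, k in zip(hard, _allocate(w, int(round(budget_hard)), "multinomial", rng)):
                emit(sp, int(k))
        n_hard_reads = serial

        # background (uncounted soft-bodied) and off-target reads
        f_bg, f_ot = cfg.background_read_fraction, other_frac
        if n_hard_reads and f_bg > 0 and bg:
            n_bg = int(round(n_hard_reads * f_bg / (1 - f_bg - f_ot)))
            for sp, k in zip(bg, _allocate(np.ones(len(bg)), n_bg,
                                           cfg.read_allocation, rng)):
                emit(sp, int(k))
        if n_hard_reads and f_ot > 0 and other:
            n_ot = int(round(n_hard_reads * f_ot / (1 - f_bg - f_ot)))
            for sp, k in zip(other, _allocate(np.ones(len(other)), n_ot,
                                              cfg.read_allocation, rng)):
                emit(sp, int(k))
        reads_by_slice[slice_id] = (r1, r2)

    count_table = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    return reads_by_slice, count_table


def simulate_study(cfg: SimulationConfig, outdir: str | Path | None = None):
    """Full study: references, communities, reads, counts, abiotics.

    With `outdir`, writes reference FASTA, gzipped paired FASTQ per slice,
    the count and abiotic TSVs and a ground-truth JSON sidecar; file bytes
    are reproducible for a fixed config.
    """
    asvs, gt = simulate_reference_sequences(cfg)
    simulate_community(cfg, gt)
    simulate_abiotics(cfg, gt)
    reads, count_table = simulate_reads(cfg, gt)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "reads").mkdir(parents=True, exist_ok=True)
        with open(outdir / "reference_asvs.fasta", "w") as fh:
            for a in asvs:
                fh.write(f">{a.asv_id}||{a.taxonomy_label}|{a.functional_group}\n"
                         f"{a.sequence}\n")
        for slice_id, (r1, r2) in sorted(reads.items()):
            stem = slice_id.replace(":", "_")
            write_fastq(outdir / "reads" / f"{stem}_R1.fastq.gz", r1)
            write_fastq(outdir / "reads" / f"{stem}_R2.fastq.gz", r2)
        count_table.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        gt.abiotic_true.to_csv(outdir / "abiotic.tsv", sep="\t", index=False)
        sidecar = {
            "true_membership": gt.true_membership,
            "species_group": gt.species_group,
            "species_kind": gt.species_kind,
            "coupling": gt.coupling,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
    return asvs, gt, reads, count_table
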