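"""Species-proxy reference library construction.

Amplicon sequence variants (ASVs) of the 18S-V4 barcode are compared by
p-distance (proportion of differing aligned positions under a global unit-cost
alignment; gap and N columns are excluded from the denominator), clustered by
group-average linkage, and the dendrogram is cut strictly below 3%
dissimilarity. Each resulting cluster ("ASV-3") is treated as a
species-compatible entity. Clusters annotated to meiofaunal phyla form the
mapping reference; the rest are retained so off-target reads can be recognised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from . import cluster as _cluster

log = logging.getLogger(__name__)

MIN_ASV_LENGTH = 325       # shorter sequences are purged as mis-paired
DEFAULT_CUT = 0.03         # ASV-3 dissimilarity threshold


class UndefinedDistanceError(ValueError):
    """Raised when two sequences share no comparable aligned positions."""


@dataclass
class ASVRecord:
    asv_id: str
    sequence: str
    taxonomy_label: str = ""         # e.g. "Spionidae_32"
    functional_group: str = "meiofauna"   # "meiofauna" | "other"

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class ASV3Cluster:
    cluster_id: str
    member_asv_ids: frozenset[str]
    representative_id: str
    taxonomy_label: str
    functional_group: str


@dataclass
class ReferenceLibrary:
    asvs: list[ASVRecord]
    clusters: list[ASV3Cluster] = field(default_factory=list)
    cut: float = DEFAULT_CUT

    @property
    def meiofauna_clusters(self) -> list[ASV3Cluster]:
        return [c for c in self.clusters if c.functional_group == "meiofauna"]

    def asv_by_id(self, asv_id: str) -> ASVRecord:
        return self._index()[asv_id]

    def cluster_of(self, asv_id: str) -> ASV3Cluster:
        for c in self.clusters:
            if asv_id in c.member_asv_ids:
                return c
        raise KeyError(asv_id)

    def _index(self) -> dict[str, ASVRecord]:
        return {a.asv_id: a for a in self.asvs}


def _alignment_columns(a: str, b: str):
    """Yield aligned (char_a, char_b) pairs; '-' marks a gap column."""
    res = edlib.align(a, b, mode="NW", task="path")
    ia = ib = 0
    num = ""
    for c in res["cigar"]:
        if c.isdigit():
            num += c
            continue
        n = int(num)
        num = ""
        if c in "=X":
            for _ in range(n):
                yield a[ia], b[ib]
                ia += 1
                ib += 1
        elif c == "I":  # gap in target (consumes query)
            for _ in range(n):
                yield a[ia], "-"
                ia += 1
        elif c == "D":  # gap in query (consumes target)
            for _ in range(n):
                yield "-", b[ib]
                ib += 1


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatched positions among comparable aligned columns.

    The global alignment minimises unit edit cost (match 0 / mismatch 1 /
    gap 1). Columns containing a gap or an N on either side do not enter the
    denominator.
    """
    if not a or not b:
        raise ValueError("p_distance requires non-empty sequences")
    a, b = a.upper(), b.upper()
    if a > b:
        # the optimal unit-cost alignment need not be unique; fixing the
        # argument order makes the distance symmetric by construction
        a, b = b, a
    comparable = mismatches = 0
    for ca, cb in _alignment_columns(a, b):
        if ca in "-N" or cb in "-N":
            continue
        comparable += 1
        if ca != cb:
            mismatches += 1
    if comparable == 0:
        raise UndefinedDistanceError("no comparable aligned positions")
    return mismatches / comparable


def build_distance_matrix(asvs: list[ASVRecord]) -> tuple[list[str], np.ndarray]:
    """All pairwise p-distances; returns (ids, symmetric matrix)."""
    if len(asvs) < 2:
        raise ValueError("need at least two ASVs")
    ids = [a.asv_id for a in asvs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate asv_id in library")
    n = len(asvs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = p_distance(asvs[i].sequence, asvs[j].sequence)
            except ValueError as e:
                raise type(e)(f"{e} (pair {ids[i]}, {ids[j]})") from e
    return ids, d


def group_average_cluster(
    ids: list[str], d: np.ndarray, cut: float = DEFAULT_CUT
) -> list[set[str]]:
    """UPGMA partition of ASVs at merge heights strictly below `cut`."""
    if not (0 < cut <= 1):
        raise ValueError("cut must lie in (0, 1]")
    return _cluster.cluster(d, ids, cut)


def _majority(labels: list[str]) -> str:
    vals, counts = np.unique([l for l in labels if l], return_counts=True)
    if len(vals) == 0:
        return ""
    return str(vals[np.argmax(counts)])


def build_library(
    asvs: list[ASVRecord], cut: float = DEFAULT_CUT, min_length: int = MIN_ASV_LENGTH
) -> ReferenceLibrary:
    """Length-filter, cluster and label a pool of ASVs into ASV-3s.

    Cluster taxonomy/functional group are the majority vote of the members;
    the representative is the longest member (ties by id).
    """
    kept = [a for a in asvs if a.length_bp >= min_length]
    for a in asvs:
        if a.length_bp < min_length:
            log.warning("purged short ASV %s (%d bp < %d)", a.asv_id, a.length_bp, min_length)
    if not kept:
        return ReferenceLibrary(asvs=[], clusters=[], cut=cut)
    if len(kept) == 1:
        parts = [{kept[0].asv_id}]
    else:
        ids, d = build_distance_matrix(kept)
        parts = group_average_cluster(ids, d, cut)
    index = {a.asv_id: a for a in kept}
    clusters = []
    for k, members in enumerate(parts):
        ms = sorted(members)
        rep = max(ms, key=lambda i: (index[i].length_bp, [-ord(c) for c in i]))
        clusters.append(
            ASV3Cluster(
                cluster_id=f"ASV3_{k:04d}",
                member_asv_ids=frozenset(ms),
                representative_id=rep,
                taxonomy_label=_majority([index[i].taxonomy_label for i in ms]),
                functional_group=_majority([index[i].functional_group for i in ms]) or "other",
            )
        )
    return ReferenceLibrary(asvs=kept, clusters=clusters, cut=cut)


def merge_libraries(
    old: ReferenceLibrary,
    new_asvs: list[ASVRecord],
    trim_to: tuple[int, int] | None = None,
    cut: float = DEFAULT_CUT,
) -> ReferenceLibrary:
    """Combine an existing library with new ASVs and re-cluster from scratch.

    Old ASVs are optionally trimmed to a coordinate window (the genomic span
    of the new primer pair); trimmed sequences shorter than the length floor
    are dropped with a logged reason. Exact duplicate sequences are collapsed
    to the lexicographically smallest id.
    """
    pool: list[ASVRecord] = []
    for a in old.asvs:
        seq = a.sequence
        if trim_to is not None:
            seq = seq[trim_to[0]: trim_to[1]]
        if len(seq) < MIN_ASV_LENGTH:
            log.warning("dropped %s: %d bp after trimming", a.asv_id, len(seq))
            continue
        pool.append(ASVRecord(a.asv_id, seq, a.taxonomy_label, a.functional_group))
    pool.extend(new_asvs)
    dedup: dict[str, ASVRecord] = {}
    for a in sorted(pool, key=lambda r: r.asv_id):
        dedup.setdefault(a.sequence, a)
    return build_library(list(dedup.values()), cut=cut)


def partition_by_annotation(
    lib: ReferenceLibrary, phylum_to_group: dict[str, str]
) -> tuple[list[ASV3Cluster], list[ASV3Cluster]]:
    """Split clusters into (meiofauna, other) via a phylum -> group table.

    The phylum is the taxonomy label up to the trailing _serial. Unmapped
    phyla default to "other" with a warning. Functional groups on the
    library's clusters are updated in place.
    """
    meio, other = [], []
    for c in lib.clusters:
        phylum = c.taxonomy_label.rsplit("_", 1)[0] if c.taxonomy_label else ""
        group = phylum_to_group.get(phylum)
        if group is None:
            log.warning("phylum %r not in annotation table; defaulting to 'other'", phylum)
            group = "other"
        c.functional_group = group
        (meio if group == "meiofauna" else other).append(c)
    return meio, other


def annotation_summary(lib: ReferenceLibrary):
    """Per-phylum ASV-3 counts by functional group (tabular summary)."""
    import pandas as pd

    rows = []
    for c in lib.clusters:
        phylum = c.taxonomy_label.rsplit("_", 1)[0] if c.taxonomy_label else "unknown"
        rows.append({"functional_group": c.functional_group, "taxon": phylum})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["functional_group", "taxon", "n_asv3"])
    out = df.value_counts().reset_index(name="n_asv3")
    return out.sort_values(["functional_group", "taxon"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# FASTA round trip; cluster membership is encoded in the defline as
# >asv_id|cluster_id|taxonomy|group

def write_library_fasta(lib: ReferenceLibrary, path: str | Path) -> None:
    cl_of = {m: c for c in lib.clusters for m in c.member_asv_ids}
    with open(path, "w") as fh:
        for a in lib.asvs:
            c = cl_of.get(a.asv_id)
            fh.write(
                f">{a.asv_id}|{c.cluster_id if c else ''}|"
                f"{a.taxonomy_label}|{a.functional_group}\n{a.sequence}\n"
            )


def read_library_fasta(path: str | Path, cut: float = DEFAULT_CUT) -> ReferenceLibrary:
    from Bio import SeqIO

    asvs, membership = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = (rec.description.split() or [rec.id])[0].split("|")
        asv_id = parts[0]
        cl = parts[1] if len(parts) > 1 else ""
        tax = parts[2] if len(parts) > 2 else ""
        grp = parts[3] if len(parts) > 3 else "meiofauna"
        asvs.append(ASVRecord(asv_id, str(rec.seq).upper(), tax, grp))
        if cl:
            membership.setdefault(cl, []).append(asv_id)
    index = {a.asv_id: a for a in asvs}
    clusters = []
    for cl, members in sorted(membership.items()):
        ms = sorted(members)
        rep = max(ms, key=lambda i: (index[i].length_bp, [-ord(c) for c in i]))
        clusters.append(
            ASV3Cluster(cl, frozenset(ms), rep,
                        _majority([index[i].taxonomy_label for i in ms]),
                        _majority([index[i].functional_group for i in ms]) or "other")
        )
    lib = ReferenceLibrary(asvs=asvs, clusters=clusters, cut=cut)
    if not clusters and asvs:
        return build_library(asvs, cut=cut)
    return lib
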