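"""Mapping merged reads to the species-proxy reference library.

A read is aligned (edlib, infix mode so primer-trimmed reads fit inside
full-length references; both strands tried) against candidate ASVs. A hit is
admissible iff mismatch fraction <= 3%, total gap fraction <= 1% of the read,
and no single gap exceeds 3 bp; all thresholds inclusive. The read is assigned
to the ASV-3 cluster of the minimum-mismatch admissible ASV, to "other" if
that ASV is non-meiofaunal, or left unmapped.

A shared 12-mer prefilter narrows the candidate set; it is a pure performance
device (`exhaustive=True` disables it and tests assert identical output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .qc import ReadFunnelStats
from .reflib import ReferenceLibrary
from .seqs import reverse_complement

_KMER = 12


@dataclass
class MappingParams:
    max_mismatch_fraction: float = 0.03
    max_gap_fraction: float = 0.01
    max_gap_length_bp: int = 3

    def __post_init__(self):
        for v in (self.max_mismatch_fraction, self.max_gap_fraction):
            if not (0 <= v <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.max_gap_length_bp < 0:
            raise ValueError("max_gap_length_bp must be non-negative")


@dataclass
class SliceProfile:
    slice_id: str
    reads_per_cluster: dict[str, int] = field(default_factory=dict)
    n_unmapped: int = 0
    n_mapped_other: int = 0

    @property
    def n_mapped_meiofauna(self) -> int:
        return sum(self.reads_per_cluster.values())

    @property
    def total(self) -> int:
        return self.n_mapped_meiofauna + self.n_mapped_other + self.n_unmapped


def _cigar_stats(cigar: str):
    """(aligned_columns, mismatches, gap_runs) from an extended CIGAR."""
    aligned = mism = 0
    gaps: list[int] = []
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
            continue
        n = int(num)
        num = ""
        if c == "=":
            aligned += n
        elif c == "X":
            aligned += n
            mism += n
        elif c in "ID":
            gaps.append(n)
    return aligned, mism, gaps


class ReadMapper:
    """Maps reads against a reference library under fixed thresholds."""

    def __init__(self, lib: ReferenceLibrary, params: MappingParams | None = None,
                 exhaustive: bool = False):
        if not lib.asvs:
            raise ValueError("empty reference library")
        self.lib = lib
        self.params = params or MappingParams()
        self.exhaustive = exhaustive
        self._cluster_of = {m: c for c in lib.clusters for m in c.member_asv_ids}
        self._refs = [(a.asv_id, a.sequence) for a in lib.asvs]
        # 12-mer -> set of reference indices
        self._index: dict[str, set[int]] = {}
        for ri, (_, seq) in enumerate(self._refs):
            for i in range(len(seq) - _KMER + 1):
                self._index.setdefault(seq[i: i + _KMER], set()).add(ri)

    def _candidates(self, read: str) -> set[int]:
        cands: set[int] = set()
        for i in range(len(read) - _KMER + 1):
            hit = self._index.get(read[i: i + _KMER])
            if hit:
                cands |= hit
        return cands

    def _hit(self, read: str, ref: str):
        """(mismatch_fraction, gap_bases, edit) if admissible else None."""
        p = self.params
        max_ed = int(len(read) * (p.max_mismatch_fraction + p.max_gap_fraction)) + 1
        res = edlib.align(read, ref, mode="HW", task="path", k=max_ed)
        if res["editDistance"] < 0:
            return None
        aligned, mism, gaps = _cigar_stats(res["cigar"])
        if aligned == 0:
            return None
        gap_bases = sum(gaps)
        if mism / aligned > p.max_mismatch_fraction:
            return None
        if gap_bases / len(read) > p.max_gap_fraction:
            return None
        if gaps and max(gaps) > p.max_gap_length_bp:
            return None
        return (mism / aligned, gap_bases, res["editDistance"])

    def map_read(self, read: str, cluster_reads: dict[str, int] | None = None):
        """Return (category, cluster_id|None) where category is
        'meiofauna' | 'other' | 'unmapped'.

        `cluster_reads` (running per-cluster tallies for the current slice)
        drives the equal-distance tie rule: the cluster with more reads so
        far wins, residual ties by lexicographic cluster id.
        """
        read = read.upper()
        if self.exhaustive:
            cand = range(len(self._refs))
        else:
            cand = self._candidates(read) | self._candidates(reverse_complement(read))
            if not cand:
                return "unmapped", None
        hits = []  # (key, cluster_id, group)
        rc = reverse_complement(read)
        for ri in sorted(cand):
            asv_id, ref = self._refs[ri]
            best = None
            for strand in (read, rc):
                h = self._hit(strand, ref)
                if h is not None and (best is None or h < best):
                    best = h
            if best is None:
                continue
            cl = self._cluster_of.get(asv_id)
            hits.append((best, cl.cluster_id if cl else None,
                         cl.functional_group if cl else "other"))
        if not hits:
            return "unmapped", None
        best_frac = min(h[0][0] for h in hits)
        top = [h for h in hits if h[0][0] == best_frac]
        if len(top) > 1 and cluster_reads is not None:
            top.sort(key=lambda h: (-(cluster_reads.get(h[1], 0)), h[1] or ""))
        else:
            top.sort(key=lambda h: (h[0], h[1] or ""))
        _, cluster_id, group = top[0]
        if group != "meiofauna":
            return "other", cluster_id
        return "meiofauna", cluster_id


def profile_slice(
    reads: list[tuple[str, str]] | list[str],
    lib: ReferenceLibrary,
    params: MappingParams | None = None,
    slice_id: str = "",
    exhaustive: bool = False,
    mapper: ReadMapper | None = None,
) -> SliceProfile:
    """Tally mapped-read outcomes for one slice's merged reads.

    Conservation: meiofaunal + other + unmapped = number of input reads.
    Deterministic given input order (ties feed on the running tally).
    """
    if mapper is None:
        mapper = ReadMapper(lib, params, exhaustive=exhaustive)
    prof = SliceProfile(slice_id=slice_id)
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        category, cluster_id = mapper.map_read(seq, prof.reads_per_cluster)
        if category == "meiofauna":
            prof.reads_per_cluster[cluster_id] = prof.reads_per_cluster.get(cluster_id, 0) + 1
        elif category == "other":
            prof.n_mapped_other += 1
        else:
            prof.n_unmapped += 1
    return prof


def attach_mapping_counts(stats: ReadFunnelStats, prof: SliceProfile) -> ReadFunnelStats:
    stats.n_mapped = prof.n_mapped_meiofauna + prof.n_mapped_other
    stats.n_mapped_meiofauna = prof.n_mapped_meiofauna
    return stats
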