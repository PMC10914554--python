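"""Read filtering and pair merging for paired-end amplicon reads.

Implements the pre-mapping funnel natively: 3' quality truncation (running-sum
rule at phred cutoff 25), anchored 5' primer removal under IUPAC degeneracy,
length / N-run filtering (min 180 bp, no more than 3 consecutive Ns), and
exhaustive-scan merging of mate pairs (amplicons are short enough that a full
overlap scan is cheap). Phred+33 qualities only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .seqs import FORWARD_PRIMER, REVERSE_PRIMER, is_iupac, iupac_match, reverse_complement


class MalformedRecordError(ValueError):
    pass


@dataclass
class QCParams:
    quality_cutoff: int = 25
    min_length_bp: int = 180
    max_consecutive_n: int = 3
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    primer_max_mismatch: int = 1
    merge_min_overlap_bp: int = 20
    merge_max_mismatch_fraction: float = 0.1

    def __post_init__(self):
        if not (0 <= self.quality_cutoff <= 41):
            raise ValueError("quality_cutoff must be in [0, 41]")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        for p in (self.forward_primer, self.reverse_primer):
            if not p or not is_iupac(p):
                raise ValueError(f"primer {p!r} contains non-IUPAC characters")


@dataclass
class ReadFunnelStats:
    """Per-slice read-count funnel (raw -> filtered -> merged -> mapped)."""
    slice_id: str = ""
    n_raw_pairs: int = 0
    n_filtered_pairs: int = 0
    n_merged: int = 0
    n_mapped: int = 0
    n_mapped_meiofauna: int = 0
    reject_reasons: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "slice_id": self.slice_id,
            "n_raw_pairs": self.n_raw_pairs,
            "n_filtered_pairs": self.n_filtered_pairs,
            "n_merged": self.n_merged,
            "n_mapped": self.n_mapped,
            "n_mapped_meiofauna": self.n_mapped_meiofauna,
        }


def trim_quality_3prime(seq: str, qual: list[int], cutoff: int) -> tuple[str, list[int]]:
    """Truncate the poor 3' side of a read.

    Keeps the prefix maximising the running sum of (quality - cutoff)
    accumulated from the 3' end (the cutadapt/BWA `-q` rule). Ties are
    resolved toward the longest prefix, so a read whose qualities all meet
    the cutoff is returned unchanged.
    """
    if len(seq) != len(qual):
        raise MalformedRecordError("sequence/quality length mismatch")
    # Cut where the suffix sum of (q - cutoff) is minimal and negative;
    # equivalently, keep the prefix with maximal running sum from the 3' end.
    suffix = 0.0
    min_val = 0.0
    cut_at = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        suffix += qual[i] - cutoff
        if suffix < min_val:
            min_val = suffix
            cut_at = i
    return seq[:cut_at], qual[:cut_at]


def remove_primer(seq: str, qual: list[int] | None, primer: str, max_mismatch: int):
    """Strip an anchored 5' primer match; None signals rejection.

    The primer must match at the very 5' end with at most `max_mismatch`
    substitutions, respecting IUPAC degeneracy (no indels).
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    if not is_iupac(primer):
        raise ValueError(f"primer {primer!r} contains non-IUPAC characters")
    if len(seq) < len(primer):
        return None
    mism = sum(
        0 if iupac_match(p, b) else 1
        for p, b in zip(primer.upper(), seq[: len(primer)].upper())
    )
    if mism > max_mismatch:
        return None
    return (seq[len(primer):], None if qual is None else qual[len(primer):])


def filter_read(seq: str, params: QCParams):
    """(True, 'pass') or (False, reason in {'short','n_run'})."""
    if len(seq) < params.min_length_bp:
        return False, "short"
    if "N" * (params.max_consecutive_n + 1) in seq.upper():
        return False, "n_run"
    return True, "pass"


def merge_pair(
    fwd_seq: str, fwd_qual: list[int],
    rev_seq: str, rev_qual: list[int],
    params: QCParams,
):
    """Merge a mate pair via exhaustive ungapped overlap scan.

    The reverse mate is reverse-complemented; every overlap length between
    `merge_min_overlap_bp` and min(len) is scored as matches - mismatches.
    The best-scoring admissible overlap (mismatch fraction within bounds)
    wins, longer overlaps win score ties. In the overlap the higher-quality
    base is called (ties go to the forward mate). Returns (seq, qual) or None.
    """
    rc = reverse_complement(rev_seq)
    rq = rev_qual[::-1]
    best = None  # (score, o)
    max_o = min(len(fwd_seq), len(rc))
    for o in range(params.merge_min_overlap_bp, max_o + 1):
        a = fwd_seq[-o:]
        b = rc[:o]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism / o > params.merge_max_mismatch_fraction:
            continue
        score = o - 2 * mism
        if best is None or score > best[0] or (score == best[0] and o > best[1]):
            best = (score, o)
    if best is None or best[0] <= 0:
        return None
    o = best[1]
    head_s, head_q = fwd_seq[:-o], fwd_qual[:-o]
    tail_s, tail_q = rc[o:], rq[o:]
    mid_s, mid_q = [], []
    for k in range(o):
        fb, fq = fwd_seq[len(fwd_seq) - o + k], fwd_qual[len(fwd_qual) - o + k]
        rb, rqk = rc[k], rq[k]
        if fb == rb:
            mid_s.append(fb)
            mid_q.append(max(fq, rqk))
        elif rqk > fq:
            mid_s.append(rb)
            mid_q.append(rqk)
        else:
            mid_s.append(fb)
            mid_q.append(fq)
    return head_s + "".join(mid_s) + tail_s, list(head_q) + mid_q + list(tail_q)


# ---------------------------------------------------------------------------
# FASTQ plumbing and the per-slice funnel


def _open(path: str | Path, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (read_id, sequence, phred_qualities) from Sanger FASTQ."""
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not qual and seq:
                raise MalformedRecordError("truncated FASTQ record")
            if not header.startswith("@") or not plus.startswith("+"):
                raise MalformedRecordError("malformed FASTQ record")
            yield header[1:].strip(), seq, [ord(c) - 33 for c in qual]


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, list[int]]]) -> None:
    path = str(path)
    if path.endswith(".gz"):
        fh = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        import io
        fh = io.TextIOWrapper(fh)
    else:
        fh = open(path, "w")
    with fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


def process_pair(fwd, rev, params: QCParams):
    """QC one mate pair; returns (merged_seq, merged_qual) or (None, reason).

    Order of operations mirrors the pipeline: 3' quality truncation, 5'
    primer removal (forward primer on R1, reverse primer on R2), length and
    N-run filtering of both mates, then merging. A failure in either mate
    rejects the pair.
    """
    (fs, fq), (rs, rq) = fwd, rev
    fs, fq = trim_quality_3prime(fs, fq, params.quality_cutoff)
    rs, rq = trim_quality_3prime(rs, rq, params.quality_cutoff)
    out = remove_primer(fs, fq, params.forward_primer, params.primer_max_mismatch)
    if out is None:
        return None, "primer_fwd"
    fs, fq = out
    out = remove_primer(rs, rq, params.reverse_primer, params.primer_max_mismatch)
    if out is None:
        return None, "primer_rev"
    rs, rq = out
    for s, which in ((fs, "fwd"), (rs, "rev")):
        ok, reason = filter_read(s, params)
        if not ok:
            return None, f"{reason}_{which}"
    merged = merge_pair(fs, fq, rs, rq, params)
    if merged is None:
        return None, "no_overlap"
    return merged, "merged"


def qc_slice(
    fwd_path: str | Path, rev_path: str | Path, params: QCParams, slice_id: str = ""
) -> tuple[list[tuple[str, str]], ReadFunnelStats]:
    """Run the full funnel on one slice's mate files.

    Returns ([(read_id, merged_sequence)], funnel stats). The stats satisfy
    raw >= filtered >= merged.
    """
    stats = ReadFunnelStats(slice_id=slice_id)
    merged_out: list[tuple[str, str]] = []
    for (fid, fs, fq), (_, rs, rq) in zip(read_fastq(fwd_path), read_fastq(rev_path)):
        stats.n_raw_pairs += 1
        result, reason = process_pair((fs, fq), (rs, rq), params)
        if result is None:
            stats.reject_reasons[reason] = stats.reject_reasons.get(reason, 0) + 1
            continue
        # pair survived filtering; did it also merge?
        stats.n_filtered_pairs += 1
        merged_out.append((fid.split()[0], result[0]))
        stats.n_merged += 1
    # pairs that filtered ok but failed merging were counted as rejects above;
    # fold them back into n_filtered_pairs for a faithful funnel
    stats.n_filtered_pairs += stats.reject_reasons.get("no_overlap", 0)
    return merged_out, stats
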