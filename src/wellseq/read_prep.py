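"""Quality filtering, truncation and overlap merging of paired reads.

Paired V4 reads (~250 nt mates over a ~291 bp amplicon) overlap by ~200 nt,
which is what makes high-confidence merging possible for this locus.  Reads
are truncated at the first low-quality base, screened on expected errors
(maxEE), and merged by scanning overlap offsets of R1 against the reverse
complement of R2.

Phred encoding is fixed to Sanger/Illumina 1.8+ (ASCII offset 33).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import revcomp

PHRED_OFFSET = 33

# maxEE-style defaults in the style of common DADA2 practice; all
# configurable at call sites.
DEFAULT_MAX_EE = 2.0
DEFAULT_TRUNC_Q = 2
DEFAULT_MIN_LEN = 50
DEFAULT_MIN_OVERLAP = 12
DEFAULT_MAX_MISMATCH_FRAC = 0.0

#: error probability per Phred score, precomputed for speed
_ERR_PROB = [10.0 ** (-q / 10.0) for q in range(128)]


@dataclass
class ReadPair:
    """One mate pair; quality lists are integer Phred scores."""

    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: list[int]
    rev_qual: list[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise ValueError(f"sequence/quality length mismatch in read {self.id!r}")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: list[int]
    overlap_len: int


def expected_errors(qual) -> float:
    """Sum of per-base error probabilities, EE = sum 10^(-Q/10)."""
    return sum(_ERR_PROB[q] for q in qual)


def _truncate(seq: str, qual: list[int], trunc_q: int) -> tuple[str, list[int]]:
    for i, q in enumerate(qual):
        if q <= trunc_q:
            return seq[:i], qual[:i]
    return seq, qual


def quality_filter(
    pair: ReadPair,
    max_ee: float = DEFAULT_MAX_EE,
    trunc_q: int = DEFAULT_TRUNC_Q,
    min_len: int = DEFAULT_MIN_LEN,
) -> ReadPair | str:
    """Truncate each mate at the first base with Q <= trunc_q and screen.

    Returns the (possibly truncated) pair, or a rejection reason string:
    ``ambiguous`` (an N survives truncation), ``short`` (a mate shorter
    than min_len), or ``max_ee`` (expected errors above the cap).
    """
    fs, fq = _truncate(pair.fwd_seq, pair.fwd_qual, trunc_q)
    rs, rq = _truncate(pair.rev_seq, pair.rev_qual, trunc_q)
    if len(fs) < min_len or len(rs) < min_len:
        return "short"
    if "N" in fs or "N" in rs:
        return "ambiguous"
    if expected_errors(fq) > max_ee or expected_errors(rq) > max_ee:
        return "max_ee"
    return ReadPair(pair.id, fs, rs, fq, rq)


def _merge_at(
    fwd: str,
    fq: list[int],
    rrc: str,
    rq_rc: list[int],
    offset: int,
) -> tuple[str, list[int], int, int]:
    """Merge with revcomp(R2) placed at ``offset`` along R1.

    Returns (seq, qual, overlap_len, n_mismatch).
    """
    ov_start = offset
    ov_end = min(len(fwd), offset + len(rrc))
    overlap = ov_end - ov_start
    seq_parts: list[str] = [fwd[:ov_start]]
    qual: list[int] = fq[:ov_start]
    mism = 0
    for k in range(overlap):
        a, b = fwd[ov_start + k], rrc[k]
        qa, qb = fq[ov_start + k], rq_rc[k]
        if a == b:
            seq_parts.append(a)
            qual.append(max(qa, qb))
        else:
            mism += 1
            if qa >= qb:
                seq_parts.append(a)
                qual.append(qa)
            else:
                seq_parts.append(b)
                qual.append(qb)
    seq_parts.append(rrc[overlap:])
    qual.extend(rq_rc[overlap:])
    return "".join(seq_parts), qual, overlap, mism


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> MergedRead | str:
    """Merge R1 with revcomp(R2) at the offset maximizing matching bases.

    The merged read is reported in R1 orientation; at disagreeing overlap
    positions the higher-Phred base wins, and agreeing positions take the
    larger of the two quality scores.  Returns the reason string
    ``no_overlap`` when no offset reaches ``min_overlap`` matches within
    the mismatch budget.
    """
    fwd, fq = pair.fwd_seq, pair.fwd_qual
    rrc = revcomp(pair.rev_seq)
    rq_rc = pair.rev_qual[::-1]
    max_offset = len(fwd) - min_overlap
    if max_offset < 0:
        return "no_overlap"

    # Fast path: seed the anchor (first min_overlap bases of revcomp(R2))
    # against R1 and check for a mismatch-free overlap at each seed hit.
    # Covers error-free overlaps without scoring every offset.
    anchor = rrc[:min_overlap]
    pos = fwd.find(anchor)
    while 0 <= pos <= max_offset:
        overlap = min(len(fwd), pos + len(rrc)) - pos
        if fwd[pos : pos + overlap] == rrc[:overlap]:
            seq, qual, ov, _ = _merge_at(fwd, fq, rrc, rq_rc, pos)
            return MergedRead(pair.id, seq, qual, ov)
        pos = fwd.find(anchor, pos + 1)

    if max_mismatch_frac <= 0:
        return "no_overlap"

    # Slow path: score every admissible offset by matching bases.
    best: tuple[int, int, int] | None = None  # (matches, -offset, offset)
    for offset in range(0, max_offset + 1):
        overlap = min(len(fwd), offset + len(rrc)) - offset
        if overlap < min_overlap:
            continue
        matches = sum(
            1 for k in range(overlap) if fwd[offset + k] == rrc[k]
        )
        key = (matches, -offset, offset)
        if best is None or key > best:
            best = key
    if best is None:
        return "no_overlap"
    offset = best[2]
    seq, qual, overlap, mism = _merge_at(fwd, fq, rrc, rq_rc, offset)
    if mism / overlap > max_mismatch_frac:
        return "no_overlap"
    return MergedRead(pair.id, seq, qual, overlap)


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, Phred+33, transparent gzip)
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(fwd_path, rev_path) -> Iterator[ReadPair]:
    """Iterate mate pairs from two FASTQ files (plain or gzip)."""
    with _open_text(fwd_path) as fh1, _open_text(rev_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, seq1, q1), (id2, seq2, q2) in zip(it1, it2, strict=True):
            rid = id1.split()[0]
            if rid != id2.split()[0]:
                raise ValueError(f"unpaired reads: {id1!r} vs {id2!r}")
            yield ReadPair(
                rid,
                seq1.upper(),
                seq2.upper(),
                [ord(c) - PHRED_OFFSET for c in q1],
                [ord(c) - PHRED_OFFSET for c in q2],
            )


def write_fastq(records, path) -> None:
    """Write (id, seq, qual-list) records as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            qstr = "".join(chr(q + PHRED_OFFSET) for q in qual)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
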