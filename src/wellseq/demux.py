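"""Assign merged reads to plate wells from their barcode+primer tags.

A merged read carries, in R1 orientation::

    [fwd barcode][515F primer] ... biological V4 ... [revcomp(805R)][revcomp(rev barcode)]

Barcodes (4-6 nt) are matched exactly at the read ends — their edit space
is too small for mismatch tolerance to be safe — while the primer window
behind each candidate barcode tolerates a configurable number of
substitutions (biological primer-site variation).  When barcodes of
different lengths both match, the longer match wins; an exact tie is an
ambiguity and the read is rejected.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from . import read_prep
from ._seq import revcomp
from .plate_scheme import BarcodeScheme, WellID

DEFAULT_MAX_PRIMER_MISMATCH = 2


@dataclass
class WellAssignment:
    plate_id: str
    well: WellID
    biological_seq: str
    provenance: str  # read id


@dataclass
class DemuxStats:
    """Exact partition of the input: assigned + sum(unassigned) == total."""

    total: int = 0
    assigned: int = 0
    unassigned_by_reason: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.total += 1
        self.unassigned_by_reason[reason] += 1

    def accept(self) -> None:
        self.total += 1
        self.assigned += 1

    def balanced(self) -> bool:
        return self.assigned + sum(self.unassigned_by_reason.values()) == self.total


def _primer_matches(seq: str, start: int, primer: str, max_mismatch: int) -> bool:
    end = start + len(primer)
    if end > len(seq):
        return False
    window = seq[start:end]
    if window == primer:
        return True
    mism = 0
    for a, b in zip(window, primer):
        if a != b:
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def match_tagged_end(
    seq: str,
    barcodes,
    primer: str,
    max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH,
) -> tuple[int, int] | str | None:
    """Find which barcode+primer tag starts ``seq``.

    Returns (barcode index, trim offset just past the primer), or None if
    no barcode matches, or the string ``"ambiguous"`` when two barcodes of
    equal length both match (a longer barcode beats a shorter prefix of
    itself).
    """
    hits: list[tuple[int, int]] = []  # (barcode length, index)
    for i, b in enumerate(barcodes):
        if seq.startswith(b) and _primer_matches(
            seq, len(b), primer, max_primer_mismatch
        ):
            hits.append((len(b), i))
    if not hits:
        return None
    hits.sort(reverse=True)
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return "ambiguous"
    blen, idx = hits[0]
    return idx, blen + len(primer)


def assign_read(
    merged: read_prep.MergedRead,
    scheme: BarcodeScheme,
    max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH,
) -> WellAssignment | str:
    """Assign one merged read to a well, or return a rejection reason
    (``no_forward``, ``no_reverse``, ``ambiguous``).

    The forward tag is sought at the 5' end; the reverse tag is sought at
    the 3' end as the reverse complement of barcode+primer (equivalently,
    at the 5' end of the reverse-complemented read).
    """
    seq = merged.seq
    f = match_tagged_end(
        seq, scheme.forward_barcodes, scheme.forward_primer, max_primer_mismatch
    )
    if f is None:
        return "no_forward"
    if f == "ambiguous":
        return "ambiguous"
    r = match_tagged_end(
        revcomp(seq), scheme.reverse_barcodes, scheme.reverse_primer,
        max_primer_mismatch,
    )
    if r is None:
        return "no_reverse"
    if r == "ambiguous":
        return "ambiguous"
    f_idx, f_trim = f
    r_idx, r_trim = r
    biological = seq[f_trim : len(seq) - r_trim]
    if not biological:
        return "no_insert"
    return WellAssignment(
        plate_id=scheme.plate_id,
        well=scheme.well_for(f_idx, r_idx),
        biological_seq=biological,
        provenance=merged.id,
    )


def demultiplex_plate(
    fwd_fastq,
    rev_fastq,
    scheme: BarcodeScheme,
    max_ee: float = read_prep.DEFAULT_MAX_EE,
    trunc_q: int = read_prep.DEFAULT_TRUNC_Q,
    min_len: int = read_prep.DEFAULT_MIN_LEN,
    min_overlap: int = read_prep.DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = read_prep.DEFAULT_MAX_MISMATCH_FRAC,
    max_primer_mismatch: int = DEFAULT_MAX_PRIMER_MISMATCH,
) -> tuple[dict[WellID, list[str]], DemuxStats]:
    """Run filter -> merge -> well assignment over one plate's FASTQ pair.

    Returns per-well lists of biological sequences (technical tags
    trimmed) plus exact partition statistics over all input pairs.
    """
    wells: dict[WellID, list[str]] = defaultdict(list)
    stats = DemuxStats()
    for pair in read_prep.read_fastq_pairs(fwd_fastq, rev_fastq):
        filtered = read_prep.quality_filter(pair, max_ee, trunc_q, min_len)
        if isinstance(filtered, str):
            stats.reject(f"filter_{filtered}")
            continue
        merged = read_prep.merge_pair(filtered, min_overlap, max_mismatch_frac)
        if isinstance(merged, str):
            stats.reject(f"merge_{merged}")
            continue
        assigned = assign_read(merged, scheme, max_primer_mismatch)
        if isinstance(assigned, str):
            stats.reject(assigned)
            continue
        stats.accept()
        wells[assigned.well].append(assigned.biological_seq)
    return dict(wells), stats
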