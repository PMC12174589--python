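"""Combinatorial barcode scheme for 96-well culture plates.

Each well of a 96-well plate receives a unique (forward, reverse) primer
pair: 12 barcoded forward primers index the plate columns and 8 barcoded
reverse primers index the rows, so the 12 x 8 combinations cover all 96
wells.  Barcodes are short (4-6 nt) tags sitting between the sequencing
adaptor tail and the V4 515F/805R primer binding sites.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import edlib

from ._seq import is_dna

logger = logging.getLogger(__name__)

N_FORWARD = 12
N_REVERSE = 8
ROW_LETTERS = "ABCDEFGH"
BARCODE_MIN_LEN = 4
BARCODE_MAX_LEN = 6

#: Minimum within-direction barcode edit distance below which a warning is
#: logged (wet-lab designs are fixed, so low distance is not an error).
MIN_DISTANCE_WARN = 2


class SchemeError(ValueError):
    """Raised when a barcode scheme violates the plate design invariants."""


@dataclass(frozen=True, order=True)
class WellID:
    """A 96-well coordinate such as G2 (row letter A-H, column 1-12)."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise ValueError(f"row must be one of {ROW_LETTERS}: {self.row!r}")
        if not 1 <= self.column <= 12:
            raise ValueError(f"column must be 1-12: {self.column}")

    def __str__(self) -> str:
        return f"{self.row}{self.column}"

    @classmethod
    def parse(cls, label: str) -> "WellID":
        """Parse a label like ``G2`` back into a WellID."""
        if len(label) < 2:
            raise ValueError(f"not a well label: {label!r}")
        return cls(row=label[0], column=int(label[1:]))


@dataclass(frozen=True)
class BarcodeScheme:
    """A validated 12 forward x 8 reverse combinatorial barcode design.

    ``well_map`` is a bijection from 0-based (forward index, reverse index)
    pairs to the 96 wells: forward index i -> column i+1, reverse index
    j -> row letter ``ROW_LETTERS[j]``.
    """

    plate_id: str
    forward_barcodes: tuple[str, ...]
    reverse_barcodes: tuple[str, ...]
    forward_primer: str
    reverse_primer: str
    well_map: dict[tuple[int, int], WellID] = field(repr=False)

    def well_for(self, f_index: int, r_index: int) -> WellID:
        return self.well_map[(f_index, r_index)]


def _validate_barcodes(barcodes, expected_n: int, direction: str) -> tuple[str, ...]:
    barcodes = tuple(barcodes)
    if len(barcodes) != expected_n:
        raise SchemeError(
            f"expected {expected_n} {direction} barcodes, got {len(barcodes)}"
        )
    for b in barcodes:
        if not BARCODE_MIN_LEN <= len(b) <= BARCODE_MAX_LEN:
            raise SchemeError(
                f"{direction} barcode {b!r} length {len(b)} outside "
                f"{BARCODE_MIN_LEN}-{BARCODE_MAX_LEN}"
            )
        if not is_dna(b):
            raise SchemeError(f"{direction} barcode {b!r} is not uppercase ACGT")
    if len(set(barcodes)) != len(barcodes):
        raise SchemeError(f"duplicate barcode within {direction} direction")
    return barcodes


def build_scheme(
    forward_barcodes,
    reverse_barcodes,
    forward_primer: str,
    reverse_primer: str,
    plate_id: str = "plate",
) -> BarcodeScheme:
    """Build and validate a scheme; forward barcodes map to columns 1-12,
    reverse barcodes to rows A-H.
    """
    fwd = _validate_barcodes(forward_barcodes, N_FORWARD, "forward")
    rev = _validate_barcodes(reverse_barcodes, N_REVERSE, "reverse")
    for name, primer in (("forward", forward_primer), ("reverse", reverse_primer)):
        if not is_dna(primer):
            raise SchemeError(f"{name} primer is not uppercase ACGT: {primer!r}")
    well_map = {
        (i, j): WellID(row=ROW_LETTERS[j], column=i + 1)
        for i in range(N_FORWARD)
        for j in range(N_REVERSE)
    }
    scheme = BarcodeScheme(
        plate_id=plate_id,
        forward_barcodes=fwd,
        reverse_barcodes=rev,
        forward_primer=forward_primer,
        reverse_primer=reverse_primer,
        well_map=well_map,
    )
    d = scheme_min_distance(scheme)
    if d < MIN_DISTANCE_WARN:
        logger.warning(
            "scheme %s: minimum within-direction barcode edit distance is %d; "
            "single errors may be uncorrectable",
            plate_id,
            d,
        )
    return scheme


def scheme_min_distance(scheme: BarcodeScheme) -> int:
    """Minimum pairwise edit distance among barcodes within each direction
    (minimum over both directions).  A QC statistic, not a hard constraint.
    """
    best = None
    for barcodes in (scheme.forward_barcodes, scheme.reverse_barcodes):
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                d = edlib.align(a, b, task="distance")["editDistance"]
                if best is None or d < best:
                    best = d
    if best is None:  # unreachable for a valid 12x8 scheme
        raise SchemeError("scheme has no barcode pairs")
    return best


def load_scheme(path, plate_id: str = "plate") -> BarcodeScheme:
    """Load a scheme from a TSV with columns direction (F/R), index
    (1-based), barcode, primer.
    """
    fwd: dict[int, str] = {}
    rev: dict[int, str] = {}
    primers: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"direction", "index", "barcode", "primer"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SchemeError(
                f"scheme file must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            direction = row["direction"].strip().upper()
            if direction not in ("F", "R"):
                raise SchemeError(f"direction must be F or R: {row['direction']!r}")
            idx = int(row["index"])
            target = fwd if direction == "F" else rev
            if idx in target:
                raise SchemeError(f"duplicate {direction} index {idx}")
            target[idx] = row["barcode"].strip()
            primer = row["primer"].strip()
            if primer:
                prev = primers.setdefault(direction, primer)
                if prev != primer:
                    raise SchemeError(f"conflicting {direction} primers")
    if sorted(fwd) != list(range(1, N_FORWARD + 1)):
        raise SchemeError(f"forward indices must be 1..{N_FORWARD}, got {sorted(fwd)}")
    if sorted(rev) != list(range(1, N_REVERSE + 1)):
        raise SchemeError(f"reverse indices must be 1..{N_REVERSE}, got {sorted(rev)}")
    if "F" not in primers or "R" not in primers:
        raise SchemeError("scheme file must give a primer for each direction")
    return build_scheme(
        [fwd[i] for i in range(1, N_FORWARD + 1)],
        [rev[i] for i in range(1, N_REVERSE + 1)],
        primers["F"],
        primers["R"],
        plate_id=plate_id,
    )


def write_scheme(scheme: BarcodeScheme, path) -> None:
    """Write a scheme as the TSV dialect read by :func:`load_scheme`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["direction", "index", "barcode", "primer"])
        for i, b in enumerate(scheme.forward_barcodes, start=1):
            writer.writerow(["F", i, b, scheme.forward_primer])
        for j, b in enumerate(scheme.reverse_barcodes, start=1):
            writer.writerow(["R", j, b, scheme.reverse_primer])
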