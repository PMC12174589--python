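"""Per-well ASV counting, purity, hit ranking and isolate pick lists.

Purity is the percentage of a well's reads that belong to one ASV — the
higher it is, the closer that well's culture is to clonal and the better a
candidate it is for streak-plate recovery.  The identification report lists,
for every ASV, the top *n* wells ranked by read count, each cell formatted
as ``plateID_wellID | count | purity``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .plate_scheme import WellID

DEFAULT_TOP_N = 3
DEFAULT_MIN_PURITY = 20.0
DEFAULT_MIN_READS = 60

RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")


def purity(asv_count: int, well_total: int) -> float:
    """Percentage of the well's reads belonging to the ASV.

    Rounded half-up to two decimals; NaN when the well is empty
    (well_total == 0), distinguishing "no data" from a true 0%.
    """
    if asv_count < 0 or well_total < 0:
        raise ValueError("counts must be non-negative")
    if asv_count > well_total:
        raise ValueError(f"asv_count {asv_count} exceeds well_total {well_total}")
    if well_total == 0:
        return math.nan
    exact = Decimal(100 * asv_count) / Decimal(well_total)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_purity(value: float) -> str:
    """Render purity the way the report prints it: two decimals with
    trailing zeros stripped ("97.05", "49.5", "100"), "NaN" if undefined.
    """
    if math.isnan(value):
        return "NaN"
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return text if text else "0"


@dataclass(frozen=True)
class WellHit:
    plate_id: str
    well: WellID
    count: int
    purity: float  # percentage, NaN when the well is empty

    def cell(self) -> str:
        return f"{self.plate_id}_{self.well} | {self.count} | {format_purity(self.purity)}"


@dataclass
class AsvWellTable:
    """Counts of each ASV in each (plate, well); the report's substrate.

    ``counts`` is indexed by asv_id with a (plate, well-label) column
    MultiIndex.  Wells with zero reads are kept as all-zero columns so that
    report filler cells can distinguish empty wells (purity NaN) from
    occupied wells lacking the ASV (purity 0).
    """

    counts: pd.DataFrame
    sequences: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_well_sequences(
        cls,
        plate_wells: dict[str, dict[WellID, list[str]]],
        seq_to_asv: dict[str, int],
        asv_seqs: dict[int, str],
        all_wells: list[WellID] | None = None,
    ) -> "AsvWellTable":
        """Tabulate denoised per-well sequences into ASV x well counts.

        ``all_wells`` (e.g. the scheme's 96 wells) forces empty wells to
        appear as zero columns for every plate.
        """
        columns: list[tuple[str, str]] = []
        for plate, wells in plate_wells.items():
            universe = all_wells if all_wells is not None else sorted(wells)
            columns.extend((plate, str(w)) for w in sorted(universe))
        ids = sorted(asv_seqs)
        counts = pd.DataFrame(
            0, index=ids, columns=pd.MultiIndex.from_tuples(columns or [("", "")])
        )
        if not columns:
            counts = counts.iloc[:, :0]
        for plate, wells in plate_wells.items():
            for well, seqs in wells.items():
                for s in seqs:
                    asv = seq_to_asv.get(s)
                    if asv is not None:
                        counts.loc[asv, (plate, str(well))] += 1
        counts.index.name = "asv_id"
        return cls(counts=counts, sequences=dict(asv_seqs))

    def well_total(self, plate_id: str, well: WellID | str) -> int:
        return int(self.counts[(plate_id, str(well))].sum())

    def asv_ids(self) -> list[int]:
        return list(self.counts.index)

    def to_long(self) -> pd.DataFrame:
        """Machine-friendly long format: asv, plate, well, count, purity."""
        totals = self.counts.sum(axis=0)
        rows = []
        for asv in self.counts.index:
            for (plate, well), count in self.counts.loc[asv].items():
                rows.append(
                    {
                        "asv": asv,
                        "plate": plate,
                        "well": well,
                        "count": int(count),
                        "purity": purity(int(count), int(totals[(plate, well)])),
                    }
                )
        return pd.DataFrame(rows)


def _hit_sort_key(hit: WellHit):
    # count desc, purity desc (zero-count wells rank equal: lexicographic
    # plate/well order decides, which is what the report's fillers show),
    p = hit.purity if hit.count > 0 and not math.isnan(hit.purity) else 0.0
    return (-hit.count, -p, hit.plate_id, hit.well)


def top_hits(asv_id: int, table: AsvWellTable, n: int = DEFAULT_TOP_N) -> list[WellHit]:
    """The top n wells for one ASV, ranked by count then purity.

    Padded with zero-count wells (in plate/well order) when the ASV occurs
    in fewer than n wells; filler purity is NaN for empty wells and 0 for
    occupied wells lacking the ASV.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if asv_id not in table.counts.index:
        raise KeyError(f"unknown asv_id {asv_id}")
    totals = table.counts.sum(axis=0)
    row = table.counts.loc[asv_id]
    hits = [
        WellHit(
            plate_id=plate,
            well=WellID.parse(well),
            count=int(count),
            purity=purity(int(count), int(totals[(plate, well)])),
        )
        for (plate, well), count in row.items()
    ]
    hits.sort(key=_hit_sort_key)
    return hits[:n]


def write_report(
    asvs: dict[int, str],
    table: AsvWellTable,
    taxonomy: dict[int, dict[str, str]] | None,
    n: int = DEFAULT_TOP_N,
    path=None,
) -> pd.DataFrame:
    """Write the identification report CSV; returns it as a DataFrame.

    Columns: ASV, Sequence, the six ranks, then top_count_1..top_count_n
    with cells like ``plate1_G2 | 1446 | 97.05``.
    """
    rows = []
    for asv_id in sorted(asvs):
        lineage = (taxonomy or {}).get(asv_id, {})
        row = {"ASV": asv_id, "Sequence": asvs[asv_id]}
        for rank in RANKS:
            row[rank] = lineage.get(rank, "")
        for i, hit in enumerate(top_hits(asv_id, table, n), start=1):
            row[f"top_count_{i}"] = hit.cell()
        rows.append(row)
    columns = ["ASV", "Sequence", *RANKS, *(f"top_count_{i}" for i in range(1, n + 1))]
    report = pd.DataFrame(rows, columns=columns)
    if path is not None:
        report.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
    return report


def select_recoverable(
    asvs,
    table: AsvWellTable,
    min_purity: float = DEFAULT_MIN_PURITY,
    min_reads: int = DEFAULT_MIN_READS,
) -> dict[int, WellHit]:
    """Pick list for isolate recovery: an ASV qualifies when any well holds
    >= min_reads of it at >= min_purity percent purity (both inclusive);
    the best such well in top-hit order is reported.
    """
    picks: dict[int, WellHit] = {}
    for asv_id in asvs:
        for hit in top_hits(asv_id, table, n=len(table.counts.columns) or 1):
            if (
                hit.count >= min_reads
                and not math.isnan(hit.purity)
                and hit.purity >= min_purity
            ):
                picks[asv_id] = hit
                break
    return picks
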