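"""Community-side analyses: rarefaction, core ASVs, isolate matching.

The community table holds amplicon counts of root-slurry samples (rows)
by ASV (columns), with a host label (e.g. pea or corn) per sample.  Core
membership and isolate categories are always computed within one host
group, since the stable microbiome differs between crops.

Two related "core" definitions coexist and are deliberately kept separate:
community core ASVs use a 70% prevalence threshold, while isolate
categorization calls an isolate a core member at 80% prevalence; both use
a 0.1% relative-abundance detection limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from ._seq import hamming

logger = logging.getLogger(__name__)

RAREFACTION_DEPTH = 13027
CORE_PREVALENCE = 0.70
CORE_DETECTION = 0.001
ISOLATE_CORE_PREVALENCE = 0.80
ISOLATE_CORE_ABUNDANCE = 0.001


class Category(str, Enum):
    CORE = "core"
    TOP50 = "top50"
    RARE = "rare"
    UNMATCHED = "unmatched"


@dataclass
class CommunityTable:
    """Sample x ASV counts plus per-sample host labels."""

    counts: pd.DataFrame  # rows: samples, columns: ASV ids or sequences
    host: pd.Series | None = None  # sample -> host label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.host is not None:
            self.host = self.host.reindex(self.counts.index)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_host(self, host: str) -> "CommunityTable":
        if self.host is None:
            raise ValueError("table has no host metadata")
        keep = self.host[self.host == host].index
        if len(keep) == 0:
            raise ValueError(f"no samples for host {host!r}")
        return CommunityTable(self.counts.loc[keep], self.host.loc[keep])

    def relative(self) -> pd.DataFrame:
        depths = self.depths()
        return self.counts.div(depths.replace(0, np.nan), axis=0).fillna(0.0)


@dataclass
class IsolateRecord:
    isolate_id: str
    seq: str
    matched_asv: str | None = None
    category: Category | None = None
    ambiguous: bool = False


def rarefy(
    table: CommunityTable, depth: int = RAREFACTION_DEPTH, seed: int = 0
) -> CommunityTable:
    """Subsample every sample without replacement to exactly ``depth``
    reads (multivariate hypergeometric); shallower samples are dropped.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    depths = table.depths()
    keep = depths[depths >= depth].index
    dropped = set(table.counts.index) - set(keep)
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d", len(dropped), depth)
    rows = {}
    for sample in keep:
        counts = table.counts.loc[sample].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows[sample] = counts
        else:
            rows[sample] = rng.multivariate_hypergeometric(counts, depth)
    new_counts = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    new_counts.columns = table.counts.columns
    host = table.host.loc[keep] if table.host is not None else None
    return CommunityTable(new_counts, host)


def core_asvs(
    table: CommunityTable,
    prevalence_min: float = CORE_PREVALENCE,
    detection: float = CORE_DETECTION,
) -> set:
    """ASVs present (rel. abundance >= detection) in at least
    ``prevalence_min`` of the table's samples.  Call on one host group
    (see :meth:`CommunityTable.subset_host`).
    """
    if len(table.counts) == 0:
        raise ValueError("empty sample group")
    rel = table.relative()
    prevalence = (rel >= detection).mean(axis=0)
    return set(prevalence.index[prevalence >= prevalence_min])


def core_asvs_by_host(table: CommunityTable, **kwargs) -> dict[str, set]:
    if table.host is None:
        raise ValueError("table has no host metadata")
    return {
        h: core_asvs(table.subset_host(h), **kwargs)
        for h in sorted(table.host.dropna().unique())
    }


def match_isolates(
    isolates: dict[str, str],
    table: CommunityTable,
    max_mismatch: int = 0,
) -> list[IsolateRecord]:
    """Match each isolate's V4 sequence to a community ASV.

    Exact string identity by default (ASVs are the unit of identity); with
    ``max_mismatch`` > 0 the unique nearest equal-length ASV within that
    many substitutions is accepted, and distance ties are reported as
    unmatched-ambiguous.
    """
    community = [str(c) for c in table.counts.columns]
    records = []
    for iso_id, seq in sorted(isolates.items()):
        rec = IsolateRecord(isolate_id=iso_id, seq=seq)
        if seq in community:
            rec.matched_asv = seq
        elif max_mismatch > 0:
            best_d, best_asvs = None, []
            for asv in community:
                if len(asv) != len(seq):
                    continue
                d = hamming(seq, asv)
                if d > max_mismatch:
                    continue
                if best_d is None or d < best_d:
                    best_d, best_asvs = d, [asv]
                elif d == best_d:
                    best_asvs.append(asv)
            if len(best_asvs) == 1:
                rec.matched_asv = best_asvs[0]
            elif len(best_asvs) > 1:
                rec.ambiguous = True
        records.append(rec)
    return records


def categorize_isolates(
    records: list[IsolateRecord],
    table: CommunityTable,
    prevalence_min: float = ISOLATE_CORE_PREVALENCE,
    abundance_min: float = ISOLATE_CORE_ABUNDANCE,
    detection: float = CORE_DETECTION,
) -> list[IsolateRecord]:
    """Assign each matched isolate a category within its host community.

    core: prevalence >= 80% of samples (at the detection limit) and mean
    relative abundance > 0.1%; otherwise top50 when the ASV's total
    relative abundance ranks in the upper half (median rank inclusive);
    otherwise rare.  Unmatched isolates stay unmatched.  The three matched
    categories partition the matched records.
    """
    rel = table.relative()
    prevalence = (rel >= detection).mean(axis=0)
    mean_rel = rel.mean(axis=0)
    total_rel = rel.sum(axis=0)
    # rank 1 = most abundant; upper half inclusive of the median position
    ranks = total_rel.rank(ascending=False, method="min")
    half = np.ceil(len(ranks) / 2)
    for rec in records:
        if rec.matched_asv is None:
            rec.category = Category.UNMATCHED
            continue
        asv = rec.matched_asv
        if prevalence[asv] >= prevalence_min and mean_rel[asv] > abundance_min:
            rec.category = Category.CORE
        elif ranks[asv] <= half:
            rec.category = Category.TOP50
        else:
            rec.category = Category.RARE
    return records


def write_isolate_table(records: list[IsolateRecord], path) -> pd.DataFrame:
    """Isolate summary TSV: isolate, sequence, matched ASV, category."""
    df = pd.DataFrame(
        {
            "isolate": [r.isolate_id for r in records],
            "sequence": [r.seq for r in records],
            "matched_asv": [r.matched_asv or "" for r in records],
            "category": [r.category.value if r.category else "" for r in records],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
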