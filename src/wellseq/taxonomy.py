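"""RDP-style naive Bayes taxonomy assignment with bootstrap confidence.

Reference sequences carry six-rank lineages (Kingdom..Genus).  Training
tallies, for each genus, which 8-mers occur in its sequences, smoothed as

    P(w | g) = (count(w, g) + 0.5) / (N_g + 1)

where N_g is the number of reference sequences in genus g.  A query is
assigned to the genus maximizing the sum of log P(w|g) over its *distinct*
k-mers.  Confidence comes from bootstrapping: each replicate redraws
ceil(m/8) of the m distinct k-mers with replacement and re-classifies; the
per-rank confidence is the percentage of replicates agreeing with the full
call at that rank.  Ranks below the confidence cutoff are blanked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .wellcall import RANKS

DEFAULT_K = 8
DEFAULT_N_BOOTSTRAP = 100
DEFAULT_CONF_CUTOFF = 50
DEFAULT_SEED = 1


@dataclass(frozen=True)
class RefRecord:
    seq: str
    lineage: tuple[str, ...]  # Kingdom..Genus, may be truncated


@dataclass
class ReferenceDB:
    records: list[RefRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference database is empty")


@dataclass
class Classification:
    """Per-rank labels with bootstrap confidences; sub-cutoff labels blank."""

    labels: dict[str, str]
    confidence: dict[str, int]

    def lineage(self) -> tuple[str, ...]:
        return tuple(self.labels[r] for r in RANKS)


def load_reference(path) -> ReferenceDB:
    """Read a FASTA whose headers are ';'-delimited lineages
    (``Kingdom;Phylum;Class;Order;Family;Genus;`` — trailing ';' tolerated).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        ranks = tuple(p.strip() for p in header.rstrip(";").split(";"))
        if len(ranks) > len(RANKS):
            ranks = ranks[: len(RANKS)]
        records.append(RefRecord(seq=str(rec.seq).upper(), lineage=ranks))
    return ReferenceDB(records)


@dataclass
class NaiveBayesClassifier:
    k: int
    genera: list[str]  # class labels (genus names)
    lineages: dict[str, tuple[str, ...]]  # genus -> full lineage
    log_p: dict[str, dict[str, float]]  # genus -> kmer -> log P(w|g)
    log_p_absent: dict[str, float]  # genus -> log of the smoothing floor
    log_prior: dict[str, float] = field(default_factory=dict)

    def _score(self, kmers: list[str]) -> str:
        best_genus, best = None, -math.inf
        for g in self.genera:
            table = self.log_p[g]
            floor = self.log_p_absent[g]
            score = sum(table.get(w, floor) for w in kmers)
            if score > best:
                best_genus, best = g, score
        assert best_genus is not None
        return best_genus


def _kmers(seq: str, k: int) -> list[str]:
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    return sorted({seq[i : i + k] for i in range(len(seq) - k + 1)})


def train_classifier(ref: ReferenceDB, k: int = DEFAULT_K) -> NaiveBayesClassifier:
    """Fit smoothed per-genus k-mer presence probabilities and priors."""
    by_genus: dict[str, list[RefRecord]] = {}
    for rec in ref.records:
        genus = rec.lineage[-1]
        by_genus.setdefault(genus, []).append(rec)
    lineages: dict[str, tuple[str, ...]] = {}
    log_p: dict[str, dict[str, float]] = {}
    log_p_absent: dict[str, float] = {}
    log_prior: dict[str, float] = {}
    total = len(ref.records)
    for genus, recs in by_genus.items():
        lineage = recs[0].lineage
        padded = lineage + ("",) * (len(RANKS) - len(lineage))
        lineages[genus] = padded
        n_g = len(recs)
        counts: dict[str, int] = {}
        for rec in recs:
            for w in _kmers(rec.seq, k):
                counts[w] = counts.get(w, 0) + 1
        log_p[genus] = {
            w: math.log((c + 0.5) / (n_g + 1.0)) for w, c in counts.items()
        }
        log_p_absent[genus] = math.log(0.5 / (n_g + 1.0))
        log_prior[genus] = math.log(n_g / total)
    return NaiveBayesClassifier(
        k=k,
        genera=sorted(by_genus),
        lineages=lineages,
        log_p=log_p,
        log_p_absent=log_p_absent,
        log_prior=log_prior,
    )


def classify(
    seq: str,
    model: NaiveBayesClassifier,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    conf_cutoff: int = DEFAULT_CONF_CUTOFF,
    seed: int = DEFAULT_SEED,
) -> Classification:
    """Classify one sequence; bootstrap subsampling is seeded (logged runs
    are exactly reproducible).
    """
    kmers = _kmers(seq.upper(), model.k)
    m = len(kmers)
    full_genus = model._score(kmers)
    full_lineage = model.lineages[full_genus]

    rng = np.random.default_rng(seed)
    n_draw = math.ceil(m / 8)
    agree = np.zeros(len(RANKS), dtype=int)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, m, size=n_draw)
        boot_genus = model._score([kmers[i] for i in idx])
        boot_lineage = model.lineages[boot_genus]
        for r in range(len(RANKS)):
            if boot_lineage[r] and boot_lineage[r] == full_lineage[r]:
                agree[r] += 1

    labels: dict[str, str] = {}
    confidence: dict[str, int] = {}
    for r, rank in enumerate(RANKS):
        conf = round(100 * agree[r] / n_bootstrap)
        confidence[rank] = conf
        labels[rank] = full_lineage[r] if conf >= conf_cutoff else ""
    return Classification(labels=labels, confidence=confidence)
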