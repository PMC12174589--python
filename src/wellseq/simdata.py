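"""Synthetic plates, reads and community tables with known ground truth.

Everything downstream is testable against the truth these generators
record: simulated plate reads carry a manifest naming each read's true
well and taxon, and simulated communities record which ASVs were planted
as core members.  The read simulator reproduces the library structure of
barcoded two-step PCR: each read is

    [fwd barcode][515F primer][V4 amplicon][revcomp(805R)][revcomp(rev barcode)]

split into overlapping mates, with substitution errors only (no indels —
tag matching is substitution-tolerant, so indel-bearing tags are expected
to be rejected, and that rejection is itself a tested behaviour).  Base
qualities are drawn consistent with the substitution rate, Q = -10 log10(rate),
so expected-error filtering behaves realistically.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .ecology import CommunityTable
from .plate_scheme import BarcodeScheme, WellID
from .read_prep import write_fastq
from .wellcall import RANKS

DEFAULT_AMPLICON_LEN = 291  # V4 515F/805R product
DEFAULT_MATE_LEN = 250
MIN_PAIRWISE_DIST = 10
_BASES = "ACGT"


@dataclass(frozen=True)
class Amplicon:
    name: str
    seq: str
    lineage: tuple[str, ...]  # Kingdom..Genus


def simulate_amplicons(
    n_taxa: int,
    length: int = DEFAULT_AMPLICON_LEN,
    seed: int = 0,
    min_dist: int = MIN_PAIRWISE_DIST,
) -> list[Amplicon]:
    """Random amplicons with pairwise Hamming distance >= min_dist
    (rejection sampling), each tagged with a toy six-rank lineage.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    attempts = 0
    while len(seqs) < n_taxa:
        attempts += 1
        if attempts > 1000 * n_taxa:
            raise ValueError(
                f"cannot place {n_taxa} sequences of length {length} at "
                f"pairwise distance >= {min_dist}"
            )
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(
            sum(a != b for a, b in zip(cand, s)) >= min_dist for s in seqs
        ):
            seqs.append(cand)
    return [
        Amplicon(
            name=f"taxon{i + 1}",
            seq=s,
            lineage=(
                "Bacteria",
                f"Phylum{i % 3 + 1}",
                f"Class{i % 3 + 1}",
                f"Order{i % 5 + 1}",
                f"Family{i % 7 + 1}",
                f"Genus{i + 1}",
            ),
        )
        for i, s in enumerate(seqs)
    ]


def write_reference_fasta(amplicons: list[Amplicon], path) -> None:
    """Toy taxonomy reference: ';'-delimited lineage headers."""
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(">" + ";".join(a.lineage) + ";\n" + a.seq + "\n")


@dataclass
class PlateTruth:
    """Ground truth for one simulated plate.

    ``composition`` maps each occupied well to (taxon name, proportion)
    pairs summing to 1; unlisted wells stay empty, as in a
    dilution-to-extinction plate where most wells never grow.
    """

    scheme: BarcodeScheme
    taxa: dict[str, str]  # taxon name -> amplicon sequence
    composition: dict[WellID, list[tuple[str, float]]]
    reads_per_well: int = 500
    error_rate: float = 0.0
    mate_len: int = DEFAULT_MATE_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        for well, comp in self.composition.items():
            total = sum(p for _, p in comp)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions in well {well} sum to {total}")
            for name, _ in comp:
                if name not in self.taxa:
                    raise ValueError(f"unknown taxon {name!r} in well {well}")


@dataclass
class ManifestEntry:
    read_id: str
    plate_id: str
    well: WellID
    taxon: str


def _quality_for_rate(rate: float) -> int:
    if rate <= 0:
        return 40
    return max(2, min(40, round(-10.0 * math.log10(rate))))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _BASES[(_BASES.index(arr[i]) + rng.integers(1, 4)) % 4]
    return "".join(arr)


def _exact_counts(comp: list[tuple[str, float]], n: int) -> list[tuple[str, int]]:
    """Largest-remainder apportionment of n reads to proportions."""
    raw = [(name, p * n) for name, p in comp]
    counts = {name: int(x) for name, x in raw}
    short = n - sum(counts.values())
    for name, _ in sorted(raw, key=lambda t: -(t[1] - int(t[1])))[:short]:
        counts[name] += 1
    return [(name, c) for name, c in counts.items() if c > 0]


def simulate_plate(
    truth: PlateTruth,
    fwd_path,
    rev_path,
    manifest_path=None,
    exact_proportions: bool = False,
) -> list[ManifestEntry]:
    """Write a paired FASTQ for one plate and return its manifest.

    With ``exact_proportions`` each well's taxon counts are apportioned
    deterministically (largest remainder); otherwise they are multinomial
    draws, which is what real wells look like.
    """
    rng = np.random.default_rng(truth.seed)
    scheme = truth.scheme
    q = _quality_for_rate(truth.error_rate)
    well_of = {v: k for k, v in scheme.well_map.items()}
    fwd_records, rev_records, manifest = [], [], []
    serial = 0
    for well in sorted(truth.composition):
        comp = truth.composition[well]
        f_idx, r_idx = well_of[well]
        fb = scheme.forward_barcodes[f_idx]
        rb = scheme.reverse_barcodes[r_idx]
        if exact_proportions:
            taxon_counts = _exact_counts(comp, truth.reads_per_well)
        else:
            draws = rng.multinomial(
                truth.reads_per_well, [p for _, p in comp]
            )
            taxon_counts = [
                (name, int(c)) for (name, _), c in zip(comp, draws) if c > 0
            ]
        for taxon, n_reads in taxon_counts:
            amplicon = truth.taxa[taxon]
            full = (
                fb
                + scheme.forward_primer
                + amplicon
                + revcomp(scheme.reverse_primer)
                + revcomp(rb)
            )
            if truth.mate_len > len(full):
                raise ValueError(
                    f"mate_len {truth.mate_len} exceeds construct length {len(full)}"
                )
            r1_t = full[: truth.mate_len]
            r2_t = revcomp(full)[: truth.mate_len]
            for _ in range(n_reads):
                serial += 1
                rid = f"{scheme.plate_id}:{serial:07d}"
                r1 = _mutate(r1_t, truth.error_rate, rng)
                r2 = _mutate(r2_t, truth.error_rate, rng)
                fwd_records.append((rid, r1, [q] * len(r1)))
                rev_records.append((rid, r2, [q] * len(r2)))
                manifest.append(
                    ManifestEntry(rid, scheme.plate_id, well, taxon)
                )
    write_fastq(fwd_records, fwd_path)
    write_fastq(rev_records, rev_path)
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["read_id", "plate", "well", "taxon"])
            for m in manifest:
                w.writerow([m.read_id, m.plate_id, str(m.well), m.taxon])
    return manifest


# ---------------------------------------------------------------------------
# Community tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCore:
    """A core ASV planted with the given per-sample occurrence probability
    and relative abundance (defaults comfortably above the 70%/0.1%
    community-core thresholds)."""

    prevalence: float = 1.0
    rel_abundance: float = 0.01


@dataclass
class CommunityTruth:
    core_asvs: set[str] = field(default_factory=set)
    sequences: dict[str, str] = field(default_factory=dict)  # column -> seq


def simulate_community(
    n_samples: int,
    n_asvs: int,
    core_spec: list[PlantedCore] | None = None,
    depth_range: tuple[int, int] = (15000, 25000),
    seed: int = 0,
    host: str = "pea",
    overdispersion: float = 0.0,
    amplicon_len: int = 60,
) -> tuple[CommunityTable, CommunityTruth]:
    """Dirichlet-multinomial community with planted core ASVs.

    Planted cores occur in every sample selected by their prevalence at
    their stated relative abundance; background ASVs are confined to at
    most half the samples so they can never cross a >=70% prevalence
    threshold — the truth's core set is therefore exact by construction.
    ``overdispersion`` = 0 gives plain multinomial sampling of the base
    proportions; larger values add Dirichlet noise between samples.
    """
    core_spec = list(core_spec or [])
    n_core = len(core_spec)
    if n_core > n_asvs:
        raise ValueError("more planted cores than ASVs")
    rng = np.random.default_rng(seed)
    amplicons = simulate_amplicons(n_asvs, length=amplicon_len, seed=seed)
    seqs = [a.seq for a in amplicons]
    core_cols = seqs[:n_core]
    bg_cols = seqs[n_core:]

    core_mass = sum(c.rel_abundance for c in core_spec)
    if core_mass >= 1.0:
        raise ValueError("planted core abundances must sum below 1")
    bg_base = (1.0 - core_mass) / max(len(bg_cols), 1)

    # background ASVs restricted to <= half the samples each
    max_occ = max(1, n_samples // 2)
    bg_samples = {
        col: set(rng.choice(n_samples, size=max_occ, replace=False))
        for col in bg_cols
    }

    samples = [f"{host}_s{i + 1}" for i in range(n_samples)]
    counts = np.zeros((n_samples, n_asvs), dtype=np.int64)
    for i in range(n_samples):
        props = np.zeros(n_asvs)
        for j, spec in enumerate(core_spec):
            if rng.random() < spec.prevalence:
                props[j] = spec.rel_abundance
        for j, col in enumerate(bg_cols, start=n_core):
            if i in bg_samples[col]:
                props[j] = bg_base
        if props.sum() == 0:
            props[n_core:] = 1.0
        props = props / props.sum()
        if overdispersion > 0:
            present = props > 0
            conc = props[present] / overdispersion
            props[present] = rng.dirichlet(conc)
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        counts[i] = rng.multinomial(depth, props)

    table = CommunityTable(
        counts=pd.DataFrame(counts, index=samples, columns=seqs),
        host=pd.Series(host, index=samples),
    )
    truth = CommunityTruth(
        core_asvs=set(core_cols),
        sequences={a.seq: a.seq for a in amplicons},
    )
    return table, truth


def default_scheme(plate_id: str = "plate1") -> BarcodeScheme:
    """A ready-made 12F x 8R scheme with 5-nt barcodes and the 515F/805R
    V4 primer pair, for simulations and examples."""
    from .plate_scheme import build_scheme

    rng = np.random.default_rng(20220715)
    def draw(n):
        out = []
        while len(out) < n:
            b = "".join(rng.choice(list(_BASES), size=5))
            if all(sum(x != y for x, y in zip(b, o)) >= 2 for o in out):
                out.append(b)
        return out

    return build_scheme(
        forward_barcodes=draw(12),
        reverse_barcodes=draw(8),
        forward_primer="GTGYCAGCMGCCGCGGTAA".replace("Y", "T").replace("M", "A"),
        reverse_primer="GGACTACNVGGGTWTCTAAT".replace("N", "A")
        .replace("V", "C")
        .replace("W", "A"),
        plate_id=plate_id,
    )
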