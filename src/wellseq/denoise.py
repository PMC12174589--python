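"""Abundance-skew denoising of dereplicated sequences into ASVs.

Sequencing errors produce low-abundance satellites a few substitutions away
from a true template.  The denoiser makes a single greedy pass over unique
sequences in decreasing abundance: the most abundant unvisited sequence
founds an ASV, and each later sequence is absorbed into the most abundant
accepted ASV within ``d_max`` substitutions (equal lengths only) whose
abundance skew permits it:

    abundance(u) / abundance(asv) <= skew(d) = 2^-(alpha * d + 1)

i.e. a satellite one substitution away must be at most 1/8 as abundant as
its parent at the default alpha=2.  Anything that fails both tests founds
its own ASV.  This is a UNOISE-style rule, not a per-base error model: it
needs no quality-aware training pass and is fully deterministic.

ASVs are called pooled across all wells and plates of a run so that one
biological sequence receives one ASV id everywhere, then counted per well.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

DEFAULT_ALPHA = 2.0
DEFAULT_D_MAX = 2


@dataclass(frozen=True)
class UniqueSeq:
    seq: str
    abundance: int


@dataclass
class Asv:
    asv_id: int  # dense from 1, by descending total abundance
    seq: str
    total_abundance: int


def skew_threshold(d: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Maximum satellite/parent abundance ratio at substitution distance d."""
    return 2.0 ** -(alpha * d + 1.0)


def dereplicate(seqs) -> list[UniqueSeq]:
    """Collapse exact duplicates; sorted by abundance desc, then sequence."""
    counts = Counter(seqs)
    return [
        UniqueSeq(seq=s, abundance=n)
        for s, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _hamming_within(a: str, b: str, d_max: int) -> int | None:
    """Hamming distance if <= d_max, else None. Lengths must be equal."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > d_max:
                return None
    return d


def denoise(
    uniques: list[UniqueSeq],
    alpha: float = DEFAULT_ALPHA,
    d_max: int = DEFAULT_D_MAX,
) -> tuple[list[Asv], dict[str, int]]:
    """Greedy abundance-ordered pass; returns ASVs and a map seq -> asv_id.

    Input must already be dereplicated (see :func:`dereplicate`); ties in
    the input ordering are part of the contract and make the pass
    deterministic.
    """
    order = sorted(uniques, key=lambda u: (-u.abundance, u.seq))
    asvs: list[Asv] = []
    mapping: dict[str, int] = {}
    for u in order:
        target: Asv | None = None
        for a in sorted(asvs, key=lambda a: (-a.total_abundance, a.seq)):
            if len(a.seq) != len(u.seq):
                continue
            d = _hamming_within(u.seq, a.seq, d_max)
            if d is None or d == 0:
                continue
            if u.abundance / a.total_abundance <= skew_threshold(d, alpha):
                target = a
                break
        if target is None:
            asvs.append(Asv(asv_id=0, seq=u.seq, total_abundance=u.abundance))
            mapping[u.seq] = len(asvs) - 1  # provisional index
        else:
            target.total_abundance += u.abundance
            mapping[u.seq] = asvs.index(target)

    # Final ids by descending total abundance, 1-based.
    ranked = sorted(
        range(len(asvs)), key=lambda i: (-asvs[i].total_abundance, asvs[i].seq)
    )
    id_of_index = {idx: rank + 1 for rank, idx in enumerate(ranked)}
    for idx, a in enumerate(asvs):
        a.asv_id = id_of_index[idx]
    asvs.sort(key=lambda a: a.asv_id)
    return asvs, {seq: id_of_index[idx] for seq, idx in mapping.items()}


def remove_chimeras(asvs: list[Asv], min_parent_fold: float = 2.0) -> list[Asv]:
    """Drop ASVs that are exact one-crossover concatenations of two
    more-abundant parents (each >= ``min_parent_fold`` times the child).

    Off by default in the pipeline; provided as an optional QC pass.
    """
    if len(asvs) < 3:
        return list(asvs)
    by_abundance = sorted(asvs, key=lambda a: -a.total_abundance)
    kept: list[Asv] = []
    for child in asvs:
        parents = [
            p
            for p in by_abundance
            if p.seq != child.seq
            and p.total_abundance >= min_parent_fold * child.total_abundance
        ]
        if _is_chimera(child.seq, parents):
            continue
        kept.append(child)
    return kept


def _is_chimera(seq: str, parents: list[Asv]) -> bool:
    same_len = [p for p in parents if len(p.seq) == len(seq) and p.seq != seq]
    for a in same_len:
        for b in same_len:
            if a.seq == b.seq:
                continue
            # single crossover at k: left half from a, right half from b
            for k in range(1, len(seq)):
                if seq[:k] == a.seq[:k] and seq[k:] == b.seq[k:]:
                    return True
    return False
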