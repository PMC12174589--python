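# Methods

This note records the models behind each stage, the defaults and why
they were chosen, and what the synthetic-data generators do and do not
emulate.

## Plate scheme

A 96-well plate is addressed by 12 forward-barcoded primers (one per
column) and 8 reverse-barcoded primers (one per row); barcodes are 4–6 nt
and sit between the sequencing-adaptor tail and the V4 515F/805R primer
binding sites. The scheme is a bijection between (forward, reverse) index
pairs and wells, with rows lettered A–H top to bottom and columns 1–12
left to right (standard microplate convention). Within-direction barcode
edit distance is a logged QC statistic, not a hard constraint: wet-lab
barcode sets are fixed artifacts and may sit at distance 1–2. Schemes are
exchanged as a four-column TSV (`direction`, `index`, `barcode`,
`primer`); an example ships in `wellseq/data/example_scheme.tsv`.

## Read preparation

Filtering truncates each mate at the first base with Q ≤ `trunc_q` and
rejects pairs with an ambiguous base, a mate shorter than `min_len`, or
expected errors EE = Σ 10^(−Q/10) above `max_ee`. Defaults (max_ee = 2.0
per mate, trunc_q = 2, min_len = 50) follow widespread amplicon
practice; they are assumptions, not measured optima, and all are
exposed. Phred encoding is fixed to offset 33.

Merging scans placements of reverse-complemented R2 along R1 and keeps
the offset with the most matching bases, requiring `min_overlap` (12)
overlapping bases and at most `max_mismatch_frac` mismatches in the
overlap (0 by default — with ~250 nt mates over a ~291 nt V4 amplicon
the overlap is ~209 nt, so exactness is affordable and maximally
conservative). At a disagreeing position the higher-quality base wins
and keeps its own quality; agreeing positions keep the larger of the two
qualities. An exact-match seed (the first 12 bases of the
reverse-complemented mate) resolves the error-free case without scoring
every offset.

## Demultiplexing

Barcodes are matched exactly and end-anchored: a 4–6 nt tag has too
small an edit space for mismatch tolerance to be safe, and anchoring
means payload content can never cause misassignment. The primer window
behind each candidate barcode tolerates up to 2 substitutions
(configurable), allowing for primer-site variation. When barcodes of
different lengths both match, the longer wins; an exact tie is counted
as `ambiguous`. Demultiplexing runs on merged reads (each end tested
once); the per-plate statistics are an exact partition of the input —
assigned plus every rejection reason sums to the read total.

## Denoising

A deterministic abundance-skew rule stands in for quality-model
denoisers: after dereplication, a single greedy pass in decreasing
abundance order absorbs a sequence into the most abundant accepted ASV
within `d_max` substitutions (equal lengths only) whose abundance ratio
satisfies ratio ≤ 2^−(αd+1); otherwise the sequence founds a new ASV.
Defaults α = 2, d_max = 2: a 1-substitution satellite must be ≤ 1/8 of
its parent, a 2-substitution satellite ≤ 1/32. Raising α only shrinks
the set of absorbable satellites. ASVs are called pooled across all
wells and plates of a run and then counted per well, so one biological
sequence keeps one ASV id everywhere — required for multi-plate hit
tables. Ids are assigned 1-based by descending total abundance with
lexicographic tie-breaks, making the whole pass deterministic. An
optional chimera filter removes ASVs that are exact one-crossover
concatenations of two ASVs each at least twice as abundant; it is off by
default. The denoiser intentionally implements no per-base error-rate
learning; on error-free input it is the identity on planted sequences,
which is what the round-trip tests exploit.

## Well calling and purity

Purity is 100 × (reads of the ASV in the well) / (all assigned reads in
the well), rounded half-up to two decimals. An empty well has no defined
purity and is rendered `NaN`, distinct from a present-but-absent 0. The
denominator counts reads after denoising, so satellite reads absorbed
into an ASV count toward it. Report cells are formatted
`plateID_wellID | count | purity` with trailing zeros stripped (`100`,
`49.5`). Hits are ranked by count, then purity, then plate/well order;
zero-count filler wells rank purely by plate/well order. The recovery
pick list takes every ASV with at least one well at ≥ 60 reads and
≥ 20 % purity (both inclusive) and reports its best well. In the
report, `0 | NaN` fillers denote empty wells and `0 | 0` occupied wells
lacking the ASV — an interpretive choice, documented here.

## Taxonomy

An RDP-style naive Bayes classifier over 8-mers: per genus g,
P(w|g) = (count(w,g) + 0.5) / (N_g + 1) with N_g reference sequences in
g; a query is assigned to the genus maximizing Σ log P(w|g) over its
distinct k-mers. Confidence: 100 bootstrap replicates each redraw
⌈m/8⌉ of the m distinct k-mers with replacement and re-classify;
per-rank confidence is the percentage of replicates agreeing with the
full-sequence call at that rank, and ranks under the cutoff (50) are
blanked. The bootstrap RNG is seeded (default 1) and the seed is part
of the run's provenance. Species rank is not assigned. The reference is
a FASTA with `Kingdom;Phylum;...;Genus;` headers (silva dialect); the
full silva database is user-supplied and deliberately not packaged.

## Dilution planning

Cells land in wells as a Poisson process, so the growing fraction is
g = 1 − e^−λ and a growing well is monoclonal with probability
λe^−λ/(1 − e^−λ) = λ(1−g)/g, strictly decreasing in g. The default
series is threefold from 2000× for six steps (to 486,000×). Acceptable
plates have 20–60 % growth (the tally bounds that drive dilution
selection), ideal 35 %; a second preset (18–55 %) matches the narrower
plate-picking range and is exposed as `plate_pick`. The two windows are
kept as distinct presets rather than reconciled. Selected dilutions are
ordered by |g − ideal| with ties going to the higher dilution (more
dilute is safer for monoclonality at equal distance).

## Ecology

Rarefaction subsamples each sample without replacement to a fixed depth
(default 13,027 reads) via a multivariate hypergeometric draw under a
seeded generator; shallower samples are dropped and logged. Community
core ASVs require ≥ 70 % prevalence within a host group, where
"present" means relative abundance ≥ 0.1 % in that sample. Isolate
categorization uses a stricter 80 % prevalence plus mean relative
abundance > 0.1 % for "core"; otherwise an isolate's matched ASV is
`top50` when its total relative abundance ranks in the upper half of
the host's ASVs (median rank inclusive) and `rare` below that. The two
prevalence thresholds intentionally coexist — they answer different
questions and are defaults of different functions. Isolate matching is
exact sequence identity by default (ASVs are the identity unit); a
substitution-tolerant mode exists and reports distance ties as
ambiguous rather than guessing. The 80 % prevalence test applies the
same 0.1 % detection rule as the community core; whether a bare nonzero
count should instead suffice is ambiguous in practice, and the
detection rule was chosen for consistency.

## Synthetic data

`simulate_plate` reproduces the two-step PCR library structure exactly
(barcode + primer + amplicon + reverse-complemented reverse tag), splits
it into overlapping mates and applies substitution errors at a uniform
per-base rate, with every base's quality set to Q = −10·log10(rate)
(Q40 for error-free reads) so EE filtering behaves consistently with
the planted error rate. It does not emulate indels, chimeras, quality
decay along the read, polymerase bias or length-variable amplicons;
tests passing on it demonstrate bookkeeping correctness (assignment,
counting, purity arithmetic) and substitution-error robustness, not
performance on degraded real libraries. Amplicons are random sequences
at pairwise Hamming distance ≥ 10 — well separated, like distinct
genera, so denoiser and classifier behaviour on closely related strains
is outside what these fixtures show. `simulate_community` plants core
ASVs at stated prevalence/abundance and confines background ASVs to at
most half the samples, which makes the planted core set exactly
recoverable by construction; `overdispersion` > 0 adds Dirichlet noise
between samples.

Problem sizes in the test suite (e.g. four plates of 96 wells at ~500
reads per well for the round-trip integration test, 30-sequence toy
references, 10–12-sample communities) were chosen as the smallest sizes
that exercise every code path convincingly.

## Numerical choices

- Purity rounding is decimal half-up (not banker's), matching how the
  report prints values like 97.05.
- Dilution-selection distances are rounded to 12 decimals before
  comparison so float representation noise cannot break ties.
- The denoiser, demultiplexer and report writer are deterministic;
  stochastic stages (bootstrap, rarefaction, simulation) take explicit
  seeds and identical seeds give byte-identical outputs.

## Known limitations

- The denoiser is not a per-base error model; at high error rates it
  will split true templates into satellite ASVs sooner than a
  quality-aware method would. A pluggable boundary (`denoise` operates
  on dereplicated uniques) allows substituting an external denoiser's
  output.
- Exact-overlap merging (`max_mismatch_frac` = 0) discards pairs whose
  overlap contains any sequencing error; raise the fraction for noisy
  libraries.
- Only 96-well schemes (12 × 8) are supported.
- Classifier accuracy on real data depends entirely on the supplied
  reference database and is not characterized here.
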