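# Methods

## Construct model and release geometry

A siPool template is a pair of RNA transcripts. The sense transcript
carries the passenger strand of each siRNA (19-nt core + 2-nt overhang) in
input order; the antisense transcript carries the guide strands in reverse
order, so antiparallel annealing brings each guide/passenger pair into
register regardless of global transcript lengths. Blocks are separated by
single-stranded spacers; a leader precedes the first block and a trailer
follows the last.

RNase T1 cleaves 3′ of guanosine in single-stranded RNA. The model's
protection rule is minimal: a G is protected **iff the G itself is
base-paired**; the pairing state of the following nucleotide is irrelevant.
Digestion is complete — every eligible site is cut, no partial-digest
species — reflecting the observed complete conversion of annealed precursor
into 21-nt product.

Release of a defined 21-nt strand therefore requires, per block and per
transcript:

* the overhang's final nucleotide is **G** — the cut defining the 3′ end;
* no other G inside the overhang (it would shorten the product);
* the residue immediately 5′ of the core is a spacer **G** — the cut
  defining the 5′ end;
* the overhang's first nucleotide is neither G (would give a 1-nt overhang)
  nor C (it would base-pair with the cut-site G facing it across the
  junction and protect it from cleavage). The default overhang is `UG`.

Spacer bodies are sampled from {A, U, C} (fewer single-stranded Gs → fewer
debris species) with the single mandatory terminal G; default length 10 nt.
The leader is `GGG` + body + terminal G (efficient T7 initiation requires
5′ Gs; its final G is the first block's upstream cut site). The T7 promoter
is the canonical 18-mer `TAATACGACTCACTATAG`; its final G **is** the
transcript's first nucleotide, so the DNA template is the promoter minus
that G followed by the full DNA transliteration of the transcript.

## Annealing model

Annealing is exact-complementarity-based: all maximal antiparallel
exact-complementary stretches of at least `min_duplex_len` (default 8) bp
are enumerated, then accepted greedily by decreasing length (ties: leftmost
on the sense strand), skipping any stretch that conflicts with accepted
pairs. No thermodynamics, no mismatches and no G·U wobble pairs: the
constructs are engineered for exact registers, and whether a wobble-paired
G is protected from T1 in this system is not established — the
exact-complement model deliberately excludes it, and this is a known
limitation for sequences where wobble-stabilised registers could compete.

## Why selection needs cross-pairing rules

With two transcripts each ~0.3–2 kb, any shared 8-mer between the "pairing
context" of two different blocks lets a sense block anneal out of register
with the wrong guide block, producing a stretch the spacers cannot remove.
Selection therefore enforces, besides the conventional filters (core GC in
[0.30, 0.60]; no homopolymer run > 3; guide 5′-end AU count ≥ guide 3′-end
AU count as a thermodynamic-asymmetry proxy; ≥ 5 nt spacing on the
target):

* **cross-pairing screen** (`cross_pairing_kmer = 8`): the k-mers of each
  accepted block's sense context (upstream cut-site G + passenger + overhang)
  must be disjoint from the reverse-complemented antisense contexts of all
  other accepted blocks, and vice versa. The junction G is included because
  it is a fixed residue no spacer choice can change.
* **self-consistency**: a core whose own block contexts share a k-mer at a
  shifted offset (an internal repeat) could anneal to its partner in the
  wrong register and is rejected.

Candidates passing all filters are ranked by a documented score — the
asymmetry margin (guide 5′ AU count minus 3′ AU count, −4…4) plus GC
centrality within the allowed window (0…1) — with ties broken by 5′-most
target position, then accepted greedily subject to spacing and
cross-pairing. Selection is fully deterministic for fixed inputs.

Spacers, leader and trailer are screened at assembly time with up to
`min_duplex_len − 1` nt of flanking context on both sides, so windows
spanning a segment boundary are screened too; the assembled template is
then re-validated by an independent whole-transcript scan
(`validate_design`) and spacers are re-sampled (bounded attempts) until the
scan is clean. An empty validation report is equivalent to: simulated
annealing + digestion releases every intended duplex exactly once and
nothing else double-stranded ≥ 8 bp — the round-trip property the test
suite checks for designs of 1–60 blocks.

## Seed-match enrichment test

The scanning motif for a guide is the reverse complement of its seed
(guide nucleotides 2–8, a 7-mer), searched on the sense strand of each
3′-UTR; overlapping occurrences are counted. The enrichment statistic is
the number of repressed transcripts whose UTR carries ≥ 1 motif occurrence.

The null is built from random seeds: `n_draw` distinct 7-mers are drawn
uniformly without replacement (the observed seed excluded), each is scanned
against the same UTR set, and the `n_keep` whose transcriptome-wide motif
match counts are **closest to the observed seed's** are retained (ties:
smaller absolute difference, then lexicographic seed). Banding makes the
null seeds comparable in background frequency to the observed seed. An
alternative `relative` mode retains seeds within a ±26% match-count band
(the relative width achieved by the closest-retention defaults at full
scale); which retention criterion was used originally is not recorded, so
both are provided, with `closest` the default because its retained-set size
is deterministic.

Two p-values are reported:

* `p_empirical = (1 + #{null ≥ observed}) / (1 + n_keep)` — the
  +1-corrected permutation tail. Its floor is `1/(n_keep+1)`; it is
  **conservative by construction** (the correction, plus ties among small
  integer counts, plus the residual over-dispersion of the banded null) and
  can never be anticonservative.
* `p_gaussian` — the upper tail of a normal fit (mean, SD with ddof = 1) to
  the null values. This is the value that quantifies observations far
  beyond the empirical floor (an empirical tail from 2 000 seeds can never
  be smaller than ~5 × 10⁻⁴, so headline values like 10⁻¹⁶ necessarily come
  from a parametric tail). If the null SD is 0 the tail degenerates to 0/1.

Measured on 1 000 synthetic null datasets at desk scale (1 000 transcripts,
`n_draw = 750`, `n_keep = 200`), the type-I error at α = 0.05 is ≈ 0.055
for `p_gaussian` (calibrated) and ≈ 0.033 for `p_empirical` (conservative,
valid); the calibration acceptance test asserts exactly this pattern —
two-sided binomial calibration and ECDF uniformity for the Gaussian p,
rejection rate not exceeding the binomial upper bound for the empirical p.
Power checks use `p_gaussian` because it resolves effect sizes beyond the
empirical floor.

When a pool is tested, each member seed is tested separately; no pooled
statistic is invented. The per-transcript pool profile reports, for every
transcript, the number of pool guides with a seed match and the
dilution-weighted burden (that number / pool size).

## Synthetic data: what it emulates and what it does not

`generate_transcriptome` draws i.i.d. residues at a target GC (G = C and
A = U split evenly; default 0.45) with log-normal lengths (default median
1 000 nt, σ = 0.5 — human-3′-UTR-like), at a desk-scale default of 1 000
transcripts. Motifs are planted by splice-in at a uniform position in an
exact simple-random sample of ⌈fraction·n⌉ transcripts, so the carrier
count is exact. `generate_repressed_set` samples without replacement with
weight `1 + β` for motif carriers (Efraimidis–Spirakis exponential keys);
β = 0 reduces exactly to uniform sampling. The calibration experiments use
a repressed-set size of 200 of 1 000 — large enough that the overlap
statistic is not dominated by ties at this scale, qualitatively mirroring
the broad transcriptome perturbation of a single-siRNA transfection.

The background model has no dinucleotide structure, no repeats, no
composition heterogeneity across transcripts and no shared UTRs between
isoforms. Passing calibration here shows the test machinery is correct
under its own assumptions; it does not show that real 3′-UTR composition
(where 7-mer frequencies are far from i.i.d. expectations) is handled —
that is precisely why the banded-null design matters in practice, since
banding absorbs motif-frequency differences without modelling them.

## Numerical and interface choices

* Coordinates: 1-based inclusive in every user-facing report and manifest;
  0-based half-open internally.
* U/T: both accepted on input; canonicalised to the declared alphabet.
  IUPAC ambiguity codes are rejected, not expanded.
* Printed 19-mer reference siRNAs are stored verbatim and tagged
  `core_only`; printed 21-mers are tagged `full_strand`. Whether the
  19-mers denote cores or full strands is not stated in the source
  material, so the tags make the ambiguity explicit rather than resolving
  it.
* Determinism: every stochastic stage takes a NumPy `Generator` or integer
  seed; the CLI derives stable per-stage sub-seeds from one global
  `--seed` (crc32 of the stage name folded into the seed, < 2³¹).
* Degenerate inputs: zero annealed pairs is a valid outcome; an empty
  repressed set is an error (the statistic is degenerate); fragments paired
  with more than one partner are reported as `complex` products — the
  designer's failure signal — never dropped.
* Problem sizes in the test suite (1 000 random strand pairs ≤ 60 nt for
  the digestion oracle, 200 calibration replicates, 50 replicates per
  effect size for power, designs of 1–60 blocks) keep the whole suite
  around two minutes on one CPU while leaving each check statistically
  meaningful.

## Known limitations

* No transcript secondary-structure (folding) prediction: intra-strand
  structure could, in reality, expose or protect Gs the inter-strand model
  does not see.
* No enzyme kinetics or partial-digestion time courses; digestion is
  all-or-nothing.
* No G·U wobble pairing (see above).
* Off-target scanning covers exact 7-mer seed matches only — no 6-mer or
  8-mer site classes, offset sites, conservation weighting or context
  scores.
* The repressed set is caller-defined; deriving it from expression data
  (normalisation, differential testing, FDR) is out of scope.
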