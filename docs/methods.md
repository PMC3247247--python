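# Methods

This note records the models, parameter choices and numerical
conventions behind each stage, what the synthetic generator does and
does not emulate, and the design decisions taken where more than one
reasonable reading existed.

## Preprocessing

*Quality trimming* is a strict 3′ suffix scan: the maximal suffix in
which **every** base is below the cutoff (default Phred 20) is
removed, stopping at the 3′-most base at or above it. This is the
minimal reading of a fixed-cutoff rule; sliding-window and
error-sum-minimisation schemes trim more aggressively and are out of
scope.

*3′ adapter removal* uses ungapped semi-global alignment of the
adapter against every read offset, with the adapter free to overhang
the read's 3′ end. The per-base weight is w(q) = 1 − 10^(−q/10), the
probability the base call is correct, contributed positively on a
match and negatively on a mismatch, so low-confidence cycles carry
little evidence either way. A placement is accepted when its score is
≥ `min_score` (default 5.0, roughly five confident matching bases net
of mismatches) and it contains ≥ `min_matches` matching bases
(default 6). Ties between offsets go to the smallest offset, i.e. the
longest trim — the conservative choice for expression counting. An
accepted placement at offset 0 is an adapter dimer and discards the
read. Both thresholds are exposed because the original tooling's
acceptance threshold is not public.

*5′ adapter removal* demands a perfect match of ≥ 10 nt between an
adapter suffix and the read's 5′ prefix; the longest such match is
trimmed (never discarded, unless it covers the whole read). The
length filter keeps 17–26 nt, both bounds inclusive, and the length
histogram is taken over all trimmed reads before filtering.

Stage order is fixed: quality → 3′ adapter → 5′ adapter → length.
The composition is idempotent for reads whose insert bases pass the
quality cutoff; if the quality decay reaches below the cutoff inside
the insert itself, a second pass can trim further (the trimming never
lengthens, so the pipeline runs each stage exactly once).

## Tag collapsing

Exact-sequence groups are visited in a canonical order (read count
descending, then length descending, then lexicographic); each group
joins the earliest-founded tag whose representative is 5′-prefix
compatible within 2 nt, or founds a new tag. Consequences:

- the representative is the founding, highest-count member (the
  dominant isoform), not the longest sequence;
- transitive chains (20/22/24-mers) resolve deterministically toward
  the highest-count tag;
- the result is invariant under permutation of the input, and read
  counts are conserved (Σ tag counts = input reads).

5′ anchoring is the default because miRNA 5′ ends are fixed by
Drosha/Dicer processing while 3′ ends vary; `anchor="both_ends"`
additionally allows suffix containment for other use cases.

## Ungapped alignment and statistics

The aligner is a deliberately ungapped BLAST-like search: on 17–26 nt
queries at the identity levels used (80–100%), gaps are immaterial
and removing them makes the score statistics exact. Exact word seeds
(word size 8 for mature-miRNA matching, 12 elsewhere) nucleate
bidirectional extensions under +1/−2 scoring with an X-drop of 6;
per diagonal the best extension is kept. Extension stops at the
running-score maximum, so among equal-scoring segments the shortest
(highest-identity) is reported. Hits are filtered by identity,
E-value and the 85% query-coverage rule, and sorted by E-value, then
score, then subject id for deterministic best-hit selection.

E-values use ungapped Karlin–Altschul statistics: λ solves
Σ_ij p_i p_j e^{λ s(i,j)} = 1 (for uniform composition and +1/−2 this
reduces to ¼e^λ + ¾e^{−2λ} = 1, λ ≈ 1.333), found by Brent's method
to |f(λ)| < 1e−12. K is fixed at 0.3: E-values act only as a filter
at fixed thresholds (0.01 for miRNA matching, 1e−3 for the longer
references), so only λ, which controls the score dependence, needs to
be exact. The search space n counts both strands of the reference
set. The E-value filter is also applied to genome mapping by default
(`genome_max_evalue`, settable to null), which suppresses spurious
short-segment genome hits from unmappable reads.

Classification tests classes in the fixed precedence
tRNA → rRNA → snRNA/snoRNA → miRNA (mature, then hairpin) → mRNA →
genome; the first passing class wins, a genome-only hit reports as
`genome_unannotated`, no hit as `unknown`. Including the hairpin
reference inside the miRNA class both annotates miRNA\* reads
correctly and keeps them out of the novel-discovery input. The
summary table counts reads (tag counts), not tags.

## Conserved miRNA quantification

Tags with > 2 reads matching a mature reference at 100% identity and
≥ 85% coverage increment that gene's mature count; matching is
sense-strand only, since small-RNA libraries are stranded and the
reverse complement of a mature is the star species, not a mature hit.
Tags matching the hairpin (same thresholds) on the arm opposite the
annotated mature — disjoint from the mature span and on the other
half of the precursor — count as miRNA\*. A tag maps to at most one
gene (best E-value, ties by gene name). Genes whose hairpin record is
missing cannot receive star counts; genes whose mature is absent from
their own hairpin raise a reference-consistency error.

Relative abundance is log2(mature reads / total mature miRNA reads of
the sample). The denominator is mature-only: the heat map excludes
miRNA\* species, and this makes the per-sample non-missing abundances
sum to exactly 1 when no gene is missing. Zero-count genes are
missing values (NaN), never −∞; no pseudocount is added.

## Novel miRNA discovery

Unannotated tags with > 5 reads are mapped to the genome by exact
full-length string match (both strands). Around each locus two
candidate precursors are excised — tag + 70 nt downstream, and 70 nt
upstream + tag — covering the mature-on-5′-arm and mature-on-3′-arm
cases; 70 nt reflects typical animal precursor lengths (~60–80 nt)
and is configurable.

Folding is Nussinov-style maximum base pairing with Watson–Crick and
GU pairs, hairpin loops ≥ 3 nt, and a deterministic pseudoknot-free
traceback (position i pairs with the largest admissible partner). An
energy model is deliberately not used: the acceptance criteria below
depend only on pairing topology, and maximum pairing keeps the
structure test exact and dependency-free.

A candidate passes when (a) the mature span lies entirely on one arm
(no self-pairing, all partners on one side), (b) ≥ 60% of mature
bases are paired, and (c) the star span — the mature's pairing
partner extended by the canonical 2-nt 3′ overhang — stays clear of
the terminal loop. The additive score,
log2(mature reads + 1) + 2·[star reads observed] + paired fraction −
log2(loop reads + 1), is reported with its components; the read
signature (mature/star/loop read counts) comes from locating the
other tags inside the precursor. Overlapping passing candidates
(regardless of strand: a stem-loop region is the same hairpin on
either strand) are reduced to the best-scoring one. This
deterministic criteria-plus-score test replaces the probabilistic
excision/signature model of miRDeep-class tools; it is a documented
simplification, adequate for libraries where the processing signature
is clean.

Seed matching compares positions 2–8 (1-based, 7 nt) exactly.
Cross-species presence requires an other-species tag matching the
candidate mature at 100% identity over ≥ 85% of the tag.

## Comparative analysis

Venn overlaps are exact set arithmetic with per-region name lists.

Average-linkage clustering merges, at each step, the cluster pair
minimising the mean of all cross-cluster pairwise Euclidean
distances, implemented with the Lance–Williams weighted-average
update (the test suite checks it against a step-by-step brute-force
recomputation and against scipy's average linkage). Missing cells use
pairwise-complete distances rescaled by √(D/d): squared differences
are summed over the d dimensions observed in both rows and scaled up
to the full dimensionality D, so sparsely shared rows are not
artificially close; a pair sharing no dimension is an error. Ties
break toward the pair whose smallest original row indices sort first;
the left child of a merge is the cluster containing the smaller
original row; leaf order is the depth-first left-to-right traversal.
The dendrogram serialises to Newick with branch length = parent merge
height − child merge height.

Ortholog triples (two ingroup species + outgroup) are compared with a
global alignment (match +1, mismatch −1, gap −2) whose 3′-terminal
gaps are free up to 3 nt and reported as a terminal 3′ length
difference rather than as changes — 3′ additions/losses of a few
bases reflect precursor-processing differences, not mutations. A
substitution at the final aligned base is likewise not a change
(plausible sequencing error, no effect on targeting). Categories:
A all three present and effectively identical; B all three present,
all pairwise different; C all three present, at least one lineage
mutated; D1 two ingroup species present and identical; D2 an
ingroup/outgroup pair present and identical (generalised to either
ingroup species); E two present with differences; F one present.

## Synthetic data generator

The generator emulates a 36-cycle single-end small-RNA run on an
embryonic library from a species with a compact genome:

- **Toy genome**: one 100 kb contig, background i.i.d. uniform bases,
  with planted elements ≥ 50 nt apart: 20 miRNA hairpins (22-nt
  mature, 8–12 nt loop, perfectly paired stem, random arm and
  strand), 5 tRNA-like (72 nt), 3 rRNA-like (120 nt), 2 snRNA-like
  (100 nt) and 4 mRNA-like (500 nt) genes. The last hairpin is held
  out of the mature/hairpin references as the known novel gene.
- **Class mixture** (fractions of 17–26 nt inserts): 14% miRNA,
  9.6% rRNA, 0.2% tRNA, 0.2% snRNA/snoRNA, 25% mRNA degradation,
  13% unannotated genomic background, 38% unmappable — the
  composition reported for an urchin embryonic library in this size
  window.
- **Expression**: conserved genes draw log-uniform weights over two
  decades (so ~100:1 skews occur); the held-out novel gene is pinned
  at 1.5% of the miRNA class, the conserved:novel read ratio typical
  of such libraries. miRNA inserts are the mature with 3′ isoform
  variation (21/22/23 nt at 0.15/0.70/0.15, the +1 base taken from
  the genomic context) and an 8% star fraction.
- **Reads**: insert + 3′ adapter, filled and truncated to 36 nt;
  ~1% of reads carry a ≥ 10 nt 5′-adapter prefix. Mean quality decays
  linearly from Phred 38 (cycle 1) to 18 (cycle 36) with sd 3,
  clipped to [2, 40] — enough decay to exercise quality trimming
  without mimicking a specific instrument. Substitution errors occur
  at 0.2% per base on average, weighted per cycle by the profile's
  implied miscall probability, so they concentrate in low-quality
  (mostly adapter) cycles. No indels: the downstream pipeline is
  ungapped.

Not emulated: ligation bias, PCR duplication, indel errors, isomiR
5′ heterogeneity, genome polymorphism, multi-contig assemblies and
repeat structure. Passing the recovery tests therefore demonstrates
the pipeline's correctness under clean Dicer-signature conditions,
not robustness to those real-data artefacts.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the full pipeline on
100,000 simulated reads (a scale at which class fractions are
binomially stable to well under a percentage point and the rarest
planted gene still receives tens of reads) and verify: ≥ 95% recovery
of planted conserved miRNAs with zero false calls, detection of the
held-out hairpin as the only novel candidate, and class fractions
within ±2 points of the mixture. Oracle-equivalence suites cover
≥ 10⁴ random/planted alignment pairs (independent all-offset Kadane
scan), ≥ 10³ folds of ≤ 16 nt sequences (exhaustive structure
enumeration) and clustering on matrices of ≤ 8 rows (step-by-step
brute force).

Numerical conventions worth knowing: λ via Brent to 1e−12; UPGMA tie
tolerance 1e−12 on distances; alignment tie-breaks as described
above; X-drop 6 is a speed heuristic that cannot clip an optimum
unless it first dips 6 below a prefix maximum (three consecutive
mismatches) and later recovers — not observed under the tested
conditions; hypothesis-based property tests run derandomised so CI
results are reproducible.

## Known limitations

- The aligner's seed requirement can miss qualifying ≥ 80%-identity
  hits on short queries whose mismatches break every exact 12-mer;
  this mirrors the behaviour of word-seeded search generally.
- The novel-miRNA scorer has no significance model (no shuffled-fold
  comparison); it is a structural/signature filter, and its score is
  a ranking aid, not a probability.
- Star-span inference assumes the canonical 2-nt 3′ overhang and a
  roughly symmetric duplex; heavily bulged precursors may fail
  criterion (c) despite genuine processing.
- Expression is quantified per gene, not per isomiR; arm switching
  across samples is not tracked.
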