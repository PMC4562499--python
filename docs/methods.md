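# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Screening model

A read pair is kept only if it passes three filters, applied in this order:

1. **Quality.** A mate fails if it contains an uncalled base (N) or if any
   sliding window of length `ceil(window_frac · read_len)` has mean phred
   below `phred_threshold`. Defaults: `window_frac = 0.15`,
   `phred_threshold = 17`. The pair fails if either mate fails.
2. **Clones.** Exactly one representative is kept per distinct
   `(seq1, seq2)` pair; the first seen wins and input order is preserved.
   Deduplication is on the *pair*, not the individual mate.
3. **Mapping.** A mate "maps" when it shares at least one exact k-mer
   (default `k = 28`, queried on both strands) with any reference tier; the
   pair is removed when *either* mate maps. Only pairs with both ends
   unmapped survive.

The exact-k-mer rule is a deliberate stand-in for a seed-based DNA aligner:
it is deterministic, dependency-free and conservative on synthetic data
(where hidden regions share no k-mer with the reference by construction, so
screening is exact rather than probabilistic). It does not emulate
mismatch-tolerant alignment; users with real alignments should enter through
`ingest_sam`, which keeps pairs whose SAM flags mark both ends unmapped and
restores reverse-flagged sequences to read orientation. Reference tiers
(genome, transcriptome, abundant sequences, bacterial/viral) are supplied as
FASTA files; since removal is identical regardless of tier, tiers matter
only for the per-stage accounting.

N bases are doubly inert: they fail the quality filter and contribute no
k-mers.

## Assembly and joining

`greedy_assemble` is a deterministic greedy maximal-overlap merger: both
orientations of every read enter the pool, contained reads are removed,
and the highest-scoring exact suffix–prefix overlap (minimum 31 bases) is
merged repeatedly, with lexicographic tie-breaking; the final contig set is
deduplicated to canonical strand. Contigs longer than 200 bases (strict) are
"long transcripts" — the conventional lncRNA length floor. This is a
desk-scale stand-in for a de Bruijn assembler, adequate for low-error
synthetic reads; it makes no attempt at repeat resolution or error
correction.

Joining then proceeds from read-pair evidence:

- Every retained pair is mapped to the long transcripts by unique best
  exact-seed placement (the count of k-mer seeds supporting the best
  diagonal; a mate that ties across two transcripts is discarded as
  ambiguous). A `LinkRecord` is emitted when the two mates place on two
  different transcripts.
- An edge joins transcripts a and b when **strictly more than**
  `min_support = 5` distinct pair ids bridge them. Distinct *pairs* are
  counted, not reads: the clone filter already enforces pair uniqueness, and
  a bridge is a property of the pair.
- Orientation: a mate mapped `+` points past its transcript's 3′ end, a mate
  mapped `−` past the 5′ end, so each link proposes an attachment side for
  both transcripts. The edge's consensus is the majority over its supporting
  links; a tie drops the edge (contradictory evidence never joins).
- Connected components that form simple paths are concatenated in path order
  with a 50-base N spacer between members, each member oriented so the chain
  runs head to tail; iterating the procedure is a fixed point. Components
  containing a branch (degree > 2) or a cycle are left unjoined and logged —
  mate evidence defines only chains, and fabricating an order from a star
  would be wrong.

`validate_joins` scores a join correct when its oriented member sequences
occur in order within one planted transcript (or its reverse complement)
with inter-member gaps of at most `max_gap = 100` bases. The slack exists
because assembled contigs can lose a few terminal bases relative to the
planted fragments when no read covered the extreme ends; exact fragments
still validate at gap 0, while a shuffled or missing member fails. With no
multi-member joins the fraction is defined as 1.0 (and logged).

## Sequence annotation

GC content is (G+C)/(A+C+G+T) with N excluded from both numerator and
denominator; the split at 0.65 is inclusive on the low side (GC ≤ 65% vs
> 65%). The GC-class × taxon contingency (2 × 4: primate, bacteria, other
eukaryote, other) is tested by Pearson χ² without continuity correction at
3 degrees of freedom. Taxon labels are ingested from a TSV rather than
computed — sequence-database searches are versioned, external, and out of
scope.

PSL (BLAT tabular) records are parsed with full block structure; the best
alignment per transcript maximizes matches − mismatches, with ties broken by
target name then coordinate. An alignment is "multi-block" (exon/intron
signature) when at least two blocks are separated by a target-side gap of at
least `min_gap = 30` bases; no authoritative threshold exists for this, so
30 is this package's declared default. A small exact-seed aligner
(`seed_align`: k-mer anchors chained by diagonal) stands in for a real
aligner on synthetic data, where transcripts are exact substrings of the
proxy genome.

## Expression and association

RPKM = (10⁹ × C)/(N × L), where C counts uniquely best-placed mates,
N is the library's unique high-quality read count (each mate is a read), and
L the transcript length. "Expressed" means RPKM above a positive threshold
whose default is 0 — any uniquely mapped read counts, since no principled
nonzero floor exists for transcripts absent from the reference; the
threshold is configurable. "Frequently expressed" means expressed in
strictly more than 10% of same-tissue samples in at least one
tissue × condition cell.

Cancer/normal association per tissue uses the two-sided Fisher exact test on
the 2 × 2 (expressing × condition) table. The test is implemented with exact
integer hypergeometric enumeration (the two-sided p is the total probability
of tables no more probable than the observed one, computed in integer
arithmetic and divided once at the end), so it agrees bit-for-bit with
enumeration oracles. A tissue is significant when its p, Bonferroni-adjusted
across tested tissues, is ≤ α = 10⁻⁴. Categories: *cancer_up* when every
significant tissue favors cancer, *normal_up* when every one favors normal,
*mixed* when both directions occur, *similar* otherwise; a *similar*
transcript frequent in at most `max_tissues = 3` tissues is flagged
tissue-specific (no canonical count defines "a few tissues"; 3 is this
package's choice). A rank-sum statistic over per-tissue frequencies is
reported as a secondary, descriptive quantity: a signed-rank test is not
well defined for the unpaired groups being compared here, so the rank-sum
(Mann–Whitney) form for two independent samples is the primary two-group
test throughout the package. It is exact (permutation distribution over
doubled mid-ranks, kept in integer arithmetic) up to a pooled size of 12 and
a tie-corrected normal approximation without continuity correction above
that; all-identical data gives p = 1.

## Genic neighborhood

Coordinates are 0-based half-open (BED) throughout; the distance between two
intervals is the gap between their closest ends, 0 on overlap, and ties go
to the smaller start coordinate. Strand is ignored when finding the nearest
feature, matching the common default of interval-closest tools. Distances
are reported as non-negative gap magnitudes; direction is recoverable from
the coordinates when needed.

Neighborhood conservation between two annotations: for each gene of A whose
homolog exists in B, the nearest neighbor in A, mapped through the homolog
table, is compared with the nearest neighbor of the homolog in B; genes
without a mappable comparison are excluded from the denominator and logged.
When a transcript aligns to several proxy species, the species with the
higher best-alignment score arbitrates (no authoritative arbitration rule
exists; score is the natural criterion).

Adjacent-gene association compares the neighbor gene's expression in
transcript-expressing vs non-expressing samples with the rank-sum test,
separately within cancer and normal strata; a stratum needs at least 3
samples per group to be tested, and the category (cancer_only, normal_only,
both, none) reflects which strata pass α.

## Histone-mark calling

For each transcript × cell line × mark, x is the ChIP-library RPKM and λ the
input-control RPKM, both over the transcript's *effective length* — the
number of positions covered by at least one read in the union of the
histone-mark libraries (the control is excluded from that union). The
p-value is the Poisson upper tail P(X ≥ x), evaluated through the
regularized lower incomplete gamma function P(x, λ): this equals the exact
tail sum Σ_{k≥x} e^(−λ)λ^k/k! at integer x and is the standard continuous
interpolation for the real-valued RPKM; an integer-floor mode is available
behind a flag for users who prefer to truncate x first. x = 0 gives p = 1
(including the zero-coverage case, which carries no evidence). Significance
is inclusive: p ≤ 10⁻⁴. Because both x and λ scale inversely with the
effective length, halving it doubles both and *sharpens* calls — Poisson
variance grows slower than the mean — so effective length is a modelling
choice with teeth, not a cosmetic normalization.

Tissue matching: over (transcript, tissue) units, a 2 × 2 of
{significant mark in a cell line of that tissue} × {frequently expressed in
that tissue}, tested with the same exact Fisher test.

## Saturation

Discovery at a subsample of libraries is detection-based: a transcript
counts as discovered when detected (count ≥ 1) in at least one library of
the subset. Re-running assembly per subset would be the stricter reading,
and a full re-assembly mode is possible at small scale through the library
API, but detection is the defensible desk-scale default and is what the
fitted curves summarize. The one-site binding curve Y = B_max·X/(K_d + X) is
fitted by bounded least squares with deterministic initialization
(B_max⁰ = max Y, K_d⁰ = median X) and parameter tolerance 10⁻¹⁰; a constant
response is returned as the degenerate boundary fit (B_max = c, K_d = 0)
rather than an error.

## The synthetic-data generator

`make_world(seed, n_genes, n_novel, hidden_fraction)` builds, from a single
integer seed (split per concern through numpy `SeedSequence` spawn keys):

- a **public reference** chromosome of `n_genes` random 1000-base genes
  separated by 500-base spacers;
- **hidden regions** — one per planted transcript — rejection-sampled so
  that no 28-mer (either strand) occurs in the public reference, which makes
  the screening invariant exact by construction; `hidden_fraction` scales
  their total length against the reference;
- a **proxy-species genome** with the same genes in the same order and the
  hidden regions inserted intergenically, plus BED annotations for both
  species and a bijective homolog table. Because insertions shift
  intergenic distances, nearest-neighbor relationships are *not* perfectly
  conserved between the two annotations — the demo world sits near 75%
  conservation, the regime the method is meant for, without any explicit
  relocation machinery;
- **planted truth**: each transcript is the full hidden region, longer than
  200 bases, partitioned into 1, 2 or 3 fragments (three 3-member chains,
  then up to five 2-member chains, then singletons) whose boundaries drive
  the joining tests; a class label cycling through cancer_up (expression
  frequency 0.5 in cancer vs 0.05 in normal of its home tissue), normal_up
  (the reverse), similar (0.30/0.30) and infrequent (0.02/0.02), with 0.02
  background frequency in other tissues; an adjacent-gene log-shift of 1.5
  in expressing samples of the conditions its class implies; and an H3K27ac
  enrichment (fold 20) in its home-tissue cell line for non-infrequent
  transcripts. The planted frequencies are the regimes the association
  analysis is designed to separate; the background rate keeps off-tissue
  expression below the 10% frequent threshold.

Read simulation draws FR mate pairs from fragment ends (default insert 300,
reads 100 bases, expected pair count depth·L/(2·read_len)); errors are
uniform substitutions at the given per-base rate, marked with quality 10
against a baseline of 40 so the quality filter has a deterministic signal.
Junction evidence is simulated so that each mate lies wholly inside one
fragment while the insert straddles the boundary — bridging pairs supply
joining support without ever letting the assembler read across a junction.

ChIP simulation draws control counts as Poisson(base_depth·L/read_len) from
an input library sequenced 50× deeper than treatment (so the background
rate estimate λ is nearly noise-free, as the single-Poisson test assumes —
with a shallow control the test would be anti-conservative by roughly √2 in
z-units), and sets library sizes so one mapped read is about one RPKM unit,
putting the real-valued RPKM statistic on the count scale on which the
Poisson tail is calibrated. Under fold = 1 the empirical call rate at
p ≤ 10⁻⁴ is ≈ 1.15 × 10⁻⁴ (measured over 2 × 10⁵ null records), i.e. the
planted null is honest; at fold 20 and 30× depth, power is 1.

What the generator does **not** emulate: realistic base composition,
repeats, splicing-aware fragmentation, indels or quality-dependent error
profiles, batch effects, library-size variation, or contamination. Tests
passing on these fixtures demonstrate the algorithms' correctness and
calibration under their stated assumptions — not robustness to the full
messiness of real cohort data.

## Problem sizes and determinism

The shipped demo world uses 20 genes and 8 planted transcripts; the joining
and screening checks use a 20-transcript world (3 + 5 chains); association
calibration uses 200 + 200 samples per condition with 10⁴ null transcripts;
ChIP calibration uses 10⁴ null records; the Fisher/enumeration agreement
sweeps all 20,475 tables with total ≤ 24. These sizes were chosen so the
whole verification runs comfortably on a laptop while keeping every
statistical check at meaningful resolution. Every stochastic step flows
from an explicit integer seed, and the pipeline manifest records sha256
digests of all outputs; reruns with the same configuration are
byte-identical.

## Known limitations

- The exact-k-mer screen cannot model mismatch-tolerant alignment; with real
  data, screening fidelity is inherited from the upstream aligner via SAM.
- The greedy assembler is not error-tolerant and will fragment at coverage
  gaps; it exists to exercise the downstream machinery, not to compete with
  real assemblers.
- The joining algorithm refuses branches and cycles rather than resolving
  them; genuinely overlapping chain candidates are left as fragments.
- Fisher-based association tests frequencies only; expression *level*
  differences among expressing samples are not part of the category calls.
- The Poisson caller treats the control rate as known; its calibration on
  real data depends on the input library being much deeper than the ChIP
  library, as discussed above.
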