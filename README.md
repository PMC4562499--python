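# orphan-transcripts

Tools for mining the reads an RNA-seq pipeline normally throws away.  In any
large paired-end RNA-seq cohort, a fraction of read pairs maps to neither the
reference genome nor the transcriptome.  Some of that is noise and
contamination — but some of it is transcription from genomic regions that are
simply missing or misassembled in the reference.  This package implements a
complete desk-scale pipeline for discovering such transcripts and asking
whether they behave like real biology:

1. **Screening** — quality filtering (sliding-window mean phred, uncalled
   bases), PCR-clone removal on the mate pair, and removal of every pair in
   which *either* mate shares an exact k-mer (default k = 28, both strands)
   with any reference tier.  Only pairs with **both ends unmapped** survive.
   Pre-aligned data can enter through SAM flag parsing instead.
2. **Assembly and joining** — a deterministic greedy overlap assembler builds
   contigs; contigs longer than 200 bases are *long transcripts*.  All
   retained pairs are mapped back to the long transcripts, and two
   transcripts are chained whenever **more than five** distinct pairs bridge
   them, with orientation taken from the mate strands; chains iterate
   (`a:b` + `b:c` → `a:b:c`), and branching evidence never joins.
3. **Annotation** — GC-content split at 65%, a 2×4 GC-class × taxon Pearson
   χ² (3 df), PSL alignment ingestion with best-score selection, and
   discontinuous-block (exon/intron) detection.
4. **Expression association** — RPKM = (10⁹ × C)/(N × L); a transcript is
   *frequently expressed* when RPKM > 0 in more than 10% of same-tissue
   samples; frequent transcripts are classified cancer-up / normal-up /
   mixed / similar by per-tissue two-sided Fisher exact tests at
   α = 10⁻⁴ (Bonferroni across tissues).
5. **Genic neighborhood** — transcripts absent from the reference are placed
   on a better-assembled proxy species; the nearest gene there is mapped back
   through one-to-one homology, neighborhood conservation is quantified, and
   the neighbor's expression is tested (rank-sum) in transcript-expressing vs
   non-expressing samples, separately in cancer and normal strata.
6. **Histone marks** — a Poisson upper-tail test 1 − F(x; λ) on ChIP vs
   input RPKM over the transcript's *effective length*, at P ≤ 10⁻⁴, with
   H3K4me3/H3K27ac pattern calls and a Fisher test for tissue matching.
7. **Saturation** — subsampled discovery counts fitted with the one-site
   binding curve Y = B·X/(K + X).

Real cohorts of this kind live behind controlled access, so the package
ships a seeded synthetic-data module that plants every structure the
pipeline assumes — hidden genomic regions (k-mer-disjoint from the public
reference, by rejection sampling), fragment/chain structure for joining,
tissue × condition expression frequencies, adjacent-gene shifts, and ChIP
fold enrichments — and every stage is tested against that planted truth.

## Worked example

```bash
orphan-transcripts run --out-dir demo --seed 0
```

runs the full nine-stage pipeline on a synthetic world with 8 planted
transcripts (three 3-member chains, five 2-member chains) and prints per-stage
counts into `demo/manifest.json`:

```
simulate  {'planted': 8, 'pairs': 1071}
screen    {'input': 1071, 'retained': 682, 'mapped': 200}
assemble  {'contigs': 19}
join      {'links': 104, 'edges': 11, 'joined': 8, 'join_correct_fraction': 1.0}
annotate  {'alignments': 8, 'gc_low': 8, 'gc_high': 4, 'chi2': 12.0, ...}
associate {'frequent': 6, 'cancer_up': 2, 'normal_up': 2, 'similar': 2}
neighbors {'assigned': 8, 'conservation': 0.75, 'cancer_only': 2,
           'normal_only': 2, 'both': 2, 'none': 2}
histone   {'signals': 48, 'marked_transcripts': 6, 'tissue_match_p': 7.4e-06}
saturate  {'sizes': [45, 90, 180, 270, 360], 'bmax': 8.25, 'kd': 9.215}
```

Reading this: all 200 reference-derived background pairs were screened out
(`mapped: 200`) while every hidden-region pair survived; the 19 assembled
contigs were re-joined into all 8 planted transcripts with perfect member
order (`join_correct_fraction: 1.0`); the association stage recovered the
planted cancer-up/normal-up/similar classes; every transcript's adjacent
gene was recovered through the proxy species, and the planted
condition-specific expression shifts reproduce the cancer-only /
normal-only / both categories; 6 of 8 transcripts carry a planted H3K27ac
mark in their home-tissue cell line, giving a strong tissue-match Fisher
signal; and discovery saturates toward the 8 discoverable transcripts
(B_max ≈ 8.25) with half-saturation near 9 libraries.

Each stage is also available as a subcommand over plain-text files
(`screen`, `join`, `annotate`, `associate`, `neighbors`, `histone`,
`saturate`) — see `orphan-transcripts <cmd> --help`.

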