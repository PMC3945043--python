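# Methods

This note documents the models and procedures implemented in `nascentscan`,
the defaults they ship with, the design decisions taken where several
reasonable choices existed, and what the synthetic-data tests do and do not
demonstrate about real data.

## Two-state HMM transcript calling

**Model.** For one strand of one chromosome, read 5′ ends are counted in
fixed-width bins (default 25 bp; the 5′ end is used because a GRO-seq read
marks the position of an engaged polymerase, so single-base attribution is
more faithful than fractional coverage and is deterministic). The count
sequence is modelled by a two-state HMM with states N (non-transcribed) and
T (transcribed). Emissions are zero-inflated gamma per state: a point mass
π_s at zero and density (1−π_s)·Γ(x; k_s, θ_s) for x > 0. Zero inflation is
required because the gamma density vanishes at 0 for shape > 1 while most
genomic bins are zero-count at typical sequencing depth; the gamma
accommodates the overdispersion of positive bin counts.

**Fixed vs fitted parameters.** Two parameters are configuration, not fit:

| parameter | default | meaning |
|---|---|---|
| `shape_n` | 5 | gamma shape of the N state |
| `neg_log_trans_t_to_n` | 200 | −ln P(T→N); exit penalty of the transcribed state |

The α-amanitin preset is `shape_n = 5`, `neg_log_trans_t_to_n = 10`: the
surviving Pol I/III units are mostly shorter than 400 nt, and a softer exit
penalty is needed to resolve them. The "negative log" is read as the
natural log, so P(T→N) = e^−200 by default; P(N→T) defaults to the same
value (it is never fitted, only configured). Remaining emission parameters
(θ_N, k_T, θ_T, π_N, π_T) are estimated by Baum–Welch EM with the
transitions held fixed.

**EM details.** Initialization is method-of-moments: bins are split at the
median of the *positive* bin values (the overall median of a GRO-seq track
is zero, which would leave the N side with no positive observations), the
lower part initializing state N and the upper part state T. The E-step is
scaled forward–backward; per-bin emission log-densities are shifted so the
better state has probability 1 before exponentiation, which keeps the
recursion away from underflow even when one state assigns astronomically
small density (e.g. a 60-count bin under the background model). The M-step
is weighted MLE: zero masses from posterior-weighted zero fractions
(clamped to [1e−6, 1−1e−6] so that no observation is ever strictly
impossible — a single zero bin inside a unit must not force a segmentation
break), θ_N = weighted mean / 5, and (k_T, θ_T) by solving the weighted
profile-likelihood equation log k − ψ(k) = log(mean) − mean(log x) with a
bracketed root solve. The observed-data log-likelihood is non-decreasing
across iterations; fitting stops after 30 iterations or at relative
improvement < 1e−4. Genome-wide calling fits one parameter set on the
pooled bins of all chromosomes and strands, then decodes each track with
it.

**Decoding.** Exact Viterbi in log space. All ties — between predecessor
states and at the final column — break toward N, so a signal-free genome
yields zero transcripts deterministically. Maximal T runs become transcript
units (bin index × bin width); no gap merging and no minimum length are
applied by default, both exist as post-processing options, and a
union-merge utility collapses overlapping same-strand calls from different
conditions. A brute-force decoder that scores all 2^n paths (n ≤ 16) with
the identical accumulation order and tie-break serves as the correctness
oracle; the two agree exactly on randomized instances.

## α-amanitin subtraction and polymerase partitioning

α-amanitin at the concentration used inhibits Pol II but not Pol I/III, so
the amanitin GRO-seq signal minus the vehicle signal isolates non-Pol II
transcription. Both tracks are depth-normalized to reads per million
(values × 10⁶ / library size), then

```
corrected[i] = max(0, treated[i] − runmax₃(control)[i] + mean_positive(control))
```

where `runmax₃` is a centered running maximum over three 25-bp bins
(truncated at chromosome ends) and `mean_positive` is the mean of the
strictly positive control bins (defined as 0 for an all-zero control so the
operation stays total). The running maximum absorbs single-bin jitter in
polymerase position between conditions; the baseline keeps genuinely
amanitin-resistant bins above zero. The result is clamped at zero because
the HMM emission model requires non-negative observations. Subtraction is
applied per strand. "Window-size three (25 bp)" is implemented as three
25-bp bins (a 75-bp maximum span); the alternative reading (a 25-bp window
of three bins) would imply non-integer bin widths.

Per-transcript polymerase labels compare mean depth-normalized density over
the transcript between conditions: `non_pol2` when treated/control ≥ 1.0
(relative enrichment under amanitin — suppression of the Pol II majority
deflates the amanitin library size, so unchanged absolute transcription is
*enriched* after normalization), `pol2` otherwise; a zero control mean with
positive treated signal is `non_pol2`, and zero in both is `pol2` (no
evidence of amanitin resistance). The 1.0 ratio threshold is exposed in
configuration.

## Functional classification

Each called unit receives exactly one of eight classes by the first
matching rule in a fixed precedence order:

1. **protein_coding** — > 20% of the unit overlaps one annotated
   protein-coding gene, same strand.
2. **non_coding** — any same-strand overlap with an annotated non-coding
   RNA gene (lncRNA or short ncRNA), with no size or quality restriction.
3. **divergent** — > 10% of the unit overlaps the proximal promoter
   (TSS ± 500 bp) of a *called* opposite-strand primary unit > 1 kb, and
   the unit is < 50% of that primary's length (this size condition is what
   keeps balanced bidirectional enhancer pairs out of this class).
4. **antisense** — > 20% of the unit overlaps > 20% of a protein-coding or
   lncRNA gene on the opposite strand.
5. **repeat** — > 50% of the unit lies in the union of RepeatMasker
   regions (strand-agnostic).
6. **intergenic** — no overlap with any gene annotation on either strand.
7. **other_genic** — fallback: touches a gene annotation but matches it
   poorly (< 20%).
8. **eRNA** — assigned afterwards by the enhancer caller as a refinement of
   intergenic.

All thresholds are strict inequalities. The precedence order is a design
choice (no tie-break order is canonical): divergent is evaluated before
antisense so a promoter-proximal opposite-strand transcript — which
satisfies both geometrically — keeps its own class, and repeat after the
genic rules so genic repeats stay genic. Rule 2 is restricted to the same
strand because opposite-strand cases are rule 4's job. Annotations are
compared as whole primary-transcript spans; exon structure is discarded on
read. Classification is deterministic and independent of annotation record
order (candidate hits are sorted by coordinates before rule evaluation).

## Enhancer (eRNA) pairing

Candidates are intergenic units shorter than 9 kb (per transcript, strict;
the rule describes "a pair of short transcripts", not a short pair span).
Every (+, −) candidate pair with nonzero interval intersection is scored by
intersection length; pairing is a greedy maximum-intersection matching
(ties to the leftmost partner), so no unit joins two pairs. The enhancer
position is the floor of the midpoint of the intersection. Overlap is
required — non-overlapping divergent pairs are not paired — because the
anchor of all downstream analyses is the midpoint *of the overlap*.

The NF-κB flag is set when some peak center lies within 1000 bp of the pair
center, boundary inclusive. The radius is configurable; 1 kb is used
because a megabase-scale window would flag essentially every enhancer and
make the distinction meaningless. The putative target is the
protein-coding or lncRNA gene with the nearest TSS in either direction
(signed distance, negative to the left; exact ties by lexicographic gene
id); TSS distance rather than gene-body distance is used because
downstream metagene analyses anchor on target TSSs.

## Quantification, regulation, GSEA ranking, metagenes

Per-unit read counts use the same 5′-end, same-strand containment rule as
binning, over non-overlapping called units; the resulting matrix is meant
for external count-based differential tools, whose output table (id, log
fold change, p, q) is re-ingested. Differential testing is deliberately
not reimplemented. Regulation flags use strict q < 0.001.

Pre-ranked GSEA lists are built in three blocks: significant (q < 0.001)
upregulated genes at the top ordered by descending fold change;
non-significant genes in the middle — upregulated side by ascending p, then
downregulated side by descending p, so significance decreases toward the
middle of the list from both ends; significant downregulated genes at the
bottom ordered by ascending fold change. The bottom-block direction and
the junction of the two middle sub-blocks are convention choices (the
obvious alternatives permute within blocks only); all ties break by gene
id, and the output is always a permutation of the input.

Metagene profiles average read 5′-end counts in offset bins (default 25 bp)
around anchors, ± 4 kb by default (± 5 kb is the other conventional flank;
both are plain config values). Offsets are strand-aware: upstream is
negative for both anchor strands, with minus-strand anchors mirroring
genomic offsets, and the mirror is exact at the bin level (a mirrored
dataset reproduces the profile bit for bit). Profiles are normalized by
anchor count only; depth normalization, if wanted, is applied upstream.
Stranded signal is split into sense/antisense relative to the anchor;
ChIP-style signal uses a combined profile.

## Simulator

The generator emulates the data regimes the pipeline targets: Poisson
per-bin counts (negative binomial via a dispersion knob) with background
rate λ_bg = 0.25 reads per 25-bp bin (10 reads/kb); log-normal unit
expression (median 10 reads/bin, σ_log = 0.5, floor 5) on top of the
background; a promoter-proximal pausing peak as a ×5 multiplier on the
first two bins of each unit; planted canonical instances of every
functional class; overlapping opposite-strand eRNA pairs (0.5–2 kb, 200-bp
overlap, half with an NF-κB peak planted within 500 bp of the center);
short (100–400 bp) highly-expressed non-Pol II units annotated as tRNAs;
and an α-amanitin condition in which Pol II unit expression is multiplied
by ε = 0.05 while non-Pol II units and background are untouched. Reads are
materialized with 5′ ends uniform within their bin and lengths uniform in
[33, 100] bp (downstream logic only uses the 5′ end). Everything is
integer-RNG deterministic: one seed yields byte-identical output files.

Planted elements occupy disjoint territories with ≥ 2 kb same-strand
spacing. This is a deliberate regime choice: transcription units closer
than the HMM's switching cost would be merged by *any* segmentation with
the default exit penalty, and the generator models distinct, resolvable
units. eRNA pair members are drawn size-balanced (length ratio within
[0.6, 1.67]) so that neither member reads as a divergent partner of the
other — mirroring the size condition in the divergent rule.

**What passing tests show, and what they do not.** The simulator plants
clean, bin-aligned units in unambiguous territories with Poisson noise.
Recovery results on it demonstrate the correctness of the inference
machinery (decoding, fitting, rule evaluation, geometry), not performance
on real chromatin: real data add mappability gaps, copy-number variation,
overlapping and nested transcription, non-stationary background, and
annotation errors, none of which are modelled. The reported sensitivity and
precision are therefore upper bounds for real-data behaviour.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 200 random decoder instances
of length ≤ 12 against the exhaustive oracle; a 10-Mb, 200-unit benchmark
genome (≈ 0.7 M reads) for caller recovery at interval Jaccard ≥ 0.8; the
full 10-Mb mixed genome (≈ 340 units of all classes) for polymerase
partitioning and enhancer geometry; 10⁵ uniform reads over 1 Mb with 50
anchors for metagene flatness; and a 2-Mb genome for the double-run
bit-reproducibility check. EM parameter recovery is checked on 10⁵ bins
sampled from a known two-state model with moderate transitions (−log 4–6;
with −log 200 a 10⁵-bin chain essentially never switches states, so
recovery there would be vacuous).

Numerical conventions collected in one place: coordinates are 0-based
half-open everywhere internally (GTF and wiggle converted exactly once at
the boundary); corrected α-amanitin signal is clamped at 0; zero masses are
clamped to [1e−6, 1−1e−6]; `mean_positive` of an all-zero vector is 0;
Viterbi ties break toward N; enhancer-pairing ties break to the leftmost
partner; nearest-gene ties break by gene id; the rDNA repeat used as a
single mapping reference is handled as an ordinary extra chromosome in the
size table, with no special-case code.

## Known limitations

- The emission family (zero-inflated gamma) and the EM fitting of the
  transcribed state are implementation choices; only the N-state shape and
  the T→N transition are externally specified constants.
- P(N→T) is never fitted; datasets with very different unit densities may
  benefit from tuning it.
- Multi-mapping reads are consumed as-is; the caller does not model
  mappability.
- The classifier assigns classes against whole transcript spans and cannot
  detect post-poly(A) read-through (no operational rule exists for it).
- Enhancer-target assignment is nearest-TSS only; no correlation- or
  contact-based linking.
- Differential statistics (negative-binomial testing, dispersion
  estimation) are delegated to external tools by design.
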