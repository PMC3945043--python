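# nascentscan

Analysis toolkit for GRO-seq (global run-on sequencing) nascent-transcription
data. GRO-seq maps the positions and orientations of transcriptionally
engaged RNA polymerases genome-wide; unlike RNA-seq it sees transcription
directly, including unstable species — enhancer RNAs (eRNAs), divergent
promoter transcripts, antisense transcripts — that never accumulate as mature
RNA. `nascentscan` turns strand-specific mapped reads (BED) into annotated
transcription units:

- **Transcript-unit calling** with a two-state hidden Markov model that
  segments each strand of each chromosome into transcribed (T) and
  non-transcribed (N) runs.
- **Functional classification** of every called unit into one of eight
  classes (protein-coding, non-coding, intergenic, eRNA, divergent,
  antisense, repeat, other-genic) by explicit overlap rules against gene and
  RepeatMasker annotations.
- **Enhancer detection**: pairing of short (< 9 kb) overlapping
  opposite-strand intergenic transcripts into bidirectional eRNA loci, with
  NF-κB ChIP-seq peak overlap (± 1 kb of the pair center) and nearest-TSS
  target-gene assignment.
- **α-amanitin polymerase partitioning**: control-signal subtraction
  (running maximum of three 25-bp bins plus the control's mean positive
  baseline) and per-transcript Pol II vs Pol I/III labelling from the
  depth-normalized amanitin/vehicle density ratio.
- **Quantification utilities**: per-unit read counting for external
  count-based differential tools, strict q < 0.001 regulation flags,
  three-block pre-ranked gene lists for GSEA, and strand-aware metagene
  profiles around TSSs, eRNA centers or peaks.
- **A ground-truth simulator** that generates strand-specific reads with
  background noise, promoter-proximal pausing peaks, planted instances of
  all eight transcript classes, eRNA pairs, and a Pol II-suppressed
  α-amanitin condition — so every stage is testable without any downloads.

## The model

Per-strand read 5′-end counts in fixed 25-bp bins are the observation
sequence of a two-state HMM. Each state emits a zero-inflated gamma: a point
mass at zero (most bins carry no reads) and a gamma density for positive
counts,

```
P(x | state s) = π_s               if x = 0
               = (1-π_s) Γ(x; k_s, θ_s)   if x > 0
```

The gamma shape of the non-transcribed state is fixed at `k_N = 5` and the
transition out of the transcribed state at `P(T→N) = e^-200` (negative
natural log 200); the remaining parameters (scales, transcribed shape, zero
masses) are fitted to each dataset by expectation-maximization. Decoding is
exact Viterbi in log space, ties broken toward N; maximal T runs become
transcript units. For α-amanitin data, where surviving Pol I/III units are
typically shorter than 400 nt, the preset `5 / 10` relaxes the exit penalty.

## Worked example

```python
from nascentscan import (SimulationConfig, simulate, bin_reads, HMMParams,
                         call_transcripts_genome, classify_all, pair_ernas)
from nascentscan.enhancers import annotate_pairs
from nascentscan.simulate import evaluate_calls

cfg = SimulationConfig(seed=0, chrom_lengths={"chrS1": 2_000_000},
                       n_genes=30, n_lncrna=3, n_divergent=3, n_antisense=3,
                       n_repeat=2, n_other_genic=2, n_intergenic=4,
                       n_erna_pairs=6, n_non_pol2=8)
sim = simulate(cfg)

tracks = []
for strand in ("+", "-"):
    per_chrom = bin_reads(sim.reads["control"], sim.sizes, 25, strand)
    tracks.extend(per_chrom[c] for c in sorted(per_chrom))
units, fitted = call_transcripts_genome(tracks, HMMParams())

metrics = evaluate_calls(units, sim.truth.expressed_units())
ann = sim.annotations
for iv in sim.repeats:
    ann.add(iv, "repeat")
classified, counts = classify_all(units, ann)
pairs = pair_ernas([ct for ct in classified if ct.cls == "intergenic"])
annotate_pairs(pairs, sim.peaks, ann)
```

Output (printing the quantities above):

```
reads (control): 180594
called units: 73
fitted scale_n=0.225 shape_t=3.20 scale_t=4.34 zero_mass_n=0.780
sensitivity=1.000 precision=1.000 boundary_error=0.0 bp
class counts: {'protein_coding': 36, 'non_coding': 11, 'divergent': 3,
               'repeat': 2, 'other_genic': 2, 'intergenic': 4, 'eRNA': 12,
               'antisense': 3}
eRNA pairs: 6  NF-kB flagged: 6
first pair: center=497025 nfkb=True target=gene_0038 (-44625 bp)
```

All 73 planted expressed units are recovered with exact bin-level
boundaries (sensitivity and precision 1.0 at interval Jaccard ≥ 0.8); the
six planted bidirectional pairs are paired and centered exactly, and the
nearest annotated TSS is assigned as each enhancer's putative target. (With
this seed all six pairs happened to receive an NF-κB peak.)

The same pipeline is available from the shell:

```
nascentscan simulate --seed 0 --out sim/
nascentscan run --reads sim/reads_control.bed --sizes sim/sizes.tsv \
    --annotations sim/genes.gtf --repeats sim/rmsk.bed --peaks sim/peaks.bed \
    --amanitin-reads sim/reads_amanitin.bed -o out/
```

`run` executes bin → subtract → call → classify → pair → count → metagene →
amanitin-call and writes `manifest.json` recording the configuration hash
and the checksum of every input and artifact; re-running with the same seed
and inputs reproduces the manifest byte for byte.

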