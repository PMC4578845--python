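# intronlens

Intron-centric analysis of splicing perturbations from bulk RNA-seq and
iCLIP data. Given a genome, an Ensembl-style annotation, coordinate-
sorted alignments for a two-condition replicate design, and single-
nucleotide crosslink tracks, `intronlens` detects **retained introns**
(RI) and **differentially used exons** (DEU), characterizes affected
introns by **5′ splice-site strength** and **differential GC content**,
quantifies **co-transcriptional splicing** from first- versus
last-intron coverage, and builds **junction-anchored iCLIP
metaprofiles**. A synthetic-data generator plants every one of these
effects with known parameters, so the whole pipeline is validated by
parameter recovery.

It is aimed at computational biologists studying core spliceosome
factors (the motivating case is siRNA depletion of a U5 snRNP protein,
3 control vs 4 depleted libraries of 100 bp paired-end reads), but every
stage is a plain library function usable on its own.

## The statistics at the core

**Normalized intron expression.** For intron *i* in gene *g*:

    mu_i = ((c_i / l_i) / (c_g / l_g)) * (1e9 / N)

with counts *c*, lengths *l* and library size *N*.

**Differential usage.** Per-feature negative-binomial GLM with offset
`log s_j + log(c_gj / mean c_gj)` (size factor times relative gene
expression), Wald test on the condition coefficient; dispersion is a
moderated method-of-moments estimate. Size factors always come from
exon counts. RI = introns with BH `q < 0.01` and positive log2 fold
change; the top 200 by fold change feed the sequence analyses, with the
non-retained introns of the same genes as contrast.

**Splice-site strength.** log2(P_s/P_b) in bits, where P_s is a
maximum-entropy model over donor 9-mers matching single-position and
adjacent-pair marginals (PWM for acceptor 23-mers) and P_b is the
background base composition. Group comparisons: Wilcoxon rank-sum and
Fisher exact on consensus (MAG|GTRAGT) matches.

**Co-transcriptional splicing ratio.** Per eligible gene,
`r = first-intron / last-intron` length- and adjacent-exon-normalized
coverage; `r < 1` means 5′-proximal introns are already spliced when the
transcript is polyadenylated.

**iCLIP metaprofiles.** Per-million library scaling, then per-junction
division by the maximum across libraries and offsets, then the mean over
junctions; condition ratios at named peak offsets carry bootstrap CIs.

## Worked example

Run the pipeline end-to-end on a small synthetic dataset:

```
intronlens run-all -o demo --seed 7 --n-genes 40 --coverage 150
```

which prints

```
complete stages: simulate, models, count, diff, seqfeat, cotx, clip
```

and writes one TSV/JSON per stage into `demo/`. On this run:

* `results_intron.tsv` labels 196 introns — 15 RI, 181 NRI
  (the generator planted 19 introns whose intronic signal at least
  doubles under depletion, at half the coverage the validation runs
  use);
* `cotx_summary.json` reports median ratio 0.31 in control versus 0.80
  under depletion (rank-sum p = 4.6e-10): co-transcriptional splicing
  dominates in control and is attenuated by the depletion, exactly as
  planted (residual gradient 4.0 -> 1.2);
* `clip_comparison.tsv` estimates the depleted/control peak ratio at
  offset −20 from the 5′ss as 0.32 with CI [0.30, 0.34] (planted 0.3)
  and 1.01 with CI [0.97, 1.05] at the unchanged −50 peak;
* `truth.introns.tsv` holds every planted parameter for comparison.

The same stages run on real data by pointing `PipelineConfig` at your
own `genome`, `annotation` and `sample_sheet` paths instead of the
simulator (the sample sheet lists sample_id, condition, replicate, bam,
clip_bed).

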