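# Methods

`intronlens` analyzes how depleting a core spliceosome factor reshapes
splicing, starting from aligned RNA-seq fragments and iCLIP crosslink
tracks. This note documents the models, the numerical choices, and what
the synthetic validation does and does not establish.

## Gene models

All stages work off per-gene merged-exon models: the exons of every
(protein-coding) transcript of a gene are unioned into disjoint blocks,
and introns are defined as the gaps between consecutive blocks. This is
the only reading under which "the intron set of a gene" is well defined
without isoform reconstruction; the alternative (a longest-path
combination of exons) is not attempted. Coordinates are 0-based
half-open internally; GTF I/O converts to and from the 1-based inclusive
convention. Intron order is transcriptional, so on the minus strand the
first intron is the one with the largest genomic coordinate.

## Counting and normalization

A *fragment* (properly paired mates merged by name) is counted once into
every feature — exon bin or intron — whose interval it overlaps by at
least one aligned base; N-gapped segments of spliced reads do not
overlap the skipped intron. Duplicate-flagged and multi-mapped (NH > 1)
records are skipped by default. The gene's exonic count `c_g` counts
fragments touching any merged exon.

Normalized intron expression is

    mu_i = ((c_i / l_i) / (c_g / l_g)) * (1e9 / N)

with intron count/length `c_i, l_i`, gene exonic count/length `c_g, l_g`
and library size `N` (total counted fragments). When `c_g = 0` the value
is reported missing, never 0 or infinity. Note `mu_i` is not
depth-invariant — the leading ratio is, but the `1e9/N` factor scales
inversely with depth; this is a property of the formula itself.

`FPKM = c_g / ((l_g/1e3) (N/1e6))`; a gene is *expressed* when FPKM is
strictly above 1 in at least one sample.

Library size factors are median-of-ratios estimates computed **from exon
bins only** (features with any zero excluded), for intron tests too:
intron counts are sparse and the perturbation changes them globally, so
they cannot anchor normalization.

## Differential usage test

For each feature the null hypothesis is "no change in usage relative to
the gene's expression". Counts are modeled as negative binomial with a
log link and offset

    o_j = log(s_j) + log(c_gj / mean_j c_gj)

so the condition coefficient `b1` measures relative-usage change;
`log2FC = b1/ln 2`, and the test is a Wald test on `b1` (statsmodels GLM
with fixed dispersion; a Rao score test is the fallback when IRLS
fails, flagged in the output).

Dispersion is estimated per feature by method of moments on
size-factor-normalized counts with within-condition residuals pooled
(n − 2 df), floored at 1e-8. Because such estimates are extremely noisy
at 3–4 replicates, each feature's value is moderated against the
across-feature median: the final dispersion is the maximum of the two.
The Wald statistic is referred to a t distribution with 6(n − 2) df
rather than the normal; this mildly heavier tail absorbs the residual
variability of the plug-in dispersion. Both choices were fixed by null
simulation: with 3 vs 4 replicates and 2-fold library-size variation the
type-I error at nominal 0.05 is ~0.05 (the acceptance run recomputes
this), while a naive per-feature plug-in with a normal reference is
anticonservative (~0.12) and a t with n − 2 df destroys power.

Introns with `q < 0.01` (Benjamini–Hochberg) and positive fold change
are retained introns (RI); all other tested introns are non-retained
(NRI). The top-k RI (default k = 200) are ranked by descending fold
change, ties broken by smaller q then feature id for reproducibility;
the NRI contrast set is the non-RI introns of genes containing a top-k
RI. Exon bins run through the identical machinery with a two-sided DEU
label. Gene-set overlap (RI genes x DEU genes within expressed genes)
uses an upper-tail hypergeometric test.

## Splice-site strength

Site windows are the donor 9-mer (last 3 exonic + first 6 intronic nt)
and acceptor 23-mer (last 20 intronic + first 3 exonic nt), in coding
orientation. The signal model is trained on the annotation's own sites:
order 0 is a position weight matrix (pseudocount 0.5); the maximum-
entropy model matches single-position and adjacent-pair marginals by
iterative proportional fitting over the enumerated k-mer space, with the
position marginals derived from the pair marginals so the constraint set
is exactly consistent (convergence criterion: marginal residual < 1e-6).
Enumeration is feasible up to k = 10, so donors use the maxent model and
acceptor 23-mers fall back to order 0. Scores are log2(P_s/P_b) in bits
against position-independent background frequencies; N-containing sites
get missing scores.

RI-vs-NRI strength comparisons use the Wilcoxon rank-sum test (exact
null distribution for groups of <= 20 without ties, normal approximation
with tie correction otherwise). Consensus-motif comparisons count sites
within <= 2 mismatches of the IUPAC donor consensus MAG|GTRAGT (both the
pattern and the mismatch budget are parameters, not fixed science) and
compare groups by two-sided Fisher exact test.

Differential GC trims 20 nt from each intron end and 3 nt from each exon
end before counting, so splicing signals do not contribute; the record
is trimmed intron GC over the mean of the two trimmed flanking exons.
Terminal introns with only one usable flanking exon use that exon alone
and are flagged. Introns of <= 40 nt are skipped (trimming exhausts
them).

## Co-transcriptional splicing ratio

For genes passing four filters — single annotated transcript, >= 2
introns, gene span >= 300 bp (shorter transcripts would be lost to
library size selection), no overlap with another gene on either strand —
the ratio is

    r = first-intron normalized coverage / last-intron normalized coverage

where each intron's normalized coverage is its fragment count per base
divided by the mean per-base coverage of its two adjacent merged exons.
`r < 1` indicates co-transcriptional splicing (5'-proximal introns
already removed at polyadenylation). Replicates are pooled (counts
summed) within condition before the ratio — the between-condition
comparison is across genes — with a per-replicate mode behind a flag.
Genes with an undefined ratio (zero last-intron or zero adjacent-exon
coverage) are dropped, pairwise across conditions for the comparison.
Conditions are compared by rank-sum on log r, with medians and Pr(r > 1)
reported.

## iCLIP metaprofiles

Crosslink tracks are single-nucleotide BED6 intervals (score = event
count); wider intervals are rejected. Profiles anchor at the 5'ss
(offset 0 = first intronic base) or 3'ss (offset 0 = first exonic base)
in transcript orientation, window ±100 nt by default. Normalization is
two-step, in this order: (1) each library is scaled to events per
million, because the per-junction step compares values *across*
libraries, which is only meaningful after depth correction; (2) for each
junction, every library's window is divided by the maximum value across
all libraries and offsets for that junction, bounding values in [0, 1]
and weighting junctions equally. The metaprofile is the per-offset mean
across junctions; only junctions of expressed genes are profiled by
default. Between-condition amplitude ratios at named offsets come with
95% bootstrap CIs over junctions (1000 seeded resamples).

## Synthetic data generator

The generator emulates the study design: two conditions (3 control vs 4
depleted replicates), 100 bp paired-end fragments (250 bp inserts), and
per-replicate depths varying up to ~2-fold to exercise size-factor code.
Genes (default 40; validation runs use up to 500) are laid out without
overlap on one chromosome, alternating strand, with 4–7 exons of
150–400 bp and introns of 200–1200 bp; exon/intron GC targets are 0.52
and 0.42. Every intron starts GT and ends AG. Donor 9-mers are drawn
from a strong-consensus PWM or, for a planted weak fraction (10%), a
GT-invariant degenerate PWM; draws are rejection-sampled into disjoint
score ranges (strong >= 6 bits, weak <= 1 bit against the strong PWM) so
the strength classes are separable. Weak-site introns also get GC
planted closer to exonic levels (0.50), mirroring the association
between retention and exon-like GC.

Retention is decided per transcript molecule: each molecule retains or
splices each intron independently. The per-condition probability
combines two mechanisms, `p = 1 - (1 - p_ret)(1 - p_res)`:

* *retention* `p_ret`: 0.02 baseline in control; under depletion a
  monotone decreasing logistic map of the planted donor score (midpoint
  3.5 bits, width 0.8) rising to 0.30 for weak sites — weak-5'ss introns
  are preferentially retained;
* *co-transcriptional residual* `p_res`: 0.04 at the first intron,
  geometrically interpolated to 0.04 x gradient at the last (gradient
  4.0 in control, attenuated to 1.2 under depletion). The intronic
  background level in unaffected introns is this exposed parameter.

A truth table records every planted quantity, including the effective
per-condition totals, the per-gene planted cotx ratio, and a `true_ri`
flag (planted intronic signal at least doubling under depletion).

Fragments per molecule are Poisson with mean proportional to molecule
length, so per-base coverage is uniform along each molecule as in real
RNA-seq — without this, intron coverage relative to exons would
underestimate retention by the molecule-length ratio. Molecules shorter
than the fragment length are skipped with a warning. Alignments are
emitted directly as coordinate-sorted BAM (alignment itself is out of
scope); spliced fragments carry N-gapped CIGARs.

Crosslink tracks place Poisson peaks at fixed offsets from splice sites
(amplitude x library depth) over a uniform gene-body background. The
default planted peak set is occupancy-balanced across conditions —
reduced at 5'ss −20 (ratio 0.3), unchanged at 5'ss −50, increased at the
3'ss boundary — modeling redistribution of spliceosome contacts rather
than net loss, so that total crosslink counts track sequencing depth and
the per-million normalization stays interpretable. An unbalanced planted
set would make every per-million value condition-confounded, which is a
real hazard of this normalization on real data too.

All three generators are byte-deterministic given the seed; per-sample
and per-stage streams are derived from the root seed.

### What the synthetic validation does not show

The generator omits sequencing errors, PCR duplicates, multi-mapping,
alternative transcript ends, NMD, and expression-level variation between
genes beyond depth factors. Detection performance on the planted data
(recall ~1 at the planted 5-fold intronic increase) therefore bounds
behavior under ideal mapping, not on real tissue data where dispersion
trends, mappability, and annotation errors matter. The calibration and
oracle-equivalence results, by contrast, are properties of the
statistics themselves and transfer directly.

## Validation experiments and problem sizes

`intronlens.validation` (exercised by `scripts/acceptance.py` and
`tests/test_acceptance.py`) runs: retention recovery on 2000 introns
(400 six-exon genes, 300 fragments/gene/sample; ~1 min), null
calibration on 2000 NB features (~10 s), cotx-gradient recovery on 500
genes (~1 min), iCLIP peak recovery on 1000 junctions (~10 s), and a
double run of the full pipeline for byte-identity (~15 s). Sizes were
chosen so each estimate's Monte-Carlo error is small against its
acceptance band while the whole run stays within a few minutes on one
CPU.

## Known limitations

* The acceptor 23-mer cannot use the enumerated maxent model; a
  factorized (chain) approximation would close this gap.
* Per-feature dispersion moderation uses a single across-feature median
  rather than a mean-dependent trend; with strongly mean-dependent
  dispersion a trend fit (behind the existing flag surface) would be
  preferable.
* The cotx ratio inherits coverage edge effects at terminal exons
  (fragment-length ramps at molecule ends); these largely cancel between
  first and last introns but are not modeled explicitly.
* `dexseq-count`-style counting is re-implemented from its documented
  semantics (overlap >= 1 base, fragment-level); no attempt is made to
  clone DEXSeq's numerics — equivalence is claimed only at the level of
  calibration properties.
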