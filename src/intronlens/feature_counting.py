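"""Fragment counting into exon/intron bins, size factors, normalization.

A *fragment* is a properly paired read pair (mates merged by name); it is
counted once for every feature whose interval it overlaps by at least one
aligned base.  Gapped (N-CIGAR) segments of spliced reads do not overlap
the skipped intron.  Library size factors are estimated from exon bins
only — intron counts are too sparse and condition-dependent to normalize
on (the whole point of the analysis is that they change).

Normalized intron expression:

    mu_i = ((c_i / l_i) / (c_g / l_g)) * (1e9 / N)

with c_i/l_i the intron's count/length, c_g/l_g the gene's exonic
count/length and N the library size (total counted fragments).

FPKM = c_g / ((l_g/1e3) * (N/1e6)); a gene is "expressed" if FPKM > 1 in
at least one sample (strictly above 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .annotation_model import GeneModel, intron_id

logger = logging.getLogger(__name__)

EXON_KIND = "exon_bin"
INTRON_KIND = "intron"


@dataclass
class CountMatrix:
    """Feature x sample fragment counts plus per-sample metadata.

    ``features`` columns: feature_id, gene_id, kind, start, end, length.
    ``samples`` columns: sample_id, condition, library_size.
    ``counts``: DataFrame indexed by feature_id with one column per sample.
    ``size_factors``: Series indexed by sample_id (exon-derived), filled by
    :func:`exon_size_factors`.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def gene_exon_counts(self) -> pd.DataFrame:
        """Per-gene exonic fragment counts c_g (may exceed the sum of exon
        bins' counts is impossible here: a fragment counts once per gene)."""
        exon_rows = self.features[self.features.kind == EXON_KIND]
        gene_ids = exon_rows.gene_id.unique()
        # c_g was tallied separately during counting and stored as gene rows
        gene_rows = self.features[self.features.kind == "gene_exonic"]
        if not gene_rows.empty:
            return self.counts.loc[gene_rows.feature_id].set_axis(
                gene_rows.gene_id.values, axis=0
            )
        # fallback: sum of exon bins (upper-bounds double counting)
        sub = self.counts.loc[exon_rows.feature_id]
        return sub.groupby(exon_rows.gene_id.values).sum().loc[gene_ids]

    def gene_exonic_lengths(self) -> pd.Series:
        exon_rows = self.features[self.features.kind == EXON_KIND]
        return exon_rows.groupby("gene_id").length.sum()


def _fragment_blocks(reads: list[pysam.AlignedSegment]) -> list[tuple[int, int]]:
    """Union of aligned reference blocks of a fragment's reads."""
    blocks: list[tuple[int, int]] = []
    for r in reads:
        blocks.extend(r.get_blocks())
    blocks.sort()
    out: list[tuple[int, int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlaps(blocks: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(bs < end and be > start for bs, be in blocks)


def _usable(read: pysam.AlignedSegment, keep_duplicates: bool) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_duplicate and not keep_duplicates:
        return False
    # multi-mapped reads (NH > 1) are excluded, as with single-hit mapping
    if read.has_tag("NH") and read.get_tag("NH") > 1:
        return False
    return True


def count_features(
    bam_paths: dict[str, str],
    models: dict[str, GeneModel],
    sample_sheet: pd.DataFrame,
    keep_duplicates: bool = False,
) -> CountMatrix:
    """Count fragments into exon bins and introns for every sample.

    ``bam_paths`` maps sample_id -> coordinate-sorted, indexed BAM.
    ``sample_sheet`` needs columns sample_id, condition.

    A fragment overlapping a feature by >= 1 aligned base increments that
    feature once.  ``c_g`` (gene exonic count) is stored as a synthetic
    ``gene_exonic`` feature row per gene.  Library size = total counted
    fragments in the sample.
    """
    feat_rows = []
    for gid in sorted(models):
        m = models[gid]
        for i, (s, e) in enumerate(m.merged_exons):
            feat_rows.append(
                dict(feature_id=f"{gid}:E{i:03d}", gene_id=gid, kind=EXON_KIND,
                     start=s, end=e, length=e - s)
            )
        for i, (s, e) in enumerate(m.introns):
            feat_rows.append(
                dict(feature_id=intron_id(gid, i), gene_id=gid, kind=INTRON_KIND,
                     start=s, end=e, length=e - s)
            )
        feat_rows.append(
            dict(feature_id=f"{gid}:gene", gene_id=gid, kind="gene_exonic",
                 start=m.start, end=m.end, length=m.exonic_length)
        )
    features = pd.DataFrame(feat_rows)

    sample_ids = list(sample_sheet.sample_id)
    feat_index = {fid: i for i, fid in enumerate(features.feature_id)}
    counts_arr = np.zeros((len(features), len(sample_ids)), dtype=np.int64)
    lib_sizes: dict[str, int] = {}

    # per-gene feature lists resolved once, not per fragment
    gene_feats: dict[str, list[tuple[int, str, int, int]]] = {}
    for row in features.itertuples():
        if row.kind == "gene_exonic":
            continue
        gene_feats.setdefault(row.gene_id, []).append(
            (feat_index[row.feature_id], row.kind, row.start, row.end)
        )

    for col, sid in enumerate(sample_ids):
        path = bam_paths[sid]
        skipped = 0
        n_fragments = 0
        with pysam.AlignmentFile(path, "rb") as bam:
            bam_refs = set(bam.references)
            model_chroms = {m.chrom for m in models.values()}
            missing = model_chroms - bam_refs
            if missing:
                raise ValueError(
                    f"chromosomes in models absent from {path}: {sorted(missing)}"
                )
            for gid in sorted(models):
                m = models[gid]
                gene_row = feat_index[f"{gid}:gene"]
                frags: dict[str, list[pysam.AlignedSegment]] = {}
                for read in bam.fetch(m.chrom, m.start, m.end):
                    if not _usable(read, keep_duplicates):
                        skipped += 1
                        continue
                    frags.setdefault(read.query_name, []).append(read)
                for reads in frags.values():
                    blocks = _fragment_blocks(reads)
                    hit_any = False
                    gene_exonic = False
                    for fi, kind, fs, fe in gene_feats[gid]:
                        if _overlaps(blocks, fs, fe):
                            counts_arr[fi, col] += 1
                            hit_any = True
                            if kind == EXON_KIND:
                                gene_exonic = True
                    if gene_exonic:
                        counts_arr[gene_row, col] += 1
                    if hit_any:
                        n_fragments += 1
        lib_sizes[sid] = n_fragments
        if skipped:
            logger.info("%s: skipped %d unusable reads", sid, skipped)

    counts = pd.DataFrame(counts_arr, index=features.feature_id, columns=sample_ids)

    samples = sample_sheet.copy()
    samples["library_size"] = [lib_sizes[s] for s in sample_ids]
    return CountMatrix(features=features, samples=samples, counts=counts)


def exon_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors from exon-bin counts.

    Per sample: median over features of count / geometric-mean(count across
    samples); features with a zero in any sample are excluded.
    """
    exon_ids = cm.features.loc[cm.features.kind == EXON_KIND, "feature_id"]
    sub = cm.counts.loc[exon_ids].to_numpy(dtype=float)
    usable = (sub > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no exon bin has nonzero counts in every sample; "
            "a larger / deeper fixture is required for size factors"
        )
    sub = sub[usable]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    factors = pd.Series(np.median(ratios, axis=0), index=cm.counts.columns)
    cm.size_factors = factors
    return factors


def normalized_intron_expression(
    c_i: float, l_i: float, c_g: float, l_g: float, n: float
) -> float:
    """Normalized intron expression mu_i; NaN when the gene has no exonic
    signal (never 0 or inf)."""
    if l_i <= 0 or l_g <= 0 or n <= 0:
        raise ValueError("lengths and library size must be positive")
    if c_g == 0:
        return math.nan
    return ((c_i / l_i) / (c_g / l_g)) * (1e9 / n)


def normalized_intron_table(cm: CountMatrix) -> pd.DataFrame:
    """mu_i for every intron x sample (long format)."""
    introns = cm.features[cm.features.kind == INTRON_KIND]
    cg = cm.gene_exon_counts()
    lg = cm.gene_exonic_lengths()
    lib = cm.samples.set_index("sample_id").library_size
    rows = []
    for row in introns.itertuples():
        for sid in cm.counts.columns:
            n = int(lib[sid])
            rows.append(
                dict(
                    feature_id=row.feature_id,
                    gene_id=row.gene_id,
                    sample_id=sid,
                    mu=normalized_intron_expression(
                        cm.counts.at[row.feature_id, sid], row.length,
                        cg.at[row.gene_id, sid], lg[row.gene_id], n,
                    ),
                )
            )
    return pd.DataFrame(rows)


def gene_fpkm(c_g: float, l_g: float, n: float) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if l_g <= 0 or n <= 0:
        raise ValueError("exonic length and library size must be positive")
    return c_g / ((l_g / 1e3) * (n / 1e6))


def fpkm_table(cm: CountMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Per-gene FPKM per sample plus the 'expressed' flag (FPKM > threshold
    in at least one sample; strictly above)."""
    cg = cm.gene_exon_counts()
    lg = cm.gene_exonic_lengths()
    lib = cm.samples.set_index("sample_id").library_size
    fpkm = pd.DataFrame(index=cg.index, columns=cg.columns, dtype=float)
    for sid in cg.columns:
        fpkm[sid] = [gene_fpkm(cg.at[g, sid], lg[g], lib[sid]) for g in cg.index]
    out = fpkm.copy()
    out["expressed"] = (fpkm > threshold).any(axis=1)
    return out
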