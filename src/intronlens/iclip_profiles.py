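"""Junction-anchored iCLIP crosslink metaprofiles.

Crosslink tracks are single-nucleotide BED6 intervals (score = count of
crosslink events at that base).  Profiles are anchored at 5' or 3' splice
sites in transcript orientation: offset 0 is the first intronic base
(5'ss anchor) or the first exonic base (3'ss anchor); negative offsets
are upstream of the junction.

Two-step normalization, in this order:

1. each library's counts are scaled to events-per-million (1e6 / library
   size) so depths are comparable;
2. for each junction, all libraries' windows are divided by the maximum
   value across *all* libraries and offsets for that junction, bounding
   every profile in [0, 1] and weighting junctions equally.

The metaprofile is the per-offset mean across junctions, per library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_model import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class CrosslinkTrack:
    """Per-nucleotide crosslink counts for one library."""

    library_id: str
    condition: str
    replicate: str
    # (chrom, strand) -> {position: count}
    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return sum(c for d in self.counts.values() for c in d.values())

    def add(self, chrom: str, pos: int, strand: str, count: int) -> None:
        d = self.counts.setdefault((chrom, strand), {})
        d[pos] = d.get(pos, 0) + count


def load_crosslinks(
    bed_path: str, library_id: str, condition: str, replicate: str = "1"
) -> CrosslinkTrack:
    """Load a single-nucleotide BED6 crosslink file.

    Lines with interval width != 1 or unparseable fields are rejected and
    tallied in the log; duplicate positions are summed.  An empty usable
    file is an error.
    """
    track = CrosslinkTrack(library_id=library_id, condition=condition, replicate=replicate)
    rejected = 0
    with open(bed_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                score = int(float(parts[4]))
                strand = parts[5]
            except (IndexError, ValueError):
                rejected += 1
                continue
            if end - start != 1 or strand not in "+-" or score < 0:
                rejected += 1
                continue
            track.add(chrom, start, strand, score)
    if rejected:
        logger.warning("%s: rejected %d malformed BED lines", bed_path, rejected)
    if track.library_size == 0:
        raise ValueError(f"{bed_path}: no usable crosslink records")
    return track


def junction_positions(
    models: dict[str, GeneModel], anchor: str, gene_subset: set[str] | None = None
) -> list[tuple[str, str, str, int]]:
    """(junction_id, chrom, strand, genomic anchor position) per intron.

    The anchor position is the base at offset 0 in transcript orientation:
    first intronic base for the 5'ss, first exonic base for the 3'ss.
    """
    out = []
    for gid in sorted(models):
        if gene_subset is not None and gid not in gene_subset:
            continue
        m = models[gid]
        for i, (istart, iend) in enumerate(m.introns):
            if anchor == "5ss":
                pos = istart if m.strand == "+" else iend - 1
            elif anchor == "3ss":
                pos = iend if m.strand == "+" else istart - 1
            else:
                raise ValueError("anchor must be '5ss' or '3ss'")
            out.append((f"{gid}:I{i:03d}", m.chrom, m.strand, pos))
    return out


def _window_counts(
    track: CrosslinkTrack, chrom: str, strand: str, anchor_pos: int, window: int
) -> np.ndarray:
    """Raw counts at transcript-orientation offsets [-W, W]."""
    vals = np.zeros(2 * window + 1)
    d = track.counts.get((chrom, strand), {})
    if not d:
        return vals
    for off in range(-window, window + 1):
        gpos = anchor_pos + off if strand == "+" else anchor_pos - off
        c = d.get(gpos)
        if c:
            vals[off + window] = c
    return vals


@dataclass
class Metaprofile:
    anchor: str
    window: int
    # library_id -> per-offset mean profile, offsets -W..W
    values: dict[str, np.ndarray]
    conditions: dict[str, str]
    n_junctions: int

    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def at_offset(self, library_id: str, offset: int) -> float:
        if abs(offset) > self.window:
            raise ValueError(f"offset {offset} outside window ±{self.window}")
        return float(self.values[library_id][offset + self.window])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lib, vals in self.values.items():
            for off, v in zip(self.offsets(), vals):
                rows.append(dict(anchor=self.anchor, offset=int(off),
                                 library=lib, condition=self.conditions[lib],
                                 value=float(v), n_junctions=self.n_junctions))
        return pd.DataFrame(rows)


def junction_metaprofile(
    tracks: list[CrosslinkTrack],
    models: dict[str, GeneModel],
    anchor: str = "5ss",
    window: int = 100,
    contig_lengths: dict[str, int] | None = None,
    gene_subset: set[str] | None = None,
    _return_matrix: bool = False,
):
    """Doubly normalized junction-anchored metaprofile per library.

    See module docstring for the normalization.  Junctions whose window
    overlaps a contig end are dropped (requires ``contig_lengths``).
    """
    juncs = junction_positions(models, anchor, gene_subset)
    if contig_lengths is not None:
        kept = []
        for j in juncs:
            _, chrom, _, pos = j
            if pos - window >= 0 and pos + window < contig_lengths[chrom]:
                kept.append(j)
            else:
                logger.info("junction %s window overlaps contig end; dropped", j[0])
        juncs = kept
    if not juncs:
        raise ValueError("no junctions available for profiling")

    lib_ids = [t.library_id for t in tracks]
    scale = {t.library_id: 1e6 / t.library_size for t in tracks}
    # matrix: junction x library x offset, after both normalization steps
    mat = np.zeros((len(juncs), len(tracks), 2 * window + 1))
    for ji, (_, chrom, strand, pos) in enumerate(juncs):
        for li, t in enumerate(tracks):
            mat[ji, li] = _window_counts(t, chrom, strand, pos, window) * scale[t.library_id]
        jmax = mat[ji].max()
        if jmax > 0:
            mat[ji] /= jmax
    profile = Metaprofile(
        anchor=anchor, window=window,
        values={lib: mat[:, li].mean(axis=0) for li, lib in enumerate(lib_ids)},
        conditions={t.library_id: t.condition for t in tracks},
        n_junctions=len(juncs),
    )
    if _return_matrix:
        return profile, mat, [j[0] for j in juncs]
    return profile


def expression_filtered_profile(
    tracks: list[CrosslinkTrack],
    models: dict[str, GeneModel],
    excluded_genes: set[str],
    anchor: str = "5ss",
    window: int = 100,
    contig_lengths: dict[str, int] | None = None,
) -> Metaprofile:
    """Metaprofile restricted to junctions of non-excluded genes."""
    unknown = excluded_genes - set(models)
    if unknown:
        raise ValueError(f"excluded genes not in models: {sorted(unknown)[:5]}")
    keep = set(models) - excluded_genes
    if not keep:
        raise ValueError("all genes excluded: no junctions to profile")
    return junction_metaprofile(
        tracks, models, anchor=anchor, window=window,
        contig_lengths=contig_lengths, gene_subset=keep,
    )


def compare_profiles(
    tracks: list[CrosslinkTrack],
    models: dict[str, GeneModel],
    condition_a: str,
    condition_b: str,
    peak_offsets: list[int],
    anchor: str = "5ss",
    window: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
    contig_lengths: dict[str, int] | None = None,
    gene_subset: set[str] | None = None,
) -> pd.DataFrame:
    """Amplitude ratio condition B / condition A at named peak offsets.

    Condition profiles are replicate means; the 95% CI comes from
    resampling junctions with replacement (seeded).
    """
    profile, mat, _ = junction_metaprofile(
        tracks, models, anchor=anchor, window=window,
        contig_lengths=contig_lengths, gene_subset=gene_subset,
        _return_matrix=True,
    )
    for off in peak_offsets:
        if abs(off) > window:
            raise ValueError(f"offset {off} outside window ±{window}")
    lib_ids = [t.library_id for t in tracks]
    cols_a = [i for i, t in enumerate(tracks) if t.condition == condition_a]
    cols_b = [i for i, t in enumerate(tracks) if t.condition == condition_b]
    if not cols_a or not cols_b:
        raise ValueError("both conditions need >= 1 library")

    rng = np.random.default_rng(seed)
    n_j = mat.shape[0]
    rows = []
    # per-junction condition means, then junction means -> ratio
    mean_a = mat[:, cols_a].mean(axis=1)  # junction x offset
    mean_b = mat[:, cols_b].mean(axis=1)
    boot_idx = rng.integers(0, n_j, size=(n_boot, n_j))
    for off in peak_offsets:
        col = off + window
        a, b = mean_a[:, col], mean_b[:, col]
        ratio = b.mean() / a.mean() if a.mean() > 0 else np.nan
        boots = []
        for idx in boot_idx:
            am = a[idx].mean()
            if am > 0:
                boots.append(b[idx].mean() / am)
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
        rows.append(dict(anchor=anchor, offset=off, ratio=float(ratio),
                         ci_lo=float(lo), ci_hi=float(hi),
                         n_junctions=n_j, n_boot=len(boots)))
    return pd.DataFrame(rows)
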