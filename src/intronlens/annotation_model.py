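"""Gene models: merged exons, derived introns, splice-site windows.

Every downstream stage works off :class:`GeneModel`: the union of all
(protein-coding) transcript exons of a gene, with introns defined as the
gaps between consecutive merged exons.  Intron order is transcriptional,
so on the minus strand the "first" intron is the one with the largest
genomic coordinate.

Coordinates are 0-based half-open internally; GTF I/O converts to/from
1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: donor window: last 3 exonic + first 6 intronic nucleotides
DONOR_EXON, DONOR_INTRON = 3, 6
#: acceptor window: last 20 intronic + first 3 exonic nucleotides
ACCEPTOR_INTRON, ACCEPTOR_EXON = 20, 3


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene's merged-exon / derived-intron structure.

    ``merged_exons`` and ``introns`` are genomic-coordinate-sorted lists of
    ``(start, end)`` half-open intervals.  Transcriptional order of introns
    is genomic order on "+" and reversed genomic order on "-".
    """

    gene_id: str
    chrom: str
    strand: str
    merged_exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...] = field(default=())
    n_transcripts: int = 1
    biotype: str = "protein_coding"

    @property
    def start(self) -> int:
        return self.merged_exons[0][0]

    @property
    def end(self) -> int:
        return self.merged_exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.merged_exons)

    def introns_transcriptional(self) -> list[tuple[int, int]]:
        """Introns ordered 5'→3' on the coding strand."""
        return list(self.introns) if self.strand == "+" else list(self.introns)[::-1]

    def intron_flanking_exons(self, intron: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
        """The merged exons immediately left and right (genomic) of an intron."""
        i = self.introns.index(intron)
        return self.merged_exons[i], self.merged_exons[i + 1]


@dataclass(frozen=True)
class SpliceSiteSeq:
    """A splice-site sequence window in coding-strand orientation.

    Donor = 9-mer (3 exonic + 6 intronic nt), acceptor = 23-mer
    (20 intronic + 3 exonic nt).
    """

    site_kind: str  # "donor" | "acceptor"
    sequence: str
    intron_id: str

    def __post_init__(self):
        expected = 9 if self.site_kind == "donor" else 23
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.site_kind} site must be {expected} nt, got {len(self.sequence)}"
            )

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and coalesced (touching merge)."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def introns_from_exons(merged: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(merged[i][1], merged[i + 1][0]) for i in range(len(merged) - 1)]


def build_gene_models(
    gtf_path: str, biotype: str | None = "protein_coding"
) -> dict[str, GeneModel]:
    """Build per-gene merged-exon models from an Ensembl-dialect GTF.

    Exons of all transcripts of the requested biotype are unioned per gene;
    introns are the gaps between consecutive merged exons.  Genes whose
    transcripts sit on both strands are rejected (logged).
    """
    gr = pr.read_gtf(gtf_path)
    df = gr.df
    exons = df[df.Feature == "exon"].copy()
    if biotype is not None and "gene_biotype" in exons.columns:
        exons = exons[exons.gene_biotype == biotype]
    models: dict[str, GeneModel] = {}
    for gene_id, sub in exons.groupby("gene_id", sort=True, observed=True):
        strands = set(sub.Strand)
        if len(strands) != 1:
            logger.warning("gene %s has transcripts on both strands; rejected", gene_id)
            continue
        chroms = set(sub.Chromosome)
        if len(chroms) != 1:
            logger.warning("gene %s spans multiple chromosomes; rejected", gene_id)
            continue
        merged = tuple(merge_intervals(zip(sub.Start, sub.End)))
        n_tx = sub.transcript_id.nunique() if "transcript_id" in sub.columns else 1
        bt = sub.gene_biotype.iloc[0] if "gene_biotype" in sub.columns else "unknown"
        models[str(gene_id)] = GeneModel(
            gene_id=str(gene_id),
            chrom=str(sub.Chromosome.iloc[0]),
            strand=str(sub.Strand.iloc[0]),
            merged_exons=merged,
            introns=tuple(introns_from_exons(merged)),
            n_transcripts=int(n_tx),
            biotype=str(bt),
        )
    return models


def select_cotx_genes(
    models: dict[str, GeneModel], min_span: int = 300
) -> dict[str, GeneModel]:
    """Gene subset eligible for the co-transcriptional splicing ratio.

    Keeps genes that (1) have a single annotated transcript, (2) have at
    least two introns, (3) span >= ``min_span`` bp (library size selection
    would otherwise miss the transcript), and (4) do not overlap any other
    gene on either strand.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models.values():
        by_chrom.setdefault(m.chrom, []).append(m)
    overlapping: set[str] = set()
    for chrom_models in by_chrom.values():
        chrom_models.sort(key=lambda m: m.start)
        for a, b in zip(chrom_models, chrom_models[1:]):
            if b.start < a.end:
                overlapping.add(a.gene_id)
                overlapping.add(b.gene_id)
    out = {}
    for gid, m in models.items():
        if (
            m.n_transcripts == 1
            and len(m.introns) >= 2
            and m.span >= min_span
            and gid not in overlapping
        ):
            out[gid] = m
    return out


def intron_id(gene_id: str, index: int) -> str:
    """Stable intron identifier; ``index`` is genomic order within the gene."""
    return f"{gene_id}:I{index:03d}"


def extract_splice_sites(
    models: dict[str, GeneModel] | Iterable[GeneModel],
    genome: Fasta | str,
    kinds: tuple[str, ...] = ("donor", "acceptor"),
) -> list[SpliceSiteSeq]:
    """Extract donor (9-mer) and acceptor (23-mer) windows for every intron.

    Sequences are reported in coding-strand orientation (reverse-complemented
    on "-" strand genes).  Sites whose window overlaps a contig end are
    dropped with a log message.
    """
    if isinstance(genome, str):
        genome = Fasta(genome)
    if isinstance(models, dict):
        models = models.values()
    sites: list[SpliceSiteSeq] = []
    for m in models:
        contig = genome[m.chrom]
        clen = len(contig)
        for idx, (istart, iend) in enumerate(m.introns):
            iid = intron_id(m.gene_id, idx)
            if m.strand == "+":
                donor_win = (istart - DONOR_EXON, istart + DONOR_INTRON)
                accept_win = (iend - ACCEPTOR_INTRON, iend + ACCEPTOR_EXON)
            else:
                # on "-" the donor is at the genomic *end* of the intron
                donor_win = (iend - DONOR_INTRON, iend + DONOR_EXON)
                accept_win = (istart - ACCEPTOR_EXON, istart + ACCEPTOR_INTRON)
            for kind, (ws, we) in (("donor", donor_win), ("acceptor", accept_win)):
                if kind not in kinds:
                    continue
                if ws < 0 or we > clen:
                    logger.warning(
                        "%s %s window [%d,%d) overlaps contig end; dropped", iid, kind, ws, we
                    )
                    continue
                seq = str(contig[ws:we]).upper()
                if m.strand == "-":
                    seq = reverse_complement(seq)
                sites.append(SpliceSiteSeq(site_kind=kind, sequence=seq, intron_id=iid))
    return sites


def models_to_gtf(models: Iterable[GeneModel], path: str, source: str = "intronlens") -> None:
    """Write models as Ensembl-dialect GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start)):
            attrs_g = f'gene_id "{m.gene_id}"; gene_biotype "{m.biotype}";'
            fh.write(
                f"{m.chrom}\t{source}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs_g}\n"
            )
            for t in range(m.n_transcripts):
                tid = f"{m.gene_id}.t{t + 1}"
                attrs_t = (
                    f'gene_id "{m.gene_id}"; transcript_id "{tid}"; '
                    f'gene_biotype "{m.biotype}";'
                )
                fh.write(
                    f"{m.chrom}\t{source}\ttranscript\t{m.start + 1}\t{m.end}\t.\t"
                    f"{m.strand}\t.\t{attrs_t}\n"
                )
                for s, e in m.merged_exons:
                    fh.write(
                        f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs_t}\n"
                    )


def models_to_table(models: Iterable[GeneModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        rows.append(
            dict(
                gene_id=m.gene_id,
                chrom=m.chrom,
                strand=m.strand,
                start=m.start,
                end=m.end,
                n_exons=len(m.merged_exons),
                n_introns=len(m.introns),
                n_transcripts=m.n_transcripts,
                biotype=m.biotype,
            )
        )
    return pd.DataFrame(rows)
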