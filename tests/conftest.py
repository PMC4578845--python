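import logging

import pandas as pd
import pytest

from intronlens.synthetic_data import (
    SyntheticConfig,
    generate_genome_annotation,
    simulate_crosslinks,
    simulate_rnaseq,
    write_annotation,
    write_genome_fasta,
)

logging.getLogger("intronlens").setLevel(logging.ERROR)


def write_gtf(path, rows):
    """rows: (chrom, feature, start1, end1, strand, attrs) in 1-based inclusive."""
    with open(path, "w") as fh:
        for chrom, feature, s, e, strand, attrs in rows:
            fh.write(f"{chrom}\ttest\t{feature}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")


def gene_rows(gene_id, chrom, strand, exons1, biotype="protein_coding", tx="t1"):
    """GTF rows for one single-transcript gene; exons1 are 1-based inclusive."""
    attrs = (f'gene_id "{gene_id}"; transcript_id "{gene_id}.{tx}"; '
             f'gene_biotype "{biotype}";')
    lo = min(s for s, _ in exons1)
    hi = max(e for _, e in exons1)
    rows = [(chrom, "gene", lo, hi, strand, f'gene_id "{gene_id}"; gene_biotype "{biotype}";'),
            (chrom, "transcript", lo, hi, strand, attrs)]
    rows += [(chrom, "exon", s, e, strand, attrs) for s, e in exons1]
    return rows


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """One small simulated dataset shared by read-level tests."""
    out = tmp_path_factory.mktemp("synth")
    cfg = SyntheticConfig(n_genes=12, mean_coverage=120, seed=5)
    genome, models, truth = generate_genome_annotation(cfg)
    write_genome_fasta(genome, str(out / "genome.fa"), cfg.chrom_name)
    write_annotation(models, str(out / "annotation.gtf"))
    bams = simulate_rnaseq(genome, models, truth, cfg, str(out))
    beds = simulate_crosslinks(models, cfg, str(out))
    sheet = pd.DataFrame(
        [dict(sample_id=s, condition=c) for s, c in cfg.sample_ids()]
    )
    return dict(cfg=cfg, genome=genome, models=models, truth=truth,
                bams=bams, beds=beds, sheet=sheet, dir=out)
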