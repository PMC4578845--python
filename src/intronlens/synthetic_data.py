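"""Synthetic genome, RNA-seq and iCLIP generator with planted effects.

The generator emulates the statistical structure of a spliceosome-factor
depletion experiment on multi-exon genes:

* two conditions (default 3 control vs 4 depleted replicates) of 100 bp
  paired-end RNA-seq coverage;
* condition-dependent intron retention whose probability under depletion
  is a monotone decreasing function of the intron's planted 5' splice-site
  strength (weak-site introns are preferentially retained) and whose GC
  content is planted closer to exonic levels;
* a 5'->3' gradient of residual (not-yet-spliced) intron coverage that
  encodes co-transcriptional splicing, attenuated under depletion;
* iCLIP crosslink tracks with Poisson peaks at fixed offsets from splice
  sites whose amplitudes differ between conditions.

Every planted parameter is recorded in a truth table so that recovery
tests can compare estimates against ground truth.  All outputs are
byte-deterministic for a fixed seed.

Retention is decided per transcript molecule: each simulated molecule
independently retains or splices each intron, and fragments are drawn
from molecules, which is how intronic reads arise in poly(A) RNA-seq.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

from .annotation_model import (
    GeneModel,
    intron_id,
    introns_from_exons,
    models_to_gtf,
    reverse_complement,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

# positional base probabilities of a strong donor 9-mer (3 exonic + 6
# intronic positions); GT at +1/+2 is invariant
STRONG_DONOR_PWM = np.array(
    [
        [0.33, 0.37, 0.18, 0.12],  # -3  (A C G T)
        [0.60, 0.13, 0.12, 0.15],  # -2
        [0.09, 0.05, 0.79, 0.07],  # -1
        [0.00, 0.00, 1.00, 0.00],  # +1 G
        [0.00, 0.00, 0.00, 1.00],  # +2 T
        [0.59, 0.03, 0.34, 0.04],  # +3
        [0.71, 0.08, 0.12, 0.09],  # +4
        [0.07, 0.06, 0.81, 0.06],  # +5
        [0.16, 0.17, 0.20, 0.47],  # +6
    ]
)

# weak donors keep the invariant GT but are near-uniform elsewhere
WEAK_DONOR_PWM = np.array(
    [
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
        [0.00, 0.00, 1.00, 0.00],
        [0.00, 0.00, 0.00, 1.00],
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
        [0.25, 0.25, 0.25, 0.25],
    ]
)

# acceptor: polypyrimidine tract then invariant AG, then 3 exonic nt
PPT_PROBS = np.array([0.08, 0.34, 0.08, 0.50])  # A C G T


def donor_log_odds(seq: str) -> float:
    """Planted-strength score of a donor 9-mer: log2 odds of the strong
    PWM versus uniform background (pseudo-floored)."""
    score = 0.0
    for i, ch in enumerate(seq):
        p = max(STRONG_DONOR_PWM[i, BASES.index(ch)], 1e-3)
        score += math.log2(p / 0.25)
    return score


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults are the conditions the pipeline is validated under: a
    7-sample two-condition design (3 control + 4 depleted), 100 bp
    paired-end fragments, a low baseline retention in control, strongly
    elevated retention of weak-5'ss introns under depletion, a 4x
    co-transcriptional residual-coverage gradient in control attenuated
    to 1.2x under depletion, and a depleted/control iCLIP peak amplitude
    ratio of 0.3 at -20 nt from the 5' splice site with an unchanged
    control peak at -50 nt.
    """

    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (200, 1200)
    gc_exon: float = 0.52
    gc_intron: float = 0.42
    gc_intron_retained: float = 0.50
    mean_coverage: float = 300.0  # fragments per gene per sample
    conditions: tuple[tuple[str, int], ...] = (("control", 3), ("depleted", 4))
    retention_base: float = 0.02
    retention_depleted_max: float = 0.30
    retention_score_mid: float = 3.5  # bits; sigmoid midpoint of the map
    retention_score_width: float = 0.8
    weak_fraction: float = 0.10
    # planted score ranges (bits): donors are resampled until their class
    # lands in its range, keeping the strength classes separable
    weak_score_max: float = 1.0
    strong_score_min: float = 6.0
    cotx_residual_base: float = 0.04  # first-intron residual retention
    cotx_gradient: dict = field(
        default_factory=lambda: {"control": 4.0, "depleted": 1.2}
    )
    # peak amplitudes are balanced across conditions in total (occupancy
    # lost at the 5'ss -20 peak redistributes to the 3'ss boundary), so
    # library size reflects sequencing depth rather than condition
    clip_peaks: tuple = (
        ("5ss", -20, {"control": 10.0, "depleted": 3.0}),
        ("5ss", -50, {"control": 6.0, "depleted": 6.0}),
        ("3ss", 0, {"control": 4.0, "depleted": 11.0}),
    )
    clip_background: float = 0.05  # Poisson rate per genic nt per library
    clip_window: int = 100
    fragment_len: int = 250
    read_len: int = 100
    intergenic_len: int = 800
    depth_factors: tuple[float, ...] = (1.0, 0.6, 1.4, 0.8, 1.2, 0.7, 1.3)
    chrom_len: int | None = None  # None = sized to fit
    chrom_name: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        for p in (
            self.gc_exon, self.gc_intron, self.gc_intron_retained,
            self.retention_base, self.retention_depleted_max,
            self.weak_fraction, self.cotx_residual_base,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/fraction {p} outside [0, 1]")
        for _, reps in self.conditions:
            if reps < 2:
                raise ValueError("each condition needs >= 2 replicates")
        if self.read_len * 2 > self.fragment_len:
            raise ValueError("fragment_len must be >= 2 * read_len")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def retention_depleted(self, donor_score: float) -> float:
        """Monotone decreasing map: 5'ss strength (bits) -> retention
        probability under depletion."""
        lo, hi = self.retention_base, self.retention_depleted_max
        sig = 1.0 / (1.0 + math.exp((donor_score - self.retention_score_mid)
                                    / self.retention_score_width))
        return lo + (hi - lo) * sig

    def sample_ids(self) -> list[tuple[str, str]]:
        """[(sample_id, condition)] in fixed order."""
        out = []
        for cond, reps in self.conditions:
            for r in range(1, reps + 1):
                out.append((f"{cond}_{r}", cond))
        return out

    def to_text(self) -> str:
        lines = []
        for key, val in asdict(self).items():
            lines.append(f"{key} = {val!r}")
        return "\n".join(lines) + "\n"


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside the synthetic data."""

    introns: pd.DataFrame  # one row per intron
    genes: pd.DataFrame  # one row per gene x condition (planted cotx ratio)
    peaks: pd.DataFrame  # planted crosslink peak amplitudes

    def write(self, prefix: str) -> None:
        self.introns.to_csv(f"{prefix}.introns.tsv", sep="\t", index=False)
        self.genes.to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
        self.peaks.to_csv(f"{prefix}.peaks.tsv", sep="\t", index=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _sample_pwm(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, p=row / row.sum())] for row in pwm)


def _sample_donor(rng: np.random.Generator, weak: bool, config: SyntheticConfig) -> str:
    """Draw a donor 9-mer from the class PWM, rejection-sampled into the
    class's planted score range so strength classes stay separable."""
    pwm = WEAK_DONOR_PWM if weak else STRONG_DONOR_PWM
    for _ in range(1000):
        donor = _sample_pwm(rng, pwm)
        score = donor_log_odds(donor)
        if weak and score <= config.weak_score_max:
            return donor
        if not weak and score >= config.strong_score_min:
            return donor
    raise RuntimeError("could not sample a donor in the requested score range")


def generate_genome_annotation(
    config: SyntheticConfig,
) -> tuple[str, dict[str, GeneModel], TruthTable]:
    """Generate the genome sequence, gene models and truth table.

    Genes are laid out non-overlapping along one chromosome, alternating
    strand.  Each intron starts GT and ends AG; donor windows are drawn
    from a strong consensus PWM or, for the planted weak fraction, from a
    degenerate consensus.  Returns (genome sequence, models, truth).
    """
    config.validate()
    rng = _rng(config.seed, 0)

    genes: dict[str, GeneModel] = {}
    layouts: list[tuple[str, int, list[int], list[int]]] = []
    cursor = config.intergenic_len
    for g in range(config.n_genes):
        gid = f"SYNG{g + 1:05d}"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
                     for _ in range(n_exons)]
        intron_lens = [int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
                       for _ in range(n_exons - 1)]
        strand = "+" if g % 2 == 0 else "-"
        span = sum(exon_lens) + sum(intron_lens)
        exon_starts = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exon_starts.append(pos)
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        merged = tuple((s, s + l) for s, l in zip(exon_starts, exon_lens))
        genes[gid] = GeneModel(
            gene_id=gid, chrom=config.chrom_name, strand=strand,
            merged_exons=merged, introns=tuple(introns_from_exons(merged)),
            n_transcripts=1, biotype="protein_coding",
        )
        layouts.append((gid, cursor, exon_lens, intron_lens))
        cursor += span + config.intergenic_len

    total_len = cursor
    if config.chrom_len is not None:
        if total_len > config.chrom_len:
            raise ValueError(
                f"infeasible layout: {config.n_genes} genes need {total_len} bp "
                f"but chrom_len={config.chrom_len}; genes cannot be placed "
                "without overlap"
            )
        total_len = config.chrom_len

    # base sequence, intergenic composition ~45% GC
    seq = _random_bases(rng, total_len, 0.45)

    intron_rows = []
    for gid, _, _, _ in layouts:
        m = genes[gid]
        # exon composition
        for s, e in m.merged_exons:
            seq[s:e] = _random_bases(rng, e - s, config.gc_exon)
        # introns: weak/strong class drawn per intron
        introns_tx = m.introns_transcriptional()
        for gi, (istart, iend) in enumerate(m.introns):
            weak = bool(rng.random() < config.weak_fraction)
            gc = config.gc_intron_retained if weak else config.gc_intron
            seq[istart:iend] = _random_bases(rng, iend - istart, gc)
            # donor / acceptor windows in coding-strand orientation;
            # donors are resampled into their class's score range
            donor = _sample_donor(rng, weak, config)
            ppt = "".join(BASES[i] for i in rng.choice(4, size=18, p=PPT_PROBS))
            acceptor = ppt + "AG" + "".join(BASES[i] for i in rng.choice(4, size=3))
            _write_sites(seq, m, istart, iend, donor, acceptor)
            score = donor_log_odds(donor)
            p_ret_control = config.retention_base
            p_ret_depleted = config.retention_depleted(score)
            tx_idx = introns_tx.index((istart, iend))
            intron_rows.append(
                dict(
                    intron_id=intron_id(gid, gi), gene_id=gid,
                    genomic_index=gi, tx_index=tx_idx,
                    start=istart, end=iend, length=iend - istart,
                    strength_class="weak" if weak else "strong",
                    donor_seq=donor, donor_score=score,
                    planted_gc=gc,
                    p_retention_control=p_ret_control,
                    p_retention_depleted=p_ret_depleted,
                )
            )

    introns_df = pd.DataFrame(intron_rows)
    introns_df = _add_total_probabilities(introns_df, genes, config)
    genes_df = _gene_truth(introns_df, config)
    peaks_df = pd.DataFrame(
        [dict(anchor=a, offset=o, **{f"amplitude_{c}": v for c, v in amps.items()})
         for a, o, amps in config.clip_peaks]
    )
    truth = TruthTable(introns=introns_df, genes=genes_df, peaks=peaks_df)
    genome = seq.tobytes().decode()
    return genome, genes, truth


def _write_sites(
    seq: np.ndarray, m: GeneModel, istart: int, iend: int, donor: str, acceptor: str
) -> None:
    """Overwrite splice-site windows (coding-strand 9-mer / 23-mer)."""
    if m.strand == "+":
        d = np.frombuffer(donor.encode(), dtype="S1")
        a = np.frombuffer(acceptor.encode(), dtype="S1")
        seq[istart - 3: istart + 6] = d
        seq[iend - 20: iend + 3] = a
    else:
        d = np.frombuffer(reverse_complement(donor).encode(), dtype="S1")
        a = np.frombuffer(reverse_complement(acceptor).encode(), dtype="S1")
        seq[iend - 6: iend + 3] = d
        seq[istart - 3: istart + 20] = a


def _total_p(p_ret: float, p_res: float) -> float:
    """Retention and residual (unspliced-yet) are independent mechanisms."""
    return 1.0 - (1.0 - p_ret) * (1.0 - p_res)


def _residual_p(config: SyntheticConfig, condition: str, tx_idx: int, n_introns: int) -> float:
    grad = config.cotx_gradient.get(condition, 1.0)
    if n_introns <= 1:
        return config.cotx_residual_base
    frac = tx_idx / (n_introns - 1)
    return config.cotx_residual_base * grad**frac


def _add_total_probabilities(
    introns_df: pd.DataFrame, genes: dict[str, GeneModel], config: SyntheticConfig
) -> pd.DataFrame:
    if introns_df.empty:
        cols = ["intron_id", "gene_id", "genomic_index", "tx_index", "start",
                "end", "length", "strength_class", "donor_seq", "donor_score",
                "planted_gc", "p_retention_control", "p_retention_depleted"]
        introns_df = pd.DataFrame(columns=cols)
    conds = [c for c, _ in config.conditions]
    n_introns = introns_df.groupby("gene_id").intron_id.transform("count")
    for cond in conds:
        p_ret = (introns_df.p_retention_control if cond == "control"
                 else introns_df.p_retention_depleted)
        p_res = [
            _residual_p(config, cond, t, n)
            for t, n in zip(introns_df.tx_index, n_introns)
        ]
        introns_df[f"p_total_{cond}"] = [
            _total_p(r, s) for r, s in zip(p_ret, p_res)
        ]
    if {"p_total_control", "p_total_depleted"} <= set(introns_df.columns):
        # a true RI is an intron whose planted intronic signal at least
        # doubles under depletion
        introns_df["true_ri"] = (
            introns_df.p_total_depleted >= 2.0 * introns_df.p_total_control
        )
    return introns_df


def _gene_truth(introns_df: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    if introns_df.empty:
        return pd.DataFrame(columns=["gene_id", "condition", "planted_cotx_ratio"])
    for gid, sub in introns_df.groupby("gene_id"):
        if len(sub) < 2:
            continue
        first = sub[sub.tx_index == sub.tx_index.min()].iloc[0]
        last = sub[sub.tx_index == sub.tx_index.max()].iloc[0]
        for cond, _ in config.conditions:
            p_last = last[f"p_total_{cond}"]
            # undefined when no intronic signal is planted at all
            ratio = first[f"p_total_{cond}"] / p_last if p_last > 0 else math.nan
            rows.append(
                dict(gene_id=gid, condition=cond, planted_cotx_ratio=ratio)
            )
    return pd.DataFrame(rows)


def write_genome_fasta(genome: str, path: str, chrom: str = "chr1", width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), width):
            fh.write(genome[i: i + width] + "\n")


def write_annotation(models: dict[str, GeneModel], path: str) -> None:
    models_to_gtf(models.values(), path)


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def _molecule_segments(
    m: GeneModel, retained: list[bool]
) -> list[tuple[int, int]]:
    """Genomic segments of a molecule: merged exons plus retained introns."""
    segs = [m.merged_exons[0]]
    for i, intr in enumerate(m.introns):
        if retained[i]:
            segs[-1] = (segs[-1][0], intr[1])  # extend through intron
            nxt = m.merged_exons[i + 1]
            segs[-1] = (segs[-1][0], nxt[1])
        else:
            segs.append(m.merged_exons[i + 1])
    # coalesce adjacent
    out = [segs[0]]
    for s, e in segs[1:]:
        if s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _map_to_genome(
    segs: list[tuple[int, int]], mol_start: int, length: int
) -> list[tuple[int, int]]:
    """Genomic blocks covered by a molecule-coordinate interval."""
    blocks = []
    pos = 0
    remaining_start = mol_start
    remaining_len = length
    for s, e in segs:
        seg_len = e - s
        if remaining_start >= seg_len:
            remaining_start -= seg_len
            continue
        take = min(seg_len - remaining_start, remaining_len)
        blocks.append((s + remaining_start, s + remaining_start + take))
        remaining_len -= take
        remaining_start = 0
        if remaining_len == 0:
            break
    return blocks


def _cigar_from_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            cig.append((3, s - blocks[i - 1][1]))  # N
        cig.append((0, e - s))  # M
    return cig


def simulate_rnaseq(
    genome: str,
    models: dict[str, GeneModel],
    truth: TruthTable,
    config: SyntheticConfig,
    out_dir: str,
) -> dict[str, str]:
    """Simulate coordinate-sorted, indexed BAMs per sample.

    Each sample draws Poisson(mean_coverage x depth factor) transcript
    molecules per gene; each molecule independently retains or splices
    each intron at the planted per-condition probability, and yields one
    paired-end fragment placed uniformly along the molecule.  Fragments
    longer than the molecule are skipped with a warning.  Returns
    sample_id -> BAM path.
    """
    config.validate()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom_name, "LN": len(genome)}],
    }
    p_by_intron = truth.introns.set_index("intron_id")
    paths: dict[str, str] = {}
    samples = config.sample_ids()
    for si, (sid, cond) in enumerate(samples):
        rng = _rng(config.seed, 1000 + si)
        depth = config.depth_factors[si % len(config.depth_factors)]
        records = []
        n_skipped = 0
        for gid in sorted(models):
            m = models[gid]
            n_int = len(m.introns)
            probs = np.array([
                p_by_intron.at[intron_id(gid, i), f"p_total_{cond}"]
                for i in range(n_int)
            ]) if n_int else np.empty(0)
            n_mol = rng.poisson(config.mean_coverage * depth)
            exonic_len = max(m.exonic_length, 1)
            for mol in range(n_mol):
                retained = (rng.random(n_int) < probs).tolist() if n_int else []
                segs = _molecule_segments(m, retained)
                mol_len = sum(e - s for s, e in segs)
                if mol_len < config.fragment_len:
                    n_skipped += 1
                    continue
                # fragments per molecule scale with its length, so per-base
                # coverage is uniform along every molecule (as in real
                # RNA-seq) and intron-body coverage over exon coverage
                # estimates the retention probability directly
                n_frag = rng.poisson(mol_len / exonic_len)
                for fi in range(n_frag):
                    fstart = int(rng.integers(0, mol_len - config.fragment_len + 1))
                    qname = f"{sid}:{gid}:{mol}:{fi}"
                    b1 = _map_to_genome(segs, fstart, config.read_len)
                    b2 = _map_to_genome(
                        segs, fstart + config.fragment_len - config.read_len,
                        config.read_len,
                    )
                    records.append((qname, b1, b2))
        if n_skipped:
            logger.warning(
                "%s: skipped %d molecules shorter than fragment length", sid, n_skipped
            )
        path = f"{out_dir}/sample_{sid}.bam"
        _write_bam(path, header, records, config)
        paths[sid] = path
    return paths


def _write_bam(path, header, records, config: SyntheticConfig) -> None:
    alns = []
    for qname, b1, b2 in records:
        r1 = pysam.AlignedSegment()
        r1.query_name = qname
        r1.reference_id = 0
        r1.reference_start = b1[0][0]
        r1.cigartuples = _cigar_from_blocks(b1)
        r1.flag = 0x1 | 0x2 | 0x40  # paired, proper, first
        r1.mapping_quality = 60
        r1.query_sequence = "A" * config.read_len
        r2 = pysam.AlignedSegment()
        r2.query_name = qname
        r2.reference_id = 0
        r2.reference_start = b2[0][0]
        r2.cigartuples = _cigar_from_blocks(b2)
        r2.flag = 0x1 | 0x2 | 0x80 | 0x10  # paired, proper, second, reverse
        r2.mapping_quality = 60
        r2.query_sequence = "A" * config.read_len
        r1.next_reference_id = 0
        r1.next_reference_start = r2.reference_start
        r2.next_reference_id = 0
        r2.next_reference_start = r1.reference_start
        tlen = b2[-1][1] - b1[0][0]
        r1.template_length = tlen
        r2.template_length = -tlen
        alns.extend([r1, r2])
    alns.sort(key=lambda r: (r.reference_start, r.query_name, r.flag))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in alns:
            bam.write(r)
    pysam.index(path)


# ---------------------------------------------------------------------------
# iCLIP simulation
# ---------------------------------------------------------------------------

def simulate_crosslinks(
    models: dict[str, GeneModel],
    config: SyntheticConfig,
    out_dir: str,
) -> dict[str, str]:
    """Simulate one BED6 crosslink track per library.

    At every intron junction, each configured peak contributes a Poisson
    count with mean amplitude x library depth factor at its fixed offset
    (transcript orientation); a uniform Poisson background covers every
    gene body on the transcribed strand.  Returns library_id -> BED path.
    """
    from .iclip_profiles import junction_positions

    paths: dict[str, str] = {}
    samples = config.sample_ids()
    for si, (sid, cond) in enumerate(samples):
        rng = _rng(config.seed, 2000 + si)
        depth = config.depth_factors[si % len(config.depth_factors)]
        events: dict[tuple[str, int, str], int] = {}
        # background across each gene body, transcribed strand
        for gid in sorted(models):
            m = models[gid]
            bg = rng.poisson(config.clip_background * depth, size=m.span)
            for i in np.nonzero(bg)[0]:
                key = (m.chrom, int(m.start + i), m.strand)
                events[key] = events.get(key, 0) + int(bg[i])
        for anchor in ("5ss", "3ss"):
            juncs = junction_positions(models, anchor)
            peaks = [(o, a.get(cond, 0.0)) for anc, o, a in config.clip_peaks
                     if anc == anchor]
            for _, chrom, strand, pos in juncs:
                for off, amp in peaks:
                    c = int(rng.poisson(amp * depth))
                    if c:
                        gpos = pos + off if strand == "+" else pos - off
                        key = (chrom, int(gpos), strand)
                        events[key] = events.get(key, 0) + c
        path = f"{out_dir}/clip_{sid}.bed"
        with open(path, "w") as fh:
            for (chrom, gpos, strand), count in sorted(events.items()):
                fh.write(f"{chrom}\t{gpos}\t{gpos + 1}\txl\t{count}\t{strand}\n")
        paths[sid] = path
    return paths
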