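"""Fragment counting semantics, size factors, normalization formulas."""

import math

import numpy as np
import pandas as pd
import pysam
import pytest

from intronlens.annotation_model import GeneModel, introns_from_exons
from intronlens.feature_counting import (
    CountMatrix,
    count_features,
    exon_size_factors,
    fpkm_table,
    gene_fpkm,
    normalized_intron_expression,
)


def make_bam(path, reads, chrom="chr1", length=10000):
    """reads: list of (qname, [(start, cigar)]) — one tuple per mate."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    alns = []
    for qname, mates in reads:
        for mi, (start, cigar) in enumerate(mates):
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = cigar
            a.flag = 0x1 | 0x2 | (0x40 if mi == 0 else 0x80 | 0x10)
            a.mapping_quality = 60
            a.query_sequence = "A" * sum(
                n for op, n in a.cigartuples if op in (0, 1, 4)
            )
            alns.append(a)
    alns.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for a in alns:
            bam.write(a)
    pysam.index(str(path))


@pytest.fixture
def two_exon_gene():
    merged = ((100, 300), (500, 700))
    return {
        "g1": GeneModel("g1", "chr1", "+", merged,
                        tuple(introns_from_exons(merged)))
    }


def run_count(tmp_path, models, reads):
    bam = tmp_path / "s.bam"
    make_bam(str(bam), reads)
    sheet = pd.DataFrame([dict(sample_id="s1", condition="c")])
    return count_features({"s1": str(bam)}, models, sheet)


def brute_force_counts(models, fragments):
    """Oracle: per-base coverage marking of each fragment's blocks."""
    out = {}
    for gid, m in models.items():
        feats = [(f"{gid}:E{i:03d}", s, e) for i, (s, e) in enumerate(m.merged_exons)]
        feats += [(f"{gid}:I{i:03d}", s, e) for i, (s, e) in enumerate(m.introns)]
        for fid, fs, fe in feats:
            n = 0
            for blocks in fragments:
                positions = set()
                for bs, be in blocks:
                    positions.update(range(bs, be))
                if positions & set(range(fs, fe)):
                    n += 1
            out[fid] = n
    return out


class TestCountingSemantics:
    def test_spliced_gap_does_not_touch_intron(self, tmp_path, two_exon_gene):
        # mate pair whose gap exactly spans the intron [300,500)
        reads = [("f1", [(200, "100M200N50M"), (550, "100M")])]
        cm = run_count(tmp_path, two_exon_gene, reads)
        assert cm.counts.at["g1:I000", "s1"] == 0
        assert cm.counts.at["g1:E000", "s1"] == 1
        assert cm.counts.at["g1:E001", "s1"] == 1
        assert cm.counts.at["g1:gene", "s1"] == 1

    def test_fragment_inside_intron(self, tmp_path, two_exon_gene):
        reads = [("f1", [(320, "100M"), (350, "100M")])]
        cm = run_count(tmp_path, two_exon_gene, reads)
        assert cm.counts.at["g1:I000", "s1"] == 1
        assert cm.counts.at["g1:gene", "s1"] == 0

    def test_boundary_straddling_fragment_counts_both(self, tmp_path, two_exon_gene):
        reads = [("f1", [(250, "100M"), (280, "100M")])]
        cm = run_count(tmp_path, two_exon_gene, reads)
        assert cm.counts.at["g1:E000", "s1"] == 1
        assert cm.counts.at["g1:I000", "s1"] == 1
        assert cm.counts.at["g1:gene", "s1"] == 1

    def test_matches_bruteforce_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        merged = ((0, 200), (400, 600), (900, 1100))
        models = {"g1": GeneModel("g1", "chr1", "+", merged,
                                  tuple(introns_from_exons(merged)))}
        reads, fragments = [], []
        for i in range(60):
            start = int(rng.integers(0, 1000))
            if rng.random() < 0.3:  # spliced over first intron
                cigar = "50M200N50M" if start < 150 else "50M"
                mates = [(start, cigar)]
            else:
                mates = [(start, "80M")]
            reads.append((f"r{i}", mates))
            blocks = []
            pos = start
            for op, n in pysam.AlignedSegment.fromstring(
                f"r\t0\tchr1\t{start + 1}\t60\t{mates[0][1]}\t*\t0\t0\t*\t*",
                pysam.AlignmentHeader.from_references(["chr1"], [10000]),
            ).cigartuples:
                if op == 0:
                    blocks.append((pos, pos + n))
                    pos += n
                elif op == 3:
                    pos += n
            fragments.append(blocks)
        cm = run_count(tmp_path, models, reads)
        oracle = brute_force_counts(models, fragments)
        for fid, n in oracle.items():
            assert cm.counts.at[fid, "s1"] == n

    def test_mates_merged_single_fragment(self, tmp_path, two_exon_gene):
        # both mates inside the same exon: fragment counted once
        reads = [("f1", [(120, "50M"), (180, "50M")])]
        cm = run_count(tmp_path, two_exon_gene, reads)
        assert cm.counts.at["g1:E000", "s1"] == 1


def _matrix(counts, conditions=("a", "b")):
    n_feat, n_samp = counts.shape
    features = pd.DataFrame(
        dict(feature_id=[f"f{i}" for i in range(n_feat)],
             gene_id=[f"g{i}" for i in range(n_feat)],
             kind=["exon_bin"] * n_feat,
             start=0, end=100, length=100)
    )
    samples = pd.DataFrame(
        dict(sample_id=[f"s{j}" for j in range(n_samp)],
             condition=list(conditions)[:n_samp],
             library_size=counts.sum(axis=0))
    )
    cdf = pd.DataFrame(counts, index=features.feature_id,
                       columns=samples.sample_id)
    return CountMatrix(features=features, samples=samples, counts=cdf)


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        cm = _matrix(np.array([[10, 20], [100, 200], [1, 2]]))
        sf = exon_size_factors(cm)
        assert sf["s0"] == pytest.approx(1 / math.sqrt(2), abs=1e-4)
        assert sf["s1"] == pytest.approx(math.sqrt(2), abs=1e-4)

    def test_identical_samples_give_unit_factors(self):
        cm = _matrix(np.array([[10, 10], [100, 100], [7, 7]]))
        assert np.allclose(exon_size_factors(cm), 1.0)

    def test_sample_permutation_symmetry(self):
        counts = np.array([[10, 20, 15], [100, 200, 150], [8, 16, 12]])
        sf = exon_size_factors(_matrix(counts, ("a", "a", "b"))).to_numpy()
        perm = [2, 0, 1]
        sf_p = exon_size_factors(
            _matrix(counts[:, perm], ("b", "a", "a"))
        ).to_numpy()
        assert np.allclose(sf[perm], sf_p)

    def test_scaling_one_sample_scales_its_factor(self):
        counts = np.array([[10, 20], [100, 200], [8, 16]])
        sf0 = exon_size_factors(_matrix(counts))
        scaled = counts.copy()
        scaled[:, 0] *= 3
        sf1 = exon_size_factors(_matrix(scaled))
        # ratio s0/s1 changes by exactly 3x
        assert sf1["s0"] / sf1["s1"] == pytest.approx(3 * sf0["s0"] / sf0["s1"])

    def test_all_zero_feature_error(self):
        cm = _matrix(np.array([[0, 5], [3, 0]]))
        with pytest.raises(ValueError, match="fixture"):
            exon_size_factors(cm)


class TestNormalizedExpression:
    def test_printed_formula_value(self):
        mu = normalized_intron_expression(10, 100, 400, 2000, 1e9)
        assert mu == pytest.approx(0.5, abs=1e-12)

    def test_zero_count_gives_zero(self):
        assert normalized_intron_expression(0, 100, 400, 2000, 1e6) == 0.0

    def test_doubling_library_size_halves_value(self):
        a = normalized_intron_expression(10, 100, 400, 2000, 1e6)
        b = normalized_intron_expression(10, 100, 400, 2000, 2e6)
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_zero_gene_count_is_missing_not_zero(self):
        assert math.isnan(normalized_intron_expression(10, 100, 0, 2000, 1e6))

    def test_count_ratio_scale_invariance(self):
        # the usage ratio (c_i/l_i)/(c_g/l_g) is depth-invariant; the
        # 1e9/N factor then scales the whole value by exactly 1/k when
        # depth (all counts and N) grows k-fold
        a = normalized_intron_expression(10, 100, 400, 2000, 1e6)
        b = normalized_intron_expression(70, 100, 2800, 2000, 7e6)
        assert b == pytest.approx(a / 7, rel=1e-12)


class TestFpkm:
    def test_printed_example(self):
        assert gene_fpkm(200, 2000, 1e6) == pytest.approx(100.0, abs=1e-12)

    def test_zero_counts(self):
        assert gene_fpkm(0, 2000, 1e6) == 0.0

    def test_exactly_one_not_expressed(self):
        # threshold is strictly "above 1"
        cm = _matrix(np.array([[10, 10]]))
        cm.features.loc[:, "length"] = 100
        cm.counts.loc["f0"] = [1, 1]
        cm.samples.loc[:, "library_size"] = [10000, 10000]
        # FPKM = 1/(0.1 * 0.01) ... build explicit: c=1, l=100, N=1e4
        # FPKM = 1 / (0.1 * 0.01) = 1000 -> use direct function instead
        assert gene_fpkm(1, 1000, 1e6) == pytest.approx(1.0)
        tbl = fpkm_table(_fpkm_matrix(np.array([[1, 1]])), threshold=1.0)
        assert not tbl.expressed.iloc[0]


def _fpkm_matrix(gene_counts):
    """CountMatrix with one gene whose FPKM is exactly gene_counts/(1k*1M)."""
    n_samp = gene_counts.shape[1]
    features = pd.DataFrame(
        [dict(feature_id="g0:E000", gene_id="g0", kind="exon_bin",
              start=0, end=1000, length=1000),
         dict(feature_id="g0:gene", gene_id="g0", kind="gene_exonic",
              start=0, end=1000, length=1000)]
    )
    samples = pd.DataFrame(
        dict(sample_id=[f"s{j}" for j in range(n_samp)],
             condition=["a"] * n_samp, library_size=[10**6] * n_samp)
    )
    counts = pd.DataFrame(
        np.vstack([gene_counts, gene_counts]),
        index=features.feature_id, columns=samples.sample_id,
    )
    return CountMatrix(features=features, samples=samples, counts=counts)
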