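"""Splice-site models, rank/exact tests, consensus matching, GC ratios."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import comb

from intronlens.sequence_features import (
    compare_site_strength,
    consensus_match_test,
    differential_gc,
    fit_maxent,
    gc_fraction,
    matches_consensus,
    train_splice_model,
)

BASES = "ACGT"


def toy_model(seqs, pseudocount=0.0, background=None, order="pwm"):
    """Train on short toy sequences, bypassing the min-signal guard."""
    return train_splice_model(
        seqs, background=background, order=order,
        pseudocount=pseudocount, min_signal=1,
    )


class TestPwmTraining:
    def test_hand_counted_marginals(self):
        m = toy_model(["AC", "AC", "AG", "GC"])
        assert m.pwm[0, BASES.index("A")] == pytest.approx(0.75)
        assert m.pwm[0, BASES.index("G")] == pytest.approx(0.25)
        assert m.pwm[1, BASES.index("C")] == pytest.approx(0.75)
        assert m.pwm[1, BASES.index("G")] == pytest.approx(0.25)

    def test_hand_score_log2_nine(self):
        m = toy_model(["AC", "AC", "AG", "GC"])
        # P_s(AC) = .75*.75 = 0.5625 over uniform background 0.0625
        assert m.score("AC") == pytest.approx(math.log2(9), abs=1e-12)

    def test_signal_equals_background_scores_zero(self):
        m = toy_model(["AC", "AG", "GC", "GG"] * 2)
        m.pwm[:] = 0.25
        for s in ("AA", "CG", "TT"):
            assert m.score(s) == pytest.approx(0.0, abs=1e-12)

    def test_consensus_sequence_attains_maximum(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(BASES), p=[.5, .2, .2, .1])
                        for _ in range(3)) for _ in range(40)]
        m = toy_model(seqs, pseudocount=0.5)
        consensus = "".join(BASES[i] for i in m.pwm.argmax(axis=1))
        best = max("".join(t) for t in itertools.product(BASES, repeat=3))
        all_scores = [m.score("".join(t)) for t in itertools.product(BASES, repeat=3)]
        assert m.score(consensus) == pytest.approx(max(all_scores))

    def test_duplicating_training_set_invariant(self):
        seqs = ["ACG", "ACT", "GCA", "ACG"]
        m1 = toy_model(seqs, pseudocount=0.5)
        m2 = toy_model(seqs * 3, pseudocount=1.5)
        assert np.allclose(m1.pwm, m2.pwm)

    def test_n_sites_get_missing_score(self):
        m = toy_model(["AC", "AG"])
        assert math.isnan(m.score("AN"))

    def test_wrong_length_error(self):
        m = toy_model(["AC", "AG"])
        with pytest.raises(ValueError, match="2-mer"):
            m.score("ACG")


def maxent_bruteforce(pos_marginals, pair_marginals):
    """Oracle: maxent distribution via its exponential-family dual.

    The entropy maximizer under linear marginal constraints has the form
    p ∝ exp(F λ); λ solves the smooth convex dual min log Z(λ) - λ·t,
    which BFGS handles directly — an entirely different route from
    iterative proportional fitting.
    """
    from scipy.special import logsumexp

    k = pos_marginals.shape[0]
    space = list(itertools.product(range(4), repeat=k))
    n = len(space)
    cols = []
    targets = []
    for i in range(k):
        for b in range(4):
            cols.append([1.0 if s[i] == b else 0.0 for s in space])
            targets.append(pos_marginals[i, b])
    if pair_marginals is not None:
        for i in range(k - 1):
            for b1 in range(4):
                for b2 in range(4):
                    cols.append([1.0 if s[i] == b1 and s[i + 1] == b2 else 0.0
                                 for s in space])
                    targets.append(pair_marginals[i, b1, b2])
    F = np.array(cols).T  # n_states x n_features
    t = np.array(targets)

    def dual(lam):
        logits = F @ lam
        lz = logsumexp(logits)
        p = np.exp(logits - lz)
        return lz - lam @ t, F.T @ p - t

    res = minimize(dual, np.zeros(len(t)), jac=True, method="BFGS",
                   options=dict(maxiter=5000, gtol=1e-12))
    logits = F @ res.x
    return np.exp(logits - logsumexp(logits))


class TestMaxent:
    def test_single_position_constraints_give_product_model(self):
        pos = np.array([[0.5, 0.3, 0.1, 0.1], [0.25, 0.25, 0.4, 0.1]])
        logp = fit_maxent(pos, None)
        p = np.exp(logp).reshape(4, 4)
        expected = np.outer(pos[0], pos[1])
        assert np.allclose(p, expected, atol=1e-9)

    def test_matches_bruteforce_entropy_maximization(self):
        rng = np.random.default_rng(1)
        raw = rng.random((2, 4, 4)) + 0.2
        pairs = raw[:1] / raw[:1].sum()
        pos = np.vstack([pairs[0].sum(axis=1), pairs[0].sum(axis=0)])
        logp = fit_maxent(pos, pairs)
        oracle = maxent_bruteforce(pos, pairs)
        assert np.allclose(np.exp(logp), oracle, atol=1e-4)

    def test_product_pair_constraint_is_noop(self):
        pos = np.array([[0.5, 0.2, 0.2, 0.1], [0.1, 0.4, 0.3, 0.2]])
        pairs = np.outer(pos[0], pos[1])[None]
        with_pairs = np.exp(fit_maxent(pos, pairs))
        without = np.exp(fit_maxent(pos, None))
        assert np.allclose(with_pairs, without, atol=1e-9)

    def test_three_position_chain_against_bruteforce(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list(BASES), p=[.4, .3, .2, .1])
                        for _ in range(3)) for _ in range(60)]
        m = toy_model(seqs, pseudocount=0.5, order="maxent")
        from intronlens.sequence_features import _pair_marginals
        pairs = _pair_marginals(seqs, 3, 0.5)
        pos = np.vstack([pairs[0].sum(axis=1), pairs[1].sum(axis=1),
                         pairs[1].sum(axis=0)])
        oracle = maxent_bruteforce(pos, pairs)
        fitted = np.exp(m.maxent_logp)
        assert np.allclose(fitted, oracle, atol=1e-4)


def wilcoxon_bruteforce(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    sums = [sum(idx) + n for idx in _rank_combinations(n + m, n)]
    total = comb(n + m, n, exact=True)
    lo = sum(1 for s in sums if s <= obs)
    hi = sum(1 for s in sums if s >= obs)
    return min(1.0, 2 * min(lo, hi) / total)


def _rank_combinations(total, k):
    return itertools.combinations(range(total), k)


class TestWilcoxon:
    def test_enumeration_example(self):
        out = compare_site_strength([1, 2, 3], [4, 5, 6])
        assert out["p"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        out = compare_site_strength([1.0, 1.0], [1.0, 1.0, 1.0])
        assert out["p"] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 9), rng.integers(2, 9)
        x = rng.permutation(100)[: n + m].astype(float)
        y = x[n:].tolist()
        x = x[:n].tolist()
        out = compare_site_strength(x, y)
        assert out["p"] == pytest.approx(wilcoxon_bruteforce(x, y), abs=1e-10)

    def test_medians_reported(self):
        out = compare_site_strength([1, 2, 3], [10, 20, 30, 40])
        assert out["median_a"] == 2 and out["median_b"] == 25


def fisher_bruteforce(table):
    """Oracle: two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(col1, x, exact=True)
                * comb(n - col1, row1 - x, exact=True)
                / comb(n, row1, exact=True))

    p_obs = prob(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestConsensusMatch:
    def test_hand_hypergeometric_example(self):
        # perfectly separated 5 vs 5 table
        out = consensus_match_test(["GT"] * 5, ["CC"] * 5, pattern="GT",
                                   max_mismatches=0)
        assert out["p"] == pytest.approx(2 / 252, rel=1e-9)

    def test_identical_groups_p_one(self):
        out = consensus_match_test(["GT", "CC"], ["GT", "CC"], pattern="GT",
                                   max_mismatches=0)
        assert out["p"] == 1.0

    def test_percentages(self):
        # 137 matching sites of 200 -> 68.50 %
        a = ["GT"] * 137 + ["CC"] * 63
        b = ["GT"] * 100
        out = consensus_match_test(a, b, pattern="GT", max_mismatches=0)
        assert out["pct_a"] == pytest.approx(68.50)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fisher_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 9), rng.integers(2, 9)
        a = ["GT" if rng.random() < 0.7 else "CC" for _ in range(na)]
        b = ["GT" if rng.random() < 0.3 else "CC" for _ in range(nb)]
        out = consensus_match_test(a, b, pattern="GT", max_mismatches=0)
        assert out["p"] == pytest.approx(fisher_bruteforce(out["table"]),
                                         rel=1e-9)

    def test_iupac_and_mismatch_rule(self):
        assert matches_consensus("CAGGTAAGT", "MAGGTRAGT", 0)
        assert matches_consensus("TTGGTAAGT", "MAGGTRAGT", 2)
        assert not matches_consensus("TTTGTAAGT", "MAGGTRAGT", 2)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            matches_consensus("ACGT", "MAG", 1)


class TestDifferentialGc:
    def test_constructed_ratio_two(self):
        intron = "A" * 20 + "G" * 10 + "C" * 10 + "A" * 20
        exon = "T" * 3 + "GCGCGATATA" + "T" * 3  # trimmed part 50% GC
        rec = differential_gc(intron, [exon, exon])
        assert rec.intron_gc == pytest.approx(1.0)
        assert rec.exon_gc == pytest.approx(0.5)
        assert rec.ratio == pytest.approx(2.0, abs=1e-12)

    def test_identical_composition_ratio_one(self):
        intron = "ACGT" * 30  # trims of 20 preserve the 50% composition
        exon = "TTT" + "ACGT" * 10 + "TTT"  # trimmed part is exactly ACGTx10
        rec = differential_gc(intron, [exon, exon])
        assert rec.ratio == pytest.approx(1.0, abs=1e-12)

    def test_length_41_single_central_base(self):
        intron = "A" * 20 + "G" + "A" * 20
        rec = differential_gc(intron, ["ACGTACGTAC"])
        assert rec.intron_gc in (0.0, 1.0)
        assert rec.intron_gc == 1.0

    def test_too_short_intron_skipped(self):
        assert differential_gc("A" * 40, ["ACGTACGTAC"]) is None

    def test_terminal_intron_single_exon_flagged(self):
        rec = differential_gc("ACGT" * 15, ["ACGTACGTAC"])
        assert rec.terminal

    def test_gc_fraction_ignores_n(self):
        assert gc_fraction("GCNN") == pytest.approx(1.0)
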