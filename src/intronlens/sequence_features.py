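"""Splice-site strength models, consensus-motif tests and differential GC.

Site strength is the log-odds score log2(P_s(x)/P_b(x)) of a site x under
a signal model P_s trained on annotated splice sites versus a background
P_b of position-independent base frequencies.  Two signal model orders are
supported:

* order 0 — a position weight matrix (independent positions);
* "maxent" — the maximum-entropy distribution over the full k-mer space
  matching the training set's single-position and adjacent-pair marginals,
  fitted by iterative proportional fitting.  Enumerating the k-mer space is
  feasible for the donor 9-mer (4^9 states); the acceptor 23-mer space is
  not enumerable, so acceptor models fall back to order 0.

Differential GC compares an intron's GC content with the average of its
flanking exons after trimming 20 nt from each intron end and 3 nt from
each exon end, so that splicing signals themselves do not contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .annotation_model import SpliceSiteSeq

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: default donor consensus: exonic MAG | intronic GTRAGT
DONOR_CONSENSUS = "MAGGTRAGT"

MAXENT_MAX_K = 10  # 4^10 ≈ 1e6 states is the enumeration limit


@dataclass
class SpliceSiteModel:
    """Trained signal/background model for donor or acceptor sites."""

    site_kind: str
    k: int
    order: str  # "pwm" | "maxent"
    pwm: np.ndarray  # (k, 4) positional probabilities (always stored)
    background: np.ndarray  # (4,) base frequencies
    pseudocount: float = 0.5
    # maxent-only: full distribution over the enumerated k-mer space
    maxent_logp: np.ndarray | None = field(default=None, repr=False)

    def _kmer_index(self, seq: str) -> int:
        idx = 0
        for ch in seq:
            idx = idx * 4 + BASE_INDEX[ch]
        return idx

    def score(self, seq: str) -> float:
        """log2(P_s/P_b) in bits; NaN for sequences containing N."""
        if len(seq) != self.k:
            raise ValueError(f"expected {self.k}-mer for {self.site_kind}, got {len(seq)}")
        seq = seq.upper()
        if any(ch not in BASE_INDEX for ch in seq):
            return float("nan")
        logp_b = sum(np.log2(self.background[BASE_INDEX[ch]]) for ch in seq)
        if self.order == "maxent":
            logp_s = self.maxent_logp[self._kmer_index(seq)] / np.log(2)
        else:
            logp_s = sum(
                np.log2(self.pwm[i, BASE_INDEX[ch]]) for i, ch in enumerate(seq)
            )
        return float(logp_s - logp_b)

    def score_sites(self, sites: list[SpliceSiteSeq]) -> pd.DataFrame:
        rows = [
            dict(intron_id=s.intron_id, site_kind=s.site_kind,
                 sequence=s.sequence, score=self.score(s.sequence))
            for s in sites
        ]
        return pd.DataFrame(rows)

    def to_table(self) -> pd.DataFrame:
        """Plain-text serializable parameter table (PWM + background)."""
        rows = [
            dict(kind="background", position=-1,
                 **{b: self.background[i] for i, b in enumerate(BASES)})
        ]
        for pos in range(self.k):
            rows.append(
                dict(kind="pwm", position=pos,
                     **{b: self.pwm[pos, i] for i, b in enumerate(BASES)})
            )
        return pd.DataFrame(rows)


def _position_marginals(seqs: list[str], k: int, pseudocount: float) -> np.ndarray:
    counts = np.full((k, 4), pseudocount, dtype=float)
    for s in seqs:
        for i, ch in enumerate(s):
            counts[i, BASE_INDEX[ch]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _pair_marginals(seqs: list[str], k: int, pseudocount: float) -> np.ndarray:
    counts = np.full((k - 1, 4, 4), pseudocount, dtype=float)
    for s in seqs:
        for i in range(k - 1):
            counts[i, BASE_INDEX[s[i]], BASE_INDEX[s[i + 1]]] += 1
    return counts / counts.sum(axis=(1, 2), keepdims=True)


def _enumerate_space(k: int) -> np.ndarray:
    """(4^k, k) integer matrix of all k-mers in lexicographic order."""
    grids = np.meshgrid(*[np.arange(4)] * k, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def fit_maxent(
    pos_marginals: np.ndarray,
    pair_marginals: np.ndarray | None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> np.ndarray:
    """Iterative proportional fitting of the maxent distribution over the
    enumerated k-mer space; returns log-probabilities (natural log).

    With only single-position constraints the result is exactly the
    product (PWM) model; adjacent-pair constraints add first-order
    dependence.  Raises on non-convergence with the residual.
    """
    k = pos_marginals.shape[0]
    if k > MAXENT_MAX_K:
        raise ValueError(f"k={k} space not enumerable (limit {MAXENT_MAX_K})")
    space = _enumerate_space(k)
    n = space.shape[0]
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        max_err = 0.0
        for i in range(k):
            cur = np.bincount(space[:, i], weights=p, minlength=4)
            max_err = max(max_err, float(np.abs(cur - pos_marginals[i]).max()))
            scale = np.where(cur > 0, pos_marginals[i] / np.maximum(cur, 1e-300), 0.0)
            p *= scale[space[:, i]]
        if pair_marginals is not None:
            for i in range(k - 1):
                pair_idx = space[:, i] * 4 + space[:, i + 1]
                cur = np.bincount(pair_idx, weights=p, minlength=16).reshape(4, 4)
                target = pair_marginals[i]
                max_err = max(max_err, float(np.abs(cur - target).max()))
                scale = np.where(cur > 0, target / np.maximum(cur, 1e-300), 0.0)
                p *= scale.ravel()[pair_idx]
        p /= p.sum()
        if max_err < tol:
            break
    else:
        raise RuntimeError(
            f"maxent fitting did not converge: marginal residual {max_err:.2e} > {tol:.0e}"
        )
    return np.log(np.maximum(p, 1e-300))


def train_splice_model(
    signal: list[SpliceSiteSeq] | list[str],
    background: np.ndarray | list[str] | None = None,
    order: str = "pwm",
    pseudocount: float = 0.5,
    use_pairs: bool = True,
    min_signal: int = 50,
) -> SpliceSiteModel:
    """Train a donor/acceptor strength model from signal site sequences.

    ``background`` may be a length-4 base-frequency vector, a list of
    background sequences, or None (uniform).  N-containing signal sites are
    excluded.  ``order`` is "pwm" or "maxent"; maxent additionally matches
    adjacent-pair marginals when ``use_pairs``.
    """
    if signal and isinstance(signal[0], SpliceSiteSeq):
        site_kind = signal[0].site_kind
        seqs = [s.sequence.upper() for s in signal if not s.has_n]
    else:
        site_kind = "donor" if len(signal[0]) == 9 else "acceptor"
        seqs = [s.upper() for s in signal if "N" not in s.upper()]
    if len(seqs) < min_signal:
        raise ValueError(f"need >= {min_signal} N-free signal sites, got {len(seqs)}")
    k = len(seqs[0])
    if any(len(s) != k for s in seqs):
        raise ValueError("signal sites have inconsistent lengths")

    if background is None:
        bg = np.full(4, 0.25)
    elif isinstance(background, np.ndarray):
        bg = background / background.sum()
    else:
        counts = np.full(4, pseudocount)
        for s in background:
            for ch in s.upper():
                if ch in BASE_INDEX:
                    counts[BASE_INDEX[ch]] += 1
        bg = counts / counts.sum()

    pwm = _position_marginals(seqs, k, pseudocount)
    maxent_logp = None
    if order == "maxent":
        if k > MAXENT_MAX_K:
            logger.warning(
                "%s %d-mer space not enumerable; falling back to order-0 PWM",
                site_kind, k,
            )
            order = "pwm"
        else:
            pairs = _pair_marginals(seqs, k, pseudocount) if use_pairs else None
            if pairs is not None:
                # position marginals implied by the pair marginals, so the
                # constraint set is exactly consistent for IPF
                pos = np.vstack([pairs[i].sum(axis=1) for i in range(k - 1)]
                                + [pairs[-1].sum(axis=0)])
            else:
                pos = pwm
            maxent_logp = fit_maxent(pos, pairs)
    return SpliceSiteModel(
        site_kind=site_kind, k=k, order=order, pwm=pwm, background=bg,
        pseudocount=pseudocount, maxent_logp=maxent_logp,
    )


def compare_site_strength(
    scores_a: np.ndarray, scores_b: np.ndarray, exact_max_n: int = 20
) -> dict:
    """Wilcoxon rank-sum comparison of two score groups (e.g. RI vs NRI).

    Exact null distribution for groups of <= ``exact_max_n`` without ties;
    otherwise the normal approximation with tie correction.  Returns
    statistic, two-sided p and group medians.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return dict(statistic=np.nan, p=1.0, median_a=float(np.median(a)),
                    median_b=float(np.median(b)))
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= exact_max_n and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return dict(
        statistic=float(res.statistic), p=float(res.pvalue),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
    )


def matches_consensus(seq: str, pattern: str, max_mismatches: int = 2) -> bool:
    """True if the site differs from the IUPAC pattern at <= max_mismatches
    positions."""
    if len(seq) != len(pattern):
        raise ValueError(f"site length {len(seq)} != pattern length {len(pattern)}")
    mism = sum(
        1 for ch, pc in zip(seq.upper(), pattern.upper()) if ch not in IUPAC[pc]
    )
    return mism <= max_mismatches


def consensus_match_test(
    sites_a: list[str],
    sites_b: list[str],
    pattern: str = DONOR_CONSENSUS,
    max_mismatches: int = 2,
) -> dict:
    """Fraction of consensus-matching sites per group and Fisher exact p.

    The 2x2 table is (match / non-match) x (group A / group B), two-sided.
    """
    ma = sum(matches_consensus(s, pattern, max_mismatches) for s in sites_a)
    mb = sum(matches_consensus(s, pattern, max_mismatches) for s in sites_b)
    table = [[ma, len(sites_a) - ma], [mb, len(sites_b) - mb]]
    _, p = st.fisher_exact(table, alternative="two-sided")
    return dict(
        pct_a=100.0 * ma / len(sites_a), pct_b=100.0 * mb / len(sites_b),
        table=table, p=float(p),
    )


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass(frozen=True)
class GcRecord:
    intron_id: str
    intron_gc: float
    exon_gc: float
    ratio: float
    terminal: bool  # only one flanking exon available


def differential_gc(
    intron_seq: str,
    exon_seqs: list[str],
    intron_id: str = "",
    intron_trim: int = 20,
    exon_trim: int = 3,
) -> GcRecord | None:
    """GC ratio of an intron versus the mean of its flanking exons.

    ``intron_trim`` nt are discarded from each intron end and ``exon_trim``
    nt from each exon end before counting.  Returns None (logged) when the
    trims exhaust the intron or every exon.
    """
    if len(intron_seq) <= 2 * intron_trim:
        logger.info("intron %s too short (%d nt) for GC trim; skipped",
                    intron_id, len(intron_seq))
        return None
    trimmed_exons = [
        e[exon_trim: len(e) - exon_trim] for e in exon_seqs if len(e) > 2 * exon_trim
    ]
    if not trimmed_exons:
        logger.info("intron %s: no flanking exon survives trimming; skipped", intron_id)
        return None
    igc = gc_fraction(intron_seq[intron_trim: len(intron_seq) - intron_trim])
    egc = float(np.mean([gc_fraction(e) for e in trimmed_exons]))
    if egc == 0 or np.isnan(egc):
        logger.info("intron %s: flanking exon GC undefined/zero; skipped", intron_id)
        return None
    return GcRecord(
        intron_id=intron_id, intron_gc=igc, exon_gc=egc, ratio=igc / egc,
        terminal=len(trimmed_exons) < 2,
    )
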