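"""Planted-effect validation experiments.

Each function generates synthetic data with one planted effect, runs the
relevant pipeline stages, and reports how well the planted parameters are
recovered.  These experiments back the package's statistical claims (test
calibration, detection power, recovery accuracy) and are what the
acceptance machinery executes.

Problem sizes default to: 2000 introns (400 six-exon genes) at 300
fragments/gene/sample for retention recovery, 500 genes for the
co-transcriptional ratio, 1000 junctions for the iCLIP peak ratio, and
2000 features for null calibration — large enough for stable estimates,
small enough to run in a few minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import logging
import os
import tempfile

import numpy as np
import pandas as pd

from .annotation_model import extract_splice_sites
from .cotx_splicing import compare_ratio_distributions, cotx_table
from .differential_usage import classify_introns, run_differential_usage, top_k_ri
from .feature_counting import count_features, exon_size_factors
from .iclip_profiles import compare_profiles, load_crosslinks
from .pipeline import PipelineConfig, run_pipeline
from .sequence_features import (
    compare_site_strength,
    consensus_match_test,
    train_splice_model,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_genome_annotation,
    simulate_crosslinks,
    simulate_rnaseq,
    write_genome_fasta,
)

logger = logging.getLogger(__name__)


def _sheet(cfg: SyntheticConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(sample_id=s, condition=c) for s, c in cfg.sample_ids()]
    )


def retention_recovery(
    seed: int,
    n_genes: int = 400,
    coverage: float = 300.0,
    top_k: int = 200,
    workdir: str | None = None,
) -> dict:
    """Recovery of planted retained introns and their weak donor sites.

    2000 introns (six-exon genes), ~10% weak-5'ss true RI whose intronic
    signal rises >= 2-fold under depletion at >= 300 fragments coverage.
    Reports RI recall and false discovery proportion at q < 0.01, the
    RI-vs-NRI donor strength comparison, and consensus-match percentages.
    """
    cfg = SyntheticConfig(
        n_genes=n_genes, exons_per_gene=(6, 6), mean_coverage=coverage,
        seed=seed, cotx_gradient={"control": 1.0, "depleted": 1.0},
    )
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        genome, models, truth = generate_genome_annotation(cfg)
        bams = simulate_rnaseq(genome, models, truth, cfg, tmp)
        cm = count_features(bams, models, _sheet(cfg))
        sf = exon_size_factors(cm)
        res = run_differential_usage(
            cm.counts, cm.features, cm.gene_exon_counts(), sf, cm.samples,
            kind="intron",
        )
        res = classify_introns(res)
        ri_top, nri_contrast = top_k_ri(res, k=top_k)

        fasta = os.path.join(tmp, "genome.fa")
        write_genome_fasta(genome, fasta, cfg.chrom_name)
        sites = extract_splice_sites(models, fasta, kinds=("donor",))
        model = train_splice_model(sites, order="maxent")
        scores = model.score_sites(sites).set_index("intron_id")

    merged = res.merge(truth.introns, left_on="feature_id", right_on="intron_id")
    ri = merged[merged.label == "RI"]
    n_true = int(truth.introns.true_ri.sum())
    recall = float(ri.true_ri.sum() / n_true) if n_true else float("nan")
    fdp = float(1 - ri.true_ri.mean()) if len(ri) else 0.0

    ri_scores = scores.loc[scores.index.isin(ri_top.feature_id), "score"]
    nri_scores = scores.loc[scores.index.isin(nri_contrast.feature_id), "score"]
    strength = compare_site_strength(ri_scores, nri_scores)
    observed_shift = strength["median_a"] - strength["median_b"]

    tr = truth.introns.set_index("intron_id")
    weak = scores.loc[tr.index[tr.strength_class == "weak"], "score"]
    strong = scores.loc[tr.index[tr.strength_class == "strong"], "score"]
    planted_shift = float(np.median(weak) - np.median(strong))

    cons = consensus_match_test(
        scores.loc[scores.index.isin(ri_top.feature_id), "sequence"].tolist(),
        scores.loc[scores.index.isin(nri_contrast.feature_id), "sequence"].tolist(),
    )
    return dict(
        n_introns=len(res), n_true_ri=n_true, n_detected_ri=int(len(ri)),
        recall=recall, fdp=fdp,
        wilcoxon_p=strength["p"],
        observed_shift_bits=float(observed_shift),
        planted_shift_bits=planted_shift,
        shift_error_bits=float(abs(observed_shift - planted_shift)),
        consensus_pct_ri=cons["pct_a"], consensus_pct_nri=cons["pct_b"],
        consensus_fisher_p=cons["p"],
    )


def null_calibration(
    seed: int, n_features: int = 2000, nominal: float = 0.05
) -> dict:
    """Type-I error of the NB usage test on null features, 3 vs 4 replicates.

    Counts are NB-simulated with no usage change; gene counts and size
    factors vary as in the study design.  The whole testing path (per-
    feature dispersion, moderation, Wald test) is exercised.
    """
    rng = np.random.default_rng([seed, 17])
    sids = [f"s{j}" for j in range(7)]
    samples = pd.DataFrame(
        dict(sample_id=sids, condition=["control"] * 3 + ["depleted"] * 4,
             library_size=1)
    )
    sf_true = np.array([1.0, 0.6, 1.4, 0.8, 1.2, 0.7, 1.3])
    alpha_true = 0.05
    n_nb = 1 / alpha_true
    mu = 100.0 * sf_true
    counts = rng.negative_binomial(
        n_nb, n_nb / (n_nb + mu), size=(n_features, 7)
    )
    features = pd.DataFrame(
        dict(feature_id=[f"f{i}" for i in range(n_features)],
             gene_id=[f"g{i}" for i in range(n_features)], kind="intron",
             start=0, end=1000, length=1000)
    )
    counts_df = pd.DataFrame(counts, index=features.feature_id, columns=sids)
    gene_counts = pd.DataFrame(
        rng.poisson(2000 * sf_true, size=(n_features, 7)),
        index=features.gene_id, columns=sids,
    )
    sf = pd.Series(sf_true, index=sids)
    res = run_differential_usage(counts_df, features, gene_counts, sf,
                                 samples, kind="intron")
    ok = res.p.notna()
    return dict(
        type_i_error=float((res.p[ok] < nominal).mean()),
        n_tested=int(ok.sum()),
    )


def cotx_recovery(
    seed: int, n_genes: int = 500, coverage: float = 300.0,
    workdir: str | None = None,
) -> dict:
    """Recovery of the planted co-transcriptional residual gradient.

    Retention is switched off so intronic reads reflect only the 5'->3'
    residual-coverage gradient (4x in control, attenuated to 1.2x under
    depletion).  Reports per-condition median ratios, the rank-sum p for
    the between-condition shift, and the relative error of the recovered
    control gradient.
    """
    cfg = SyntheticConfig(
        n_genes=n_genes, exons_per_gene=(3, 5), mean_coverage=coverage,
        seed=seed, retention_base=0.0, retention_depleted_max=0.0,
        weak_fraction=0.0,
    )
    grad_control = cfg.cotx_gradient["control"]
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        genome, models, truth = generate_genome_annotation(cfg)
        bams = simulate_rnaseq(genome, models, truth, cfg, tmp)
        cm = count_features(bams, models, _sheet(cfg))
    table = cotx_table(cm, models)
    ctrl = table[table.condition == "control"]
    depl = table[table.condition == "depleted"]
    out = compare_ratio_distributions(ctrl, depl)
    est_gradient = 1.0 / out["median_control"]
    return dict(
        n_genes=out["n_genes"],
        median_ratio_control=out["median_control"],
        median_ratio_depleted=out["median_depleted"],
        rank_sum_p=out["p"],
        frac_gt1_control=out["frac_gt1_control"],
        frac_gt1_depleted=out["frac_gt1_depleted"],
        planted_gradient=grad_control,
        estimated_gradient=float(est_gradient),
        gradient_rel_error=float(abs(est_gradient - grad_control) / grad_control),
    )


def iclip_recovery(
    seed: int, n_genes: int = 200, workdir: str | None = None
) -> dict:
    """Recovery of planted crosslink peak amplitude ratios at the 5'ss.

    1000 junctions (200 six-exon genes); planted depleted/control ratio
    0.3 at offset -20 and 1.0 at -50.  Reports both estimated ratios with
    bootstrap CIs.
    """
    cfg = SyntheticConfig(n_genes=n_genes, exons_per_gene=(6, 6), seed=seed)
    planted = {off: amps["depleted"] / amps["control"]
               for anchor, off, amps in cfg.clip_peaks if anchor == "5ss"}
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        _, models, _ = generate_genome_annotation(cfg)
        beds = simulate_crosslinks(models, cfg, tmp)
        tracks = [load_crosslinks(beds[sid], sid, cond)
                  for sid, cond in cfg.sample_ids()]
        comp = compare_profiles(
            tracks, models, "control", "depleted",
            peak_offsets=sorted(planted), anchor="5ss", window=100,
            n_boot=1000, seed=seed,
        ).set_index("offset")
    out = dict(n_junctions=int(comp.n_junctions.iloc[0]))
    for off, target in planted.items():
        row = comp.loc[off]
        key = f"m{abs(off)}" if off < 0 else f"p{off}"
        out[f"ratio_{key}"] = float(row.ratio)
        out[f"ratio_{key}_ci_lo"] = float(row.ci_lo)
        out[f"ratio_{key}_ci_hi"] = float(row.ci_hi)
        out[f"ratio_{key}_planted"] = float(target)
        out[f"ratio_{key}_rel_error"] = float(abs(row.ratio - target) / target) \
            if target > 0 else float("nan")
    return out


def _bundle_digest(out_dir: str) -> str:
    h = hashlib.sha256()
    for name in sorted(os.listdir(out_dir)):
        if name == "intronlens.log":
            continue
        h.update(name.encode())
        with open(os.path.join(out_dir, name), "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()


def determinism_check(
    seed: int, n_genes: int = 10, coverage: float = 100.0,
    workdir: str | None = None,
) -> dict:
    """Run the full pipeline twice with one seed; compare bundle bytes."""
    digests = []
    for _ in range(2):
        with tempfile.TemporaryDirectory(dir=workdir) as tmp:
            cfg = PipelineConfig(
                out_dir=tmp, seed=seed, n_boot=200,
                synthetic=SyntheticConfig(n_genes=n_genes, mean_coverage=coverage),
            )
            run_pipeline(cfg)
            digests.append(_bundle_digest(tmp))
    return dict(identical=int(digests[0] == digests[1]), digest=digests[0][:16])
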