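"""End-to-end orchestration: simulate -> models -> count -> diff -> seqfeat
-> cotx -> clip, with a run manifest and cached, resumable stages.

Each stage writes TSV outputs plus an entry in ``manifest.json`` recording
the stage's parameter hash (which chains the upstream stage hashes, so a
changed threshold invalidates exactly the stages at and downstream of the
change).  Reruns skip stages whose hash matches and whose outputs exist.
All randomness flows from the single root seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .annotation_model import (
    build_gene_models,
    extract_splice_sites,
    models_to_table,
    select_cotx_genes,
)
from .cotx_splicing import compare_ratio_distributions, cotx_table
from .differential_usage import (
    classify_exon_bins,
    classify_introns,
    overlap_test,
    run_differential_usage,
    top_k_ri,
)
from .feature_counting import (
    CountMatrix,
    count_features,
    exon_size_factors,
    fpkm_table,
    normalized_intron_table,
)
from .iclip_profiles import compare_profiles, junction_metaprofile, load_crosslinks
from .sequence_features import (
    DONOR_CONSENSUS,
    compare_site_strength,
    consensus_match_test,
    differential_gc,
    train_splice_model,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_genome_annotation,
    simulate_crosslinks,
    simulate_rnaseq,
    write_annotation,
    write_genome_fasta,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "models", "count", "diff", "seqfeat", "cotx", "clip"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and scoring options for one pipeline run."""

    out_dir: str
    # inputs; when None the simulate stage generates them
    genome: str | None = None
    annotation: str | None = None
    sample_sheet: str | None = None
    # thresholds
    q_threshold: float = 0.01
    top_k: int = 200
    fpkm_threshold: float = 1.0
    cotx_min_span: int = 300
    # scoring
    model_order: str = "maxent"
    consensus_pattern: str = DONOR_CONSENSUS
    consensus_mismatches: int = 2
    # iCLIP
    window: int = 100
    peak_offsets: tuple[int, ...] = (-20, -50)
    n_boot: int = 1000
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        if self.q_threshold <= 0 or self.top_k <= 0 or self.fpkm_threshold <= 0:
            raise ValueError("thresholds must be positive")
        # one root seed drives simulation and bootstrap alike
        self.synthetic.seed = self.seed

    def scientific_params(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d


def _hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = config.out_dir
        os.makedirs(self.out, exist_ok=True)
        self.manifest_path = os.path.join(self.out, "manifest.json")
        self.manifest = self._load_manifest()

    def _load_manifest(self) -> dict:
        if os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                return json.load(fh)
        return {"version": __version__, "stages": {}}

    def _save_manifest(self) -> None:
        self.manifest["version"] = __version__
        self.manifest["seed"] = self.config.seed
        self.manifest["config_hash"] = _hash(self.config.scientific_params())
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def _path(self, name: str) -> str:
        return os.path.join(self.out, name)

    def _stage_fresh(self, stage: str, params_hash: str, outputs: list[str]) -> bool:
        entry = self.manifest["stages"].get(stage)
        return (
            entry is not None
            and entry.get("hash") == params_hash
            and entry.get("complete")
            and all(os.path.exists(self._path(o)) for o in entry.get("outputs", outputs))
        )

    def _mark(self, stage: str, params_hash: str, outputs: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "hash": params_hash, "complete": True, "outputs": outputs,
        }
        self._save_manifest()

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> str:
        cfg = self.config
        h = _hash(("simulate", dataclasses.asdict(cfg.synthetic)))
        outputs = ["genome.fa", "annotation.gtf", "sample_sheet.tsv", "config.txt"]
        if self._stage_fresh("simulate", h, outputs):
            logger.info("simulate: cached")
            return h
        genome, models, truth = generate_genome_annotation(cfg.synthetic)
        write_genome_fasta(genome, self._path("genome.fa"), cfg.synthetic.chrom_name)
        write_annotation(models, self._path("annotation.gtf"))
        truth.write(self._path("truth"))
        bams = simulate_rnaseq(genome, models, truth, cfg.synthetic, self.out)
        beds = simulate_crosslinks(models, cfg.synthetic, self.out)
        sheet = pd.DataFrame(
            [dict(sample_id=sid, condition=cond,
                  replicate=sid.rsplit("_", 1)[1],
                  bam=os.path.basename(bams[sid]),
                  clip_bed=os.path.basename(beds[sid]))
             for sid, cond in cfg.synthetic.sample_ids()]
        )
        sheet.to_csv(self._path("sample_sheet.tsv"), sep="\t", index=False)
        with open(self._path("config.txt"), "w") as fh:
            fh.write(cfg.synthetic.to_text())
        self._mark("simulate", h, outputs)
        return h

    def _genome_path(self) -> str:
        return self.config.genome or self._path("genome.fa")

    def _annotation_path(self) -> str:
        return self.config.annotation or self._path("annotation.gtf")

    def _sheet(self) -> pd.DataFrame:
        path = self.config.sample_sheet or self._path("sample_sheet.tsv")
        return pd.read_csv(path, sep="\t", dtype=str)

    def stage_models(self, upstream: str) -> str:
        h = _hash(("models", upstream, self.config.cotx_min_span))
        outputs = ["gene_models.tsv", "cotx_genes.txt"]
        if self._stage_fresh("models", h, outputs):
            logger.info("models: cached")
            return h
        models = build_gene_models(self._annotation_path())
        models_to_table(models.values()).to_csv(
            self._path("gene_models.tsv"), sep="\t", index=False
        )
        cotx = select_cotx_genes(models, min_span=self.config.cotx_min_span)
        with open(self._path("cotx_genes.txt"), "w") as fh:
            fh.write("\n".join(sorted(cotx)) + "\n")
        self._mark("models", h, outputs)
        return h

    def stage_count(self, upstream: str) -> str:
        h = _hash(("count", upstream, self.config.fpkm_threshold))
        outputs = ["counts.tsv", "size_factors.tsv", "normalized.tsv", "fpkm.tsv"]
        if self._stage_fresh("count", h, outputs):
            logger.info("count: cached")
            return h
        models = build_gene_models(self._annotation_path())
        sheet = self._sheet()
        bam_paths = {r.sample_id: self._resolve(r.bam) for r in sheet.itertuples()}
        cm = count_features(bam_paths, models, sheet)
        sf = exon_size_factors(cm)
        merged = cm.features.merge(
            cm.counts, left_on="feature_id", right_index=True
        )
        merged.to_csv(self._path("counts.tsv"), sep="\t", index=False)
        sf.rename("size_factor").to_csv(self._path("size_factors.tsv"), sep="\t")
        normalized_intron_table(cm).to_csv(
            self._path("normalized.tsv"), sep="\t", index=False
        )
        fpkm_table(cm, self.config.fpkm_threshold).to_csv(
            self._path("fpkm.tsv"), sep="\t"
        )
        cm.samples.to_csv(self._path("samples.tsv"), sep="\t", index=False)
        self._mark("count", h, outputs)
        return h

    def _resolve(self, name: str) -> str:
        return name if os.path.isabs(name) else self._path(name)

    def _load_count_matrix(self) -> CountMatrix:
        merged = pd.read_csv(self._path("counts.tsv"), sep="\t")
        samples = pd.read_csv(self._path("samples.tsv"), sep="\t")
        feat_cols = ["feature_id", "gene_id", "kind", "start", "end", "length"]
        features = merged[feat_cols]
        counts = merged.set_index("feature_id")[list(samples.sample_id)]
        sf = pd.read_csv(self._path("size_factors.tsv"), sep="\t", index_col=0)[
            "size_factor"
        ]
        return CountMatrix(features=features, samples=samples, counts=counts,
                           size_factors=sf)

    def stage_diff(self, upstream: str) -> str:
        cfg = self.config
        h = _hash(("diff", upstream, cfg.q_threshold, cfg.top_k))
        outputs = ["results_intron.tsv", "results_exon.tsv", "ri_top.tsv",
                   "nri_contrast.tsv", "overlap.json"]
        if self._stage_fresh("diff", h, outputs):
            logger.info("diff: cached")
            return h
        cm = self._load_count_matrix()
        gene_counts = cm.gene_exon_counts()
        res_i = run_differential_usage(
            cm.counts, cm.features, gene_counts, cm.size_factors, cm.samples,
            kind="intron",
        )
        res_i = classify_introns(res_i, cfg.q_threshold)
        res_i.to_csv(self._path("results_intron.tsv"), sep="\t", index=False)
        ri, nri = top_k_ri(res_i, cfg.top_k)
        ri.to_csv(self._path("ri_top.tsv"), sep="\t", index=False)
        nri.to_csv(self._path("nri_contrast.tsv"), sep="\t", index=False)
        res_e = run_differential_usage(
            cm.counts, cm.features, gene_counts, cm.size_factors, cm.samples,
            kind="exon_bin",
        )
        res_e = classify_exon_bins(res_e, cfg.q_threshold)
        res_e.to_csv(self._path("results_exon.tsv"), sep="\t", index=False)
        # gene-set overlap: RI genes x DEU genes within expressed genes
        fpkm = pd.read_csv(self._path("fpkm.tsv"), sep="\t", index_col=0)
        universe = set(fpkm.index[fpkm.expressed])
        ri_genes = set(res_i.loc[res_i.label == "RI", "gene_id"]) & universe
        deu_genes = set(res_e.loc[res_e.label == "DEU", "gene_id"]) & universe
        if universe:
            n_overlap, p = overlap_test(ri_genes, deu_genes, universe)
        else:
            n_overlap, p = 0, float("nan")
        with open(self._path("overlap.json"), "w") as fh:
            json.dump(
                dict(n_ri_genes=len(ri_genes), n_deu_genes=len(deu_genes),
                     n_overlap=n_overlap, n_universe=len(universe), p=p),
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        self._mark("diff", h, outputs)
        return h

    def stage_seqfeat(self, upstream: str) -> str:
        cfg = self.config
        h = _hash(("seqfeat", upstream, cfg.model_order, cfg.consensus_pattern,
                   cfg.consensus_mismatches))
        outputs = ["donor_scores.tsv", "seqfeat_summary.json", "gc.tsv"]
        if self._stage_fresh("seqfeat", h, outputs):
            logger.info("seqfeat: cached")
            return h
        models = build_gene_models(self._annotation_path())
        genome = Fasta(self._genome_path())
        sites = extract_splice_sites(models, genome, kinds=("donor",))
        usable_sites = [s for s in sites if not s.has_n]
        model = train_splice_model(
            usable_sites, order=cfg.model_order,
            min_signal=min(50, max(10, len(usable_sites))),
        )
        scores = model.score_sites(sites)
        ri = pd.read_csv(self._path("ri_top.tsv"), sep="\t")
        nri = pd.read_csv(self._path("nri_contrast.tsv"), sep="\t")
        scores["set"] = np.where(
            scores.intron_id.isin(ri.feature_id), "RI",
            np.where(scores.intron_id.isin(nri.feature_id), "NRI", "other"),
        )
        scores.to_csv(self._path("donor_scores.tsv"), sep="\t", index=False)
        ri_scores = scores.loc[scores.set == "RI", "score"].to_numpy()
        nri_scores = scores.loc[scores.set == "NRI", "score"].to_numpy()
        summary: dict = {}
        if len(ri_scores) and len(nri_scores):
            summary["strength"] = compare_site_strength(ri_scores, nri_scores)
            ri_seqs = scores.loc[scores.set == "RI", "sequence"].tolist()
            nri_seqs = scores.loc[scores.set == "NRI", "sequence"].tolist()
            cons = consensus_match_test(
                ri_seqs, nri_seqs, cfg.consensus_pattern, cfg.consensus_mismatches
            )
            summary["consensus"] = {k: v for k, v in cons.items() if k != "table"}
            summary["consensus"]["table"] = [list(r) for r in cons["table"]]
        # differential GC for every intron
        gc_rows = []
        for gid in sorted(models):
            m = models[gid]
            for i, intr in enumerate(m.introns):
                left, right = m.intron_flanking_exons(intr)
                iseq = str(genome[m.chrom][intr[0]: intr[1]])
                eseqs = [str(genome[m.chrom][left[0]: left[1]]),
                         str(genome[m.chrom][right[0]: right[1]])]
                rec = differential_gc(iseq, eseqs, intron_id=f"{gid}:I{i:03d}")
                if rec is not None:
                    gc_rows.append(dataclasses.asdict(rec))
        pd.DataFrame(gc_rows).to_csv(self._path("gc.tsv"), sep="\t", index=False)
        with open(self._path("seqfeat_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")
        self._mark("seqfeat", h, outputs)
        return h

    def stage_cotx(self, upstream: str) -> str:
        cfg = self.config
        h = _hash(("cotx", upstream, cfg.cotx_min_span))
        outputs = ["cotx.tsv", "cotx_summary.json"]
        if self._stage_fresh("cotx", h, outputs):
            logger.info("cotx: cached")
            return h
        models = build_gene_models(self._annotation_path())
        eligible = select_cotx_genes(models, min_span=cfg.cotx_min_span)
        cm = self._load_count_matrix()
        table = cotx_table(cm, eligible)
        table.to_csv(self._path("cotx.tsv"), sep="\t", index=False)
        conds = list(dict.fromkeys(cm.samples.condition))
        summary: dict = {}
        if len(conds) == 2 and not table.empty:
            ctrl = table[table.condition == conds[0]]
            depl = table[table.condition == conds[1]]
            if not ctrl.empty and not depl.empty:
                summary = compare_ratio_distributions(ctrl, depl)
        with open(self._path("cotx_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")
        self._mark("cotx", h, outputs)
        return h

    def stage_clip(self, upstream: str) -> str:
        cfg = self.config
        h = _hash(("clip", upstream, cfg.window, cfg.peak_offsets, cfg.n_boot,
                   cfg.seed))
        outputs = ["clip_profile.tsv", "clip_comparison.tsv"]
        if self._stage_fresh("clip", h, outputs):
            logger.info("clip: cached")
            return h
        models = build_gene_models(self._annotation_path())
        genome = Fasta(self._genome_path())
        contig_lengths = {name: len(genome[name]) for name in genome.keys()}
        sheet = self._sheet()
        tracks = [
            load_crosslinks(self._resolve(r.clip_bed), r.sample_id, r.condition,
                            r.replicate)
            for r in sheet.itertuples()
        ]
        # only junctions of expressed genes are profiled
        fpkm = pd.read_csv(self._path("fpkm.tsv"), sep="\t", index_col=0)
        expressed = set(fpkm.index[fpkm.expressed])
        subset = expressed if expressed else None
        frames = []
        comps = []
        conds = list(dict.fromkeys(sheet.condition))
        for anchor in ("5ss", "3ss"):
            prof = junction_metaprofile(
                tracks, models, anchor=anchor, window=cfg.window,
                contig_lengths=contig_lengths, gene_subset=subset,
            )
            frames.append(prof.to_frame())
            if len(conds) == 2:
                comps.append(
                    compare_profiles(
                        tracks, models, conds[0], conds[1],
                        list(cfg.peak_offsets), anchor=anchor,
                        window=cfg.window, n_boot=cfg.n_boot, seed=cfg.seed,
                        contig_lengths=contig_lengths, gene_subset=subset,
                    )
                )
        pd.concat(frames).to_csv(self._path("clip_profile.tsv"), sep="\t", index=False)
        if comps:
            pd.concat(comps).to_csv(
                self._path("clip_comparison.tsv"), sep="\t", index=False
            )
        self._mark("clip", h, outputs)
        return h

    def run_all(self) -> dict:
        stage = "simulate"
        try:
            h = self.stage_simulate() if self.config.genome is None else _hash("external")
            stage = "models"
            h = self.stage_models(h)
            stage = "count"
            h = self.stage_count(h)
            stage = "diff"
            h_diff = self.stage_diff(h)
            stage = "seqfeat"
            self.stage_seqfeat(h_diff)
            stage = "cotx"
            self.stage_cotx(h)
            stage = "clip"
            self.stage_clip(h)
        except Exception as err:
            raise RuntimeError(f"pipeline aborted at stage '{stage}': {err}") from err
        return self.manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest."""
    return Pipeline(config).run_all()
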