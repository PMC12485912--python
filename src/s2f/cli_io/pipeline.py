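"""Top-level pipeline driver.

Chains simulate -> encode -> prep -> baseline -> train -> ism -> annotate
-> evaluate, writing each stage's outputs under the configured directory
and recording a manifest with seeds, a config hash and per-file SHA-256
checksums.  Stages are deterministic given (config, seed), so reruns
produce bit-identical checksums.
"""

from __future__ import annotations

import json
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import baseline_en, cohort_prep, evaluation, functional_annotation, ism_hsv
from .. import synthetic_data as sd
from ..genome_encoding import encode_cohort
from ..s2f_model import ExpressionPredictor, GeneData, ModelConfig, TrunkConfig, train_single_gene
from . import io as fio
from .config import PipelineConfig

log = logging.getLogger("s2f")

STAGES = ("simulate", "encode", "prep", "baseline", "train", "ism", "annotate", "evaluate")


@dataclass
class PipelineContext:
    """In-memory state shared between stages plus the output manifest."""

    config: PipelineConfig
    out_dir: Path
    ref: sd.ReferenceWindow | None = None
    vt: sd.VariantTable | None = None
    truth: sd.SyntheticTruth | None = None
    dataset: sd.CohortDataset | None = None
    tracks: tuple | None = None
    pwms: list | None = None
    encodings: np.ndarray | None = None
    gene_cohort: cohort_prep.GeneCohort | None = None
    split: np.ndarray | None = None
    en_model: baseline_en.ENModel | None = None
    model: ExpressionPredictor | None = None
    hsv_sets: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def record(self, stage: str, files: list[Path], elapsed: float) -> None:
        self.manifest[stage] = {
            "files": {str(p.relative_to(self.out_dir)): fio.sha256sum(p) for p in files},
            "wall_time_s": round(elapsed, 3),
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(ctx: PipelineContext) -> list[Path]:
    cfg, s = ctx.config, ctx.config.seed
    sim = cfg.sim
    ctx.ref = sd.simulate_reference(sim.length, sim.gc, seed=s)
    ctx.vt = sd.simulate_cohort(ctx.ref, sim.n_individuals, sim.n_sites,
                                maf_mix=sim.maf_mix, seed=s + 1,
                                ld_block_size=sim.ld_block_size)
    ctx.truth = sd.plant_effects(ctx.vt, sim.n_causal, sim.h2,
                                 rare_var_share=sim.rare_var_share, seed=s + 2)
    cov, cov_names = sd.simulate_covariates(sim.n_individuals, sim.n_geno_pcs,
                                            sim.n_expr_pcs, seed=s + 3)
    ctx.dataset = sd.simulate_expression(
        ctx.truth, ctx.vt, cov, cov_names, seed=s + 4,
        protein_altering_fraction=sim.protein_altering_fraction)
    tiling, ccre, pwms = sd.simulate_annotations(
        ctx.ref, n_pwms=sim.n_pwms, pwm_width=sim.pwm_width, seed=s + 5)
    ctx.tracks = (tiling, ccre)
    ctx.pwms = pwms

    d = ctx.out_dir / "sim"
    d.mkdir(parents=True, exist_ok=True)
    files = [
        fio.write_fasta(d / "reference.fa", ctx.ref),
        fio.write_vcf(d / "cohort.vcf", ctx.ref, ctx.vt),
        fio.write_expression_tsv(d / "expression.tsv", ctx.dataset),
        fio.write_consequence_tsv(d / "consequences.tsv", ctx.dataset.consequence_table),
        fio.write_bed(d / "chromhmm.bed", tiling, chrom=ctx.ref.chrom),
        fio.write_bed(d / "ccre.bed", ccre, chrom=ctx.ref.chrom),
        fio.write_meme(d / "motifs.meme", pwms),
    ]
    truth_df = pd.DataFrame({
        "variant_index": np.arange(ctx.vt.n_variants),
        "pos": ctx.vt.positions,
        "beta": ctx.truth.beta,
        "causal": np.isin(np.arange(ctx.vt.n_variants), ctx.truth.causal_indices),
        "maf": ctx.vt.maf,
    })
    truth_path = d / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    files.append(truth_path)
    return files


def stage_encode(ctx: PipelineContext) -> list[Path]:
    if ctx.ref is None:
        ref = fio.read_fasta(ctx.config.reference_fasta)
        ctx.ref = ref
        ctx.vt = fio.read_vcf(ctx.config.vcf, ref)
    batch = encode_cohort(ctx.ref, ctx.vt)
    ctx.encodings = batch.matrix
    p = ctx.out_dir / "encodings.npz"
    np.savez_compressed(p, individuals=np.array(batch.individuals), shape=batch.matrix.shape)
    return [p]


def stage_prep(ctx: PipelineContext) -> list[Path]:
    gc = cohort_prep.exclude_protein_altering(ctx.dataset, gene="gene")
    gc = cohort_prep.split_cohort(gc, seed=ctx.config.seed + 10)
    ctx.gene_cohort = gc
    ctx.split = cohort_prep.split_vector(gc, ctx.dataset.individuals)
    df = pd.DataFrame({"individual": ctx.dataset.individuals, "split": ctx.split})
    p = ctx.out_dir / "splits.tsv"
    df.to_csv(p, sep="\t", index=False)
    return [p]


def _retained_mask(ctx: PipelineContext) -> np.ndarray:
    return ctx.split != ""


def stage_baseline(ctx: PipelineContext) -> list[Path]:
    ctx.en_model = baseline_en.fit_gene_baseline(
        ctx.vt, ctx.dataset.expression, ctx.split)
    p = ctx.out_dir / "baseline.json"
    p.write_text(json.dumps({
        "penalty": ctx.en_model.penalty,
        "l1_ratio": ctx.en_model.l1_ratio,
        "n_nonzero": ctx.en_model.n_nonzero,
        "val_r2": ctx.en_model.val_r2,
        "test_r2": ctx.en_model.test_r2,
        "test_pcc": ctx.en_model.test_pcc,
        "cis_h2_estimate": baseline_en.estimate_cis_h2(ctx.en_model),
    }, indent=2))
    return [p]


def _model_config(ctx: PipelineContext) -> ModelConfig:
    t = ctx.config.train
    return ModelConfig(
        length=ctx.ref.length,
        n_covariates=ctx.dataset.covariates.shape[1],
        trunk=TrunkConfig(conv_channels=tuple(t.conv_channels),
                          kernels=tuple(t.kernels),
                          dilations=tuple(t.dilations),
                          readout_channels=t.readout_channels),
        head_hidden=t.head_hidden, alpha=t.alpha, lr_peak=t.lr_peak,
        warmup_frac=t.warmup_frac, batch_size=t.batch_size,
        accum_steps=t.accum_steps, epochs=t.epochs,
        weight_decay=t.weight_decay, patience=t.patience,
        seed=ctx.config.seed + 20,
    )


def _gene_data(ctx: PipelineContext) -> GeneData:
    return GeneData(encodings=ctx.encodings, expression=ctx.dataset.expression,
                    covariates=ctx.dataset.covariates, split=ctx.split)


def stage_train(ctx: PipelineContext) -> list[Path]:
    model, history = train_single_gene(_gene_data(ctx), _model_config(ctx))
    ctx.model = model
    p = ctx.out_dir / "history.json"
    p.write_text(json.dumps(history, indent=2))
    return [p]


def stage_ism(ctx: PipelineContext) -> list[Path]:
    cov_mean = ctx.dataset.covariates.mean(axis=0)
    ref_enc = ctx.ref.one_hot()
    ismap = ism_hsv.ism_map(ctx.model, ref_enc, covariates=cov_mean,
                            positions=ctx.vt.positions, model_id="surrogate")
    hsv_en = ism_hsv.hsv_from_elastic_net(ctx.en_model, ctx.vt)
    hsv_deep = ism_hsv.select_hsv(ismap, ctx.vt, n=ctx.en_model.n_nonzero,
                                  model_id="surrogate")
    ctx.hsv_sets = {"surrogate": hsv_deep, "elastic_net": hsv_en}
    rows = []
    for name, hsv in ctx.hsv_sets.items():
        for m in hsv.members:
            rows.append({"model": name, "rank": m.rank, "pos": m.pos,
                         "variant_index": m.variant_index, "score": m.score,
                         "maf": ctx.vt.maf[m.variant_index]})
    p = ctx.out_dir / "hsv.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    return [p]


def stage_annotate(ctx: PipelineContext) -> list[Path]:
    tiling, ccre = ctx.tracks
    out = {}
    enr = functional_annotation.chromhmm_enrichment(
        {"gene": ctx.hsv_sets["surrogate"]}, {"gene": tiling})
    out["chromhmm"] = [
        {"state": e.state, "observed": e.observed, "expected": e.expected,
         "ratio": e.ratio if e.expected > 0 else None}
        for e in enr
    ]
    out["ccre"] = functional_annotation.ccre_overlap_fraction(
        {"gene": ctx.hsv_sets["surrogate"]}, {"gene": ccre})
    calls, frac = functional_annotation.motif_effects(
        ctx.hsv_sets["surrogate"], ctx.vt, ctx.ref, ctx.pwms,
        scan_halfwidth=ctx.config.scan_halfwidth)
    out["motif_fraction_with_effect"] = frac
    ld = {
        name: functional_annotation.ld_redundancy(hsv, ctx.vt).redundancy_fraction
        for name, hsv in ctx.hsv_sets.items()
    }
    out["ld_redundancy"] = ld
    p = ctx.out_dir / "annotation.json"
    p.write_text(json.dumps(out, indent=2))
    return [p]


def stage_evaluate(ctx: PipelineContext) -> list[Path]:
    data = _gene_data(ctx)
    rep = evaluation.evaluate(ctx.model, data)
    masked = evaluation.masked_evaluation(
        ctx.model, data, ctx.ref, ctx.vt, ctx.config.maf_mask_threshold)
    p = ctx.out_dir / "metrics.json"
    p.write_text(json.dumps({
        "surrogate": {"r2": rep.r2, "pcc": rep.pcc, "spearman": rep.spearman, "n": rep.n},
        "elastic_net": {"r2": ctx.en_model.test_r2, "pcc": ctx.en_model.test_pcc},
        "masked": masked,
    }, indent=2))
    return [p]


_STAGE_FN = {
    "simulate": stage_simulate,
    "encode": stage_encode,
    "prep": stage_prep,
    "baseline": stage_baseline,
    "train": stage_train,
    "ism": stage_ism,
    "annotate": stage_annotate,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: PipelineConfig, upto: str = "evaluate") -> PipelineContext:
    """Run stages in order up to (and including) ``upto``.

    Any stage failure aborts with the stage name attached; a manifest
    with config hash, seed, package version and per-file checksums is
    written at the end.
    """
    from .. import __version__

    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ctx = PipelineContext(config=config, out_dir=out_dir)
    stages = STAGES[: STAGES.index(upto) + 1]
    if not config.simulate:
        stages = [st for st in stages if st != "simulate"]
    for stage in stages:
        t0 = time.time()
        log.info("stage=%s seed=%d starting", stage, config.seed)
        try:
            files = _STAGE_FN[stage](ctx)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        elapsed = time.time() - t0
        ctx.record(stage, files, elapsed)
        log.info("stage=%s seed=%d wall_time=%.2fs done", stage, config.seed, elapsed)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": ctx.manifest,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ctx
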