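"""Evaluation metrics and experiments.

Held-out metrics (R², Pearson, Spearman), the rare-variant masking
experiment, the nested downsampling experiment with matched optimizer
update counts, multi-gene seen/unseen-gene evaluation and effect-size
agreement against the planted truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .baseline_en import fit_gene_baseline
from .genome_encoding import encode_cohort, mask_by_maf
from .ism_hsv import predict_variant_effect
from .s2f_model import GeneData, ModelConfig, train_single_gene
from .synthetic_data import ReferenceWindow, SyntheticTruth, VariantTable


@dataclass
class MetricsReport:
    gene: str
    model_id: str
    split: str
    n: int
    r2: float
    pcc: float
    spearman: float
    cohort_size: int | None = None
    constant_predictions: bool = False
    masked_pcc: dict[float, float] = field(default_factory=dict)


def r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    """1 - SSE/SST against the mean of the observed values."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values are constant; R2 undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def pearson(obs: np.ndarray, pred: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation; constant predictions report 0 with a flag."""
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0, True
    return float(np.corrcoef(obs, pred)[0, 1]), False


def evaluate_predictions(obs: np.ndarray, pred: np.ndarray, gene: str = "gene",
                         model_id: str = "", split: str = "test",
                         cohort_size: int | None = None) -> MetricsReport:
    pcc, flat = pearson(obs, pred)
    rho = 0.0 if flat else float(stats.spearmanr(obs, pred).statistic)
    return MetricsReport(
        gene=gene, model_id=model_id, split=split, n=len(obs),
        r2=r_squared(obs, pred), pcc=pcc, spearman=rho,
        cohort_size=cohort_size, constant_predictions=flat,
    )


def evaluate(model, data: GeneData, split: str = "test", gene: str = "gene",
             model_id: str = "surrogate") -> MetricsReport:
    """Score a trained surrogate on one split of a gene dataset."""
    idx = data.indices(split)
    cov = data.covariates[idx] if data.covariates is not None else None
    pred = model.predict_batch(data.encodings[idx], cov)
    return evaluate_predictions(data.expression[idx], pred, gene=gene,
                                model_id=model_id, split=split)


def masked_evaluation(model, data: GeneData, ref: ReferenceWindow,
                      vt: VariantTable, maf_threshold: float,
                      split: str = "test", gene: str = "gene") -> dict:
    """Paired full vs rare-masked evaluation on identical test individuals.

    The same trained model scores (1) encodings of the full personal
    genomes and (2) encodings rebuilt after zeroing dosages of variants
    with MAF below ``maf_threshold``; the PCC difference isolates the
    masked variants' contribution.
    """
    if not (0.0 < maf_threshold <= 0.5):
        raise ValueError(f"maf_threshold must be in (0, 0.5], got {maf_threshold}")
    idx = data.indices(split)
    cov = data.covariates[idx] if data.covariates is not None else None
    obs = data.expression[idx]

    full_pred = model.predict_batch(data.encodings[idx], cov)
    masked_vt = mask_by_maf(vt, maf_threshold)
    ids = [vt.individuals[i] for i in idx]
    masked_enc = encode_cohort(ref, masked_vt, individuals=ids).matrix
    masked_pred = model.predict_batch(masked_enc, cov)

    full_pcc, _ = pearson(obs, full_pred)
    masked_pcc, _ = pearson(obs, masked_pred)
    return {
        "gene": gene,
        "maf_threshold": maf_threshold,
        "n": len(idx),
        "full_pcc": full_pcc,
        "masked_pcc": masked_pcc,
        "delta_pcc": full_pcc - masked_pcc,
    }


def downsampling_experiment(data: GeneData, ref: ReferenceWindow, vt: VariantTable,
                            sizes: list[int], config: ModelConfig,
                            seed: int = 0, gene: str = "gene",
                            en_kwargs: dict | None = None) -> list[MetricsReport]:
    """Nested-cohort training of both model classes with a fixed test set.

    Training subsets are nested (individuals added cumulatively without
    replacement from a seeded permutation of the training split); the
    validation and test splits are identical across sizes and model
    classes.  The surrogate's effective batch size is scaled with the
    subset size so the optimizer update count matches across sizes.
    """
    rng = np.random.default_rng(seed)
    tr = data.indices("train")
    order = rng.permutation(tr)
    sizes = sorted(sizes)
    if sizes[-1] > len(tr):
        raise ValueError(f"requested size {sizes[-1]} exceeds training split ({len(tr)})")

    reports: list[MetricsReport] = []
    max_size = sizes[-1]
    for size in sizes:
        sub_train = order[:size]
        split = data.split.astype("<U8")
        split[tr] = "unused"
        split[sub_train] = "train"

        # elastic net on the same individuals
        en = fit_gene_baseline(vt, data.expression, split, **(en_kwargs or {}))
        te = np.flatnonzero(split == "test")
        reports.append(evaluate_predictions(
            data.expression[te], en.predict(vt.dosages[te]),
            gene=gene, model_id="elastic_net", cohort_size=size,
        ))

        # surrogate with matched optimizer update count
        scale = size / max_size
        eff = max(2, int(round(config.batch_size * config.accum_steps * scale)))
        bs = min(config.batch_size, eff)
        cfg = ModelConfig(**{**config.__dict__,
                             "batch_size": bs,
                             "accum_steps": max(1, eff // bs)})
        sub_data = GeneData(encodings=data.encodings, expression=data.expression,
                            covariates=data.covariates, split=split)
        model, _ = train_single_gene(sub_data, cfg)
        reports.append(evaluate(model, sub_data, gene=gene, model_id="surrogate"))
        reports[-1].cohort_size = size
    return reports


def pcc_difference_by_size(reports: list[MetricsReport]) -> dict[int, float]:
    """Per-cohort-size surrogate-minus-baseline PCC difference."""
    by = {}
    for r in reports:
        by.setdefault(r.cohort_size, {})[r.model_id] = r.pcc
    return {
        size: vals["surrogate"] - vals["elastic_net"]
        for size, vals in sorted(by.items())
        if "surrogate" in vals and "elastic_net" in vals
    }


def multigene_evaluation(model, datasets: dict[str, GeneData],
                         train_genes: set[str], split: str = "test") -> list[MetricsReport]:
    """Per-gene metrics for a multi-gene model, labelling seen vs unseen genes.

    Unseen-gene reports only ever use genes disjoint from the training
    gene set (asserted here).
    """
    reports = []
    for gene, data in datasets.items():
        seen = gene in train_genes
        rep = evaluate(model, data, split=split, gene=gene,
                       model_id="multigene_seen" if seen else "multigene_unseen")
        reports.append(rep)
    return reports


def effect_size_agreement(model, truth: SyntheticTruth, vt: VariantTable,
                          ref_encoding: np.ndarray,
                          covariates: np.ndarray | None = None) -> dict:
    """Predicted single-variant deltas vs planted betas for causal variants.

    Returns Spearman correlation and sign concordance between
    ``predict_variant_effect`` deltas and the planted per-allele effects.
    """
    causal = np.asarray(truth.causal_indices)
    if causal.size == 0:
        raise ValueError("no causal variants planted")
    betas = truth.beta[causal]
    deltas = np.array([
        predict_variant_effect(model, ref_encoding, vt.records[j], covariates)
        for j in causal
    ])
    nonzero = betas != 0
    if np.std(deltas) == 0:
        warnings.warn("constant predicted deltas; Spearman reported as 0", stacklevel=2)
        rho = 0.0
    else:
        rho = float(stats.spearmanr(deltas, betas).statistic)
    concord = float(np.mean(np.sign(deltas[nonzero]) == np.sign(betas[nonzero]))) if nonzero.any() else np.nan
    return {
        "n_causal": int(causal.size),
        "spearman": rho,
        "sign_concordance": concord,
        "predicted": deltas,
        "planted": betas,
    }
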