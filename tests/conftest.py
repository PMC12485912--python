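"""Shared fixtures: small synthetic gene bundles built fresh per test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import s2f.synthetic_data as sd
from s2f.baseline_en import ENModel, fit_gene_baseline
from s2f.cohort_prep import GeneCohort, split_cohort, split_vector
from s2f.genome_encoding import encode_cohort
from s2f.s2f_model import ExpressionPredictor, GeneData, ModelConfig, TrunkConfig, train_single_gene

#: trunk without convolutions — fastest configuration for training-heavy tests
FAST_TRUNK = TrunkConfig(conv_channels=(), kernels=(), dilations=())


@dataclass
class GeneBundle:
    """Everything a downstream test needs for one synthetic gene."""

    ref: sd.ReferenceWindow
    vt: sd.VariantTable
    truth: sd.SyntheticTruth
    dataset: sd.CohortDataset
    covariates: np.ndarray
    split: np.ndarray
    encodings: np.ndarray

    @property
    def gene_data(self) -> GeneData:
        return GeneData(encodings=self.encodings, expression=self.dataset.expression,
                        covariates=self.covariates, split=self.split)


def make_gene(seed: int, length: int = 1024, n: int = 1200, n_sites: int = 100,
              h2: float = 0.6, n_causal: int = 16,
              causal_indices: np.ndarray | None = None,
              rare_var_share: float | None = None,
              interactions: list | None = None,
              ld_block_size: int = 1, ld_flip_prob: float = 0.05,
              sigma_e: float | None = None) -> GeneBundle:
    """Deterministic synthetic gene with encodings and a 60/20/20 split."""
    ref = sd.simulate_reference(length, seed=seed)
    vt = sd.simulate_cohort(ref, n, n_sites, seed=seed + 1,
                            ld_block_size=ld_block_size, ld_flip_prob=ld_flip_prob)
    truth = sd.plant_effects(vt, n_causal, h2, rare_var_share=rare_var_share,
                             interactions=interactions, seed=seed + 2,
                             causal_indices=causal_indices)
    cov, names = sd.simulate_covariates(n, seed=seed + 3)
    dataset = sd.simulate_expression(truth, vt, cov, names, sigma_e=sigma_e, seed=seed + 4)
    gc = split_cohort(GeneCohort(gene="gene", retained=list(vt.individuals)),
                      seed=seed + 5)
    split = split_vector(gc, list(vt.individuals))
    encodings = encode_cohort(ref, vt).matrix
    return GeneBundle(ref=ref, vt=vt, truth=truth, dataset=dataset,
                      covariates=cov, split=split, encodings=encodings)


def train_fast(bundle: GeneBundle, seed: int = 0, epochs: int = 25,
               lr_peak: float = 5e-3, batch_size: int = 32, accum_steps: int = 1,
               **overrides) -> ExpressionPredictor:
    """Train the no-conv surrogate quickly on a bundle."""
    cfg = ModelConfig(length=bundle.ref.length,
                      n_covariates=bundle.covariates.shape[1],
                      epochs=epochs, seed=seed, lr_peak=lr_peak,
                      batch_size=batch_size, accum_steps=accum_steps,
                      trunk=FAST_TRUNK,
                      weight_decay=0.05, patience=8, **overrides)
    model, _ = train_single_gene(bundle.gene_data, cfg)
    return model


def fit_baseline(bundle: GeneBundle) -> ENModel:
    return fit_gene_baseline(bundle.vt, bundle.dataset.expression, bundle.split)


@pytest.fixture(scope="session")
def small_gene() -> GeneBundle:
    """A small additive gene reused by read-only tests."""
    return make_gene(seed=42, length=512, n=400, n_sites=50, h2=0.5, n_causal=8)
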