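"""In silico mutagenesis scoring and high-scoring-variant selection.

ISM is defined on the *reference* sequence: every position is mutated to
each of the three non-reference bases, one at a time, and the score at a
position is the signed mean of the three (mutant - reference) prediction
differences.  HSV sets are the top-n observed variants by absolute ISM
score, with n matched to the elastic-net nonzero-coefficient count so the
two model classes are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline_en import ENModel
from .synthetic_data import BASE_INDEX, ReferenceWindow, VariantTable


@dataclass
class ISMap:
    """Per-position ISM scores plus the reference prediction."""

    scores: np.ndarray  # (L,); NaN where not computed
    reference_prediction: float
    model_id: str = ""

    def at(self, pos: int) -> float:
        s = self.scores[pos]
        if np.isnan(s):
            raise ValueError(f"ISM score not computed at position {pos}")
        return float(s)


@dataclass
class HSVMember:
    variant_index: int
    pos: int
    score: float
    rank: int


@dataclass
class HSVSet:
    """Top-|members| observed variants by |score| (ties by position)."""

    gene: str
    n_target: int
    members: list[HSVMember]
    source_model: str = ""

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.members], dtype=np.int64)

    @property
    def variant_indices(self) -> np.ndarray:
        return np.array([m.variant_index for m in self.members], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.members)


def _check_reference_one_hot(enc: np.ndarray) -> None:
    if enc.ndim != 2 or enc.shape[1] != 4:
        raise ValueError(f"reference encoding must be (L, 4), got {enc.shape}")
    if not np.all(np.isin(enc, (0.0, 1.0))) or not np.all(enc.sum(axis=1) == 1.0):
        raise ValueError(
            "ISM is defined on the reference one-hot; personal encodings "
            "(fractional rows) are rejected"
        )


def ism_map(model, ref_encoding: np.ndarray, covariates: np.ndarray | None = None,
            positions: np.ndarray | None = None, batch_positions: int = 128,
            model_id: str = "") -> ISMap:
    """Saturation mutagenesis map over the window (or a position subset).

    ``model`` is anything exposing ``predict_batch(encodings, covariates)``.
    Mutants are scored in batches but the result is numerically identical
    to mutating one position at a time.  ``covariates``, if given, is a
    single vector (e.g. the cohort mean) reused for every mutant.
    """
    ref_encoding = np.asarray(ref_encoding)
    _check_reference_one_hot(ref_encoding)
    L = ref_encoding.shape[0]
    if positions is None:
        positions = np.arange(L)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size and (positions.min() < 0 or positions.max() >= L):
            raise ValueError("requested ISM positions outside the window")

    cov1 = None if covariates is None else np.atleast_2d(np.asarray(covariates))
    f_ref = float(model.predict_batch(ref_encoding[None], cov1)[0])

    ref_base = ref_encoding.argmax(axis=1)
    scores = np.full(L, np.nan)
    for lo in range(0, positions.size, batch_positions):
        chunk = positions[lo:lo + batch_positions]
        mut_encs = []
        for p in chunk:
            for b in range(4):
                if b == ref_base[p]:
                    continue
                m = ref_encoding.copy()
                m[p] = 0.0
                m[p, b] = 1.0
                mut_encs.append(m)
        batch = np.stack(mut_encs)
        cov = None if cov1 is None else np.repeat(cov1, batch.shape[0], axis=0)
        preds = model.predict_batch(batch, cov)
        deltas = preds.reshape(len(chunk), 3) - f_ref
        scores[chunk] = deltas.mean(axis=1)
    return ISMap(scores=scores, reference_prediction=f_ref, model_id=model_id)


def ism_map_affine_closed_form(weights: np.ndarray, ref_encoding: np.ndarray) -> np.ndarray:
    """Analytic ISM scores for an affine model with weight matrix (L, 4):
    score(p) = mean over the 3 non-reference bases b of (w[p,b] - w[p,ref_p])."""
    ref_encoding = np.asarray(ref_encoding)
    _check_reference_one_hot(ref_encoding)
    ref_base = ref_encoding.argmax(axis=1)
    L = weights.shape[0]
    w_ref = weights[np.arange(L), ref_base]
    return (weights.sum(axis=1) - w_ref) / 3.0 - w_ref


def select_hsv(ismap: ISMap, vt: VariantTable, n: int, gene: str = "gene",
               model_id: str = "") -> HSVSet:
    """Top-n observed variants by absolute ISM score.

    Candidates are restricted to positions carrying a variant in ``vt``;
    ties in |score| break by ascending genomic position so output files
    are deterministic.  ``n`` larger than the variant count saturates.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    pos = vt.positions
    scores = np.array([ismap.at(p) for p in pos])
    order = sorted(range(len(pos)), key=lambda j: (-abs(scores[j]), pos[j]))
    take = order[: min(n, len(pos))]
    members = [
        HSVMember(variant_index=j, pos=int(pos[j]), score=float(scores[j]), rank=r + 1)
        for r, j in enumerate(take)
    ]
    return HSVSet(gene=gene, n_target=n, members=members, source_model=model_id)


def hsv_from_elastic_net(en_model: ENModel, vt: VariantTable,
                         gene: str = "gene") -> HSVSet:
    """HSV set from the elastic-net coefficient support (score = coefficient)."""
    idx = en_model.nonzero_indices()
    pos = vt.positions
    coefs = en_model.coefficients
    order = sorted(idx, key=lambda j: (-abs(coefs[j]), pos[j]))
    members = [
        HSVMember(variant_index=int(j), pos=int(pos[j]), score=float(coefs[j]), rank=r + 1)
        for r, j in enumerate(order)
    ]
    return HSVSet(gene=gene, n_target=len(members), members=members,
                  source_model="elastic_net")


def predict_variant_effect(model, ref_encoding: np.ndarray, variant,
                           covariates: np.ndarray | None = None) -> float:
    """Predicted expression change from substituting one alt allele into
    the reference: f(ref with alt at pos) - f(ref)."""
    ref_encoding = np.asarray(ref_encoding)
    _check_reference_one_hot(ref_encoding)
    if not (0 <= variant.pos < ref_encoding.shape[0]):
        raise ValueError(f"variant position {variant.pos} outside window")
    cov1 = None if covariates is None else np.atleast_2d(np.asarray(covariates))
    mut = ref_encoding.copy()
    mut[variant.pos] = 0.0
    mut[variant.pos, BASE_INDEX[variant.alt]] = 1.0
    pair = np.stack([ref_encoding, mut])
    cov = None if cov1 is None else np.repeat(cov1, 2, axis=0)
    f = model.predict_batch(pair, cov)
    return float(f[1] - f[0])
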