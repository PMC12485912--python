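"""Per-gene cohort preparation.

Sample exclusion for epitope-binding artifacts (protein-altering variant
carriers), protein selection criteria, and the 60/20/20 split shared by
the linear baseline and the surrogate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import CohortDataset

#: consequence classes triggering per-gene sample exclusion
EXCLUSION_CLASSES = frozenset(
    {"missense", "stop_gained", "stop_lost", "start_lost", "frameshift"}
)
#: protein-altering classes that disqualify a cis signal for protein selection
SELECTION_PA_CLASSES = frozenset({"frameshift", "missense", "start_lost", "stop_gained"})

SPLIT_LABELS = ("train", "val", "test")


@dataclass
class GeneCohort:
    """Retained individuals, exclusions with reasons, and split assignment."""

    gene: str
    retained: list[str]
    excluded: dict[str, str] = field(default_factory=dict)
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.excluded)
        if overlap:
            raise ValueError(f"individuals both retained and excluded: {sorted(overlap)[:5]}")

    def ids_for(self, label: str) -> list[str]:
        return [i for i in self.retained if self.split.get(i) == label]

    @property
    def n_train(self) -> int:
        return len(self.ids_for("train"))

    @property
    def n_val(self) -> int:
        return len(self.ids_for("val"))

    @property
    def n_test(self) -> int:
        return len(self.ids_for("test"))


def exclude_protein_altering(cohort: CohortDataset, gene: str = "gene",
                             gene_body: tuple[int, int] | None = None) -> GeneCohort:
    """Drop individuals carrying any protein-altering variant in the gene body.

    ``gene_body`` is a 0-based half-open interval filter on the consequence
    table's ``pos`` column; rows with ``pos < 0`` (position unknown) are
    treated as inside the gene body.
    """
    table = cohort.consequence_table
    if table is None:
        raise ValueError("consequence table required for exclusion")
    hits = table[table["consequence"].isin(EXCLUSION_CLASSES)]
    if gene_body is not None and len(hits):
        lo, hi = gene_body
        inside = (hits["pos"] < 0) | ((hits["pos"] >= lo) & (hits["pos"] < hi))
        hits = hits[inside]
    flagged = {}
    for _, row in hits.iterrows():
        flagged.setdefault(row["individual"], row["consequence"])
    retained = [i for i in cohort.individuals if i not in flagged]
    if not retained:
        raise ValueError(f"all individuals excluded for gene {gene}")
    excluded = {i: f"protein_altering:{c}" for i, c in flagged.items() if i in set(cohort.individuals)}
    return GeneCohort(gene=gene, retained=retained, excluded=excluded)


def select_proteins(expression: pd.DataFrame, missingness_threshold: int,
                    pqtl_table: pd.DataFrame) -> list[str]:
    """Protein (gene) selection by missingness and cis-signal criteria.

    A gene is kept iff (1) its missing-measurement count across individuals
    is strictly below ``missingness_threshold`` and (2) the pqtl table has
    at least one in-window cis signal for it whose consequence is not
    protein-altering.

    ``expression`` is individuals x genes (NaN = missing); ``pqtl_table``
    needs columns ``gene``, ``in_window`` (bool) and ``consequence``.
    """
    missing = expression.isna().sum(axis=0)
    ok_signal = pqtl_table[
        pqtl_table["in_window"] & ~pqtl_table["consequence"].isin(SELECTION_PA_CLASSES)
    ]
    genes_with_signal = set(ok_signal["gene"])
    return [
        g for g in expression.columns
        if missing[g] < missingness_threshold and g in genes_with_signal
    ]


def split_cohort(gene_cohort: GeneCohort,
                 fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                 seed: int = 0) -> GeneCohort:
    """Random 60/20/20 (by default) split of the retained individuals.

    Validation and test sizes are floored; the remainder goes to training.
    Deterministic given the seed; the same split is reused by the elastic
    net and the surrogate model.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    ids = list(gene_cohort.retained)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 individuals to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    split = {}
    for k, idx in enumerate(order):
        if k < n_train:
            lab = "train"
        elif k < n_train + n_val:
            lab = "val"
        else:
            lab = "test"
        split[ids[idx]] = lab
    return GeneCohort(
        gene=gene_cohort.gene,
        retained=ids,
        excluded=dict(gene_cohort.excluded),
        split=split,
    )


def split_vector(gene_cohort: GeneCohort, individuals: list[str]) -> np.ndarray:
    """Split labels aligned to an individual ordering ('' if not retained)."""
    return np.array([gene_cohort.split.get(i, "") for i in individuals])
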