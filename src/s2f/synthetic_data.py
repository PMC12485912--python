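"""Synthetic cohort generator.

Produces every input the pipeline consumes — a reference window, cohort
genotypes with a rare-heavy allele-frequency spectrum, a phenotype with a
known (planted) genetic architecture, covariates, consequence annotations,
annotation tracks and PWMs — so all downstream stages are testable without
any external download.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: consequence classes that flag an individual for per-gene exclusion
PROTEIN_ALTERING_CLASSES = frozenset(
    {"missense", "stop_gained", "stop_lost", "start_lost", "frameshift"}
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceWindow:
    """A contiguous stretch of reference sequence centred on a TSS.

    Coordinates are 0-based half-open; ``tss_offset`` is the index of the
    transcription start site *within* the window.
    """

    chrom: str
    start: int
    length: int
    tss_offset: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        if not (0 <= self.tss_offset < self.length):
            raise ValueError(f"tss_offset {self.tss_offset} outside [0, {self.length})")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")

    @property
    def end(self) -> int:
        return self.start + self.length

    def one_hot(self, dtype=np.float32) -> np.ndarray:
        """Pure one-hot (L, 4) matrix of the reference sequence."""
        idx = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        lut = np.full(256, -1, dtype=np.int64)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        cols = lut[idx]
        out = np.zeros((self.length, 4), dtype=dtype)
        out[np.arange(self.length), cols] = 1
        return out

    def base_indices(self) -> np.ndarray:
        """Per-position reference base as an integer in 0..3."""
        return self.one_hot().argmax(axis=1)


@dataclass
class VariantRecord:
    """A biallelic SNV at a window-relative position (0-based)."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at position {self.pos}")


@dataclass
class VariantTable:
    """Biallelic SNVs with per-individual dosages and cohort MAF.

    ``dosages`` is an (individuals x variants) matrix with entries in
    {0, 1, 2}; ``maf`` is the empirical minor allele frequency per variant
    and is always recomputable from the dosage matrix.
    """

    records: list[VariantRecord]
    dosages: np.ndarray
    maf: np.ndarray
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.records):
            raise ValueError("dosage matrix shape inconsistent with records")
        if not self.individuals:
            self.individuals = [f"ind{i:05d}" for i in range(self.dosages.shape[0])]
        if len(self.individuals) != self.dosages.shape[0]:
            raise ValueError("individuals inconsistent with dosage matrix")
        seen = set()
        for r in self.records:
            key = (r.pos, r.alt)
            if key in seen:
                raise ValueError(f"duplicate record for position {r.pos} alt {r.alt}")
            seen.add(key)
        self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.pos for r in self.records], dtype=np.int64)

    def alt_allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant, dosage-column mean / 2."""
        if self.n_individuals == 0:
            return np.zeros(self.n_variants)
        return self.dosages.mean(axis=0) / 2.0

    def recompute_maf(self) -> np.ndarray:
        af = self.alt_allele_frequency()
        return np.minimum(af, 1.0 - af)

    def subset_individuals(self, index) -> "VariantTable":
        """Row-subset (by positional index) preserving records; MAF recomputed."""
        idx = np.asarray(index)
        sub = VariantTable(
            records=list(self.records),
            dosages=self.dosages[idx].copy(),
            maf=np.zeros(self.n_variants),
            individuals=[self.individuals[i] for i in idx],
        )
        sub.maf = sub.recompute_maf()
        return sub

    def validate_against_reference(self, ref: ReferenceWindow) -> None:
        for r in self.records:
            if not (0 <= r.pos < ref.length):
                raise ValueError(f"variant position {r.pos} outside window [0, {ref.length})")
            if ref.sequence[r.pos] != r.ref:
                raise ValueError(
                    f"ref allele mismatch at position {r.pos}: "
                    f"table says {r.ref}, reference has {ref.sequence[r.pos]}"
                )


@dataclass
class SyntheticTruth:
    """Planted genetic architecture used as ground truth in recovery tests."""

    causal_indices: np.ndarray
    beta: np.ndarray  # dense, one entry per variant; zero off the causal set
    interaction_pairs: list[tuple[int, int, float]]
    h2: float
    sigma_e: float
    covariate_effects: np.ndarray

    def genetic_component(self, vt: VariantTable) -> np.ndarray:
        """Additive + epistatic genetic value per individual."""
        g = vt.dosages.astype(float) @ self.beta
        for i, j, c in self.interaction_pairs:
            g = g + c * vt.dosages[:, i] * vt.dosages[:, j]
        return g


@dataclass
class CohortDataset:
    """Phenotype + covariates for one gene's cohort."""

    individuals: list[str]
    expression: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]
    consequence_table: "pd.DataFrame"  # columns: individual, consequence, pos
    split: np.ndarray | None = None  # per-individual label in {train,val,test}

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")
        if np.isnan(self.covariates).any():
            raise ValueError("covariate matrix has missing entries")


@dataclass
class AnnotationTrack:
    """Labelled intervals (0-based half-open) within a window."""

    intervals: list[tuple[int, int, str]]
    window_length: int
    tiling: bool = False

    def __post_init__(self) -> None:
        for s, e, _ in self.intervals:
            if not (0 <= s < e <= self.window_length):
                raise ValueError(f"interval ({s}, {e}) outside [0, {self.window_length})")
        if self.tiling:
            ordered = sorted(self.intervals)
            pos = 0
            for s, e, _ in ordered:
                if s != pos:
                    raise ValueError("tiling track has a gap or overlap")
                pos = e
            if pos != self.window_length:
                raise ValueError("tiling track does not cover the window")

    def coverage_fraction(self, label: str) -> float:
        return sum(e - s for s, e, lab in self.intervals if lab == label) / self.window_length

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, lab in self.intervals:
            seen.setdefault(lab)
        return list(seen)

    def label_at(self, pos: int) -> str | None:
        """Label at a position; first matching interval wins."""
        for s, e, lab in self.intervals:
            if s <= pos < e:
                return lab
        return None


@dataclass
class PWM:
    """A position weight matrix with background and pseudocount.

    ``matrix`` is 4 x w (rows in A,C,G,T order) of probabilities; the
    effective matrix after pseudocount regularisation is what scanners use.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A,C,G,T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(self.effective_matrix() <= 0):
            raise ValueError("zero-probability PWM cell without pseudocount")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def effective_matrix(self) -> np.ndarray:
        """Probability matrix after pseudocount, columns renormalised."""
        m = self.matrix + self.pseudocount
        return m / m.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_reference(length: int, gc: float = 0.41, seed: int = 0,
                       chrom: str = "chrS") -> ReferenceWindow:
    """I.i.d. reference sequence with a target GC fraction.

    The TSS is placed at ``floor(length / 2)``.
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])
    return ReferenceWindow(
        chrom=chrom, start=0, length=length, tss_offset=length // 2, sequence=seq
    )


def sample_site_frequencies(n_sites: int, rng: np.random.Generator,
                            rare_weight: float = 0.6,
                            beta_a: float = 0.2, beta_b: float = 8.0) -> np.ndarray:
    """Allele frequencies from a rare-heavy mixture.

    With probability ``rare_weight`` a site frequency is drawn from
    Beta(a, b) (mass concentrated near zero), otherwise from
    Uniform(0.05, 0.5).  The mixture makes the count of observed rare
    variants grow with cohort size, as in population sequencing data.
    """
    from_beta = rng.random(n_sites) < rare_weight
    freqs = np.where(
        from_beta,
        rng.beta(beta_a, beta_b, size=n_sites),
        rng.uniform(0.05, 0.5, size=n_sites),
    )
    return np.clip(freqs, 1e-6, 0.5)


def simulate_cohort(ref: ReferenceWindow, n: int, n_sites: int,
                    maf_mix: dict | None = None, seed: int = 0,
                    ld_block_size: int = 1, ld_flip_prob: float = 0.05) -> VariantTable:
    """Cohort genotypes at Hardy–Weinberg proportions.

    Sites are distinct positions in the window; per-site allele frequencies
    come from :func:`sample_site_frequencies`; genotypes are Binomial(2, f)
    dosages.  Monomorphic sites (empirical alt frequency 0 or 1) are
    dropped so the table never contains MAF-0 records.

    With ``ld_block_size > 1``, consecutive sites form blocks whose dosage
    columns are copies of the block seed column with per-individual
    re-draws at probability ``ld_flip_prob`` — a crude but controllable
    block-LD mode for redundancy statistics.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if n_sites >= ref.length:
        raise ValueError(f"n_sites ({n_sites}) must be < window length ({ref.length})")
    rng = np.random.default_rng(seed)
    maf_mix = maf_mix or {}
    positions = np.sort(rng.choice(ref.length, size=n_sites, replace=False))
    freqs = sample_site_frequencies(n_sites, rng, **maf_mix)

    dosages = np.empty((n, n_sites), dtype=np.int8)
    if ld_block_size <= 1:
        dosages[:] = rng.binomial(2, freqs[None, :], size=(n, n_sites))
    else:
        col = None
        for j in range(n_sites):
            if j % ld_block_size == 0 or col is None:
                col = rng.binomial(2, freqs[j], size=n).astype(np.int8)
            else:
                redraw = rng.random(n) < ld_flip_prob
                col = col.copy()
                col[redraw] = rng.binomial(2, freqs[j], size=int(redraw.sum()))
            dosages[:, j] = col

    ref_bases = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    records = []
    keep = []
    for j, pos in enumerate(positions):
        af = dosages[:, j].mean() / 2.0
        if af == 0.0 or af == 1.0:
            continue  # monomorphic in this cohort
        ref_base = chr(ref_bases[pos])
        alts = [b for b in BASES if b != ref_base]
        alt = alts[rng.integers(3)]
        records.append(VariantRecord(pos=int(pos), ref=ref_base, alt=alt))
        keep.append(j)
    vt = VariantTable(
        records=records,
        dosages=dosages[:, keep],
        maf=np.zeros(len(keep)),
    )
    vt.maf = vt.recompute_maf()
    return vt


def plant_effects(vt: VariantTable, n_causal: int, h2: float,
                  rare_var_share: float | None = None,
                  interactions: list[tuple[int, int, float]] | None = None,
                  seed: int = 0, rare_maf_threshold: float = 0.05,
                  covariate_effects: np.ndarray | None = None,
                  causal_indices: np.ndarray | None = None) -> SyntheticTruth:
    """Plant additive (and optionally epistatic) effects at a target h².

    Additive betas are drawn N(0, 1) on a random causal subset and then
    rescaled so the empirical genetic variance on this cohort equals
    ``h2`` (total phenotypic variance is normalised to 1:
    ``sigma_e = sqrt(1 - h2)``).  When ``rare_var_share`` is given, the
    causal variants with MAF < ``rare_maf_threshold`` are scaled to
    contribute exactly that share of the genetic variance.

    Interaction coefficients are taken literally (the phenotype includes
    exactly ``c * dos_i * dos_j``); the additive part absorbs the h²
    normalisation around them.

    ``causal_indices`` fixes the causal set explicitly (otherwise a
    random subset of size ``n_causal`` is drawn).
    """
    if not (0.0 <= h2 < 1.0):
        raise ValueError(f"h2 must be in [0, 1), got {h2}")
    if n_causal > vt.n_variants:
        raise ValueError("n_causal exceeds variant count")
    rng = np.random.default_rng(seed)
    interactions = list(interactions or [])
    cov_eff = np.asarray(covariate_effects if covariate_effects is not None else [])

    beta = np.zeros(vt.n_variants)
    if causal_indices is not None:
        causal = np.sort(np.asarray(causal_indices, dtype=np.int64))
        n_causal = causal.size
        if causal.size and (causal.min() < 0 or causal.max() >= vt.n_variants):
            raise ValueError("causal_indices outside variant range")
    else:
        causal = np.sort(rng.choice(vt.n_variants, size=n_causal, replace=False))
    if h2 == 0.0:
        return SyntheticTruth(causal, beta, [], 0.0, 1.0, cov_eff)

    beta[causal] = rng.standard_normal(n_causal)
    X = vt.dosages.astype(float)

    g_int = np.zeros(vt.n_individuals)
    for i, j, c in interactions:
        g_int += c * X[:, i] * X[:, j]
    v_int = g_int.var()
    if v_int >= h2:
        raise ValueError("interaction variance alone exceeds target h2")

    rare = np.zeros(vt.n_variants, dtype=bool)
    rare[causal] = vt.maf[causal] < rare_maf_threshold
    if rare_var_share is not None and rare_var_share > 0 and not rare.any():
        raise ValueError("rare_var_share requested but no rare causal variants available")

    if rare_var_share is not None and rare.any() and (~rare[causal]).any():
        common = np.zeros(vt.n_variants, dtype=bool)
        common[causal] = ~rare[causal]
        g_r = X[:, rare] @ beta[rare]
        g_c = X[:, common] @ beta[common]
        v_r = g_r.var()
        if v_r > 0:
            beta[rare] *= np.sqrt(rare_var_share * h2 / v_r)
            g_r = X[:, rare] @ beta[rare]
        # solve a >= 0 with var(a*g_c + g_r + g_int) = h2
        other = g_r + g_int
        v_c = g_c.var()
        cov = np.cov(g_c, other)[0, 1] if v_c > 0 else 0.0
        rhs = h2 - other.var()
        if v_c > 0 and rhs > 0:
            a = (-cov + np.sqrt(cov**2 + v_c * rhs)) / v_c
            beta[common] *= a
        elif v_c > 0:
            beta[common] = 0.0
    else:
        g_a = X @ beta
        v_a = g_a.var()
        cov = np.cov(g_a, g_int)[0, 1] if (v_a > 0 and v_int > 0) else 0.0
        rhs = h2 - v_int
        if v_a > 0:
            a = (-cov + np.sqrt(cov**2 + v_a * rhs)) / v_a
            beta *= a

    return SyntheticTruth(
        causal_indices=causal,
        beta=beta,
        interaction_pairs=interactions,
        h2=h2,
        sigma_e=float(np.sqrt(1.0 - h2)),
        covariate_effects=cov_eff,
    )


DEFAULT_COVARIATE_EFFECT = 0.05


def simulate_covariates(n: int, n_geno_pcs: int = 5, n_expr_pcs: int = 5,
                        seed: int = 0) -> tuple[np.ndarray, list[str]]:
    """Covariate matrix emulating (sex, age, BMI, genotype PCs, expression
    PCs, eGFR); all columns standardised except binary sex."""
    rng = np.random.default_rng(seed)
    names = (
        ["sex", "age", "bmi"]
        + [f"geno_pc{i+1}" for i in range(n_geno_pcs)]
        + [f"expr_pc{i+1}" for i in range(n_expr_pcs)]
        + ["egfr"]
    )
    cols = [rng.integers(0, 2, size=n).astype(float)]
    cols += [rng.standard_normal(n) for _ in range(len(names) - 1)]
    return np.column_stack(cols), names


def simulate_expression(truth: SyntheticTruth, vt: VariantTable,
                        covariates: np.ndarray | None = None,
                        covariate_names: list[str] | None = None,
                        sigma_e: float | None = None, seed: int = 0,
                        protein_altering_fraction: float = 0.0) -> CohortDataset:
    """NPX-like continuous phenotype from the planted architecture.

    expression = genetic component + covariate effects + N(0, sigma_e²).
    The genetic component is fully determined by ``truth`` and ``vt``;
    only the noise (and the protein-altering carrier flags) consume the
    seed, so two seeds share an identical genetic component.
    """
    import pandas as pd

    if sigma_e is None:
        sigma_e = truth.sigma_e
    if sigma_e < 0:
        raise ValueError("sigma_e must be non-negative")
    rng = np.random.default_rng(seed)
    n = vt.n_individuals

    g = truth.genetic_component(vt)
    y = g.copy()
    if covariates is None:
        covariates = np.zeros((n, 0))
        covariate_names = []
    covariates = np.asarray(covariates, dtype=float)
    if covariate_names is None:
        covariate_names = [f"cov{i}" for i in range(covariates.shape[1])]
    eff = truth.covariate_effects
    if eff.size == 0 and covariates.shape[1] > 0:
        eff = np.full(covariates.shape[1], DEFAULT_COVARIATE_EFFECT)
    if covariates.shape[1]:
        if eff.shape[0] != covariates.shape[1]:
            raise ValueError("covariate_effects length mismatch")
        y = y + covariates @ eff
    y = y + rng.normal(0.0, sigma_e, size=n)

    carriers = rng.random(n) < protein_altering_fraction
    consequence_rows = [
        {"individual": vt.individuals[i], "consequence": "missense", "pos": -1}
        for i in np.flatnonzero(carriers)
    ]
    consequence_table = pd.DataFrame(
        consequence_rows, columns=["individual", "consequence", "pos"]
    )
    return CohortDataset(
        individuals=list(vt.individuals),
        expression=y,
        covariates=covariates,
        covariate_names=list(covariate_names),
        consequence_table=consequence_table,
    )


def simulate_annotations(ref: ReferenceWindow,
                         state_config: dict[str, float] | None = None,
                         ccre_config: dict[str, float] | None = None,
                         n_pwms: int = 3, pwm_width: int = 8,
                         pwm_concentration: float = 20.0,
                         seed: int = 0,
                         mean_interval: int = 200) -> tuple[AnnotationTrack, AnnotationTrack, list[PWM]]:
    """ChromHMM-style tiling track, sparse cCRE-style track, and PWMs.

    ``state_config`` maps state name -> target coverage fraction (sum <= 1);
    uncovered intervals get the filler state ``"Quies"``.  The tiling track
    partitions [0, L).  ``ccre_config`` maps cCRE class -> coverage
    fraction for the sparse track.
    """
    state_config = state_config if state_config is not None else {"Enh": 0.15, "TssA": 0.05}
    ccre_config = ccre_config if ccre_config is not None else {"pELS": 0.05, "dELS": 0.05, "PLS": 0.02}
    total = sum(state_config.values())
    if total > 1.0 + 1e-12:
        raise ValueError(f"state coverage fractions sum to {total} > 1")
    if sum(ccre_config.values()) > 1.0 + 1e-12:
        raise ValueError("cCRE coverage fractions sum to > 1")
    rng = np.random.default_rng(seed)
    L = ref.length

    # tiling track: random breakpoints, greedy quota assignment
    n_iv = max(2, int(round(L / mean_interval)))
    breaks = np.sort(rng.choice(np.arange(1, L), size=min(n_iv - 1, L - 1), replace=False))
    bounds = np.concatenate([[0], breaks, [L]])
    ivs = [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]
    order = rng.permutation(len(ivs))
    quotas = {s: f * L for s, f in state_config.items()}
    labelled = []
    for k in order:
        s, e = ivs[k]
        width = e - s
        lab = "Quies"
        for state in quotas:
            if quotas[state] > 0:
                lab = state
                quotas[state] -= width
                break
        labelled.append((s, e, lab))
    tiling = AnnotationTrack(sorted(labelled), window_length=L, tiling=True)

    # sparse cCRE track: non-overlapping elements
    element_width = max(20, mean_interval // 2)
    ccre_ivs: list[tuple[int, int, str]] = []
    occupied = np.zeros(L, dtype=bool)
    for cls, frac in ccre_config.items():
        target = int(frac * L)
        placed = 0
        attempts = 0
        while placed < target and attempts < 10_000:
            attempts += 1
            s = int(rng.integers(0, L - element_width))
            e = s + element_width
            if occupied[s:e].any():
                continue
            occupied[s:e] = True
            ccre_ivs.append((s, e, cls))
            placed += element_width
    ccre = AnnotationTrack(sorted(ccre_ivs), window_length=L, tiling=False)

    pwms = []
    for m in range(n_pwms):
        cols = []
        for _ in range(pwm_width):
            alpha = np.ones(4)
            alpha[rng.integers(4)] = pwm_concentration
            cols.append(rng.dirichlet(alpha))
        pwms.append(PWM(motif_id=f"MOTIF{m+1}", matrix=np.array(cols).T))
    return tiling, ccre, pwms


def nested_subsets(n_total: int, sizes: list[int]) -> dict[int, np.ndarray]:
    """Nested index subsets (first-k) for the downsampling experiment."""
    out = {}
    for k in sorted(sizes):
        if k > n_total:
            raise ValueError(f"requested size {k} exceeds cohort size {n_total}")
        out[k] = np.arange(k)
    return out


def realized_h2(truth: SyntheticTruth, vt: VariantTable,
                dataset: CohortDataset | None = None) -> float:
    """Empirical genetic-variance fraction Var(g) / (Var(g) + sigma_e²)."""
    g = truth.genetic_component(vt)
    return float(g.var() / (g.var() + truth.sigma_e**2))
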