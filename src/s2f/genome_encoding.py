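"""Personalised one-hot genome encoding.

Batch reconstruction of individualised L x 4 sequence matrices from a
variant table plus reference window, with the 0 / 0.5 / 1 dosage
convention: at a biallelic SNV carried at dosage d in {0, 1, 2}, the alt
channel gets d/2 and the ref channel 1 - d/2, so every row stays on the
one-hot simplex.  Channels are ordered (A, C, G, T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import BASE_INDEX, BASES, ReferenceWindow, VariantTable


@dataclass
class PersonalEncoding:
    """One individual's L x 4 dosage-weighted one-hot matrix."""

    individual: str
    matrix: np.ndarray

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


@dataclass
class EncodingBatch:
    """Encodings for a cohort, stacked as (individuals, L, 4)."""

    individuals: list[str]
    matrix: np.ndarray

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, i: int) -> PersonalEncoding:
        return PersonalEncoding(self.individuals[i], self.matrix[i])


def encode_cohort(ref: ReferenceWindow, vt: VariantTable,
                  individuals: list[str] | None = None,
                  dtype=np.float32) -> EncodingBatch:
    """Vectorised construction of per-individual encodings.

    A single pass over the variant table updates all individuals at once;
    the result is bit-identical to building each consensus sequence
    base-by-base.  Non-SNV records are skipped with a warning; a ref
    allele that contradicts the reference sequence is an error.

    Raises
    ------
    ValueError
        On out-of-window positions, ref-allele mismatch, or two records at
        the same position (ambiguous overlay).
    """
    if individuals is None:
        individuals = list(vt.individuals)
    ind_index = {ind: i for i, ind in enumerate(vt.individuals)}
    try:
        rows = np.array([ind_index[i] for i in individuals])
    except KeyError as e:
        raise ValueError(f"unknown individual {e.args[0]!r}") from None

    base = ref.one_hot(dtype=dtype)
    out = np.broadcast_to(base, (len(individuals), ref.length, 4)).copy()

    keep, ref_idx, alt_idx, positions = [], [], [], []
    seen_pos: set[int] = set()
    for j, rec in enumerate(vt.records):
        if len(rec.ref) != 1 or len(rec.alt) != 1 or rec.ref not in BASES or rec.alt not in BASES:
            warnings.warn(
                f"skipping non-SNV record at position {rec.pos} ({rec.ref}>{rec.alt})",
                stacklevel=2,
            )
            continue
        if not (0 <= rec.pos < ref.length):
            raise ValueError(f"variant position {rec.pos} outside window [0, {ref.length})")
        if ref.sequence[rec.pos] != rec.ref:
            raise ValueError(
                f"ref allele mismatch at position {rec.pos}: table {rec.ref}, "
                f"reference {ref.sequence[rec.pos]}"
            )
        if rec.pos in seen_pos:
            raise ValueError(f"two variant records at position {rec.pos}")
        seen_pos.add(rec.pos)
        keep.append(j)
        positions.append(rec.pos)
        ref_idx.append(BASE_INDEX[rec.ref])
        alt_idx.append(BASE_INDEX[rec.alt])

    if keep:
        half = (vt.dosages[np.ix_(rows, keep)].astype(dtype)) / 2.0  # (n, v)
        positions = np.array(positions)
        out[:, positions, np.array(alt_idx)] = half
        out[:, positions, np.array(ref_idx)] = 1.0 - half
    return EncodingBatch(individuals=list(individuals), matrix=out)


def extract_window(genome, chrom: str, tss: int, length: int) -> ReferenceWindow:
    """Extract a TSS-centred window from an indexed FASTA.

    ``tss`` is 1-based (as in annotation files); the returned window is
    0-based half-open ``[tss - 1 - L//2, tss - 1 - L//2 + L)`` with
    ``tss_offset = L // 2``.

    ``genome`` may be a path to a FASTA file or an open
    :class:`pyfaidx.Fasta` handle.
    """
    import pyfaidx

    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(str(genome))
    if chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom!r}")
    chrom_len = len(genome[chrom])
    start = tss - 1 - length // 2
    end = start + length
    if start < 0 or end > chrom_len:
        raise ValueError(
            f"window [{start}, {end}) out of bounds for {chrom} (length {chrom_len})"
        )
    seq = str(genome[chrom][start:end]).upper()
    return ReferenceWindow(
        chrom=chrom, start=start, length=length, tss_offset=length // 2, sequence=seq
    )


def mask_by_maf(vt: VariantTable, threshold: float) -> VariantTable:
    """Zero the dosages of variants with MAF strictly below ``threshold``.

    Returns a copy; retained variants (MAF >= threshold) are untouched.
    Encoding the masked table yields the "rare-masked genome" in which
    masked sites revert to the reference allele for every individual.
    """
    if not (0.0 < threshold <= 0.5):
        raise ValueError(f"threshold must be in (0, 0.5], got {threshold}")
    dosages = vt.dosages.copy()
    masked = vt.maf < threshold
    dosages[:, masked] = 0
    out = VariantTable(
        records=list(vt.records),
        dosages=dosages,
        maf=np.zeros(vt.n_variants),
        individuals=list(vt.individuals),
    )
    out.maf = out.recompute_maf()
    return out


def recover_variants(encoding: PersonalEncoding, ref: ReferenceWindow) -> list[tuple[int, str, str, int]]:
    """Invert an encoding back to (pos, ref, alt, dosage) for dosage > 0."""
    ref_oh = ref.one_hot(dtype=encoding.matrix.dtype)
    diff_pos = np.flatnonzero(np.abs(encoding.matrix - ref_oh).sum(axis=1) > 0)
    out = []
    for p in diff_pos:
        row = encoding.matrix[p]
        ref_i = BASE_INDEX[ref.sequence[p]]
        alt_i = int(np.argmax(np.where(np.arange(4) == ref_i, -1.0, row)))
        dosage = int(round(float(row[alt_i]) * 2))
        out.append((int(p), ref.sequence[p], BASES[alt_i], dosage))
    return out
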