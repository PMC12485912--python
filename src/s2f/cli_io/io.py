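"""Readers and writers for the pipeline's standard text formats.

Conventions: VCF is 1-based (v4.2, GT-only, unphased accepted and phased
separators collapsed to dosage); BED and all internal window coordinates
are 0-based half-open.  Conversions happen only here.  Every writer puts
the coordinate convention in the file header.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ..synthetic_data import (
    AnnotationTrack,
    CohortDataset,
    PWM,
    ReferenceWindow,
    VariantRecord,
    VariantTable,
)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path, ref: ReferenceWindow, line_width: int = 60) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f">{ref.chrom} window_start={ref.start} tss_offset={ref.tss_offset} "
                 "coords=0-based_half_open\n")
        for i in range(0, ref.length, line_width):
            fh.write(ref.sequence[i:i + line_width] + "\n")
    return path


def read_fasta(path) -> ReferenceWindow:
    """Read a single-record FASTA written by :func:`write_fasta`."""
    header = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if header is not None:
                raise ValueError("expected a single-record FASTA")
            header = line[1:]
        elif line.strip():
            chunks.append(line.strip())
    if header is None:
        raise ValueError("no FASTA record found")
    fields = header.split()
    chrom = fields[0]
    meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
    seq = "".join(chunks).upper()
    return ReferenceWindow(
        chrom=chrom,
        start=int(meta.get("window_start", 0)),
        length=len(seq),
        tss_offset=int(meta.get("tss_offset", len(seq) // 2)),
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, ref: ReferenceWindow, vt: VariantTable) -> Path:
    """VCF v4.2 with unphased GT fields; POS is 1-based absolute."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.chrom},length={ref.end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##coordinate_convention=VCF 1-based; window coords 0-based half-open\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.individuals) + "\n")
        for j, rec in enumerate(vt.records):
            gts = "\t".join(_GT_BY_DOSAGE[int(d)] for d in vt.dosages[:, j])
            fh.write(f"{ref.chrom}\t{ref.start + rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def read_vcf(path, ref: ReferenceWindow) -> VariantTable:
    """Parse biallelic SNVs into a VariantTable (window-relative positions).

    GT-only; phased separators are collapsed to dosage; non-SNV or
    multi-allelic records are skipped with a warning; missing genotypes
    count as reference.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        records: list[VariantRecord] = []
        columns: list[np.ndarray] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(f"skipping multi-allelic record at {rec.pos}", stacklevel=2)
                continue
            ref_a, alt_a = rec.ref, rec.alts[0]
            if len(ref_a) != 1 or len(alt_a) != 1:
                warnings.warn(f"skipping non-SNV record at {rec.pos}", stacklevel=2)
                continue
            dos = np.zeros(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT") or ()
                dos[i] = sum(1 for a in gt if a == 1)
            records.append(VariantRecord(pos=rec.start - ref.start, ref=ref_a, alt=alt_a))
            columns.append(dos)
    dosages = (np.column_stack(columns) if columns
               else np.zeros((len(samples), 0), dtype=np.int8))
    vt = VariantTable(records=records, dosages=dosages,
                      maf=np.zeros(len(records)), individuals=samples)
    vt.maf = vt.recompute_maf()
    return vt


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_expression_tsv(path, dataset: CohortDataset) -> Path:
    path = Path(path)
    df = pd.DataFrame({"individual": dataset.individuals, "npx": dataset.expression})
    for k, name in enumerate(dataset.covariate_names):
        df[name] = dataset.covariates[:, k]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_expression_tsv(path) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    individuals = df["individual"].astype(str).tolist()
    expression = df["npx"].to_numpy(dtype=float)
    cov_names = [c for c in df.columns if c not in ("individual", "npx")]
    covariates = df[cov_names].to_numpy(dtype=float) if cov_names else np.zeros((len(df), 0))
    return individuals, expression, covariates, cov_names


def write_consequence_tsv(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_consequence_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual": str})


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(path, track: AnnotationTrack, chrom: str = "chrS") -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write('track name="annotation" description="coords=0-based_half_open"\n')
        for s, e, lab in sorted(track.intervals):
            fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")
    return path


def read_bed(path, window_length: int, tiling: bool = False) -> AnnotationTrack:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        intervals.append((int(fields[1]), int(fields[2]), fields[3]))
    return AnnotationTrack(intervals=intervals, window_length=window_length, tiling=tiling)


# ---------------------------------------------------------------------------
# MEME minimal-format PWMs
# ---------------------------------------------------------------------------


def write_meme(path, pwms: list[PWM]) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width} "
                     f"nsites= 20 E= 0\n")
            for col in p.matrix.T:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")
    return path


def read_meme(path, pseudocount: float = 1e-3) -> list[PWM]:
    lines = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            width = int(lines[i].split("w=")[1].split()[0])
            cols = []
            for k in range(width):
                i += 1
                cols.append([float(v) for v in lines[i].split()])
            matrix = np.array(cols).T
            matrix = matrix / matrix.sum(axis=0, keepdims=True)  # tolerate rounding
            pwms.append(PWM(motif_id=motif_id, matrix=matrix,
                            background=background, pseudocount=pseudocount))
        i += 1
    return pwms


# ---------------------------------------------------------------------------
# checksums
# ---------------------------------------------------------------------------


def sha256sum(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
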