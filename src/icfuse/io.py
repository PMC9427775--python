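"""Readers and writers for the pipeline's plain-text formats.

Formats: TSV matrices (first column = feature ids, header = sample ids),
GMT gene-set files, variant candidate tables (TSV or minimal VCF v4 with
AD/DP genotype fields), and the clinical table. TSV dialect: tab-separated,
UTF-8, "." for missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ClinicalRecord,
    Effect,
    GeneSetCollection,
    Layer,
    OmicsMatrix,
    ValidationError,
    VariantRecord,
    clinical_from_frame,
    clinical_to_frame,
)

log = logging.getLogger("icfuse")

_MISSING = "."


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------

def read_omics_tsv(path: str | Path, layer: Layer | str) -> OmicsMatrix:
    """Read a features x samples TSV into a validated :class:`OmicsMatrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_MISSING])
    if df.columns.size == 0:
        raise ValidationError(f"{path}: malformed header (no sample columns)")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[~df[col].map(_is_number)][0]
            raise ValidationError(
                f"{path}: non-numeric cell at feature {bad!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(df.astype(float), layer)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_omics_tsv(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> gene ...).

    The description column is discarded; duplicate genes within a line are
    deduplicated (count logged); lines with fewer than three fields raise a
    parse error naming the line.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                f"got {len(parts)}"
            )
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        seen: set[str] = set()
        uniq = [g for g in genes if not (g in seen or seen.add(g))]
        if len(uniq) < len(genes):
            log.info("gmt: %s line %d: removed %d duplicate genes",
                     name, lineno, len(genes) - len(uniq))
        if name in sets:
            raise ValidationError(f"{path}: line {lineno}: duplicate set {name!r}")
        sets[name] = uniq
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, _MISSING, *genes]) + "\n")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_BOOL_FIELDS = (
    "is_indel", "is_hotspot", "in_snp_db", "in_simple_repeat",
    "seen_in_paired_normal", "copy_neutral", "confirmed_somatic_by_wes",
)
_INT_FIELDS = ("pos", "depth_tumor", "depth_normal", "alt_reads_tumor",
               "reads_fwd", "reads_rev")
_FLOAT_FIELDS = ("vaf_tumor", "vaf_normal", "mapq", "baseq", "ebcall_p",
                 "fisher_p")


def read_variants(path: str | Path, format: str = "tsv") -> list[VariantRecord]:
    """Read candidate variants from a TSV table or a minimal VCF v4 file.

    Missing flag columns default to False, missing effect to ``ambiguous``;
    ``vaf_tumor`` is recomputed as alt/depth when absent.
    """
    if format == "tsv":
        return _read_variants_tsv(path)
    if format == "vcf_minimal":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant format: {format!r}")


def _read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_MISSING])
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for name in VariantRecord.field_names():
            if name not in row or pd.isna(row[name]):
                continue
            v = row[name]
            if name in _BOOL_FIELDS:
                v = str(v).strip().lower() in ("true", "1", "yes")
            elif name in _INT_FIELDS:
                v = int(float(v))
            elif name in _FLOAT_FIELDS:
                v = float(v)
            kwargs[name] = v
        if "vaf_tumor" not in kwargs and kwargs.get("depth_tumor"):
            kwargs["vaf_tumor"] = kwargs.get("alt_reads_tumor", 0) / kwargs["depth_tumor"]
        if "reads_fwd" not in kwargs and "reads_rev" not in kwargs:
            alt = kwargs.get("alt_reads_tumor", 0)
            kwargs["reads_fwd"] = alt - alt // 2
            kwargs["reads_rev"] = alt // 2
        records.append(VariantRecord(**kwargs))
    return records


def _read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for var in vcf:
        ad = var.format("AD")
        dp = var.format("DP")
        if ad is None or dp is None:
            raise ValidationError(
                f"{path}: {var.CHROM}:{var.POS}: missing AD/DP genotype fields"
            )
        ref_reads, alt_reads = int(ad[0][0]), int(ad[0][1])
        depth = int(dp[0][0]) if np.ndim(dp[0]) else int(dp[0])
        gene = var.INFO.get("GENE") or _MISSING
        case = samples[0] if samples else _MISSING
        alt_allele = var.ALT[0] if var.ALT else _MISSING
        records.append(VariantRecord(
            case_id=str(case),
            chrom=str(var.CHROM),
            pos=int(var.POS),
            ref=str(var.REF),
            alt=str(alt_allele),
            gene=str(gene),
            effect=Effect(var.INFO.get("EFFECT", "ambiguous")),
            is_indel=len(var.REF) != len(alt_allele),
            depth_tumor=depth,
            alt_reads_tumor=alt_reads,
            vaf_tumor=alt_reads / depth if depth else 0.0,
            reads_fwd=alt_reads - alt_reads // 2,
            reads_rev=alt_reads // 2,
        ))
    return records


def write_variants(records: list[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in VariantRecord.field_names()}
        row["effect"] = r.effect.value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", na_values=[_MISSING])
    df["case_id"] = df["case_id"].astype(str)
    return clinical_from_frame(df)


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    df = clinical_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep=_MISSING)


# ---------------------------------------------------------------------------
# cohort validation
# ---------------------------------------------------------------------------

def validate_cohort(
    omics: list[OmicsMatrix],
    clinical: list[ClinicalRecord] | None = None,
    variants: list[VariantRecord] | None = None,
) -> dict:
    """Check sample agreement across omics layers and annotate stragglers.

    All omics layers must carry the same sample-id set (order may differ;
    layers after the first are re-ordered in place of the returned copies).
    Cases present only in the clinical or variant tables are reported, not
    fatal. Returns a report dict with the aligned matrices.
    """
    if not omics:
        raise ValidationError("at least one omics layer is required")
    ref_ids = omics[0].sample_ids
    ref_set = set(ref_ids)
    aligned = [omics[0]]
    for layer in omics[1:]:
        ids = set(layer.sample_ids)
        if ids != ref_set:
            missing = sorted(ref_set - ids) + sorted(ids - ref_set)
            raise ValidationError(
                f"omics layers disagree on samples; mismatched ids: {missing}"
            )
        aligned.append(layer.reorder_samples(ref_ids))
    clinical_only = sorted(
        {r.case_id for r in clinical or []} - ref_set
    )
    variants_only = sorted(
        {r.case_id for r in variants or []} - ref_set
    )
    report = {
        "n_samples": len(ref_ids),
        "n_layers": len(omics),
        "mismatches": 0,
        "clinical_only": clinical_only,
        "variants_only": variants_only,
        "aligned": aligned,
    }
    log.info("cohort: %d samples across %d layers, %d mismatches",
             report["n_samples"], report["n_layers"], report["mismatches"])
    return report
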