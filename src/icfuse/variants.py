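"""Somatic variant filter rule sets, subclonality and pathway burden.

Two rule sets are encoded: the whole-exome (WES) criteria with a relaxed
variant for known hotspot positions, and the targeted deep-sequencing
criteria with their exclusion list (SNP-database hits, simple repeats,
variants seen in paired normals, and the 0.45-0.55 VAF germline band in
copy-neutral regions unless confirmed somatic by WES). Each failing record
is annotated with the first violated rule, following the numbered order of
the criteria.
"""

from __future__ import annotations

import logging

from scipy.stats import fisher_exact

from .config import (
    DeepSeqFilterThresholds,
    HotspotThresholds,
    PathwayDefinition,
    WESFilterThresholds,
)
from .types import Effect, NON_SILENT_EFFECTS, ValidationError, VariantRecord

log = logging.getLogger("icfuse")


def _first_fail_wes(r: VariantRecord, t: WESFilterThresholds,
                    h: HotspotThresholds) -> str | None:
    """First violated WES rule id, or None when the record passes."""
    if r.is_hotspot:
        if r.mapq < h.mapq_min:
            return "mapq"
        if r.baseq < h.baseq_min:
            return "baseq"
        if r.depth_tumor < h.depth_min or r.depth_normal < h.depth_min:
            return "depth"
        if r.alt_reads_tumor < h.alt_reads_min:
            return "alt_reads"
        if r.vaf_tumor < h.vaf_tumor_min:
            return "vaf_tumor"
        if r.vaf_normal >= h.vaf_normal_max:
            return "vaf_normal"
        if r.fisher_p > h.fisher_p_max:
            return "fisher_p"
        return None  # hotspot calls bypass the post-exclusions
    if r.mapq < t.mapq_min:
        return "mapq"
    if r.baseq < t.baseq_min:
        return "baseq"
    if r.depth_tumor < t.depth_min or r.depth_normal < t.depth_min:
        return "depth"
    if r.alt_reads_tumor < t.alt_reads_min:
        return "alt_reads"
    vaf_min = t.vaf_tumor_min_indel if r.is_indel else t.vaf_tumor_min_snv
    if r.vaf_tumor < vaf_min:
        return "vaf_tumor"
    if r.vaf_normal >= t.vaf_normal_max:
        return "vaf_normal"
    if r.ebcall_p > t.ebcall_p_max:
        return "ebcall_p"
    if r.fisher_p > t.fisher_p_max:
        return "fisher_p"
    # post-exclusions (non-hotspot candidates only)
    if r.effect in (Effect.SYNONYMOUS, Effect.AMBIGUOUS):
        return "synonymous_or_ambiguous"
    if r.effect is Effect.NONCODING:
        return "noncoding"
    if r.reads_fwd == 0 or r.reads_rev == 0:
        return "single_direction"
    return None


def filter_wes(
    records: list[VariantRecord],
    thresholds: WESFilterThresholds | None = None,
    hotspot_thresholds: HotspotThresholds | None = None,
) -> tuple[list[VariantRecord], dict[int, str]]:
    """Apply the WES criteria; hotspot records use the relaxed thresholds.

    Returns the passing records and a map from input index to the first
    violated rule id for each failing record.
    """
    thresholds = thresholds or WESFilterThresholds()
    hotspot_thresholds = hotspot_thresholds or HotspotThresholds()
    passed, reasons = [], {}
    for i, r in enumerate(records):
        reason = _first_fail_wes(r, thresholds, hotspot_thresholds)
        if reason is None:
            passed.append(r)
        else:
            reasons[i] = reason
    log.info("filter_wes: %d/%d records pass", len(passed), len(records))
    return passed, reasons


def _first_fail_deepseq(r: VariantRecord, t: DeepSeqFilterThresholds) -> str | None:
    if r.mapq < t.mapq_min:
        return "mapq"
    if r.baseq < t.baseq_min:
        return "baseq"
    if r.depth_tumor < t.depth_min:
        return "depth"
    if r.alt_reads_tumor < t.alt_read_pairs_min:
        return "alt_reads"
    if r.vaf_tumor < t.vaf_min:
        return "vaf_tumor"
    if r.ebcall_p > t.ebcall_p_max:
        return "ebcall_p"
    # exclusions, in the published order
    if r.effect in (Effect.SYNONYMOUS, Effect.SPLICE_SITE):
        return "synonymous_or_splice"
    if r.reads_fwd == 0 or r.reads_rev == 0:
        return "single_direction"
    if r.in_snp_db and not r.is_indel:
        return "snp_db"
    if r.in_simple_repeat:
        return "simple_repeat"
    if r.seen_in_paired_normal:
        return "paired_normal"
    lo, hi = t.germline_band
    if (r.copy_neutral and lo <= r.vaf_tumor <= hi
            and not r.confirmed_somatic_by_wes):
        return "germline_band"
    return None


def filter_deepseq(
    records: list[VariantRecord],
    thresholds: DeepSeqFilterThresholds | None = None,
) -> tuple[list[VariantRecord], dict[int, str]]:
    """Apply the targeted deep-sequencing criteria and exclusions."""
    thresholds = thresholds or DeepSeqFilterThresholds()
    passed, reasons = [], {}
    for i, r in enumerate(records):
        reason = _first_fail_deepseq(r, thresholds)
        if reason is None:
            passed.append(r)
        else:
            reasons[i] = reason
    log.info("filter_deepseq: %d/%d records pass", len(passed), len(records))
    return passed, reasons


def flag_subclonal(records: list[VariantRecord], threshold: float = 0.10,
                   strict: bool = True) -> list[bool]:
    """Subclonal iff tumor VAF < threshold (strict by default)."""
    if strict:
        return [r.vaf_tumor < threshold for r in records]
    return [r.vaf_tumor <= threshold for r in records]


def pathway_burden(records: list[VariantRecord],
                   pathway: PathwayDefinition,
                   case_ids: list[str]) -> dict[str, int]:
    """Per-case count of distinct non-silent pathway mutations.

    Records should already be filter-passed; duplicates of the same
    (case, chrom, pos, alt) collapse to one. Cases absent from the records
    report zero.
    """
    pathway.validate()
    genes = set(pathway.genes)
    counts = {str(c): 0 for c in case_ids}
    seen: set[tuple] = set()
    for r in records:
        if r.gene not in genes or r.effect not in NON_SILENT_EFFECTS:
            continue
        key = (r.case_id, r.chrom, r.pos, r.alt)
        if key in seen:
            continue
        seen.add(key)
        counts.setdefault(r.case_id, 0)
        counts[r.case_id] += 1
    return {c: counts[c] for c in (str(x) for x in case_ids)}


def burden_group(count: int) -> str:
    """0 -> none; 1-2 -> low; >=3 -> high."""
    if count < 0:
        raise ValidationError("burden count cannot be negative")
    if count == 0:
        return "none"
    return "low" if count <= 2 else "high"


def fisher_exact_2x2(table) -> float:
    """Two-sided exact hypergeometric P for a 2x2 contingency table."""
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("all-zero contingency table")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
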