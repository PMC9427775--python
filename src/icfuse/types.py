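"""Core domain containers shared by every pipeline stage.

The pipeline works on two bulk omics layers per cohort — a variance-stabilized
log-scale expression matrix and a DNA-methylation matrix (beta fractions or
their logit-2 "M-value" transform) — plus per-case somatic variant candidate
tables and a clinical table carrying event-free / overall survival endpoints.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class Layer(str, enum.Enum):
    """Which omics layer a matrix belongs to (and hence its value scale)."""

    EXPRESSION_LOG = "expression_log"
    METHYLATION_BETA = "methylation_beta"
    METHYLATION_M = "methylation_M"


class Effect(str, enum.Enum):
    """Coding consequence of a somatic variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    AMBIGUOUS = "ambiguous"
    NONCODING = "noncoding"


#: effects counted as non-silent protein-altering events
NON_SILENT_EFFECTS = frozenset(
    {Effect.MISSENSE, Effect.NONSENSE, Effect.FRAMESHIFT, Effect.INFRAME_INDEL,
     Effect.SPLICE_SITE}
)


class OmicsMatrix:
    """A features x samples real matrix tagged with its omics layer.

    Values are held in a pandas DataFrame (rows = features, columns =
    samples). Construction validates the layer invariants: unique non-empty
    identifiers, no missing values, and beta values confined to [0, 1].
    """

    def __init__(self, values: pd.DataFrame, layer: Layer | str):
        self.layer = Layer(layer)
        if not isinstance(values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        self.values = values
        self.validate()

    # -- introspection -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if len(idx) == 0 or len(cols) == 0:
            raise ValidationError("omics matrix must have >=1 feature and >=1 sample")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.columns[
                [not np.issubdtype(d, np.number) for d in self.values.dtypes]
            ][0]
            raise ValidationError(f"non-numeric values in column {bad!r}")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.layer is Layer.METHYLATION_BETA:
            if arr.min() < 0.0 or arr.max() > 1.0:
                r, c = np.argwhere((arr < 0) | (arr > 1))[0]
                raise ValidationError(
                    f"beta out of [0,1] at probe {idx[r]!r}, sample {cols[c]!r}: "
                    f"{arr[r, c]}"
                )

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(feature_ids)], self.layer)

    def reorder_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[:, list(sample_ids)], self.layer)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), self.layer)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        f, s = self.shape
        return f"OmicsMatrix(layer={self.layer.value}, features={f}, samples={s})"


class GeneSetCollection:
    """Named gene sets (e.g. B-lineage developmental marker signatures)."""

    def __init__(self, sets: dict[str, list[str]]):
        self.sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = list(genes)
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if name in self.sets:
                raise ValidationError(f"duplicate gene set name: {name!r}")
            seen: set[str] = set()
            uniq = [g for g in genes if not (g in seen or seen.add(g))]
            self.sets[name] = uniq

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restrict_to(self, genes, min_size: int = 1) -> "GeneSetCollection":
        """Drop genes absent from `genes`; drop sets falling below min_size."""
        universe = set(genes)
        kept = {}
        for name, members in self.sets.items():
            present = [g for g in members if g in universe]
            if len(present) >= min_size:
                kept[name] = present
        return GeneSetCollection(kept)


@dataclass
class VariantRecord:
    """One candidate somatic call with the quantities the filters consume.

    Coordinates are 1-based (VCF convention). ``ebcall_p`` is the posterior
    P value emitted by the upstream empirical-Bayes caller and is consumed,
    never recomputed.
    """

    case_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: Effect = Effect.AMBIGUOUS
    is_indel: bool = False
    depth_tumor: int = 0
    depth_normal: int = 0
    alt_reads_tumor: int = 0
    vaf_tumor: float = 0.0
    vaf_normal: float = 0.0
    mapq: float = 60.0
    baseq: float = 30.0
    ebcall_p: float = 1.0
    fisher_p: float = 1.0
    reads_fwd: int = 0
    reads_rev: int = 0
    is_hotspot: bool = False
    in_snp_db: bool = False
    in_simple_repeat: bool = False
    seen_in_paired_normal: bool = False
    copy_neutral: bool = False
    confirmed_somatic_by_wes: bool = False

    def __post_init__(self):
        self.effect = Effect(self.effect)
        if self.alt_reads_tumor > self.depth_tumor:
            raise ValidationError(
                f"{self.case_id} {self.chrom}:{self.pos}: alt reads "
                f"{self.alt_reads_tumor} exceed tumor depth {self.depth_tumor}"
            )
        if self.reads_fwd + self.reads_rev != self.alt_reads_tumor:
            raise ValidationError(
                f"{self.case_id} {self.chrom}:{self.pos}: strand reads "
                f"{self.reads_fwd}+{self.reads_rev} != alt reads "
                f"{self.alt_reads_tumor}"
            )
        for name in ("vaf_tumor", "vaf_normal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.case_id} {self.chrom}:{self.pos}: {name}={v} "
                    "outside [0,1]"
                )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass
class ClinicalRecord:
    """Per-case clinical covariates and survival endpoints."""

    case_id: str
    age_months: float
    sex: str
    wbc: float
    cns_involved: bool
    protocol: str
    fusion_partner: str
    remission_failure: bool
    efs_time_days: float
    efs_event: bool
    os_time_days: float
    os_event: bool
    cluster_label: str | None = None

    def __post_init__(self):
        if self.efs_time_days < 0 or self.os_time_days < 0:
            raise ValidationError(f"{self.case_id}: negative survival time")
        if self.remission_failure and not self.efs_event:
            raise ValidationError(
                f"{self.case_id}: remission failure implies an EFS event"
            )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = [{f: getattr(r, f) for f in ClinicalRecord.field_names()} for r in records]
    return pd.DataFrame(rows).set_index("case_id", drop=False)


def clinical_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    recs = []
    for _, row in df.iterrows():
        kwargs = {f: row[f] for f in ClinicalRecord.field_names() if f in row}
        for b in ("cns_involved", "remission_failure", "efs_event", "os_event"):
            kwargs[b] = bool(kwargs[b])
        cl = kwargs.get("cluster_label")
        if cl is None or (isinstance(cl, float) and np.isnan(cl)):
            kwargs["cluster_label"] = None
        recs.append(ClinicalRecord(**kwargs))
    return recs
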