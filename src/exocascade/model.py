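"""Shared data model for cohort variants, genotype calls and annotations.

The model mirrors what a multi-sample exome VCF carries per record: the locus
and alleles, one genotype call per sample (zygosity, GQ, DP and the two allele
depths AD1/AD2), and an optional annotation bundle holding population minor
allele frequencies, categorical pathogenicity-predictor verdicts, and the
CADD (Phred-scaled) and REVEL scores consumed by the prioritization cascade.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Mapping, Optional, Tuple


class ExocascadeError(Exception):
    """Base class for package errors."""


class ConfigError(ExocascadeError):
    """Invalid configuration or parameter values."""


class ParseError(ExocascadeError):
    """Malformed input file."""


class Zygosity(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class FuncClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class PredictorCall(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


#: The ten categorical pathogenicity predictors consulted by the consensus vote
#: (dbNSFP-style panel: sequence-conservation, structural and meta predictors).
PREDICTOR_TOOLS: Tuple[str, ...] = (
    "sift",
    "provean",
    "polyphen2_hvar",
    "polyphen2_hdiv",
    "fathmm",
    "mutation_assessor",
    "mutation_taster",
    "lrt",
    "meta_svm",
    "meta_lr",
)

#: Population-frequency databases an annotation bundle may carry.
MAF_DATABASES: Tuple[str, ...] = ("kg1000", "esp", "exac", "gnomad")


@dataclasses.dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype call at one site.

    ``ad1``/``ad2`` are the approximated read depths supporting the first and
    second allele as listed in the AD field; ``dp`` is the total approximated
    read depth, which need not equal ``ad1 + ad2``.  ``None`` marks a missing
    field, distinct from an observed zero.
    """

    sample_id: str
    zygosity: Zygosity
    gq: Optional[int] = None
    dp: Optional[int] = None
    ad1: Optional[int] = None
    ad2: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("dp", "ad1", "ad2"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


@dataclasses.dataclass(frozen=True)
class VariantSite:
    """A biallelic genomic locus (1-based) with gene and functional class."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    func_class: FuncClass = FuncClass.OTHER

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclasses.dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotations: MAFs, predictor verdicts, CADD and REVEL.

    ``maf_by_db`` holds only the databases where the variant was observed; a
    database key that is absent means the variant is unreported there.
    ``predictor_calls`` always carries exactly the configured tool panel, with
    :attr:`PredictorCall.UNKNOWN` for tools that did not score the variant.
    """

    maf_by_db: Mapping[str, float] = dataclasses.field(default_factory=dict)
    predictor_calls: Mapping[str, PredictorCall] = dataclasses.field(
        default_factory=dict
    )
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None

    def __post_init__(self) -> None:
        for db, maf in self.maf_by_db.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF for {db} outside [0,1]: {maf}")
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise ValueError(f"REVEL outside [0,1]: {self.revel}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD Phred must be non-negative: {self.cadd_phred}")
        calls = dict(self.predictor_calls)
        for tool in PREDICTOR_TOOLS:
            calls.setdefault(tool, PredictorCall.UNKNOWN)
        unexpected = set(calls) - set(PREDICTOR_TOOLS)
        if unexpected:
            raise ValueError(f"unknown predictor tools: {sorted(unexpected)}")
        object.__setattr__(self, "predictor_calls", calls)
        object.__setattr__(self, "maf_by_db", dict(self.maf_by_db))

    def maf(self, db: str) -> Optional[float]:
        return self.maf_by_db.get(db)

    def n_damaging(self) -> int:
        return sum(
            1 for c in self.predictor_calls.values() if c is PredictorCall.DAMAGING
        )


@dataclasses.dataclass(frozen=True)
class CohortVariant:
    """One VCF record: a site, one call per cohort sample, and annotations.

    ``cascade_stage`` records the index of the last prioritization stage the
    variant passed (set by the cascade; ``None`` before any run).
    """

    site: VariantSite
    calls: Tuple[GenotypeCall, ...]
    annotation: Optional[AnnotationBundle] = None
    cascade_stage: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "calls", tuple(self.calls))

    @property
    def sample_ids(self) -> Tuple[str, ...]:
        return tuple(c.sample_id for c in self.calls)


def cohort_samples(variants) -> Tuple[str, ...]:
    """Sample names of a cohort, in file order (empty cohort -> empty tuple)."""
    for v in variants:
        return v.sample_ids
    return ()
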