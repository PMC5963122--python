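"""The prioritization cascade: ordered conjunctive filters with accounting.

Under an autosomal-dominant hypothesis a single heterozygous variant can be
causal, so the funnel starts from heterozygous calls and narrows them through:

1. primary selection   — het genotype, GQ >= gq_min, DP >= dp_min
2. het reliability     — allele-balance screen (:mod:`exocascade.het`)
3. rare + functional   — kept functional classes, MAF <= maf_max in every
                         consulted database (absence everywhere = novel = rare)
4. predictor consensus — >= consensus_k of the ten tools call it damaging
5. CADD/REVEL gate     — CADD Phred > cadd_min (strict) and
                         REVEL >= revel_min (inclusive)

Every stage is a pure conjunctive predicate, so the survivor set is invariant
to stage order; the staged form exists for the per-stage report (variants,
genes, patients surviving each stage).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .het import classify_het
from .model import (
    AnnotationBundle,
    CohortVariant,
    ConfigError,
    FuncClass,
    GenotypeCall,
    PredictorCall,
    PREDICTOR_TOOLS,
    Zygosity,
)

#: Stage names in funnel order; "input" is the pre-filter row of the report.
STAGE_NAMES: Tuple[str, ...] = (
    "input",
    "primary_selection",
    "het_reliability",
    "rare_functional",
    "predictor_consensus",
    "cadd_revel_gate",
)

_MISSING_POLICIES = ("fail", "pass_if_nonsense", "pass")


@dataclasses.dataclass
class CascadeConfig:
    """Thresholds of the cascade.

    ``gq_min`` defaults to 99, the conventional cap of VCF genotype quality,
    and is compared inclusively.  ``cadd_min`` is a strict lower bound (a CADD
    Phred above 20 marks the top 1% most deleterious substitutions), while
    ``revel_min`` is inclusive.  ``missing_score_policy`` resolves variants a
    score is unavailable for: ``fail`` (default), ``pass`` or
    ``pass_if_nonsense`` (truncating variants are unscored by several
    missense-only predictors).
    """

    gq_min: int = 99
    dp_min: int = 50
    ratio_max: float = 0.3
    maf_max: float = 0.01
    maf_databases: Tuple[str, ...] = ("kg1000", "esp")
    consensus_k: int = 4
    cadd_min: float = 20.0
    revel_min: float = 0.75
    func_classes_kept: FrozenSet[FuncClass] = frozenset(
        {FuncClass.MISSENSE, FuncClass.NONSENSE}
    )
    missing_score_policy: str = "fail"
    # a run where annotation is absent for more than this fraction of variants
    # aborts: downstream gates would silently eliminate everything
    max_missing_annotation_fraction: float = 0.5

    def validate(self) -> None:
        if not 0 < self.maf_max < 1:
            raise ConfigError(f"maf_max must be in (0,1), got {self.maf_max}")
        if not 0 < self.consensus_k <= len(PREDICTOR_TOOLS):
            raise ConfigError(
                f"consensus_k must be in [1,{len(PREDICTOR_TOOLS)}], "
                f"got {self.consensus_k}"
            )
        if self.missing_score_policy not in _MISSING_POLICIES:
            raise ConfigError(
                f"missing_score_policy must be one of {_MISSING_POLICIES}"
            )
        if self.ratio_max <= 0:
            raise ConfigError(f"ratio_max must be positive, got {self.ratio_max}")
        if self.dp_min < 0 or self.gq_min < 0:
            raise ConfigError("dp_min and gq_min must be non-negative")
        for value, name in ((self.cadd_min, "cadd_min"), (self.revel_min, "revel_min")):
            if not (value == value and abs(value) != float("inf")):
                raise ConfigError(f"{name} must be finite")
        if not set(self.maf_databases):
            raise ConfigError("maf_databases must name at least one database")
        if not 0 <= self.max_missing_annotation_fraction <= 1:
            raise ConfigError("max_missing_annotation_fraction must be in [0,1]")

    def to_dict(self) -> Dict[str, object]:
        d = dataclasses.asdict(self)
        d["maf_databases"] = list(self.maf_databases)
        d["func_classes_kept"] = sorted(c.value for c in self.func_classes_kept)
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "CascadeConfig":
        kwargs = dict(d)
        if "maf_databases" in kwargs:
            kwargs["maf_databases"] = tuple(kwargs["maf_databases"])
        if "func_classes_kept" in kwargs:
            kwargs["func_classes_kept"] = frozenset(
                FuncClass(c) for c in kwargs["func_classes_kept"]
            )
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class StageCount:
    stage: str
    n_variants: int
    n_genes: int
    n_patients: int


@dataclasses.dataclass(frozen=True)
class CascadeReport:
    """Per-stage funnel counts plus the same-gene recurrence check.

    ``n_patients_two_variants_same_gene`` counts patients carrying two or more
    distinct surviving variants in one gene (reported, never filtered on).
    """

    stages: Tuple[StageCount, ...]
    n_patients_two_variants_same_gene: int = 0

    def counts(self) -> List[int]:
        return [s.n_variants for s in self.stages]

    def to_rows(self) -> List[Dict[str, object]]:
        return [dataclasses.asdict(s) for s in self.stages]


def passes_primary(call: GenotypeCall, cfg: CascadeConfig) -> bool:
    """Primary selection: heterozygous with GQ >= gq_min and DP >= dp_min.

    Missing GQ or DP fails (the filter cannot vouch for the call).
    """
    if call.zygosity is not Zygosity.HET:
        return False
    if call.gq is None or call.dp is None:
        return False
    return call.gq >= cfg.gq_min and call.dp >= cfg.dp_min


def is_rare(ann: Optional[AnnotationBundle], cfg: CascadeConfig) -> bool:
    """Rarity: MAF missing or <= maf_max in every consulted database.

    A variant unreported in all consulted databases is novel, hence rare; an
    entirely missing annotation bundle is treated the same way.
    """
    if ann is None:
        return True
    for db in cfg.maf_databases:
        maf = ann.maf(db)
        if maf is not None and maf > cfg.maf_max:
            return False
    return True


def consensus_damaging(
    ann: Optional[AnnotationBundle], cfg: CascadeConfig
) -> Tuple[int, bool]:
    """Count damaging predictor votes; verdict is vote_count >= consensus_k.

    ``unknown`` and ``tolerated`` verdicts both count as non-damaging votes.
    """
    votes = ann.n_damaging() if ann is not None else 0
    return votes, votes >= cfg.consensus_k


def passes_combined_gate(
    ann: Optional[AnnotationBundle],
    cfg: CascadeConfig,
    func_class: Optional[FuncClass] = None,
) -> bool:
    """Joint gate: CADD Phred > cadd_min (strict) AND REVEL >= revel_min.

    A missing score is resolved by ``cfg.missing_score_policy``; under the
    default ``fail`` policy either score missing fails the gate.
    """
    cadd = ann.cadd_phred if ann is not None else None
    revel = ann.revel if ann is not None else None
    if cfg.missing_score_policy == "pass":
        missing_ok = True
    elif cfg.missing_score_policy == "pass_if_nonsense":
        missing_ok = func_class is FuncClass.NONSENSE
    else:
        missing_ok = False
    cadd_ok = missing_ok if cadd is None else cadd > cfg.cadd_min
    revel_ok = missing_ok if revel is None else revel >= cfg.revel_min
    return cadd_ok and revel_ok


def _stage_count(
    name: str, survivors: Sequence[Tuple[CohortVariant, FrozenSet[str]]]
) -> StageCount:
    genes = {v.site.gene for v, _ in survivors if v.site.gene}
    patients: Set[str] = set()
    for _, carriers in survivors:
        patients.update(carriers)
    return StageCount(name, len(survivors), len(genes), len(patients))


def run_cascade(
    cohort: Sequence[CohortVariant], cfg: CascadeConfig
) -> Tuple[List[CohortVariant], CascadeReport]:
    """Run the five-stage funnel and account for every stage.

    A variant survives a per-call stage (primary selection, het reliability)
    when at least one sample's call survives it; the surviving calls define
    the carriers counted in the patient column of later stages.  Survivors are
    returned as copies tagged with ``cascade_stage`` set to the final stage
    index; the input is never mutated.  An empty cohort yields an empty
    survivor list and an all-zero report.
    """
    cfg.validate()

    # (variant, surviving carrier sample_ids)
    state: List[Tuple[CohortVariant, FrozenSet[str]]] = [
        (v, frozenset(c.sample_id for c in v.calls if c.zygosity is Zygosity.HET))
        for v in cohort
    ]
    rows = [_stage_count("input", state)]

    nxt = []
    for v, _ in state:
        carriers = frozenset(
            c.sample_id for c in v.calls if passes_primary(c, cfg)
        )
        if carriers:
            nxt.append((v, carriers))
    state = nxt
    rows.append(_stage_count("primary_selection", state))

    nxt = []
    for v, carriers in state:
        kept = frozenset(
            c.sample_id
            for c in v.calls
            if c.sample_id in carriers
            and classify_het(c, cfg.dp_min, cfg.ratio_max).reliable
        )
        if kept:
            nxt.append((v, kept))
    state = nxt
    rows.append(_stage_count("het_reliability", state))

    state = [
        (v, carriers)
        for v, carriers in state
        if v.site.func_class in cfg.func_classes_kept and is_rare(v.annotation, cfg)
    ]
    rows.append(_stage_count("rare_functional", state))

    state = [
        (v, carriers)
        for v, carriers in state
        if consensus_damaging(v.annotation, cfg)[1]
    ]
    rows.append(_stage_count("predictor_consensus", state))

    state = [
        (v, carriers)
        for v, carriers in state
        if passes_combined_gate(v.annotation, cfg, v.site.func_class)
    ]
    rows.append(_stage_count("cadd_revel_gate", state))

    survivors = [
        dataclasses.replace(v, cascade_stage=len(STAGE_NAMES) - 1)
        for v, _ in state
    ]

    per_patient_gene: Dict[str, Dict[str, int]] = {}
    for v, carriers in state:
        for s in carriers:
            gene_counts = per_patient_gene.setdefault(s, {})
            gene_counts[v.site.gene] = gene_counts.get(v.site.gene, 0) + 1
    n_two_same_gene = sum(
        1
        for gene_counts in per_patient_gene.values()
        if any(n >= 2 for n in gene_counts.values())
    )

    report = CascadeReport(tuple(rows), n_two_same_gene)
    return survivors, report
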