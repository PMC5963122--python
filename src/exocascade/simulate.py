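"""Synthetic annotated exome cohorts with per-call ground truth.

The generator emulates the statistical structure the prioritization cascade
assumes, at the level the cascade can observe:

* per-call depths from a negative binomial (``dp_dispersion = 0`` fixes the
  depth at the mean exactly);
* true heterozygotes draw the first allele depth from Binomial(DP, 0.5);
* false-positive heterozygotes (calls the caller labels het at a truly
  homozygous site) draw the minor depth from Binomial(DP,
  ``false_het_alt_fraction``) — a skewed allele-fraction draw, agnostic of
  the artifact mechanism, since the screen only ever sees AD and DP;
* population MAFs come from a rare-tail spectrum with a point mass of novel
  (unreported) variants;
* the ten predictor verdicts, CADD and REVEL are coupled through a shared
  latent damaging indicator with mixing weight ``score_correlation``;
* ``n_planted`` variants are constructed to pass every default filter, with
  a gene drawn from the bundled "PD"/"neuron" example lists.

A single RNG stream consumed in (variant index, sample index) order makes
generation reproducible; the same seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io as cohort_io
from .cascade import CascadeConfig
from .genes import bundled_gene_set
from .het import classify_het
from .model import (
    AnnotationBundle,
    CohortVariant,
    ConfigError,
    ExocascadeError,
    FuncClass,
    GenotypeCall,
    MAF_DATABASES,
    PredictorCall,
    PREDICTOR_TOOLS,
    VariantSite,
    Zygosity,
)

_BASES = ("A", "C", "G", "T")
_UNKNOWN_RATE = 0.05  # chance a predictor did not score a (non-planted) variant
_DB_PRESENT_RATE = 0.85  # chance a non-novel variant is reported in a given DB
_HOM_ALT_RATE = 0.02
_DECOY_LIST_GENE_RATE = 0.02  # non-planted variants landing in a listed gene


@dataclasses.dataclass
class SimulationParams:
    """Knobs of the synthetic cohort.

    Defaults describe a 48-patient exome cohort with deep coverage over the
    screen's operating range (negative-binomial depth, mean 100, dispersion
    10), a 10% expected minor-allele fraction for artifact heterozygotes, a
    rare-skewed frequency spectrum with 10% novel variants, and five planted
    candidates that survive every default filter.  Per-call het fractions
    (8% true, 2% artifact) give each site a handful of carriers in a
    48-sample cohort, approximating a rare-variant exome while exercising
    every QC branch.
    """

    n_samples: int = 48
    n_variants: int = 2000
    seed: int = 0
    dp_mean: float = 100.0
    dp_dispersion: float = 10.0
    true_het_fraction: float = 0.08
    false_het_fraction: float = 0.02
    false_het_alt_fraction: float = 0.1
    rare_fraction: float = 0.7
    novel_fraction: float = 0.1
    maf_tail_shape: float = 0.5
    predictor_damaging_rate: float = 0.15
    score_correlation: float = 0.7
    low_gq_fraction: float = 0.05
    missing_score_rate: float = 0.05
    n_planted: int = 5

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_variants < 0:
            raise ConfigError("n_samples >= 1 and n_variants >= 0 required")
        if not 0 <= self.n_planted <= self.n_variants:
            raise ConfigError("n_planted must be in [0, n_variants]")
        for name in (
            "true_het_fraction",
            "false_het_fraction",
            "rare_fraction",
            "novel_fraction",
            "low_gq_fraction",
            "missing_score_rate",
            "score_correlation",
            "predictor_damaging_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.true_het_fraction + self.false_het_fraction > 1.0:
            raise ConfigError("true_het_fraction + false_het_fraction must be <= 1")
        if not 0.0 < self.false_het_alt_fraction < 0.5:
            raise ConfigError("false_het_alt_fraction must be in (0, 0.5)")
        if self.dp_mean <= 0 or self.dp_dispersion < 0:
            raise ConfigError("dp_mean > 0 and dp_dispersion >= 0 required")
        if self.maf_tail_shape <= 0:
            raise ConfigError("maf_tail_shape must be positive")


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one variant: true zygosities and artifact flags."""

    key: str
    true_zygosity: Dict[str, Zygosity]
    is_false_het: Dict[str, bool]
    is_planted_candidate: bool


def _planted_gene_cycle() -> List[str]:
    pd_set = bundled_gene_set("PD").genes
    neuron_set = bundled_gene_set("neuron").genes
    dual = sorted(pd_set & neuron_set)
    rest = sorted((pd_set | neuron_set) - set(dual))
    return dual + rest


def _draw_dp(rng: np.random.Generator, p: SimulationParams) -> int:
    if p.dp_dispersion == 0:
        return int(round(p.dp_mean))
    prob = p.dp_dispersion / (p.dp_dispersion + p.dp_mean)
    return int(rng.negative_binomial(p.dp_dispersion, prob))


def _draw_maf_base(rng: np.random.Generator, p: SimulationParams) -> Optional[float]:
    """Variant-level base frequency; None = novel (unreported everywhere)."""
    if rng.random() < p.novel_fraction:
        return None
    if rng.random() < p.rare_fraction:
        return 0.01 * float(rng.beta(p.maf_tail_shape, 1.0))
    return float(rng.uniform(0.011, 0.5))


def _channel_damaging(
    rng: np.random.Generator, shared: bool, p: SimulationParams
) -> bool:
    if rng.random() < p.score_correlation:
        return shared
    return rng.random() < p.predictor_damaging_rate


def _make_annotation(
    rng: np.random.Generator, p: SimulationParams, planted: bool
) -> AnnotationBundle:
    maf_by_db: Dict[str, float] = {}
    if planted:
        base = None if rng.random() < 0.5 else float(rng.uniform(0.0001, 0.006))
    else:
        base = _draw_maf_base(rng, p)
    if base is not None:
        for db in MAF_DATABASES:
            if rng.random() < _DB_PRESENT_RATE:
                value = base * float(rng.uniform(0.8, 1.2))
                maf_by_db[db] = round(min(max(value, 1e-6), 0.999999), 6)

    shared = True if planted else rng.random() < p.predictor_damaging_rate
    calls: Dict[str, PredictorCall] = {}
    for tool in PREDICTOR_TOOLS:
        if planted:
            calls[tool] = (
                PredictorCall.DAMAGING
                if rng.random() < 0.9
                else PredictorCall.TOLERATED
            )
        elif rng.random() < _UNKNOWN_RATE:
            calls[tool] = PredictorCall.UNKNOWN
        else:
            calls[tool] = (
                PredictorCall.DAMAGING
                if _channel_damaging(rng, shared, p)
                else PredictorCall.TOLERATED
            )
    if planted:  # construction guarantee: at least 4 damaging votes
        damaged = [t for t in PREDICTOR_TOOLS if calls[t] is PredictorCall.DAMAGING]
        for tool in PREDICTOR_TOOLS:
            if len(damaged) >= 4:
                break
            if calls[tool] is not PredictorCall.DAMAGING:
                calls[tool] = PredictorCall.DAMAGING
                damaged.append(tool)

    if planted:
        cadd: Optional[float] = round(float(rng.uniform(22.0, 35.0)), 2)
        revel: Optional[float] = round(float(rng.uniform(0.78, 0.98)), 3)
    else:
        if rng.random() < p.missing_score_rate:
            cadd = None
        else:
            mean, sd = (28.0, 5.0) if _channel_damaging(rng, shared, p) else (9.0, 6.0)
            cadd = round(max(0.0, float(rng.normal(mean, sd))), 2)
        if rng.random() < p.missing_score_rate:
            revel = None
        else:
            a, b = (8.0, 2.0) if _channel_damaging(rng, shared, p) else (1.2, 8.0)
            revel = round(min(max(float(rng.beta(a, b)), 0.0), 1.0), 3)
    return AnnotationBundle(maf_by_db, calls, cadd, revel)


def _balanced_het_depths(rng: np.random.Generator, dp: int) -> Tuple[int, int]:
    """AD draw for a guaranteed-reliable het (balance strictly below 0.25)."""
    while True:
        ad1 = int(rng.binomial(dp, 0.5))
        if abs(2 * ad1 - dp) / dp < 0.25:
            return ad1, dp - ad1


def simulate_cohort(
    params: SimulationParams,
) -> Tuple[List[CohortVariant], List[TruthRecord]]:
    """Generate an in-memory annotated cohort plus its truth records."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    samples = [f"P{j + 1:03d}" for j in range(params.n_samples)]
    planted_idx = set(
        int(i)
        for i in rng.choice(params.n_variants, size=params.n_planted, replace=False)
    ) if params.n_planted else set()
    gene_cycle = _planted_gene_cycle()

    variants: List[CohortVariant] = []
    truth: List[TruthRecord] = []
    n_planted_seen = 0
    for i in range(params.n_variants):
        planted = i in planted_idx
        chrom = str(1 + (i % 22))
        pos = 1_000_000 + 97 * i
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(rng.integers(3)) + _BASES.index(ref) + 1) % 4]
        if planted:
            gene = gene_cycle[n_planted_seen % len(gene_cycle)]
            n_planted_seen += 1
            func_class = FuncClass.MISSENSE
        elif rng.random() < _DECOY_LIST_GENE_RATE:
            gene = gene_cycle[int(rng.integers(len(gene_cycle)))]
            func_class = FuncClass(
                str(rng.choice(["missense", "nonsense", "synonymous", "other"],
                               p=[0.60, 0.03, 0.22, 0.15]))
            )
        else:
            gene = f"GENE{i:05d}"
            func_class = FuncClass(
                str(rng.choice(["missense", "nonsense", "synonymous", "other"],
                               p=[0.60, 0.03, 0.22, 0.15]))
            )
        site = VariantSite(chrom, pos, ref, alt, gene, func_class)
        annotation = _make_annotation(rng, params, planted)

        carrier = int(rng.integers(params.n_samples)) if planted else -1
        calls: List[GenotypeCall] = []
        true_zyg: Dict[str, Zygosity] = {}
        false_het: Dict[str, bool] = {}
        for j, sid in enumerate(samples):
            dp = _draw_dp(rng, params)
            u = rng.random()
            gq = 99 if rng.random() >= params.low_gq_fraction else int(
                rng.integers(20, 99)
            )
            if planted and j == carrier:
                dp = max(dp, 60)
                ad1, ad2 = _balanced_het_depths(rng, dp)
                calls.append(GenotypeCall(sid, Zygosity.HET, 99, dp, ad1, ad2))
                true_zyg[sid] = Zygosity.HET
                false_het[sid] = False
                continue
            if u < params.true_het_fraction and dp > 0:
                ad1 = int(rng.binomial(dp, 0.5))
                calls.append(GenotypeCall(sid, Zygosity.HET, gq, dp, ad1, dp - ad1))
                true_zyg[sid] = Zygosity.HET
                false_het[sid] = False
            elif (
                u < params.true_het_fraction + params.false_het_fraction and dp > 0
            ):
                minor = int(rng.binomial(dp, params.false_het_alt_fraction))
                calls.append(
                    GenotypeCall(sid, Zygosity.HET, gq, dp, dp - minor, minor)
                )
                true_zyg[sid] = Zygosity.HOM_REF
                false_het[sid] = True
            elif rng.random() < _HOM_ALT_RATE:
                calls.append(GenotypeCall(sid, Zygosity.HOM_ALT, gq, dp, 0, dp))
                true_zyg[sid] = Zygosity.HOM_ALT
                false_het[sid] = False
            else:
                calls.append(GenotypeCall(sid, Zygosity.HOM_REF, gq, dp, dp, 0))
                true_zyg[sid] = Zygosity.HOM_REF
                false_het[sid] = False
        variants.append(CohortVariant(site, tuple(calls), annotation))
        truth.append(TruthRecord(site.key, true_zyg, false_het, planted))
    return variants, truth


def generate_cohort(
    params: SimulationParams, out_dir
) -> Tuple[Path, Path, List[TruthRecord]]:
    """Write a cohort VCF + annotation sidecar; return their paths and truth.

    Parameters are validated before any file is written; identical parameters
    and seed give byte-identical files.
    """
    params.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants, truth = simulate_cohort(params)
    vcf_path = out_dir / "cohort.vcf"
    sidecar_path = out_dir / "annotations.tsv"
    cohort_io.write_cohort_vcf(
        variants, vcf_path, with_annotations=False, with_stage=False
    )
    cohort_io.write_sidecar(variants, sidecar_path)
    return vcf_path, sidecar_path, truth


def write_truth(truth: Sequence[TruthRecord], out_path) -> int:
    """Write truth records as a long TSV (one row per variant-sample pair)."""
    rows = []
    for t in truth:
        for sid, zyg in t.true_zygosity.items():
            rows.append(
                {
                    "key": t.key,
                    "sample": sid,
                    "true_zygosity": zyg.value,
                    "is_false_het": int(t.is_false_het[sid]),
                    "is_planted": int(t.is_planted_candidate),
                }
            )
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return len(rows)


def read_truth(path) -> List[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "sample": str})
    out: List[TruthRecord] = []
    for key, grp in df.groupby("key", sort=False):
        out.append(
            TruthRecord(
                key=str(key),
                true_zygosity={
                    r["sample"]: Zygosity(r["true_zygosity"])
                    for _, r in grp.iterrows()
                },
                is_false_het={
                    r["sample"]: bool(r["is_false_het"]) for _, r in grp.iterrows()
                },
                is_planted_candidate=bool(grp["is_planted"].iloc[0]),
            )
        )
    return out


def evaluate_screen(
    cohort: Union[str, Path, Sequence[CohortVariant]],
    truth: Sequence[TruthRecord],
    cfg: Optional[CascadeConfig] = None,
) -> Tuple[float, float]:
    """Sensitivity and specificity of the het-reliability screen.

    Over all calls the caller labelled heterozygous, sensitivity is the
    fraction of truly heterozygous calls the screen retains and specificity
    the fraction of false-positive heterozygotes it rejects.  A class with no
    calls contributes a vacuous 1.0.  ``cohort`` may be a VCF path or an
    in-memory variant list.
    """
    cfg = cfg or CascadeConfig()
    if isinstance(cohort, (str, Path)):
        cohort = cohort_io.read_cohort(cohort)
    if not cohort:
        raise ExocascadeError("cannot evaluate the screen on an empty cohort")
    by_key = {t.key: t for t in truth}
    n_true = kept_true = n_false = rejected_false = 0
    for v in cohort:
        t = by_key.get(v.site.key)
        if t is None:
            raise ExocascadeError(f"no truth record for variant {v.site.key}")
        for c in v.calls:
            if c.zygosity is not Zygosity.HET:
                continue
            if c.sample_id not in t.true_zygosity:
                raise ExocascadeError(
                    f"no truth for sample {c.sample_id} at {v.site.key}"
                )
            reliable = classify_het(c, cfg.dp_min, cfg.ratio_max).reliable
            if t.is_false_het[c.sample_id]:
                n_false += 1
                rejected_false += not reliable
            elif t.true_zygosity[c.sample_id] is Zygosity.HET:
                n_true += 1
                kept_true += reliable
    sensitivity = kept_true / n_true if n_true else 1.0
    specificity = rejected_false / n_false if n_false else 1.0
    return sensitivity, specificity
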