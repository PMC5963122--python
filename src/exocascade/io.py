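"""Multi-sample VCF and sidecar-annotation I/O.

Cohorts are exchanged as VCF v4.2 with per-sample FORMAT fields GT:AD:DP:GQ.
Annotations travel either as INFO keys (``CADD_PHRED``, ``REVEL``,
``MAF_<DB>``, ``PRED_<TOOL>``) or as a tab-separated sidecar table keyed by
``chrom, pos, ref, alt`` with columns of the same names; on conflict the
sidecar wins (with a logged warning).  Only biallelic records are loaded —
the allele-balance statistic is defined for exactly two alleles — and
multiallelic records are skipped with a warning and counted.  A
split-multiallelic hook (``bcftools norm -m-``) can be applied upstream;
normalization itself is out of scope.

Float INFO values pass through htslib's 32-bit float encoding; on read the
shortest decimal representation of the float32 is recovered, so scores
written with six or fewer significant digits round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .model import (
    AnnotationBundle,
    CohortVariant,
    FuncClass,
    GenotypeCall,
    MAF_DATABASES,
    ParseError,
    PredictorCall,
    PREDICTOR_TOOLS,
    VariantSite,
    Zygosity,
)

logger = logging.getLogger("exocascade")


@dataclasses.dataclass(frozen=True)
class AnnotationSchema:
    """Names of the annotation transport keys (INFO keys / sidecar columns)."""

    cadd_key: str = "CADD_PHRED"
    revel_key: str = "REVEL"
    maf_prefix: str = "MAF_"
    pred_prefix: str = "PRED_"

    def maf_key(self, db: str) -> str:
        return self.maf_prefix + db.upper()

    def pred_key(self, tool: str) -> str:
        return self.pred_prefix + tool.upper()


DEFAULT_SCHEMA = AnnotationSchema()

_KEY_COLS = ("chrom", "pos", "ref", "alt")


def _float_from_f32(x: float) -> float:
    """Shortest decimal that reproduces the float32 ``x`` (htslib precision)."""
    return float(np.format_float_positional(np.float32(x), unique=True))


def _zygosity_from_gt(gt: Optional[Tuple[Optional[int], ...]]) -> Zygosity:
    if gt is None:
        return Zygosity.MISSING
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Zygosity.MISSING
    if all(a == 0 for a in alleles):
        return Zygosity.HOM_REF
    if all(a == 1 for a in alleles):
        return Zygosity.HOM_ALT
    if set(alleles) == {0, 1}:
        return Zygosity.HET
    return Zygosity.MISSING


_GT_BY_ZYGOSITY = {
    Zygosity.HOM_REF: (0, 0),
    Zygosity.HET: (0, 1),
    Zygosity.HOM_ALT: (1, 1),
    Zygosity.MISSING: (None, None),
}


def _read_call(sample_id: str, fmt) -> GenotypeCall:
    ad = fmt.get("AD")
    ad1 = ad2 = None
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        ad1, ad2 = int(ad[0]), int(ad[1])
    dp = fmt.get("DP")
    gq = fmt.get("GQ")
    return GenotypeCall(
        sample_id=sample_id,
        zygosity=_zygosity_from_gt(fmt.get("GT")),
        gq=None if gq is None else int(gq),
        dp=None if dp is None else int(dp),
        ad1=ad1,
        ad2=ad2,
    )


def _info_get(info, key: str, declared, default=None):
    # pysam raises on lookups of keys absent from the header declaration
    if key not in declared:
        return default
    v = info.get(key)
    return default if v is None else v


def _annotation_from_info(info, schema: AnnotationSchema, declared):
    """Extract (maf_by_db, predictor_calls, cadd, revel, any_present) from INFO."""
    maf_by_db: Dict[str, float] = {}
    for db in MAF_DATABASES:
        v = _info_get(info, schema.maf_key(db), declared)
        if v is not None:
            maf_by_db[db] = _float_from_f32(float(v))
    calls: Dict[str, PredictorCall] = {}
    for tool in PREDICTOR_TOOLS:
        v = _info_get(info, schema.pred_key(tool), declared)
        if v is not None:
            calls[tool] = PredictorCall(str(v))
    cadd = _info_get(info, schema.cadd_key, declared)
    revel = _info_get(info, schema.revel_key, declared)
    cadd = None if cadd is None else _float_from_f32(float(cadd))
    revel = None if revel is None else _float_from_f32(float(revel))
    present = bool(maf_by_db or calls) or cadd is not None or revel is not None
    return maf_by_db, calls, cadd, revel, present


def _read_sidecar(path: Path, schema: AnnotationSchema) -> Dict[str, Dict[str, object]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    missing = [c for c in _KEY_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"sidecar {path} lacks key columns {missing}")
    rows: Dict[str, Dict[str, object]] = {}
    for rec in df.to_dict("records"):
        key = f"{rec['chrom']}:{int(rec['pos'])}:{rec['ref']}:{rec['alt']}"
        rows[key] = {
            k: v
            for k, v in rec.items()
            if k not in _KEY_COLS and not (isinstance(v, float) and np.isnan(v))
        }
    return rows


def read_cohort(
    vcf_path,
    annotation_sidecar=None,
    schema: AnnotationSchema = DEFAULT_SCHEMA,
) -> List[CohortVariant]:
    """Load a multi-sample VCF (plus optional sidecar) into CohortVariants.

    One :class:`CohortVariant` per biallelic record, calls in the file's
    sample order; records with missing FORMAT fields are retained with
    missing markers.  Multiallelic records are skipped with a logged warning.
    Sidecar values override INFO values on conflict (warning logged).
    """
    vcf_path = Path(vcf_path)
    sidecar = (
        _read_sidecar(Path(annotation_sidecar), schema)
        if annotation_sidecar is not None
        else {}
    )
    variants: List[CohortVariant] = []
    n_multi = 0
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        declared = set(vf.header.info.keys())
        try:
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    n_multi += 1
                    logger.warning(
                        "skipping non-biallelic record %s:%d", rec.chrom, rec.pos
                    )
                    continue
                site = VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=str(_info_get(rec.info, "GENE", declared, "")),
                    func_class=FuncClass(
                        _info_get(rec.info, "FUNC_CLASS", declared, "other")
                    ),
                )
                calls = tuple(_read_call(s, rec.samples[s]) for s in samples)
                maf_by_db, pred, cadd, revel, present = _annotation_from_info(
                    rec.info, schema, declared
                )
                side = sidecar.get(site.key)
                if side is not None:
                    present = True
                    site, maf_by_db, pred, cadd, revel = _apply_sidecar(
                        site, maf_by_db, pred, cadd, revel, side, schema
                    )
                annotation = (
                    AnnotationBundle(maf_by_db, pred, cadd, revel) if present else None
                )
                variants.append(CohortVariant(site, calls, annotation))
        except (OSError, ValueError) as exc:
            raise ParseError(f"malformed record in {vcf_path}: {exc}") from exc
    if n_multi:
        logger.warning(
            "%s: skipped %d multiallelic record(s)", vcf_path.name, n_multi
        )
    return variants


def _warn_conflict(key: str, field: str, old, new) -> None:
    logger.warning(
        "annotation conflict at %s for %s: INFO=%r sidecar=%r (sidecar wins)",
        key,
        field,
        old,
        new,
    )


def _apply_sidecar(site, maf_by_db, pred, cadd, revel, side, schema):
    if "gene" in side:
        site = dataclasses.replace(site, gene=str(side["gene"]))
    if "func_class" in side:
        site = dataclasses.replace(site, func_class=FuncClass(str(side["func_class"])))
    for db in MAF_DATABASES:
        col = schema.maf_key(db)
        if col in side:
            v = float(side[col])
            if db in maf_by_db and abs(maf_by_db[db] - v) > 1e-12:
                _warn_conflict(site.key, col, maf_by_db[db], v)
            maf_by_db[db] = v
    for tool in PREDICTOR_TOOLS:
        col = schema.pred_key(tool)
        if col in side:
            v = PredictorCall(str(side[col]))
            if tool in pred and pred[tool] is not v:
                _warn_conflict(site.key, col, pred[tool].value, v.value)
            pred[tool] = v
    if schema.cadd_key in side:
        v = float(side[schema.cadd_key])
        if cadd is not None and abs(cadd - v) > 1e-12:
            _warn_conflict(site.key, schema.cadd_key, cadd, v)
        cadd = v
    if schema.revel_key in side:
        v = float(side[schema.revel_key])
        if revel is not None and abs(revel - v) > 1e-12:
            _warn_conflict(site.key, schema.revel_key, revel, v)
        revel = v
    return site, maf_by_db, pred, cadd, revel


def _build_header(
    samples: Sequence[str],
    contigs: Sequence[str],
    schema: AnnotationSchema,
    with_annotations: bool,
) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line("##source=exocascade")
    for c in contigs:
        h.add_line(f"##contig=<ID={c}>")
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    h.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Approximated read depth per allele">'
    )
    h.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximated read depth">'
    )
    h.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    )
    h.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    h.add_line(
        '##INFO=<ID=FUNC_CLASS,Number=1,Type=String,'
        'Description="Functional class of the variant">'
    )
    h.add_line(
        '##INFO=<ID=CASCADE_STAGE,Number=1,Type=Integer,'
        'Description="Index of the last prioritization stage passed">'
    )
    if with_annotations:
        h.add_line(
            f'##INFO=<ID={schema.cadd_key},Number=1,Type=Float,'
            'Description="CADD Phred-scaled score">'
        )
        h.add_line(
            f'##INFO=<ID={schema.revel_key},Number=1,Type=Float,'
            'Description="REVEL ensemble pathogenicity score">'
        )
        for db in MAF_DATABASES:
            h.add_line(
                f'##INFO=<ID={schema.maf_key(db)},Number=1,Type=Float,'
                f'Description="Minor allele frequency in {db}">'
            )
        for tool in PREDICTOR_TOOLS:
            h.add_line(
                f'##INFO=<ID={schema.pred_key(tool)},Number=1,Type=String,'
                f'Description="Verdict of {tool}">'
            )
    for s in samples:
        h.add_sample(s)
    return h


def write_cohort_vcf(
    variants: Sequence[CohortVariant],
    out_path,
    schema: AnnotationSchema = DEFAULT_SCHEMA,
    with_annotations: bool = True,
    with_stage: bool = True,
) -> int:
    """Write variants to a VCF; returns the number of records written."""
    out_path = Path(out_path)
    samples = list(variants[0].sample_ids) if variants else []
    contigs: List[str] = []
    for v in variants:
        if v.site.chrom not in contigs:
            contigs.append(v.site.chrom)
    header = _build_header(samples, contigs, schema, with_annotations)
    n = 0
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.site.chrom,
                start=v.site.pos - 1,
                alleles=(v.site.ref, v.site.alt),
            )
            if v.site.gene:
                rec.info["GENE"] = v.site.gene
            rec.info["FUNC_CLASS"] = v.site.func_class.value
            if with_stage and v.cascade_stage is not None:
                rec.info["CASCADE_STAGE"] = int(v.cascade_stage)
            if with_annotations and v.annotation is not None:
                ann = v.annotation
                if ann.cadd_phred is not None:
                    rec.info[schema.cadd_key] = float(ann.cadd_phred)
                if ann.revel is not None:
                    rec.info[schema.revel_key] = float(ann.revel)
                for db, maf in ann.maf_by_db.items():
                    rec.info[schema.maf_key(db)] = float(maf)
                for tool, call in ann.predictor_calls.items():
                    if call is not PredictorCall.UNKNOWN:
                        rec.info[schema.pred_key(tool)] = call.value
            for call in v.calls:
                fmt = rec.samples[call.sample_id]
                fmt["GT"] = _GT_BY_ZYGOSITY[call.zygosity]
                if call.ad1 is not None and call.ad2 is not None:
                    fmt["AD"] = (call.ad1, call.ad2)
                if call.dp is not None:
                    fmt["DP"] = call.dp
                if call.gq is not None:
                    fmt["GQ"] = call.gq
            out.write(rec)
            n += 1
    return n


def write_sidecar(
    variants: Sequence[CohortVariant],
    out_path,
    schema: AnnotationSchema = DEFAULT_SCHEMA,
) -> int:
    """Write per-variant annotations as a tab-separated sidecar table."""
    out_path = Path(out_path)
    cols = (
        list(_KEY_COLS)
        + ["gene", "func_class", schema.cadd_key, schema.revel_key]
        + [schema.maf_key(db) for db in MAF_DATABASES]
        + [schema.pred_key(t) for t in PREDICTOR_TOOLS]
    )
    rows = []
    for v in variants:
        ann = v.annotation
        row: Dict[str, object] = {
            "chrom": v.site.chrom,
            "pos": v.site.pos,
            "ref": v.site.ref,
            "alt": v.site.alt,
            "gene": v.site.gene,
            "func_class": v.site.func_class.value,
        }
        if ann is not None:
            if ann.cadd_phred is not None:
                row[schema.cadd_key] = repr(ann.cadd_phred)
            if ann.revel is not None:
                row[schema.revel_key] = repr(ann.revel)
            for db, maf in ann.maf_by_db.items():
                row[schema.maf_key(db)] = repr(maf)
            for tool, call in ann.predictor_calls.items():
                row[schema.pred_key(tool)] = call.value
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(out_path, sep="\t", index=False, na_rep=".")
    return len(rows)


def _calls_long_table(variants: Sequence[CohortVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        for c in v.calls:
            rows.append(
                {
                    "chrom": v.site.chrom,
                    "pos": v.site.pos,
                    "ref": v.site.ref,
                    "alt": v.site.alt,
                    "gene": v.site.gene,
                    "func_class": v.site.func_class.value,
                    "cascade_stage": v.cascade_stage,
                    "sample": c.sample_id,
                    "zygosity": c.zygosity.value,
                    "gq": c.gq,
                    "dp": c.dp,
                    "ad1": c.ad1,
                    "ad2": c.ad2,
                }
            )
    return pd.DataFrame(rows)


def write_candidates(variants: Sequence[CohortVariant], out_path) -> int:
    """Write candidate variants with their cascade-stage tag.

    The format follows the extension: ``.vcf`` emits a VCF whose records
    (sites, calls and annotations) survive a read/write round trip; ``.tsv``
    emits a flat one-row-per-call report table.  Missing scores are encoded
    as absent keys, never as zero.  An empty list yields a valid header and
    zero records.
    """
    out_path = Path(out_path)
    if out_path.suffix == ".tsv":
        df = _calls_long_table(variants)
        df.to_csv(out_path, sep="\t", index=False, na_rep=".")
        return len(variants)
    return write_cohort_vcf(
        variants, out_path, with_annotations=True, with_stage=True
    )
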