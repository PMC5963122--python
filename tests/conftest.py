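"""Shared fixtures: in-memory variant factory and hand-written VCF text."""

from __future__ import annotations

import textwrap

import pytest

from exocascade.model import (
    AnnotationBundle,
    CohortVariant,
    FuncClass,
    GenotypeCall,
    PredictorCall,
    VariantSite,
    Zygosity,
)


@pytest.fixture
def make_variant():
    """Factory for small, fully-specified cohort variants.

    ``calls`` is a list of (sample_id, zygosity, gq, dp, ad1, ad2) tuples;
    annotation fields are passed through keyword arguments.
    """

    def _make(
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        gene="GENE1",
        func_class=FuncClass.MISSENSE,
        calls=(("S1", "het", 99, 80, 40, 40),),
        maf_by_db=None,
        n_damaging=0,
        cadd=None,
        revel=None,
        annotated=True,
    ):
        site = VariantSite(chrom, pos, ref, alt, gene, func_class)
        gcalls = tuple(
            GenotypeCall(sid, Zygosity(z), gq, dp, ad1, ad2)
            for sid, z, gq, dp, ad1, ad2 in calls
        )
        annotation = None
        if annotated:
            from exocascade.model import PREDICTOR_TOOLS

            preds = {
                tool: (
                    PredictorCall.DAMAGING
                    if i < n_damaging
                    else PredictorCall.TOLERATED
                )
                for i, tool in enumerate(PREDICTOR_TOOLS)
            }
            annotation = AnnotationBundle(
                maf_by_db or {}, preds, cadd, revel
            )
        return CohortVariant(site, gcalls, annotation)

    return _make


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=12>
    ##contig=<ID=1>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
    ##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
    ##INFO=<ID=FUNC_CLASS,Number=1,Type=String,Description="Functional class">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
    """
)


@pytest.fixture
def fixture_vcf(tmp_path):
    """A 3-record, 2-sample VCF written as plain text.

    Record 1 carries the depth/balance values of a validated reliable het
    (GT=0/1, AD=33,42, DP=75, GQ=99); record 2 has no AD field; record 3 is
    hom-ref in both samples.
    """
    body = "\n".join(
        [
            "12\t40713899\t.\tC\tT\t.\t.\tGENE=LRRK2;FUNC_CLASS=missense\t"
            "GT:AD:DP:GQ\t0/1:33,42:75:99\t0/0:70,0:70:99",
            "1\t1000\t.\tA\tG\t.\t.\tGENE=GENEA;FUNC_CLASS=missense\t"
            "GT:DP:GQ\t0/1:60:99\t0/1:55:98",
            "1\t2000\t.\tG\tC\t.\t.\tGENE=GENEB;FUNC_CLASS=synonymous\t"
            "GT:AD:DP:GQ\t0/0:50,0:50:99\t1/1:0,66:66:99",
        ]
    )
    path = tmp_path / "fixture.vcf"
    path.write_text(VCF_HEADER + body + "\n")
    return path
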