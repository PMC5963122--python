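"""Keyword gene-set selection and cohort-level summaries.

The functional-assessment step selects surviving variants whose gene appears
in user-supplied keyword gene sets (plain-text lists standing in for a
literature-network query, e.g. keywords "PD" and "neuron"), reports which
selected genes each keyword matched and which genes matched every keyword,
and summarizes the cohort: patients carrying candidates, patients with
candidates in two or more genes, and genes hit by multiple distinct variants.

Gene symbol matching is exact and case-insensitive; no alias resolution.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .model import CohortVariant, ConfigError, Zygosity


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A keyword label and the set of gene symbols it selects."""

    keyword: str
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ConfigError("gene set keyword must be non-empty")
        object.__setattr__(
            self, "genes", frozenset(g.upper() for g in self.genes)
        )

    @classmethod
    def from_file(cls, keyword: str, path) -> "GeneSet":
        """Load a one-symbol-per-line gene list (# comments, blank lines ok)."""
        genes = set()
        for line in Path(path).read_text().splitlines():
            symbol = line.split("#", 1)[0].strip()
            if symbol:
                genes.add(symbol.upper())
        if not genes:
            raise ConfigError(f"gene set {keyword!r} from {path} is empty")
        return cls(keyword, frozenset(genes))


def bundled_gene_set(keyword: str) -> GeneSet:
    """Example gene lists shipped with the package ("PD", "neuron").

    Small illustrative lists for testing and demos; real analyses should
    supply curated lists.
    """
    fname = {"PD": "pd_genes.txt", "neuron": "neuron_genes.txt"}.get(keyword)
    if fname is None:
        raise ConfigError(f"no bundled gene set for keyword {keyword!r}")
    ref = resources.files("exocascade.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return GeneSet.from_file(keyword, path)


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Cohort-level counts over the selected candidate variants.

    ``pct_patients_with_candidate`` is the exact percentage; rendering rounds
    it to the nearest integer for display.
    """

    n_candidate_variants: int
    n_candidate_genes: int
    n_patients_with_candidate: int
    pct_patients_with_candidate: float
    n_patients_with_two_genes: int
    genes_with_multiple_variants: Dict[str, int]
    both_keyword_genes: FrozenSet[str] = frozenset()


def filter_by_gene_sets(
    survivors: Sequence[CohortVariant], sets: Sequence[GeneSet]
) -> Tuple[List[CohortVariant], Dict[str, Set[str]], Set[str]]:
    """Select survivors whose gene appears in the union of the gene sets.

    Returns ``(selected, per_keyword, both)`` where ``per_keyword`` maps each
    keyword to the selected genes it matched and ``both`` is the intersection
    across all keywords, restricted to selected genes.  Supplying no sets, or
    any empty set, is a configuration error (an empty set would silently
    filter everything, which is distinct from "no filter").
    """
    if not sets:
        raise ConfigError("at least one gene set is required")
    by_keyword: Dict[str, Set[str]] = {}
    for s in sets:
        if not s.genes:
            raise ConfigError(f"gene set {s.keyword!r} is empty")
        by_keyword.setdefault(s.keyword, set()).update(s.genes)
    union = set().union(*by_keyword.values())
    selected = [v for v in survivors if v.site.gene.upper() in union]
    selected_genes = {v.site.gene.upper() for v in selected}
    per_keyword = {k: selected_genes & genes for k, genes in by_keyword.items()}
    both = set(selected_genes)
    for genes in by_keyword.values():
        both &= genes
    return selected, per_keyword, both


def summarize_cohort(
    selected: Sequence[CohortVariant],
    cohort_size: int,
    both_keyword_genes: FrozenSet[str] = frozenset(),
) -> CohortSummary:
    """Summarize candidate burden across the cohort.

    A patient carries a candidate when they have a heterozygous call at a
    selected variant.  ``genes_with_multiple_variants`` lists only genes hit
    by two or more distinct selected variants.
    """
    if cohort_size < 1:
        raise ConfigError(f"cohort_size must be >= 1, got {cohort_size}")
    genes_per_patient: Dict[str, Set[str]] = {}
    variants_per_gene: Dict[str, Set[str]] = {}
    for v in selected:
        if v.site.gene:
            variants_per_gene.setdefault(v.site.gene, set()).add(v.site.key)
        for c in v.calls:
            if c.zygosity is Zygosity.HET:
                genes_per_patient.setdefault(c.sample_id, set()).add(v.site.gene)
    n_with = len(genes_per_patient)
    return CohortSummary(
        n_candidate_variants=len({v.site.key for v in selected}),
        n_candidate_genes=len({v.site.gene for v in selected if v.site.gene}),
        n_patients_with_candidate=n_with,
        pct_patients_with_candidate=100.0 * n_with / cohort_size,
        n_patients_with_two_genes=sum(
            1 for genes in genes_per_patient.values() if len(genes) >= 2
        ),
        genes_with_multiple_variants={
            g: len(keys) for g, keys in sorted(variants_per_gene.items())
            if len(keys) >= 2
        },
        both_keyword_genes=frozenset(both_keyword_genes),
    )
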