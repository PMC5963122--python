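"""Screen for false-positive heterozygotes by read depth and allele balance.

Exome callers report some heterozygous genotypes at sites that orthogonal
(Sanger) validation shows to be homozygous; such artifact calls typically show
a strongly skewed ratio between the two allele depths.  The screen accepts a
heterozygous call as reliable when

    DP >= dp_min   and   |AD1 - AD2| / DP < ratio_max

with defaults DP >= 50 and ratio < 0.3.  Both inequalities are applied exactly
as stated: the depth bound is inclusive, the balance bound strict, and the
comparison uses the full-precision ratio (displays round to two decimals).
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

from .model import GenotypeCall, Zygosity


class HetReason(str, enum.Enum):
    PASS = "pass"
    NOT_HET = "not_het"
    MISSING_FIELDS = "missing_fields"
    LOW_DP = "low_dp"
    HIGH_IMBALANCE = "high_imbalance"


@dataclasses.dataclass(frozen=True)
class HetVerdict:
    """Outcome of the reliable-heterozygote screen for one call.

    ``ratio`` is |AD1 - AD2| / DP at full precision (``None`` when DP or an
    allele depth is missing, or DP is zero).  ``reliable`` is true iff
    ``reason`` is :attr:`HetReason.PASS`.
    """

    ratio: Optional[float]
    reliable: bool
    reason: HetReason


def allele_balance(ad1: int, ad2: int, dp: int) -> float:
    """Allele-balance statistic |ad1 - ad2| / dp of a heterozygous call.

    Symmetric in the two allele depths and invariant under a common scaling
    of all three inputs.  ``ad1 + ad2`` need not equal ``dp``.

    Raises
    ------
    ValueError
        If ``dp <= 0`` (the ratio is undefined) or any input is negative.
    """
    if ad1 < 0 or ad2 < 0:
        raise ValueError(f"allele depths must be non-negative: {ad1}, {ad2}")
    if dp <= 0:
        raise ValueError(f"allele balance undefined for DP <= 0 (got {dp})")
    return abs(ad1 - ad2) / dp


def classify_het(
    call: GenotypeCall, dp_min: int = 50, ratio_max: float = 0.3
) -> HetVerdict:
    """Apply the reliable-heterozygote rule to one genotype call.

    The verdict's ``reason`` records the first failed criterion, checked in
    the order: not heterozygous, missing AD/DP fields, depth below ``dp_min``,
    allele imbalance at or above ``ratio_max``.
    """
    ratio: Optional[float] = None
    if (
        call.dp is not None
        and call.dp > 0
        and call.ad1 is not None
        and call.ad2 is not None
    ):
        ratio = allele_balance(call.ad1, call.ad2, call.dp)

    if call.zygosity is not Zygosity.HET:
        return HetVerdict(ratio, False, HetReason.NOT_HET)
    if call.dp is None or call.ad1 is None or call.ad2 is None:
        return HetVerdict(ratio, False, HetReason.MISSING_FIELDS)
    if call.dp < dp_min:
        return HetVerdict(ratio, False, HetReason.LOW_DP)
    # dp >= dp_min > 0 here, so the ratio is defined
    assert ratio is not None
    if ratio >= ratio_max:
        return HetVerdict(ratio, False, HetReason.HIGH_IMBALANCE)
    return HetVerdict(ratio, True, HetReason.PASS)
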