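"""Funnel-report rendering and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

from .cascade import CascadeReport
from .genes import CohortSummary


def report_tsv(report: CascadeReport) -> str:
    lines = ["stage\tvariants\tgenes\tpatients"]
    for s in report.stages:
        lines.append(f"{s.stage}\t{s.n_variants}\t{s.n_genes}\t{s.n_patients}")
    return "\n".join(lines) + "\n"


def summary_dict(summary: CohortSummary) -> Dict[str, object]:
    d = dataclasses.asdict(summary)
    d["both_keyword_genes"] = sorted(summary.both_keyword_genes)
    return d


def render_report(
    report: CascadeReport, summary: Optional[CohortSummary] = None
) -> Tuple[str, str]:
    """Human-readable funnel plus machine-readable TSV (identical numbers)."""
    tsv = report_tsv(report)
    width = max(len(s.stage) for s in report.stages)
    lines = ["Prioritization funnel (variants / genes / patients)"]
    for s in report.stages:
        lines.append(
            f"  {s.stage:<{width}}  {s.n_variants:>8d}  {s.n_genes:>6d}"
            f"  {s.n_patients:>6d}"
        )
    lines.append(
        "  patients with two surviving variants in one gene: "
        f"{report.n_patients_two_variants_same_gene}"
    )
    if summary is not None:
        lines.append("Cohort summary")
        lines.append(f"  candidate variants: {summary.n_candidate_variants}")
        lines.append(f"  candidate genes:    {summary.n_candidate_genes}")
        lines.append(
            f"  patients with a candidate: {summary.n_patients_with_candidate}"
            f" ({round(summary.pct_patients_with_candidate)}%)"
        )
        lines.append(
            f"  patients with candidates in two genes: "
            f"{summary.n_patients_with_two_genes}"
        )
        if summary.genes_with_multiple_variants:
            recur = ", ".join(
                f"{g}={n}" for g, n in summary.genes_with_multiple_variants.items()
            )
            lines.append(f"  genes with multiple variants: {recur}")
        if summary.both_keyword_genes:
            lines.append(
                "  genes matching every keyword: "
                + ", ".join(sorted(summary.both_keyword_genes))
            )
    return "\n".join(lines) + "\n", tsv


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one run: inputs, config, version, counts."""

    version: str
    created_utc: str
    inputs: Dict[str, str]
    config: Dict[str, object]
    stage_counts: Dict[str, int]
    seed: Optional[int] = None

    @classmethod
    def create(
        cls,
        version: str,
        input_paths: Sequence[Path],
        config: Dict[str, object],
        report: CascadeReport,
        seed: Optional[int] = None,
    ) -> "RunManifest":
        return cls(
            version=version,
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            inputs={str(p): _sha256(Path(p)) for p in input_paths},
            config=dict(config),
            stage_counts={s.stage: s.n_variants for s in report.stages},
            seed=seed,
        )

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )
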