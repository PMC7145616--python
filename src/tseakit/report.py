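"""Study reports and the small arithmetic helpers they share.

``format_pct`` and ``tally`` are the single implementations used everywhere
a report prints a percentage or sums a breakdown, so printed numbers always
recompute from their inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ContractError

__all__ = ["format_pct", "tally", "StudyReport"]

SCHEMA_VERSION = 1


def format_pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded to ``decimals`` places (e.g. 45/105 -> 42.9)."""
    if denominator == 0:
        raise ContractError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def tally(counts) -> int:
    """Sum of a breakdown of integer counts."""
    return int(sum(int(c) for c in counts))


@dataclass
class StudyReport:
    """Machine-readable record of one full study run.

    Mirrors a trait page: QC numbers, gene-score summary, TAG-set sizes and
    qualification, per-panel enrichment P-values, top tissues with their
    GSEA validation, and provenance (input hashes, seed, version)."""

    study_id: str
    qc: dict
    n_genes_scored: int = 0
    study_qualified: bool = False
    tag_summary: dict = field(default_factory=dict)   # threshold -> {size, qualified}
    tsea: dict = field(default_factory=dict)          # panel_id -> long rows
    top_tissues: dict = field(default_factory=dict)   # panel_id -> [gsea dicts]
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    @property
    def passed(self) -> bool:
        return bool(self.qc.get("passed", False))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StudyReport":
        p = Path(str(source))
        data = json.loads(p.read_text() if p.is_file() else str(source))
        data.pop("passed", None)
        return cls(**data)

    def validate_consistency(self) -> None:
        """Spot-check that derived numbers re-derive from their parts."""
        qc = self.qc
        removed = tally(f["n_removed"] for f in qc.get("filters_applied", []))
        if qc["n_variants_in"] - removed != qc["n_variants_out"]:
            raise ContractError("QC variant counts do not reconcile with filter removals")
        for thr, info in self.tag_summary.items():
            size_ok = 20 <= info["size"] <= 3000
            if bool(info["qualified"]) != size_ok:
                raise ContractError(f"TAG qualification flag inconsistent at {thr}")
        for panel, records in self.top_tissues.items():
            if len(records) > 3:
                raise ContractError(f"more than 3 top tissues reported for {panel}")
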