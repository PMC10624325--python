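"""Canonical-MAIT classification of sorted single cells.

MAIT cells are defined by a semi-invariant alpha chain: TRAV1-2 joined to
TRAJ12, TRAJ20 or TRAJ33. Flow sorting on surface markers (Vα7.2+ CD161hi)
is imperfect in the colon, so sorted wells contain contaminant T cells;
this module applies the sequence-level rule — a cell is canonical iff it
carries a productive TRAV1-2/TRAJ12/20/33 alpha chain *and* a productive
beta chain (the "productive paired" requirement) — and tabulates per-sample
canonical fractions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genes import CANONICAL_TRAJ, is_trav1_2, normalize_gene
from .models import CellRecord

__all__ = [
    "MaitClassification",
    "FilterSummary",
    "classify_cell",
    "summarize_filter",
    "canonical_cells",
    "REASONS",
]

#: Classification reasons, in the fixed precedence order applied by
#: :func:`classify_cell` (first failing reason wins).
REASONS = (
    "canonical",
    "missing_alpha",
    "nonproductive_alpha",
    "wrong_trav",
    "wrong_traj",
    "missing_beta",
)


@dataclass(frozen=True)
class MaitClassification:
    cell_id: str
    is_canonical: bool
    reason: str

    def __post_init__(self) -> None:
        assert (self.reason == "canonical") == self.is_canonical


@dataclass
class FilterSummary:
    """Per-sample canonical/contaminant tabulation (one biopsy = one row)."""

    donor_id: str
    tissue: str
    inflammation: str
    n_total: int = 0
    n_canonical: int = 0
    traj_usage: dict[str, int] = field(default_factory=dict)

    @property
    def n_noncanonical(self) -> int:
        return self.n_total - self.n_canonical

    @property
    def canonical_fraction(self) -> float:
        return self.n_canonical / self.n_total if self.n_total else 0.0


def classify_cell(cell: CellRecord, alpha_only: bool = False) -> MaitClassification:
    """Classify one cell against the canonical MAIT alpha-chain rule.

    Reasons are assigned in the fixed order missing_alpha →
    nonproductive_alpha → wrong_trav → wrong_traj → missing_beta, so counts
    are reproducible. A present-but-nonproductive beta chain fails the
    "productive paired" requirement and is reported as ``missing_beta``.
    With ``alpha_only=True`` the beta requirement is waived (for alpha-only
    canonical tabulations).
    """
    alpha = cell.alpha
    if alpha is None:
        return MaitClassification(cell.cell_id, False, "missing_alpha")
    if not alpha.productive:
        return MaitClassification(cell.cell_id, False, "nonproductive_alpha")
    if not is_trav1_2(alpha.v_call):
        return MaitClassification(cell.cell_id, False, "wrong_trav")
    if normalize_gene(alpha.j_call) not in CANONICAL_TRAJ:
        return MaitClassification(cell.cell_id, False, "wrong_traj")
    if not alpha_only and (cell.beta is None or not cell.beta.productive):
        return MaitClassification(cell.cell_id, False, "missing_beta")
    return MaitClassification(cell.cell_id, True, "canonical")


def canonical_cells(
    cells: list[CellRecord], alpha_only: bool = False
) -> list[CellRecord]:
    """The subset of cells passing the canonical filter."""
    return [
        c for c in cells if classify_cell(c, alpha_only=alpha_only).is_canonical
    ]


def summarize_filter(
    cells: list[CellRecord], alpha_only: bool = False
) -> list[FilterSummary]:
    """Tabulate canonical vs contaminant counts per sample plus a TOTAL row.

    A sample is one (donor, tissue, inflammation) triple — i.e. one biopsy.
    ``traj_usage`` counts the TRAJ gene of each canonical cell's alpha
    chain, so per sample Σ traj_usage == n_canonical.
    """
    if not cells:
        raise ValueError("summarize_filter requires at least one cell")
    samples: dict[tuple[str, str, str], FilterSummary] = {}
    total = FilterSummary(donor_id="TOTAL", tissue="", inflammation="")
    total_traj: Counter[str] = Counter()
    for cell in cells:
        key = (cell.donor_id, cell.tissue, cell.inflammation)
        summary = samples.get(key)
        if summary is None:
            summary = FilterSummary(*key)
            samples[key] = summary
        cls = classify_cell(cell, alpha_only=alpha_only)
        summary.n_total += 1
        total.n_total += 1
        if cls.is_canonical:
            summary.n_canonical += 1
            total.n_canonical += 1
            traj = normalize_gene(cell.alpha.j_call)
            summary.traj_usage[traj] = summary.traj_usage.get(traj, 0) + 1
            total_traj[traj] += 1
    total.traj_usage = dict(sorted(total_traj.items()))
    out = [samples[k] for k in sorted(samples)]
    out.append(total)
    return out
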