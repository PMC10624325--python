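"""Clonotype identity, clonal sharing, colon↔blood overlap, and publicity.

Two identity levels coexist deliberately:

* **paired nucleotide clonotypes** — identical (V, J, CDR3 nt) on *both*
  chains; used within the single-cell colon data where full paired
  sequences exist ("exact same TCR alpha and beta sequences");
* **β-chain CDR3 amino-acid keys** — used for every comparison that
  involves bulk blood repertoires or crosses donors, because bulk data
  carries no alpha chain and publicity is conventionally counted on the
  CDR3β amino-acid sequence alone (V/J not conditioned on).

Both levels are exposed so the identity choice is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import floor

from .models import BulkClone, CellRecord, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "PairedClonotype",
    "SharingEdge",
    "OverlapRow",
    "PublicPartition",
    "build_clonotypes",
    "sharing_edges",
    "colon_blood_overlap",
    "public_partition",
    "round_pct",
    "repertoire_from_cells",
    "OVERLAP_STRATA",
]

OVERLAP_STRATA = ("HC", "CD all", "CD NC", "CD IC", "total")

EDGE_CLASSES = (
    "within_HC_biopsy",
    "within_CD_inflamed",
    "within_CD_uninflamed",
    "CD_cross_inflammation",
    "cross_donor_public",  # only emitted when explicitly requested
)

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PairedClonotype:
    """Nucleotide-level paired clonotype key of one canonical cell."""

    alpha_key: tuple[str, str, str]  # (v_call, j_call, cdr3_nt)
    beta_key: tuple[str, str, str]

    @classmethod
    def from_cell(cls, cell: CellRecord) -> "PairedClonotype":
        a, b = cell.alpha, cell.beta
        if a is None or b is None:
            raise ValueError(f"cell {cell.cell_id} lacks a paired receptor")
        return cls(
            alpha_key=(a.v_call, a.j_call, a.cdr3_nt),
            beta_key=(b.v_call, b.j_call, b.cdr3_nt),
        )


@dataclass(frozen=True)
class SharingEdge:
    """One unordered pair of distinct cells carrying an identical
    paired clonotype (a thin line in a circos-style sharing plot)."""

    cell_id_1: str
    cell_id_2: str
    clonotype: PairedClonotype
    edge_class: str


@dataclass(frozen=True)
class OverlapRow:
    """One stratum of the colon↔blood overlap accounting.

    ``in_both`` counts unique colonic CDR3β amino-acid sequences found in
    *any* blood repertoire; ``autologous``/``allogeneic`` count those found
    in the same donor's / another donor's blood. The categories overlap: a
    sequence in both autologous and allogeneic blood increments all three.
    """

    stratum: str
    total_colon_unique: int
    in_both: int
    autologous: int
    allogeneic: int

    @property
    def pct_both(self) -> int:
        return round_pct(self.in_both, self.total_colon_unique)

    @property
    def pct_autologous(self) -> int:
        return round_pct(self.autologous, self.total_colon_unique)

    @property
    def pct_allogeneic(self) -> int:
        return round_pct(self.allogeneic, self.total_colon_unique)


@dataclass
class PublicPartition:
    """Blood CDR3β sequences carried by ≥2 donors, split by carrier cohort."""

    carriers: dict[str, set[str]]  # public sequence -> donor ids
    classes: dict[str, str]  # public sequence -> "cd_only"|"hc_only"|"shared"

    @property
    def n_public(self) -> int:
        return len(self.carriers)

    @property
    def n_cd_only(self) -> int:
        return sum(1 for c in self.classes.values() if c == "cd_only")

    @property
    def n_hc_only(self) -> int:
        return sum(1 for c in self.classes.values() if c == "hc_only")

    @property
    def n_shared(self) -> int:
        return sum(1 for c in self.classes.values() if c == "shared")


def round_pct(numerator: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero.

    This is the convention overlap tables of this shape print; unlike
    Python's default round-half-to-even, 1/8 yields 13%, not 12%.
    """
    if denominator == 0:
        return 0
    return int(floor(100.0 * numerator / denominator + 0.5))


def build_clonotypes(
    canonical_cells: list[CellRecord],
) -> dict[PairedClonotype, list[str]]:
    """Group canonical cells by their paired nucleotide clonotype.

    Cells whose CDR3 nucleotide sequence contains an ambiguity base 'N' are
    excluded from exact matching and logged. Returns a mapping clonotype →
    sorted list of member cell ids; clonotypes with ≥2 cells are expanded.
    """
    out: dict[PairedClonotype, list[str]] = {}
    for cell in canonical_cells:
        ct = PairedClonotype.from_cell(cell)
        if "N" in ct.alpha_key[2] or "N" in ct.beta_key[2]:
            logger.warning(
                "cell %s: CDR3 contains 'N'; excluded from clonotype matching",
                cell.cell_id,
            )
            continue
        out.setdefault(ct, []).append(cell.cell_id)
    for members in out.values():
        members.sort()
    return out


def _edge_class(c1: CellRecord, c2: CellRecord) -> str:
    if c1.donor_id != c2.donor_id:
        return "cross_donor_public"
    if c1.cohort == "HC":
        return "within_HC_biopsy"
    states = {c1.inflammation, c2.inflammation}
    if states == {"inflamed"}:
        return "within_CD_inflamed"
    if states == {"uninflamed"}:
        return "within_CD_uninflamed"
    return "CD_cross_inflammation"


def sharing_edges(
    clonotypes: dict[PairedClonotype, list[str]],
    cells: dict[str, CellRecord] | list[CellRecord],
    include_cross_donor: bool = False,
) -> list[SharingEdge]:
    """One edge per unordered cell pair within each clonotype.

    Edge classes mirror the sharing-plot colouring: green within an HC
    biopsy, red within inflamed CD tissue, blue within uninflamed CD
    tissue, purple when a CD donor's inflamed and uninflamed biopsies share
    a clonotype. Cross-donor pairs are dropped unless
    ``include_cross_donor`` is set (then labelled ``cross_donor_public``).
    """
    if isinstance(cells, list):
        cells = {c.cell_id: c for c in cells}
    edges: list[SharingEdge] = []
    for ct in sorted(
        clonotypes, key=lambda k: (k.alpha_key, k.beta_key)
    ):
        for id1, id2 in combinations(clonotypes[ct], 2):
            c1, c2 = cells[id1], cells[id2]
            klass = _edge_class(c1, c2)
            if klass == "cross_donor_public" and not include_cross_donor:
                continue
            edges.append(SharingEdge(id1, id2, ct, klass))
    return edges


def _beta_aa(cell: CellRecord) -> str | None:
    """β CDR3 amino-acid key of a canonical cell; None when ambiguous."""
    if cell.beta is None or not cell.beta.cdr3_aa:
        return None
    aa = cell.beta.cdr3_aa
    if set(aa) - _AA20:
        return None
    return aa


def _stratum_cells(colon_cells: list[CellRecord], stratum: str) -> list[CellRecord]:
    if stratum == "HC":
        return [c for c in colon_cells if c.cohort == "HC"]
    if stratum == "CD all":
        return [c for c in colon_cells if c.cohort == "CD"]
    if stratum == "CD NC":
        return [c for c in colon_cells
                if c.cohort == "CD" and c.inflammation == "uninflamed"]
    if stratum == "CD IC":
        return [c for c in colon_cells
                if c.cohort == "CD" and c.inflammation == "inflamed"]
    if stratum == "total":
        return list(colon_cells)
    raise ValueError(f"unknown stratum {stratum!r}")


def colon_blood_overlap(
    colon_cells: list[CellRecord], blood: list[Repertoire]
) -> list[OverlapRow]:
    """Account for colonic CDR3β overlap with blood, per stratum.

    ``colon_cells`` must already be canonical-filtered. Strata: HC, CD all,
    CD NC, CD IC, total; CD all and total de-duplicate sequences seen in
    both of a donor's biopsies. A sequence's carriers are the colonic
    donors presenting it within the stratum; autologous requires a
    carrier's own blood, allogeneic requires any *other* donor's blood
    (blood from either cohort counts). Donors without a blood sample are
    logged; their sequences can still overlap allogeneically.
    """
    blood_sets = {rep.donor_id: rep.aa_set() for rep in blood}
    colon_donors = {c.donor_id for c in colon_cells}
    for donor in sorted(colon_donors - set(blood_sets)):
        logger.info(
            "colon donor %s has no blood repertoire; autologous overlap "
            "undefined for this donor", donor,
        )
    rows: list[OverlapRow] = []
    for stratum in OVERLAP_STRATA:
        carriers: dict[str, set[str]] = {}
        for cell in _stratum_cells(colon_cells, stratum):
            aa = _beta_aa(cell)
            if aa is not None:
                carriers.setdefault(aa, set()).add(cell.donor_id)
        in_both = autologous = allogeneic = 0
        for aa, donors in carriers.items():
            hit_any = any(aa in s for s in blood_sets.values())
            hit_auto = any(aa in blood_sets.get(d, ()) for d in donors)
            hit_allo = any(
                aa in s for d, s in blood_sets.items() if d not in donors
            )
            in_both += hit_any
            autologous += hit_auto
            allogeneic += hit_allo
        rows.append(
            OverlapRow(stratum, len(carriers), in_both, autologous, allogeneic)
        )
    return rows


def public_partition(repertoires: list[Repertoire]) -> PublicPartition:
    """Partition blood CDR3β sequences present in ≥2 donors by cohort.

    A sequence is *public* iff carried by at least two distinct donors;
    public sequences are classed ``cd_only`` / ``hc_only`` / ``shared``
    by the cohorts of their carriers, and the three classes always sum to
    the public total.
    """
    if len({r.donor_id for r in repertoires}) < 2:
        raise ValueError("public_partition requires repertoires from >=2 donors")
    cohort_of = {r.donor_id: r.cohort for r in repertoires}
    carriers: dict[str, set[str]] = {}
    for rep in repertoires:
        for aa in rep.aa_set():
            carriers.setdefault(aa, set()).add(rep.donor_id)
    public = {aa: d for aa, d in carriers.items() if len(d) >= 2}
    classes: dict[str, str] = {}
    for aa, donors in public.items():
        cohorts = {cohort_of[d] for d in donors}
        if cohorts == {"CD"}:
            classes[aa] = "cd_only"
        elif cohorts == {"HC"}:
            classes[aa] = "hc_only"
        else:
            classes[aa] = "shared"
    return PublicPartition(carriers=public, classes=classes)


def repertoire_from_cells(
    cells: list[CellRecord], donor_id: str, cohort: str
) -> Repertoire:
    """Collapse canonical colon cells into a β-amino-acid-level repertoire,
    so the same diversity statistics apply to single-cell samples."""
    counts: dict[str, int] = {}
    for cell in cells:
        aa = _beta_aa(cell)
        if aa is not None:
            counts[aa] = counts.get(aa, 0) + 1
    clones = [BulkClone(cdr3_aa=aa, count=n) for aa, n in sorted(counts.items())]
    return Repertoire(donor_id=donor_id, cohort=cohort, clones=clones,
                      tissue="colon")
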