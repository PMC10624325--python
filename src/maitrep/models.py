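"""Domain types for single-cell and bulk TCR repertoire data.

The package distinguishes two data shapes that mirror the two sequencing
arms of the study design it supports:

* **single-cell paired records** (:class:`CellRecord`) — one sorted cell with
  up to one α and one β :class:`ChainRecord`, carrying donor / cohort /
  tissue / inflammation metadata; and
* **bulk β-chain repertoires** (:class:`Repertoire` of :class:`BulkClone`) —
  one row per unique rearrangement with a template count, the unit on which
  diversity and overlap statistics operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import Seq

from .errors import MaitRepError

__all__ = [
    "ChainRecord",
    "CellRecord",
    "BulkClone",
    "Repertoire",
    "translate_cdr3",
    "chain_violations",
    "cell_violations",
    "COHORTS",
    "TISSUES",
    "INFLAMMATION_STATES",
]

COHORTS = ("HC", "CD")
TISSUES = ("colon", "blood")
INFLAMMATION_STATES = ("inflamed", "uninflamed", "not_applicable")

_NT_ALPHABET = set("ACGTN")


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate a CDR3 nucleotide junction to single-letter amino acids.

    Trailing partial codons are marked '_' (frameshift), matching the
    convention that productive junctions are a whole number of codons.
    Codons containing 'N' translate to 'X'.
    """
    nt = cdr3_nt.strip().upper()
    n_full = len(nt) // 3 * 3
    aa = ""
    for i in range(0, n_full, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            aa += "X"
        else:
            aa += str(Seq(codon).translate())
    if len(nt) != n_full:
        aa += "_"
    return aa


@dataclass(frozen=True)
class ChainRecord:
    """One sequenced TCR chain as reported by an IMGT-style aligner.

    ``cdr3_nt``/``cdr3_aa`` use the IMGT junction convention: the conserved
    cysteine through the conserved F/W anchor are included, so a canonical
    MAIT alpha junction reads e.g. ``CAVMDSNYQLIW``.
    """

    locus: str  # "TRA" | "TRB"
    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    d_call: str = ""  # TRB only; empty for TRA

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise MaitRepError(f"unknown locus {self.locus!r}")
        object.__setattr__(self, "cdr3_nt", self.cdr3_nt.strip().upper())


@dataclass(frozen=True)
class CellRecord:
    """One sorted cell: metadata plus zero or one chain per locus."""

    cell_id: str
    donor_id: str
    cohort: str  # "HC" | "CD"
    tissue: str  # "colon" | "blood"
    inflammation: str  # "inflamed" | "uninflamed" | "not_applicable"
    alpha: Optional[ChainRecord] = None
    beta: Optional[ChainRecord] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise MaitRepError(f"unknown cohort {self.cohort!r}")
        if self.tissue not in TISSUES:
            raise MaitRepError(f"unknown tissue {self.tissue!r}")
        if self.inflammation not in INFLAMMATION_STATES:
            raise MaitRepError(f"unknown inflammation {self.inflammation!r}")

    def with_donor(self, donor_id: str) -> "CellRecord":
        return replace(self, donor_id=donor_id)


@dataclass(frozen=True)
class BulkClone:
    """One unique β-chain rearrangement in a bulk repertoire.

    ``count`` is the template (or read) abundance; gene calls may be empty
    when the source export reports the CDR3 amino-acid sequence only.
    """

    cdr3_aa: str
    count: int
    v_call: str = ""
    j_call: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise MaitRepError(f"clone count must be >= 1, got {self.count}")
        if not self.cdr3_aa:
            raise MaitRepError("clone cdr3_aa must be non-empty")


@dataclass
class Repertoire:
    """A donor+compartment clone collection: the unit of diversity/overlap.

    ``clones`` hold unique (cdr3_aa, v_call, j_call) keys; ``total_cells``
    is the sum of clone counts (N in the diversity estimators).
    """

    donor_id: str
    cohort: str
    clones: list[BulkClone] = field(default_factory=list)
    tissue: str = "blood"

    @property
    def total_cells(self) -> int:
        return sum(c.count for c in self.clones)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def counts(self) -> list[int]:
        return [c.count for c in self.clones]

    def aa_counts(self) -> dict[str, int]:
        """Clone counts aggregated to the β CDR3 amino-acid level."""
        out: dict[str, int] = {}
        for c in self.clones:
            out[c.cdr3_aa] = out.get(c.cdr3_aa, 0) + c.count
        return out

    def aa_set(self) -> set[str]:
        return {c.cdr3_aa for c in self.clones}


def chain_violations(chain: ChainRecord) -> list[str]:
    """Invariant check for a chain; returns human-readable violations.

    Violations are reported, not raised: real single-cell Sanger data
    contains imperfect records that must still be loaded and counted.
    """
    problems: list[str] = []
    if chain.locus == "TRA" and chain.d_call:
        problems.append(f"TRA chain carries d_call {chain.d_call!r}")
    if chain.cdr3_nt and (set(chain.cdr3_nt) - _NT_ALPHABET):
        bad = sorted(set(chain.cdr3_nt) - _NT_ALPHABET)
        problems.append(f"cdr3_nt contains non-IUPAC characters {bad}")
    if chain.productive:
        if "*" in chain.cdr3_aa or "_" in chain.cdr3_aa:
            problems.append("productive chain with stop/frameshift in cdr3_aa")
        if chain.cdr3_nt and len(chain.cdr3_nt) % 3 != 0:
            problems.append("productive chain with cdr3_nt length not multiple of 3")
        elif chain.cdr3_nt and chain.cdr3_aa:
            expected = translate_cdr3(chain.cdr3_nt)
            if "N" not in chain.cdr3_nt and expected != chain.cdr3_aa:
                problems.append(
                    f"cdr3_aa {chain.cdr3_aa!r} != translation {expected!r}"
                )
    return problems


def cell_violations(cell: CellRecord) -> list[str]:
    """Invariant check for a cell record (metadata + both chains)."""
    problems: list[str] = []
    if cell.tissue == "blood" and cell.inflammation != "not_applicable":
        problems.append("blood cell with inflammation status set")
    if cell.alpha is not None and cell.alpha.locus != "TRA":
        problems.append("alpha slot holds a non-TRA chain")
    if cell.beta is not None and cell.beta.locus != "TRB":
        problems.append("beta slot holds a non-TRB chain")
    for label, chain in (("alpha", cell.alpha), ("beta", cell.beta)):
        if chain is not None:
            problems.extend(f"{label}: {p}" for p in chain_violations(chain))
    return problems
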