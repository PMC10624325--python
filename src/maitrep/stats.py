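"""Repertoire summary statistics.

* **Simpson clonality** — the unbiased estimator
  ``Σ n_i(n_i−1) / (N(N−1))``: the probability that two distinct cells
  drawn without replacement share a clonotype. 1 means monoclonal; 0 means
  every cell carries a different β sequence. The biased plug-in form
  ``Σ p_i²`` never reaches 0 on finite samples and is therefore not used
  as the default.
* **Morisita overlap** — by default the frequency-based Morisita–Horn
  index ``2 Σ p_i q_i / (Σ p_i² + Σ q_i²)``, robust to unequal sample
  sizes; the classical count-based Morisita form is available via
  ``variant="classical"``.
* **Gene usage** and **consensus CDR3 motifs** for the semi-invariant
  alpha chain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import UndefinedDiversityError
from .genes import normalize_gene
from .models import CellRecord, Repertoire

__all__ = [
    "DiversityResult",
    "OverlapMatrix",
    "ConsensusMotif",
    "simpson_clonality",
    "morisita_overlap",
    "overlap_matrix",
    "consensus_motif",
    "gene_usage",
]


@dataclass(frozen=True)
class DiversityResult:
    simpson: float
    n_cells: int
    n_clones: int
    clone_counts: tuple[int, ...]


@dataclass
class OverlapMatrix:
    donors: list[str]
    cohorts: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal
    groups: dict[str, list[float]]  # HCvsHC / CDvsCD / HCvsCD


@dataclass(frozen=True)
class ConsensusMotif:
    """Positional consensus, e.g. ``CAV[M/R]DSNYQLIW``: single residues where
    one residue reaches the majority threshold, bracketed two-residue
    alternatives where the top two do jointly, 'X' otherwise."""

    motif: str
    support: float

    def tokens(self) -> list[set[str]]:
        """Expand the motif into per-position allowed-residue sets
        ('X' → any residue)."""
        out: list[set[str]] = []
        i = 0
        while i < len(self.motif):
            ch = self.motif[i]
            if ch == "[":
                j = self.motif.index("]", i)
                out.append(set(self.motif[i + 1 : j].split("/")))
                i = j + 1
            elif ch == "X":
                out.append(set())
                i += 1
            else:
                out.append({ch})
                i += 1
        return out

    def matches(self, seq: str) -> bool:
        toks = self.tokens()
        if len(seq) != len(toks):
            return False
        return all(not tok or ch in tok for ch, tok in zip(seq, toks))


def simpson_clonality(rep: Repertoire) -> DiversityResult:
    """Unbiased Simpson clonality of a repertoire.

    Raises :class:`UndefinedDiversityError` for N < 2 (no cell pair exists).
    """
    counts = np.asarray(rep.counts(), dtype=np.int64)
    n = int(counts.sum())
    if n < 2:
        raise UndefinedDiversityError(
            f"Simpson clonality undefined for N={n} (need >= 2 cells)"
        )
    simpson = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    return DiversityResult(
        simpson=simpson,
        n_cells=n,
        n_clones=len(counts),
        clone_counts=tuple(int(c) for c in counts),
    )


def morisita_overlap(
    rep_a: Repertoire, rep_b: Repertoire, variant: str = "horn"
) -> float:
    """Morisita overlap of two repertoires matched on β CDR3 amino acids.

    ``variant="horn"`` (default): 2 Σ p_i q_i / (Σ p_i² + Σ q_i²) on
    relative frequencies; ``variant="classical"``: the count-based
    Morisita index 2 Σ x_i y_i / ((λ_x + λ_y) X Y) with
    λ = Σ n(n−1)/(N(N−1)). Both are 0 for disjoint clone sets; the Horn
    form is exactly 1 for identical frequency vectors, while the classical
    form approaches 1 from above as identical samples grow (it can exceed
    1 on finite counts).
    """
    ca, cb = rep_a.aa_counts(), rep_b.aa_counts()
    if not ca or not cb:
        raise UndefinedDiversityError("morisita_overlap requires nonempty repertoires")
    union = sorted(set(ca) | set(cb))
    x = np.array([ca.get(k, 0) for k in union], dtype=float)
    y = np.array([cb.get(k, 0) for k in union], dtype=float)
    if variant == "horn":
        p = x / x.sum()
        q = y / y.sum()
        denom = float((p * p).sum() + (q * q).sum())
        return float(2.0 * (p * q).sum() / denom)
    if variant == "classical":
        nx, ny = x.sum(), y.sum()
        if nx < 2 or ny < 2:
            raise UndefinedDiversityError(
                "classical Morisita requires >= 2 cells per repertoire"
            )
        lam_x = float((x * (x - 1)).sum() / (nx * (nx - 1)))
        lam_y = float((y * (y - 1)).sum() / (ny * (ny - 1)))
        if lam_x + lam_y == 0:
            return 0.0
        return float(2.0 * (x * y).sum() / ((lam_x + lam_y) * nx * ny))
    raise ValueError(f"unknown Morisita variant {variant!r}")


def overlap_matrix(
    reps: list[Repertoire], variant: str = "horn"
) -> OverlapMatrix:
    """All-pairs Morisita overlap with cohort-pair grouping.

    Emits C(n,2) off-diagonal values, each assigned to exactly one of the
    groups HCvsHC, CDvsCD, HCvsCD.
    """
    if len(reps) < 2:
        raise ValueError("overlap_matrix requires >= 2 repertoires")
    n = len(reps)
    mat = np.eye(n)
    groups: dict[str, list[float]] = {"HCvsHC": [], "CDvsCD": [], "HCvsCD": []}
    for i, j in combinations(range(n), 2):
        value = morisita_overlap(reps[i], reps[j], variant=variant)
        mat[i, j] = mat[j, i] = value
        pair = {reps[i].cohort, reps[j].cohort}
        if pair == {"HC"}:
            groups["HCvsHC"].append(value)
        elif pair == {"CD"}:
            groups["CDvsCD"].append(value)
        else:
            groups["HCvsCD"].append(value)
    return OverlapMatrix(
        donors=[r.donor_id for r in reps],
        cohorts=[r.cohort for r in reps],
        matrix=mat,
        groups=groups,
    )


def consensus_motif(
    cdr3_list: list[str], majority: float = 0.5
) -> ConsensusMotif:
    """Positional consensus over CDR3 sequences of the modal length.

    Per position: the single most frequent residue if its frequency is
    ≥ ``majority``; else the two most frequent residues bracketed if they
    jointly reach ``majority``; else 'X'. Support is the fraction of
    modal-length sequences matching the expanded motif. Ties on modal
    length resolve to the shorter length; the result is invariant to
    input order.
    """
    if not cdr3_list:
        raise ValueError("consensus_motif requires at least one sequence")
    lengths = Counter(len(s) for s in cdr3_list)
    top = max(lengths.values())
    modal_len = min(L for L, c in lengths.items() if c == top)
    seqs = [s for s in cdr3_list if len(s) == modal_len]
    n = len(seqs)
    parts: list[str] = []
    for pos in range(modal_len):
        freq = Counter(s[pos] for s in seqs)
        # deterministic tie-break: frequency desc, then alphabetical
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
        best, best_n = ranked[0]
        if best_n / n >= majority:
            parts.append(best)
        elif len(ranked) >= 2 and (best_n + ranked[1][1]) / n >= majority:
            second = ranked[1][0]
            parts.append(f"[{best}/{second}]")
        else:
            parts.append("X")
    motif = ConsensusMotif(motif="".join(parts), support=1.0)
    support = sum(motif.matches(s) for s in seqs) / n
    return ConsensusMotif(motif=motif.motif, support=support)


_SEGMENT_FIELD = {
    "TRAJ": ("alpha", "j_call"),
    "TRAV": ("alpha", "v_call"),
    "TRBV": ("beta", "v_call"),
    "TRBD": ("beta", "d_call"),
    "TRBJ": ("beta", "j_call"),
}


def gene_usage(
    records: list[CellRecord] | Repertoire,
    segment: str,
    per_clonotype: bool = False,
) -> dict[str, float]:
    """Gene-usage fractions for one segment class.

    For cell lists, counts are per cell by default; ``per_clonotype=True``
    weights each paired nucleotide clonotype once (removes clonal-expansion
    weighting). For a bulk :class:`Repertoire`, usage is over unique clones
    (V for ``TRBV``, J for ``TRBJ``). Fractions sum to 1 over observed
    genes; missing or empty calls are skipped.
    """
    counts: Counter[str] = Counter()
    if isinstance(records, Repertoire):
        field = {"TRBV": "v_call", "TRBJ": "j_call"}.get(segment)
        if field is None:
            raise ValueError(f"segment {segment!r} unavailable for bulk data")
        for clone in records.clones:
            gene = normalize_gene(getattr(clone, field))
            if gene:
                counts[gene] += 1
    else:
        try:
            chain_slot, field = _SEGMENT_FIELD[segment]
        except KeyError as exc:
            raise ValueError(f"unknown segment {segment!r}") from exc
        if per_clonotype:
            from .clonotypes import build_clonotypes

            clonotypes = build_clonotypes(records)
            by_id = {c.cell_id: c for c in records}
            records = [by_id[members[0]] for members in clonotypes.values()]
        for cell in records:
            chain = getattr(cell, chain_slot)
            if chain is None:
                continue
            gene = normalize_gene(getattr(chain, field))
            if gene:
                counts[gene] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no {segment} calls present in input")
    return {g: c / total for g, c in sorted(counts.items())}
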