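"""Readers and writers for single-cell paired TCR tables and bulk repertoires.

Two dialects each:

* single cells — ``airr`` (AIRR Rearrangement TSV, one row per chain, standard
  column names ``cell_id, locus, v_call, d_call, j_call, junction,
  junction_aa, productive`` plus the study metadata columns) and
  ``study_tsv`` (one row per cell with ``alpha_*`` / ``beta_*`` column pairs);
* bulk repertoires — ``airr`` and ``immunoseq`` (tab-separated vendor export
  with a configurable column-name mapping).

All outputs are UTF-8 TSV with a mandatory header row. Reading never
silently drops a cell: every rejected record is logged, so
``len(input cell ids) == len(records) + len(logged rejects)``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AmbiguityError, EmptyRepertoireError, FormatError, MaitRepError
from .genes import normalize_gene
from .models import (
    BulkClone,
    CellRecord,
    ChainRecord,
    Repertoire,
    cell_violations,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_single_cell_table",
    "read_bulk_repertoire",
    "write_cell_table",
    "write_repertoire",
    "write_table",
    "IMMUNOSEQ_DEFAULT_COLUMNS",
]

_AIRR_CHAIN_COLS = ["cell_id", "locus", "v_call", "d_call", "j_call",
                    "junction", "junction_aa", "productive"]
_META_COLS = ["donor_id", "cohort", "tissue", "inflammation"]
_STUDY_COLS = ["cell_id"] + _META_COLS + [
    "alpha_v_call", "alpha_j_call", "alpha_cdr3_nt", "alpha_cdr3_aa",
    "alpha_productive",
    "beta_v_call", "beta_d_call", "beta_j_call", "beta_cdr3_nt",
    "beta_cdr3_aa", "beta_productive",
]

#: Default column mapping for immunoSEQ-style exports (override per file).
IMMUNOSEQ_DEFAULT_COLUMNS: dict[str, str] = {
    "cdr3_aa": "amino_acid",
    "v_call": "v_gene",
    "j_call": "j_gene",
    "count": "templates",
}

_TRUE = {"t", "true", "1", "yes", "y"}
_FALSE = {"f", "false", "0", "no", "n", ""}


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


def _fmt_bool(value: bool) -> str:
    return "T" if value else "F"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file does not exist: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def _norm_call(raw: str, cell_id: str, which: str) -> tuple[str, bool]:
    """Normalize a gene call; an unparseable non-empty call is kept verbatim
    but flags the chain nonproductive (spec for upstream aligner failures)."""
    if not raw.strip():
        return "", True
    norm = normalize_gene(raw)
    if norm is None:
        logger.warning(
            "cell %s: unparseable %s gene call %r; chain marked nonproductive",
            cell_id, which, raw,
        )
        return raw.strip(), False
    return norm, True


def _build_chain(
    locus: str,
    cell_id: str,
    v_call: str,
    d_call: str,
    j_call: str,
    cdr3_nt: str,
    cdr3_aa: str,
    productive: bool,
) -> ChainRecord:
    v_norm, v_ok = _norm_call(v_call, cell_id, f"{locus} V")
    j_norm, j_ok = _norm_call(j_call, cell_id, f"{locus} J")
    d_norm = ""
    d_ok = True
    if d_call.strip():
        d_norm, d_ok = _norm_call(d_call, cell_id, f"{locus} D")
    chain = ChainRecord(
        locus=locus,
        v_call=v_norm,
        d_call=d_norm,
        j_call=j_norm,
        cdr3_nt=cdr3_nt.strip().upper(),
        cdr3_aa=cdr3_aa.strip(),
        productive=productive and v_ok and j_ok and d_ok,
    )
    return chain


def _check_meta(row: Mapping[str, str], path: Path) -> dict[str, str]:
    meta = {k: str(row[k]).strip() for k in _META_COLS}
    cell = CellRecord(  # validation only; raises MaitRepError on bad enums
        cell_id="_probe", donor_id=meta["donor_id"], cohort=meta["cohort"],
        tissue=meta["tissue"], inflammation=meta["inflammation"],
    )
    del cell
    return meta


def read_single_cell_table(
    path: str | Path, dialect: str = "airr"
) -> list[CellRecord]:
    """Read a single-cell paired TCR table into :class:`CellRecord` objects.

    Parameters
    ----------
    path
        TSV file in the requested dialect.
    dialect
        ``"airr"`` — one row per chain with standard AIRR Rearrangement
        columns plus donor/cohort/tissue/inflammation metadata columns;
        ``"study_tsv"`` — one row per cell with alpha/beta column pairs.

    Notes
    -----
    * Exactly duplicated chain rows are deduplicated.
    * Two *differing productive* chains on the same locus of one cell mark
      the cell a doublet: it is dropped with a logged warning (single-cell
      Sanger cannot phase two alpha chains).
    * Any other conflicting duplicate raises :class:`AmbiguityError`.
    * Invariant violations (e.g. a TRA chain with a D call) are logged; the
      record is still returned.
    """
    path = Path(path)
    df = _read_tsv(path)
    if dialect == "airr":
        return _read_cells_airr(df, path)
    if dialect == "study_tsv":
        return _read_cells_study(df, path)
    raise FormatError(f"unknown single-cell dialect {dialect!r}")


def _read_cells_airr(df: pd.DataFrame, path: Path) -> list[CellRecord]:
    _require_columns(df, _AIRR_CHAIN_COLS + _META_COLS, path)
    if "d_call" not in df.columns:
        df["d_call"] = ""
    records: list[CellRecord] = []
    df = df.drop_duplicates()  # byte-identical rows collapse
    doublets: list[str] = []
    conflicts: list[str] = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        chains: dict[str, ChainRecord] = {}
        meta = _check_meta(group.iloc[0], path)
        is_doublet = False
        for locus, locus_rows in group.groupby("locus"):
            built = []
            for _, row in locus_rows.iterrows():
                locus_name = str(row["locus"]).strip().upper()
                if locus_name not in ("TRA", "TRB"):
                    raise FormatError(
                        f"{path}: cell {cell_id}: unknown locus {row['locus']!r}"
                    )
                built.append(
                    _build_chain(
                        locus_name, str(cell_id),
                        row["v_call"], row.get("d_call", ""), row["j_call"],
                        row["junction"], row["junction_aa"],
                        _parse_bool(row["productive"]),
                    )
                )
            uniq = list(dict.fromkeys(built))
            if len(uniq) > 1:
                if all(c.productive for c in uniq):
                    is_doublet = True
                else:
                    conflicts.append(str(cell_id))
                continue
            chains[uniq[0].locus] = uniq[0]
        if conflicts and conflicts[-1] == str(cell_id):
            continue
        if is_doublet:
            doublets.append(str(cell_id))
            logger.warning(
                "cell %s: two differing productive chains on one locus; "
                "rejected as doublet", cell_id,
            )
            continue
        cell = CellRecord(
            cell_id=str(cell_id), alpha=chains.get("TRA"),
            beta=chains.get("TRB"), **meta,
        )
        _log_violations(cell)
        records.append(cell)
    if conflicts:
        raise AmbiguityError(
            f"{path}: duplicate (cell_id, locus) rows with conflicting "
            f"content for cell(s): {', '.join(sorted(set(conflicts)))}"
        )
    return records


def _read_cells_study(df: pd.DataFrame, path: Path) -> list[CellRecord]:
    _require_columns(df, _STUDY_COLS, path)
    dup = df["cell_id"][df["cell_id"].duplicated()].tolist()
    if dup:
        raise AmbiguityError(
            f"{path}: duplicate cell_id rows: {', '.join(sorted(set(dup)))}"
        )
    records: list[CellRecord] = []
    for _, row in df.iterrows():
        meta = _check_meta(row, path)
        cell_id = str(row["cell_id"]).strip()
        alpha = beta = None
        if row["alpha_v_call"].strip() or row["alpha_cdr3_nt"].strip():
            alpha = _build_chain(
                "TRA", cell_id, row["alpha_v_call"], "", row["alpha_j_call"],
                row["alpha_cdr3_nt"], row["alpha_cdr3_aa"],
                _parse_bool(row["alpha_productive"]),
            )
        if row["beta_v_call"].strip() or row["beta_cdr3_nt"].strip():
            beta = _build_chain(
                "TRB", cell_id, row["beta_v_call"], row["beta_d_call"],
                row["beta_j_call"], row["beta_cdr3_nt"], row["beta_cdr3_aa"],
                _parse_bool(row["beta_productive"]),
            )
        cell = CellRecord(cell_id=cell_id, alpha=alpha, beta=beta, **meta)
        _log_violations(cell)
        records.append(cell)
    return records


def _log_violations(cell: CellRecord) -> None:
    for problem in cell_violations(cell):
        logger.warning("cell %s: invariant violation: %s", cell.cell_id, problem)


def read_bulk_repertoire(
    path: str | Path,
    dialect: str = "airr",
    donor_id: str | None = None,
    cohort: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Repertoire:
    """Read a bulk β-chain repertoire table.

    Rows sharing a normalized (cdr3_aa, v_call, j_call) key are merged with
    counts summed; nonproductive rows (stop ``*`` or frameshift ``_`` in the
    CDR3) are excluded and their number logged. Donor and cohort come from
    ``donor_id``/``cohort`` columns when present, else from the keyword
    arguments.

    Raises
    ------
    FormatError
        For a missing column or a non-positive count.
    EmptyRepertoireError
        When no productive clone survives filtering.
    """
    path = Path(path)
    df = _read_tsv(path)
    if dialect == "airr":
        cols = {"cdr3_aa": "junction_aa", "v_call": "v_call",
                "j_call": "j_call", "count": "duplicate_count"}
    elif dialect == "immunoseq":
        cols = dict(IMMUNOSEQ_DEFAULT_COLUMNS)
        if column_map:
            cols.update(column_map)
    else:
        raise FormatError(f"unknown bulk dialect {dialect!r}")
    _require_columns(df, [cols["cdr3_aa"], cols["count"]], path)

    donor = donor_id
    if donor is None and "donor_id" in df.columns and len(df):
        donor = str(df["donor_id"].iloc[0])
    coh = cohort
    if coh is None and "cohort" in df.columns and len(df):
        coh = str(df["cohort"].iloc[0])
    if donor is None or coh is None:
        raise FormatError(
            f"{path}: donor_id/cohort not present in file and not supplied"
        )

    merged: dict[tuple[str, str, str], int] = {}
    n_nonproductive = 0
    for _, row in df.iterrows():
        aa = str(row[cols["cdr3_aa"]]).strip()
        if not aa:
            continue
        if "*" in aa or "_" in aa:
            n_nonproductive += 1
            continue
        raw_count = str(row[cols["count"]]).strip()
        try:
            count = int(float(raw_count))
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable count {raw_count!r}") from exc
        if count <= 0:
            raise FormatError(f"{path}: non-positive count {count} for {aa!r}")
        v = normalize_gene(str(row.get(cols["v_call"], "") or "")) or ""
        j = normalize_gene(str(row.get(cols["j_call"], "") or "")) or ""
        merged[(aa, v, j)] = merged.get((aa, v, j), 0) + count
    if n_nonproductive:
        logger.info(
            "%s: excluded %d nonproductive row(s)", path, n_nonproductive
        )
    if not merged:
        raise EmptyRepertoireError(f"{path}: no productive clones after filtering")
    clones = [
        BulkClone(cdr3_aa=k[0], v_call=k[1], j_call=k[2], count=n)
        for k, n in sorted(merged.items())
    ]
    return Repertoire(donor_id=donor, cohort=coh, clones=clones, tissue="blood")


# ---------------------------------------------------------------------------
# writers


def write_cell_table(
    cells: Sequence[CellRecord],
    path: str | Path,
    dialect: str = "airr",
    force: bool = False,
) -> None:
    """Write cells in the requested dialect; round-trips with the reader."""
    if not cells and not force:
        raise MaitRepError("refusing to write an empty cell table without force")
    path = Path(path)
    rows: list[dict[str, str]] = []
    if dialect == "airr":
        for cell in cells:
            for chain in (cell.alpha, cell.beta):
                if chain is None:
                    continue
                rows.append({
                    "cell_id": cell.cell_id,
                    "locus": chain.locus,
                    "v_call": chain.v_call,
                    "d_call": chain.d_call,
                    "j_call": chain.j_call,
                    "junction": chain.cdr3_nt,
                    "junction_aa": chain.cdr3_aa,
                    "productive": _fmt_bool(chain.productive),
                    "donor_id": cell.donor_id,
                    "cohort": cell.cohort,
                    "tissue": cell.tissue,
                    "inflammation": cell.inflammation,
                })
        columns = _AIRR_CHAIN_COLS + _META_COLS
    elif dialect == "study_tsv":
        for cell in cells:
            a, b = cell.alpha, cell.beta
            rows.append({
                "cell_id": cell.cell_id,
                "donor_id": cell.donor_id,
                "cohort": cell.cohort,
                "tissue": cell.tissue,
                "inflammation": cell.inflammation,
                "alpha_v_call": a.v_call if a else "",
                "alpha_j_call": a.j_call if a else "",
                "alpha_cdr3_nt": a.cdr3_nt if a else "",
                "alpha_cdr3_aa": a.cdr3_aa if a else "",
                "alpha_productive": _fmt_bool(a.productive) if a else "",
                "beta_v_call": b.v_call if b else "",
                "beta_d_call": b.d_call if b else "",
                "beta_j_call": b.j_call if b else "",
                "beta_cdr3_nt": b.cdr3_nt if b else "",
                "beta_cdr3_aa": b.cdr3_aa if b else "",
                "beta_productive": _fmt_bool(b.productive) if b else "",
            })
        columns = _STUDY_COLS
    else:
        raise FormatError(f"unknown single-cell dialect {dialect!r}")
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def write_repertoire(
    rep: Repertoire,
    path: str | Path,
    dialect: str = "airr",
    force: bool = False,
) -> None:
    """Write a bulk repertoire; round-trips with :func:`read_bulk_repertoire`."""
    if not rep.clones and not force:
        raise MaitRepError("refusing to write an empty repertoire without force")
    path = Path(path)
    rows = []
    if dialect == "airr":
        for clone in rep.clones:
            rows.append({
                "junction_aa": clone.cdr3_aa,
                "v_call": clone.v_call,
                "j_call": clone.j_call,
                "duplicate_count": clone.count,
                "locus": "TRB",
                "productive": "T",
                "donor_id": rep.donor_id,
                "cohort": rep.cohort,
            })
    elif dialect == "immunoseq":
        for clone in rep.clones:
            rows.append({
                "amino_acid": clone.cdr3_aa,
                "v_gene": clone.v_call,
                "j_gene": clone.j_call,
                "templates": clone.count,
                "donor_id": rep.donor_id,
                "cohort": rep.cohort,
            })
    else:
        raise FormatError(f"unknown bulk dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_table(
    records: Sequence[CellRecord] | Repertoire | Iterable[Repertoire],
    path: str | Path,
    dialect: str = "airr",
    force: bool = False,
) -> None:
    """Dispatching writer: cell collections or repertoires to TSV."""
    if isinstance(records, Repertoire):
        write_repertoire(records, path, dialect=dialect, force=force)
        return
    records = list(records)  # type: ignore[arg-type]
    if records and isinstance(records[0], CellRecord):
        write_cell_table(records, path, dialect=dialect, force=force)  # type: ignore[arg-type]
        return
    if not records:
        if force:
            write_cell_table([], path, dialect=dialect, force=True)
            return
        raise MaitRepError("refusing to write an empty collection without force")
    raise MaitRepError(f"cannot write records of type {type(records[0]).__name__}")
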