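"""IMGT-style TCR gene-name normalization.

Gene calls arrive in several spellings: IMGT ("TRAV1-2*01"), lower case,
zero-padded Adaptive/immunoSEQ style ("TCRBV06-04*01"). Downstream clonotype
matching and gene-usage tables work at the gene level only, so allele
suffixes are stripped and numeric fields lose their zero padding. The
normal form is idempotent: ``normalize_gene(normalize_gene(x)) ==
normalize_gene(x)``.
"""

from __future__ import annotations

import re

__all__ = ["normalize_gene", "is_trav1_2", "CANONICAL_TRAJ"]

#: TRAJ genes that complete a canonical MAIT (semi-invariant) alpha chain.
CANONICAL_TRAJ = frozenset({"TRAJ12", "TRAJ20", "TRAJ33"})

# family number, optional gene number, optional /DV cross-reference
# (e.g. TRAV14/DV4), optional allele suffix.
_GENE_RE = re.compile(
    r"^(TR[ABGD])([VDJ])(\d+)(?:-(\d+))?(?:/DV(\d+))?(?:\*\d+)?$"
)


def normalize_gene(name: str | None) -> str | None:
    """Return the gene-level IMGT normal form of a TCR gene call.

    Uppercases, maps the Adaptive "TCRBV06-04*01" spelling onto IMGT
    "TRBV6-4", strips allele suffixes and zero padding. Returns ``None``
    for empty input or a call that cannot be parsed as a TR gene name.
    """
    if name is None:
        return None
    s = name.strip().upper().replace(" ", "")
    if not s:
        return None
    if s.startswith("TCR"):
        s = "TR" + s[3:]
    m = _GENE_RE.match(s)
    if m is None:
        return None
    locus, segment, family, gene, dv = m.groups()
    out = f"{locus}{segment}{int(family)}"
    if gene is not None:
        out += f"-{int(gene)}"
    if dv is not None:
        out += f"/DV{int(dv)}"
    return out


def is_trav1_2(v_call: str | None) -> bool:
    """True iff the call names the MAIT-defining TRAV1-2 segment.

    TRAV1-1 is a distinct gene and is rejected.
    """
    return normalize_gene(v_call) == "TRAV1-2"
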