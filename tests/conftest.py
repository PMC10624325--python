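from __future__ import annotations

import pytest

from maitrep import SimConfig, simulate_cohort, worked_example_cohort


@pytest.fixture(scope="session")
def worked_example():
    """Tiny hand-computable cohort: (cells, blood, expected values)."""
    return worked_example_cohort()


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at study-scale defaults, shared across tests."""
    return simulate_cohort(SimConfig(seed=11))


def make_chain(locus="TRA", v="TRAV1-2", j="TRAJ33", aa="CAVMDSNYQLIW",
               productive=True, d=""):
    """Chain with a nucleotide junction consistent with its translation."""
    from maitrep.models import ChainRecord

    codon = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
        "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
        "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
        "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
        "*": "TAA",
    }
    nt = "".join(codon[c] for c in aa)
    return ChainRecord(locus=locus, v_call=v, j_call=j, d_call=d,
                       cdr3_nt=nt, cdr3_aa=aa, productive=productive)


def make_cell(cell_id, alpha=None, beta=None, donor="HC01", cohort="HC",
              tissue="colon", inflammation="uninflamed"):
    from maitrep.models import CellRecord

    return CellRecord(cell_id=cell_id, donor_id=donor, cohort=cohort,
                      tissue=tissue, inflammation=inflammation,
                      alpha=alpha, beta=beta)
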