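"""Clonotype identity, sharing edges, colon-blood overlap, publicity."""

from __future__ import annotations

import logging

import pytest

from maitrep import (
    BulkClone,
    Repertoire,
    SimConfig,
    build_clonotypes,
    canonical_cells,
    colon_blood_overlap,
    public_partition,
    round_pct,
    sharing_edges,
    simulate_cohort,
)

from conftest import make_cell, make_chain


def paired_cell(cid, beta_aa, donor="HC01", cohort="HC",
                inflammation="uninflamed", alpha_aa="CAVMDSNYQLIW"):
    return make_cell(
        cid,
        alpha=make_chain(aa=alpha_aa),
        beta=make_chain(locus="TRB", v="TRBV6-4", j="TRBJ2-1", aa=beta_aa,
                        d="TRBD1"),
        donor=donor, cohort=cohort, inflammation=inflammation,
    )


class TestBuildClonotypes:
    def test_identical_chains_one_clonotype(self):
        cells = [paired_cell("a", "CASSLAPGF"), paired_cell("b", "CASSLAPGF")]
        cmap = build_clonotypes(cells)
        assert len(cmap) == 1
        assert list(cmap.values()) == [["a", "b"]]

    def test_nucleotide_level_distinction(self):
        """Same amino acids, different codons: two clonotypes."""
        c1 = paired_cell("a", "CASSLAPGF")
        beta2 = make_chain(locus="TRB", v="TRBV6-4", j="TRBJ2-1",
                           aa="CASSLAPGF", d="TRBD1")
        # synonymous change: TCT -> AGT for the first serine
        nt = beta2.cdr3_nt.replace("TCT", "AGT", 1)
        from dataclasses import replace

        c2 = make_cell("b", alpha=c1.alpha, beta=replace(beta2, cdr3_nt=nt))
        cmap = build_clonotypes([c1, c2])
        assert len(cmap) == 2

    def test_sizes(self):
        cells = [paired_cell("a", "CASSLAPGF"), paired_cell("b", "CASSLAPGF"),
                 paired_cell("c", "CASSQETQF")]
        sizes = sorted(len(v) for v in build_clonotypes(cells).values())
        assert sizes == [1, 2]

    def test_ambiguous_nt_excluded_and_logged(self, caplog):
        cell = paired_cell("a", "CASSLAPGF")
        from dataclasses import replace

        bad = make_cell("b", alpha=cell.alpha,
                        beta=replace(cell.beta,
                                     cdr3_nt="N" + cell.beta.cdr3_nt[1:]))
        with caplog.at_level(logging.WARNING):
            cmap = build_clonotypes([cell, bad])
        assert sum(len(v) for v in cmap.values()) == 1
        assert any("'N'" in r.message for r in caplog.records)


class TestSharingEdges:
    def test_pair_counts(self):
        cells = [paired_cell(c, "CASSLAPGF") for c in "abc"]
        edges = sharing_edges(build_clonotypes(cells), cells)
        assert len(edges) == 3  # C(3,2)

    def test_singleton_no_edges(self):
        cells = [paired_cell("a", "CASSLAPGF")]
        assert sharing_edges(build_clonotypes(cells), cells) == []

    @pytest.mark.parametrize(
        "cohort,states,expected",
        [
            ("HC", ("uninflamed", "uninflamed"), "within_HC_biopsy"),
            ("CD", ("inflamed", "inflamed"), "within_CD_inflamed"),
            ("CD", ("uninflamed", "uninflamed"), "within_CD_uninflamed"),
            ("CD", ("inflamed", "uninflamed"), "CD_cross_inflammation"),
        ],
    )
    def test_edge_classes(self, cohort, states, expected):
        cells = [
            paired_cell("a", "CASSLAPGF", donor="D1", cohort=cohort,
                        inflammation=states[0]),
            paired_cell("b", "CASSLAPGF", donor="D1", cohort=cohort,
                        inflammation=states[1]),
        ]
        edges = sharing_edges(build_clonotypes(cells), cells)
        assert [e.edge_class for e in edges] == [expected]

    def test_cross_donor_needs_flag(self):
        cells = [paired_cell("a", "CASSLAPGF", donor="D1"),
                 paired_cell("b", "CASSLAPGF", donor="D2")]
        cmap = build_clonotypes(cells)
        assert sharing_edges(cmap, cells) == []
        flagged = sharing_edges(cmap, cells, include_cross_donor=True)
        assert [e.edge_class for e in flagged] == ["cross_donor_public"]


def blood(donor, cohort, counts):
    return Repertoire(
        donor_id=donor, cohort=cohort,
        clones=[BulkClone(aa, n) for aa, n in sorted(counts.items())],
    )


class TestColonBloodOverlap:
    def test_category_semantics(self):
        """A sequence in autologous AND allogeneic blood increments
        in_both, autologous and allogeneic each once."""
        cells = [paired_cell("a", "CASSLAPGF", donor="HC01")]
        reps = [blood("HC01", "HC", {"CASSLAPGF": 2}),
                blood("CD01", "CD", {"CASSLAPGF": 1})]
        row = colon_blood_overlap(cells, reps)[0]  # HC stratum
        assert (row.total_colon_unique, row.in_both, row.autologous,
                row.allogeneic) == (1, 1, 1, 1)

    def test_zero_sharing_cohort_all_zero(self):
        cfg = SimConfig(seed=3, colon_blood_autologous_rate=0.0,
                        colon_blood_allogeneic_rate=0.0)
        cells, reps, _ = simulate_cohort(cfg)
        for row in colon_blood_overlap(canonical_cells(cells), reps):
            assert row.in_both == row.autologous == row.allogeneic == 0

    def test_cd_all_deduplicates_nc_ic(self):
        """A sequence in both biopsies of one CD donor counts once in CD all."""
        cells = [
            paired_cell("a", "CASSLAPGF", donor="CD01", cohort="CD",
                        inflammation="uninflamed"),
            paired_cell("b", "CASSLAPGF", donor="CD01", cohort="CD",
                        inflammation="inflamed"),
        ]
        rows = {r.stratum: r for r in colon_blood_overlap(cells, [])}
        assert rows["CD NC"].total_colon_unique == 1
        assert rows["CD IC"].total_colon_unique == 1
        assert rows["CD all"].total_colon_unique == 1

    def test_donor_without_blood_is_flagged(self, caplog):
        cells = [paired_cell("a", "CASSLAPGF", donor="HC09")]
        with caplog.at_level(logging.INFO):
            colon_blood_overlap(cells, [blood("HC01", "HC", {"CASSXF": 1})])
        assert any("HC09" in r.message for r in caplog.records)

    def test_invariants_on_simulated_cohorts(self):
        """OverlapTable invariants hold for every stratum over seeds."""
        for seed in (0, 1, 2):
            cells, reps, _ = simulate_cohort(SimConfig(seed=seed))
            for r in colon_blood_overlap(canonical_cells(cells), reps):
                assert max(r.autologous, r.allogeneic) <= r.in_both
                assert r.in_both <= r.autologous + r.allogeneic <= 2 * r.in_both
                assert r.in_both <= r.total_colon_unique
                for count, pct in [(r.in_both, r.pct_both),
                                   (r.autologous, r.pct_autologous),
                                   (r.allogeneic, r.pct_allogeneic)]:
                    assert pct == round_pct(count, r.total_colon_unique)

    def test_ground_truth_recovery_exact(self, default_cohort):
        cells, reps, truth = default_cohort
        rows = {r.stratum: r for r in
                colon_blood_overlap(canonical_cells(cells), reps)}
        total = rows["total"]
        auto, allo = truth.autologous_seqs(), truth.allogeneic_seqs()
        assert total.autologous == len(auto)
        assert total.allogeneic == len(allo)
        assert total.in_both == len(auto | allo)

    def test_donor_relabeling_permutes_without_changing_counts(
        self, default_cohort
    ):
        cells, reps, _ = default_cohort
        mapping = {}
        for d in sorted({c.donor_id for c in cells} | {r.donor_id for r in reps}):
            mapping[d] = "X" + d[::-1]
        relabeled_cells = [c.with_donor(mapping[c.donor_id])
                           for c in canonical_cells(cells)]
        relabeled_reps = [
            Repertoire(donor_id=mapping[r.donor_id], cohort=r.cohort,
                       clones=r.clones, tissue=r.tissue)
            for r in reps
        ]
        before = colon_blood_overlap(canonical_cells(cells), reps)
        after = colon_blood_overlap(relabeled_cells, relabeled_reps)
        for a, b in zip(before, after):
            assert (a.total_colon_unique, a.in_both, a.autologous,
                    a.allogeneic) == (b.total_colon_unique, b.in_both,
                                      b.autologous, b.allogeneic)


class TestPublicPartition:
    def test_classes(self):
        reps = [
            blood("CD01", "CD", {"P1": 1, "P3": 1}),
            blood("CD02", "CD", {"P1": 2, "P2": 1}),
            blood("HC01", "HC", {"P2": 1, "Q1": 5}),
            blood("HC02", "HC", {"ONLYME": 1}),
        ]
        part = public_partition(reps)
        assert part.classes == {"P1": "cd_only", "P2": "shared"}
        assert part.n_public == 2
        assert part.n_cd_only + part.n_hc_only + part.n_shared == part.n_public

    def test_singleton_not_public(self):
        reps = [blood("HC01", "HC", {"A": 1}), blood("HC02", "HC", {"B": 1})]
        assert public_partition(reps).n_public == 0

    def test_requires_two_donors(self):
        with pytest.raises(ValueError):
            public_partition([blood("HC01", "HC", {"A": 1})])

    def test_ground_truth_recovery_exact(self, default_cohort):
        _, reps, truth = default_cohort
        part = public_partition(reps)
        expected = truth.expected_public()
        assert set(part.carriers) == set().union(*expected.values())
        assert part.n_cd_only == len(expected["cd_only"])
        assert part.n_hc_only == len(expected["hc_only"])
        assert part.n_shared == len(expected["shared"])

    def test_partition_sums_exactly(self, default_cohort):
        """The three carrier-cohort classes always partition the public set."""
        _, reps, _ = default_cohort
        part = public_partition(reps)
        assert part.n_cd_only + part.n_hc_only + part.n_shared == part.n_public


class TestRoundPct:
    @pytest.mark.parametrize("num,den,expected", [
        (37, 87, 43),
        (16, 78, 21),
        (7, 59, 12),
        (0, 10, 0),
        (5, 5, 100),
        (1, 8, 13),    # 12.5 rounds up (away from zero), not to even 12
        (3, 200, 2),   # 1.5 likewise
    ])
    def test_half_away_from_zero(self, num, den, expected):
        assert round_pct(num, den) == expected
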