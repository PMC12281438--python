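"""Clonotype calling, expansion classes, coverage and Venn sharing."""

import itertools

import pandas as pd
import pytest

from ibrd import tcr


def contig(barcode, chain, cdr3, umis=5, productive=True, biopsy="b1"):
    return dict(
        barcode=barcode, biopsy=biopsy, chain=chain, cdr3_nt=cdr3,
        umis=umis, productive=productive,
    )


class TestCallClonotypes:
    def test_unpaired_cell_dropped(self):
        contigs = pd.DataFrame([contig("c1", "TRA", "ACGT" * 8)])
        assert tcr.call_clonotypes(contigs).empty

    def test_identical_pairs_share_clonotype(self):
        a, b = "ACGT" * 8, "TGCA" * 8
        contigs = pd.DataFrame(
            [contig(c, ch, s) for c in ("c1", "c2") for ch, s in (("TRA", a), ("TRB", b))]
        )
        out = tcr.call_clonotypes(contigs)
        assert out["clonotype_id"].nunique() == 1
        assert (out["clone_size"] == 2).all()

    def test_extra_chain_resolved_by_umis(self):
        contigs = pd.DataFrame(
            [
                contig("c1", "TRA", "AAAA" * 8),
                contig("c1", "TRB", "CCCC" * 8, umis=7),
                contig("c1", "TRB", "GGGG" * 8, umis=3),
            ]
        )
        out = tcr.call_clonotypes(contigs)
        assert out["cdr3b_nt"].iloc[0] == "CCCC" * 8

    def test_umi_tie_breaks_lexicographically(self):
        contigs = pd.DataFrame(
            [
                contig("c1", "TRA", "TTTT" * 8, umis=4),
                contig("c1", "TRA", "AAAA" * 8, umis=4),
                contig("c1", "TRB", "CCCC" * 8),
            ]
        )
        assert tcr.call_clonotypes(contigs)["cdr3a_nt"].iloc[0] == "AAAA" * 8

    def test_duplicate_rows_collapsed_with_summed_umis(self):
        contigs = pd.DataFrame(
            [
                contig("c1", "TRA", "AAAA" * 8, umis=2),
                contig("c1", "TRA", "AAAA" * 8, umis=2),
                contig("c1", "TRA", "GGGG" * 8, umis=3),
                contig("c1", "TRB", "CCCC" * 8),
            ]
        )
        out = tcr.call_clonotypes(contigs)
        assert out["cdr3a_nt"].iloc[0] == "AAAA" * 8  # 2+2 beats 3

    def test_idempotent_on_own_projection(self, small_fixture):
        first = tcr.call_clonotypes(small_fixture.contigs)
        rows = []
        for _, r in first.iterrows():
            rows.append(contig(r["cell_id"], "TRA", r["cdr3a_nt"]))
            rows.append(contig(r["cell_id"], "TRB", r["cdr3b_nt"]))
        second = tcr.call_clonotypes(pd.DataFrame(rows))
        merged = first.merge(second, on="cell_id", suffixes=("_1", "_2"))
        assert (merged["clonotype_id_1"] == merged["clonotype_id_2"]).all()

    def test_clone_sizes_sum_to_cells(self, small_fixture):
        out = tcr.call_clonotypes(small_fixture.contigs)
        sizes = out.drop_duplicates("clonotype_id")["clone_size"]
        assert sizes.sum() == len(out)


class TestExpansion:
    def test_all_unique_no_expansion(self):
        table = pd.DataFrame(
            {
                "cell_id": ["c1", "c2"],
                "clonotype_id": ["ct1", "ct2"],
                "clone_size": [1, 1],
            }
        )
        summary = tcr.expansion_summary(table)
        assert (summary["n_cells"] == 0).all()

    def test_strict_inequality_at_thresholds(self):
        table = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(6)],
                "clonotype_id": ["ct"] * 6,
                "clone_size": [6] * 6,
            }
        )
        summary = tcr.expansion_summary(table).set_index("threshold")
        assert summary.loc[1, "n_cells"] == 6
        assert summary.loc[5, "n_cells"] == 6
        assert summary.loc[10, "n_cells"] == 0

    def test_matches_brute_force_and_monotone(self, small_fixture):
        out = tcr.call_clonotypes(small_fixture.contigs)
        summary = tcr.expansion_summary(out).set_index("threshold")
        for t in (1, 5, 10, 20):
            by_ct = out.groupby("clonotype_id").size()
            assert summary.loc[t, "n_cells"] == int(by_ct[by_ct > t].sum())
            assert summary.loc[t, "n_clonotypes"] == int((by_ct > t).sum())
        assert (summary["n_cells"].diff().dropna() <= 0).all()


class TestCoverage:
    def test_full_and_empty_coverage(self):
        cells = pd.DataFrame(
            {"cell_id": ["c1", "c2"], "biopsy_id": "b1", "cluster": ["x", "y"]}
        )
        full = pd.DataFrame({"cell_id": ["c1", "c2"], "clonotype_id": "ct", "clone_size": 2})
        assert (tcr.coverage_per_cluster(cells, full) == 100.0).all()
        none = full.iloc[:0]
        assert (tcr.coverage_per_cluster(cells, none) == 0.0).all()

    def test_matches_brute_force_join(self, small_fixture):
        out = tcr.call_clonotypes(small_fixture.contigs)
        cov = tcr.coverage_per_cluster(small_fixture.cells, out)
        with_tcr = set(out["cell_id"])
        for cluster in small_fixture.cells["cluster"].unique():
            sub = small_fixture.cells[small_fixture.cells["cluster"] == cluster]
            expected = 100.0 * sub["cell_id"].isin(with_tcr).mean()
            assert cov[cluster] == pytest.approx(expected)


class TestSharing:
    @staticmethod
    def _table(assignments):
        """assignments: {group: [clonotype sequences per cell]}"""
        rows, part = [], {}
        i = 0
        for group, seqs in assignments.items():
            for seq in seqs:
                cell = f"c{i}"
                rows.append(dict(cell_id=cell, clonotype_id=seq, clone_size=0))
                part[cell] = group
                i += 1
        table = pd.DataFrame(rows)
        sizes = table.groupby("clonotype_id")["cell_id"].transform("size")
        table["clone_size"] = sizes
        return table, pd.Series(part)

    def test_identity_partition_full_overlap(self):
        table, part = self._table({"g1": ["A", "A"], "g2": ["A", "A"]})
        venn = tcr.shared_clonotypes(table, part)
        assert venn[frozenset({"g1", "g2"})] == 1
        assert venn[frozenset({"g1"})] == 0

    def test_disjoint_sequences_no_overlap(self):
        table, part = self._table({"g1": ["A", "A"], "g2": ["B", "B"]})
        venn = tcr.shared_clonotypes(table, part)
        assert venn[frozenset({"g1", "g2"})] == 0

    def test_three_group_hand_venn(self):
        # expanded clonotypes: A in all, B in g1+g2, C in g1, D in g2, E in g3
        table, part = self._table(
            {
                "g1": ["A", "A", "B", "C", "C"],
                "g2": ["A", "B", "D", "D"],
                "g3": ["A", "E", "E"],
            }
        )
        venn = tcr.shared_clonotypes(table, part)
        assert venn[frozenset({"g1", "g2", "g3"})] == 1  # A
        assert venn[frozenset({"g1", "g2"})] == 1  # B
        assert venn[frozenset({"g1"})] == 1  # C
        assert venn[frozenset({"g2"})] == 1  # D
        assert venn[frozenset({"g3"})] == 1  # E
        assert venn[frozenset({"g1", "g3"})] == 0
        assert venn[frozenset({"g2", "g3"})] == 0

    def test_venn_matches_enumeration(self, small_fixture):
        out = tcr.call_clonotypes(small_fixture.contigs)
        part = small_fixture.cells.set_index("cell_id")["biopsy_id"].map(
            small_fixture.metadata.set_index("biopsy_id")["activity"]
        )
        venn = tcr.shared_clonotypes(out, part, min_size=2)
        expanded = out[out["clone_size"] >= 2]
        labels = expanded["cell_id"].map(part)
        groups = sorted(part.unique())
        member = {
            g: set(expanded.loc[(labels == g).to_numpy(), "clonotype_id"])
            for g in groups
        }
        for r in range(1, len(groups) + 1):
            for subset in itertools.combinations(groups, r):
                exact = set.intersection(*(member[g] for g in subset))
                for g in groups:
                    if g not in subset:
                        exact -= member[g]
                assert venn[frozenset(subset)] == len(exact)

    def test_unlabeled_cell_errors(self):
        table, part = self._table({"g1": ["A", "A"]})
        with pytest.raises(ValueError, match="unlabeled"):
            tcr.shared_clonotypes(table, part.iloc[:1])
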