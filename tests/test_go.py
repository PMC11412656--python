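"""Gene linking, GO enrichment, term clustering and defining genes."""

import numpy as np
import pandas as pd
import pytest

from ctmwas.go import (
    GeneSet,
    GeneSetCollection,
    assign_defining_genes,
    cluster_terms,
    filter_significant_terms,
    go_term_enrichment,
    link_cpgs_to_genes,
    select_go_input,
)

from conftest import make_result_table


def _annotation(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def brute_force_links(cpgs, annotation, upstream):
    """Exhaustive O(n*m) oracle for the body-or-upstream linking rule."""
    out = {}
    for chrom, pos in cpgs:
        hits = []
        for g in annotation.itertuples(index=False):
            if str(g.chrom) != str(chrom):
                continue
            in_body = g.start <= pos <= g.end
            if g.strand == "+":
                in_up = max(1, g.start - upstream) <= pos <= g.start - 1
            else:
                in_up = g.end + 1 <= pos <= g.end + upstream
            if in_body or in_up:
                hits.append(g.gene_id)
        out[(str(chrom), int(pos))] = sorted(hits)
    return out


class TestLinking:
    def test_plus_strand_boundaries(self):
        ann = _annotation([("gA", "1", 15_000, 18_000, "+")])
        links = link_cpgs_to_genes(
            [("1", 14_999), ("1", 18_001), ("1", 5_000), ("1", 4_999), ("1", 15_000)],
            ann,
            upstream=10_000,
        )
        assert links[("1", 14_999)] == ["gA"]  # upstream window
        assert links[("1", 5_000)] == ["gA"]  # exactly 10 kb upstream
        assert links[("1", 4_999)] == []  # one bp beyond the window
        assert links[("1", 18_001)] == []  # downstream of the body
        assert links[("1", 15_000)] == ["gA"]  # body start

    def test_minus_strand_upstream_follows_tss_at_end(self):
        ann = _annotation([("gB", "1", 5_000, 8_000, "-")])
        links = link_cpgs_to_genes(
            [("1", 9_000), ("1", 18_000), ("1", 18_001), ("1", 4_999)], ann
        )
        assert links[("1", 9_000)] == ["gB"]
        assert links[("1", 18_000)] == ["gB"]  # exactly 10 kb past the TSS
        assert links[("1", 18_001)] == []
        assert links[("1", 4_999)] == []  # no upstream window on the start side

    def test_multi_gene_links_allowed(self):
        ann = _annotation(
            [("g1", "2", 100, 500, "+"), ("g2", "2", 300, 900, "-")]
        )
        links = link_cpgs_to_genes([("2", 400)], ann)
        assert links[("2", 400)] == ["g1", "g2"]

    def test_matches_brute_force_oracle_on_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_genes = int(rng.integers(1, 12))
            rows = []
            for gi in range(n_genes):
                start = int(rng.integers(1, 50_000))
                end = start + int(rng.integers(1, 5_000))
                rows.append(
                    (f"g{gi}", str(rng.integers(1, 3)), start, end,
                     "+" if rng.random() < 0.5 else "-")
                )
            ann = _annotation(rows)
            cpgs = [
                (str(rng.integers(1, 3)), int(rng.integers(1, 60_000)))
                for _ in range(25)
            ]
            upstream = int(rng.choice([0, 100, 10_000]))
            assert link_cpgs_to_genes(cpgs, ann, upstream) == brute_force_links(
                cpgs, ann, upstream
            )

    def test_malformed_annotation_rejected(self):
        with pytest.raises(ValueError):
            link_cpgs_to_genes([("1", 5)], _annotation([("g", "1", 10, 5, "+")]))
        with pytest.raises(ValueError):
            link_cpgs_to_genes([("1", 5)], _annotation([("g", "1", 5, 10, "*")]))


class TestSelectGoInput:
    def test_unit_replication_pvalues_give_empty_selection(self):
        primary = make_result_table([("1", 10, "bulk", 1e-9), ("1", 20, "bulk", 0.5)])
        replication = make_result_table([("1", 10, "bulk", 1.0), ("1", 20, "bulk", 1.0)])
        assert select_go_input(primary, replication) == set()

    def test_replication_copy_returns_suggestive_set(self):
        rows = [("1", 10 * i, "monocyte", 1e-9 if i < 4 else 0.3) for i in range(1, 30)]
        primary = make_result_table(rows)
        assert select_go_input(primary, primary.copy()) == {
            ("1", 10), ("1", 20), ("1", 30)
        }

    def test_same_unit_required_for_replication_support(self):
        primary = make_result_table([("1", 10, "monocyte", 1e-9)])
        replication = make_result_table(
            [("1", 10, "monocyte", 0.9), ("1", 10, "NK", 1e-4)]
        )
        assert select_go_input(primary, replication) == set()

    def test_presence_only_mode(self):
        primary = make_result_table([("1", 10, "monocyte", 1e-9)])
        replication = make_result_table([("1", 10, "monocyte", 0.9)])
        got = select_go_input(
            primary, replication, require_nominal_replication=False
        )
        assert got == {("1", 10)}


class TestTermEnrichment:
    def _setup(self):
        # 200 CpGs on one chromosome; genes tile the first half
        universe = [("1", 100 * i) for i in range(1, 201)]
        ann = _annotation(
            [(f"g{i}", "1", 100 * i - 50, 100 * i + 40, "+") for i in range(1, 101)]
        )
        return universe, ann

    def test_term_capturing_all_selected_genes_is_enriched(self):
        universe, ann = self._setup()
        selected = {("1", 100 * i) for i in range(1, 11)}
        target = GeneSet("T1", "target", "biological_process",
                         tuple(f"g{i}" for i in range(1, 11)))
        decoy = GeneSet("T2", "decoy", "biological_process",
                        tuple(f"g{i}" for i in range(60, 100)))
        table = go_term_enrichment(
            selected, universe, ann, GeneSetCollection([target, decoy]),
            n_permutations=1000, seed=0, upstream=0,
        )
        row = table.set_index("term_id").loc["T1"]
        assert row["odds_ratio"] > 1
        assert row["p"] < 0.05
        assert row["overlap"] == 10

    def test_empty_selection_gives_empty_table(self):
        universe, ann = self._setup()
        coll = GeneSetCollection([GeneSet("T", "t", "c", ("g1",))])
        table = go_term_enrichment(set(), universe, ann, coll, 10, 0)
        assert len(table) == 0

    def test_term_without_universe_genes_skipped(self):
        universe, ann = self._setup()
        coll = GeneSetCollection(
            [GeneSet("T1", "a", "c", ("g1", "g2")), GeneSet("T2", "b", "c", ("zz",))]
        )
        table = go_term_enrichment(
            {("1", 100)}, universe, ann, coll, n_permutations=50, seed=0
        )
        assert list(table["term_id"]) == ["T1"]

    def test_null_selection_pvalues_not_extreme(self):
        universe, ann = self._setup()
        rng = np.random.default_rng(1)
        terms = [
            GeneSet(f"T{i}", f"t{i}", "c",
                    tuple(f"g{j}" for j in rng.choice(100, size=15, replace=False) + 1))
            for i in range(10)
        ]
        selected = {universe[i] for i in rng.choice(200, size=15, replace=False)}
        table = go_term_enrichment(
            selected, universe, ann, GeneSetCollection(terms),
            n_permutations=400, seed=2,
        )
        # under a random selection no term should be wildly enriched
        assert (table["p"] > 0.01).mean() >= 0.8


class TestFilter:
    def test_low_overlap_removed_despite_significance(self):
        table = pd.DataFrame(
            {"term_id": ["a", "b"], "overlap": [2, 3], "p": [0.04, 0.04],
             "genes": [("x", "y"), ("x", "y", "z")]}
        )
        kept = filter_significant_terms(table)
        assert list(kept["term_id"]) == ["b"]

    def test_study_laughing_gas_terms_all_pass(self):
        # printed term statistics: overlaps 6,6,5,5; p-values up to 0.0373
        table = pd.DataFrame(
            {
                "term_id": ["GO:0005929", "GO:0045597", "GO:0045664", "GO:0016462"],
                "overlap": [6, 6, 5, 5],
                "p": [0.0014, 0.0235, 0.0373, 0.0309],
                "genes": [()] * 4,
            }
        )
        assert len(filter_significant_terms(table)) == 4

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["term_id", "overlap", "p", "genes"])
        assert len(filter_significant_terms(empty)) == 0


def _term_table(spec):
    """spec: list of (term_id, p, genes)."""
    return pd.DataFrame(
        {
            "term_id": [s[0] for s in spec],
            "name": [s[0] for s in spec],
            "category": "biological_process",
            "overlap": [len(s[2]) for s in spec],
            "odds_ratio": 2.0,
            "p": [s[1] for s in spec],
            "genes": [tuple(s[2]) for s in spec],
        }
    )


class TestClustering:
    def test_disjoint_gene_supports_give_two_clusters(self):
        table = _term_table(
            [
                ("t1", 0.01, ["a", "b", "c"]),
                ("t2", 0.02, ["a", "b", "d"]),
                ("t3", 0.01, ["x", "y", "z"]),
                ("t4", 0.02, ["x", "y", "w"]),
            ]
        )
        tcg = cluster_terms(table)
        assert tcg.n_clusters == 2
        assert tcg.clusters["t1"] == tcg.clusters["t2"]
        assert tcg.clusters["t3"] == tcg.clusters["t4"]

    def test_terms_sharing_one_common_gene_form_single_cluster(self):
        table = _term_table(
            [
                ("t1", 0.01, ["g", "a"]),
                ("t2", 0.01, ["g", "b"]),
                ("t3", 0.01, ["g", "c"]),
                ("t4", 0.01, ["g", "d"]),
            ]
        )
        assert cluster_terms(table).n_clusters == 1

    def test_study_like_four_terms_three_clusters(self):
        """Four significant terms of which only the two cell-differentiation
        terms share genes: a 2-term cluster plus two singletons."""
        table = _term_table(
            [
                ("cilium", 0.0014, ["c1", "c2", "c3", "c4", "c5", "c6"]),
                ("pos_reg_cell_diff", 0.0235, ["d1", "d2", "d3", "d4", "d5", "CDON"]),
                ("reg_neuron_diff", 0.0373, ["d1", "d2", "d3", "d4", "CDON"]),
                ("pyrophosphatase", 0.0309, ["p1", "p2", "p3", "p4", "p5"]),
            ]
        )
        tcg = cluster_terms(table)
        assert tcg.n_clusters == 3
        assert tcg.clusters["pos_reg_cell_diff"] == tcg.clusters["reg_neuron_diff"]
        assert len({tcg.clusters["cilium"], tcg.clusters["pyrophosphatase"],
                    tcg.clusters["pos_reg_cell_diff"]}) == 3

    def test_row_order_invariance_with_fixed_seed(self):
        table = _term_table(
            [
                ("t1", 0.01, ["a", "b", "c"]),
                ("t2", 0.02, ["b", "c", "d"]),
                ("t3", 0.01, ["x", "y"]),
                ("t4", 0.02, ["y", "z"]),
            ]
        )
        c1 = cluster_terms(table, seed=0).clusters
        shuffled = table.iloc[[2, 0, 3, 1]].reset_index(drop=True)
        c2 = cluster_terms(shuffled, seed=0).clusters
        # same partition of terms, labels may differ
        part1 = {frozenset(t for t, c in c1.items() if c == k) for k in set(c1.values())}
        part2 = {frozenset(t for t, c in c2.items() if c == k) for k in set(c2.values())}
        assert part1 == part2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cluster_terms(_term_table([]))


class TestDefiningGenes:
    def test_gene_in_single_cluster_is_defining(self):
        table = _term_table([("t1", 0.01, ["a", "b", "c"])])
        dg = assign_defining_genes(cluster_terms(table))
        assert dg["defining"].all()

    def test_majority_cluster_wins(self):
        table = _term_table(
            [
                ("a1", 0.01, ["g", "a", "b", "c"]),
                ("a2", 0.01, ["g", "a", "b", "d"]),
                ("a3", 0.01, ["g", "a", "c", "d"]),
                ("b1", 0.001, ["g", "x", "y", "z"]),
                ("b2", 0.01, ["x", "y", "w"]),
                ("b3", 0.01, ["x", "z", "w"]),
            ]
        )
        tcg = cluster_terms(table)
        # ensure the construction really yields two clusters
        assert tcg.clusters["a1"] == tcg.clusters["a2"] == tcg.clusters["a3"]
        assert tcg.clusters["b1"] != tcg.clusters["a1"]
        dg = assign_defining_genes(tcg).set_index(["gene", "term_id"])
        assert dg.loc[("g", "a1"), "defining"]
        assert not dg.loc[("g", "b1"), "defining"]

    def test_tie_broken_by_most_significant_term(self):
        # gene g sits in exactly one term of each two-term cluster
        table = _term_table(
            [
                ("t1", 0.04, ["g", "a", "b"]),
                ("t1b", 0.02, ["a", "b", "c"]),
                ("t2", 0.001, ["g", "x", "y"]),
                ("t2b", 0.02, ["x", "y", "z"]),
            ]
        )
        tcg = cluster_terms(table)
        assert tcg.clusters["t1"] != tcg.clusters["t2"]
        dg = assign_defining_genes(tcg).set_index(["gene", "term_id"])
        assert dg.loc[("g", "t2"), "defining"]
        assert not dg.loc[("g", "t1"), "defining"]

    def test_defining_rows_confined_to_one_cluster_per_gene(self):
        rng = np.random.default_rng(3)
        spec = [
            (f"t{i}", float(rng.uniform(0.001, 0.05)),
             [f"g{j}" for j in rng.choice(12, size=4, replace=False)])
            for i in range(8)
        ]
        dg = assign_defining_genes(cluster_terms(_term_table(spec)))
        for _, grp in dg[dg["defining"]].groupby("gene"):
            assert grp["cluster"].nunique() == 1
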