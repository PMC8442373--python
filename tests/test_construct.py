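"""Local graph construction: intervals, clustering, building, updating."""

import json
import random

import pytest

from panmosaic.construct import (
    Interval,
    LocalGraph,
    RccParams,
    build_local_graph,
    cluster_rows,
    find_intervals,
    is_one_reference_like,
    load_tree,
    save_tree,
    update_local_graph,
)
from panmosaic.msa import Msa, degap, ref_of_alignment

from conftest import random_msa

P = RccParams()


@pytest.mark.parametrize(
    "row,expected",
    [("AC-GT", "ACGT"), ("----", ""), ("ANT-A", "ATA"), ("ACGT", "ACGT")],
)
def test_degap_removes_non_bases(row, expected):
    assert degap(row) == expected


@pytest.mark.parametrize(
    "rows,expected",
    [
        (["ACGT", "ACGT", "AGGT"], "ACGT"),
        (["A-G", "ACG"], "ACG"),   # gaps never vote
        (["A", "C"], "A"),          # lexicographic tie-break
        (["--", "--"], ""),         # all-gap columns contribute nothing
    ],
)
def test_reference_of_alignment(rows, expected):
    assert ref_of_alignment(Msa(rows)) == expected


class TestFindIntervals:
    def test_identical_rows_form_one_match(self):
        ivs = find_intervals(Msa(["ACGTACGTA"] * 2), P)
        assert ivs == [Interval(0, 9, "match")]

    def test_snp_splits_into_match_nonmatch_match(self):
        rows = ["AAAAAAAAACAAAAAAAAA", "AAAAAAAAAGAAAAAAAAA"]
        ivs = find_intervals(Msa(rows), P)
        assert [(i.start, i.end, i.kind) for i in ivs] == [
            (0, 9, "match"),
            (9, 10, "non-match"),
            (10, 19, "match"),
        ]

    def test_gap_only_differences_are_one_match(self):
        # de-gapped slices agree, so the slice holds a single sequence
        ivs = find_intervals(Msa(["ACGT--ACA", "ACGTAC--A"]), P)
        assert ivs == [Interval(0, 9, "match")]

    def test_short_agreement_stays_nonmatch(self):
        rows = ["ACGTA", "ACGTC"]  # identical run of 4 < m
        ivs = find_intervals(Msa(rows), P)
        assert all(iv.kind == "non-match" for iv in ivs)

    def test_intervals_tile_alignment(self):
        rng = random.Random(0)
        for _ in range(50):
            msa = Msa(random_msa(rng))
            ivs = find_intervals(msa, P)
            assert ivs[0].start == 0 and ivs[-1].end == msa.n_cols
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start
            for iv in ivs:
                if iv.kind == "match":
                    assert iv.end - iv.start >= P.min_match_len


class TestOneReferenceLike:
    def test_identical_rows_pass(self):
        assert is_one_reference_like([Msa(["ACGT"] * 3)], 0.2)

    def test_half_divergent_rows_fail(self):
        rows = ["AAAAAAAAAA", "AAAAACCCCC"]
        assert not is_one_reference_like([Msa(rows)], 0.2)

    def test_two_tight_clusters_pass(self):
        a = Msa(["AAAAAAAAAA", "AAAAAAAAAC"])
        b = Msa(["GGGGGGGGGG", "GGGGGGGGGT"])
        assert is_one_reference_like([a, b], 0.2)


class TestClusterRows:
    def test_two_separated_groups_recovered(self):
        rows = ["AAAAAAAAAAAA"] * 3 + ["CCCCCCCCCCCC"] * 3
        part = cluster_rows(Msa(rows), P, seed=42)
        groups = {frozenset(g) for g in part}
        assert groups == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_identical_rows_stay_single_cluster(self):
        part = cluster_rows(Msa(["ACGTACGT"] * 4), P, seed=42)
        assert part == [[0, 1, 2, 3]]

    def test_clustering_always_terminates(self):
        # rows engineered so no K passes the one-reference criterion
        rng = random.Random(5)
        rows = ["".join(rng.choice("ACGT") for _ in range(20)) for _ in range(12)]
        part = cluster_rows(Msa(rows), P, seed=42)
        assert sum(len(g) for g in part) == 12


class TestBuildLocalGraph:
    def test_single_row_gives_linear_graph(self):
        g, _ = build_local_graph(Msa(["ACGTACGT"]), P)
        real = [s for s in g.nodes.values() if s]
        assert real == ["ACGTACGT"]
        assert g.spells("ACGTACGT")

    def test_single_allele_msa_is_linear(self):
        # many identical alleles collapse to one node (linear graph)
        g, _ = build_local_graph(Msa(["ACGTACGTACGT"] * 5), P)
        assert len([s for s in g.nodes.values() if s]) == 1

    def test_snp_with_long_flanks_gives_bubble(self):
        rows = ["AAAAAAAAACAAAAAAAAA", "AAAAAAAAAGAAAAAAAAA"]
        g, _ = build_local_graph(Msa(rows), P)
        assert g.path_sequences() == {degap(r) for r in rows}
        # flank, two branch nodes, flank
        assert sorted(s for s in g.nodes.values() if s) == ["AAAAAAAAA", "AAAAAAAAA", "C", "G"]

    def test_empty_msa_rejected(self):
        with pytest.raises(ValueError):
            Msa([])

    def test_spellability_dagness_depth(self):
        """Every row's de-gapped sequence is spelled; output is a DAG."""
        rng = random.Random(1)
        for _ in range(200):
            msa = Msa(random_msa(rng))
            g, _ = build_local_graph(msa, P, seed=42)
            assert g.is_acyclic()
            for row in msa.rows:
                assert g.spells(degap(row))

    def test_deterministic_serialization(self):
        rng = random.Random(2)
        rows = random_msa(rng)
        g1, t1 = build_local_graph(Msa(rows, locus_id="x"), P, seed=42)
        g2, t2 = build_local_graph(Msa(rows, locus_id="x"), P, seed=42)
        assert g1.to_gfa() == g2.to_gfa()
        assert json.dumps(t1.to_dict()) == json.dumps(t2.to_dict())

    def test_gfa_round_trip(self):
        g, _ = build_local_graph(Msa(["AAAAAAAAACAAAAAAAAA", "AAAAAAAAAGAAAAAAAAA"]), P)
        g2 = LocalGraph.from_gfa(g.to_gfa())
        assert g2.path_sequences() == g.path_sequences()


class TestUpdateLocalGraph:
    ROWS = ["AAAAAAAAACAAAAAAAAA", "AAAAAAAAAGAAAAAAAAA"]

    def test_re_adding_existing_allele_is_idempotent(self):
        g, t = build_local_graph(Msa(self.ROWS), P)
        g2, _ = update_local_graph(t, [degap(self.ROWS[0])], "x")
        assert g2.to_gfa().replace("LI:Z:x", "LI:Z:") == g.to_gfa().replace("LI:Z:", "LI:Z:")
        assert g2.path_sequences() == g.path_sequences()

    def test_new_snp_in_existing_bubble(self):
        g, t = build_local_graph(Msa(self.ROWS), P)
        new = "AAAAAAAAATAAAAAAAAA"
        g2, _ = update_local_graph(t, [new], "x")
        for s in [degap(r) for r in self.ROWS] + [new]:
            assert g2.spells(s)

    def test_snp_inside_match_interval_splits_it(self):
        g, t = build_local_graph(Msa(["ACGTACGTACGTACGT"]), P)
        new = "ACGTACGAACGTACGT"
        g2, _ = update_local_graph(t, [new], "x")
        assert g2.spells("ACGTACGTACGTACGT") and g2.spells(new)

    def test_update_matches_scratch_build_language(self):
        """Updating with a new allele spells the same set as building from
        the augmented alignment directly (simple SNP cases)."""
        rows = ["AAAAAAAAACAAAAAAAAA", "AAAAAAAAAGAAAAAAAAA"]
        new = "AAAAAAAAATAAAAAAAAA"
        _, t = build_local_graph(Msa(rows), P)
        g_upd, _ = update_local_graph(t, [new], "x")
        g_scratch, _ = build_local_graph(Msa(rows + [new]), P)
        assert g_upd.path_sequences() == g_scratch.path_sequences()

    def test_updated_tree_survives_serialization(self, tmp_path):
        _, t = build_local_graph(Msa(self.ROWS), P)
        _, t2 = update_local_graph(t, ["AAAAAAAAATAAAAAAAAA"], "x")
        path = tmp_path / "tree.json"
        save_tree(t2, path)
        t3 = load_tree(path)
        from panmosaic.construct import tree_to_graph

        assert tree_to_graph(t3, "x").path_sequences() == tree_to_graph(t2, "x").path_sequences()

    def test_random_updates_preserve_old_and_add_new(self):
        rng = random.Random(3)
        for _ in range(30):
            msa = Msa(random_msa(rng, max_rows=4, max_cols=40))
            degs = [degap(r) for r in msa.rows]
            if not any(degs):
                continue
            g, t = build_local_graph(msa, P, seed=42)
            # mutate one row into a new allele
            src = max(degs, key=len)
            if len(src) < 2:
                continue
            i = rng.randrange(len(src))
            new = src[:i] + rng.choice([b for b in "ACGT" if b != src[i]]) + src[i + 1 :]
            g2, _ = update_local_graph(t, [new], "x", P, seed=42)
            assert g2.is_acyclic()
            for s in degs + [new]:
                assert g2.spells(s), (msa.rows, new, s)
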