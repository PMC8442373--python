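"""Pan-genome variant dedup, recall definitions and probe scoring."""

import random

import pytest

from panmosaic.evaluate import (
    AlleleTriple,
    PairwiseVariant,
    apply_vcf_to_reference,
    avg_allelic_recall,
    dedup_pan_variants,
    filter_pan_variants,
    pan_variant_recall,
    precision_score,
    recall_by_truth_probes,
)


def pwv(g1, p1, b1, g2, p2, b2, chrom="c"):
    return PairwiseVariant(
        AlleleTriple(g1, chrom, p1, b1), AlleleTriple(g2, chrom, p2, b2)
    )


class UnionFind:
    """Independent oracle for the dedup partition."""

    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        self.p[self.find(a)] = self.find(b)


class TestDedup:
    def test_shared_allele_merges(self):
        a = pwv("g1", 5, "A", "g2", 9, "C")
        b = pwv("g2", 9, "C", "g3", 2, "A")
        out = dedup_pan_variants([a, b])
        assert len(out) == 1
        assert len(out[0].members) == 2

    def test_disjoint_pairs_stay_separate(self):
        a = pwv("g1", 5, "A", "g2", 9, "C")
        b = pwv("g1", 50, "G", "g2", 90, "T")
        assert len(dedup_pan_variants([a, b])) == 2

    def test_chain_transitivity(self):
        chain = [
            pwv("g1", 1, "A", "g2", 2, "C"),
            pwv("g2", 2, "C", "g3", 3, "A"),
            pwv("g3", 3, "A", "g4", 4, "C"),
        ]
        out = dedup_pan_variants(chain)
        assert len(out) == 1
        assert len(out[0].alleles) == 4

    def test_partition_matches_union_find_oracle(self):
        """Components agree with an independent union-find on 10^4 random
        pairwise-variant sets."""
        rng = random.Random(42)
        total_pairs = 0
        while total_pairs < 10_000:
            n = rng.randint(2, 40)
            pairs = []
            for _ in range(n):
                g1, g2 = rng.sample(range(8), 2)
                p1, p2 = rng.randrange(5), rng.randrange(5)
                b1, b2 = rng.sample("ACGT", 2)
                pairs.append(pwv(f"g{g1}", p1, b1, f"g{g2}", p2, b2))
            total_pairs += n
            out = dedup_pan_variants(pairs)
            # surjection: every pairwise variant in exactly one component
            counts = [0] * len(pairs)
            idx_of = {id(pv): i for i, pv in enumerate(pairs)}
            for pgv in out:
                for pv in pgv.members:
                    counts[idx_of[id(pv)]] += 1
            assert counts == [1] * len(pairs)
            # oracle partition
            uf = UnionFind(len(pairs))
            for i in range(len(pairs)):
                for j in range(i + 1, len(pairs)):
                    keys_i = {a.key for a in pairs[i].alleles}
                    keys_j = {a.key for a in pairs[j].alleles}
                    if keys_i & keys_j:
                        uf.union(i, j)
            oracle = {}
            for i in range(len(pairs)):
                oracle.setdefault(uf.find(i), set()).add(i)
            got = {frozenset(idx_of[id(pv)] for pv in pgv.members) for pgv in out}
            assert got == {frozenset(s) for s in oracle.values()}


class TestFilter:
    def test_triallelic_removed(self):
        pairs = [
            pwv("g1", 1, "A", "g2", 1, "C"),
            pwv("g2", 1, "C", "g3", 1, "G"),
        ]
        assert filter_pan_variants(dedup_pan_variants(pairs)) == []

    def test_paralog_two_alleles_one_genome_removed(self):
        pairs = [
            pwv("g1", 1, "A", "g2", 1, "C"),
            pwv("g1", 9, "A", "g2", 1, "C"),  # second allele from g1
        ]
        assert filter_pan_variants(dedup_pan_variants(pairs)) == []

    def test_clean_biallelic_snp_retained(self):
        # one A carrier paired against five C carriers: one shared site
        pairs = [pwv("g0", 1, "A", f"g{i}", 1, "C") for i in range(1, 6)]
        out = filter_pan_variants(dedup_pan_variants(pairs))
        assert len(out) == 1
        assert len(out[0].alleles) == 6


from conftest import three_gene_scenario


class TestRecallDefinitions:
    def test_worked_example_pan_variant_recall(self):
        pan, det = three_gene_scenario()
        assert pan_variant_recall(det, pan) == pytest.approx(2 / 3)

    def test_worked_example_avg_allelic_recall(self):
        pan, det = three_gene_scenario()
        assert avg_allelic_recall(det, pan) == pytest.approx((2 / 2 + 2 / 10 + 5 / 20) / 3)

    def test_everything_found_gives_one(self):
        pan, det = three_gene_scenario()
        full = {i: {k: True for k in d} for i, d in det.items()}
        assert pan_variant_recall(full, pan) == 1.0
        assert avg_allelic_recall(full, pan) == 1.0

    def test_nothing_found_gives_zero(self):
        pan, det = three_gene_scenario()
        none = {i: {k: False for k in d} for i, d in det.items()}
        assert pan_variant_recall(none, pan) == 0.0
        assert avg_allelic_recall(none, pan) == 0.0

    def test_empty_truth_set_rejected(self):
        with pytest.raises(ValueError):
            pan_variant_recall({}, [])


class TestProbeScoring:
    TRUTH = {"t": "ACGTACTGACGGATCCGTAGCATCGATCGGTTACCGATGCAGTCAGT"}

    def test_exact_allele_scores_one(self):
        probe = self.TRUTH["t"][5:30]
        agg, scores = precision_score([(probe, 10, 5)], self.TRUTH)
        assert scores == [1.0]

    def test_one_mismatch_in_ten_columns(self):
        t = self.TRUTH["t"]
        allele = t[10:20]
        allele = allele[:4] + ("A" if allele[4] != "A" else "C") + allele[5:]
        probe = t[0:10] + allele + t[20:30]
        agg, scores = precision_score([(probe, 10, 10)], self.TRUTH)
        assert scores == [pytest.approx(0.9)]

    def test_ambiguous_multimapping_excluded(self):
        repeat = "ACGTACTGACGGATCCGTAGC"
        truth = {"t": repeat + "TTTTTTTTTT" + repeat}
        agg, scores = precision_score([(repeat, 5, 8)], truth)
        assert scores == []

    def test_vcf_application_right_to_left(self):
        ref = "AAAAAAAAAA"
        out = apply_vcf_to_reference(ref, [(3, "A", "C"), (7, "A", "G")])
        assert out == "AACAAAGAAA"

    def test_truth_probe_detects_applied_variant(self):
        truth_seqs = {("g1", "c"): "ACGTACTGACGGATCCGTAGCATCGATCGGTTACCGATGC"}
        ref = "ACGTACTGACGTATCCGTAGCATCGATCGGTTACCGATGC"  # differs at pos 11
        pan = filter_pan_variants(
            dedup_pan_variants(
                [pwv("g1", 11, "G", "g2", 11, "T", chrom="c")]
            )
        )
        mutated = {"g1": {"c": apply_vcf_to_reference(ref, [(12, "T", "G")])}, "g2": {"c": ref}}
        det = recall_by_truth_probes(pan, {("g1", "c"): truth_seqs[("g1", "c")], ("g2", "c"): ref}, mutated, flank=10)
        assert det[0][("g1", "c", 11)] is True
        assert det[0][("g2", "c", 11)] is True

    def test_dropped_variant_probe_fails(self):
        truth_seqs = {("g1", "c"): "ACGTACTGACGGATCCGTAGCATCGATCGGTTACCGATGC"}
        ref = "ACGTACTGACGTATCCGTAGCATCGATCGGTTACCGATGC"
        pan = filter_pan_variants(
            dedup_pan_variants([pwv("g1", 11, "G", "g2", 11, "T", chrom="c")])
        )
        mutated = {"g1": {"c": ref}, "g2": {"c": ref}}  # call never applied
        det = recall_by_truth_probes(
            pan, {("g1", "c"): truth_seqs[("g1", "c")], ("g2", "c"): ref}, mutated, flank=10
        )
        assert det[0][("g1", "c", 11)] is False
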