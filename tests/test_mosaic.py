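"""Negative-binomial coverage model and maximum-likelihood path DP."""

import math
import random

import numpy as np
import pytest

from panmosaic.kmergraph import KmerGraph
from panmosaic.mosaic import (
    NegBinParams,
    fit_negbin_moments,
    max_likelihood_path,
    negbin_log_pmf,
)
from panmosaic.sketch import MinimizerParams


class TestMomentFit:
    def test_mean10_var20_solves_exactly(self):
        # p = mean/var, r = mean^2/(var - mean)
        nb = fit_negbin_moments([5, 15, 10, 10])  # mean 10, var 12.5
        assert nb.p == pytest.approx(10 / 12.5)
        assert nb.r == pytest.approx(100 / 2.5)

    @pytest.mark.parametrize("mean,var,r,p", [(10, 20, 10, 0.5), (4, 8, 4, 0.5)])
    def test_printed_moment_algebra(self, mean, var, r, p):
        assert mean / var == pytest.approx(p)
        assert mean**2 / (var - mean) == pytest.approx(r)
        nb = NegBinParams(r, p)
        assert nb.mean == pytest.approx(mean)
        assert nb.variance == pytest.approx(var)

    def test_parameter_recovery_from_draws(self):
        rng = np.random.default_rng(0)
        draws = rng.negative_binomial(10, 0.5, 100_000)
        nb = fit_negbin_moments(draws)
        assert abs(nb.r - 10) / 10 < 0.10
        assert abs(nb.p - 0.5) / 0.5 < 0.05

    def test_underdispersed_data_warns_and_inflates(self):
        with pytest.warns(UserWarning):
            nb = fit_negbin_moments([10, 10, 10, 10])
        assert nb.variance > nb.mean


class TestLogPmf:
    def test_zero_count_reduces_to_r_log_p(self):
        nb = NegBinParams(3.0, 0.4)
        assert negbin_log_pmf(0, nb) == pytest.approx(3.0 * math.log(0.4))

    def test_r1_is_geometric(self):
        nb = NegBinParams(1.0, 0.3)
        for s in range(6):
            assert negbin_log_pmf(s, nb) == pytest.approx(math.log(0.3) + s * math.log(0.7))

    def test_normalization(self):
        nb = NegBinParams(10.0, 0.5)
        total = sum(math.exp(negbin_log_pmf(s, nb)) for s in range(10_001))
        assert total == pytest.approx(1.0, abs=1e-6)


def random_coverage_dag(rng: random.Random) -> KmerGraph:
    """Layered DAG with random per-node coverage, standing in for a k-mer
    graph (only topology and coverage matter to the DP)."""
    kg = KmerGraph("toy", MinimizerParams(w=3, k=4))
    kg._add(None, "")
    layers = [[0]]
    for _ in range(rng.randint(2, 5)):
        cur = []
        for _ in range(rng.randint(1, 3)):
            node = kg._add(None, "XXXX")
            node.placement = ((node.id, 0, 4),)
            node.coverage["s"] = [rng.randrange(0, 25), 0]
            cur.append(node.id)
        for c in cur:
            for p in rng.sample(layers[-1], rng.randint(1, len(layers[-1]))):
                kg.add_edge(p, c)
        layers.append(cur)
    sink = kg._add(None, "")
    for p in layers[-1]:
        kg.add_edge(p, sink.id)
    for n in kg.nodes[1:-1]:
        if not kg.pred[n.id]:
            kg.add_edge(0, n.id)
        if not kg.succ[n.id]:
            kg.add_edge(n.id, sink.id)
    return kg


def brute_force_best_score(kg: KmerGraph, nb: NegBinParams, cap: int) -> float:
    best = -math.inf
    stack = [[kg.source]]
    while stack:
        p = stack.pop()
        if p[-1] == kg.sink:
            lls = [
                negbin_log_pmf(kg.nodes[n].covg("s"), nb)
                for n in p
                if not kg.nodes[n].is_terminal
            ]
            if lls:
                best = max(best, sum(lls) / min(cap, len(lls)))
            continue
        for s in kg.succ[p[-1]]:
            stack.append(p + [s])
    return best


class TestMaxLikelihoodPath:
    NB = NegBinParams(10, 0.5)

    def test_linear_graph_returns_only_path(self):
        kg = KmerGraph("lin", MinimizerParams(w=3, k=4))
        kg._add(None, "")
        prev = 0
        for i in range(3):
            n = kg._add(None, "XXXX")
            n.placement = ((n.id, 0, 4),)
            kg.add_edge(prev, n.id)
            prev = n.id
        sink = kg._add(None, "")
        kg.add_edge(prev, sink.id)
        mp = max_likelihood_path(kg, "s", self.NB)
        assert mp.node_ids == [0, 1, 2, 3, 4]

    def test_covered_branch_beats_uncovered(self):
        kg = KmerGraph("b", MinimizerParams(w=3, k=4))
        kg._add(None, "")
        a = kg._add(None, "AAAA"); a.placement = ((1, 0, 4),); a.coverage["s"] = [10, 0]
        b = kg._add(None, "CCCC"); b.placement = ((2, 0, 4),); b.coverage["s"] = [0, 0]
        sink = kg._add(None, "")
        kg.add_edge(0, a.id); kg.add_edge(0, b.id)
        kg.add_edge(a.id, sink.id); kg.add_edge(b.id, sink.id)
        mp = max_likelihood_path(kg, "s", self.NB)
        assert a.id in mp.node_ids and b.id not in mp.node_ids

    def test_dp_matches_exhaustive_enumeration(self):
        rng = random.Random(11)
        for trial in range(100):
            kg = random_coverage_dag(rng)
            for cap in (2, 100):
                mp = max_likelihood_path(kg, "s", self.NB, score_cap=cap)
                assert mp.score == pytest.approx(
                    brute_force_best_score(kg, self.NB, cap), abs=1e-9
                )
                for u, v in zip(mp.node_ids, mp.node_ids[1:]):
                    assert v in kg.succ[u]

    def test_score_monotone_in_path_coverage(self):
        """Raising a low on-path coverage toward the distribution mode
        never lowers the optimal score (the pmf rises on [0, mode])."""
        mode = 4  # floor((r-1)(1-p)/p) for NB(10, 0.5)
        rng = random.Random(13)
        for _ in range(20):
            kg = random_coverage_dag(rng)
            mp = max_likelihood_path(kg, "s", self.NB)
            low = [n for n in mp.node_ids if not kg.nodes[n].is_terminal
                   and kg.nodes[n].covg("s") < mode]
            if not low:
                continue
            kg.nodes[low[0]].coverage["s"] = [mode, 0]
            mp2 = max_likelihood_path(kg, "s", self.NB)
            assert mp2.score >= mp.score - 1e-12

    def test_no_path_raises(self):
        kg = KmerGraph("x", MinimizerParams(w=3, k=4))
        kg._add(None, "")
        kg._add(None, "")
        with pytest.raises(ValueError):
            max_likelihood_path(kg, "s", self.NB)


class TestPathSpelling:
    def test_mosaic_round_trip_through_simulation(self, small_cohort):
        """Inferred mosaic sequences reproduce the simulated sample
        haplotypes (error-free reads, all alleles in the panel).  Path
        sequences are unique only outside the first/last w-1 bases, so
        the comparison excludes that terminal zone."""
        from panmosaic.pipeline import map_and_infer

        panel, panrg, samples, reads = small_cohort
        w = panrg.params.w
        res = map_and_infer(panrg, reads["s0"], "s0", "long")
        assert res.present_loci
        for locus in res.present_loci:
            got = res.mosaics[locus].sequence
            want = samples["s0"].sequences[locus]
            assert len(got) == len(want)
            assert got[w - 1 : -(w - 1)] == want[w - 1 : -(w - 1)]

    def test_respelled_sketch_matches_path(self, small_cohort):
        """Re-sketching a spelled mosaic finds its own path nodes again."""
        from panmosaic.pipeline import map_and_infer
        from panmosaic.sketch import string_minimizers

        panel, panrg, samples, reads = small_cohort
        res = map_and_infer(panrg, reads["s0"], "s0", "long")
        locus = res.present_loci[0]
        mp = res.mosaics[locus]
        kg = panrg.loci[locus].kmer_graph
        path_hashes = {kg.nodes[n].hash for n in mp.node_ids if not kg.nodes[n].is_terminal}
        sketch_hashes = {m.hash for m in string_minimizers(mp.sequence, panrg.params)}
        assert sketch_hashes <= path_hashes
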