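"""VCF reference inference, site enumeration, genotyping and filters."""

import math
import random

import pytest

from panmosaic.genotype import (
    FilterConfig,
    SampleCall,
    VcfSite,
    apply_filters,
    genotype_confidence,
    genotype_locus,
    infer_vcf_reference,
    write_presence_matrix,
    write_vcf,
    write_vcf_reference_fasta,
)
from panmosaic.mosaic import MosaicPath
from panmosaic.pipeline import run_cohort

from conftest import kmer_graph_paths


class TestGenotypeConfidence:
    def test_equal_likelihoods_give_zero(self):
        assert genotype_confidence([-10.0, -10.0]) == 0.0

    def test_gap_is_best_minus_second(self):
        assert genotype_confidence([-5.0, -20.0]) == 15.0

    def test_permutation_invariance(self):
        lls = [-3.0, -7.5, -1.2, -9.9]
        rng = random.Random(0)
        for _ in range(10):
            rng.shuffle(lls)
            assert genotype_confidence(lls) == pytest.approx(1.8)

    def test_single_allele_is_infinite(self):
        assert genotype_confidence([-3.0]) == math.inf


class TestApplyFilters:
    def _site(self, fwd, rev, gaps=0.0, conf=50.0):
        site = VcfSite("l", 1, "A", ["C"], [[1], [2]])
        site.calls["s"] = SampleCall(0, [-1.0, -20.0], conf, [fwd, 0], [rev, 0], [gaps, 0])
        return site

    def test_low_coverage_masked(self):
        site = self._site(fwd=2, rev=2)  # 4x < 5x minimum
        apply_filters([site], FilterConfig.illumina(), {"s": 30})
        assert site.calls["s"].genotype is None

    def test_strand_bias_masked(self):
        site = self._site(fwd=100, rev=2)  # 2/102 < 5%
        apply_filters([site], FilterConfig.illumina(), {"s": 30})
        assert site.calls["s"].genotype is None

    def test_gaps_filter_boundary(self):
        ok = self._site(fwd=20, rev=20, gaps=0.75)
        bad = self._site(fwd=20, rev=20, gaps=0.85)
        apply_filters([ok, bad], FilterConfig.illumina(), {"s": 30})
        assert ok.calls["s"].genotype == 0
        assert bad.calls["s"].genotype is None

    def test_confidence_threshold(self):
        site = self._site(fwd=20, rev=20, conf=1.0)
        cfg = FilterConfig.illumina()
        cfg.min_gt_conf = 5.0
        apply_filters([site], cfg, {"s": 30})
        assert site.calls["s"].genotype is None


class TestVcfReference:
    def test_single_sample_reference_is_its_mosaic(self, small_cohort):
        from panmosaic.pipeline import map_and_infer

        panel, panrg, samples, reads = small_cohort
        res = map_and_infer(panrg, reads["s0"], "s0", "long")
        locus = res.present_loci[0]
        loc = panrg.loci[locus]
        ref = infer_vcf_reference(loc.kmer_graph, [res.mosaics[locus]], loc.graph)
        assert ref.node_ids == res.mosaics[locus].node_ids

    def test_majority_branch_wins(self, small_cohort):
        """With sample paths 2:1 over a bubble, the reference follows the
        majority; verified against exhaustive path enumeration."""
        from panmosaic.pipeline import map_and_infer

        panel, panrg, samples, reads = small_cohort
        r0 = map_and_infer(panrg, reads["s0"], "s0", "long")
        r1 = map_and_infer(panrg, reads["s1"], "s1", "long")
        shared = sorted(set(r0.present_loci) & set(r1.present_loci))
        assert shared
        for locus in shared[:2]:
            loc = panrg.loci[locus]
            paths = [r0.mosaics[locus], r0.mosaics[locus], r1.mosaics[locus]]
            ref = infer_vcf_reference(loc.kmer_graph, paths, loc.graph)
            counts = {}
            for mp in paths:
                for n in mp.node_ids:
                    counts[n] = counts.get(n, 0) + 1
            # exhaustive check over all kmer-graph paths (skip huge graphs)
            best = None
            n_paths = 0
            for p in kmer_graph_paths(loc.kmer_graph):
                n_paths += 1
                if n_paths > 3000:
                    break
                score = sum(
                    math.log((counts.get(n, 0) + 0.01) / (len(paths) + 0.01))
                    for n in p
                    if not loc.kmer_graph.nodes[n].is_terminal
                )
                ln = sum(1 for n in p if not loc.kmer_graph.nodes[n].is_terminal)
                score = score / min(100, max(ln, 1))
                if best is None or score > best[0]:
                    best = (score, p)
            if n_paths <= 3000:
                ref_score = sum(
                    math.log((counts.get(n, 0) + 0.01) / (len(paths) + 0.01))
                    for n in ref.node_ids
                    if not loc.kmer_graph.nodes[n].is_terminal
                )
                ln = sum(1 for n in ref.node_ids if not loc.kmer_graph.nodes[n].is_terminal)
                assert ref_score / min(100, ln) == pytest.approx(best[0], abs=1e-9)


@pytest.fixture(scope="module")
def cohort(small_cohort):
    panel, panrg, samples, reads = small_cohort
    return samples, run_cohort(panrg, dict(reads), "long", denovo=False)


class TestCohortGenotyping:
    def test_identical_samples_segregate_nowhere_wrong(self, cohort):
        """Genotype calls at segregating sites match the simulated truth
        (substitution-only simulation keeps coordinates aligned)."""
        samples, res = cohort
        good = bad = 0
        for locus, sites in res.sites.items():
            for site in sites:
                for sid, call in site.calls.items():
                    truth = samples[sid].sequences.get(locus)
                    if truth is None or call.genotype is None:
                        continue
                    allele = site.alleles[call.genotype]
                    seen = truth[site.pos - 1 : site.pos - 1 + len(allele)]
                    good += seen == allele
                    bad += seen != allele
        assert good > 0
        assert bad / max(good + bad, 1) <= 0.01

    def test_null_on_mosaic_likelihood_conflict(self, cohort):
        """Whenever the mosaic-path allele is not the likelihood winner
        the genotype must be null, never a wrong call."""
        import numpy as np

        samples, res = cohort
        for locus, sites in res.sites.items():
            for site in sites:
                for sid, call in site.calls.items():
                    if call.genotype is not None:
                        assert call.genotype == int(np.argmax(call.likelihoods))

    def test_written_vcf_round_trips(self, cohort, tmp_path):
        samples, res = cohort
        sids = sorted(samples)
        vcf_path = tmp_path / "out.vcf"
        write_vcf(res.sites, res.refs, sids, vcf_path)
        write_vcf_reference_fasta(res.refs, tmp_path / "ref.fa")
        from panmosaic.report import parse_vcf, read_fasta

        got_samples, records = parse_vcf(vcf_path)
        assert got_samples == sids
        assert len(records) == sum(len(s) for s in res.sites.values())
        refs = read_fasta(tmp_path / "ref.fa")
        for rec in records:
            seq = refs[rec["chrom"]]
            assert seq[rec["pos"] - 1 : rec["pos"] - 1 + len(rec["ref"])] == rec["ref"]

    def test_null_rendered_as_dot(self, cohort, tmp_path):
        samples, res = cohort
        sids = sorted(samples)
        # force one null call
        for sites in res.sites.values():
            if sites:
                sites[0].calls[sids[0]].genotype = None
                break
        vcf_path = tmp_path / "null.vcf"
        write_vcf(res.sites, res.refs, sids, vcf_path)
        assert "\t.:" in vcf_path.read_text()

    def test_presence_matrix_shape(self, cohort, tmp_path):
        samples, res = cohort
        path = tmp_path / "presence.tsv"
        write_presence_matrix(
            {s: {l: True for l in samples[s].sequences} for s in samples}, sorted(samples), path
        )
        lines = path.read_text().strip().splitlines()
        assert lines[0].split("\t")[1:] == sorted(samples)
        assert len(lines) == 1 + len({l for s in samples.values() for l in s.sequences})
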