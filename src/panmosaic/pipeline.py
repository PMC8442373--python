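"""End-to-end workflow: build, index, map, infer, discover, genotype.

The `PanRG` container holds one local graph + recursion tree + k-mer
graph per locus and the global minimizer index.  `run_cohort` drives the
full two-pass workflow: quasi-map every sample and infer mosaic
sequences, discover candidate novel alleles from low-coverage regions,
augment the graphs with all candidates from all samples at once, re-map
against the augmented PanRG (no discovery on the second pass), and
jointly genotype everything against the inferred VCF reference.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .construct import LocalGraph, RccNode, RccParams, build_local_graph, update_local_graph
from .discover import (
    DiscoveryParams,
    coverage_profile,
    discover_region_alleles,
    find_candidate_regions,
)
from .genotype import FilterConfig, VcfReference, VcfSite, apply_filters, genotype_locus
from .index import PanRGIndex, build_index
from .kmergraph import KmerGraph, minimizers_and_kmer_graph
from .mapping import MappingResult, PresenceCall, filter_present_loci, map_sample
from .mosaic import MosaicPath, NegBinParams, fit_negbin_moments, max_likelihood_path, spell_kmer_path
from .msa import Msa
from .sketch import MinimizerParams


@dataclass
class Locus:
    locus_id: str
    graph: LocalGraph
    tree: RccNode
    kmer_graph: KmerGraph


@dataclass
class PanRG:
    params: MinimizerParams
    rcc_params: RccParams
    loci: dict[str, Locus] = field(default_factory=dict)
    index: Optional[PanRGIndex] = None
    seed: int = 42

    @property
    def kmer_graphs(self) -> dict[str, KmerGraph]:
        return {l: loc.kmer_graph for l, loc in self.loci.items()}

    def build_index(self) -> PanRGIndex:
        self.index = build_index([loc.kmer_graph for loc in self.loci.values()])
        return self.index

    def augment(self, candidates: dict[str, set[str]]) -> list[str]:
        """Add candidate alleles to their loci, re-sketch the affected
        local graphs, and rebuild the index; returns updated locus ids."""
        updated = []
        for locus_id, alleles in sorted(candidates.items()):
            if not alleles or locus_id not in self.loci:
                continue
            loc = self.loci[locus_id]
            graph, tree = update_local_graph(
                loc.tree, sorted(alleles), locus_id, self.rcc_params, self.seed
            )
            _, kg = minimizers_and_kmer_graph(graph, self.params)
            self.loci[locus_id] = Locus(locus_id, graph, tree, kg)
            updated.append(locus_id)
        if updated:
            self.build_index()
        return updated


def build_panrg(
    msas: Iterable[Msa],
    params: MinimizerParams | None = None,
    rcc_params: RccParams | None = None,
    seed: int = 42,
) -> PanRG:
    params = params or MinimizerParams()
    rcc_params = rcc_params or RccParams()
    panrg = PanRG(params, rcc_params, seed=seed)
    for msa in msas:
        graph, tree = build_local_graph(msa, rcc_params, seed)
        _, kg = minimizers_and_kmer_graph(graph, params)
        panrg.loci[msa.locus_id] = Locus(msa.locus_id, graph, tree, kg)
    panrg.build_index()
    return panrg


@dataclass
class SampleResult:
    sample_id: str
    mapping: MappingResult
    mosaics: dict[str, MosaicPath] = field(default_factory=dict)
    presence: dict[str, PresenceCall] = field(default_factory=dict)
    negbin: Optional[NegBinParams] = None
    expected_depth: float = 0.0

    @property
    def present_loci(self) -> list[str]:
        return sorted(l for l, c in self.presence.items() if c.present)


def map_and_infer(
    panrg: PanRG,
    reads: list[tuple[str, str]],
    sample_id: str,
    mode: str = "long",
    min_rel_cov: float = 0.05,
    min_abs_cov: float = 3.0,
    score_cap: int = 100,
) -> SampleResult:
    """Quasi-map one sample and infer per-locus mosaic sequences.

    The negative binomial is fitted per sample from the k-mer coverages
    of all candidate loci jointly; candidate loci whose inferred-path
    coverage sits far below the sample average are then filtered out."""
    for kg in panrg.kmer_graphs.values():
        kg.reset_coverage(sample_id)
    mapping = map_sample(reads, panrg.index, panrg.kmer_graphs, sample_id, mode)
    result = SampleResult(sample_id, mapping)

    covs: list[int] = []
    for locus in mapping.candidate_loci:
        kg = panrg.loci[locus].kmer_graph
        covs.extend(n.covg(sample_id) for n in kg.real_nodes)
    if not covs or max(covs) == 0:
        return result
    # fit on supported k-mers: zero-coverage nodes are dominated by the
    # absent alleles of each graph, which the NB is not meant to model
    # (a zero-inflated fit would make uncovered branches look likely)
    positive = [c for c in covs if c > 0]
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = fit_negbin_moments(positive if len(positive) >= 10 else covs)
    except ValueError:
        return result
    result.negbin = nb

    path_covs = []
    for locus in mapping.candidate_loci:
        loc = panrg.loci[locus]
        mp = max_likelihood_path(loc.kmer_graph, sample_id, nb, score_cap=score_cap)
        mp.sequence, mp.node_offsets = spell_kmer_path(loc.graph, loc.kmer_graph, mp.node_ids)
        result.mosaics[locus] = mp
        node_covs = [
            loc.kmer_graph.nodes[n].covg(sample_id)
            for n in mp.node_ids
            if not loc.kmer_graph.nodes[n].is_terminal
        ]
        mean_c = float(np.mean(node_covs)) if node_covs else 0.0
        med_c = float(np.median(node_covs)) if node_covs else 0.0
        result.presence[locus] = PresenceCall(
            locus, True, len(mapping.clusters[locus]), mean_c, med_c
        )
        path_covs.append(mean_c)
    filter_present_loci(result.presence, min_rel_cov, min_abs_cov)
    present_means = [result.presence[l].mean_covg for l in result.present_loci]
    result.expected_depth = float(np.mean(present_means)) if present_means else 0.0
    return result


def discover_sample(
    panrg: PanRG,
    result: SampleResult,
    reads: dict[str, str],
    params: DiscoveryParams | None = None,
) -> dict[str, set[str]]:
    """Candidate novel alleles per locus from one sample's low-coverage
    mosaic regions."""
    params = params or DiscoveryParams()
    k = panrg.params.k
    out: dict[str, set[str]] = {}
    for locus in result.present_loci:
        loc = panrg.loci[locus]
        mp = result.mosaics[locus]
        if not mp.sequence:
            continue
        cov = coverage_profile(loc.kmer_graph, mp, result.sample_id, k)
        max_run = params.resolved_max_run(panrg.params.w, panrg.params.k)
        regions = find_candidate_regions(cov, locus, params, max_run)
        for region in regions:
            alleles = discover_region_alleles(
                region, mp, result.mapping.clusters.get(locus, []), reads, k, params
            )
            if alleles:
                out.setdefault(locus, set()).update(alleles)
    return out


@dataclass
class CohortResult:
    samples: dict[str, SampleResult]
    refs: dict[str, VcfReference] = field(default_factory=dict)
    sites: dict[str, list[VcfSite]] = field(default_factory=dict)
    candidates: dict[str, set[str]] = field(default_factory=dict)

    def presence_matrix(self) -> dict[str, dict[str, bool]]:
        return {
            s: {l: c.present for l, c in res.presence.items()}
            for s, res in self.samples.items()
        }


def run_cohort(
    panrg: PanRG,
    sample_reads: dict[str, list[tuple[str, str]]],
    mode: str = "long",
    denovo: bool = True,
    discovery_params: DiscoveryParams | None = None,
    filters: FilterConfig | None = None,
    score_cap: int = 100,
) -> CohortResult:
    """The full two-pass compare workflow over a cohort of samples."""
    results = {
        s: map_and_infer(panrg, reads, s, mode, score_cap=score_cap)
        for s, reads in sample_reads.items()
    }
    candidates: dict[str, set[str]] = {}
    if denovo:
        for s, res in results.items():
            read_dict = dict(sample_reads[s])
            found = discover_sample(panrg, res, read_dict, discovery_params)
            for locus, alleles in found.items():
                candidates.setdefault(locus, set()).update(alleles)
        if candidates:
            panrg.augment(candidates)
            results = {
                s: map_and_infer(panrg, reads, s, mode, score_cap=score_cap)
                for s, reads in sample_reads.items()
            }
    cohort = CohortResult(results, candidates=candidates)

    # joint genotyping per locus over samples where the locus is present
    expected_depth = {s: res.expected_depth for s, res in results.items()}
    loci = sorted({l for res in results.values() for l in res.present_loci})
    for locus in loci:
        loc = panrg.loci[locus]
        paths = {
            s: res.mosaics[locus]
            for s, res in results.items()
            if locus in res.mosaics and res.presence[locus].present
        }
        if not paths:
            continue
        ref, sites = genotype_locus(loc.kmer_graph, loc.graph, paths, expected_depth)
        cohort.refs[locus] = ref
        cohort.sites[locus] = sites
    if filters is not None:
        for locus, sites in cohort.sites.items():
            apply_filters(sites, filters, expected_depth)
    return cohort
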