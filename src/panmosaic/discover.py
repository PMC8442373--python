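"""De novo discovery of alleles missing from the PanRG.

Variants absent from the graph leave a footprint: the minimizer k-mers
of the inferred mosaic that overlap the novel site get no read support.
Low-coverage intervals on the mosaic become candidate regions; the read
slices overlapping each region are assembled into a small de Bruijn
graph, anchored to the mosaic flanks, and all adequately covered
anchor-to-anchor paths are enumerated as candidate alleles.  Candidates
from all samples are gathered and routed back into the local graphs.
"""

from __future__ import annotations

import statistics
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .mapping import HitCluster
from .mosaic import MosaicPath
from .kmergraph import KmerGraph
from .sketch import revcomp

_BASES = "ACGT"


@dataclass
class DiscoveryParams:
    low_cov_threshold: int = 2          # c: positions below this are candidate
    min_run: int = 1                    # l: runs must be strictly longer
    max_run: int | None = None          # m: and strictly shorter than this
    padding: int = 28                   # w: bases added either side
    k_dbg: int = 11                     # de Bruijn k-mer size
    max_paths: int = 500                # |V_r| cap before f-escalation
    step: float = 0.1                   # s: f-escalation step
    max_low_nodes: int | None = None    # low-coverage node budget (default 2k)
    max_path_factor: int = 2            # path length cap = factor * region span

    def low_budget(self) -> int:
        return self.max_low_nodes if self.max_low_nodes is not None else 2 * self.k_dbg

    def resolved_max_run(self, w: int, k: int) -> int:
        """A variant suppresses minimizer hits over a footprint of up to
        ~2(w+k) bases (every sketch window overlapping it reshuffles), so
        the run cap must scale with the sketch span."""
        return self.max_run if self.max_run is not None else 2 * (w + k) + 10


@dataclass
class CandidateRegion:
    locus_id: str
    start: int          # low-coverage run start on the mosaic sequence
    end: int            # run end (exclusive)
    pad_start: int      # padded slice start
    pad_end: int        # padded slice end

    @property
    def span(self) -> tuple[int, int]:
        return self.pad_start, self.pad_end


def coverage_profile(kg: KmerGraph, path: MosaicPath, sample_id: str, k: int) -> np.ndarray:
    """Per-base coverage along the mosaic sequence: the minimum coverage
    of the path k-mers spanning each base (a base counts as supported
    only if every minimizer overlapping it is supported); bases outside
    any path k-mer inherit the nearest k-mer's coverage."""
    n = len(path.sequence)
    cov = np.full(n, -1.0)
    if path.node_offsets:
        INF = float("inf")
        mins = np.full(n, INF)
        for nid, off in path.node_offsets.items():
            c = kg.nodes[nid].covg(sample_id)
            end = min(off + k, n)
            mins[off:end] = np.minimum(mins[off:end], c)
        covered = mins < INF
        cov[covered] = mins[covered]
        # fill terminal gaps with nearest covered value
        idx = np.nonzero(covered)[0]
        if idx.size:
            cov[: idx[0]] = cov[idx[0]]
            cov[idx[-1] + 1 :] = cov[idx[-1]]
    else:
        cov[:] = 0
    return cov


def find_candidate_regions(
    coverage: np.ndarray,
    locus_id: str,
    params: DiscoveryParams,
    max_run: int | None = None,
) -> list[CandidateRegion]:
    """Maximal runs of positions with coverage < c whose length L obeys
    l < L < m, padded by w bases (clamped to the locus)."""
    c, l, w = params.low_cov_threshold, params.min_run, params.padding
    m = max_run if max_run is not None else (params.max_run or 30)
    low = coverage < c
    regions = []
    n = len(low)
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        if l < j - i < m:
            regions.append(
                CandidateRegion(locus_id, i, j, max(0, i - w), min(n, j + w))
            )
        i = j
    return regions


def build_pileup(
    region: CandidateRegion,
    mosaic: MosaicPath,
    clusters: list[HitCluster],
    reads: dict[str, str],
    k: int,
) -> list[str]:
    """Extract, for each read overlapping the region, the slice spanning
    the padded region, located via the read's nearest on-path minimizer
    hits and orientation-normalized to the locus strand."""
    offsets = mosaic.node_offsets or {}
    s, e = region.span
    slices = []
    for cl in clusters:
        on_path = [(h, offsets[h.node_id]) for h in cl.hits if h.node_id in offsets]
        if not on_path:
            continue
        lo_off = min(off for _, off in on_path)
        hi_off = max(off for _, off in on_path) + k
        if hi_off <= s or lo_off >= e:
            continue  # cluster does not overlap the region
        read = reads.get(cl.hits[0].read_id)
        if read is None:
            continue
        hl = min(on_path, key=lambda t: abs(t[1] - s))
        hr = min(on_path, key=lambda t: abs(t[1] - e))
        if not cl.reverse:
            rs = hl[0].read_pos + (s - hl[1])
            re_ = hr[0].read_pos + (e - hr[1])
            frag = read[max(0, rs) : max(0, re_)]
        else:
            rs = hl[0].read_pos + hl[1] + k - e
            re_ = hr[0].read_pos + hr[1] + k - s
            lo, hi = min(rs, re_), max(rs, re_)
            frag = revcomp(read[max(0, lo) : max(0, hi)])
        if frag:
            slices.append(frag)
    return slices


@dataclass
class LocalDbg:
    k: int
    counts: dict[str, int] = field(default_factory=dict)
    a_L: str = ""
    a_R: str = ""
    pos_L: int = 0   # mosaic position of a_L's first base
    pos_R: int = 0   # mosaic position of a_R's first base

    def successors(self, node: str):
        suf = node[1:]
        for b in _BASES:
            nxt = suf + b
            if nxt in self.counts:
                yield nxt

    def predecessors(self, node: str):
        pre = node[:-1]
        for b in _BASES:
            prv = b + pre
            if prv in self.counts:
                yield prv

    @property
    def expected_coverage(self) -> float:
        return statistics.median(self.counts.values()) if self.counts else 0.0


def assemble_and_anchor(
    pileup: list[str],
    mosaic_seq: str,
    region: CandidateRegion,
    params: DiscoveryParams,
) -> LocalDbg | None:
    """Build the pileup de Bruijn graph and pick flank anchors: the
    outermost left-flank k-mer and outermost right-flank k-mer present in
    the graph.  Missing anchors abort discovery for the region (normal)."""
    k = params.k_dbg
    dbg = LocalDbg(k)
    for s in pileup:
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) <= set(_BASES):
                dbg.counts[kmer] = dbg.counts.get(kmer, 0) + 1
    if not dbg.counts:
        return None
    # scan from the outermost flank inwards (even into the region: k-mers
    # containing the variant are absent from the pileup graph, so the scan
    # stops at the first k-mer the reads actually support)
    a_L = ""
    for i in range(region.pad_start, region.pad_end - k + 1):
        kmer = mosaic_seq[i : i + k]
        if kmer in dbg.counts:
            a_L, dbg.pos_L = kmer, i
            break
    a_R = ""
    for i in range(region.pad_end - k, region.pad_start - 1, -1):
        kmer = mosaic_seq[i : i + k]
        if kmer in dbg.counts:
            a_R, dbg.pos_R = kmer, i
            break
    if not a_L or not a_R or dbg.pos_R < dbg.pos_L:
        return None
    dbg.a_L, dbg.a_R = a_L, a_R
    return dbg


def reverse_bfs_distance_map(dbg: LocalDbg, a_R: str) -> dict[str, int]:
    """Minimum number of edges from each node to the right anchor,
    explored over predecessors; unreachable nodes are absent."""
    dist = {a_R: 0}
    queue = deque([a_R])
    while queue:
        node = queue.popleft()
        for prv in dbg.predecessors(node):
            if prv not in dist:
                dist[prv] = dist[node] + 1
                queue.append(prv)
    return dist


def enumerate_candidate_paths(
    dbg: LocalDbg, params: DiscoveryParams, region_span: int
) -> list[str] | None:
    """DFS all anchor-to-anchor walks with bounded length and a budget of
    low-coverage nodes; if too many survive, the coverage fraction f is
    raised by the step size and enumeration repeats; abandoned (None)
    once f exceeds 1."""
    dist = reverse_bfs_distance_map(dbg, dbg.a_R)
    if dbg.a_L not in dist:
        return None
    max_len = params.max_path_factor * max(region_span, 1)
    e_r = dbg.expected_coverage
    n_iter = 1
    while True:
        f = n_iter * params.step
        if f > 1.0 + 1e-9:
            return None
        thresh = f * e_r
        paths = _dfs_paths(dbg, dist, max_len, thresh, params.low_budget(), params.max_paths)
        if paths is None:  # too many: escalate f
            n_iter += 1
            continue
        return paths


def _dfs_paths(
    dbg: LocalDbg,
    dist: dict[str, int],
    max_len: int,
    low_thresh: float,
    low_budget: int,
    max_paths: int,
) -> list[str] | None:
    out: list[str] = []
    lowstart = 1 if dbg.counts[dbg.a_L] < low_thresh else 0
    stack = [(dbg.a_L, dbg.a_L, lowstart)]
    while stack:
        node, seq, low = stack.pop()
        if node == dbg.a_R:
            out.append(seq)
            if len(out) > max_paths:
                return None
            continue
        walked = len(seq) - len(dbg.a_L)
        for nxt in dbg.successors(node):
            d = dist.get(nxt)
            if d is None or d > max_len - (walked + 1):
                continue
            lo = low + (1 if dbg.counts[nxt] < low_thresh else 0)
            if lo > low_budget:
                continue
            stack.append((nxt, seq + nxt[-1], lo))
    return out


def discover_region_alleles(
    region: CandidateRegion,
    mosaic: MosaicPath,
    clusters: list[HitCluster],
    reads: dict[str, str],
    minimizer_k: int,
    params: DiscoveryParams,
) -> set[str]:
    """Full per-region discovery: pileup, assembly, anchored enumeration;
    returns full-length candidate alleles (mosaic with the anchored slice
    replaced), excluding the mosaic itself."""
    pileup = build_pileup(region, mosaic, clusters, reads, minimizer_k)
    if not pileup:
        return set()
    dbg = assemble_and_anchor(pileup, mosaic.sequence, region, params)
    if dbg is None:
        return set()
    span = region.pad_end - region.pad_start
    paths = enumerate_candidate_paths(dbg, params, span)
    if not paths:
        return set()
    out = set()
    seq = mosaic.sequence
    for p in paths:
        allele = seq[: dbg.pos_L] + p + seq[dbg.pos_R + params.k_dbg :]
        if allele != seq:
            out.add(allele)
    return out
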