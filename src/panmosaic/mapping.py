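"""Quasi-mapping reads to a PanRG by shared minimizers.

Reads are never aligned at base level: each read is sketched with the
same (w,k)-minimizer scheme as the graphs, sketch hashes are looked up in
the global index, and hits from one read to one locus in one orientation
are clustered by read coordinate.  Loci supported by a sufficiently large
cluster are called present, and the hits record per-node strand coverage
on the locus k-mer graph for the downstream mosaic inference.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .index import PanRGIndex
from .kmergraph import KmerGraph
from .sketch import MinimizerParams, StringMinimizer, string_minimizers

DEFAULT_MIN_CLUSTER_HITS = 10
DEFAULT_CLUSTER_FRACTION = 0.2


@dataclass
class ReadSketch:
    read_id: str
    minimizers: list[StringMinimizer]
    length: int


@dataclass(frozen=True)
class Hit:
    read_id: str
    read_pos: int
    locus_id: str
    node_id: int
    reverse: bool  # found in reverse orientation w.r.t. the graph


@dataclass
class HitCluster:
    locus_id: str
    reverse: bool
    hits: list[Hit]

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class PresenceCall:
    locus_id: str
    present: bool
    n_clusters: int = 0
    mean_covg: float = 0.0
    median_covg: float = 0.0


def sketch_read(seq: str, params: MinimizerParams, read_id: str = "") -> ReadSketch:
    """Sketch a read with the index parameters; reads shorter than one
    full window fall back to a single window over their k-mers."""
    mins = string_minimizers(seq.upper(), params, allow_short=True)
    return ReadSketch(read_id, mins, len(seq))


def cluster_hits(hits: Iterable[Hit], max_hit_gap: int) -> list[HitCluster]:
    """Partition one read's hits by (locus, orientation), then split runs
    where adjacent read positions are more than max_hit_gap apart."""
    groups: dict[tuple[str, bool], list[Hit]] = {}
    for h in hits:
        groups.setdefault((h.locus_id, h.reverse), []).append(h)
    clusters = []
    for (locus, rev), hs in sorted(groups.items()):
        hs.sort(key=lambda h: (h.read_pos, h.node_id))
        cur = [hs[0]]
        for h in hs[1:]:
            if h.read_pos - cur[-1].read_pos > max_hit_gap:
                clusters.append(HitCluster(locus, rev, cur))
                cur = []
            cur.append(h)
        clusters.append(HitCluster(locus, rev, cur))
    return clusters


def is_sufficient_cluster(
    cluster: HitCluster,
    kmer_graph: KmerGraph,
    sketch: ReadSketch,
    mode: str,
    min_hits: int = DEFAULT_MIN_CLUSTER_HITS,
    fraction: float = DEFAULT_CLUSTER_FRACTION,
) -> bool:
    """At least ``min_hits`` hits, and at least 1/5 of the shortest k-mer
    graph path (long reads) or of the read sketch size (short reads)."""
    n = len(cluster)
    if n < min_hits:
        return False
    if mode == "long":
        target = kmer_graph.shortest_path_node_count()
    elif mode == "short":
        target = len(sketch.minimizers)
    else:
        raise ValueError("mode must be 'long' or 'short'")
    need = math.ceil(fraction * target - 1e-9)
    return n >= need


def record_coverage(clusters: Iterable[HitCluster], graphs: dict[str, KmerGraph], sample_id: str) -> int:
    """Increment per-node strand coverage for every hit of every
    sufficient cluster; returns the number of increments."""
    n = 0
    for cl in clusters:
        kg = graphs[cl.locus_id]
        for h in cl.hits:
            kg.nodes[h.node_id].add_coverage(sample_id, h.reverse)
            n += 1
    return n


def fill_gap_coverage(
    clusters: Iterable[HitCluster],
    graphs: dict[str, KmerGraph],
    reads: dict[str, str],
    sample_id: str,
    max_gap: int | None = None,
) -> int:
    """Credit k-mer-graph nodes lying between consecutive hits of a read.

    The union-over-paths minimizer definition places some k-mers on a
    walk via windows that mix branches, so a read following that walk
    never samples them in its own sketch ("ghost" minimizers).  Between
    two consecutive hits of one read there is a unique short k-mer-graph
    path whose spelled sequence equals the read fragment; its interior
    nodes are incremented so path coverage reflects the read evidence.
    Returns the number of increments."""
    from .sketch import revcomp

    n = 0
    for cl in clusters:
        kg = graphs[cl.locus_id]
        read = reads.get(cl.hits[0].read_id)
        if read is None:
            continue
        k = kg.params.k
        gap_cap = max_gap if max_gap is not None else 2 * (kg.params.w + k)
        hits = sorted(cl.hits, key=lambda h: h.read_pos)
        for h1, h2 in zip(hits, hits[1:]):
            if h2.read_pos - h1.read_pos > gap_cap or h2.read_pos == h1.read_pos:
                continue
            frag = read[h1.read_pos : h2.read_pos + k]
            if cl.reverse:
                frag = revcomp(frag)
                src, dst = h2.node_id, h1.node_id
            else:
                src, dst = h1.node_id, h2.node_id
            interior = _matching_interior(kg, src, dst, frag)
            for nid in interior:
                kg.nodes[nid].add_coverage(sample_id, cl.reverse)
                n += 1
    return n


def _edge_advance(kg: KmerGraph, u: int, v: int) -> int:
    """Start-position distance between adjacent minimizers u -> v along
    their shared walk (k when v starts right after u ends)."""
    from .kmergraph import _positions_of_placement

    pos_u = _positions_of_placement(kg.nodes[u].placement)
    start_v = _positions_of_placement(kg.nodes[v].placement)[0]
    if start_v in pos_u:
        return pos_u.index(start_v)
    return kg.params.k


def _matching_interior(kg: KmerGraph, src: int, dst: int, frag: str) -> list[int]:
    """Interior nodes of the src->dst k-mer-graph path spelling ``frag``."""
    k = kg.params.k
    if kg.nodes[src].seq != frag[:k]:
        return []
    stack: list[tuple[int, int, list[int]]] = [(src, 0, [])]
    # state: (node, start offset of node's k-mer in frag, interior so far)
    while stack:
        node, off, interior = stack.pop()
        if node == dst:
            if off + k == len(frag):
                return interior
            continue
        for nxt in kg.succ[node]:
            nd = kg.nodes[nxt]
            if nd.is_terminal:
                continue
            adv = _edge_advance(kg, node, nxt)
            end = off + adv + k
            if end > len(frag):
                continue
            if frag[off + adv : end] == nd.seq:
                stack.append((nxt, off + adv, interior if nxt == dst else interior + [nxt]))
    return []


@dataclass
class MappingResult:
    """Per-sample outcome of quasi-mapping: sufficient clusters per locus
    and the presence calls (pre coverage-filter)."""

    sample_id: str
    clusters: dict[str, list[HitCluster]] = field(default_factory=dict)
    n_reads: int = 0
    n_hits_recorded: int = 0

    @property
    def candidate_loci(self) -> list[str]:
        return sorted(self.clusters)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ file (optionally gzipped)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].split()[0], seq


def map_sample(
    reads: Iterable[tuple[str, str]],
    index: PanRGIndex,
    graphs: dict[str, KmerGraph],
    sample_id: str,
    mode: str = "long",
    max_hit_gap: int | None = None,
    min_hits: int = DEFAULT_MIN_CLUSTER_HITS,
    fraction: float = DEFAULT_CLUSTER_FRACTION,
) -> MappingResult:
    """Quasi-map a read set: sketch, hit, cluster, filter, record coverage."""
    params = index.params
    reads = list(reads)
    if max_hit_gap is None:
        max_hit_gap = 2 * (params.w + params.k)
    # node strand lookup per locus
    strand_of = {
        locus: {n.id: n.strand for n in kg.real_nodes} for locus, kg in graphs.items()
    }
    result = MappingResult(sample_id)
    for read_id, seq in reads:
        result.n_reads += 1
        sketch = sketch_read(seq, params, read_id)
        hits = []
        for m in sketch.minimizers:
            for locus, node in index.lookup(m.hash):
                rev = bool(m.strand != strand_of[locus][node])
                hits.append(Hit(read_id, m.pos, locus, node, rev))
        if not hits:
            continue
        for cl in cluster_hits(hits, max_hit_gap):
            if is_sufficient_cluster(cl, graphs[cl.locus_id], sketch, mode, min_hits, fraction):
                result.clusters.setdefault(cl.locus_id, []).append(cl)
    for locus, cls in result.clusters.items():
        result.n_hits_recorded += record_coverage(cls, graphs, sample_id)
    if result.clusters:
        read_dict = dict(reads)
        for locus, cls in result.clusters.items():
            fill_gap_coverage(cls, graphs, read_dict, sample_id)
    return result


def filter_present_loci(
    calls: dict[str, PresenceCall],
    min_rel_cov: float = 0.05,
    min_abs_cov: float = 3.0,
) -> dict[str, PresenceCall]:
    """Post-hoc coverage filter: loci whose inferred-sequence coverage is
    far below the global average are marked absent (false positive seeds).

    ``calls`` must carry mean/median coverage along the inferred mosaic;
    the global average is the mean of per-locus means over present loci.
    """
    present = [c for c in calls.values() if c.present]
    if not present:
        return calls
    global_avg = sum(c.mean_covg for c in present) / len(present)
    for c in present:
        low = min(c.mean_covg, c.median_covg)
        if low < min_rel_cov * global_avg or low < min_abs_cov:
            c.present = False
    return calls
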