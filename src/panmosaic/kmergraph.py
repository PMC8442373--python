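"""(w,k)-minimizers of local graphs and the induced k-mer graph.

The minimizers of a DAG are the union of window minimizers over all walks
of w + k - 1 bases.  Each minimizer becomes a node of the k-mer graph;
an edge joins u to v when v is the first minimizer after u on some walk.
For w <= k the k-mer graph determines walk sequences uniquely outside the
first and last w + k - 1 bases, which is what makes quasi-mapping and
mosaic path inference possible without base-level alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .construct import LocalGraph
from .sketch import MinimizerParams, canonical_kmer, kmer_hash

Position = tuple[int, int]            # (local-graph node id, base offset)
PlacementPiece = tuple[int, int, int]  # (node id, start offset, end offset)
Placement = tuple[PlacementPiece, ...]


@dataclass(frozen=True)
class GraphMinimizer:
    """A minimizing k-mer placed on a local graph."""

    hash: int
    placement: Placement
    strand: int  # 0: canonical k-mer read along the walk; 1: its revcomp

    @property
    def start(self) -> Position:
        n, s, _ = self.placement[0]
        return (n, s)

    @property
    def end(self) -> Position:
        n, _, e = self.placement[-1]
        return (n, e - 1)


def _positions_of_placement(p: Placement) -> list[Position]:
    out = []
    for node, s, e in p:
        out.extend((node, o) for o in range(s, e))
    return out


def _placement_of_positions(pos: list[Position]) -> Placement:
    pieces: list[list[int]] = []
    for node, off in pos:
        if pieces and pieces[-1][0] == node and pieces[-1][2] == off:
            pieces[-1][2] = off + 1
        else:
            pieces.append([node, off, off + 1])
    return tuple((a, b, c) for a, b, c in pieces)


class GraphWalker:
    """Base-position navigation over a local graph (skipping empty nodes)."""

    def __init__(self, g: LocalGraph):
        self.g = g
        order = g.topological_order()
        self.topo_index = {n: i for i, n in enumerate(order)}
        self._next_entry: dict[int, list[Position]] = {}
        self._prev_entry: dict[int, list[Position]] = {}
        self._next_reaches_end: dict[int, bool] = {}
        self._prev_reaches_start: dict[int, bool] = {}
        for n in reversed(order):
            entries: list[Position] = []
            reaches = n == g.sink
            for s in g.succ[n]:
                if g.nodes[s]:
                    entries.append((s, 0))
                else:
                    entries.extend(self._next_entry[s])
                    reaches = reaches or self._next_reaches_end[s]
            self._next_entry[n] = entries
            self._next_reaches_end[n] = reaches
        for n in order:
            entries = []
            reaches = n == g.source
            for p in g.pred[n]:
                if g.nodes[p]:
                    entries.append((p, len(g.nodes[p]) - 1))
                else:
                    entries.extend(self._prev_entry[p])
                    reaches = reaches or self._prev_reaches_start[p]
            self._prev_entry[n] = entries
            self._prev_reaches_start[n] = reaches

    def base(self, pos: Position) -> str:
        return self.g.nodes[pos[0]][pos[1]]

    def next_positions(self, pos: Position) -> list[Position]:
        node, off = pos
        if off + 1 < len(self.g.nodes[node]):
            return [(node, off + 1)]
        return self._next_entry[node]

    def at_end(self, pos: Position) -> bool:
        node, off = pos
        if off + 1 < len(self.g.nodes[node]):
            return False
        return self._next_reaches_end[node]

    def prev_positions(self, pos: Position) -> list[Position]:
        node, off = pos
        if off > 0:
            return [(node, off - 1)]
        return self._prev_entry[node]

    def at_start(self, pos: Position) -> bool:
        node, off = pos
        if off > 0:
            return False
        return self._prev_reaches_start[node]

    def first_positions(self) -> list[Position]:
        src = self.g.source
        if self.g.nodes[src]:
            return [(src, 0)]
        return self._next_entry[src]

    def all_positions(self) -> list[Position]:
        out = []
        for n in sorted(self.g.nodes, key=self.topo_index.get):
            out.extend((n, o) for o in range(len(self.g.nodes[n])))
        return out

    def longest_path_bases(self) -> int:
        order = sorted(self.g.nodes, key=self.topo_index.get)
        best = {n: 0 for n in self.g.nodes}
        for n in order:
            ln = best[n] + len(self.g.nodes[n])
            for s in self.g.succ[n]:
                best[s] = max(best[s], ln)
        return best[self.g.sink]


def _windows_from(walker: GraphWalker, start: Position, length: int):
    """All base-paths of exactly ``length`` positions starting at ``start``."""
    stack = [[start]]
    while stack:
        path = stack.pop()
        if len(path) == length:
            yield path
            continue
        for nxt in walker.next_positions(path[-1]):
            stack.append(path + [nxt])


def _full_paths(walker: GraphWalker):
    stack = [[p] for p in walker.first_positions()]
    if not stack:
        yield []
        return
    while stack:
        path = stack.pop()
        nxts = walker.next_positions(path[-1])
        if walker.at_end(path[-1]):
            yield path
        for nxt in nxts:
            stack.append(path + [nxt])


def _window_minimizers(
    walker: GraphWalker, path: list[Position], params: MinimizerParams
) -> list[GraphMinimizer]:
    s = "".join(walker.base(p) for p in path)
    k = params.k
    nkmers = len(s) - k + 1
    if nkmers < 1:
        return []
    best: Optional[int] = None
    args: list[tuple[int, int]] = []
    for i in range(nkmers):
        kmer = s[i : i + k]
        canon, strand = canonical_kmer(kmer)
        h = kmer_hash(canon)
        if best is None or h < best:
            best, args = h, [(i, strand)]
        elif h == best:
            args.append((i, strand))
    out = []
    for i, strand in args:
        placement = _placement_of_positions(path[i : i + k])
        out.append(GraphMinimizer(best, placement, strand))
    return out


def graph_minimizers(g: LocalGraph, params: MinimizerParams) -> set[GraphMinimizer]:
    """Union of (w,k)-minimizers over all length-(w+k-1) walks of the graph.

    Graphs whose longest walk is shorter than one full window are indexed
    by treating every full source-to-sink walk as a single window, so that
    short intergenic loci remain findable.
    """
    walker = GraphWalker(g)
    L = params.w + params.k - 1
    out: set[GraphMinimizer] = set()
    if walker.longest_path_bases() < L:
        for path in _full_paths(walker):
            if path:
                out.update(_window_minimizers(walker, path, params))
        return out
    for start in walker.all_positions():
        for path in _windows_from(walker, start, L):
            out.update(_window_minimizers(walker, path, params))
    return out


# ---------------------------------------------------------------------------
# k-mer graph


class KmerNode:
    __slots__ = ("id", "hash", "placement", "strand", "seq", "coverage")

    def __init__(self, nid: int, minimizer: Optional[GraphMinimizer], seq: str):
        self.id = nid
        self.hash = minimizer.hash if minimizer else -1
        self.placement = minimizer.placement if minimizer else ()
        self.strand = minimizer.strand if minimizer else 0
        self.seq = seq  # k bases read along the walk (graph orientation)
        self.coverage: dict[str, list[int]] = {}  # sample -> [fwd, rev]

    @property
    def is_terminal(self) -> bool:
        return not self.placement

    def covg(self, sample: str) -> int:
        c = self.coverage.get(sample)
        return (c[0] + c[1]) if c else 0

    def add_coverage(self, sample: str, reverse: bool, n: int = 1) -> None:
        c = self.coverage.setdefault(sample, [0, 0])
        c[1 if reverse else 0] += n


class KmerGraph:
    """DAG over the minimizers of one local graph, with a synthetic source
    (id 0) and sink (last id); carries per-sample strand coverage."""

    def __init__(self, locus_id: str, params: MinimizerParams):
        self.locus_id = locus_id
        self.params = params
        self.nodes: list[KmerNode] = []
        self.succ: dict[int, list[int]] = {}
        self.pred: dict[int, list[int]] = {}

    def _add(self, minimizer: Optional[GraphMinimizer], seq: str) -> KmerNode:
        node = KmerNode(len(self.nodes), minimizer, seq)
        self.nodes.append(node)
        self.succ[node.id] = []
        self.pred[node.id] = []
        return node

    def add_edge(self, a: int, b: int) -> None:
        if b not in self.succ[a]:
            self.succ[a].append(b)
            self.pred[b].append(a)

    @property
    def source(self) -> int:
        return 0

    @property
    def sink(self) -> int:
        return len(self.nodes) - 1

    @property
    def real_nodes(self) -> list[KmerNode]:
        return [n for n in self.nodes if not n.is_terminal]

    def topological_order(self) -> list[int]:
        indeg = {n.id: len(self.pred[n.id]) for n in self.nodes}
        stack = sorted([i for i, d in indeg.items() if d == 0])
        order = []
        while stack:
            n = stack.pop(0)
            order.append(n)
            for s in self.succ[n]:
                indeg[s] -= 1
                if indeg[s] == 0:
                    stack.append(s)
            stack.sort()
        if len(order) != len(self.nodes):
            raise ValueError("k-mer graph contains a cycle")
        return order

    def shortest_path_node_count(self) -> int:
        """Number of real minimizer nodes on the sparsest source-sink path."""
        INF = 10**9
        dist = {n.id: INF for n in self.nodes}
        dist[self.source] = 0
        for n in self.topological_order():
            if dist[n] == INF:
                continue
            w = 0 if self.nodes[n].is_terminal else 1
            for s in self.succ[n]:
                if dist[n] + w < dist[s]:
                    dist[s] = dist[n] + w
        d = dist[self.sink]
        return 0 if d >= INF else d

    def reset_coverage(self, sample: str | None = None) -> None:
        for n in self.nodes:
            if sample is None:
                n.coverage = {}
            else:
                n.coverage.pop(sample, None)


def _walk_to_first_minimizer(
    walker: GraphWalker,
    by_start: dict[Position, list[GraphMinimizer]],
    init_path: list[Position],
    init_candidates: bool,
) -> tuple[set[Placement], bool]:
    """Walk forward collecting, per branch, the first minimizer whose whole
    placement lies on the walk; returns (their placements, reaches_end).

    ``init_path`` seeds the walk (a placement to follow, or a single first
    base); candidates starting inside it are tracked, completing only once
    their k bases are all walked and matched.
    """
    found: set[Placement] = set()
    reaches_end = False
    k = len(_positions_of_placement(next(iter(by_start.values()))[0].placement)) if by_start else 0

    # active candidate: (positions list, matched_count)
    def new_cands(pos: Position) -> list[list[Position]]:
        return [_positions_of_placement(m.placement) for m in by_start.get(pos, [])]

    start_t = 1 if init_candidates else 0
    active: list[tuple[list[Position], int]] = []
    for t in range(start_t, len(init_path)):
        pos = init_path[t]
        active = [(c, m + 1) for c, m in active if c[m] == pos]
        for c in new_cands(pos):
            active.append((c, 1))
    # none can have completed inside init_path (candidates end beyond it)
    stack = [(init_path[-1], active)]
    seen = set()
    while stack:
        pos, active = stack.pop()
        key = (pos, tuple((tuple(c[0]), c[1]) for c in active))
        if key in seen:
            continue
        seen.add(key)
        nxts = walker.next_positions(pos)
        if walker.at_end(pos):
            reaches_end = True
        for nxt in nxts:
            cont = [(c, m + 1) for c, m in active if c[m] == nxt]
            done = [c for c, m in cont if m == len(c)]
            if done:
                for c in done:
                    found.add(_placement_of_positions(c))
                continue
            cont = cont + [(c, 1) for c in new_cands(nxt)]
            done2 = [c for c, m in cont if m == len(c)]
            if done2:  # k == 1 corner case
                for c in done2:
                    found.add(_placement_of_positions(c))
                continue
            stack.append((nxt, cont))
    return found, reaches_end


def build_kmer_graph(
    g: LocalGraph, mins: Iterable[GraphMinimizer], params: MinimizerParams
) -> KmerGraph:
    """Assemble the k-mer graph: nodes are minimizers, edges join each
    minimizer to the first minimizer(s) after it along local-graph walks;
    a synthetic empty source and sink bracket the DAG."""
    walker = GraphWalker(g)
    mins = list(mins)
    order_key = {}
    for m in mins:
        n0, s0 = m.start
        order_key[m] = (walker.topo_index[n0], s0, m.placement)
    mins.sort(key=order_key.get)

    kg = KmerGraph(g.locus_id, params)
    source = kg._add(None, "")
    id_of: dict[Placement, int] = {}
    for m in mins:
        seq = "".join(walker.base(p) for p in _positions_of_placement(m.placement))
        id_of[m.placement] = kg._add(m, seq).id

    by_start: dict[Position, list[GraphMinimizer]] = {}
    for m in mins:
        by_start.setdefault(m.start, []).append(m)

    sink_pending = []
    for m in mins:
        path = _positions_of_placement(m.placement)
        nexts, reaches_end = _walk_to_first_minimizer(walker, by_start, path, True)
        for p in nexts:
            kg.add_edge(id_of[m.placement], id_of[p])
        if reaches_end or not nexts:
            sink_pending.append(id_of[m.placement])

    firsts: set[Placement] = set()
    src_reaches_end = False
    for p0 in walker.first_positions():
        f, re_ = _walk_to_first_minimizer(walker, by_start, [p0], False)
        # candidates may start at the very first base
        for m in by_start.get(p0, []):
            cand = _positions_of_placement(m.placement)
            # verify the placement is walkable from p0 (it is, by construction)
            f.add(m.placement)
            # a minimizer starting at the first base pre-empts later ones on
            # walks that follow its placement; keep both conservatively
        firsts.update(f)
        src_reaches_end = src_reaches_end or re_
    sink = None
    for p in firsts:
        kg.add_edge(kg.source, id_of[p])
    sink = kg._add(None, "")
    for nid in sink_pending:
        kg.add_edge(nid, sink.id)
    if not mins:
        kg.add_edge(kg.source, sink.id)
    return kg


def minimizers_and_kmer_graph(
    g: LocalGraph, params: MinimizerParams
) -> tuple[set[GraphMinimizer], KmerGraph]:
    mins = graph_minimizers(g, params)
    return mins, build_kmer_graph(g, mins, params)
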