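"""Local graph construction from MSAs by recursive cluster-and-collapse.

Each locus graph is built by recursively partitioning the alignment
*vertically* into match / non-match column intervals and *horizontally*
(within non-match intervals) into K-means clusters of similar alleles,
until every remaining sub-alignment is either collapsed to the single
sequence it represents or enumerated as one node per unique sequence.
The recursion tree is memoized so that novel alleles discovered later can
be routed to the leaf where they belong and only that leaf recomputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from sklearn.cluster import KMeans

from .msa import Msa, degap, ref_of_alignment

_DNA = frozenset("ACGT")


@dataclass
class RccParams:
    """Tunable knobs of the recursive cluster-and-collapse construction."""

    min_match_len: int = 7      # m: minimum columns for a match interval
    max_hamming_frac: float = 0.2  # d: one-reference-like threshold
    max_clusters: int = 10      # K-means tried for K = 2..max_clusters
    max_recursion: int = 5      # r: recursion depth cap

    def __post_init__(self) -> None:
        if self.min_match_len < 1:
            raise ValueError("min_match_len must be >= 1")
        if not 0 < self.max_hamming_frac < 1:
            raise ValueError("max_hamming_frac must be in (0,1)")
        if self.max_clusters < 2:
            raise ValueError("max_clusters must be >= 2")
        if self.max_recursion < 1:
            raise ValueError("max_recursion must be >= 1")


@dataclass(frozen=True)
class Interval:
    start: int
    end: int
    kind: str  # "match" | "non-match"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("interval must satisfy 0 <= start < end")
        if self.kind not in ("match", "non-match"):
            raise ValueError("kind must be 'match' or 'non-match'")


def _slice_is_match(rows: Sequence[str], i: int, j: int) -> bool:
    """True iff the column slice [i, j) has exactly one distinct non-empty
    de-gapped sequence (gap-only rows are allowed alongside it)."""
    seqs = {degap(r[i:j]) for r in rows}
    seqs.discard("")
    return len(seqs) == 1


def find_intervals(msa: Msa, params: RccParams) -> list[Interval]:
    """Tile the alignment columns into maximal match runs (>= m columns,
    single non-trivial de-gapped sequence) and the remaining non-match runs.

    The scan is greedy left-to-right: from each start column the run is
    extended to the farthest end column still satisfying the match
    criterion (gap-shifted slices may transiently disagree and re-agree,
    so each candidate end is tested, not just the first failure).
    """
    rows = msa.rows
    n = msa.n_cols
    m = params.min_match_len
    is_match_col = [False] * n
    matches: list[tuple[int, int]] = []
    i = 0
    while i < n:
        best_j = _scan_maximal_match(rows, i, n)
        if best_j - i >= m:
            matches.append((i, best_j))
            for c in range(i, best_j):
                is_match_col[c] = True
            i = best_j
        else:
            i += 1
    # coalesce the remaining columns into non-match intervals
    out: list[Interval] = []
    mi = 0
    c = 0
    while c < n:
        if mi < len(matches) and matches[mi][0] == c:
            out.append(Interval(matches[mi][0], matches[mi][1], "match"))
            c = matches[mi][1]
            mi += 1
        else:
            start = c
            while c < n and not is_match_col[c]:
                c += 1
            out.append(Interval(start, c, "non-match"))
    return out


def _scan_maximal_match(rows: Sequence[str], i: int, n: int) -> int:
    """Largest j such that [i, j) satisfies the match criterion; i if none.

    Incremental: tracks each row's de-gapped slice against a growing
    consensus.  A row is permanently inconsistent once it disagrees on
    content; rows lagging by trailing gaps may still catch up.
    """
    consensus: list[str] = []
    plen = [0] * len(rows)
    bad = [False] * len(rows)
    best = i
    j = i
    while j < n:
        col = j
        for ri, r in enumerate(rows):
            ch = r[col]
            if ch not in _DNA:
                continue
            p = plen[ri]
            if p < len(consensus):
                if ch != consensus[p]:
                    bad[ri] = True
            else:
                consensus.append(ch)
            plen[ri] += 1
        j += 1
        if any(bad):
            # content mismatch can never heal; keep best found so far
            break
        if consensus and all(p == len(consensus) for p, b in zip(plen, bad) if p > 0):
            # every non-empty row currently spells the full consensus
            if any(p > 0 for p in plen):
                best = j
    return best


def _hamming_to_ref(row: str, ref: str, ref_cols: Sequence[int]) -> int:
    """Mismatches between an aligned row and the modal reference, counted
    over the alignment columns where the reference has a base."""
    return sum(1 for rp, c in enumerate(ref_cols) if row[c] != ref[rp])


def _ref_columns(rows: Sequence[str]) -> list[int]:
    """Alignment columns contributing a base to ref(A) (not all-gap)."""
    cols = []
    for c in range(len(rows[0])):
        if any(r[c] in _DNA for r in rows):
            cols.append(c)
    return cols


def is_one_reference_like(sub_msas: Iterable[Msa], d: float) -> bool:
    """True iff in every sub-alignment every row is within d * len(A)
    mismatches of that sub-alignment's modal reference."""
    for sub in sub_msas:
        ref = ref_of_alignment(sub)
        cols = _ref_columns(sub.rows)
        thresh = d * sub.n_cols
        for row in sub.rows:
            if _hamming_to_ref(row, ref, cols) >= thresh:
                return False
    return True


def _mmer_vectors(seqs: Sequence[str], m: int) -> np.ndarray:
    universe = sorted({s[i : i + m] for s in seqs for i in range(len(s) - m + 1)})
    pos = {u: i for i, u in enumerate(universe)}
    X = np.zeros((len(seqs), max(len(universe), 1)))
    for r, s in enumerate(seqs):
        for i in range(len(s) - m + 1):
            X[r, pos[s[i : i + m]]] += 1
    return X


def cluster_rows(msa: Msa, params: RccParams, seed: int = 42) -> list[list[int]]:
    """Partition rows by K-means on m-mer count vectors of the de-gapped
    sequences, growing K from 2 until the partition is one-reference-like
    or K reaches the cap (the capped partition is then accepted)."""
    degs = msa.degapped()
    distinct = sorted(set(degs))
    if len(distinct) < 2:
        return [list(range(msa.n_rows))]
    X = _mmer_vectors(distinct, params.min_match_len)
    kmax = min(params.max_clusters, len(distinct))
    partition: list[list[int]] = [list(range(msa.n_rows))]
    import warnings

    for K in range(2, kmax + 1):
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        with warnings.catch_warnings():
            # duplicate m-mer vectors (e.g. all shorter than m) collapse clusters
            warnings.simplefilter("ignore")
            labels = km.fit_predict(X)
        seq_label = {s: l for s, l in zip(distinct, labels)}
        groups: dict[int, list[int]] = {}
        for ri, s in enumerate(degs):
            groups.setdefault(seq_label[s], []).append(ri)
        # order clusters deterministically by smallest member row
        partition = sorted(groups.values(), key=lambda g: g[0])
        subs = [msa.subset_rows(g) for g in partition]
        if is_one_reference_like(subs, params.max_hamming_frac):
            return partition
    return partition


# ---------------------------------------------------------------------------
# Recursion tree


@dataclass
class RccNode:
    """One node of the memoized recursion tree.

    kinds: ``vertical`` (children = column intervals), ``horizontal``
    (children = row clusters), ``match`` (collapsed single sequence) and
    ``seqs`` (leaf enumerating unique de-gapped sequences).
    """

    kind: str
    depth: int
    children: list["RccNode"] = field(default_factory=list)
    intervals: list[Interval] = field(default_factory=list)  # vertical only
    seq: str = ""               # match only
    has_empty: bool = False     # match only: some rows de-gap to ""
    seqs: list[str] = field(default_factory=list)  # seqs leaf only
    rep_seqs: list[str] = field(default_factory=list)  # routing representatives
    ref: str = ""               # vertical only: modal reference of sub-alignment
    ref_spans: list[tuple[int, int]] = field(default_factory=list)  # vertical

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "depth": self.depth,
            "children": [c.to_dict() for c in self.children],
            "intervals": [[iv.start, iv.end, iv.kind] for iv in self.intervals],
            "seq": self.seq,
            "has_empty": self.has_empty,
            "seqs": self.seqs,
            "rep_seqs": self.rep_seqs,
            "ref": self.ref,
            "ref_spans": [list(s) for s in self.ref_spans],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RccNode":
        return cls(
            kind=d["kind"],
            depth=d["depth"],
            children=[cls.from_dict(c) for c in d["children"]],
            intervals=[Interval(*iv) for iv in d["intervals"]],
            seq=d["seq"],
            has_empty=d["has_empty"],
            seqs=d["seqs"],
            rep_seqs=d["rep_seqs"],
            ref=d["ref"],
            ref_spans=[tuple(s) for s in d["ref_spans"]],
        )


def _build_vertical(msa: Msa, depth: int, params: RccParams, seed: int) -> RccNode:
    degs = msa.degapped()
    distinct_nonempty = {s for s in degs if s}
    if depth >= params.max_recursion or len(distinct_nonempty) <= 1:
        return _seqs_leaf(degs, depth)
    intervals = find_intervals(msa, params)
    if len(intervals) == 1 and intervals[0].kind == "non-match":
        # nothing collapsible at this level: go straight to clustering
        return _build_horizontal(msa, depth, params, seed)
    node = RccNode("vertical", depth, rep_seqs=sorted(set(degs)))
    node.intervals = intervals
    spans = []
    ref_parts = []
    for iv in intervals:
        sub = msa.slice_cols(iv.start, iv.end)
        part = ref_of_alignment(sub)
        spans.append((sum(len(p) for p in ref_parts), sum(len(p) for p in ref_parts) + len(part)))
        ref_parts.append(part)
        if iv.kind == "match":
            sub_degs = {degap(r) for r in sub.rows}
            has_empty = "" in sub_degs
            sub_degs.discard("")
            (seq,) = sub_degs
            node.children.append(
                RccNode("match", depth, seq=seq, has_empty=has_empty, rep_seqs=[seq])
            )
        else:
            node.children.append(_build_horizontal(sub, depth, params, seed))
    node.ref = "".join(ref_parts)
    node.ref_spans = spans
    return node


def _build_horizontal(msa: Msa, depth: int, params: RccParams, seed: int) -> RccNode:
    degs = msa.degapped()
    distinct_nonempty = {s for s in degs if s}
    if len(distinct_nonempty) <= 1 or depth + 1 >= params.max_recursion:
        return _seqs_leaf(degs, depth)
    partition = cluster_rows(msa, params, seed)
    if len(partition) <= 1:
        return _seqs_leaf(degs, depth)
    node = RccNode("horizontal", depth, rep_seqs=sorted(set(degs)))
    for group in partition:
        node.children.append(_build_vertical(msa.subset_rows(group), depth + 1, params, seed))
    return node


def _seqs_leaf(degs: Sequence[str], depth: int) -> RccNode:
    uniq = sorted(set(degs))
    return RccNode("seqs", depth, seqs=uniq, rep_seqs=list(uniq))


# ---------------------------------------------------------------------------
# Local graph


class LocalGraph:
    """Directed acyclic sequence graph of one locus.

    Node 0 is an empty source and the highest id an empty sink; every
    source-to-sink path concatenation spells one recombinant allele.
    """

    def __init__(self, locus_id: str):
        self.locus_id = locus_id
        self.nodes: dict[int, str] = {}
        self.succ: dict[int, list[int]] = {}
        self.pred: dict[int, list[int]] = {}

    # -- construction ------------------------------------------------------
    def add_node(self, seq: str) -> int:
        nid = len(self.nodes)
        self.nodes[nid] = seq
        self.succ[nid] = []
        self.pred[nid] = []
        return nid

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

    # -- queries -----------------------------------------------------------
    def topological_order(self) -> list[int]:
        indeg = {n: len(self.pred[n]) for n in self.nodes}
        stack = sorted([n for n, d in indeg.items() if d == 0])
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
            raise ValueError("graph contains a cycle")
        return order

    def is_acyclic(self) -> bool:
        try:
            self.topological_order()
            return True
        except ValueError:
            return False

    def spells(self, seq: str) -> bool:
        """Does some source-to-sink path concatenate exactly to ``seq``?"""
        seen = set()
        stack = [(self.source, 0)]
        while stack:
            node, pos = stack.pop()
            if (node, pos) in seen:
                continue
            seen.add((node, pos))
            s = self.nodes[node]
            if seq[pos : pos + len(s)] != s:
                continue
            end = pos + len(s)
            if node == self.sink:
                if end == len(seq):
                    return True
                continue
            for nxt in self.succ[node]:
                stack.append((nxt, end))
        return False

    def path_sequences(self, limit: int = 10000) -> set[str]:
        """All spelled source-to-sink sequences (for small test graphs)."""
        out: set[str] = set()
        stack = [(self.source, "")]
        while stack:
            node, acc = stack.pop()
            acc = acc + self.nodes[node]
            if node == self.sink:
                out.add(acc)
                if len(out) > limit:
                    raise ValueError("too many paths")
                continue
            for nxt in self.succ[node]:
                stack.append((nxt, acc))
        return out

    # -- serialization -----------------------------------------------------
    def to_gfa(self) -> str:
        lines = [f"H\tVN:Z:1.0\tLI:Z:{self.locus_id}"]
        for nid in sorted(self.nodes):
            seq = self.nodes[nid] or "*"
            lines.append(f"S\t{nid}\t{seq}")
        for a in sorted(self.succ):
            for b in self.succ[a]:
                lines.append(f"L\t{a}\t+\t{b}\t+\t0M")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_gfa(cls, text: str) -> "LocalGraph":
        locus = ""
        segs: dict[int, str] = {}
        links: list[tuple[int, int]] = []
        for line in text.strip().splitlines():
            parts = line.split("\t")
            if parts[0] == "H":
                for tag in parts[1:]:
                    if tag.startswith("LI:Z:"):
                        locus = tag[5:]
            elif parts[0] == "S":
                seq = "" if parts[2] == "*" else parts[2]
                segs[int(parts[1])] = seq
            elif parts[0] == "L":
                links.append((int(parts[1]), int(parts[3])))
        g = cls(locus)
        for nid in sorted(segs):
            assert g.add_node(segs[nid]) == nid
        for a, b in links:
            g.add_edge(a, b)
        return g


def _emit(node: RccNode, g: LocalGraph) -> tuple[list[int], list[int]]:
    """Pre-order emission of the recursion tree into graph nodes; returns
    (head ids, tail ids) of the emitted subgraph."""
    if node.kind == "match":
        nid = g.add_node(node.seq)
        ids = [nid]
        if node.has_empty:
            ids.append(g.add_node(""))
        return ids, ids
    if node.kind == "seqs":
        ids = [g.add_node(s) for s in node.seqs]
        return ids, ids
    if node.kind == "horizontal":
        heads: list[int] = []
        tails: list[int] = []
        for child in node.children:
            h, t = _emit(child, g)
            heads.extend(h)
            tails.extend(t)
        return heads, tails
    # vertical: chain the interval subgraphs
    heads: list[int] = []
    prev_tails: list[int] = []
    for idx, child in enumerate(node.children):
        h, t = _emit(child, g)
        if idx == 0:
            heads = h
        else:
            for a in prev_tails:
                for b in h:
                    g.add_edge(a, b)
        prev_tails = t
    return heads, prev_tails


def tree_to_graph(tree: RccNode, locus_id: str) -> LocalGraph:
    g = LocalGraph(locus_id)
    g.add_node("")  # source
    heads, tails = _emit(tree, g)
    sink = g.add_node("")
    for h in heads:
        g.add_edge(g.source, h)
    for t in tails:
        g.add_edge(t, sink)
    return g


def build_local_graph(
    msa: Msa, params: RccParams | None = None, seed: int = 42
) -> tuple[LocalGraph, RccNode]:
    """Build the local graph and its memoized recursion tree from an MSA."""
    params = params or RccParams()
    tree = _build_vertical(msa, 0, params, seed)
    return tree_to_graph(tree, msa.locus_id), tree


# ---------------------------------------------------------------------------
# Updating with new alleles


def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def _pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences, returning gapped rows of equal length."""
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    res = edlib.align(a, b, task="path", mode="NW")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def _ref_to_query_map(query: str, ref: str) -> list[int]:
    """For each reference position p (and p == len(ref)), the number of
    query characters consumed before reaching p in a global alignment."""
    if not ref:
        return [len(query)]
    if not query:
        return [0] * (len(ref) + 1)
    res = edlib.align(query, ref, task="path", mode="NW")
    cig = res["cigar"]
    mapping = [0] * (len(ref) + 1)
    qpos = rpos = 0
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            for _ in range(ln):
                mapping[rpos] = qpos
                qpos += 1
                rpos += 1
        elif ch == "I":  # in query only
            qpos += ln
        elif ch == "D":  # in reference only
            for _ in range(ln):
                mapping[rpos] = qpos
                rpos += 1
    mapping[len(ref)] = len(query)
    return mapping


def _route(node: RccNode, allele: str, params: RccParams, seed: int) -> RccNode:
    """Insert one (sub-)allele into the subtree; returns the (possibly
    replaced) subtree node."""
    if node.kind == "seqs":
        if allele not in node.seqs:
            node.seqs = sorted(set(node.seqs) | {allele})
            node.rep_seqs = list(node.seqs)
        return node
    if node.kind == "match":
        if allele == node.seq:
            return node
        if allele == "":
            node.has_empty = True
            return node
        # the collapsed interval splits: realign and recompute locally
        ra, rb = _pairwise_align(node.seq, allele)
        rows = [ra, rb]
        ids = ["collapsed", "novel"]
        if node.has_empty:
            rows.append("-" * len(ra))
            ids.append("empty")
        sub = Msa(rows, ids)
        return _build_vertical(sub, node.depth, params, seed)
    if node.kind == "horizontal":
        dists = [
            min(_edit_distance(allele, s) for s in child.rep_seqs) if child.rep_seqs else len(allele)
            for child in node.children
        ]
        best = int(np.argmin(dists))
        node.children[best] = _route(node.children[best], allele, params, seed)
        return node
    # vertical: split the allele over the child intervals via the reference
    mapping = _ref_to_query_map(allele, node.ref)
    for idx, child in enumerate(node.children):
        rs, re = node.ref_spans[idx]
        piece = allele[mapping[rs] : mapping[re]]
        node.children[idx] = _route(child, piece, params, seed)
    if allele not in node.rep_seqs:
        node.rep_seqs = sorted(set(node.rep_seqs) | {allele})
    return node


def update_local_graph(
    tree: RccNode,
    new_alleles: Iterable[str],
    locus_id: str = "",
    params: RccParams | None = None,
    seed: int = 42,
) -> tuple[LocalGraph, RccNode]:
    """Route new alleles into the memoized recursion tree and re-emit the
    graph.  Previously spellable sequences remain spellable; each new
    allele becomes spellable."""
    params = params or RccParams()
    for allele in new_alleles:
        allele = degap(allele)
        tree = _route(tree, allele, params, seed)
    return tree_to_graph(tree, locus_id), tree


def save_tree(tree: RccNode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree.to_dict()))


def load_tree(path: str | Path) -> RccNode:
    return RccNode.from_dict(json.loads(Path(path).read_text()))
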