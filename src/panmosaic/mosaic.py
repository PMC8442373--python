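"""Mosaic sequence inference: the maximum-likelihood path through a k-mer graph.

Per-node k-mer coverage is modelled as negative binomial (overdispersed
Poisson: r failures-to-success count, p success probability, so the mean
is (1-p)r/p and the variance (1-p)r/p^2).  The score of a source-to-sink
path sums the log pmf of every minimizer node's coverage and averages by
min(M, path length): capping the denominator keeps scores comparable
across loci of very different lengths without leaving distal nodes
unscored.  The maximizing path — the sample's closest mosaic of panel
sequences — is found by dynamic programming over the DAG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .construct import LocalGraph
from .kmergraph import (
    GraphWalker,
    KmerGraph,
    _positions_of_placement,
)

DEFAULT_SCORE_CAP = 100  # M: number of scoring k-mers averaged over


@dataclass(frozen=True)
class NegBinParams:
    r: float
    p: float

    def __post_init__(self) -> None:
        if self.r <= 0 or not 0 < self.p < 1:
            raise ValueError("require r > 0 and 0 < p < 1")

    @property
    def mean(self) -> float:
        return (1 - self.p) * self.r / self.p

    @property
    def variance(self) -> float:
        return (1 - self.p) * self.r / self.p**2


def fit_negbin_moments(coverages: Sequence[int]) -> NegBinParams:
    """Method-of-moments fit: p = mean/var, r = mean^2/(var - mean).

    Underdispersed data (variance <= mean) cannot arise under the model;
    the variance is then inflated to 1.1 * mean + 1 with a warning.
    """
    cov = np.asarray(coverages, dtype=float)
    if cov.size == 0 or cov.mean() <= 0:
        raise ValueError("need positive mean coverage to fit")
    mean = cov.mean()
    var = cov.var()
    if var <= mean:
        warnings.warn(
            "coverage variance <= mean; inflating variance for the negative binomial fit"
        )
        var = 1.1 * mean + 1.0
    return NegBinParams(r=mean**2 / (var - mean), p=mean / var)


def negbin_log_pmf(s: int | np.ndarray, params: NegBinParams) -> float | np.ndarray:
    """log f(s; r, p) = log[ Gamma(r+s)/(Gamma(r) s!) p^r (1-p)^s ]."""
    out = stats.nbinom.logpmf(s, params.r, params.p)
    return float(out) if np.isscalar(s) else out


@dataclass
class MosaicPath:
    locus_id: str
    sample_id: str
    node_ids: list[int]          # source ... sink of the k-mer graph
    score: float                 # averaged log-likelihood
    sequence: str = ""
    node_offsets: dict[int, int] | None = None  # node id -> start offset in sequence


def max_likelihood_path(
    kg: KmerGraph,
    sample_id: str,
    params: NegBinParams,
    score_cap: int = DEFAULT_SCORE_CAP,
    node_log_prob: Optional[Callable[[int], float]] = None,
) -> MosaicPath:
    """Maximum average-log-likelihood source-to-sink path by DP.

    The score sums log-probabilities over all real nodes of the path and
    divides by min(score_cap, path length).  ``node_log_prob`` overrides
    the negative-binomial coverage term (used for VCF reference inference,
    where a node's probability is proportional to how many samples cover
    it).  Ties are broken deterministically by preferring smaller
    predecessor ids.
    """
    M = max(1, score_cap)
    n = len(kg.nodes)
    if node_log_prob is None:
        def node_log_prob(nid: int) -> float:  # noqa: F811
            return float(negbin_log_pmf(kg.nodes[nid].covg(sample_id), params))

    order = kg.topological_order()
    NEG = -np.inf
    # f[v][c]: best total log prob over source->v paths whose real-node
    # count is exactly c (c < M) or at least M (c == M); every node
    # contributes to the sum, the count only fixes the final divisor.
    f = np.full((n, M + 1), NEG)
    parent = np.full((n, M + 1), -1, dtype=np.int64)
    pcount = np.full((n, M + 1), -1, dtype=np.int64)
    f[kg.source, 0] = 0.0
    for v in order:
        if v == kg.source:
            continue
        is_real = not kg.nodes[v].is_terminal
        ll = node_log_prob(v) if is_real else 0.0
        for u in sorted(kg.pred[v]):
            fu = f[u]
            if is_real:
                # (u, c-1) -> (v, c); counts saturate at M, ll always added
                for c_from, c_to in [(M, M)] + [(c - 1, c) for c in range(1, M + 1)]:
                    val = fu[c_from] + ll
                    if val > f[v, c_to]:
                        f[v, c_to] = val
                        parent[v, c_to] = u
                        pcount[v, c_to] = c_from
            else:
                for c in range(M + 1):
                    if fu[c] > f[v, c]:
                        f[v, c] = fu[c]
                        parent[v, c] = u
                        pcount[v, c] = c
    sink = kg.sink
    best_score, best_c = NEG, None
    for c in range(1, M + 1):
        if f[sink, c] == NEG:
            continue
        s = f[sink, c] / c  # c == M pools longer paths, averaged over M
        if s > best_score:
            best_score, best_c = s, c
    if best_c is None:
        raise ValueError(f"no source-to-sink path in k-mer graph {kg.locus_id}")

    path = []
    v, c = sink, best_c
    while v != -1:
        path.append(v)
        v, c = int(parent[v, c]), int(pcount[v, c])
    path.reverse()
    return MosaicPath(kg.locus_id, sample_id, path, float(best_score))


def spell_kmer_path(g: LocalGraph, kg: KmerGraph, node_ids: Sequence[int]) -> tuple[str, dict[int, int]]:
    """Spell the DNA sequence of a k-mer-graph path and record each node's
    start offset in it.

    Consecutive minimizers overlap by at least k - w bases; the shared
    bases are checked for consistency.  The bases before the first and
    after the last minimizer are filled in by a deterministic walk to the
    graph ends (unique except when variation falls entirely within the
    terminal w - 1 bases).
    """
    walker = GraphWalker(g)
    real = [nid for nid in node_ids if not kg.nodes[nid].is_terminal]
    if not real:
        return "", {}
    first = kg.nodes[real[0]]
    last = kg.nodes[real[-1]]

    prefix = _walk_terminal(walker, first.placement[0][0], first.placement[0][1], backward=True)
    seq = list(prefix)
    offsets: dict[int, int] = {}
    pos_prev = _positions_of_placement(kg.nodes[real[0]].placement)
    offsets[real[0]] = len(seq)
    seq.extend(kg.nodes[real[0]].seq)
    for prev_id, cur_id in zip(real, real[1:]):
        prev, cur = kg.nodes[prev_id], kg.nodes[cur_id]
        cur_pos = _positions_of_placement(cur.placement)
        start = cur_pos[0]
        if start in pos_prev:
            d = pos_prev.index(start)
        else:
            d = len(pos_prev)  # starts right after prev ends (w == k case)
        overlap = len(pos_prev) - d
        if overlap > 0 and prev.seq[d:] != cur.seq[:overlap]:
            raise AssertionError("inconsistent overlap between adjacent minimizers")
        offsets[cur_id] = len(seq) - overlap
        seq.extend(cur.seq[overlap:])
        pos_prev = cur_pos
    n_last, _, e_last = last.placement[-1]
    suffix = _walk_terminal(walker, n_last, e_last - 1, backward=False)
    return "".join(seq) + suffix, offsets


def _walk_terminal(walker: GraphWalker, node: int, offset: int, backward: bool) -> str:
    """Deterministic walk from a position to the nearest graph end,
    returning the bases strictly beyond the position (in forward order)."""
    out: list[str] = []
    pos = (node, offset)
    while True:
        nxts = walker.prev_positions(pos) if backward else walker.next_positions(pos)
        if backward and walker.at_start(pos):
            nxts = []
        if not backward and walker.at_end(pos):
            nxts = []
        if not nxts:
            break
        pos = min(nxts, key=lambda p: (walker.topo_index[p[0]], p[1]))
        out.append(walker.base(pos))
    if backward:
        out.reverse()
    return "".join(out)
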