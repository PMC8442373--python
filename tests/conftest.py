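"""Shared generators and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from panmosaic.construct import LocalGraph
from panmosaic.kmergraph import (
    GraphMinimizer,
    GraphWalker,
    _placement_of_positions,
)
from panmosaic.sketch import MinimizerParams, canonical_kmer, kmer_hash


def random_msa(rng: random.Random, max_rows: int = 6, max_cols: int = 60):
    """A random gapped alignment over ACGT- (occasionally N)."""
    n_rows = rng.randint(1, max_rows)
    n_cols = rng.randint(1, max_cols)
    rows = []
    base = [rng.choice("ACGT") for _ in range(n_cols)]
    for _ in range(n_rows):
        row = []
        for c in range(n_cols):
            r = rng.random()
            if r < 0.08:
                row.append("-")
            elif r < 0.10:
                row.append(rng.choice("ACGT"))
            elif r < 0.105:
                row.append("N")
            else:
                row.append(base[c])
        rows.append("".join(row))
    return rows


def random_bubble_graph(
    rng: random.Random, n_bubbles: int | None = None, flank: int = 6, core: int = 4
) -> LocalGraph:
    """A chain of flanks and 2-branch bubbles (occasionally a deletion
    branch), the shape local graphs take for SNP/indel variation."""
    g = LocalGraph("toy")
    g.add_node("")
    prev = [0]

    def seq(n: int) -> str:
        return "".join(rng.choice("ACGT") for _ in range(n))

    nb = n_bubbles if n_bubbles is not None else rng.randint(1, 4)
    for _ in range(nb):
        f = g.add_node(seq(flank + rng.randrange(3)))
        for p in prev:
            g.add_edge(p, f)
        a = g.add_node(seq(core))
        b = g.add_node(seq(core) if rng.random() < 0.7 else "")
        g.add_edge(f, a)
        g.add_edge(f, b)
        prev = [a, b]
    f = g.add_node(seq(flank))
    for p in prev:
        g.add_edge(p, f)
    s = g.add_node("")
    g.add_edge(f, s)
    return g


def window_minimizers_of_string(s: str, w: int, k: int):
    """Brute-force (hash, start, strand) minimizer triples of a string."""
    out = set()
    if len(s) < w + k - 1:
        return out
    H = []
    for i in range(len(s) - k + 1):
        c, r = canonical_kmer(s[i : i + k])
        H.append((kmer_hash(c), r))
    for j in range(len(s) - w - k + 2):
        window = H[j : j + w]
        m = min(h for h, _ in window)
        for t, (h, r) in enumerate(window):
            if h == m:
                out.add((h, j + t, r))
    return out


def oracle_graph_minimizers(g: LocalGraph, params: MinimizerParams) -> set[GraphMinimizer]:
    """Exhaustive oracle: enumerate every source-to-sink base path and take
    the union of window minimizers, with graph placements."""
    walker = GraphWalker(g)
    out: set[GraphMinimizer] = set()
    L = params.w + params.k - 1
    short_graph = walker.longest_path_bases() < L

    def full_paths():
        stack = [[p] for p in walker.first_positions()]
        while stack:
            path = stack.pop()
            if walker.at_end(path[-1]):
                yield path
            for nxt in walker.next_positions(path[-1]):
                stack.append(path + [nxt])

    for path in full_paths():
        s = "".join(walker.base(p) for p in path)
        if len(s) < L:
            if short_graph and len(s) >= params.k:
                windows = [(0, len(s) - params.k + 1)]
            else:
                continue
        else:
            windows = [(j, params.w) for j in range(len(s) - L + 1)]
        for j, nk in windows:
            best, args = None, []
            for t in range(nk):
                i = j + t
                c, r = canonical_kmer(s[i : i + params.k])
                h = kmer_hash(c)
                if best is None or h < best:
                    best, args = h, [(i, r)]
                elif h == best:
                    args.append((i, r))
            for i, r in args:
                out.add(
                    GraphMinimizer(best, _placement_of_positions(path[i : i + params.k]), r)
                )
    return out


def kmer_graph_paths(kg):
    """All source-to-sink node-id paths of a k-mer graph."""
    stack = [[kg.source]]
    while stack:
        p = stack.pop()
        if p[-1] == kg.sink:
            yield p
            continue
        for s in kg.succ[p[-1]]:
            stack.append(p + [s])


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by mapping/genotyping tests."""
    from panmosaic.pipeline import build_panrg
    from panmosaic.simulate import PanelSpec, simulate_panel, simulate_reads, simulate_sample

    spec = PanelSpec(
        n_loci=8, n_panel_genomes=6, locus_len=(400, 600), snps_per_allele=4, rare_frac=0.2, seed=3
    )
    panel = simulate_panel(spec)
    panrg = build_panrg(panel.msas.values(), MinimizerParams(w=8, k=11), seed=42)
    samples = {}
    reads = {}
    for i in range(2):
        sid = f"s{i}"
        st = simulate_sample(panel, sid, seed=50 + i)
        genome, _ = st.genome()
        rd, _ = simulate_reads(genome, depth=30, read_len=300, error_rate=0, seed=90 + i, sample_id=sid)
        samples[sid] = st
        reads[sid] = rd
    return panel, panrg, samples, reads


def three_gene_scenario():
    """Three biallelic SNPs at different carriage frequencies with a
    partial detection matrix: both alleles of a rare gene's SNP found; one
    carrier of each allele of an intermediate gene's SNP (of 5 G + 5 T);
    all 5 minor-allele carriers but no major-allele carriers of a core
    gene's SNP (15 A + 5 T)."""
    from panmosaic.evaluate import (
        AlleleTriple,
        PairwiseVariant,
        dedup_pan_variants,
        filter_pan_variants,
    )

    def pwv(g1, p1, b1, g2, p2, b2, chrom):
        return PairwiseVariant(
            AlleleTriple(g1, chrom, p1, b1), AlleleTriple(g2, chrom, p2, b2)
        )

    p1 = [pwv("g0", 1, "A", "g1", 1, "C", chrom="gene1")]
    p2 = [
        pwv(a, 2, "G", b, 2, "T", chrom="gene2")
        for a in [f"g{i}" for i in range(5)]
        for b in [f"g{i}" for i in range(5, 10)]
    ]
    p3 = [
        pwv(a, 3, "A", b, 3, "T", chrom="gene3")
        for a in [f"g{i}" for i in range(15)]
        for b in [f"g{i}" for i in range(15, 20)]
    ]
    pan = filter_pan_variants(dedup_pan_variants(p1 + p2 + p3))
    assert len(pan) == 3
    pan.sort(key=lambda p: min(p.alleles)[1])
    detections = {}
    for i, pgv in enumerate(pan):
        chrom = min(pgv.alleles)[1]
        det = {}
        for key, seq in pgv.alleles.items():
            if chrom == "gene1":
                det[key] = True
            elif chrom == "gene2":
                det[key] = key in {("g0", "gene2", 2), ("g5", "gene2", 2)}
            else:
                det[key] = seq == "T"
        detections[i] = det
    return pan, detections
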