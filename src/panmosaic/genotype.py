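"""Joint genotyping of samples on k-mer graphs and multi-sample VCF output.

A per-locus VCF reference path is inferred to be maximally close to the
sample mosaic paths (node probability proportional to the number of
samples covering it), so segregating differences become short alleles
instead of long near-duplicate haplotypes.  Each bubble off the
reference becomes a VCF site; per sample, each allele gets an
independent Poisson log-likelihood from its mean k-mer coverage, and an
allele is called only when it is both on the sample's mosaic path and
the likelihood maximizer — disagreement between those two yields a null
call rather than a wrong one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .construct import LocalGraph
from .kmergraph import KmerGraph
from .mosaic import MosaicPath, NegBinParams, max_likelihood_path, spell_kmer_path

ERROR_RATE_EPS = 0.01  # off-allele Poisson rate = eps * expected depth


@dataclass
class FilterConfig:
    min_covg: float = 5.0
    strand_bias_min: float = 0.05
    gaps_max: float = 0.8
    min_gt_conf: float = 0.0

    @classmethod
    def illumina(cls) -> "FilterConfig":
        return cls(min_covg=5, strand_bias_min=0.05, gaps_max=0.8)

    @classmethod
    def nanopore(cls) -> "FilterConfig":
        return cls(min_covg=10, strand_bias_min=0.05, gaps_max=0.6)


@dataclass
class VcfReference:
    locus_id: str
    node_ids: list[int]
    sequence: str
    node_offsets: dict[int, int]


@dataclass
class SampleCall:
    genotype: Optional[int]          # allele index or None
    likelihoods: list[float]
    gt_conf: float
    mean_fwd: list[float]            # per allele
    mean_rev: list[float]
    gaps_frac: list[float]           # fraction of allele k-mers barely covered
    filtered: bool = False


@dataclass
class VcfSite:
    locus_id: str
    pos: int                          # 1-based on the VCF reference
    ref: str
    alts: list[str]
    allele_nodes: list[list[int]]     # interior k-mer nodes per allele
    flank_left: int = -1              # reference k-mer node opening the bubble
    flank_right: int = -1             # reference k-mer node closing it
    calls: dict[str, SampleCall] = field(default_factory=dict)

    @property
    def alleles(self) -> list[str]:
        return [self.ref] + self.alts


def infer_vcf_reference(
    kg: KmerGraph, sample_paths: Sequence[MosaicPath], g: LocalGraph
) -> VcfReference:
    """Mosaic-path DP on a copy of the graph where a node's probability
    is proportional to the number of sample mosaic paths covering it."""
    if not sample_paths:
        raise ValueError("need at least one sample path")
    counts = {n.id: 0 for n in kg.nodes}
    for mp in sample_paths:
        for nid in mp.node_ids:
            counts[nid] += 1
    n_samples = len(sample_paths)

    def log_prob(nid: int) -> float:
        return math.log((counts[nid] + 0.01) / (n_samples + 0.01))

    path = max_likelihood_path(
        kg, "__ref__", NegBinParams(1.0, 0.5), node_log_prob=log_prob
    )
    seq, offsets = spell_kmer_path(g, kg, path.node_ids)
    return VcfReference(kg.locus_id, path.node_ids, seq, offsets)


def _trim_alleles(seqs: list[str], pos0: int) -> tuple[int, list[str]]:
    """VCF-style normalization: drop shared suffix then shared prefix,
    always keeping at least one base per allele."""
    seqs = list(seqs)
    while all(len(s) > 1 for s in seqs) and len({s[-1] for s in seqs}) == 1:
        seqs = [s[:-1] for s in seqs]
    while all(len(s) > 1 for s in seqs) and len({s[0] for s in seqs}) == 1:
        seqs = [s[1:] for s in seqs]
        pos0 += 1
    return pos0, seqs


def enumerate_sites(
    kg: KmerGraph, ref: VcfReference, max_alleles: int = 64
) -> list[VcfSite]:
    """One site per top-level bubble off the reference path.

    Scanning along the reference, a divergence opens a site; the site
    closes at the first reference node where every off-reference branch
    has rejoined, and overlapping divergences merge into one record.
    Alleles are the spelled branch sequences, trimmed to minimal VCF
    representation (a SNP bubble on the reference becomes a single-base
    REF/ALT pair).
    """
    path = ref.node_ids
    on_ref = {nid: i for i, nid in enumerate(path)}
    sites: list[VcfSite] = []
    i = 0
    while i < len(path) - 1:
        u = path[i]
        nxt = path[i + 1]
        if all(s == nxt for s in kg.succ[u]):
            i += 1
            continue
        # a bubble opens at index i; find the smallest closing index
        j = _closing_index(kg, path, on_ref, i)
        if j is None:
            i += 1
            continue
        if kg.nodes[path[i]].is_terminal or kg.nodes[path[j]].is_terminal:
            # bubble touches the synthetic source/sink: variation within
            # the terminal window has no anchored reference coordinate
            i = j
            continue
        alleles = _enumerate_allele_paths(kg, path[i], path[j], on_ref, i, j, max_alleles)
        site = _make_site(kg, ref, path, i, j, alleles)
        if site is not None:
            sites.append(site)
        i = j
    return sites


def _closing_index(
    kg: KmerGraph, path: list[int], on_ref: dict[int, int], i: int
) -> Optional[int]:
    """Smallest reference index j > i such that every path leaving the
    reference in [i, j) has rejoined by j; grows j as nested or staggered
    divergences extend the bubble."""
    j = i + 1
    while j < len(path):
        # does any node in path[i:j] start an excursion ending beyond j?
        far = j
        ok = True
        for t in range(i, j):
            for s in kg.succ[path[t]]:
                if t + 1 < len(path) and s == path[t + 1]:
                    continue
                end = _excursion_end(kg, s, on_ref)
                if end is None:
                    continue
                if end > far:
                    far = end
                if end > j:
                    ok = False
        if ok and far <= j:
            return j
        j = far if far > j else j + 1
    return None


def _excursion_end(kg: KmerGraph, start: int, on_ref: dict[int, int]) -> Optional[int]:
    """Reference index where an off-reference excursion first rejoins
    (maximum over branches; None if it never rejoins)."""
    seen = set()
    stack = [start]
    worst = None
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        if n in on_ref:
            worst = on_ref[n] if worst is None else max(worst, on_ref[n])
            continue
        for s in kg.succ[n]:
            stack.append(s)
    return worst


def _enumerate_allele_paths(
    kg: KmerGraph,
    u: int,
    v: int,
    on_ref: dict[int, int],
    i: int,
    j: int,
    max_alleles: int,
) -> list[list[int]]:
    """All u -> v k-mer-graph paths staying strictly between the bubble's
    reference endpoints (interior may touch intermediate ref nodes)."""
    out: list[list[int]] = []
    stack: list[list[int]] = [[u]]
    while stack and len(out) < max_alleles:
        p = stack.pop()
        last = p[-1]
        if last == v:
            out.append(p)
            continue
        if last in on_ref and not (i <= on_ref[last] < j):
            continue
        for s in kg.succ[last]:
            if kg.nodes[s].is_terminal:
                continue
            if s in on_ref and on_ref[s] > j:
                continue
            stack.append(p + [s])
    return out


def _spell_allele(kg: KmerGraph, nodes: list[int]) -> Optional[str]:
    """Sequence spelled by a chain of adjacent minimizers (k-mer overlap
    stitching); None on inconsistency."""
    from .kmergraph import _positions_of_placement

    first = kg.nodes[nodes[0]]
    seq = list(first.seq)
    prev_pos = _positions_of_placement(first.placement)
    prev_seq = first.seq
    for nid in nodes[1:]:
        cur = kg.nodes[nid]
        pos = _positions_of_placement(cur.placement)
        start = pos[0]
        d = prev_pos.index(start) if start in prev_pos else len(prev_pos)
        overlap = len(prev_pos) - d
        if overlap > 0 and cur.seq[:overlap] != prev_seq[d:]:
            return None
        seq.extend(cur.seq[overlap:])
        prev_pos = pos
        prev_seq = cur.seq
    return "".join(seq)


def _make_site(
    kg: KmerGraph,
    ref: VcfReference,
    path: list[int],
    i: int,
    j: int,
    allele_paths: list[list[int]],
) -> Optional[VcfSite]:
    ref_nodes = path[i : j + 1]
    spelled = []
    interiors = []
    ref_idx = None
    for ap in allele_paths:
        s = _spell_allele(kg, ap)
        if s is None:
            continue
        spelled.append(s)
        interiors.append([n for n in ap[1:-1]])
        if ap == ref_nodes:
            ref_idx = len(spelled) - 1
    if ref_idx is None:
        s = _spell_allele(kg, ref_nodes)
        if s is None:
            return None
        spelled.insert(0, s)
        interiors.insert(0, [n for n in ref_nodes[1:-1]])
        ref_idx = 0
    if len(spelled) < 2:
        return None
    # put the reference allele first
    order = [ref_idx] + [t for t in range(len(spelled)) if t != ref_idx]
    spelled = [spelled[t] for t in order]
    interiors = [interiors[t] for t in order]
    # deduplicate identical alt spellings
    seen = {}
    keep_seqs, keep_int = [], []
    for s, ii in zip(spelled, interiors):
        if s in seen:
            continue
        seen[s] = True
        keep_seqs.append(s)
        keep_int.append(ii)
    if len(keep_seqs) < 2:
        return None
    pos0 = ref.node_offsets[path[i]]
    pos0, trimmed = _trim_alleles(keep_seqs, pos0)
    return VcfSite(
        locus_id=kg.locus_id,
        pos=pos0 + 1,
        ref=trimmed[0],
        alts=trimmed[1:],
        allele_nodes=keep_int,
        flank_left=path[i],
        flank_right=path[j],
    )


def genotype_confidence(likelihoods: Sequence[float]) -> float:
    """Log-likelihood gap between the best and second-best genotype."""
    if len(likelihoods) < 2:
        return float("inf")
    top = sorted(likelihoods, reverse=True)
    return top[0] - top[1]


def genotype_site(
    site: VcfSite,
    kg: KmerGraph,
    sample: str,
    mosaic: Optional[MosaicPath],
    expected_depth: float,
    flank: tuple[int, int],
    eps: float = ERROR_RATE_EPS,
) -> SampleCall:
    """Poisson genotyping of one sample at one site.

    Each allele's log-likelihood treats its observed mean coverage as
    Poisson(expected depth) and every other allele's as Poisson(eps *
    expected depth).  The call is the allele on the sample's mosaic path
    if it is also the likelihood maximizer, else null.
    """
    n_alleles = len(site.alleles)
    means_f, means_r, gaps = [], [], []
    for a in range(n_alleles):
        nodes = site.allele_nodes[a] or list(flank)
        f = [kg.nodes[n].coverage.get(sample, [0, 0])[0] for n in nodes]
        r = [kg.nodes[n].coverage.get(sample, [0, 0])[1] for n in nodes]
        tot = [x + y for x, y in zip(f, r)]
        means_f.append(float(np.mean(f)))
        means_r.append(float(np.mean(r)))
        gaps.append(float(np.mean([t <= 0.1 * expected_depth for t in tot])))
    d = max(expected_depth, 1e-6)
    lls = []
    for a in range(n_alleles):
        ll = 0.0
        for b in range(n_alleles):
            rate = d if b == a else eps * d
            obs = int(round(means_f[b] + means_r[b]))
            ll += float(stats.poisson.logpmf(obs, rate))
        lls.append(ll)
    conf = genotype_confidence(lls)
    # which allele is on the mosaic path?
    mosaic_allele = None
    if mosaic is not None:
        path_nodes = set(mosaic.node_ids)
        pairs = list(zip(mosaic.node_ids, mosaic.node_ids[1:]))
        for a in range(n_alleles):
            interior = site.allele_nodes[a]
            if interior:
                if all(n in path_nodes for n in interior):
                    mosaic_allele = a
                    break
            else:
                if (flank[0], flank[1]) in pairs:
                    mosaic_allele = a
                    break
    best = int(np.argmax(lls))
    if mosaic_allele is None or sum(means_f) + sum(means_r) == 0:
        gt = None
    elif best == mosaic_allele:
        gt = best
    else:
        gt = None  # global/local incompatibility -> null
    return SampleCall(gt, lls, conf, means_f, means_r, gaps)


def apply_filters(
    sites: list[VcfSite], cfg: FilterConfig, expected_depth: dict[str, float]
) -> None:
    """Mask genotypes failing coverage, strand-bias, gaps or confidence
    filters (in place; the call becomes null but keeps its annotations)."""
    for site in sites:
        for sample, call in site.calls.items():
            if call.genotype is None:
                continue
            a = call.genotype
            f, r = call.mean_fwd[a], call.mean_rev[a]
            tot = f + r
            fail = (
                tot < cfg.min_covg
                or (tot > 0 and min(f, r) / tot < cfg.strand_bias_min)
                or call.gaps_frac[a] >= cfg.gaps_max
                or call.gt_conf < cfg.min_gt_conf
            )
            if fail:
                call.genotype = None
                call.filtered = True


def genotype_locus(
    kg: KmerGraph,
    g: LocalGraph,
    sample_paths: dict[str, MosaicPath],
    expected_depth: dict[str, float],
    max_alleles: int = 64,
) -> tuple[VcfReference, list[VcfSite]]:
    """Infer the VCF reference for one locus and genotype every sample at
    every bubble site."""
    ref = infer_vcf_reference(kg, list(sample_paths.values()), g)
    sites = enumerate_sites(kg, ref, max_alleles)
    for site in sites:
        flank = (site.flank_left, site.flank_right)
        for sample, mp in sample_paths.items():
            site.calls[sample] = genotype_site(
                site, kg, sample, mp, expected_depth.get(sample, 0.0), flank
            )
    return ref, sites


# ---------------------------------------------------------------------------
# Output


def write_vcf(
    sites_by_locus: dict[str, list[VcfSite]],
    refs: dict[str, VcfReference],
    samples: list[str],
    path: str | Path,
) -> None:
    """Multi-sample VCF v4.2; one CHROM per locus, positions on the
    inferred per-locus reference (written separately as FASTA)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=MEAN_FWD_COVG,Number=R,Type=Float,Description="Mean forward k-mer coverage per allele">',
        '##FORMAT=<ID=MEAN_REV_COVG,Number=R,Type=Float,Description="Mean reverse k-mer coverage per allele">',
        '##FORMAT=<ID=LIKELIHOOD,Number=R,Type=Float,Description="Log-likelihood per allele">',
        '##FORMAT=<ID=GT_CONF,Number=1,Type=Float,Description="Genotype confidence">',
    ]
    for locus in sorted(refs):
        lines.append(f"##contig=<ID={locus},length={len(refs[locus].sequence)}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for locus in sorted(sites_by_locus):
        for site in sorted(sites_by_locus[locus], key=lambda s: s.pos):
            cols = [
                locus,
                str(site.pos),
                ".",
                site.ref or ".",
                ",".join(site.alts) or ".",
                ".",
                "PASS",
                ".",
                "GT:MEAN_FWD_COVG:MEAN_REV_COVG:LIKELIHOOD:GT_CONF",
            ]
            for s in samples:
                call = site.calls.get(s)
                if call is None:
                    cols.append(".")
                    continue
                gt = "." if call.genotype is None else str(call.genotype)
                cols.append(
                    f"{gt}:"
                    f"{','.join(f'{x:.1f}' for x in call.mean_fwd)}:"
                    f"{','.join(f'{x:.1f}' for x in call.mean_rev)}:"
                    f"{','.join(f'{x:.2f}' for x in call.likelihoods)}:"
                    f"{call.gt_conf:.2f}"
                )
            lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf_reference_fasta(refs: dict[str, VcfReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus in sorted(refs):
            fh.write(f">{locus}\n{refs[locus].sequence}\n")


def write_presence_matrix(
    presence: dict[str, dict[str, bool]], samples: list[str], path: str | Path
) -> None:
    """Loci x samples presence/absence TSV."""
    loci = sorted({l for d in presence.values() for l in d})
    with open(path, "w") as fh:
        fh.write("locus\t" + "\t".join(samples) + "\n")
        for locus in loci:
            row = [locus] + ["1" if presence.get(s, {}).get(locus, False) else "0" for s in samples]
            fh.write("\t".join(row) + "\n")
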