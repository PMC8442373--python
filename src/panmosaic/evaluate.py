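"""Pan-genome variant evaluation: dedup, recall and precision scoring.

There is no universal coordinate system across bacterial genomes, so a
truth set is built from pairwise variants: an allele is a (genome,
chromosome, position) triple, a pairwise variant a pair of alleles from
two genomes, and a pan-genome variant the equivalence class of pairwise
variants connected by shared alleles.  Recall then splits into
pan-variant recall (PVR: both alleles of a site found somewhere) and
average allelic recall (AvgAR: mean fraction of allele instances found),
and precision is scored by aligning call probes back to truth genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import networkx as nx

AlleleKey = tuple[str, str, int]  # (genome, chromosome, 0-based position)


@dataclass(frozen=True)
class AlleleTriple:
    genome: str
    chrom: str
    pos: int
    seq: str  # base(s) carried at this position

    @property
    def key(self) -> AlleleKey:
        return (self.genome, self.chrom, self.pos)


@dataclass(frozen=True)
class PairwiseVariant:
    a1: AlleleTriple
    a2: AlleleTriple

    def __post_init__(self) -> None:
        if self.a1.genome == self.a2.genome:
            raise ValueError("pairwise variant needs alleles from two genomes")
        if self.a1.seq == self.a2.seq:
            raise ValueError("pairwise variant alleles must differ in sequence")

    @property
    def alleles(self) -> tuple[AlleleTriple, AlleleTriple]:
        return (self.a1, self.a2)


@dataclass
class PanGenomeVariant:
    alleles: dict[AlleleKey, str]         # key -> sequence
    members: list[PairwiseVariant] = field(default_factory=list)

    @property
    def allele_seqs(self) -> set[str]:
        return set(self.alleles.values())

    def carriers_of(self, seq: str) -> list[AlleleKey]:
        return [k for k, s in self.alleles.items() if s == seq]


def dedup_pan_variants(pairwise: Sequence[PairwiseVariant]) -> list[PanGenomeVariant]:
    """Group pairwise variants into pan-genome variants: nodes are
    pairwise variants, edges join pairs sharing an allele, and each
    connected component is one pan-genome variant (so membership is a
    partition and shared-allele transitivity holds by construction)."""
    G = nx.Graph()
    G.add_nodes_from(range(len(pairwise)))
    by_allele: dict[AlleleKey, list[int]] = {}
    for i, pv in enumerate(pairwise):
        for a in pv.alleles:
            by_allele.setdefault(a.key, []).append(i)
    for members in by_allele.values():
        for i, j in zip(members, members[1:]):
            G.add_edge(i, j)
    out = []
    for comp in nx.connected_components(G):
        alleles: dict[AlleleKey, str] = {}
        members = sorted(comp)
        for i in members:
            for a in pairwise[i].alleles:
                alleles[a.key] = a.seq
        out.append(PanGenomeVariant(alleles, [pairwise[i] for i in members]))
    out.sort(key=lambda p: min(p.alleles))
    return out


def filter_pan_variants(pan_variants: Iterable[PanGenomeVariant]) -> list[PanGenomeVariant]:
    """Keep only clean biallelic SNPs: at most one allele per genome and
    exactly two distinct single-base allele sequences."""
    out = []
    for pgv in pan_variants:
        genomes = [k[0] for k in pgv.alleles]
        if len(genomes) != len(set(genomes)):
            continue
        seqs = pgv.allele_seqs
        if len(seqs) != 2 or any(len(s) != 1 for s in seqs):
            continue
        out.append(pgv)
    return out


def pan_variant_recall(detections: dict[int, dict[AlleleKey, bool]], pan_variants: Sequence[PanGenomeVariant]) -> float:
    """Fraction of pan-variants with both allele sequences found in at
    least one carrier each (a site scores 1 however often its alleles
    were seen, 0 otherwise)."""
    if not pan_variants:
        raise ValueError("empty truth set")
    score = 0
    for i, pgv in enumerate(pan_variants):
        found = detections.get(i, {})
        seq_found = {s: False for s in pgv.allele_seqs}
        for key, ok in found.items():
            if ok:
                seq_found[pgv.alleles[key]] = True
        if all(seq_found.values()):
            score += 1
    return score / len(pan_variants)


def avg_allelic_recall(detections: dict[int, dict[AlleleKey, bool]], pan_variants: Sequence[PanGenomeVariant]) -> float:
    """Mean over pan-variants of the fraction of allele instances
    (carrier genomes) in which the allele was found."""
    if not pan_variants:
        raise ValueError("empty truth set")
    total = 0.0
    for i, pgv in enumerate(pan_variants):
        found = detections.get(i, {})
        n = len(pgv.alleles)
        hit = sum(1 for key in pgv.alleles if found.get(key, False))
        total += hit / n
    return total / len(pan_variants)


# ---------------------------------------------------------------------------
# Probe-based scoring


@dataclass
class ProbeAlignment:
    score: float          # matches / alignment columns over the allele span
    ambiguous: bool
    mapped: bool


def _allele_columns_score(
    probe: str, target: str, allele_start: int, allele_len: int
) -> Optional[float]:
    """Align the probe (allele + flanks) to the truth sequence and score
    matches / alignment-columns over the allele portion only."""
    res = edlib.align(probe, target, mode="HW", task="path")
    if res["editDistance"] == -1 or not res.get("cigar"):
        return None
    qpos = 0
    matches = 0
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch == "=":
            for _ in range(ln):
                if allele_start <= qpos < allele_start + allele_len:
                    matches += 1
                    columns += 1
                qpos += 1
        elif ch == "X":
            for _ in range(ln):
                if allele_start <= qpos < allele_start + allele_len:
                    columns += 1
                qpos += 1
        elif ch == "I":  # probe base absent from target
            for _ in range(ln):
                if allele_start <= qpos < allele_start + allele_len:
                    columns += 1
                qpos += 1
        elif ch == "D":  # target base absent from probe
            if allele_start <= qpos < allele_start + allele_len:
                columns += ln
    if columns == 0:
        return None
    return matches / columns


def precision_score(
    probes: Sequence[tuple[str, int, int]],
    truth_seqs: dict[str, str],
    masked: dict[str, list[tuple[int, int]]] | None = None,
    ambiguity_margin: int = 10,
) -> tuple[float, list[float]]:
    """Score call probes (sequence, allele start, allele length) against
    truth genome sequences.

    Each probe is aligned to every truth sequence; if the best and
    second-best placements are within the ambiguity margin (edit
    distance), the call is dropped rather than guessed.  The aggregate
    is the mean per-call score over evaluated calls.
    """
    scores = []
    for probe, astart, alen in probes:
        placements = []
        for name, target in truth_seqs.items():
            if not target or not probe:
                continue
            res = edlib.align(probe, target, mode="HW")
            if res["editDistance"] >= 0:
                for loc in res["locations"][:8]:
                    placements.append((res["editDistance"], name, loc))
        if not placements:
            continue
        placements.sort(key=lambda t: t[0])
        if len(placements) > 1 and placements[1][0] - placements[0][0] < ambiguity_margin:
            # also ambiguous when one target has two equally good spots
            if placements[1][1:] != placements[0][1:]:
                continue
        dist, name, loc = placements[0]
        if masked and _overlaps_mask(loc, masked.get(name, [])):
            continue
        s = _allele_columns_score(probe, truth_seqs[name], astart, alen)
        if s is not None:
            scores.append(s)
    agg = sum(scores) / len(scores) if scores else 0.0
    return agg, scores


def _overlaps_mask(loc: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    s, e = loc
    return any(not (e < a or s > b) for a, b in intervals)


def apply_vcf_to_reference(
    ref_seq: str, records: Sequence[tuple[int, str, str]]
) -> str:
    """Apply (1-based pos, ref allele, called allele) substitutions to a
    reference sequence, right-to-left so coordinates stay valid."""
    s = ref_seq
    for pos, ref, alt in sorted(records, key=lambda r: -r[0]):
        i = pos - 1
        if s[i : i + len(ref)] != ref:
            continue  # stale record; skip rather than corrupt
        s = s[:i] + alt + s[i + len(ref) :]
    return s


def recall_by_truth_probes(
    pan_variants: Sequence[PanGenomeVariant],
    truth_seqs: dict[tuple[str, str], str],
    mutated_refs: dict[str, dict[str, str]],
    flank: int = 50,
) -> dict[int, dict[AlleleKey, bool]]:
    """Build a probe (allele + flanks from its own genome) for every
    allele instance of every pan-variant and map it to each sample's
    mutated reference; an instance is detected only if every allele base
    matches in some placement of the probe on that genome's callset."""
    detections: dict[int, dict[AlleleKey, bool]] = {}
    for i, pgv in enumerate(pan_variants):
        det: dict[AlleleKey, bool] = {}
        for key, seq in pgv.alleles.items():
            genome, chrom, pos = key
            src = truth_seqs.get((genome, chrom))
            if src is None:
                det[key] = False
                continue
            lo = max(0, pos - flank)
            probe = src[lo : pos + len(seq) + flank]
            astart = pos - lo
            targets = mutated_refs.get(genome, {})
            found = False
            for target in ([targets.get(chrom)] if chrom in targets else list(targets.values())):
                if not target:
                    continue
                score = _allele_columns_score(probe, target, astart, len(seq))
                if score == 1.0:
                    found = True
                    break
            det[key] = found
        detections[i] = det
    return detections
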