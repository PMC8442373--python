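"""Pan-variant recall (PVR) and average allelic recall (AvgAR) by hand.

Three genes each carry one biallelic SNP: a rare gene present in 2
genomes (alleles A and C, both found by the caller), an intermediate
gene in 10 genomes (5 G + 5 T, one carrier of each allele found), and a
core gene in 20 genomes (15 A + 5 T; all five T carriers found, no A).
PVR scores a site 1 only if both alleles were found somewhere; AvgAR
averages the per-site fraction of carrier genomes in which the allele
was detected.
"""

from panmosaic import (
    AlleleTriple,
    PairwiseVariant,
    avg_allelic_recall,
    dedup_pan_variants,
    filter_pan_variants,
    pan_variant_recall,
)


def pwv(g1, b1, g2, b2, chrom, pos):
    return PairwiseVariant(
        AlleleTriple(g1, chrom, pos, b1), AlleleTriple(g2, chrom, pos, b2)
    )


pairwise = [pwv("g0", "A", "g1", "C", "gene1", 10)]
pairwise += [pwv(f"g{i}", "G", f"g{j}", "T", "gene2", 20) for i in range(5) for j in range(5, 10)]
pairwise += [pwv(f"g{i}", "A", f"g{j}", "T", "gene3", 30) for i in range(15) for j in range(15, 20)]

pan = filter_pan_variants(dedup_pan_variants(pairwise))
print(f"{len(pairwise)} pairwise variants deduplicate to {len(pan)} pan-variants")

detections = {}
for i, pgv in enumerate(sorted(pan, key=lambda p: min(p.alleles)[1])):
    gene = min(pgv.alleles)[1]
    det = {}
    for key, base in pgv.alleles.items():
        if gene == "gene1":
            det[key] = True
        elif gene == "gene2":
            det[key] = key[0] in ("g0", "g5")
        else:
            det[key] = base == "T"
    detections[i] = det

pan_sorted = sorted(pan, key=lambda p: min(p.alleles)[1])
pvr = pan_variant_recall(detections, pan_sorted)
avgar = avg_allelic_recall(detections, pan_sorted)
print(f"PVR   = {pvr:.4f}   # (1 + 1 + 0) / 3: gene3's A allele was never found")
print(f"AvgAR = {avgar:.4f}   # (2/2 + 2/10 + 5/20) / 3: fraction of carriers detected")
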