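"""Scoring a callset against a simulator truth ledger.

Glue between the three representations: the truth JSON written by the
generator (genome sequences + pairwise variant list), the multi-sample
VCF + per-locus reference FASTA written by the genotyper, and the
pan-genome variant machinery that computes PVR / AvgAR / precision.
"""

from __future__ import annotations

import json
from pathlib import Path

from .evaluate import (
    AlleleTriple,
    PairwiseVariant,
    apply_vcf_to_reference,
    avg_allelic_recall,
    dedup_pan_variants,
    filter_pan_variants,
    pan_variant_recall,
    precision_score,
    recall_by_truth_probes,
)


def load_truth(path: str | Path) -> tuple[dict[tuple[str, str], str], list[PairwiseVariant]]:
    doc = json.loads(Path(path).read_text())
    seqs = {
        (genome, chrom): seq
        for genome, chroms in doc["genomes"].items()
        for chrom, seq in (chroms.items() if isinstance(chroms, dict) else [])
    }
    pairwise = []
    for pv in doc["pairwise_variants"]:
        g1, c1, p1, b1 = pv["allele1"]
        g2, c2, p2, b2 = pv["allele2"]
        pairwise.append(
            PairwiseVariant(AlleleTriple(g1, c1, p1, b1), AlleleTriple(g2, c2, p2, b2))
        )
    return seqs, pairwise


def parse_vcf(path: str | Path) -> tuple[list[str], list[dict]]:
    samples: list[str] = []
    records: list[dict] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            samples = line.split("\t")[9:]
            continue
        parts = line.split("\t")
        chrom, pos, _, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
        alts = alt.split(",") if alt != "." else []
        calls = {}
        fmt = parts[8].split(":")
        for sample, cell in zip(samples, parts[9:]):
            if cell == ".":
                calls[sample] = None
                continue
            fields = dict(zip(fmt, cell.split(":")))
            gt = fields.get("GT", ".")
            calls[sample] = None if gt == "." else int(gt)
        records.append({"chrom": chrom, "pos": pos, "ref": ref, "alts": alts, "calls": calls})
    return samples, records


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    buf: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(buf)
            name = line[1:].split()[0]
            buf = []
        else:
            buf.append(line.strip())
    if name is not None:
        seqs[name] = "".join(buf)
    return seqs


def mutated_references(
    records: list[dict], vcf_refs: dict[str, str], samples: list[str]
) -> dict[str, dict[str, str]]:
    """Per sample, apply its called alleles to the per-locus VCF
    reference, yielding the genome each callset implies."""
    out: dict[str, dict[str, str]] = {s: dict(vcf_refs) for s in samples}
    by_locus: dict[str, list[dict]] = {}
    for rec in records:
        by_locus.setdefault(rec["chrom"], []).append(rec)
    for sample in samples:
        for locus, recs in by_locus.items():
            if locus not in vcf_refs:
                continue
            subs = []
            for rec in recs:
                gt = rec["calls"].get(sample)
                if gt is None or gt == 0:
                    continue
                alleles = [rec["ref"]] + rec["alts"]
                subs.append((rec["pos"], rec["ref"], alleles[gt]))
            out[sample][locus] = apply_vcf_to_reference(vcf_refs[locus], subs)
    return out


def evaluate_callset(
    truth_json: str | Path,
    vcf_path: str | Path,
    vcf_ref_path: str | Path,
    probe_flank: int = 150,
) -> dict:
    """PVR, AvgAR and precision of a multi-sample callset against the
    simulator's truth ledger."""
    truth_seqs, pairwise = load_truth(truth_json)
    pan_variants = filter_pan_variants(dedup_pan_variants(pairwise))
    samples, records = parse_vcf(vcf_path)
    vcf_refs = read_fasta(vcf_ref_path)
    mutated = mutated_references(records, vcf_refs, samples)
    detections = recall_by_truth_probes(pan_variants, truth_seqs, mutated)
    pvr = pan_variant_recall(detections, pan_variants) if pan_variants else 0.0
    avgar = avg_allelic_recall(detections, pan_variants) if pan_variants else 0.0

    # precision: probe each called allele (with reference flanks) against
    # the calling sample's own truth sequences
    probes: list[tuple[str, int, int]] = []
    per_sample_truth: dict[str, dict[str, str]] = {}
    for (genome, chrom), seq in truth_seqs.items():
        per_sample_truth.setdefault(genome, {})[chrom] = seq
    scores_all: list[float] = []
    for sample in samples:
        sample_probes = []
        for rec in records:
            gt = rec["calls"].get(sample)
            if gt is None:
                continue
            allele = ([rec["ref"]] + rec["alts"])[gt]
            refseq = vcf_refs.get(rec["chrom"])
            if refseq is None:
                continue
            i = rec["pos"] - 1
            lo = max(0, i - probe_flank)
            probe = refseq[lo:i] + allele + refseq[i + len(rec["ref"]) : i + len(rec["ref"]) + probe_flank]
            sample_probes.append((probe, i - lo, len(allele)))
        if sample_probes and sample in per_sample_truth:
            _, scores = precision_score(sample_probes, per_sample_truth[sample])
            scores_all.extend(scores)
    precision = sum(scores_all) / len(scores_all) if scores_all else 0.0
    return {
        "n_pan_variants": len(pan_variants),
        "pan_variant_recall": pvr,
        "avg_allelic_recall": avgar,
        "precision": precision,
        "n_evaluated_calls": len(scores_all),
    }
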