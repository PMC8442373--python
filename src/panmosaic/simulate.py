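"""Synthetic panels, sample genomes, reads and truth ledgers.

The generator emulates the statistical structure the method assumes: a
reference panel of loci whose carriage frequencies follow the asymmetric
U-shape seen in bacterial pan-genomes (most loci either rare or nearly
core), sample genomes assembled as crossover mosaics of panel alleles
with occasional novel SNPs absent from the panel, and uniform shotgun
reads with a configurable per-base substitution error rate.  Every
random choice is recorded in a ledger so downstream truth queries
(presence, pairwise variants, implanted SNPs) need no re-alignment.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .msa import Msa
from .sketch import revcomp

_BASES = "ACGT"


@dataclass
class PanelSpec:
    """Conditions for the reference panel of locus alignments.

    The carriage-frequency mixture is two-component: ``rare_frac`` of
    loci are carried by ``rare_freq`` of genomes, the rest by
    ``core_freq`` — the two modes of the U-shaped distribution.
    """

    n_loci: int = 50
    n_panel_genomes: int = 10
    locus_len: tuple[int, int] = (800, 1200)
    snps_per_allele: int = 4       # substitutions from the locus ancestor
    rare_frac: float = 0.3
    rare_freq: float = 0.1
    core_freq: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locus_len[0] < 50:
            raise ValueError("locus length too small to sketch")
        for f in (self.rare_freq, self.core_freq):
            if not 0 < f <= 1:
                raise ValueError("frequencies must be in (0, 1]")


@dataclass
class Panel:
    spec: PanelSpec
    msas: dict[str, Msa] = field(default_factory=dict)
    locus_freq: dict[str, float] = field(default_factory=dict)
    ancestors: dict[str, str] = field(default_factory=dict)

    @property
    def locus_ids(self) -> list[str]:
        return sorted(self.msas)

    def write_msa_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for locus, msa in self.msas.items():
            with open(outdir / f"{locus}.fa", "w") as fh:
                for rid, row in zip(msa.row_ids, msa.rows):
                    fh.write(f">{rid}\n{row}\n")


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _mutate(rng: random.Random, seq: str, n_snps: int) -> str:
    s = list(seq)
    for pos in rng.sample(range(len(s)), min(n_snps, len(s))):
        s[pos] = rng.choice([b for b in _BASES if b != s[pos]])
    return "".join(s)


def simulate_panel(spec: PanelSpec) -> Panel:
    """Draw the locus panel: per locus an ancestor sequence, one derived
    allele per carrying panel genome, and a U-shaped carriage frequency."""
    rng = random.Random(spec.seed)
    panel = Panel(spec)
    for i in range(spec.n_loci):
        locus = f"locus{i:04d}"
        freq = spec.rare_freq if rng.random() < spec.rare_frac else spec.core_freq
        length = rng.randint(*spec.locus_len)
        ancestor = _random_seq(rng, length)
        carriers = [g for g in range(spec.n_panel_genomes) if rng.random() < freq]
        if not carriers:
            carriers = [rng.randrange(spec.n_panel_genomes)]
        rows = [_mutate(rng, ancestor, spec.snps_per_allele) for _ in carriers]
        panel.msas[locus] = Msa(rows, [f"panel{g}" for g in carriers], locus)
        panel.locus_freq[locus] = freq
        panel.ancestors[locus] = ancestor
    return panel


@dataclass
class SampleTruth:
    """One simulated sample: per-locus sequence, mosaic recipe and
    implanted novel SNPs (position, panel base, novel base)."""

    sample_id: str
    sequences: dict[str, str] = field(default_factory=dict)
    recipes: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    novel_snps: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)

    def present(self, locus: str) -> bool:
        return locus in self.sequences

    def genome(self, locus_order: list[str] | None = None) -> tuple[str, dict[str, int]]:
        """Concatenated genome and per-locus start offsets."""
        order = locus_order or sorted(self.sequences)
        offsets = {}
        parts = []
        at = 0
        for locus in order:
            if locus in self.sequences:
                offsets[locus] = at
                parts.append(self.sequences[locus])
                at += len(self.sequences[locus])
        return "".join(parts), offsets


def simulate_sample(
    panel: Panel,
    sample_id: str,
    seed: int,
    recomb_rate: float = 0.3,
    novel_snp_rate: float = 0.0,
) -> SampleTruth:
    """Assemble a sample as, per carried locus, a crossover mosaic of 1-3
    panel alleles plus Poisson(novel_snp_rate * length) novel SNPs, each
    guaranteed absent from the panel alignment column."""
    rng = random.Random(seed)
    truth = SampleTruth(sample_id)
    for locus in panel.locus_ids:
        if rng.random() >= panel.locus_freq[locus]:
            continue
        msa = panel.msas[locus]
        n = msa.n_cols
        n_seg = 1
        if len(msa.rows) > 1 and rng.random() < recomb_rate:
            n_seg = rng.choice([2, 3])
        cuts = sorted(rng.sample(range(1, n), min(n_seg - 1, n - 1))) if n_seg > 1 else []
        bounds = [0] + cuts + [n]
        seq = []
        recipe = []
        for s, e in zip(bounds, bounds[1:]):
            row = rng.randrange(len(msa.rows))
            seq.append(msa.rows[row][s:e])
            recipe.append((msa.row_ids[row], s, e))
        seq = list("".join(seq))
        novel = []
        n_novel = _poisson(rng, novel_snp_rate * n)
        positions = rng.sample(range(n), min(n_novel, n))
        for pos in sorted(positions):
            col = {r[pos] for r in msa.rows}
            options = [b for b in _BASES if b not in col]
            if not options:
                continue
            alt = rng.choice(options)
            novel.append((pos, seq[pos], alt))
            seq[pos] = alt
        truth.sequences[locus] = "".join(seq)
        truth.recipes[locus] = recipe
        truth.novel_snps[locus] = novel
    return truth


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    import math

    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


@dataclass
class ReadLedger:
    """Origin of every simulated read: genome offset, strand, errors."""

    entries: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (read_id, genome start, strand 0/1, n_errors)


def simulate_reads(
    genome: str,
    depth: float,
    read_len: int,
    error_rate: float,
    seed: int,
    sample_id: str = "sample",
) -> tuple[list[tuple[str, str]], ReadLedger]:
    """Uniform shotgun reads from a circularized genome with substitution
    errors; returns (read records, origin ledger)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = random.Random(seed)
    g2 = genome + genome[:read_len]  # circular wrap
    n_reads = int(len(genome) * depth / read_len)
    reads = []
    ledger = ReadLedger()
    for i in range(n_reads):
        start = rng.randrange(len(genome))
        frag = g2[start : start + read_len]
        strand = rng.randrange(2)
        n_err = 0
        if error_rate > 0:
            s = list(frag)
            for j in range(len(s)):
                if rng.random() < error_rate:
                    s[j] = rng.choice([b for b in _BASES if b != s[j]])
                    n_err += 1
            frag = "".join(s)
        if strand:
            frag = revcomp(frag)
        rid = f"{sample_id}.read{i}"
        reads.append((rid, frag))
        ledger.entries.append((rid, start, strand, n_err))
    return reads, ledger


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Truth ledgers for the evaluation machinery


def pairwise_variants(samples: list[SampleTruth]) -> list[dict]:
    """All pairwise single-position variants between sample genomes, as
    allele-triple pairs keyed by (genome, chromosome=locus, position).

    Valid because the generator is substitution-only: locus sequences
    share coordinates, so a direct column comparison is exact.
    """
    out = []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            for locus in sorted(set(a.sequences) & set(b.sequences)):
                sa, sb = a.sequences[locus], b.sequences[locus]
                for pos, (x, y) in enumerate(zip(sa, sb)):
                    if x != y:
                        out.append(
                            {
                                "allele1": [a.sample_id, locus, pos, x],
                                "allele2": [b.sample_id, locus, pos, y],
                            }
                        )
    return out


def write_truth_json(
    samples: list[SampleTruth], path: str | Path, include_sequences: bool = True
) -> None:
    doc = {
        "genomes": {
            s.sample_id: (s.sequences if include_sequences else sorted(s.sequences))
            for s in samples
        },
        "novel_snps": {s.sample_id: s.novel_snps for s in samples},
        "pairwise_variants": pairwise_variants(samples),
    }
    Path(path).write_text(json.dumps(doc))
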