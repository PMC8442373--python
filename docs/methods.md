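# Methods

This note records the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Local graph construction

A locus graph is built from its MSA by recursive cluster-and-collapse.
Vertical partition: columns are tiled into maximal *match* runs — a run
[i, j) is a match when j − i ≥ m (default m = 7 columns) and the slice
holds exactly one distinct non-empty de-gapped sequence — and the
remaining *non-match* runs. The scan is greedy left-to-right, extending
each start to the farthest end still satisfying the criterion; because
gap-shifted rows can transiently disagree and re-agree, every candidate
end is tested, with early exit once any row disagrees on content (which
can never heal). Horizontal partition: the rows of a non-match slice are
embedded as m-mer count vectors (sequences shorter than m give the zero
vector) and split by K-means (k-means++ init, 10 restarts, fixed seed,
K = 2, 3, …) until each cluster passes the one-reference-like test —
every row within d·len(A) mismatches of the cluster consensus, d = 0.2,
counted per alignment column over positions where the consensus has a
base, a row gap counting as a mismatch. If no K up to 10 passes, the
K = 10 partition is accepted and recursion continues; depth is capped at
r = 5, after which each remaining sub-alignment contributes one node per
unique de-gapped sequence. Consensus ties resolve to the
lexicographically smallest base, so construction is deterministic.

Two representational details follow from the spellability requirement
(every input allele must be a source-to-sink path): a match interval in
which some rows are entirely gapped emits an empty bypass node alongside
the collapsed sequence node, and empty nodes are legal throughout
(deletion branches). Graphs serialize to GFA v1 with the locus id in a
header tag; the recursion tree is memoized to a JSON sidecar.

Updating with new alleles routes each allele down the memoized tree:
vertical nodes slice the allele by a global alignment to the node's
consensus (edlib, NW mode), horizontal nodes send it to the child with
the smallest edit distance to any member sequence, sequence leaves
simply gain the allele, and a match leaf that no longer matches is
re-aligned pairwise and its subtree recomputed in place. Re-adding an
existing allele is a no-op, and updating then re-emitting preserves all
previously spellable sequences.

## Minimizer sketching and the k-mer graph

The k-mer hash is a fixed splitmix64-style invertible mix of the 2-bit
packed k-mer; canonical orientation is the strand with the smaller hash
(palindromes resolve forward). String sketches keep every k-mer
achieving the window minimum (ties are not broken). Graph sketches are
the union of window minimizers over all walks of w + k − 1 bases,
computed by enumerating the distinct base paths from every start
position; graphs whose longest walk is shorter than one window are
indexed by treating each full source-to-sink walk as a single window, so
short intergenic loci stay findable. Windows containing non-ACGT
symbols are skipped. Defaults are w = 14, k = 15; w ≤ k is enforced
because it makes path sequences unique outside the first and last
w + k − 1 bases.

K-mer-graph edges join each minimizer to the first minimizer(s) after it
along a walk. This is computed by walking forward from each minimizer's
placement while tracking partially matched candidate placements; a
candidate completes (and terminates its branch) only when its entire
placement has been walked, so two branches diverging inside a candidate's
span each get their own successor. Source and sink edges come from the
same walk anchored at the graph ends.

## Quasi-mapping and coverage

Hits are exact minimizer-hash matches between a read sketch and the
index, clustered per (read, locus, orientation) with a gap threshold of
2(w + k) bases (the paper-level description names only "a certain
distance"). Sufficiency uses ceilings: ≥ 10 hits and ≥ ⌈0.2·target⌉
where target is the shortest-path node count (long mode) or the sketch
size (short mode). Hits of sufficient clusters increment per-node
forward/reverse counters.

One addition proved necessary: the union-over-walks definition places
some k-mers on a walk via windows that mix branches, so a read following
that walk never samples them in its own sketch ("ghost" minimizers).
Left at zero coverage they made the path DP prefer wrong branches (only
~60% of loci were recovered exactly in early measurements). After
cluster filtering, the unique k-mer-graph path between two consecutive
hits of one read whose spelled sequence equals the read fragment has its
interior nodes credited. This is a constant-size exact string
comparison between anchored minimizers, not base-level alignment; with
it, mosaic recovery is exact outside the terminal zone on every locus of
the test cohorts.

The post-hoc presence filter marks a candidate locus absent when the
mean or median coverage along its inferred path falls below 5% of the
sample's average locus coverage or below 3x; both constants are exposed.

## Mosaic path inference

Node coverage s is modelled as negative binomial with pmf
Γ(r+s)/(Γ(r)s!)·p^r(1−p)^s; (r, p) solve mean = (1−p)r/p and
variance = (1−p)r/p² by moments. The fit uses the sample's k-mers with
positive coverage: zero-coverage nodes are dominated by the absent
alleles of each graph, which the model is not meant to describe — a
zero-inflated fit would make uncovered branches look likely.
Underdispersed data (variance ≤ mean, impossible under the model) gets
its variance inflated to 1.1·mean + 1 with a warning.

The path score sums log-pmf over all real nodes of a source-to-sink
path and divides by min(M, path length), M = 100. Capping the
denominator (rather than scoring only a prefix) keeps scores comparable
across loci of very different lengths without leaving distal bubbles
unscored; a prefix cap would resolve any bubble beyond the first M
minimizers arbitrarily. The DP state is (node, min(count, M)) with
exact counts below M; ties are broken deterministically by preferring
the smallest predecessor id. Spelling a path stitches the overlapping
minimizer placements (consistency asserted) and fills the bases before
the first and after the last minimizer with a deterministic
smallest-topological-neighbour walk to the graph ends — those terminal
w − 1 bases are the one place the sketch cannot distinguish branches,
so "exact recovery" is always stated outside that zone.

## De novo discovery

Per-base coverage along the mosaic is the minimum over the path k-mers
spanning the base (a base is supported only if every minimizer covering
it is), with uncovered terminal bases inheriting the nearest value.
Candidate regions are maximal runs below c (default 2) of length more
than l = 1 and less than the run cap. The cap scales with the sketch:
a single variant suppresses read-sketch sampling of every window
overlapping it, widening the low-coverage footprint to ~2(w + k) bases,
so the default cap is 2(w + k) + 10 rather than a fixed constant.
Regions are padded by 28 bases; read slices are located by the nearest
on-path minimizer hits (orientation-normalized), assembled into a de
Bruijn graph with k = 11 and per-k-mer counts. Anchors scan the mosaic
from the outermost pad inwards and may enter the region itself — k-mers
containing the variant are absent from the pileup graph, so the scan
stops at the first k-mer the reads support; discovery aborts (normally)
if either anchor is missing. Enumeration is DFS from the left anchor
pruned by a reversed-BFS distance map from the right anchor (nodes that
cannot reach it within the remaining length budget are cut, which also
bounds cycles), a path-length cap of twice the padded region, and a
budget of 2k low-coverage nodes below f·e_r, where e_r is the median
k-mer count and f = n·s escalates in steps of s = 0.1 whenever more
than 500 paths survive, abandoning past f > 1. Each accepted path
replaces its anchored slice of the mosaic to form a full-length
candidate allele; candidates from all samples are pooled, routed into
the local graphs, and the second mapping pass runs with no further
discovery. Variants within ~w_pad + k of a locus end cannot be anchored
on both sides and are structurally undiscoverable at this stage.

## Genotyping and the VCF reference

The VCF reference reuses the mosaic DP with node log-probability
log((c + 0.01)/(N + 0.01)), c the number of sample mosaic paths through
the node, N the number of samples. Sites are bubbles off the reference
path: a divergence opens a site, the site closes at the first reference
node where every excursion has rejoined, and overlapping divergences
merge (so records never overlap; nested variation appears as extra
alleles). Allele sequences are trimmed to minimal VCF form (shared
suffix then prefix, keeping one base), which renders a SNP bubble on the
reference as a single-base REF/ALT pair. Bubbles touching the synthetic
source or sink have no anchored coordinate and are not emitted.

Per allele and sample, mean forward and reverse coverage is taken over
the allele's interior k-mers (a pure-deletion allele falls back to the
bubble's flanking nodes — deletion genotyping is correspondingly
weaker). The allele log-likelihood is Poisson: the allele's rounded
mean coverage at rate d (the sample's expected depth, estimated as the
mean path coverage over present loci) plus every other allele's at rate
εd with ε = 0.01. A site is called for the allele on the sample's
mosaic path iff it is also the likelihood argmax; otherwise the
genotype is null — a deliberate refusal to guess when global and local
evidence disagree. gt-conf is the gap between the two best
log-likelihoods. Filters (Illumina 5x / Nanopore 10x minimum coverage,
5% per-strand minimum, gaps 0.8 / 0.6 where the gaps fraction counts
allele k-mers at or below 10% of expected depth) mask calls to null
rather than dropping records.

## Evaluation machinery

Pan-genome variants are connected components of the graph whose nodes
are pairwise variants and whose edges join pairs sharing a (genome,
chromosome, position) allele; filtering keeps components with at most
one allele per genome and exactly two distinct single-base alleles.
PVR and AvgAR follow directly from the detection matrix. Probe scoring
uses edlib in infix mode: precision probes are the called allele with
150 bp of reference flank, scored as matches over alignment columns
within the allele span only, with calls discarded when the best and
second-best placements are within 10 edits of each other (ambiguity) or
fall in masked regions; recall probes are each truth allele with flanks
from its own genome, mapped to the calling sample's mutated reference
(VCF applied right-to-left), detected only when every allele base
matches.

## Synthetic data

The generator emulates the structure the method assumes: loci drawn
with a two-component carriage mixture (30% of loci present in 10% of
genomes, the rest in 95% — the two modes of the U-shape), per-locus
ancestors with 4 substitutions per derived allele, sample genomes as
1–3-segment crossover mosaics of panel alleles with Poisson-implanted
novel SNPs guaranteed absent from the panel column, and uniform
circular shotgun reads with substitution errors only. Substitution-only
simulation keeps all alleles of a locus the same length, so truth
coordinates align with VCF-reference coordinates and genotype
concordance can be checked by direct substring comparison. What this
does not exercise: indel variation and alignment gaps in panels (these
are covered by hand-built construction tests instead), structured error
profiles (homopolymer bias), contamination, and true structural
variation — conclusions from passing tests extend to real data only for
the SNP-dominated, moderate-divergence regime the simulator mimics.

Default test conditions are 50 loci of 0.8–1.2 kb, 10 panel genomes, 3
samples at 30x with error-free 600 bp reads — small enough to run the
whole pipeline in a couple of minutes while leaving every stage
(clustering, bubbles, discovery, joint genotyping) non-trivially
exercised.

## Known limitations

- Variation confined to the first/last w − 1 bases of a locus is
  invisible to the sketch; terminal bubbles are neither emitted as VCF
  sites nor recoverable in mosaics.
- De novo discovery cannot anchor variants within ~w_pad + k of locus
  ends, and merges of nearby variants whose joint footprint exceeds the
  run cap are skipped.
- Pure-deletion alleles are genotyped from flanking coverage only.
- The mosaic DP tie-break is deterministic (smallest predecessor id)
  but not globally lexicographic on node sequences.
- Per-locus graphs carry no ordering information; gene-order inference
  is out of scope.
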