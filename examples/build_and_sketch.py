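"""Build a local graph from a toy MSA and sketch it with minimizers.

Two alleles of a short locus differ by one SNP; the recursive
cluster-and-collapse construction turns the alignment into a four-node
bubble graph, which is then sketched with (w,k)-minimizers to give the
k-mer graph used by every downstream step.
"""

from panmosaic import (
    Msa,
    RccParams,
    MinimizerParams,
    build_local_graph,
    minimizers_and_kmer_graph,
)

msa = Msa(
    rows=["ACGTGGCTAGCAATCGGCTA", "ACGTGGCTAACAATCGGCTA"],
    row_ids=["allele1", "allele2"],
    locus_id="toy_gene",
)

graph, tree = build_local_graph(msa, RccParams())
print("local graph nodes (id -> sequence):")
for nid, seq in graph.nodes.items():
    print(f"  {nid}: {seq or '(empty)'}")
print("spelled alleles:", sorted(graph.path_sequences()))

params = MinimizerParams(w=4, k=5)
mins, kmer_graph = minimizers_and_kmer_graph(graph, params)
print(f"\n(w={params.w}, k={params.k}) minimizers: {len(mins)}")
print(f"k-mer graph: {len(kmer_graph.real_nodes)} minimizer nodes + source/sink")

# The two branch nodes of the bubble (G vs A at position 9) appear as
# alternative k-mers; every allele of the locus remains spellable as a
# path through the k-mer graph, which is what makes alignment-free
# genotyping possible.
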