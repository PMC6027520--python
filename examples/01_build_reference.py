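"""Build per-species core-genome references from gene catalogues.

Each species' core genes are concatenated into a single reference
sequence; the entry length l_i is what later converts mixture weights
into relative abundances.
"""

import coremix as cm

gene_sets = [
    cm.SpeciesGeneSet("E_exemplaris", ("ACGTACGTACGT", "GGGCCCAAATTT")),
    cm.SpeciesGeneSet("B_fictus", ("TTTTAAAACCCC",)),
]
refset = cm.build_reference(gene_sets)

for entry in refset:
    print(entry.species_id, "length", entry.length, "gene offsets", entry.offsets)

cm.write_reference_fasta(refset, "scratch_reference.fasta",
                         "scratch_reference.lengths.tsv")
loaded = cm.load_reference("scratch_reference.fasta")
print("round-trip ok:", loaded.lengths == refset.lengths)
# The two lengths (24, 12) are the l_i in the abundance formula
# a_i = (theta_i / l_i) / sum_s (theta_s / l_s).
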