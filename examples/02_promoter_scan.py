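"""Plant consensus boxes in a synthetic genome and recover them by scanning.

Each gene's promoter window runs from 300 nt upstream to 150 nt downstream
of the translation start (first base of the start codon = position 0). The
scan slides the 22-nt consensus over both strands of every window and
reports the best hit per gene.
"""

from regulonscan import (
    ConsensusMotif,
    generate_genome,
    make_degenerate_motif,
    plant_motif,
    scan_genome,
)

consensus = ConsensusMotif()
genome = generate_genome(n_contigs=1, genes_per_contig=6, intergenic_nt=600,
                         gene_nt=900, gc=0.606, seed=11)

# a perfect box upstream of one gene, a 1-mismatch box inside another's CDS
genome = plant_motif(genome, "g1_2", consensus.sequence, distance_nt=-120,
                     strand="+")
weaker = make_degenerate_motif(consensus, n_mismatches_outside=1, seed=4)
genome = plant_motif(genome, "g1_5", weaker, distance_nt=40, strand="-")

hits = scan_genome(genome, min_identity_pct=90.0)
print(hits.to_string(index=False))
print(
    "\nNegative distances are upstream of the start codon; strand '-' means"
    " the box matches the reverse complement of the gene-oriented frame."
)
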