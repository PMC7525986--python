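# Example locus configuration for equid MHC class II exon-2 analysis.
#
# exon2_length: analyzed amplicon length in bp.  DQB loci carry the complete
#   269-bp exon 2; DRB amplicons miss the nine 3' exon nucleotides (the
#   nested reverse primer sits on the exon-intron boundary), so DRB records
#   are 260 bp.
# abs_codons: 1-based codon positions of the putative antigen binding site
#   within the trimmed exon.  The lists below are an EXAMPLE derived from
#   the human/murine class II peptide-contact residues of the beta-1 domain;
#   substitute your own structure-based list for production analyses.
# gene_interval: 0-based half-open reference coordinates used for
#   depth-table extraction (EquCab3.0 chr20 coordinates).

loci:
  DRB1:
    exon2_length: 260
    abs_codons: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65,
                 67, 68, 70, 71, 74, 78, 81, 85, 86]
    primer_fwd: TGACCGGATCCTTCCTGTAC
    primer_rev: GCGCTCACCTCGCCGAC
    gene_interval: {reference: chr20, start: 33625486, end: 33631729}
  DRB2:
    exon2_length: 260
    abs_codons: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65,
                 67, 68, 70, 71, 74, 78, 81, 85, 86]
    primer_fwd: TGACCCGATCSTTCCTGTAT
    primer_rev: GCGCTCACCTCGCCGAG
    gene_interval: {reference: chr20, start: 34096674, end: 34108525}
  DRB3:
    exon2_length: 260
    abs_codons: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65,
                 67, 68, 70, 71, 74, 78, 81, 85, 86]
    primer_fwd: TGACCGGATCCTTCCTGTAC
    primer_rev: GCGCTCACCTCGCCGAT
    gene_interval: {reference: chr20, start: 34266650, end: 34285281}
  DQB1:
    exon2_length: 269
    abs_codons: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65,
                 67, 68, 70, 71, 74, 78, 81, 85, 86, 89]
    primer_fwd: CCTCTGGGGTAACGTTCCAG
    primer_rev: CGGCCTTGCTTTAGGTTTATC
    gene_interval: {reference: chr20, start: 33812678, end: 33820407}
  DQB2:
    exon2_length: 269
    abs_codons: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65,
                 67, 68, 70, 71, 74, 78, 81, 85, 86, 89]
    primer_fwd: AGGTTTCTCCCACTCAACTGCC
    primer_rev: TGAGGACGCGCCCACCTCCCTGTCC
    gene_interval: {reference: chr20, start: 33941931, end: 33956144}
  DQB3:
    exon2_length: 269
    abs_codons: [9, 11, 13, 26, 28, 30, 32, 37, 38, 47, 56, 57, 60, 61, 65,
                 67, 68, 70, 71, 74, 78, 81, 85, 86, 89]
    primer_fwd: AGGTTTATCCGATCCAACCG
    primer_rev: GCTGCGCCCTCCCAGCTCCGAGACT
    gene_interval: {reference: chr20, start: 34031397, end: 34037071}
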