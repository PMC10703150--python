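# Default region definitions over the concatenated exon 2 + exon 3 protein
# alignment of HLA class I (positions 1-183; exon 2 = 1-90, exon 3 = 91-183).
#
# These are documented defaults drawn from the structural literature, meant
# to be edited per study:
#   * peptide_binding: the classical peptide-contacting pocket residues of
#     the class I groove (pockets A-F).
#   * bw4: the canonical Bw4 public-epitope positions 77-83, the main KIR
#     ligand motif on HLA-B (and some HLA-A) molecules.
#   * loop / helices / groove: a coarse structural partition of 1-183 into
#     the beta-sheet groove floor, the alpha-1/alpha-2 helices (minus the
#     Bw4 stretch, which forms its own region) and the connecting loops.
#     The four sets are disjoint and cover every position exactly once.
#
# Position entries may be integers or "a-b" inclusive range strings.

peptide_binding:
  - 5
  - 7
  - 9
  - 24
  - 25
  - 33
  - 34
  - 45
  - 59
  - 62
  - 63
  - 66
  - 67
  - 69
  - 70
  - 73
  - 74
  - 76
  - 77
  - 80
  - 81
  - 84
  - 95
  - 97
  - 99
  - 113
  - 114
  - 116
  - 118
  - 123
  - 124
  - 133
  - 143
  - 146
  - 147
  - 152
  - 155
  - 156
  - 159
  - 160
  - 163
  - 167
  - 171

bw4:
  - "77-83"

helices:
  - "50-76"
  - 84
  - "138-176"

groove:
  - "1-49"
  - "91-137"

loop:
  - "85-90"
  - "177-183"

exon2:
  - "1-90"

exon3:
  - "91-183"

# Alleles excluded from phylogenetic analysis (e.g. recombination or gene
# conversion within exon 2/3).  Empty by default; supply your own list.
excluded_alleles: []
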