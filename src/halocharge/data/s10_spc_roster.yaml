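# S10-spc cluster ribosomal protein roster.
#
# The bacterial roster lists, in operon order, the 11 r-proteins of the E.
# coli S10 operon followed by the 10 r-proteins of the spc operon (21 total).
# Archaea and Eukarya carry the same 21 plus four additional r-protein genes
# within the equivalent conserved cluster; their identity here (eS4, eL32,
# eL19, eL15) follows the conserved archaeal cluster layout and is editable
# data, not code.  Eukaryal cluster figures additionally show an RNase P
# protein subunit entry (RNP1); it is an optional, non-r-protein member.
#
# Synonyms are matched case-insensitively on word boundaries; they must be
# pairwise disjoint across entries.  Universal names follow the
# (u|b|e)(L|S)<number> nomenclature.

members:
  uS10: {synonyms: [S10, rpsJ]}
  uL3:  {synonyms: [L3, rplC]}
  uL4:  {synonyms: [L4, rplD]}
  uL23: {synonyms: [L23, rplW, L23a]}
  uL2:  {synonyms: [L2, rplB, L8e]}
  uS19: {synonyms: [S19, rpsS, S15e]}
  uL22: {synonyms: [L22, rplV, L17e]}
  uS3:  {synonyms: [S3, rpsC]}
  uL16: {synonyms: [L16, rplP, L10e]}
  uL29: {synonyms: [L29, rpmC, L35e]}
  uS17: {synonyms: [S17, rpsQ, S11e]}
  uL14: {synonyms: [L14, rplN, L23e]}
  uL24: {synonyms: [L24, rplX, L26e]}
  uL5:  {synonyms: [L5, rplE, L11e]}
  uS14: {synonyms: [S14, rpsN, S29e]}
  uS8:  {synonyms: [S8, rpsH, S15Ae]}
  uL6:  {synonyms: [L6, rplF, L9e]}
  uL18: {synonyms: [L18, rplR, L5e]}
  uS5:  {synonyms: [S5, rpsE, S2e]}
  uL30: {synonyms: [L30, rpmD, L7e]}
  uL15: {synonyms: [L15, rplO, L27Ae]}
  eS4:  {synonyms: [S4e, rps4e]}
  eL32: {synonyms: [L32e, rpl32e]}
  eL19: {synonyms: [L19e, rpl19e]}
  eL15: {synonyms: [L15e, rpl15e]}
  RNP1:
    synonyms: [RNase P1, RNase P protein 1]
    non_rprotein: true

domains:
  Bacteria:
    members: [uS10, uL3, uL4, uL23, uL2, uS19, uL22, uS3, uL16, uL29, uS17,
              uL14, uL24, uL5, uS14, uS8, uL6, uL18, uS5, uL30, uL15]
  Archaea:
    members: [uS10, uL3, uL4, uL23, uL2, uS19, uL22, uS3, uL16, uL29, uS17,
              uL14, uL24, eS4, uL5, uS14, uS8, uL6, eL32, eL19, uL18, uS5,
              uL30, eL15, uL15]
  Eukarya:
    members: [uS10, uL3, uL4, uL23, uL2, uS19, uL22, uS3, uL16, uL29, uS17,
              uL14, uL24, eS4, uL5, uS14, uS8, uL6, eL32, eL19, uL18, uS5,
              uL30, eL15, uL15]
    optional_members: [RNP1]
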