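# Case-encoded promoter consensus motifs.
# Uppercase = strongly conserved position, lowercase = weakly conserved;
# IUPAC degenerate letters allowed (M = A or C).  spacing_min/max give the
# native spacer window of the source consensus (nucleotides strictly between
# the -35 and -10 elements).
motifs:
  - sigma_label: 28
    source: B_fibrisolvens
    minus35: TAAA
    minus10: MCGATAa
    spacing_min: 16
    spacing_max: 17
  - sigma_label: 43
    source: B_fibrisolvens
    minus35: TTtACA
    minus10: cATAAT
    spacing_min: 19
    spacing_max: 19
  - sigma_label: 28
    source: general
    minus35: TAAA
    minus10: CCGATAT
    spacing_min: 15
    spacing_max: 15
  - sigma_label: 43
    source: general
    minus35: TTGACA
    minus10: TATAAT
    spacing_min: 15
    spacing_max: 15
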