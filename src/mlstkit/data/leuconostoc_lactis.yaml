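# Eight-locus housekeeping-gene MLST scheme for Leuconostoc lactis.
# Loci are listed alphabetically; this order fixes profile-table columns.
# reference_span coordinates refer to the L. mesenteroides subsp.
# mesenteroides ATCC 8293 genome and are documentation only.
name: leuconostoc_lactis
loci:
  - name: carB
    protein: carbamoyl phosphate synthase large subunit
    forward_primer: ATGGGTTGTGGGAGTTGTA
    reverse_primer: ACTTGTTGCGTCGTGGTGT
    amplicon_length: 833
    reference_span: [1202174, 1205353]
  - name: groEL
    protein: chaperonin GroEL
    forward_primer: CGGTGATAAGGCTGCTGT
    reverse_primer: TTTGTTGGGTCCACGATA
    amplicon_length: 892
    reference_span: [1734716, 1736335]
  - name: murC
    protein: UDP-N-acetylmuramate-L-alanine ligase
    forward_primer: TTTCATAGGCGAACTCAT
    reverse_primer: GTGCCATTGTTTGGTCAG
    amplicon_length: 619
    reference_span: [679802, 681136]
  - name: pheS
    protein: phenylalanyl-tRNA synthetase subunit alpha
    forward_primer: TTTCTTAGGTTTAGGCTTTG
    reverse_primer: CCTTTCGGTTAAATTGTGA
    amplicon_length: 665
    reference_span: [406737, 407813]
  - name: pyrG
    protein: CTP synthase
    forward_primer: AGCAAACACCCAAGAACG
    reverse_primer: TGGTGAAGCGAAGACAAA
    amplicon_length: 598
    reference_span: [481322, 482935]
  - name: recA
    protein: recombinase A
    forward_primer: GGAGTCGTTTCTGGGTTAC
    reverse_primer: GTTGCTTTAGGCGTTGGTG
    amplicon_length: 550
    reference_span: [555064, 556221]
  - name: rpoB
    protein: DNA-directed RNA polymerase subunit beta
    forward_primer: CACTGTGCGGTCGTCTTCC
    reverse_primer: GCGTTCTCCTGGTATCTATT
    amplicon_length: 608
    reference_span: [1798123, 1801731]
  - name: uvrC
    protein: excinuclease ABC subunit C
    forward_primer: AGAAATACAAGCCGTACTACAA
    reverse_primer: TCTTCATCAGCGGAACCAA
    amplicon_length: 560
    reference_span: [483053, 484852]
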