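# Default peptide-binding-region codon mask for a 298-nt class II B
# exon-2 fragment read in frame 0 (99 complete codons, 0-based indices).
#
# The positions follow the classical human DRB beta-chain peptide-contact
# residues, assuming fragment codon 0 corresponds to mature beta-chain
# residue 6. This offset is an interpretation, not a measured anchor:
# edit this file to match the fragment actually genotyped.
frame_offset: 0
total_codons: 99
pbr_codons: [3, 5, 7, 20, 22, 24, 26, 31, 32, 41, 50, 51, 54, 55, 59, 61, 62, 64, 65, 68, 72, 75, 76, 79, 80, 82, 83]
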