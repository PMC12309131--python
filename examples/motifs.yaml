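# Illustrative motif configuration for icrscan.
#
# NOTE: the ZMO strings below are an ILLUSTRATIVE example set (the ZFP57
# hexamer extended by one base on either side), NOT the published ZFBS-morph
# overlap list. Supply your own 'zmos' list to reproduce published scans.
#
# Schema:
#   hexamer: ZFP57 binding hexamer (default TGCCGC)
#   zmos: explicit list of composite element strings (takes precedence)
#   morphemes: morpheme lexicon; composites are derived by overlap enumeration
#   min_overlap: minimum shared bases for derivation (default 1)
#   strand_policy: both_strands | forward_only (default both_strands)

hexamer: TGCCGC
strand_policy: both_strands
zmos:
  - TGCCGCA
  - TGCCGCC
  - TGCCGCT
  - ATGCCGC
  - CTGCCGC
  - GTGCCGC

# Alternative: derive composites from a morpheme lexicon instead.
# morphemes:
#   - CGCA
#   - GCCGCC
# min_overlap: 2
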