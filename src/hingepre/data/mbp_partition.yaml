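# Domain partition for maltose-binding protein (PDB numbering, inclusive
# residue ranges).  Follows the common NTD / hinge / CTD convention for MBP
# hinge-bending analyses; the partition is a modelling convention and is
# always a configuration input, never hard-coded.  Interdomain angles shift
# by ~1-2 degrees under alternative hinge definitions.
ntd:
  - [1, 109]
  - [264, 309]
hinge:
  - [110, 113]
  - [259, 263]
  - [310, 315]
ctd:
  - [114, 258]
  - [316, 370]
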