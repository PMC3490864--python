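# Motif-anchored cutting rules for the four cellulase architectures.
#
# Pattern syntax used by cellink.segmentation:
#   UPPERCASE letter -> residue required at that position
#   [XY]             -> required, one of the listed residues
#   (X)              -> wildcard position preferring X (scored, not required)
#   .                -> wildcard, no preference
#
# Offsets are residue counts; windows limit motif searches.  Edit and pass
# to cellink.segmentation.load_schemes() to tune rules without code changes.

CBM1_GH6:
  signal_anchor: QCGG          # first occurrence anchors the CBM1 N-terminus
  signal_keep_upstream: 6      # residues kept N-terminal to the anchor (signal trim)
  cbm_end_motif: (S)QC(L)      # CBM ends after this motif
  cbm_end_window: 60           # search span downstream of the signal anchor
  gh_start_motif: (G)N(P)(F)   # GH6 N-terminal motif
  gh_start_offset: 5           # GH begins this many residues N-terminal to the motif

GH7_CBM1:
  gh_end_motif: "[ST][ND]IK"   # GH7 C-terminal motif
  gh_end_tail: 9               # GH keeps this many residues after the motif
  cbm_anchor: QCGG
  cbm_keep_upstream: 6         # CBM begins this many residues N-terminal to QCGG

CBM2_GH6:
  cbm_window: 140              # leading span searched for the conserved Cys
  cbm_tail: 2                  # CBM keeps this many residues after the Cys
  gh_start_motifs:             # first is preferred, later entries are fallbacks
    - RVDN
    - YVD

GH6_CBM2:
  gh_end_motif: FVML
  gh_end_tail: 8
  cbm_start_residues: CLIF     # CBM begins at the first of these residues...
  min_linker: 10               # ...at least this far downstream of the GH cut
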