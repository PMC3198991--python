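# Functional-residue fingerprint configuration, in precursor numbering of the
# packaged H. salinarum bacteriorhodopsin anchor (mature index + 13).
#
# acceptor/donor: Schiff-base proton acceptor (Asp98) and donor (Asp109) in
# Helix C.  schiff_lysine: the retinal-binding lysine (K229 = mature K216).
# helixG_diagnostic: the Helix-G aspartate column (mature D212) where
# xenorhodopsins carry a conserved proline.
numbering_offset: 13
acceptor_pos: 98
donor_pos: 109
schiff_lysine_pos: 229
helixG_diag_pos: 225
inward_pump_pos: 230          # ASR D217E engineering site; annotated, never classified on
pocket_min_fraction: 0.8
min_aligned_fraction: 0.5
# Retinal-binding pocket, anchored positions with allowed residues
# (bacteriorhodopsin literature set; Helix-G D212 excluded -- it is the
# diagnostic column above).
pocket_positions:
  99:  [W]          # W86
  102: [T, S]       # T89
  103: [T, S]       # T90
  131: [M, L]       # M118
  135: [G, A]       # G122
  151: [W]          # W138
  154: [S, T, A]    # S141
  155: [T, S]       # T142
  158: [M, L]       # M145
  195: [W]          # W182
  198: [Y, F]       # Y185
  202: [W]          # W189
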