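# Protease cleavage-rule registry.
#
# Each entry defines a site-specificity rule:
#   c_terminal_of:   cut the bond on the C-terminal side of these residues
#   n_terminal_of:   cut the bond on the N-terminal side of these residues
#   blocked_p1prime: residues that veto a cut when they sit immediately
#                    C-terminal to the candidate bond (P1' position)
#
# A bond after residue i is cut iff
#   (residue_i in c_terminal_of  OR  residue_{i+1} in n_terminal_of)
#   AND residue_{i+1} not in blocked_p1prime.
#
# The default four enzymes model the gastric (pepsin) and intestinal
# (trypsin + chymotrypsin) digestion phases plus bromelain, the food-grade
# protease used for hydrolysate preparation. The *_strict variants carry the
# classic textbook exception (no cut before Pro); they are not used unless
# requested. pepsin_ph_gt2 / pepsin_ph1.3 are registry aliases for the two
# BIOPEP pepsin models; further enzymes can be appended here without code
# changes.

pepsin:
  c_terminal_of: [F, I, Y, W]
  n_terminal_of: [M, E, L, F]
  blocked_p1prime: []

pepsin_ph_gt2:
  c_terminal_of: [F, I, Y, W]
  n_terminal_of: [M, E, L, F]
  blocked_p1prime: []

pepsin_ph1.3:
  c_terminal_of: [F, I, Y, W]
  n_terminal_of: [M, E, L, F]
  blocked_p1prime: []

trypsin:
  c_terminal_of: [H, K, R]
  n_terminal_of: []
  blocked_p1prime: []

trypsin_strict:
  c_terminal_of: [H, K, R]
  n_terminal_of: []
  blocked_p1prime: [P]

chymotrypsin:
  c_terminal_of: [F, Y, W]
  n_terminal_of: []
  blocked_p1prime: []

chymotrypsin_strict:
  c_terminal_of: [F, Y, W]
  n_terminal_of: []
  blocked_p1prime: [P]

bromelain:
  # Cuts between a hydrophobic residue (P1) and a basic residue (P1'):
  # expressed as C-terminal-of-hydrophobic with every non-basic P1' vetoed.
  c_terminal_of: [A, V, L, I, P, F, M, W, G]
  n_terminal_of: []
  blocked_p1prime: [A, C, D, E, F, G, I, L, M, N, P, Q, S, T, V, W, Y]
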