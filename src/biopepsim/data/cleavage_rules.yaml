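# Bundled protease specificity rulebook.
#
# Grammar: a YAML list of enzymes.  Each enzyme has
#   name:        unique display name
#   ec:          EC number, or "-" when unassigned
#   clauses:     list of site clauses; a peptide bond is a candidate cut iff
#                at least one clause matches the P2-P1-P1'-P2' window around
#                it (the bond is between P1 and P1').  Each clause maps any
#                subset of {p2, p1, p1prime, p2prime} to a list of allowed
#                residues; absent positions match any residue.  Window
#                positions beyond the termini fail constrained positions.
#   exceptions:  optional list of clauses with the same shape; a matching
#                exception vetoes the cut.
#
# The encodings below are documented simplifications of publicly described
# specificities (PeptideCutter-style), restricted to the four-residue
# window.  They define this package's reproducible local convention and are
# not a reconstruction of any web service's internal rules.

- name: trypsin
  ec: 3.4.21.4
  clauses:
    - p1: [K, R]
  exceptions:
    - p1prime: [P]

- name: chymotrypsin A
  ec: 3.4.21.1
  # high-specificity chymotrypsin: aromatic P1, not before proline
  clauses:
    - p1: [F, Y, W]
  exceptions:
    - p1prime: [P]

- name: chymotrypsin C
  ec: 3.4.21.2
  # low-specificity variant: additionally Leu and Met at P1
  clauses:
    - p1: [F, Y, W, L, M]
  exceptions:
    - p1prime: [P]

- name: pepsin (pH > 2)
  ec: 3.4.23.1
  # hydrophobic/aromatic preference on either side of the bond
  clauses:
    - p1: [F, L, W, Y]
    - p1prime: [F, L, W, Y]
  exceptions:
    - p1prime: [P]
    - p2: [P]
    - p1: [H, K, R]

- name: papain
  ec: 3.4.22.2
  # bulky hydrophobic at P2, basic or hydrophobic at P1
  clauses:
    - p2: [A, V, L, I, F, W, Y]
      p1: [K, R, A, G, L, V]
  exceptions:
    - p1prime: [P]

- name: bromelain
  ec: 3.4.22.32
  clauses:
    - p1: [K, A, Y, G]
  exceptions:
    - p1prime: [P]

- name: ficin
  ec: 3.4.22.3
  clauses:
    - p2: [A, V, L, I, F, W, Y]
      p1: [A, G, Y, F]
  exceptions:
    - p1prime: [P]

- name: thermolysin
  ec: 3.4.24.27
  # cleaves N-terminally to bulky hydrophobic residues
  clauses:
    - p1prime: [A, F, I, L, M, V]
  exceptions:
    - p1: [D, E]
    - p2prime: [P]

- name: proteinase K
  ec: 3.4.21.67
  clauses:
    - p1: [A, E, F, I, L, T, V, W, Y]

- name: pancreatic elastase
  ec: 3.4.21.36
  clauses:
    - p1: [A, V, G, S]
  exceptions:
    - p1prime: [P]

- name: glutamyl endopeptidase
  ec: 3.4.21.19
  clauses:
    - p1: [E]
  exceptions:
    - p1prime: [P, E]

- name: proline endopeptidase
  ec: 3.4.21.26
  clauses:
    - p2: [H, K, R]
      p1: [P]
  exceptions:
    - p1prime: [P]
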