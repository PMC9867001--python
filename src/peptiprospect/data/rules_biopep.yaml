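# Protease cleavage specificity, BIOPEP-UWM "Enzyme Action" dialect.
#
# Each rule cuts the peptide bond between P1 and P1'.  A rule fires when the
# P1 residue is in `p1` or the P1' residue is in `p1_prime`.  An exception
# pattern (mapping of window positions P4..P2prime to residue sets) blocks the
# cut when every listed position matches; an override pattern re-enables a
# blocked cut.  Window positions that fall outside the sequence never match.
dialect: BIOPEP
enzymes:
  pepsin_ph_gt2:
    name: Pepsin (pH > 2)
    ec_number: 3.4.23.1
    rules:
      - p1: [F, L, G, Y, A, E, Q, T, N, K, D, M]
        p1_prime: [V, I]
  trypsin:
    name: Trypsin
    ec_number: 3.4.21.4
    rules:
      - p1: [K, R]
        exceptions:
          # P after K blocks enzyme action (R-P is cleavable in this dialect)
          - {P1: [K], P1prime: [P]}
  chymotrypsin_A:
    name: Chymotrypsin A
    ec_number: 3.4.21.1
    rules:
      - p1: [F, Y, W, L, N, H, M]
        exceptions:
          # P after Y, F, L or W blocks; M after W blocks
          - {P1: [Y, F, L, W], P1prime: [P]}
          - {P1: [W], P1prime: [M]}
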