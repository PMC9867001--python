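# Protease cleavage specificity, ExPASy PeptideCutter dialect.
# Same schema as rules_biopep.yaml.
#
# The pepsin (pH > 2) entry is a transcription of PeptideCutter's positional
# rule matrix: cleavage wherever F, L, W or Y sits at P1 or at P1', with
# context blockers (proline at P2, P1' or P2'; H/K/R at P1 when the
# hydrophobic driver is at P1'; R at P3 when the driver is at P1).  It is kept
# in data so the matrix can be amended without a code change.
dialect: EXPASY
enzymes:
  pepsin_ph_gt2:
    name: Pepsin (pH > 2)
    ec_number: 3.4.23.1
    rules:
      # driver: hydrophobic residue entering P1'
      - p1_prime: [F, L, W, Y]
        exceptions:
          - {P1: [H, K, R]}
          - {P2: [P]}
          - {P2prime: [P]}
      # driver: hydrophobic residue at P1
      - p1: [F, L, W, Y]
        exceptions:
          - {P1prime: [P]}
          - {P2: [P]}
          - {P3: [R]}
  trypsin:
    name: Trypsin
    ec_number: 3.4.21.4
    rules:
      - p1: [R, K]
        exceptions:
          - {P1prime: [P]}
          - {P1: [K], P2: [D], P1prime: [D]}
          - {P1: [K], P2: [C], P1prime: [D]}
          - {P1: [K], P2: [C], P1prime: [H]}
          - {P1: [K], P2: [C], P1prime: [Y]}
          - {P1: [R], P2: [R], P1prime: [H]}
          - {P1: [R], P2: [C], P1prime: [K]}
          - {P1: [R], P2: [R], P1prime: [R]}
        overrides:
          # the P1'=P block is lifted for W-K-P and M-R-P contexts
          - {P1: [K], P2: [W], P1prime: [P]}
          - {P1: [R], P2: [M], P1prime: [P]}
  chymotrypsin_A:
    name: Chymotrypsin (low specificity)
    ec_number: 3.4.21.1
    rules:
      # H at P1 is cleavable here (it carries its own blocking contexts);
      # compile_ruleset can drop it for a strict five-residue P1 set.
      - p1: [F, Y, W, L, M, H]
        exceptions:
          - {P1prime: [P]}
          - {P1: [W], P1prime: [M]}
          - {P1: [M], P1prime: [Y]}
          - {P1: [H], P1prime: [D, M, W]}
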