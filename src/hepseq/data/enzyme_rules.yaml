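# Editable enzyme specificity tables.
#
# Residue specs are attribute -> list-of-allowed-values maps.  Attributes:
#   class          residue class name (delta_uronic, uronic, hexosamine,
#                  anhydromannitol, ring_contracted)
#   epimer         I / G / unknown   ("unknown" satisfies any epimer spec)
#   sulfo_2O, sulfo_3O, sulfo_6O     booleans
#   n_substituent  NS / NAc / NH2
#
# Lyase patterns match glucosamine->uronic bonds (donor = glucosamine on the
# NRE side of the bond, acceptor = uronic on the RE side).  A site is cut iff
# some pattern of an active enzyme matches and no blocking rule applies.
lyases:
  hepI:
    # A(NS,3X,6X) -> I(2S)
    - donor: {n_substituent: [NS]}
      acceptor: {epimer: [I], sulfo_2O: [true]}
  hepII:
    # broad specificity: any N-substituted glucosamine -> any uronic
    - donor: {n_substituent: [NS, NAc, NH2]}
      acceptor: {}
  hepIII:
    # A(NAc,6X) -> I(2OH)  and  A(NS,6X) -> G(2OH)
    - donor: {n_substituent: [NAc]}
      acceptor: {epimer: [I], sulfo_2O: [false]}
    - donor: {n_substituent: [NS]}
      acceptor: {epimer: [G], sulfo_2O: [false]}

# Blocking rules veto an otherwise matching lyase site.  "plus2" is the
# residue two positions past the bond (the glucosamine following the
# acceptor uronic); the rule applies only when that residue exists.
blocking:
  - id: B1     # A-G bond protected when followed by a 3-O-sulfated glucosamine
    enzymes: [hepI, hepII, hepIII]
    acceptor: {epimer: [G]}
    plus2: {class: [hexosamine], sulfo_3O: [true]}
  - id: B2     # unnatural reducing end: bond next to aM.ol is not processed
    enzymes: [hepI, hepII, hepIII]
    plus2: {class: [anhydromannitol]}

# Heparanase (endo-beta-D-glucuronidase) susceptibility rules, evaluated in
# order at each unsulfated-glucuronic -> glucosamine bond; the first matching
# rule decides.  Context fields:
#   acceptor  glucosamine on the RE side of the bond
#   minus1    glucosamine preceding the glucuronic acid (NRE side), if any
#   minus2    uronic residue two before the bond, if any
heparanase:
  - id: R0-end      # never observed to release an anhydro/ring-contracted RE
    acceptor: {class: [anhydromannitol, ring_contracted]}
    verdict: resist
  - id: R0-nac      # G->A(NAc) cleavage unobserved; default resist (unvalidated)
    acceptor: {n_substituent: [NAc, NH2]}
    verdict: resist
  - id: R1          # acceptor glucosamine lacks 6-O-sulfate -> resistant
    acceptor: {sulfo_6O: [false]}
    verdict: resist
  - id: R2          # preceding glucosamine lacks 6-O-sulfate -> resistant
    minus1: {class: [hexosamine], sulfo_6O: [false]}
    verdict: resist
  - id: R3          # 2-O-sulfated uronic two back: high sulfation inhibits -> partial
    minus2: {sulfo_2O: [true]}
    verdict: partial
  - id: R4          # default
    verdict: cleave
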