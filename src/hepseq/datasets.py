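"""Reference species and digestion-evidence records used throughout.

These are the published reference structures for (a) the major and minor
isomeric undecasulfated octasaccharides of a dalteparin octasaccharide
fraction, and (b) the heparinase-resistant antithrombin-binding-region
(ATBR) tetrasaccharides of a bovine mucosal heparin (BMH) fraction with
high antithrombin affinity, together with the fate of each species under
heparanase treatment.  They serve both as worked inputs and as the
regression fixtures for the digestion and inference engines.
"""

from __future__ import annotations

from .inference import EvidenceRecord
from .nomenclature import parse_code, parse_sequence

__all__ = [
    "DALTEPARIN_OCTAMER_G",
    "DALTEPARIN_OCTAMER_I2S",
    "DALTEPARIN_OCTAMER_MINOR_1",
    "DALTEPARIN_OCTAMER_MINOR_2",
    "DALTEPARIN_OCTAMER_EVIDENCE",
    "BMH_TETRASACCHARIDES",
]

#: The two major U8,11,0–aM.ol isomers: glucuronic-initiated (heparanase
#: releases the NRE monosaccharide) and all-iduronic (heparanase resistant).
DALTEPARIN_OCTAMER_G = parse_sequence("G–ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S")
DALTEPARIN_OCTAMER_I2S = parse_sequence("I2S–ANS6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S")

#: Minor isomers carrying the G–ANS3S6S motif within the chain; heparanase
#: hydrolyzes them only partially (tri-/pentasaccharide pairs appear while
#: the parent survives).
DALTEPARIN_OCTAMER_MINOR_1 = parse_sequence("I2S–ANS6S–G–ANS3S6S–I2S–ANS6S–I2S–aM.ol6S")
DALTEPARIN_OCTAMER_MINOR_2 = parse_sequence("I2S–ANS6S–I2S–ANS6S–G–ANS3S6S–I2S–aM.ol6S")

#: Heparanase evidence for the G-initiated major isomer: the species
#: disappears, a heptasaccharide of unchanged sulfation appears, and a
#: trace glucuronic-acid monosaccharide supports NRE-monosaccharide release.
DALTEPARIN_OCTAMER_EVIDENCE = [
    EvidenceRecord(
        subject=parse_code("U8,11,0–aM.ol"),
        treatment=frozenset({"heparanase"}),
        fate="disappears",
        companions=((parse_code("A7,11,0–aM.ol"), False), (parse_code("U1,0,0"), True)),
    )
]

#: ATBR-related BMH tetrasaccharides: (composition code with isomer label,
#: proposed structure, observed fate under heparanase).  Fates transcribe
#: the chromatogram annotations: species marked as retaining some intensity
#: after heparanase addition are ``some_resistance``; species that are
#: substantially digested are ``susceptible``.  The trisulfated-glucosamine
#: monomer A1,2,0 (ANS3S) detected in traces supports the assignments whose
#: reducing end lacks 6-O-sulfation.
BMH_TETRASACCHARIDES = [
    ("ΔU4,3,1", "ΔU–ANAc6S–G–ANS3S", "some_resistance"),
    ("ΔU4,4,1 (1)", "ΔU–ANAc6S–G–ANS3S6S", "susceptible"),
    ("ΔU4,4,1 (2)", "ΔU2S–ANAc6S–G–ANS3S", "some_resistance"),
    ("ΔU4,4,0 (1)", "ΔU–ANS6S–G–ANS3S", "some_resistance"),
    ("ΔU4,4,0 (2)", "ΔU2S–ANS–G–ANS3S", "some_resistance"),
    ("ΔU4,5,0 (1)", "ΔU–ANS6S–G–ANS3S6S", "susceptible"),
    ("ΔU4,5,0 (2)", "ΔU2S–ANS–G–ANS3S6S", "some_resistance"),
    ("ΔU4,5,0 (3)", "ΔU2S–ANS6S–G–ANS3S", "some_resistance"),
    ("ΔU4,5,1", "ΔU2S–ANAc6S–G–ANS3S6S", "susceptible"),
    ("ΔU4,6,0", "ΔU2S–ANS6S–G–ANS3S6S", "some_resistance"),
]
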