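"""Exact monoisotopic masses and negative-mode ion m/z arithmetic.

Heparin oligosaccharides are analyzed by ion-pair reversed-phase LC-MS in
negative mode with dibutylamine (DBA) as the pairing agent.  The prevalent
ion forms are ``[M − h·H + k·DBA]^h−``: ``h`` protons removed, ``k``
*neutral* dibutylamine molecules attached, charge ``z = h``.  All masses
here are monoisotopic and derived from standard atomic masses at import
time, so every constant is reproducible from first principles.

Neutral mass of a chain is the sum of the *free* residue masses minus one
water per glycosidic bond, plus 79.95682 Da per sulfate (on any position,
N- or O-linked) and 42.01057 Da per N-acetyl.  The 4,5-unsaturated uronic
residue produced by lyase β-elimination weighs exactly one water less than
its saturated counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nomenclature import CompositionCode, GAGSequence, Residue, ResidueClass

__all__ = [
    "IonForm",
    "ATOMIC_MASS",
    "RESIDUE_MASS",
    "MASS_SO3",
    "MASS_ACETYL",
    "MASS_H2O",
    "MASS_CO2",
    "MASS_PROTON",
    "MASS_DBA",
    "LINKAGE_REGION_MASS",
    "formula_mass",
    "neutral_mass",
    "mz",
    "match_composition",
]

#: Monoisotopic atomic masses (Da), CODATA/IUPAC values.
ATOMIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an atom-count dictionary."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


#: Molecular formulae of the free (unsubstituted) residues.
RESIDUE_FORMULA = {
    ResidueClass.DELTA_URONIC: {"C": 6, "H": 8, "O": 6},
    ResidueClass.URONIC: {"C": 6, "H": 10, "O": 7},
    ResidueClass.HEXOSAMINE: {"C": 6, "H": 13, "N": 1, "O": 5},
    ResidueClass.ANHYDROMANNITOL: {"C": 6, "H": 12, "O": 5},
    # The ring-contracted nitrous-acid side product: its exact chemical
    # identity is debated, but its mass is pinned by the observed m/z of
    # Rc-containing octasaccharides to C6H12O5, same as anhydromannitol.
    ResidueClass.RING_CONTRACTED: {"C": 6, "H": 12, "O": 5},
}

RESIDUE_MASS = {cls: formula_mass(f) for cls, f in RESIDUE_FORMULA.items()}

MASS_SO3 = formula_mass({"S": 1, "O": 3})          # sulfation: +SO3 (79.95682)
MASS_ACETYL = formula_mass({"C": 2, "H": 2, "O": 1})  # N-acetyl vs free amine (+42.01057)
MASS_H2O = formula_mass({"H": 2, "O": 1})
MASS_CO2 = formula_mass({"C": 1, "O": 2})
MASS_DBA = formula_mass({"C": 8, "H": 19, "N": 1})  # dibutylamine, neutral adduct
MASS_PROTON = 1.007276

#: Auxiliary free-residue masses for linkage-region species
#: (ΔU–Gal–Gal–Xyl–Ser and variants); provided for mass-table completeness.
LINKAGE_REGION_MASS = {
    "Gal": formula_mass({"C": 6, "H": 12, "O": 6}),
    "Xyl": formula_mass({"C": 5, "H": 10, "O": 5}),
    "Ser": formula_mass({"C": 3, "H": 7, "N": 1, "O": 3}),
    "Ser-Ac": formula_mass({"C": 3, "H": 7, "N": 1, "O": 3}) + MASS_ACETYL,
    "CH2COOH": formula_mass({"C": 2, "H": 4, "O": 2}),  # oxidized (serine-less) terminus
}


@dataclass(frozen=True)
class IonForm:
    """``[M − h·H + k·DBA]^h−``: remove ``h`` protons, add ``k`` neutral DBA."""

    h: int
    k: int = 0

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("at least one proton must be removed (h >= 1)")
        if self.k < 0:
            raise ValueError("adduct count k must be >= 0")

    @property
    def charge(self) -> int:
        return self.h

    def __str__(self) -> str:
        dba = f" + {self.k}DBA" if self.k else ""
        return f"[M − {self.h}H{dba}]{self.h}−"


def residue_mass(r: Residue) -> float:
    """Free monoisotopic mass of one residue including its substituents."""
    m = RESIDUE_MASS[r.cls] + r.sulfate_count * MASS_SO3
    if r.is_acetylated:
        m += MASS_ACETYL
    return m


def neutral_mass(species: GAGSequence | CompositionCode) -> float:
    """Neutral monoisotopic mass of a sequence or a composition code.

    A composition code determines the mass completely: residue-class counts
    follow from chain parity and end-group flags, and sulfates/acetyls are
    positionless mass increments.
    """
    if isinstance(species, GAGSequence):
        return sum(residue_mass(r) for r in species) - (len(species) - 1) * MASS_H2O
    counts = species.class_counts()
    m = sum(RESIDUE_MASS[cls] * n for cls, n in counts.items())
    m -= (species.n_residues - 1) * MASS_H2O
    m += species.n_sulfates * MASS_SO3 + species.n_acetyls * MASS_ACETYL
    return m


def mz(mass: float, ion: IonForm) -> float:
    """m/z of ``[M − h·H + k·DBA]^h−`` for a neutral mass ``M`` (> 0)."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (mass - ion.h * MASS_PROTON + ion.k * MASS_DBA) / ion.h


def match_composition(
    mz_obs: float,
    z: int,
    candidates: set[CompositionCode] | list[CompositionCode],
    tol: float = 0.01,
    k_range: range | None = None,
) -> list[tuple[CompositionCode, IonForm, float]]:
    """Annotate an observed peak against candidate compositions.

    Tries every candidate with every adduct count in ``k_range`` (default
    ``0..z+1``) at charge ``z`` and returns ``(code, ion_form, error_Da)``
    triples with ``|error| <= tol`` on the m/z scale, sorted by ``|error|``.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    ks = k_range if k_range is not None else range(0, z + 2)
    out = []
    for code in candidates:
        m = neutral_mass(code)
        for k in ks:
            ion = IonForm(h=z, k=k)
            err = mz(m, ion) - mz_obs
            if abs(err) <= tol:
                out.append((code, ion, err))
    out.sort(key=lambda t: abs(t[2]))
    return out
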