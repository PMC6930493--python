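"""CID fragment-ion enumeration and MS/MS peak annotation.

Fragment classes follow the Domon–Costello scheme for glycans: glycosidic
cleavages give B/C ions (nonreducing-end side) and Y/Z ions (reducing-end
side); 0,2 cross-ring cleavage of a glucosamine ring splits it into a
C1–C2 unit (carrying the anomeric carbon and the N-substituent; base
composition C2H5NO) and a C3–C6 unit (carrying the 3-O, ring-O and 6-O
positions; C4H8O4), whose masses sum exactly to the free residue.

Because collisional activation scrambles and strips the labile sulfates,
every fragment is emitted with all sulfate-retention counts from 0 up to
the number of sulfates borne by the atoms it covers, and annotations report
the retention count (the ``(+1 SO3)`` style).  Neutral losses of one CO2
(requires a covered uronic carboxyl) and one H2O are enumerated on top.

Two empirical CID-propensity rules encode the isomer-discriminating
behaviour of heparin disaccharide spectra:

* the bare C3–C6 cross-ring piece (the low-mass "0,2A-type" ion) is emitted
  only when the glucosamine is 3-O-sulfated — a hard form of the
  observation that these ions are favoured by a more sulfated glucosamine;
* an H2O neutral loss requires at least one free (unsulfated,
  non-anomeric) hydroxyl among the covered residues, so a fully substituted
  glucosamine (N-, 3-O- and 6-O-sulfated) cannot dehydrate.

Both rules are what lets a trisulfated ``U–ANS3S6S`` disaccharide be told
apart from its ``U2S–ANS6S`` isomer on fragment presence alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .masses import (
    MASS_ACETYL,
    MASS_CO2,
    MASS_H2O,
    MASS_PROTON,
    MASS_SO3,
    formula_mass,
    residue_mass,
)
from .nomenclature import GAGSequence, Residue, ResidueClass

__all__ = [
    "FragmentIon",
    "MASS_C1C2_UNIT",
    "MASS_C3C6_UNIT",
    "glycosidic_fragments",
    "crossring_fragments",
    "all_fragments",
    "annotate_msms",
    "diagnostic_comparison",
]

#: 0,2 cross-ring pieces of a glucosamine ring (free-unit neutral masses).
MASS_C1C2_UNIT = formula_mass({"C": 2, "H": 5, "N": 1, "O": 1})  # 59.0371
MASS_C3C6_UNIT = formula_mass({"C": 4, "H": 8, "O": 4})          # 120.0423


@dataclass(frozen=True)
class FragmentIon:
    """One enumerated fragment candidate.

    ``kind`` ∈ {B, C, Y, Z, X02, A02, internal}; ``index`` is the canonical
    bond/residue index (1-based from the relevant terminus); ``losses``
    counts neutral losses as (n_H2O, n_CO2).
    """

    kind: str
    index: int
    sulfates_retained: int
    losses: tuple[int, int]  # (H2O, CO2)
    charge: int
    mz: float

    @property
    def label(self) -> str:
        loss = ""
        if self.losses[1]:
            loss += " − CO2"
        if self.losses[0]:
            loss += " − H2O"
        ret = f" (+{self.sulfates_retained} SO3)" if self.sulfates_retained else ""
        if self.kind in ("B", "C", "Y", "Z"):
            name = f"{self.kind}{self.index}"
        elif self.kind == "X02":
            name = f"0,2X{self.index}"
        elif self.kind == "A02":
            name = f"0,2A{self.index}"
        else:
            name = f"0,2(int){self.index}"
        return f"{name}{loss}{ret}"


def _skeleton_mass(r: Residue) -> float:
    """Free residue mass stripped of all sulfates (acetyl kept)."""
    return residue_mass(r) - r.sulfate_count * MASS_SO3


def _free_hydroxyls(r: Residue) -> int:
    """Count of free, non-anomeric hydroxyls available for dehydration."""
    if r.cls.is_uronic_type:
        return int(not r.sulfo_2O) + 1  # 2-OH (if free) and 3-OH
    if r.cls is ResidueClass.HEXOSAMINE:
        return int(not r.sulfo_3O) + int(not r.sulfo_6O)
    if r.cls is ResidueClass.ANHYDROMANNITOL:
        return 1 + int(not r.sulfo_6O)  # C1/C3 hydroxyls plus 6-OH if free
    return 1  # ring-contracted: unsubstituted


def _emit(
    out: list[FragmentIon],
    kind: str,
    index: int,
    base_neutral: float,
    sulf_avail: int,
    h2o_ok: bool,
    co2_ok: bool,
    max_charge: int,
) -> None:
    for ret in range(sulf_avail + 1):
        for h2o in range(2 if h2o_ok else 1):
            for co2 in range(2 if co2_ok else 1):
                neutral = base_neutral + ret * MASS_SO3 - h2o * MASS_H2O - co2 * MASS_CO2
                if neutral <= 0:
                    continue
                for z in range(1, min(max_charge, ret + 1) + 1):
                    out.append(
                        FragmentIon(
                            kind,
                            index,
                            ret,
                            (h2o, co2),
                            z,
                            (neutral - z * MASS_PROTON) / z,
                        )
                    )


def glycosidic_fragments(seq: GAGSequence, max_charge: int = 2) -> list[FragmentIon]:
    """All B/C/Y/Z candidates of a chain of at least two residues.

    For the bond after residue ``i`` (1-based): B_i/C_i cover the first
    ``i`` residues, Y_(n−i)/Z_(n−i) the rest; neutral(B) + neutral(Y) and
    neutral(C) + neutral(Z) both equal the precursor mass exactly.
    """
    n = len(seq)
    if n < 2:
        return []
    out: list[FragmentIon] = []
    for i in range(1, n):  # bond after residue i
        prefix = seq.residues[:i]
        suffix = seq.residues[i:]
        pre_free = sum(_skeleton_mass(r) for r in prefix) - (len(prefix) - 1) * MASS_H2O
        suf_free = sum(_skeleton_mass(r) for r in suffix) - (len(suffix) - 1) * MASS_H2O
        pre_s = sum(r.sulfate_count for r in prefix)
        suf_s = sum(r.sulfate_count for r in suffix)
        pre_h2o = any(_free_hydroxyls(r) for r in prefix)
        suf_h2o = any(_free_hydroxyls(r) for r in suffix)
        pre_co2 = any(r.cls.is_uronic_type for r in prefix)
        suf_co2 = any(r.cls.is_uronic_type for r in suffix)
        _emit(out, "B", i, pre_free - MASS_H2O, pre_s, pre_h2o, pre_co2, max_charge)
        _emit(out, "C", i, pre_free, pre_s, pre_h2o, pre_co2, max_charge)
        _emit(out, "Y", n - i, suf_free, suf_s, suf_h2o, suf_co2, max_charge)
        _emit(out, "Z", n - i, suf_free - MASS_H2O, suf_s, suf_h2o, suf_co2, max_charge)
    return out


def crossring_fragments(seq: GAGSequence, max_charge: int = 2) -> list[FragmentIon]:
    """0,2 cross-ring candidates at every glucosamine ring.

    For the ring at (1-based) position ``p``: the reducing-end-retaining
    piece (0,2X) is the C1–C2 unit plus everything past ``p``; the
    nonreducing-end-retaining piece (0,2A) is everything before ``p`` plus
    the C3–C6 unit.  The bare C3–C6 unit (one glycosidic plus one
    cross-ring cut) is emitted only for 3-O-sulfated rings — see the
    module notes on CID propensity.
    """
    n = len(seq)
    out: list[FragmentIon] = []
    for p0, r in enumerate(seq.residues):
        if r.cls is not ResidueClass.HEXOSAMINE:
            continue
        p = p0 + 1
        c1c2 = MASS_C1C2_UNIT + (MASS_ACETYL if r.is_acetylated else 0.0)
        c1c2_avail = int(r.n_substituent == "NS")
        c3c6_avail = int(r.sulfo_3O) + int(r.sulfo_6O)
        # reducing-end side: C1-C2 unit (+ suffix beyond p, if any)
        suffix = seq.residues[p0 + 1 :]
        if suffix:
            suf_free = sum(_skeleton_mass(x) for x in suffix) - (len(suffix) - 1) * MASS_H2O
            base = c1c2 + suf_free - MASS_H2O
            avail = c1c2_avail + sum(x.sulfate_count for x in suffix)
            h2o_ok = any(_free_hydroxyls(x) for x in suffix)
            co2_ok = any(x.cls.is_uronic_type for x in suffix)
        else:
            base, avail, h2o_ok, co2_ok = c1c2, c1c2_avail, False, False
        _emit(out, "X02", p, base, avail, h2o_ok, co2_ok, max_charge)
        # nonreducing-end side: prefix + C3-C6 unit
        prefix = seq.residues[:p0]
        if prefix:
            pre_free = sum(_skeleton_mass(x) for x in prefix) - (len(prefix) - 1) * MASS_H2O
            base = pre_free - MASS_H2O + MASS_C3C6_UNIT
            avail = c3c6_avail + sum(x.sulfate_count for x in prefix)
            h2o_ok = (not r.sulfo_3O) or (not r.sulfo_6O) or any(
                _free_hydroxyls(x) for x in prefix
            )
            co2_ok = any(x.cls.is_uronic_type for x in prefix)
            _emit(out, "A02", p, base, avail, h2o_ok, co2_ok, max_charge)
            # bare C3-C6 unit: glycosidic + cross-ring double cut, gated on
            # 3-O-sulfation (the ion is not observed for less sulfated rings)
            if r.sulfo_3O:
                _emit(
                    out,
                    "internal",
                    p,
                    MASS_C3C6_UNIT,
                    c3c6_avail,
                    (not r.sulfo_3O) or (not r.sulfo_6O),
                    False,
                    max_charge,
                )
        else:
            if r.sulfo_3O:
                _emit(out, "A02", p, MASS_C3C6_UNIT, c3c6_avail, False, False, max_charge)
    return out


def all_fragments(seq: GAGSequence, max_charge: int = 2) -> list[FragmentIon]:
    return glycosidic_fragments(seq, max_charge) + crossring_fragments(seq, max_charge)


def annotate_msms(
    peaks: Iterable[tuple[float, int]] | pd.DataFrame,
    seq: GAGSequence,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Annotate observed MS/MS peaks with the closest fragment candidate.

    ``peaks`` is a DataFrame with columns ``mz`` and ``z`` (``intensity``
    optional) or an iterable of ``(mz, z)`` pairs.  Each peak receives the
    minimum-|error| candidate within ``tol`` (m/z scale); unmatched peaks
    are kept with a null annotation so they can be reported.
    """
    if isinstance(peaks, pd.DataFrame):
        rows = [(float(r.mz), int(r.z)) for r in peaks.itertuples()]
    else:
        rows = [(float(m), int(z)) for m, z in peaks]
    cands = all_fragments(seq)
    out = []
    for mz_obs, z in rows:
        best = None
        for c in cands:
            if c.charge != z:
                continue
            err = c.mz - mz_obs
            if abs(err) <= tol and (best is None or abs(err) < abs(best[1])):
                best = (c, err)
        if best:
            c, err = best
            out.append(
                {
                    "mz": mz_obs,
                    "z": z,
                    "kind": c.kind,
                    "index": c.index,
                    "label": c.label,
                    "sulfates_retained": c.sulfates_retained,
                    "loss_h2o": c.losses[0],
                    "loss_co2": c.losses[1],
                    "error_mDa": (err) * 1000.0,
                }
            )
        else:
            out.append(
                {
                    "mz": mz_obs,
                    "z": z,
                    "kind": None,
                    "index": None,
                    "label": None,
                    "sulfates_retained": None,
                    "loss_h2o": None,
                    "loss_co2": None,
                    "error_mDa": None,
                }
            )
    return pd.DataFrame(out)


def diagnostic_comparison(
    peaks: Iterable[tuple[float, int]] | pd.DataFrame,
    seq_a: GAGSequence,
    seq_b: GAGSequence,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Flag peaks explained by one candidate sequence but not the other.

    This is the isomer-discrimination logic: a peak with a fragment
    candidate for exactly one of the two sequences is diagnostic of it.
    """
    ann_a = annotate_msms(peaks, seq_a, tol)
    ann_b = annotate_msms(peaks, seq_b, tol)
    df = pd.DataFrame(
        {
            "mz": ann_a["mz"],
            "z": ann_a["z"],
            "label_a": ann_a["label"],
            "label_b": ann_b["label"],
        }
    )
    df["matches_a"] = df["label_a"].notna()
    df["matches_b"] = df["label_b"].notna()
    df["diagnostic"] = df["matches_a"] != df["matches_b"]
    return df
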