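"""Domain model and residue-level nomenclature for heparin/LMWH oligosaccharides.

Heparin-type glycosaminoglycans are linear chains of strictly alternating
uronic acid (iduronic ``I`` / glucuronic ``G``, optionally 2-O-sulfated) and
glucosamine (``A``, N-sulfated / N-acetylated / free amine, optionally 3-O-
and 6-O-sulfated) residues, written from the nonreducing end (NRE) to the
reducing end (RE).  Lyase depolymerization leaves a 4,5-unsaturated uronic
acid (``ΔU``) at the NRE of the downstream product; nitrous-acid
depolymerization (dalteparin-style LMWH) leaves a 2,5-anhydromannitol
(``aM.ol``) and occasionally a ring-contracted residue (``Rc``) at the RE.

This module defines:

* :class:`Residue`, :class:`GAGSequence` — the chain model, with invariants
  enforced on construction;
* :func:`parse_sequence` / :func:`format_sequence` — the ``I2S–ANS6S``-style
  residue string grammar (en dash or ASCII hyphen separated);
* :class:`CompositionCode` with :func:`parse_code` / :func:`format_code` —
  the compact ``ΔU/U/A n,s,a`` species summary (residue count, sulfate
  count, N-acetyl count, plus ``–aM.ol`` / ``,Rc`` end-group flags and an
  opaque isomer label such as ``(2)``);
* :func:`composition_of` — sequence → composition summary;
* :func:`enumerate_sequences` — the exhaustive, constraint-pruned candidate
  space for a composition, which downstream structure inference filters
  against enzymatic evidence.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

__all__ = [
    "ResidueClass",
    "Residue",
    "GAGSequence",
    "CompositionCode",
    "EnumerationConstraints",
    "ParseError",
    "EnumerationCapError",
    "parse_sequence",
    "format_sequence",
    "parse_code",
    "format_code",
    "composition_of",
    "enumerate_sequences",
    "DASH",
]

#: Canonical token separator (en dash, as conventionally printed); ASCII "-"
#: is accepted on input.
DASH = "–"


class ParseError(ValueError):
    """Raised for malformed residue strings or composition codes."""


class EnumerationCapError(ValueError):
    """Raised when a composition exceeds the enumeration residue cap."""


class ResidueClass(Enum):
    DELTA_URONIC = "delta_uronic"
    URONIC = "uronic"
    HEXOSAMINE = "hexosamine"
    ANHYDROMANNITOL = "anhydromannitol"
    RING_CONTRACTED = "ring_contracted"

    @property
    def is_uronic_type(self) -> bool:
        return self in (ResidueClass.DELTA_URONIC, ResidueClass.URONIC)

    @property
    def is_amine_type(self) -> bool:
        return not self.is_uronic_type


_URONIC_TYPES = (ResidueClass.DELTA_URONIC, ResidueClass.URONIC)


@dataclass(frozen=True)
class Residue:
    """One monosaccharide unit.

    ``epimer`` applies to uronic classes only (``"I"``, ``"G"`` or
    ``"unknown"``; a ΔU residue has lost its epimeric identity and is always
    ``"unknown"``).  ``n_substituent`` (``"NS"``/``"NAc"``/``"NH2"``) and
    ``sulfo_3O`` apply to hexosamine only.  ``sulfo_6O`` applies to
    hexosamine and anhydromannitol.  Ring-contracted residues carry no
    substituent flags at all.
    """

    cls: ResidueClass
    epimer: str | None = None
    sulfo_2O: bool = False
    n_substituent: str | None = None
    sulfo_3O: bool = False
    sulfo_6O: bool = False

    def __post_init__(self) -> None:
        c = self.cls
        if c.is_uronic_type:
            if self.epimer not in ("I", "G", "unknown"):
                raise ValueError(f"uronic residue needs an epimer, got {self.epimer!r}")
            if c is ResidueClass.DELTA_URONIC and self.epimer != "unknown":
                raise ValueError("ΔU carries no epimeric identity")
            if self.n_substituent is not None or self.sulfo_3O or self.sulfo_6O:
                raise ValueError("uronic residues carry no N-substituent / 3-O / 6-O flags")
        else:
            if self.epimer is not None or self.sulfo_2O:
                raise ValueError("amine-type residues carry no epimer / 2-O flags")
            if c is ResidueClass.HEXOSAMINE:
                if self.n_substituent not in ("NS", "NAc", "NH2"):
                    raise ValueError(
                        f"hexosamine needs an N-substituent, got {self.n_substituent!r}"
                    )
            else:
                if self.n_substituent is not None or self.sulfo_3O:
                    raise ValueError("aM.ol/Rc carry no N-substituent or 3-O flag")
                if c is ResidueClass.RING_CONTRACTED and self.sulfo_6O:
                    raise ValueError("Rc carries no substituent flags")

    @property
    def sulfate_count(self) -> int:
        return (
            int(self.sulfo_2O)
            + int(self.sulfo_3O)
            + int(self.sulfo_6O)
            + int(self.n_substituent == "NS")
        )

    @property
    def is_acetylated(self) -> bool:
        return self.n_substituent == "NAc"

    def token(self) -> str:
        """Canonical residue token (e.g. ``I2S``, ``ANS3S6S``, ``aM.ol6S``)."""
        c = self.cls
        if c is ResidueClass.DELTA_URONIC:
            return "ΔU" + ("2S" if self.sulfo_2O else "")
        if c is ResidueClass.URONIC:
            sym = self.epimer if self.epimer in ("I", "G") else "U"
            return sym + ("2S" if self.sulfo_2O else "")
        if c is ResidueClass.HEXOSAMINE:
            return (
                "A"
                + self.n_substituent
                + ("3S" if self.sulfo_3O else "")
                + ("6S" if self.sulfo_6O else "")
            )
        if c is ResidueClass.ANHYDROMANNITOL:
            return "aM.ol" + ("6S" if self.sulfo_6O else "")
        return "Rc"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


# ---------------------------------------------------------------------------
# Residue token grammar
# ---------------------------------------------------------------------------

_RE_DELTA = re.compile(r"^(?:ΔU|dU)(2S)?$")
_RE_URONIC = re.compile(r"^([IGU])(2S)?$")
_RE_HEXN = re.compile(r"^A(NS|NAc|NH2)(3S)?(6S)?$")
_RE_AMOL = re.compile(r"^aM\.ol(6S)?$")


def residue_from_token(token: str) -> Residue:
    """Parse a single residue token."""
    tok = token.strip()
    m = _RE_DELTA.match(tok)
    if m:
        return Residue(ResidueClass.DELTA_URONIC, epimer="unknown", sulfo_2O=bool(m.group(1)))
    m = _RE_URONIC.match(tok)
    if m:
        epimer = m.group(1) if m.group(1) in ("I", "G") else "unknown"
        return Residue(ResidueClass.URONIC, epimer=epimer, sulfo_2O=bool(m.group(2)))
    m = _RE_HEXN.match(tok)
    if m:
        return Residue(
            ResidueClass.HEXOSAMINE,
            n_substituent=m.group(1),
            sulfo_3O=bool(m.group(2)),
            sulfo_6O=bool(m.group(3)),
        )
    m = _RE_AMOL.match(tok)
    if m:
        return Residue(ResidueClass.ANHYDROMANNITOL, sulfo_6O=bool(m.group(1)))
    if tok == "Rc":
        return Residue(ResidueClass.RING_CONTRACTED)
    raise ParseError(f"unknown residue token {token!r}")


@dataclass(frozen=True)
class GAGSequence:
    """An oligosaccharide chain, NRE (index 0) to RE (last index).

    Invariants enforced on construction: the chain is non-empty; residue
    classes strictly alternate uronic-type (ΔU/U) and amine-type
    (A/aM.ol/Rc); ΔU may appear only at the NRE; aM.ol only at the RE.
    """

    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        rs = self.residues
        if not rs:
            raise ValueError("empty sequence")
        for i, r in enumerate(rs):
            if i > 0 and rs[i - 1].cls.is_uronic_type == r.cls.is_uronic_type:
                raise ValueError(
                    f"alternation violation at position {i + 1}: "
                    f"{rs[i - 1].token()}{DASH}{r.token()}"
                )
            if r.cls is ResidueClass.DELTA_URONIC and i != 0:
                raise ValueError(f"ΔU allowed only at the nonreducing end (position {i + 1})")
            if r.cls is ResidueClass.ANHYDROMANNITOL and i != len(rs) - 1:
                raise ValueError(f"aM.ol allowed only at the reducing end (position {i + 1})")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __str__(self) -> str:
        return format_sequence(self)

    @property
    def n_sulfates(self) -> int:
        return sum(r.sulfate_count for r in self.residues)

    @property
    def n_acetyls(self) -> int:
        return sum(1 for r in self.residues if r.is_acetylated)


def parse_sequence(text: str) -> GAGSequence:
    """Parse a residue string such as ``"G–ANS3S6S–I2S–ANS6S"``.

    Tokens may be separated by an en dash (as printed) or an ASCII hyphen.
    Raises :class:`ParseError` naming the offending token and its position.
    """
    if not text or not text.strip():
        raise ParseError("empty sequence string")
    tokens = re.split(r"[–—-]", text.strip())
    residues = []
    for i, tok in enumerate(tokens, start=1):
        try:
            residues.append(residue_from_token(tok))
        except ParseError:
            raise ParseError(f"unknown residue token {tok!r} at position {i}") from None
    try:
        return GAGSequence(tuple(residues))
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def format_sequence(seq: GAGSequence) -> str:
    """Canonical residue string (en-dash separated)."""
    return DASH.join(r.token() for r in seq.residues)


# ---------------------------------------------------------------------------
# Composition codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionCode:
    """The compact ``ΔU/U/A n,s,a`` species summary.

    ``nre_class`` is ``"ΔU"``, ``"U"`` or ``"A"`` (4,5-unsaturated uronic,
    saturated uronic, or glucosamine at the NRE).  ``label`` carries an
    opaque isomer annotation such as ``"2"`` and never participates in
    equality.
    """

    nre_class: str
    n_residues: int
    n_sulfates: int
    n_acetyls: int
    has_amol: bool = False
    has_rc: bool = False
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.nre_class not in ("ΔU", "U", "A"):
            raise ValueError(f"bad NRE class {self.nre_class!r}")
        if self.n_residues < 1 or self.n_sulfates < 0 or self.n_acetyls < 0:
            raise ValueError("counts out of range")

    def __str__(self) -> str:
        return format_code(self)

    def without_label(self) -> "CompositionCode":
        return replace(self, label=None)

    def class_counts(self) -> dict[ResidueClass, int]:
        """Residue-class multiset implied by the code.

        Position parity fixes the number of uronic-type vs amine-type
        residues; ``has_amol``/``has_rc`` each displace one generic
        glucosamine.  Raises ``ValueError`` if the flags are inconsistent
        with the chain parity (e.g. aM.ol claimed at the RE of a chain whose
        RE must be uronic-type).
        """
        n = self.n_residues
        starts_uronic = self.nre_class in ("ΔU", "U")
        n_first = (n + 1) // 2
        n_second = n // 2
        n_uro = n_first if starts_uronic else n_second
        n_amine = n - n_uro
        if self.has_amol:
            re_is_amine = (n % 2 == 0) if starts_uronic else (n % 2 == 1)
            if not re_is_amine:
                raise ValueError(f"{self}: aM.ol flag inconsistent with chain parity")
        counts = {
            ResidueClass.DELTA_URONIC: 1 if self.nre_class == "ΔU" else 0,
            ResidueClass.ANHYDROMANNITOL: 1 if self.has_amol else 0,
            ResidueClass.RING_CONTRACTED: 1 if self.has_rc else 0,
        }
        counts[ResidueClass.URONIC] = n_uro - counts[ResidueClass.DELTA_URONIC]
        counts[ResidueClass.HEXOSAMINE] = (
            n_amine - counts[ResidueClass.ANHYDROMANNITOL] - counts[ResidueClass.RING_CONTRACTED]
        )
        if min(counts.values()) < 0 or counts[ResidueClass.HEXOSAMINE] < 0:
            raise ValueError(f"{self}: end-group flags inconsistent with residue count")
        return counts


_RE_CODE = re.compile(
    r"^(ΔU|dU|U|A)(\d+),(\d+),(\d+)(,Rc)?(?:[–-]aM\.ol)?(?:\s*\((\w+)\))?$"
)


def parse_code(text: str) -> CompositionCode:
    """Parse a composition code such as ``"U8,10,0,Rc–aM.ol"`` or ``"ΔU4,5,0 (2)"``."""
    t = text.strip()
    m = _RE_CODE.match(t)
    if not m:
        raise ParseError(f"malformed composition code {text!r}")
    nre = "ΔU" if m.group(1) in ("ΔU", "dU") else m.group(1)
    return CompositionCode(
        nre_class=nre,
        n_residues=int(m.group(2)),
        n_sulfates=int(m.group(3)),
        n_acetyls=int(m.group(4)),
        has_rc=bool(m.group(5)),
        has_amol="aM.ol" in t,
        label=m.group(6),
    )


def format_code(code: CompositionCode) -> str:
    s = f"{code.nre_class}{code.n_residues},{code.n_sulfates},{code.n_acetyls}"
    if code.has_rc:
        s += ",Rc"
    if code.has_amol:
        s += DASH + "aM.ol"
    if code.label:
        s += f" ({code.label})"
    return s


def composition_of(seq: GAGSequence) -> CompositionCode:
    """Summarize a sequence as a composition code (label-free)."""
    first = seq.residues[0].cls
    if first is ResidueClass.DELTA_URONIC:
        nre = "ΔU"
    elif first is ResidueClass.URONIC:
        nre = "U"
    else:
        nre = "A"
    return CompositionCode(
        nre_class=nre,
        n_residues=len(seq),
        n_sulfates=seq.n_sulfates,
        n_acetyls=seq.n_acetyls,
        has_amol=any(r.cls is ResidueClass.ANHYDROMANNITOL for r in seq),
        has_rc=any(r.cls is ResidueClass.RING_CONTRACTED for r in seq),
    )


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnumerationConstraints:
    """Substituent rules that prune the candidate space of a composition.

    Defaults encode what heparin biosynthesis and the depolymerization
    chemistry make plausible for chains of this size:

    * ``sulfo3_requires_ns`` — 3-O-sulfation occurs on N-sulfated
      glucosamine only (the antithrombin-binding-region marker).
    * ``sulfo3_requires_g_context`` — a 3-O-sulfated glucosamine must be
      preceded by an *unsulfated* glucuronic acid (or unsulfated ΔU whose
      epimeric identity was erased by lyase action, or sit at the NRE).
      This is the absence-of-U2,4,0 argument: trisulfated glucosamine is
      never found after a 2-O-sulfated iduronic acid.
    * ``max_sulfo3`` — at most one 3-O-sulfated residue per chain (the
      ATBR occurs at most once in oligosaccharides of this size); set to
      ``None`` to lift, e.g. for two-cleavage-site hexasaccharide
      hypotheses.
    * ``iduronic_if_2S`` — a 2-O-sulfated uronic residue is enumerated as
      iduronic only; an unsulfated one may be either epimer.
    * ``allow_nh2`` — free-amine glucosamine, off by default.
    """

    allow_nh2: bool = False
    iduronic_if_2S: bool = True
    sulfo3_requires_ns: bool = True
    sulfo3_requires_g_context: bool = True
    max_sulfo3: int | None = 1
    max_residues: int = 10


_MAX_SULF = {
    ResidueClass.DELTA_URONIC: 1,
    ResidueClass.URONIC: 1,
    ResidueClass.HEXOSAMINE: 3,
    ResidueClass.ANHYDROMANNITOL: 1,
    ResidueClass.RING_CONTRACTED: 0,
}


def _class_skeletons(code: CompositionCode) -> list[tuple[ResidueClass, ...]]:
    """All residue-class layouts consistent with the code (Rc placements vary)."""
    n = code.n_residues
    starts_uronic = code.nre_class in ("ΔU", "U")
    base: list[ResidueClass | None] = []
    for i in range(n):
        uronic_slot = (i % 2 == 0) == starts_uronic
        if uronic_slot:
            if i == 0 and code.nre_class == "ΔU":
                base.append(ResidueClass.DELTA_URONIC)
            else:
                base.append(ResidueClass.URONIC)
        else:
            base.append(ResidueClass.HEXOSAMINE)
    if code.has_amol:
        if base[-1] is not ResidueClass.HEXOSAMINE:
            return []
        base[-1] = ResidueClass.ANHYDROMANNITOL
    if not code.has_rc:
        return [tuple(base)]
    skeletons = []
    for i in range(1, n - 1):  # Rc is internal
        if base[i] is ResidueClass.HEXOSAMINE:
            sk = list(base)
            sk[i] = ResidueClass.RING_CONTRACTED
            skeletons.append(tuple(sk))
    return skeletons


def _residue_options(
    cls: ResidueClass,
    prev: Residue | None,
    constraints: EnumerationConstraints,
    sulfo3_left: int | None,
) -> list[Residue]:
    c = constraints
    if cls is ResidueClass.DELTA_URONIC:
        return [
            Residue(cls, epimer="unknown", sulfo_2O=False),
            Residue(cls, epimer="unknown", sulfo_2O=True),
        ]
    if cls is ResidueClass.URONIC:
        opts = [Residue(cls, epimer=e, sulfo_2O=False) for e in ("I", "G")]
        if c.iduronic_if_2S:
            opts.append(Residue(cls, epimer="I", sulfo_2O=True))
        else:
            opts += [Residue(cls, epimer=e, sulfo_2O=True) for e in ("I", "G")]
        return opts
    if cls is ResidueClass.ANHYDROMANNITOL:
        return [Residue(cls, sulfo_6O=False), Residue(cls, sulfo_6O=True)]
    if cls is ResidueClass.RING_CONTRACTED:
        return [Residue(cls)]
    # hexosamine
    nsubs = ["NS", "NAc"] + (["NH2"] if c.allow_nh2 else [])
    sulfo3_ok = sulfo3_left is None or sulfo3_left > 0
    if sulfo3_ok and c.sulfo3_requires_g_context and prev is not None:
        sulfo3_ok = prev.cls.is_uronic_type and not prev.sulfo_2O and (
            prev.cls is ResidueClass.DELTA_URONIC or prev.epimer == "G"
        )
    opts = []
    for ns, s3, s6 in itertools.product(nsubs, (False, True), (False, True)):
        if s3:
            if not sulfo3_ok:
                continue
            if c.sulfo3_requires_ns and ns != "NS":
                continue
        opts.append(Residue(cls, n_substituent=ns, sulfo_3O=s3, sulfo_6O=s6))
    return opts


def enumerate_sequences(
    code: CompositionCode,
    constraints: EnumerationConstraints | None = None,
) -> set[GAGSequence]:
    """Exhaustively enumerate sequences matching ``code`` under ``constraints``.

    Every returned sequence satisfies ``composition_of(seq) == code``
    (ignoring the isomer label) and all constraint rules; the set is
    exhaustive under those rules.  An infeasible code yields an empty set;
    a code longer than ``constraints.max_residues`` raises
    :class:`EnumerationCapError`.
    """
    c = constraints or EnumerationConstraints()
    if code.n_residues > c.max_residues:
        raise EnumerationCapError(
            f"{code.n_residues} residues exceeds enumeration cap {c.max_residues}"
        )
    results: set[GAGSequence] = set()
    for skel in _class_skeletons(code):
        max_tail = [0] * (len(skel) + 1)
        for i in range(len(skel) - 1, -1, -1):
            max_tail[i] = max_tail[i + 1] + _MAX_SULF[skel[i]]
        hexn_tail = [0] * (len(skel) + 1)
        for i in range(len(skel) - 1, -1, -1):
            hexn_tail[i] = hexn_tail[i + 1] + (skel[i] is ResidueClass.HEXOSAMINE)

        def dfs(pos: int, acc: list[Residue], s_left: int, a_left: int, s3_left: int | None):
            if s_left < 0 or a_left < 0:
                return
            if pos == len(skel):
                if s_left == 0 and a_left == 0:
                    results.add(GAGSequence(tuple(acc)))
                return
            if s_left > max_tail[pos] or a_left > hexn_tail[pos]:
                return
            prev = acc[-1] if acc else None
            for r in _residue_options(skel[pos], prev, c, s3_left):
                dfs(
                    pos + 1,
                    acc + [r],
                    s_left - r.sulfate_count,
                    a_left - int(r.is_acetylated),
                    None if s3_left is None else s3_left - int(r.sulfo_3O),
                )

        dfs(0, [], code.n_sulfates, code.n_acetyls, c.max_sulfo3)
    return results


def read_sequences(lines: Iterable[str]) -> list[GAGSequence]:
    """Parse a sequence text stream: one sequence per line, ``#`` comments."""
    out = []
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(parse_sequence(line))
    return out
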