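"""Rule-based in-silico depolymerization of heparin oligosaccharides.

Two enzyme families with different chemistry:

* **Heparin lyases (heparinase I/II/III)** cleave glucosamine→uronic bonds
  by β-elimination: the bond water is *not* restored, and the uronic residue
  on the new nonreducing end becomes 4,5-unsaturated (ΔU), losing its
  epimeric identity but keeping its 2-O-sulfate.  Product masses therefore
  sum exactly to the parent mass.

* **Heparanase** is an endo-β-D-glucuronidase: it hydrolyzes the bond
  between an *unsulfated glucuronic acid* and the following glucosamine,
  adding one water per cut.  Its susceptibility depends on the sulfation
  context around the cleavage site; the ordered rule table (shipped as
  ``data/enzyme_rules.yaml``, editable) distinguishes full cleavage,
  partial cleavage and resistance.

All rule tables are data, not code: patterns are attribute→allowed-values
maps over the donor/acceptor residues and their neighbours.  An ``unknown``
uronic epimer satisfies any epimer pattern (lyase side); heparanase sites
require an explicit glucuronic epimer, since candidate enumeration always
produces concrete epimers.

Digestion iterates to a fixed point.  Within one molecule all sites of the
winning verdict are cut simultaneously, which makes the fixed point
independent of cleavage order by construction; a ``sequential`` strategy
(randomized single cuts) is provided and is equivalent — the verdict context
of a site can never be altered by another admissible cut.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .nomenclature import GAGSequence, Residue, ResidueClass

__all__ = [
    "CleavageSite",
    "DigestResult",
    "EnzymeRules",
    "load_rules",
    "DEFAULT_RULES",
    "LYASES",
    "lyase_sites",
    "heparanase_sites",
    "heparanase_verdict",
    "digest_lyase",
    "digest_heparanase",
    "digest_combined",
]

LYASES = ("hepI", "hepII", "hepIII")


@dataclass(frozen=True)
class CleavageSite:
    """A candidate cleavage at the bond between residues ``bond`` and ``bond+1``
    (0-based; the donor is ``seq[bond]``, the acceptor ``seq[bond+1]``)."""

    bond: int
    donor: Residue
    acceptor: Residue
    enzyme: str
    verdict: str = "cleave"  # cleave | partial | resist
    rule_id: str | None = None


@dataclass
class DigestResult:
    """Products of a digestion run.

    ``products`` is the multiset of stable products at the fixed point;
    ``partial_survivors`` holds species that carry only partially-cleaved
    sites and therefore remain observable alongside their fragments;
    ``provenance`` maps each emitted product to ``(parent, bond, enzyme)``.
    """

    products: Counter = field(default_factory=Counter)
    partial_survivors: Counter = field(default_factory=Counter)
    provenance: list[tuple[GAGSequence, GAGSequence, int, str]] = field(default_factory=list)

    def observed(self) -> Counter:
        """Everything a chromatogram would show: products plus survivors."""
        return self.products + self.partial_survivors

    def merge(self, other: "DigestResult") -> None:
        self.products += other.products
        self.partial_survivors += other.partial_survivors
        self.provenance += other.provenance


# ---------------------------------------------------------------------------
# Rule tables
# ---------------------------------------------------------------------------

_CLASS_BY_NAME = {c.value: c for c in ResidueClass}


def _residue_matches(residue: Residue | None, spec: Mapping) -> bool:
    if residue is None:
        return False
    for attr, allowed in spec.items():
        if attr == "class":
            if residue.cls not in {_CLASS_BY_NAME[v] for v in allowed}:
                return False
        elif attr == "epimer":
            # an epimer erased by prior lyase action or left unresolved by
            # parsing matches any epimer requirement
            if residue.epimer != "unknown" and residue.epimer not in allowed:
                return False
        else:
            if getattr(residue, attr) not in allowed:
                return False
    return True


@dataclass(frozen=True)
class EnzymeRules:
    """Parsed enzyme specificity tables (see ``data/enzyme_rules.yaml``)."""

    lyase_patterns: Mapping[str, tuple[Mapping, ...]]
    blocking: tuple[Mapping, ...]
    heparanase: tuple[Mapping, ...]


def load_rules(source: str | None = None) -> EnzymeRules:
    """Load rule tables from a YAML file path, or the packaged defaults."""
    if source is None:
        text = resources.files("hepseq").joinpath("data/enzyme_rules.yaml").read_text("utf-8")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return EnzymeRules(
        lyase_patterns={k: tuple(v) for k, v in raw["lyases"].items()},
        blocking=tuple(raw.get("blocking", ())),
        heparanase=tuple(raw["heparanase"]),
    )


DEFAULT_RULES = load_rules()


# ---------------------------------------------------------------------------
# Site finding
# ---------------------------------------------------------------------------


def lyase_sites(
    seq: GAGSequence,
    enzymes: Iterable[str] = LYASES,
    rules: EnzymeRules = DEFAULT_RULES,
) -> list[CleavageSite]:
    """Cleavable glucosamine→uronic bonds for the given lyase subset.

    A bond is a site iff some pattern of an active enzyme matches the
    donor/acceptor pair and no blocking rule fires.  Blocking rules capture
    the protected A–G bond of the antithrombin binding region (the
    following glucosamine is 3-O-sulfated) and the refractory bond next to
    an anhydromannitol reducing end.
    """
    active = [e for e in LYASES if e in set(enzymes)]
    sites: list[CleavageSite] = []
    rs = seq.residues
    for b in range(len(rs) - 1):
        donor, acceptor = rs[b], rs[b + 1]
        if not (donor.cls.is_amine_type and acceptor.cls is ResidueClass.URONIC):
            continue
        plus2 = rs[b + 2] if b + 2 < len(rs) else None
        for enz in active:
            matched = any(
                _residue_matches(donor, pat["donor"]) and _residue_matches(acceptor, pat["acceptor"])
                for pat in rules.lyase_patterns[enz]
            )
            if not matched:
                continue
            blocked = False
            for rule in rules.blocking:
                if enz not in rule.get("enzymes", LYASES):
                    continue
                if "acceptor" in rule and not _residue_matches(acceptor, rule["acceptor"]):
                    continue
                if "plus2" in rule and not _residue_matches(plus2, rule["plus2"]):
                    continue
                blocked = True
                break
            if not blocked:
                sites.append(CleavageSite(b, donor, acceptor, enz))
                break  # one site per bond; record the first matching enzyme
    return sites


def heparanase_verdict(seq: GAGSequence, bond: int, rules: EnzymeRules = DEFAULT_RULES) -> CleavageSite:
    """Apply the ordered heparanase rule table to a glucuronic→glucosamine bond."""
    rs = seq.residues
    donor, acceptor = rs[bond], rs[bond + 1]
    if not (
        donor.cls is ResidueClass.URONIC
        and donor.epimer == "G"
        and not donor.sulfo_2O
        and acceptor.cls.is_amine_type
    ):
        raise ValueError(f"bond {bond} is not an unsulfated-G -> glucosamine linkage")
    minus1 = rs[bond - 1] if bond >= 1 else None
    minus2 = rs[bond - 2] if bond >= 2 else None
    context = {"acceptor": acceptor, "minus1": minus1, "minus2": minus2}
    for rule in rules.heparanase:
        ok = True
        for key in ("acceptor", "minus1", "minus2"):
            if key in rule and not _residue_matches(context[key], rule[key]):
                ok = False
                break
        if ok:
            return CleavageSite(bond, donor, acceptor, "heparanase", rule["verdict"], rule["id"])
    raise RuntimeError("heparanase rule table has no default rule")  # pragma: no cover


def heparanase_sites(seq: GAGSequence, rules: EnzymeRules = DEFAULT_RULES) -> list[CleavageSite]:
    """All unsulfated-glucuronic→glucosamine bonds with their verdicts."""
    rs = seq.residues
    sites = []
    for b in range(len(rs) - 1):
        d, a = rs[b], rs[b + 1]
        if (
            d.cls is ResidueClass.URONIC
            and d.epimer == "G"
            and not d.sulfo_2O
            and a.cls.is_amine_type
        ):
            sites.append(heparanase_verdict(seq, b, rules))
    return sites


# ---------------------------------------------------------------------------
# Cutting chemistry
# ---------------------------------------------------------------------------


def _cut_eliminative(seq: GAGSequence, bonds: list[int]) -> list[GAGSequence]:
    """Cut at ``bonds`` with lyase chemistry: the uronic residue starting each
    downstream piece becomes 4,5-unsaturated (epimer erased, 2-O-sulfate kept)."""
    pieces = []
    starts = [0] + sorted(b + 1 for b in bonds)
    ends = sorted(b + 1 for b in bonds) + [len(seq)]
    for s, e in zip(starts, ends):
        rs = list(seq.residues[s:e])
        if s > 0:
            u = rs[0]
            rs[0] = Residue(ResidueClass.DELTA_URONIC, epimer="unknown", sulfo_2O=u.sulfo_2O)
        pieces.append(GAGSequence(tuple(rs)))
    return pieces


def _cut_hydrolytic(seq: GAGSequence, bonds: list[int]) -> list[GAGSequence]:
    """Cut at ``bonds`` with hydrolase chemistry: residues are unchanged, the
    upstream piece ends in a free glucuronic acid (one water gained per cut)."""
    pieces = []
    starts = [0] + sorted(b + 1 for b in bonds)
    ends = sorted(b + 1 for b in bonds) + [len(seq)]
    for s, e in zip(starts, ends):
        pieces.append(GAGSequence(seq.residues[s:e]))
    return pieces


# ---------------------------------------------------------------------------
# Fixed-point digestion
# ---------------------------------------------------------------------------


def _as_counter(pool: Iterable[GAGSequence] | Counter) -> Counter:
    return Counter(pool) if not isinstance(pool, Counter) else Counter(pool)


def digest_lyase(
    pool: Iterable[GAGSequence] | Counter,
    enzymes: Iterable[str] = LYASES,
    rules: EnzymeRules = DEFAULT_RULES,
    strategy: str = "simultaneous",
    rng: random.Random | None = None,
) -> DigestResult:
    """Exhaustive digestion of a pool with a subset of heparinases I/II/III."""
    result = DigestResult()
    enzymes = tuple(enzymes)
    rng = rng or random.Random(0)
    for parent, count in _as_counter(pool).items():
        for piece in _digest_one_lyase(parent, enzymes, rules, strategy, rng, result, parent):
            result.products[piece] += count
    return result


def _digest_one_lyase(seq, enzymes, rules, strategy, rng, result, root) -> list[GAGSequence]:
    sites = lyase_sites(seq, enzymes, rules)
    if not sites:
        return [seq]
    if strategy == "sequential":
        site = rng.choice(sites)
        bonds = [site.bond]
    else:
        bonds = [s.bond for s in sites]
    pieces = _cut_eliminative(seq, bonds)
    for s in sites:
        if s.bond in bonds:
            result.provenance.append((root, seq, s.bond, s.enzyme))
    out = []
    for piece in pieces:
        out += _digest_one_lyase(piece, enzymes, rules, strategy, rng, result, root)
    return out


def digest_heparanase(
    pool: Iterable[GAGSequence] | Counter,
    rules: EnzymeRules = DEFAULT_RULES,
    strategy: str = "simultaneous",
    rng: random.Random | None = None,
) -> DigestResult:
    """Exhaustive heparanase digestion of a pool.

    Sites with verdict ``cleave`` are cut to the fixed point.  A molecule
    whose remaining sites are all ``partial`` emits both its cleavage
    fragments (as products) and itself (into ``partial_survivors``);
    ``resist`` sites never cut.
    """
    result = DigestResult()
    rng = rng or random.Random(0)
    for parent, count in _as_counter(pool).items():
        for piece in _digest_one_hep(parent, rules, strategy, rng, result, parent, count):
            result.products[piece] += count
    return result


def _digest_one_hep(seq, rules, strategy, rng, result, root, count) -> list[GAGSequence]:
    sites = heparanase_sites(seq, rules)
    cleave = [s for s in sites if s.verdict == "cleave"]
    partial = [s for s in sites if s.verdict == "partial"]
    if cleave:
        if strategy == "sequential":
            bonds = [rng.choice(cleave).bond]
        else:
            bonds = [s.bond for s in cleave]
        for b in bonds:
            result.provenance.append((root, seq, b, "heparanase"))
        out = []
        for piece in _cut_hydrolytic(seq, bonds):
            out += _digest_one_hep(piece, rules, strategy, rng, result, root, count)
        return out
    if partial:
        bonds = [s.bond for s in partial]
        for b in bonds:
            result.provenance.append((root, seq, b, "heparanase(partial)"))
        result.partial_survivors[seq] += count
        out = []
        for piece in _cut_hydrolytic(seq, bonds):
            out += _digest_one_hep(piece, rules, strategy, rng, result, root, count)
        return out
    return [seq]


def digest_combined(
    pool: Iterable[GAGSequence] | Counter,
    lyases: Iterable[str] = LYASES,
    then_heparanase: bool = True,
    rules: EnzymeRules = DEFAULT_RULES,
) -> DigestResult:
    """Sequential lyase digestion followed (optionally) by heparanase.

    Mirrors the bench workflow of adding heparanase to an exhaustive
    heparinase digest; provenance of both stages is chained.
    """
    stage1 = digest_lyase(pool, lyases, rules)
    if not then_heparanase:
        return stage1
    stage2 = digest_heparanase(stage1.products, rules)
    stage2.provenance = stage1.provenance + stage2.provenance
    return stage2
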