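"""Evidence-constrained sequence inference.

The structural deduction at the core of the heparanase strategy: a
composition code (from accurate mass) admits many sequences; the fate of
the species under enzyme treatments — resistant, partially hydrolyzed, or
gone, together with which product compositions appear — is simulated for
every candidate with the digestion engine, and only candidates whose
predicted behaviour matches every observation survive.

Fate vocabulary.  Observations are recorded at the granularity the
chromatograms support:

* ``resistant`` — no cleavable or partially-cleavable site;
* ``disappears`` — at least one fully cleavable site;
* ``partial`` — partially-cleavable site(s) only;
* ``susceptible`` — substantially digested (``disappears`` or ``partial``);
* ``some_resistance`` — detectable after treatment (``resistant`` or
  ``partial``).

The last two match the two-level annotation of digest chromatograms
(species gone vs species still seen) without forcing a three-way call the
data does not make.

Companions (product compositions observed to appear) must all be among the
candidate's predicted products; companions flagged *trace* are soft
evidence — they must be producible by at least one candidate in the final
set (for a resistant subject this means leakage through a nominally
uncleaved site), not by every candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .digestion import (
    DEFAULT_RULES,
    LYASES,
    EnzymeRules,
    _cut_hydrolytic,
    digest_combined,
    digest_heparanase,
    digest_lyase,
    heparanase_sites,
    lyase_sites,
)
from .nomenclature import (
    CompositionCode,
    EnumerationConstraints,
    GAGSequence,
    composition_of,
    enumerate_sequences,
)

__all__ = [
    "EvidenceRecord",
    "InferenceResult",
    "simulate_record",
    "matches_fate",
    "infer",
    "table2_report",
]


@dataclass(frozen=True)
class EvidenceRecord:
    """One observation: a species' fate under an enzyme treatment.

    ``treatment`` is a set of enzyme names out of ``hepI``/``hepII``/
    ``hepIII``/``heparanase`` (lyases act before heparanase when mixed).
    ``companions`` are ``(composition, trace)`` pairs for products observed
    to appear alongside.
    """

    subject: CompositionCode
    treatment: frozenset[str]
    fate: str
    companions: tuple[tuple[CompositionCode, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.fate not in ("resistant", "disappears", "partial", "susceptible", "some_resistance"):
            raise ValueError(f"unknown fate {self.fate!r}")
        if not self.treatment:
            raise ValueError("empty treatment")


def simulate_record(
    seq: GAGSequence,
    treatment: frozenset[str] | set[str],
    rules: EnzymeRules = DEFAULT_RULES,
) -> tuple[str, set[CompositionCode]]:
    """Predict the fate of ``seq`` and its product compositions under a treatment.

    Returns one of the three *simulated* fates (``resistant`` /
    ``disappears`` / ``partial``) plus the composition multiset (as a set)
    of all stable products and partial-cleavage fragments, excluding the
    intact parent itself.
    """
    treatment = set(treatment)
    lyases = [e for e in LYASES if e in treatment]
    use_hep = "heparanase" in treatment

    if lyases and lyase_sites(seq, lyases, rules):
        fate = "disappears"
    elif use_hep:
        verdicts = {s.verdict for s in heparanase_sites(seq, rules)}
        if "cleave" in verdicts:
            fate = "disappears"
        elif "partial" in verdicts:
            fate = "partial"
        else:
            fate = "resistant"
    else:
        fate = "resistant"

    if lyases and use_hep:
        result = digest_combined([seq], lyases, True, rules)
    elif lyases:
        result = digest_lyase([seq], lyases, rules)
    else:
        result = digest_heparanase([seq], rules)
    codes = {
        composition_of(p)
        for p in result.observed()
        if p != seq
    }
    return fate, codes


def matches_fate(simulated: str, observed: str) -> bool:
    if observed in ("resistant", "disappears", "partial"):
        return simulated == observed
    if observed == "susceptible":
        return simulated in ("disappears", "partial")
    if observed == "some_resistance":
        return simulated in ("resistant", "partial")
    raise ValueError(observed)


def _trace_producible(
    seq: GAGSequence, trace: CompositionCode, rules: EnzymeRules
) -> bool:
    """Could ``trace`` leak out of ``seq`` through any heparanase site,
    regardless of the site's verdict?  (Trace products are seen even for
    nominally resistant species.)"""
    for site in heparanase_sites(seq, rules):
        for piece in _cut_hydrolytic(seq, [site.bond]):
            if composition_of(piece) == trace.without_label():
                return True
    return False


@dataclass
class InferenceResult:
    """Outcome of :func:`infer`."""

    code: CompositionCode
    candidates: set[GAGSequence]
    #: candidate -> list of (simulated fate, matched?) per evidence record
    verdict_matrix: dict[GAGSequence, list[tuple[str, bool]]] = field(default_factory=dict)
    #: trace composition -> satisfied by >= 1 surviving candidate
    trace_support: dict[str, bool] = field(default_factory=dict)
    infeasible: bool = False

    def formatted(self) -> list[str]:
        return sorted(str(s) for s in self.candidates)


def infer(
    code: CompositionCode,
    evidence: Sequence[EvidenceRecord],
    constraints: EnumerationConstraints | None = None,
    rules: EnzymeRules = DEFAULT_RULES,
) -> InferenceResult:
    """Candidate sequences of ``code`` consistent with every evidence record.

    Candidates are enumerated under ``constraints``, then filtered: the
    simulated fate under each record's treatment must match the observed
    fate, and the simulated products must include every non-trace
    companion.  Infeasible evidence yields an empty (reported, not raised)
    result.  Adding records can only shrink the returned set.
    """
    if not evidence:
        raise ValueError("evidence must be non-empty")
    candidates = enumerate_sequences(code.without_label(), constraints)
    matrix: dict[GAGSequence, list[tuple[str, bool]]] = {}
    surviving = set()
    for cand in candidates:
        row = []
        ok = True
        for rec in evidence:
            fate, codes = simulate_record(cand, rec.treatment, rules)
            good = matches_fate(fate, rec.fate)
            if good:
                for comp, trace in rec.companions:
                    if not trace and comp.without_label() not in codes:
                        good = False
                        break
            row.append((fate, good))
            ok = ok and good
        matrix[cand] = row
        if ok:
            surviving.add(cand)
    trace_support = {}
    for rec in evidence:
        for comp, trace in rec.companions:
            if trace:
                trace_support[str(comp)] = any(
                    _trace_producible(c, comp, rules) for c in surviving
                )
    return InferenceResult(
        code=code,
        candidates=surviving,
        verdict_matrix=matrix,
        trace_support=trace_support,
        infeasible=not surviving,
    )


def table2_report(
    rows: Sequence[tuple[str, str, str]] | None = None,
    constraints: EnumerationConstraints | None = None,
    rules: EnzymeRules = DEFAULT_RULES,
) -> list[dict]:
    """Consistency report for the ATBR tetrasaccharide assignments.

    For each (code, proposed structure, heparanase fate) row, runs
    :func:`infer` on the heparanase evidence alone and reports whether the
    proposed structure is in the consistent set.  Rows default to the
    published bovine-heparin tetrasaccharide table.
    """
    from . import datasets  # deferred: datasets imports EvidenceRecord from here
    from .nomenclature import parse_code, parse_sequence

    rows = rows if rows is not None else datasets.BMH_TETRASACCHARIDES
    report = []
    for code_text, structure_text, fate in rows:
        code = parse_code(code_text)
        structure = parse_sequence(structure_text)
        rec = EvidenceRecord(
            subject=code, treatment=frozenset({"heparanase"}), fate=fate
        )
        res = infer(code, [rec], constraints, rules)
        report.append(
            {
                "code": code_text,
                "structure": structure_text,
                "fate": fate,
                "n_consistent": len(res.candidates),
                "consistent": res.formatted(),
                "structure_in_set": structure in res.candidates,
            }
        )
    return report
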