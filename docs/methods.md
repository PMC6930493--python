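# Methods

This note records the models, rules, parameters and numerical choices
behind `hepseq`, and what the test suite does and does not demonstrate.

## Chain model and nomenclature

A chain is an ordered list of residues, nonreducing end (NRE) first,
strictly alternating uronic-type (ΔU, U) and amine-type (A, aM.ol, Rc)
classes.  Flags per residue: 2-*O*-sulfation and epimer (I/G/unknown) on
uronics; N-substituent (NS/NAc/NH2), 3-*O*- and 6-*O*-sulfation on
glucosamine; 6-*O*-sulfation on anhydromannitol.  ΔU (the 4,5-unsaturated
uronic acid produced by lyase β-elimination) is legal only at the NRE and
carries no epimer; aM.ol (2,5-anhydromannitol, the nitrous-acid reducing
end of dalteparin-type LMWH) only at the RE.  The ring-contracted residue
Rc is accepted at internal amine-type positions and carries no substituent
flags.  Composition codes `ΔU/U/A n,s,a` (+ `,Rc`, `–aM.ol`, isomer label
`(k)`) summarize residue, sulfate and acetyl counts; the isomer label is
opaque and never participates in identity.

An epimer parsed from a bare `U` token is `unknown` and matches either
epimer in lyase pattern matching; heparanase sites, by contrast, require
an explicit unsulfated `G`, because inference always works on enumerated
candidates with concrete epimers.

## Masses and ion forms

All constants derive from standard atomic monoisotopic masses at import:
ΔU 176.03209 (C6H8O6), U 194.04265 (C6H10O7), A 179.07937 (C6H13NO5),
aM.ol 164.06847 (C6H12O5); +79.95682 per sulfate (N- or O-linked),
+42.01057 per N-acetyl, −18.01056 per glycosidic bond.  The mass of Rc is
not chemically settled; it is pinned to C6H12O5 because that is the only
value reproducing the observed m/z of Rc-containing octasaccharides.  An
auxiliary table carries linkage-region residues (Gal, Xyl, Ser and
variants) for mass-table completeness only.

Negative-mode ion-pair ESI forms are `[M − h·H + k·DBA]^h−`: h protons
removed (charge h), k neutral dibutylamine molecules attached.  m/z =
(M − h·1.007276 + k·129.15175)/h.  This is the only reading that
reproduces all published caption values; one published caption labels the
449.469 ion of `A3,5,0–aM.ol` as `[M − 2H + DBA]2−` although the value
computes as `[M − 2H]2−` (the +DBA form would be ≈514.05) — treated as a
caption typo; similarly `[M + 2DBA]2−` is read charge-consistently as
`[M − 2H + 2DBA]2−`.  Intact-species m/z are reported to 3 decimals,
fragment ions to 2, matching customary print precision.  Peak-to-
composition matching applies its tolerance on the m/z scale.

## Digestion engines

Rule tables live in `src/hepseq/data/enzyme_rules.yaml` (editable;
patterns are attribute→allowed-values maps).

**Lyases.**  heparinase I cleaves A(NS, any 3/6-O-S)→I(2S); heparinase III
cleaves A(NAc, any 6S)→I(2OH) and A(NS, any 6S)→G(2OH); heparinase II is
modeled maximally broad (any N-substituted glucosamine → any uronic) and
then narrowed by blocking rules — the published description is
qualitative, and the broad model plus blocks reproduces every published
digest product while staying editable.  Blocking rules: (B1) an A→G bond
followed by a 3-*O*-sulfated glucosamine is protected (the ATBR
signature); (B2) the bond adjacent to an anhydromannitol reducing end is
not processed, for all three lyases (this is what leaves the terminal
`ΔU4,5,0–aM.ol` tetrasaccharide).  Cleavage chemistry: the downstream
uronic becomes ΔU (epimer erased, 2-*O*-sulfate kept); product masses sum
exactly to the parent.

**Heparanase.**  Sites are unsulfated-G→glucosamine bonds.  Ordered rules:
(R0) amine-type acceptors that are aM.ol/Rc, or N-acetylated/free-amine
glucosamine, resist (G→A(NAc) cleavage is unobserved; the default is
flagged unvalidated in the table); (R1) acceptor lacking 6-*O*-sulfate →
resist; (R2) preceding glucosamine lacking 6-*O*-sulfate → resist; (R3)
2-*O*-sulfated uronic two positions upstream (including a 2-*O*-sulfated
ΔU) → partial, encoding the inhibition of highly sulfated environments;
(R4) otherwise cleave.  Hydrolytic chemistry: one water gained per cut;
the upstream product ends in free glucuronic acid.  "Partial" is
qualitative — the parent survives *and* its fragments appear — with a
surviving-fraction knob only in the synthetic noise model, because the
observations are presence/absence, not rates.

**Fixed point and confluence.**  Within a molecule, all sites of the
winning verdict are cut simultaneously; pieces are re-digested until
stable.  A randomized sequential mode exists and provably agrees: lyase
blocking context (the residue two past the bond) is never separated from
its site by another lyase cut, and a heparanase R3 context residue is
2-*O*-sulfated and hence can never itself be a cleavable G, so no
admissible cut alters another site's verdict.  A heparanase cut *can*
unblock a lyase site (it can remove the B1-protecting glucosamine); the
engines are staged lyases-then-heparanase, as on the bench, so this has no
effect on results.

## Fragment enumeration

Glycosidic B/C/Y/Z ions per Domon–Costello with exact complementarity
(B+Y = C+Z = M).  0,2 cross-ring cleavage of a glucosamine splits it into
the C1–C2 unit (C2H5NO, 59.0371, carries the N-substituent) and the C3–C6
unit (C4H8O4, 120.0423, carries O3/O6); the units sum exactly to the free
residue.  Double cleavages are capped at one glycosidic plus one
cross-ring cut (the bare C3–C6 unit), which covers all published ions
while keeping the candidate space small.  Sulfate retention is
combinatorial from 0 to the number of sulfates on the covered atoms —
CID scrambles and strips sulfates, so retention is reported as a count
(`(+1 SO3)`), not a position.  Neutral losses: ≤1 CO2 (requires a covered
uronic carboxyl) and ≤1 H2O.  Fragment charges run 1..min(2, retained+1).

Two CID-propensity rules are hard gates rather than intensity heuristics,
because presence/absence is what discriminates isomers in practice:

1. the bare C3–C6 ion is emitted only for 3-*O*-sulfated glucosamine
   (cross-ring A-type ions are favoured by more sulfated rings; the only
   rings for which the ion is observed are trisulfated);
2. an H2O loss requires a free non-anomeric hydroxyl among the covered
   residues — a fully substituted glucosamine (NS+3S+6S) cannot dehydrate.

With these, the published fragment table of the two trisulfated
disaccharide isomers (`U–A(NS3S6S)` vs `U2S–A(NS6S)`) reproduces exactly,
including which ions are absent for which isomer.  The subscripts the
annotator assigns are canonical (Y/Z indexed from the RE); display labels
are regenerated, not copied.

## Candidate enumeration and inference

Enumeration defaults (all switchable in `EnumerationConstraints`):
3-*O*-sulfate only on N-sulfated glucosamine; a 3-*O*-sulfated glucosamine
must be preceded by an unsulfated glucuronic acid, an unsulfated ΔU, or
the NRE (this is the digest-based deduction that trisulfated glucosamine
never follows 2-*O*-sulfated iduronic — no tetrasulfated disaccharides are
seen — plus the ATBR-marker rule that `A(NS3S)` follows G); at most one
3-*O*-sulfated residue per chain (the ATBR occurs at most once at these
lengths; lift `max_sulfo3` for two-site hexasaccharide hypotheses);
2-*O*-sulfated uronic is iduronic; free-amine glucosamine off; cap 10
residues.  Without the one-3S default, a second, double-ATBR-motif
octasaccharide would also satisfy the dalteparin evidence; with it, the
inference example has the unique answer the data supports.

Fates: simulated three-way (resistant / disappears / partial, from site
verdicts) are matched against observations that may also be recorded
two-level, as chromatograms support: `susceptible` (= disappears or
partial) and `some_resistance` (= resistant or partial).  The shipped
tetrasaccharide evidence uses the two-level vocabulary because the source
annotations (species gone vs species still visible) do not distinguish
partial from complete digestion; the pentasulfated `ΔU2S–A(NAc6S)–G–
A(NS3S6S)` species, for instance, simulates as partial under R3 and was
annotated susceptible.  Non-trace companions must be among a candidate's
predicted products; trace companions (e.g. the `A1,2,0` monomer backing
the 6-*O*-desulfated reducing-end assignments) need only be producible by
some candidate in the final set through a site of any verdict —
resistant species still leak traces.  The elution-order/steric-hindrance
argument that orders some isomer pairs is deliberately *not* a scoring
rule: where digestion evidence cannot distinguish two structures (e.g. the
two tetrasulfated `ΔU4,4,0` isomers) the report returns both.

## Synthetic generator

Defaults emulate a heparin-like population: per-residue draws with
P(2-*O*-S on uronic) = 0.8, P(6-*O*-S) = 0.8, P(NAc) = 0.15, unsulfated
uronics glucuronic with P = 0.3; one ATBR motif per parent with
probability 0.15 (N-sulfated variant fraction 1.0 for the dalteparin-style
model, 0.4 for the bovine-style model); even lengths 4–12.  Nitrous-acid
depolymerization cuts A(NS)→U bonds with probability 0.35 per bond and
deaminates the cut glucosamine to aM.ol (6-*O*-sulfate kept, N/3-O lost);
because only N-sulfated glucosamine is attacked, `G–A(NS3S6S)`-initiated
fragments arise from the N-sulfated ATBR variant only — the generator
reproduces that mechanism by construction, and a test asserts it.  Ring
contraction replaces an internal glucosamine with probability 0.02 per
chain (no published frequency exists; 2 % keeps Rc visible without
dominating).  The ion-form policy mirrors the observed forms by mass band:
z = 1, k ∈ {0,1} below 700 Da; z = 2, k ∈ {0..3} to 1600 Da; z = 3,
k ∈ {3,4} above.  Noise: Gaussian m/z jitter, Bernoulli dropout, Poisson
decoys, and a survival fraction for partially cleaved parents.

What the generator does *not* emulate: chromatographic retention,
realistic intensity/abundance distributions, isotope patterns, in-source
sulfate loss, and long-range sulfation correlation (real heparin has
domain structure; draws here are independent).  Passing recovery tests
therefore demonstrate the *logical* soundness of the evidence loop —
planted chain always within the consistent set under noiseless evidence —
not performance on real spectra.

## Problem sizes and numerics

The recovery experiment runs 200 chains at lengths 4–8: candidate spaces
grow combinatorially with length, and 4–8 covers every chain family the
method is demonstrated on, keeping exhaustive enumeration exact (budget
pruning on sulfate/acetyl counts, no sampling).  Exact-arithmetic
invariants (mass conservation, B/Y complementarity, cross-ring unit sums)
are asserted to 1e-9 Da; comparisons against published values use the
printed number of decimals.  Ties in MS/MS annotation (identical m/z from
e.g. B and C−H2O of the same bond) resolve to the first-enumerated,
lowest-|error| candidate; annotations are reported with errors in mDa.

## Known limitations

* Heparanase on G→A(NAc) bonds defaults to resist but is unvalidated;
  the exact structures of the heparinase-resistant hexasaccharides are
  left open by the data — the engine supports two-site hypotheses but the
  rule table cannot generate the `A2,2,0` product some hypotheses imply
  (its reducing-end glucosamine lacks 6-*O*-sulfation, which R1 blocks).
* Only the 0,2 cross-ring series is enumerated (1,5 / 2,4 / 3,5 are
  documented extension points); no intensity prediction.
* `partial` is presence/absence, not kinetics.
* mzML ingestion is out of scope; peak lists enter as CSV.
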