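# hepseq

In-silico toolkit for elucidating the structure of heparin and
low-molecular-weight heparin (LMWH) oligosaccharides from enzymatic
digestion and ion-pair LC-MS data.

Heparin-type glycosaminoglycans are alternating chains of uronic acid
(iduronic *I* / glucuronic *G*, optionally 2-*O*-sulfated) and glucosamine
(*A*, N-sulfated/N-acetylated, optionally 3-*O*- and 6-*O*-sulfated).
Accurate mass alone gives only a *composition* — residue count, sulfate
count, acetyl count (written `ΔU/U/A n,s,a`, e.g. `U8,11,0–aM.ol`) — not a
sequence.  The package implements the strategy of combining two enzyme
families with complementary, sulfation-dependent specificities to pin the
sequence down:

* **heparin lyases** (heparinases I/II/III), which cleave
  glucosamine→uronic bonds by β-elimination but cannot touch the
  A–G linkage of the antithrombin binding region (ATBR,
  `A(NX6S)–G–A(NS3S6S)–I2S–A(NS6S)`), and
* **heparanase**, an endo-β-D-glucuronidase that hydrolyzes unsulfated-
  glucuronic→glucosamine bonds with a context-dependent verdict
  (cleave / partial / resist) determined by the 6-*O*-sulfation of the
  flanking glucosamines and the 2-*O*-sulfation further upstream.

Whether a species survives each treatment, and which product compositions
appear, is simulated for every sequence compatible with its composition;
candidates inconsistent with any observation are discarded.  This is the
workflow that identifies the `G–A(NS3S6S)` nonreducing-end signature of
dalteparin octasaccharides and assigns the heparinase-resistant ATBR
tetrasaccharides of bovine mucosal heparin.

## What's in the box

| module | contents |
| --- | --- |
| `hepseq.nomenclature` | residue/sequence/composition types, the `I2S–ANS6S` grammar, constraint-pruned candidate enumeration |
| `hepseq.masses` | exact monoisotopic masses; `[M − h·H + k·DBA]^h−` ion m/z (dibutylamine ion pairing); peak→composition matching |
| `hepseq.digestion` | lyase and heparanase engines with editable YAML rule tables, fixed-point digestion with provenance |
| `hepseq.fragments` | Domon–Costello B/C/Y/Z and 0,2 cross-ring CID fragment enumeration with combinatorial sulfate retention; MS/MS annotation and isomer discrimination |
| `hepseq.inference` | evidence records, candidate filtering, tetrasaccharide consistency reports |
| `hepseq.synthetic` | heparin-like chain generator (ATBR insertion, nitrous-acid reducing ends), simulated digests/peak lists, closed-loop recovery |
| `hepseq.io`, `hepseq.cli` | CSV/JSON/YAML formats and the `hepseq` command |

## Worked example

Mass of the unsaturated trisulfated disaccharide released by lyases from
the regular `I2S–A(NS6S)` repeat:

```
$ hepseq mass "ΔU2S–ANS6S" --z 1 --dba 0
species       ΔU2S–ANS6S
neutral mass  576.9713 Da
ion form      [M − 1H]1−
m/z           575.964
```

Heparanase digestion of the glucuronic-initiated dalteparin octasaccharide
releases the nonreducing-end monosaccharide and a heptasaccharide that
keeps all eleven sulfates:

```
$ echo "G–ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S" > seqs.txt
$ hepseq digest --enzymes heparanase --input seqs.txt --output products.csv
$ cat products.csv
sequence,composition,neutral_mass,count,role
ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S,"A7,11,0–aM.ol",2054.89612,1,product
G,"U1,0,0",194.04265,1,product
```

The heptasaccharide's `[M − 3H + 4DBA]3−` ion computes to m/z 856.160 —
the new chromatographic peak that identifies the octasaccharide as
G-initiated.  In Python, the same deduction runs as constraint inference:

```python
>>> import hepseq as h
>>> from hepseq.datasets import DALTEPARIN_OCTAMER_EVIDENCE
>>> res = h.infer(h.parse_code("U8,11,0–aM.ol"), DALTEPARIN_OCTAMER_EVIDENCE)
>>> res.formatted()
['G–ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S']
```

Of all undecasulfated octasaccharide sequences, exactly one is consistent
with "disappears under heparanase, `A7,11,0–aM.ol` appears, trace
monosaccharide `U1,0,0`".

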