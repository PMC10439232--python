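# yalicraft

An in-silico modular CRISPR/Cas9 cloning toolkit: every wet-lab operation of
a hierarchical Golden Gate engineering system for *Yarrowia lipolytica*-style
strain construction is modeled as a deterministic, sequence-level operation
with verifiable products.

## Who this is for

Synthetic biologists and strain engineers who design multi-step cloning
campaigns — entry parts, transcription-unit (TU) assembly, multi-TU donors,
gRNA re-targeting, marker-free integration — and want to *simulate the whole
campaign before touching a pipette*: predict every intermediate plasmid,
check fusion-site fidelity, and confirm the final edited genome, junction by
junction.

## What it models

The simulator covers seven module families of a modular cloning toolkit:

- **Lvl0 / Exp** — one-pot Golden Gate assembly with Type IIS enzymes
  (BsaI-class for entry parts, BsmBI-class for multi-TU assembly).  A Type
  IIS enzyme cuts outside its non-palindromic recognition sequence, leaving
  a programmable 4-nt overhang; in a cycling one-pot reaction the products
  that accumulate are exactly the circles that have lost every recognition
  site.  `golden_gate` enumerates all circular ligation products and
  classifies them into *stable* (site-free) and *unstable* re-ligations.
  Empty vectors are named by the toolkit grammar — `pE8US1.1` is an empty
  level-1/sublevel-1 vector with homology arms (HAs) for locus 8 on
  chromosome E, a **U**RA3 marker and **s**pectinomycin resistance — and
  the sublevel encodes TU position (Lvl1) or capacity (Lvl2, up to 3 TUs).
- **Pro** — single-step promoter cloning upstream of a resident hrGFP
  reporter with mScarlet dropout screening.
- **Del** — single-step assembly of disruption constructs: two PCR'd
  homology arms replace the mScarlet/sfGFP reporter pair around a URA3
  cassette.
- **Int** — one-pot exchange of homology arms between two undigested
  plasmids via two AarI sites (CACCTGC 4/8) that separate backbone-with-HAs
  from the TU-bearing central section.  Exchange between overexpression
  vectors is reversible; transfer into a Del construct drops its
  AarI-flanked URA3 and is irreversible.
- **MEx** — Cre-mediated marker excision in a Cre-expressing assembly host:
  a lox71–marker–lox66 cassette resolves into a marker-free backbone
  carrying a single inert lox72 scar, with exact DNA conservation.
- **Cas** — gRNA re-encoding by λ-Red recombineering: a single 90-base
  oligonucleotide (35-nt homology + 20-nt spacer + 35-nt homology) replaces
  the rpsL-kanR counter-selection cassette of an empty Cas9 helper, so the
  helper is re-targeted in one transformation.  Protospacer scanning uses
  the canonical SpCas9 rule: 20-nt spacer, NGG PAM, blunt cut 3 bp 5′ of
  the PAM.
- **Genome operations** — homology-arm design (500 bp by default) and
  HR-mediated integration/disruption as exact, unique double-crossover
  replacement, with in-silico junction verification standing in for colony
  PCR.
- **Promoter assay** — relative promoter strength from plate-reader or
  flow-cytometry fluorescence, blanked on the parent strain (0%) and
  normalized to the TEF1 promoter (100%):
  `strength = 100·(F − F_blank)/(F_TEF1 − F_blank)`, computed per
  (medium, instrument) batch, replicates normalized individually then
  averaged.

A deterministic fixture generator (`build_fixture_toolkit`) emulates the
physical toolkit — 97 plasmids including the five empty-vector variants for
each of 16 named intergenic loci (IntA1 …) plus a Zeta series, and a
six-chromosome toy genome with planted aminotransferase-like ORFs — so the
entire package builds and tests itself with no downloads.

## Worked example

Assemble three TUs, redirect them to a genomic locus, drop the marker, and
integrate — the in-silico equivalent of a month of cloning:

```python
from yalicraft import *

tk = build_fixture_toolkit(FixtureSpec(seed=1))
cfg = tk.config

lvl1 = assemble_lvl1(tk["pZUA1.1"], tk.entry("TEF1"), tk.entry("HPD1"),
                     tk.entry("Tsyn1"), cfg)
print(f"{lvl1.id}: {len(lvl1.seq)} bp")

donors = [lvl1,
          assemble_lvl1(tk["pZUA1.2"], tk.entry("ALK1"), tk.entry("ARO4"),
                        tk.entry("Tsyn2"), cfg),
          assemble_lvl1(tk["pZUA1.3"], tk.entry("RPL25"), tk.entry("ARO7"),
                        tk.entry("Tsyn1"), cfg)]
lvl2 = assemble_lvl2(tk["pZUA2.3"], donors, cfg)
print(f"{lvl2.id}: {len(lvl2.seq)} bp")

moved = exchange_has(lvl2, tk["pE1US1.1"], cfg).product   # Int module
mf = cre_excise(moved, cfg.lox).retained                  # MEx module
print(f"{mf.id}: {len(mf.seq)} bp (URA3 absent: {mf.find_feature('URA3') is None})")

donor = donor_from_plasmid(mf)
edited = simulate_integration(tk.genome.chromosomes, donor,
                              tk.genome.locus("IntE1"))
report = verify_junctions(edited, donor)
print(f"junctions: {report.left_count}/{report.right_count}")
```

prints

```
pZUA1.1-HPD1: 3138 bp
pZUA2.3-HPD1-ARO4-ARO7: 5116 bp
pE1US-HPD1-ARO4-ARO7-mf: 4678 bp (URA3 absent: True)
junctions: 1/1
```

The three-TU vector assembled on Zeta flanks is moved intact onto the IntE1
backbone (selected in silico by spectinomycin resistance plus sfGFP
dropout, exactly the screen a cloning workflow applies), Cre excision
removes the 438-bp lox-flanked URA3 cassette leaving a lox72 scar, and the
marker-free cassette integrates between its 500-bp arms with both junctions
unique in the edited genome.

The same flow is scriptable from the shell:

```sh
yalicraft simulate pipeline --seed 1 --out-dir run/ --json-report run/report.json
```

exits non-zero if any assembly, selection or junction check fails.  See
`yalicraft --help` for the individual verbs (`assemble-lvl1`, `exchange-ha`,
`excise-marker`, `recombineer`, `scan-targets`, `design-grna-oligo`,
`integrate`, `disrupt`, `assay`, …).

## Layout

| Module | Contents |
| --- | --- |
| `yalicraft.model` | `DnaMolecule`/`SeqFeature`/`Interval`, circular-aware search and canonical comparison |
| `yalicraft.io` | GenBank/FASTA round-trip IO with a logged feature-vocabulary mapping |
| `yalicraft.typeiis` | digestion, sticky-end ligation, one-pot Golden Gate, overhang fidelity |
| `yalicraft.config` | the toolkit grammar as data (enzymes, junction overhangs, reporters, lox sites) |
| `yalicraft.grammar` | vector naming, Lvl1/Lvl2/Pro/Del planners, AarI homology-arm exchange |
| `yalicraft.recomb` | Cre-lox excision, λ-Red single-oligo recombineering, counter-selection |
| `yalicraft.cas` | protospacer scanning, cut arithmetic, 90-mer design, helper verification |
| `yalicraft.genome` | homology-arm design, HR integration/disruption, junction verification |
| `yalicraft.assay` | promoter-strength normalization and library summarization |
| `yalicraft.fixtures` | the deterministic synthetic toolkit + genome generator |
| `yalicraft.cli` | the `yalicraft` command |

Design notes, parameter choices and known limitations are documented in
[`docs/methods.md`](docs/methods.md).
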