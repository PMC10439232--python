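# Methods

This note records the models behind each simulator component, the defaults
and why they were chosen, what the synthetic fixtures do and do not emulate,
and the numerical/design decisions a maintainer would want to know.

## Sequence model

DNA is a string over {A,C,G,T,N}; coordinates are 0-based half-open
everywhere, reduced modulo length on circular molecules.  Features that
span the circular origin carry a `wraps` flag.  IUPAC degeneracy codes are
accepted in *search patterns* (enzyme recognition, PAMs, lox sites) but not
in molecule sequences: assemblies are concrete, recognition is degenerate.

Circular identity is defined up to rotation and strand: the canonical form
is the lexicographically minimal rotation over both strands (computed with
Booth's least-rotation algorithm, O(n)).  This gives a total order on
products, so Golden Gate output is deterministic and independent of input
order or rotation — a property the test suite asserts directly.

GenBank is the interchange format; the LOCUS topology field is honored.
Files written by the package embed the controlled feature-vocabulary key in
a `/note` qualifier so round-trips are exact; foreign files fall back to an
ordered, user-extensible label-heuristic table, and every heuristic mapping
is logged rather than silent, because deposited plasmid files in the wild
use wildly inconsistent feature keys.

## Type IIS digestion and one-pot assembly

An enzyme is (recognition, top-strand offset, bottom-strand offset); the
overhang length is the offset difference.  Built-in definitions: a
BsaI-class entry enzyme GGTCTC(1/5), a BsmBI-class level-2 enzyme
CGTCTC(1/5), and AarI CACCTGC(4/8) for homology-arm exchange.  All three
leave 4-nt 5′ overhangs.  The configuration format lists enzymes by *role*
(`entry`, `lvl2`, `exchange`), and every definition is overridable.

A digest of a circular molecule with *k* sites yields exactly *k*
fragments.  Each fragment stores its full top strand including both
overhang regions, so two ends ligate exactly when their overhang strings
are equal; this single representation covers both orientations because
flipping a fragment reverse-complements the stored string.  Cut windows
that overlap raise an error naming the positions — such substrates are
physically ambiguous.

One-pot semantics: `ligate_cyclic` enumerates every distinct circle
formable using each fragment at most once (a configuration flag enables
dimers, capped at two copies — multimeric assemblies are real but rarely
intended), and `golden_gate` classifies circles by whether they still carry
a recognition site.  Site-free circles are what reaction cycling enriches;
no kinetics are modeled.  Overhang-fidelity warnings (duplicates,
palindromes, reverse-complement collisions) are computed over the ends of
*persistent* (site-free) fragments only, because the transient backbone
ends recut anyway.  Ligation-fidelity prediction from empirical mismatch
tables is out of scope: junctions either match exactly or do not ligate.

## The assembly grammar

The junction overhangs are data, not code.  The default set
(entry: GGAG/AATG/GCTT/CGCT; positions: TGCC/GCAA/ACTA/TTAC; exchange:
AGGT/CGTT) was chosen to pass the fidelity check and to create no stray
recognition site in any fixed scar context; `SyntaxConfig.validate`
re-derives both properties for any user-supplied set.  Deletion-construct
junctions reuse the entry set — the two reactions never share a pot.

Level semantics: a Lvl1 acceptor of sublevel *k* flanks its TU with
position junctions P(k−1)/P(k) behind level-2 enzyme sites, so the donor's
sublevel mechanically fixes its slot in a Lvl2 assembly; a Lvl2.2 acceptor
spans P0–P2 by direct junction re-assignment (no filler part).  Donor
position sets are validated from vector names before anything is digested.

Selection emulation: real workflows pick clones by antibiotic resistance
and fluorescence dropout.  The planners apply the same filters
declaratively over enumerated products and log them.  This matters most
for homology-arm exchange, where the desired product still carries both
AarI sites (that is what makes the exchange *reversible*) and therefore is
not "stable" in the site-free sense: it is selected by the empty vector's
resistance plus sfGFP loss.  Exchanging two vectors that share a bacterial
resistance is rejected as ambiguous, mirroring the bench reality that the
selection cannot distinguish them.  Transfer into a deletion construct, by
contrast, drops the AarI-flanked URA3 of the Del vector, and the single
site-free circle is the product — irreversibility falls out of the site
arithmetic rather than being asserted.

## Cre-lox marker excision

Sites are 13-nt arms around the 8-nt asymmetric spacer (34 nt total), with
the published lox66 (right-arm mutant) and lox71 (left-arm mutant)
sequences as defaults.  Excision requires exactly one of each in direct
orientation on a circular substrate; inversion (opposite orientation) and
more than two sites are distinct errors.  Crossover is modeled as exact
string surgery at the spacer: each product receives one hybrid site (left
arm of one parent site, right arm of the other), so DNA is conserved
exactly — the two product lengths sum to the substrate length.  The
fixture cassettes place lox71 upstream and lox66 downstream of the marker,
which puts the double-mutant lox72 on the retained backbone (the standard
design goal: the scar is inert to further Cre exposure, making excision
effectively irreversible and the operation idempotent).  The retained
circle is identified by its replication origin/resistance annotation, with
a size fallback for unannotated substrates.

## λ-Red recombineering

The 90-mer is 35-nt left homology + 20-nt spacer + 35-nt right homology,
the spacer centered.  Homology matching is exact and must be unique on the
helper; mismatch tolerance exists as a knob but defaults off, because
recombineering efficiency collapses with mismatches and no tolerance value
is defensible a priori.  Oligo strand is ignored — lagging-strand
preference changes efficiency, not product sequence.  The replaced span is
exactly the arc between the homology inner edges, so recombineering never
alters sequence outside it (asserted as a test invariant).  Because the
90-mer cannot encode the ~500-bp counter-selection cassette, the
"round-trip" law is stated over successive spacer replacements: swapping
spacer A → B → A restores the first recombinant exactly.

## CRISPR arithmetic

Canonical SpCas9: 20-nt protospacer, NGG PAM (configurable pattern), blunt
double-strand break 3 bp 5′ of the PAM, i.e. between spacer bases 17 and
18.  Scanning returns both strands in deterministic (position, strand)
order; cutting requires the concrete spacer+PAM 23-mer to occur exactly
once in the target — uniqueness within the provided sequence is the only
specificity model, deliberately: off-target scoring is a different problem
with different data requirements.

Helper verification is annotation-level: the four sgRNA cassette elements
(hybrid Pol III promoter SCR1'-tRNAGly, spacer slot, tracrRNA, poly-T
terminator) in order, the spacer slot directly abutting the promoter (a
9-nt residual linker is reported as an error), the Cas9 CDS with its SV40
NLS annotation, the nourseothricin marker, and a yeast ARS.

## Homologous-recombination genome editing

HR is exact, unique, double-crossover replacement: both arms must match
one chromosome, once each, in order, on one strand (arms matching the
minus strand integrate the flipped donor; mixed strands are an inversion
error).  The genomic span between the arm inner edges is replaced by the
cassette; an intergenic insertion point (zero-length span) is a pure
insertion.  NHEJ and indels are not modeled — in this system the
double-strand break is selection biology, not sequence arithmetic.
Junction verification extracts 40-mer probes across both arm/cassette
junctions and counts genome-wide occurrences; one each is a clean single
integration, more flags multiple insertion.  Telomere-truncation editing
is representable as an integration whose right arm abuts a chromosome end
with an empty distal segment; it needs no dedicated operation.

## Promoter assay

Raw fluorescence is only comparable within a (medium, instrument) batch,
so normalization is per batch: blank = mean of the parent-strain rows,
reference = mean of the TEF1 rows, each sample replicate normalized
individually and then averaged.  Averaging after normalization (rather
than normalizing pooled means) matches the replicate-wise reporting
convention of promoter-library figures; with batch-mean anchors the two
orders coincide for the anchors themselves, which is what pins the
reference to exactly 100% and the blank to exactly 0%.  Normalized values
below 0% or above 100% are reported as-is with a `below_blank` flag —
sub-blank readings are informative noise, and clipping would bias library
statistics.  A batch missing either anchor is rejected with a message, not
silently skipped.  No significance machinery is attached: the output is
descriptive strength, as promoter libraries report it.

## Synthetic fixtures

The generator emulates the *structure* of a physical toolkit: entry
vectors for 3 promoters, 4 genes and 2 terminators; the five empty
Lvl1/Lvl2 variants (1.1, 1.2, 1.3, 2.2, 2.3) for each of 16 intergenic
loci named IntA1… across six 8-kb chromosomes, plus a Zeta series on
random flanks with a distinct (ampicillin) resistance so exchange
selection is unambiguous; the Pro, Del and Cas vectors; and four planted
600-bp aminotransferase-like ORFs as disruption targets.  Homology arms
are 500 bp, the common donor-design default.  All sizes are scaled down
(8-kb chromosomes, ~0.3–0.7-kb parts) to keep the full simulated campaign
in seconds; the grammar, not the sequence length, is what the tests
exercise.

Two hygiene rules make the fixtures seed-robust.  First, every random
element is scrubbed of all configured recognition sequences on both
strands.  Second, every element boundary is padded with `AA`: none of the
recognition sequences contains `AA` or begins/ends with `A`, so no
concatenation of clean padded elements can create a site across a
boundary.  Composed ORFs (fixed ATG/stop around a random interior) are
re-drawn until clean as a whole.  Every built plasmid is then asserted to
carry exactly its designed site counts.  Everything derives from one
integer seed through independent sub-streams for genome and parts; the
same seed yields byte-identical files (GenBank dates are fixed for this
reason).

What the fixtures do **not** emulate: real genome composition (GC skew,
repeats, gene density), real part sequences, transformation and assembly
*efficiencies*, or growth phenotypes.  A passing suite therefore
demonstrates that the combinatorial and sequence arithmetic of the toolkit
is right, not that any particular wet-lab protocol will reach its reported
yield.

## Numerical and degenerate-input choices

- Patterns longer than the molecule: empty hit list, not an error.
- A circular molecule with zero sites is returned undigested and flagged;
  downstream reports list it explicitly.
- A single-site circular digest yields one fragment with identical
  (self-complementary in the ligation sense) ends, which re-circularizes
  to the parent — the inverse law holds for every k ≥ 1.
- Features truncated by a cut are clipped to the fragment, not dropped;
  features destroyed by a genomic replacement are dropped.
- Blunt ligation is disabled by default (amplicon end-scraps stay inert).
- Vector-name parsing errors name the failing field (chromosome, locus,
  level, sublevel) rather than rejecting wholesale.

## Known limitations

- No kinetic or thermodynamic modeling anywhere: no ligation-efficiency
  tables, no primer Tm, no Cas9 activity scores.  The simulator answers
  "what molecules can form and which would be selected", not "how often".
- Multi-copy (>2) concatemers are not enumerated even with the dimer flag.
- Cre inversion (inverted lox pairs) and recombination between more than
  two sites are rejected rather than modeled.
- The HR model enforces genome-wide arm uniqueness; repeat-mediated or
  single-crossover integration is out of scope.
- At most three TUs per Lvl2 vector, matching the position-junction set;
  extending the set in configuration lifts this.
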