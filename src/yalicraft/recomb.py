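"""Sequence-level simulation of the two E. coli assembly hosts.

*EcoCre* constitutively expresses Cre recombinase: any circular plasmid
carrying a yeast marker between lox66 and lox71 sites in direct orientation
loses the marker the moment it enters the cell, leaving the inert
double-mutant lox72 scar on the retained backbone (MEx module).

*EcoRed* expresses the lambda-Red functions (gam, bet, exo): a co-transformed
single-stranded 90-base oligonucleotide whose 35-nt end homologies flank the
rpsL-kanR counter-selection cassette of an empty Cas9 helper replaces that
cassette with the 20 central bases — the new crRNA spacer (Cas module).

Both operations are modeled as exact string surgery: recombination
chemistry determines the products, efficiencies are wet-lab observables and
are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .config import LoxConfig, SyntaxConfig, default_config
from .model import DnaMolecule, Interval, SeqFeature, find_sites, revcomp
from .typeiis import Enzyme, golden_gate

__all__ = [
    "Oligo90",
    "CreReport",
    "MarkerFreePair",
    "RecombineeringError",
    "NoTargetError",
    "AmbiguousTargetError",
    "OrientationError",
    "CreError",
    "cre_excise",
    "marker_free_pair",
    "lambda_red_replace",
    "counterselect_check",
]


class CreError(ValueError):
    """Cre recombination cannot proceed on this substrate."""


class RecombineeringError(ValueError):
    pass


class NoTargetError(RecombineeringError):
    pass


class AmbiguousTargetError(RecombineeringError):
    pass


class OrientationError(RecombineeringError):
    pass


@dataclass(frozen=True)
class Oligo90:
    """A 90-base recombineering oligonucleotide.

    The 20 target-specific bases sit in the middle of the sequence, flanked
    by two 35-nt homologies to the helper plasmid.
    """

    seq: str
    homology_len: int = 35

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) != 90:
            raise ValueError(f"oligo must be 90 nt, got {len(self.seq)}")
        if set(self.seq) - set("ACGT"):
            raise ValueError("oligo must be plain ACGT")

    @classmethod
    def from_parts(cls, left: str, spacer: str, right: str) -> "Oligo90":
        if len(spacer) != 20:
            raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
        if len(left) != 35 or len(right) != 35:
            raise ValueError("homologies must be 35 nt each")
        return cls(left + spacer + right)

    @property
    def left_homology(self) -> str:
        return self.seq[:self.homology_len]

    @property
    def spacer(self) -> str:
        return self.seq[self.homology_len:-self.homology_len]

    @property
    def right_homology(self) -> str:
        return self.seq[-self.homology_len:]

    def reverse_complement(self) -> "Oligo90":
        return Oligo90(revcomp(self.seq), self.homology_len)


@dataclass
class CreReport:
    retained: DnaMolecule
    excised: DnaMolecule


def _arc_features(mol: DnaMolecule, start: int, length: int,
                  offset: int) -> list[SeqFeature]:
    """Features fully inside the circular arc [start, start+length),
    re-based to ``offset`` in the product."""
    n = len(mol.seq)
    out = []
    for f in mol.features:
        iv = f.interval
        flen = iv.length(n)
        rel = (iv.start - start) % n
        if rel + flen <= length:
            out.append(replace(
                f, interval=Interval(offset + rel, offset + rel + flen)))
    return out


def _hybrid_label(seq: str, lox: LoxConfig) -> str:
    for name in ("lox72", "loxP", "lox66", "lox71"):
        if seq == getattr(lox, f"{name}_seq"):
            return name
    return "lox_hybrid"


def cre_excise(molecule: DnaMolecule, lox_config: LoxConfig | None = None) -> CreReport:
    """Excise the lox66/lox71-flanked segment of a circular molecule.

    Cre crossover within the 8-nt asymmetric spacers resolves the circle
    into two: the backbone (identified by its replication origin or
    resistance feature) retains one hybrid site — lox72 under the standard
    lox71-marker-lox66 arrangement — and the marker leaves on the other
    circle.  DNA is conserved exactly: the two product lengths sum to the
    substrate length.
    """
    lox = lox_config or LoxConfig()
    if not molecule.is_circular:
        raise CreError(f"{molecule.id}: Cre excision needs a circular substrate")
    hits66 = find_sites(molecule, lox.lox66_seq)
    hits71 = find_sites(molecule, lox.lox71_seq)
    if len(hits66) + len(hits71) > 2:
        raise CreError(
            f"{molecule.id}: more than two lox sites, excision is ambiguous")
    if len(hits66) != 1 or len(hits71) != 1:
        raise CreError(f"{molecule.id}: no substrate (needs one lox66 and one lox71)")
    (p66, s66), (p71, s71) = hits66[0], hits71[0]
    if s66 != s71:
        raise CreError(
            f"{molecule.id}: lox sites in inverted orientation; "
            "inversion not modeled")
    work = molecule if s66 == "+" else molecule.reverse_complement()
    if s66 == "-":
        (p66, _), (p71, _) = (find_sites(work, lox.lox66_seq)[0],
                              find_sites(work, lox.lox71_seq)[0])

    n = len(work.seq)
    site_len = 2 * lox.arm_len + lox.spacer_len
    armL66, spacer, armR66 = lox.split(lox.lox66_seq)
    armL71, _, armR71 = lox.split(lox.lox71_seq)

    def build(pos_a: int, armL: str, armR: str, pos_b: int, tag: str) -> DnaMolecule:
        # hybrid site = left arm of the site at pos_a + spacer + right arm of
        # the site at pos_b, followed by the arc from pos_b's end to pos_a
        hybrid = armL + spacer + armR
        arc_start = (pos_b + site_len) % n
        arc_len = (pos_a - arc_start) % n
        seq = hybrid + work.region(arc_start, arc_start + arc_len)
        feats = [SeqFeature("lox_site", _hybrid_label(hybrid, lox),
                            Interval(0, site_len))]
        feats.extend(_arc_features(work, arc_start, arc_len, site_len))
        return DnaMolecule(f"{molecule.id}::{tag}", seq, "circular", feats)

    prod_a = build(p66, armL66, armR71, p71, "creA")
    prod_b = build(p71, armL71, armR66, p66, "creB")

    def is_backbone(m: DnaMolecule) -> bool:
        return bool(m.features_by_key("origin") or m.features_by_key("resistance"))

    a_back, b_back = is_backbone(prod_a), is_backbone(prod_b)
    if a_back == b_back:
        # annotation cannot decide; fall back to size (backbone is larger)
        retained, excised = sorted((prod_a, prod_b), key=len, reverse=True)
    else:
        retained, excised = (prod_a, prod_b) if a_back else (prod_b, prod_a)
    retained = retained.with_id(f"{molecule.id}-mf")
    excised = excised.with_id(f"{molecule.id}::excised-marker")
    return CreReport(retained=retained, excised=excised)


@dataclass
class MarkerFreePair:
    """Both outcomes of transforming one Golden Gate mix in parallel into a
    standard host and into the Cre-expressing host."""

    marker_based: DnaMolecule
    marker_free: DnaMolecule | None
    warnings: list[str] = field(default_factory=list)


def marker_free_pair(gg_reaction_inputs: Sequence[DnaMolecule],
                     enzyme: Enzyme | None = None,
                     config: SyntaxConfig | None = None) -> MarkerFreePair:
    """Run one Golden Gate reaction and derive both plasmid versions.

    The stable product stands for the clone picked from the standard host;
    Cre excision of its lox-flanked marker stands for the clone picked from
    the EcoCre host.  If the marker lacks lox flanks the marker-free
    version is absent, with a warning.
    """
    cfg = config or default_config()
    enz = enzyme or cfg.entry_enzyme
    report = golden_gate(list(gg_reaction_inputs), enz)
    if len(report.stable) != 1:
        raise ValueError(
            f"assembly did not yield a single stable product "
            f"({len(report.stable)}); warnings: {report.warnings}")
    marker_based = report.stable[0]
    try:
        marker_free = cre_excise(marker_based, cfg.lox).retained
        warnings = []
    except CreError as exc:
        marker_free = None
        warnings = [f"marker-free version unavailable: {exc}"]
    return MarkerFreePair(marker_based, marker_free, warnings)


def lambda_red_replace(helper: DnaMolecule, oligo: Oligo90,
                       _flipped: bool = False) -> DnaMolecule:
    """Replace a helper segment by single-oligo lambda-Red recombineering.

    The oligo's two 35-nt homologies must each match the circular helper
    exactly once; the helper segment between them (the rpsL-kanR cassette
    on an empty Cas9 helper) is replaced by the oligo's central bases.
    Either oligo strand is accepted — lagging-strand preference affects
    efficiency, not product sequence.  Matching is exact: recombineering
    efficiency collapses with mismatched homologies.
    """
    if not helper.is_circular:
        raise RecombineeringError(f"{helper.id}: helper must be circular")
    left, middle, right = (oligo.left_homology, oligo.spacer,
                           oligo.right_homology)
    lhits = find_sites(helper, left)
    rhits = find_sites(helper, right)
    if not lhits or not rhits:
        missing = "left" if not lhits else "right"
        raise NoTargetError(
            f"{helper.id}: no target for the {missing} homology")
    if len(lhits) > 1 or len(rhits) > 1:
        raise AmbiguousTargetError(
            f"{helper.id}: homology matches multiple positions "
            f"(left x{len(lhits)}, right x{len(rhits)})")
    (pl, sl), (pr, sr) = lhits[0], rhits[0]
    if sl != sr:
        raise OrientationError(
            f"{helper.id}: homologies match on opposite strands")
    if sl == "-":
        if _flipped:
            raise OrientationError(f"{helper.id}: inconsistent homology strands")
        return lambda_red_replace(helper, oligo.reverse_complement(),
                                  _flipped=True)

    n = len(helper.seq)
    hlen = oligo.homology_len
    rep_start = (pl + hlen) % n        # end of left homology
    rep_end = pr                       # start of right homology
    keep_len = (rep_start - rep_end) % n
    if keep_len < 2 * hlen:
        raise OrientationError(
            f"{helper.id}: homologies overlap or are out of order")
    label = "crRNA_spacer" if len(middle) == 20 else "oligo_insert"
    feats: list[SeqFeature] = []
    if middle:
        feats.append(SeqFeature("misc", label, Interval(0, len(middle))))
    feats.extend(_arc_features(helper, rep_end, keep_len, len(middle)))
    seq = middle + helper.region(rep_end, rep_end + keep_len)
    return DnaMolecule(f"{helper.id}::recombined", seq, "circular", feats)


def counterselect_check(molecule: DnaMolecule,
                        config: SyntaxConfig | None = None,
                        cassette_seq: str | None = None) -> bool:
    """True iff the rpsL-kanR counter-selection cassette is gone.

    Clones passing this check survive streptomycin in the rpsL-mutant
    recombineering host.  The check is feature-based, optionally backed by
    a sequence scan when the cassette sequence is supplied.
    """
    cfg = config or default_config()
    for f in molecule.features:
        if f.label == cfg.counter_select:
            return False
    if cassette_seq and find_sites(molecule, cassette_seq):
        return False
    return True
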