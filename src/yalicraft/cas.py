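"""CRISPR target scanning, cut-site computation, 90-mer oligo design, and
structural verification of Cas9 helper plasmids.

SpCas9 recognises a 20-nt protospacer followed by an NGG PAM and leaves a
blunt double-strand break 3 bp 5' of the PAM (between spacer bases 17 and
18).  Helper plasmids express Cas9 and the single guide from an episome;
re-targeting a helper means changing only the 20 crRNA bases, which is what
:func:`design_oligo` plus lambda-Red recombineering accomplish.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .config import SyntaxConfig, default_config
from .model import DnaMolecule, find_sites, iupac_regex, revcomp
from .recomb import Oligo90

__all__ = [
    "Protospacer",
    "HelperModel",
    "HelperReport",
    "CutResult",
    "TargetError",
    "scan_protospacers",
    "design_oligo",
    "verify_helper",
    "cut_genome",
]

CUT_OFFSET = 3  # blunt DSB 3 bp 5' of the PAM (canonical SpCas9)
SPACER_LEN = 20


class TargetError(ValueError):
    """A protospacer that is absent or not unique in its target."""


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt Cas9 recognition sequence with its PAM and cut position.

    ``start`` is the leftmost + strand coordinate of the 20-mer;
    ``cut_position`` is the coordinate of the blunt cut point.
    """

    seq: str
    pam: str
    strand: str
    start: int
    cut_position: int

    def __post_init__(self) -> None:
        if len(self.seq) != SPACER_LEN:
            raise ValueError(f"protospacer must be {SPACER_LEN} nt")
        if len(self.pam) != 3:
            raise ValueError("PAM must be 3 nt")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def target(self) -> str:
        """Protospacer + PAM as a concrete 23-mer (protospacer strand)."""
        return self.seq + self.pam


def _seq_of(locus: "DnaMolecule | str") -> tuple[str, bool]:
    if isinstance(locus, DnaMolecule):
        return locus.seq, locus.is_circular
    return locus.upper(), False


def scan_protospacers(locus_seq: "DnaMolecule | str",
                      pam_pattern: str = "NGG") -> list[Protospacer]:
    """All 20-nt spacers adjacent to a PAM, on both strands.

    Deterministic order: position, then strand.  Coordinates are 0-based
    on the + strand of the input.
    """
    seq, circular = _seq_of(locus_seq)
    n = len(seq)
    plen = len(pam_pattern)
    if n < SPACER_LEN + plen:
        return []
    pam_re = iupac_regex(pam_pattern)
    rc_pam_re = iupac_regex(revcomp(pam_pattern))
    search = seq + seq[:SPACER_LEN + plen - 1] if circular else seq
    out = []
    # + strand: [spacer 20][PAM]
    for i in range(len(search) - plen + 1):
        if i - SPACER_LEN < 0 or i >= n:
            continue
        if pam_re.fullmatch(search, i, i + plen):
            start = i - SPACER_LEN
            out.append(Protospacer(
                seq=search[start:i], pam=search[i:i + plen], strand="+",
                start=start % n,
                cut_position=(start + SPACER_LEN - CUT_OFFSET) % n if circular
                else start + SPACER_LEN - CUT_OFFSET))
    # - strand: [rc PAM][rc spacer] on the + strand
    for i in range(len(search) - plen + 1):
        if i + plen + SPACER_LEN > len(search) or i >= n:
            continue
        if rc_pam_re.fullmatch(search, i, i + plen):
            s0 = i + plen
            out.append(Protospacer(
                seq=revcomp(search[s0:s0 + SPACER_LEN]),
                pam=revcomp(search[i:i + plen]), strand="-",
                start=s0 % n,
                cut_position=(i + plen + CUT_OFFSET) % n if circular
                else i + plen + CUT_OFFSET))
    return sorted(out, key=lambda p: (p.start, p.strand))


def design_oligo(spacer: "Protospacer | str", helper: DnaMolecule,
                 config: SyntaxConfig | None = None) -> Oligo90:
    """Build the 90-base re-encoding oligo for a helper plasmid.

    The oligo is 35 nt of helper sequence immediately left of the
    counter-selection cassette, the 20-nt spacer, and 35 nt immediately
    right of the cassette; recombineering with it inserts exactly the
    spacer.  Non-unique flanks on the helper are rejected.
    """
    cfg = config or default_config()
    spacer_seq = spacer.seq if isinstance(spacer, Protospacer) else spacer.upper()
    if len(spacer_seq) != SPACER_LEN:
        raise ValueError(f"spacer must be {SPACER_LEN} nt, got {len(spacer_seq)}")
    slot = helper.find_feature(cfg.counter_select)
    if slot is None:
        raise TargetError(
            f"{helper.id}: no {cfg.counter_select} cassette feature")
    iv = slot.interval
    if not helper.is_circular and (iv.start < 35 or iv.end + 35 > len(helper.seq)):
        raise TargetError(f"{helper.id}: cassette flank runs off the molecule")
    left = helper.region(iv.start - 35, iv.start)
    right = helper.region(iv.end, iv.end + 35)
    for name, flank in (("left", left), ("right", right)):
        hits = find_sites(helper, flank)
        if len(hits) != 1:
            raise TargetError(
                f"{helper.id}: {name} 35-nt flank is not unique "
                f"({len(hits)} matches)")
    return Oligo90.from_parts(left, spacer_seq, right)


@dataclass
class HelperModel:
    """Structural summary of a verified Cas9 helper."""

    sgrna_promoter: str
    spacer_slot: str
    tracrrna: str
    terminator: str
    cas9_present: bool
    nat_marker_present: bool
    ars_present: bool
    counter_select_present: bool


@dataclass
class HelperReport:
    model: HelperModel | None
    errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


_SGRNA_ELEMENTS = ("SCR1p-tRNAGly", None, "tracrRNA", "polyT_terminator")


def verify_helper(molecule: DnaMolecule,
                  config: SyntaxConfig | None = None) -> HelperReport:
    """Check the structure of a Cas9 helper plasmid.

    Verifies the four-element sgRNA cassette order (hybrid Pol III promoter
    SCR1'-tRNAGly, spacer slot, tracrRNA, poly-T terminator), that the
    spacer slot directly abuts the promoter (no residual 5' linker), the
    Cas9 cassette with its SV40 nuclear localisation signal, the
    nourseothricin marker and the yeast replication origin.  Every missing
    or misordered element is reported individually.
    """
    cfg = config or default_config()
    errors: list[str] = []
    n = len(molecule.seq)

    def find_label(label: str):
        return molecule.find_feature(label)

    promoter = find_label("SCR1p-tRNAGly")
    tracr = find_label("tracrRNA")
    polyt = find_label("polyT_terminator")
    slot = find_label(cfg.counter_select) or find_label("crRNA_spacer")
    for name, feat in (("SCR1p-tRNAGly promoter", promoter),
                       ("spacer slot", slot), ("tracrRNA", tracr),
                       ("poly-T terminator", polyt)):
        if feat is None:
            errors.append(f"missing sgRNA cassette element: {name}")

    if None not in (promoter, slot, tracr, polyt):
        order = [promoter, slot, tracr, polyt]
        anchor = order[0].interval.start
        starts = [(f.interval.start - anchor) % n for f in order]
        if starts != sorted(starts):
            errors.append("sgRNA cassette elements out of order")
        gap = (slot.interval.start - promoter.interval.end) % n
        if gap != 0:
            errors.append(
                f"{gap}-nt linker between promoter and spacer slot "
                "(should directly abut)")

    cas9 = None
    for f in molecule.features:
        if f.key == "CDS" and "Cas9" in f.label:
            cas9 = f
            break
    if cas9 is None:
        errors.append("missing Cas9 cassette")
    elif "SV40" not in cas9.label:
        errors.append("Cas9 lacks the C-terminal SV40 NLS annotation")

    nat = any(f.key == "marker" and f.label in ("NAT", "nourseothricin")
              for f in molecule.features)
    if not nat:
        errors.append("missing nourseothricin (Nat) resistance marker")
    ars = any(f.key == "origin" and "ARS" in f.label for f in molecule.features)
    if not ars:
        errors.append("missing yeast replicative origin (ARS)")

    if errors:
        return HelperReport(None, errors)
    return HelperReport(HelperModel(
        sgrna_promoter=promoter.label,
        spacer_slot=slot.label,
        tracrrna=tracr.label,
        terminator=polyt.label,
        cas9_present=True,
        nat_marker_present=True,
        ars_present=True,
        counter_select_present=slot.label == cfg.counter_select,
    ), [])


@dataclass
class CutResult:
    """A Cas9 double-strand break applied to one molecule."""

    cut_position: int
    pieces: list[DnaMolecule]

    @property
    def left(self) -> DnaMolecule:
        return self.pieces[0]

    @property
    def right(self) -> DnaMolecule:
        return self.pieces[-1]


def cut_genome(genome: DnaMolecule, protospacer: Protospacer) -> CutResult:
    """Apply the Cas9 blunt cut for a protospacer present exactly once.

    A linear molecule yields two linear pieces; a circular one is
    linearised at the cut.  Absent or multiply-matched targets raise
    :class:`TargetError`.
    """
    hits = find_sites(genome, protospacer.target)
    if not hits:
        raise TargetError(
            f"{genome.id}: target {protospacer.target} not found")
    if len(hits) > 1:
        raise TargetError(
            f"{genome.id}: target {protospacer.target} matches "
            f"{len(hits)} positions")
    pos, strand = hits[0]
    if strand == "+":
        cut = pos + SPACER_LEN - CUT_OFFSET
    else:
        cut = pos + 3 + CUT_OFFSET  # rc-PAM occupies [pos, pos+3)
    n = len(genome.seq)
    cut %= n
    if genome.is_circular:
        lin = genome.rotated(cut)
        lin = DnaMolecule(f"{genome.id}::linearized", lin.seq, "linear",
                          [f for f in lin.features if not f.interval.wraps])
        return CutResult(cut, [lin])
    left = DnaMolecule(f"{genome.id}::left", genome.seq[:cut], "linear",
                       [f for f in genome.features
                        if f.interval.end <= cut])
    right_feats = []
    for f in genome.features:
        if f.interval.start >= cut:
            iv = f.interval
            right_feats.append(
                f.__class__(f.key, f.label,
                            iv.__class__(iv.start - cut, iv.end - cut),
                            f.strand))
    right = DnaMolecule(f"{genome.id}::right", genome.seq[cut:], "linear",
                        right_feats)
    return CutResult(cut, [left, right])
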