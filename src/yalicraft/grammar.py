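"""The modular-cloning grammar: vector naming, level/sublevel assembly
planners, and AarI-mediated homology-arm exchange.

Vector names compress the full construct description: ``pE8US1.1`` is an
empty level-1, sublevel-1 vector with homology arms for locus 8 on
chromosome E, a URA3 yeast marker (U) and spectinomycin resistance (S).
Zeta vectors (``pZUA2.3``) carry random-integration Zeta flanks instead of
a numbered locus.

Assembly planners delegate to the one-pot Golden Gate engine and then apply
the same selection a cloning workflow applies to E. coli transformants:
antibiotic-resistance and fluorescence-dropout filters over the enumerated
products.  Filters are explicit and logged, never silent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

from .config import SyntaxConfig, default_config
from .model import DnaMolecule, SeqFeature, molecules_equal
from .typeiis import Enzyme, Fragment, GGReport, digest, find_sites, golden_gate

__all__ = [
    "VectorName",
    "AssemblyPlan",
    "NameParseError",
    "AssemblyError",
    "JunctionMismatchError",
    "parse_name",
    "format_name",
    "enumerate_empty_vectors",
    "assemble_lvl1",
    "assemble_lvl2",
    "assemble_pro",
    "assemble_del",
    "exchange_has",
    "transfer_to_del",
    "ExchangeResult",
    "dropout_check",
]

log = logging.getLogger("yalicraft.grammar")

CHROMOSOMES = "ABCDEF"
ZETA = "Z"

_VALID_SUBLEVELS = {1: (1, 2, 3), 2: (2, 3)}


class NameParseError(ValueError):
    """A vector name that does not follow the naming system."""


class AssemblyError(RuntimeError):
    """An assembly that did not yield the single expected product."""

    def __init__(self, message: str, report: GGReport | None = None):
        super().__init__(message)
        self.report = report


class JunctionMismatchError(AssemblyError):
    """A part whose fusion sites do not fit the slot it was given."""


@dataclass(frozen=True)
class VectorName:
    """Parsed form of the toolkit naming system."""

    chromosome: str
    locus_number: int | None
    yeast_marker: str
    bacterial_resistance: str
    level: int
    sublevel: int
    suffix: str = ""

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES + ZETA:
            raise NameParseError(
                f"chromosome: {self.chromosome!r} is not one of A-F or Z")
        if self.chromosome == ZETA:
            if self.locus_number is not None:
                raise NameParseError("locus_number: Zeta vectors carry no locus")
        elif self.locus_number is None or self.locus_number < 1:
            raise NameParseError("locus_number: must be a positive integer")
        if self.level not in _VALID_SUBLEVELS:
            raise NameParseError(f"level: {self.level} is not 1 or 2")
        if self.sublevel not in _VALID_SUBLEVELS[self.level]:
            raise NameParseError(
                f"sublevel: {self.sublevel} invalid for level {self.level}")

    @property
    def base(self) -> str:
        locus = "" if self.locus_number is None else str(self.locus_number)
        return (f"p{self.chromosome}{locus}{self.yeast_marker}"
                f"{self.bacterial_resistance}")

    def marker_name(self, config: SyntaxConfig) -> str:
        return config.markers[self.yeast_marker]

    def resistance_name(self, config: SyntaxConfig) -> str:
        return config.resistances[self.bacterial_resistance]


_NAME_RE = re.compile(
    r"^p(?P<chrom>[A-Z])(?P<locus>\d+)?"
    r"(?P<marker>[A-Z])(?P<res>[A-Z])"
    r"(?P<level>\d)\.(?P<sub>\d)"
    r"(?:-(?P<suffix>.+))?$"
)


def parse_name(text: str) -> VectorName:
    """Parse a vector name such as ``pE8US1.1`` or ``pZUA2.3-HPD1-ARO4-ARO7``."""
    m = _NAME_RE.match(text)
    if not m:
        raise NameParseError(
            f"name: {text!r} does not match "
            "p<Chromosome><locus?><Marker><Resistance><level>.<sublevel>[-suffix]")
    return VectorName(
        chromosome=m.group("chrom"),
        locus_number=int(m.group("locus")) if m.group("locus") else None,
        yeast_marker=m.group("marker"),
        bacterial_resistance=m.group("res"),
        level=int(m.group("level")),
        sublevel=int(m.group("sub")),
        suffix=m.group("suffix") or "",
    )


def format_name(name: VectorName) -> str:
    suffix = f"-{name.suffix}" if name.suffix else ""
    return f"{name.base}{name.level}.{name.sublevel}{suffix}"


_LOCUS_RE = re.compile(r"^(?:Int)?(?P<chrom>[A-F])(?P<num>\d+)$|^(?:Zeta|Z)$")


def enumerate_empty_vectors(loci: Sequence[str], *, marker: str = "U",
                            resistance: str = "S") -> list[VectorName]:
    """Names of the empty Lvl1/Lvl2 vector series for a locus list.

    Each locus receives the five level/sublevel variants {1.1, 1.2, 1.3,
    2.2, 2.3} for a fixed marker pair, so ``len(result) == 5 * len(loci)``.
    Loci may be given as ``IntE8``, ``E8`` or ``Zeta``.
    """
    names = []
    for locus in loci:
        text = locus if isinstance(locus, str) else getattr(locus, "name")
        m = _LOCUS_RE.match(text)
        if not m:
            raise NameParseError(f"locus: cannot parse {text!r}")
        if m.group("chrom"):
            chrom, num = m.group("chrom"), int(m.group("num"))
        else:
            chrom, num = ZETA, None
        for level, sub in ((1, 1), (1, 2), (1, 3), (2, 2), (2, 3)):
            names.append(VectorName(chrom, num, marker, resistance, level, sub))
    return names


@dataclass
class AssemblyPlan:
    """Declarative record of one assembly reaction (for logs and reports)."""

    inputs: list[tuple[str, str]] = field(default_factory=list)
    enzyme: str = ""
    expected_dropouts: list[str] = field(default_factory=list)
    expected_product_features: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# product inspection helpers


def feature_labels(mol: DnaMolecule, key: str) -> set[str]:
    return {f.label for f in mol.features if f.key == key}


def dropout_check(mol: DnaMolecule, config: SyntaxConfig) -> bool:
    """True when no bacterial dropout reporter remains on the product."""
    return not (feature_labels(mol, "reporter") & config.dropout_labels())


def _resistance_label(mol: DnaMolecule) -> str:
    labels = feature_labels(mol, "resistance")
    if len(labels) != 1:
        raise AssemblyError(
            f"{mol.id}: expected exactly one resistance feature, found "
            f"{sorted(labels) or 'none'}")
    return labels.pop()


def _released_part(mol: DnaMolecule, enzyme: Enzyme) -> Fragment:
    """The single sticky-ended, site-free fragment a part vector releases."""
    res = digest(mol, enzyme)
    if res.undigested is not None:
        raise JunctionMismatchError(
            f"{mol.id}: no {enzyme.name} site, releases no part")
    parts = [f for f in res.fragments
             if f.left.seq and f.right.seq and not f.has_site(enzyme)]
    if len(parts) != 1:
        raise JunctionMismatchError(
            f"{mol.id}: expected one released part fragment, found {len(parts)}")
    return parts[0]


def _require_junctions(mol: DnaMolecule, enzyme: Enzyme,
                       expected: tuple[str, str], role: str) -> Fragment:
    frag = _released_part(mol, enzyme)
    got = (frag.left.seq, frag.right.seq)
    if got != expected:
        raise JunctionMismatchError(
            f"{mol.id} used as {role}: fusion sites {got} do not match the "
            f"slot {expected}")
    return frag


def _single_stable(report: GGReport, what: str) -> DnaMolecule:
    if len(report.stable) != 1:
        raise AssemblyError(
            f"{what}: expected exactly one stable product, got "
            f"{len(report.stable)}; warnings: {report.warnings}", report)
    return report.stable[0]


def _cyclic_positions(mol: DnaMolecule, labels: Sequence[str]) -> list[int]:
    pos = []
    for label in labels:
        feat = mol.find_feature(label)
        if feat is None:
            raise AssemblyError(f"product lacks expected feature {label!r}")
        pos.append(feat.interval.start)
    return pos


def _in_cyclic_order(mol: DnaMolecule, labels: Sequence[str]) -> bool:
    """True when the features appear in the given order along the circle."""
    pos = _cyclic_positions(mol, labels)
    if len(pos) < 3:
        return True
    anchored = [(p - pos[0]) % len(mol.seq) for p in pos]
    return anchored == sorted(anchored)


def _part_label(frag: Fragment, keys: Sequence[str]) -> str:
    for key in keys:
        for f in frag.features:
            if f.key == key:
                return f.label
    return frag.parent_id


def _site_count(mol: DnaMolecule, enzyme: Enzyme) -> int:
    return len(find_sites(mol, enzyme.recognition))


# ---------------------------------------------------------------------------
# level assemblies (Exp module)


def assemble_lvl1(empty_lvl1: DnaMolecule, promoter_part: DnaMolecule,
                  gene_part: DnaMolecule, terminator_part: DnaMolecule,
                  config: SyntaxConfig | None = None) -> DnaMolecule:
    """Assemble a single transcription unit into an empty Lvl1 vector.

    The product carries promoter-gene-terminator in order between the empty
    vector's homology arms and markers, and the bacterial dropout reporter
    is gone.  Anything else raises :class:`AssemblyError` with the full
    Golden Gate report attached.
    """
    cfg = config or default_config()
    enz = cfg.entry_enzyme
    a, b, c, d = cfg.entry_junctions()
    prom = _require_junctions(promoter_part, enz, (a, b), "promoter")
    gene = _require_junctions(gene_part, enz, (b, c), "gene")
    term = _require_junctions(terminator_part, enz, (c, d), "terminator")
    plan = AssemblyPlan(
        inputs=[(empty_lvl1.id, "acceptor"), (promoter_part.id, "promoter"),
                (gene_part.id, "gene"), (terminator_part.id, "terminator")],
        enzyme=enz.name,
        expected_dropouts=[cfg.reporters["assembly_dropout"]],
    )
    log.info("Lvl1 assembly plan: %s", plan)
    report = golden_gate(
        [empty_lvl1, promoter_part, gene_part, terminator_part], enz)
    product = _single_stable(report, f"Lvl1 assembly into {empty_lvl1.id}")
    if not dropout_check(product, cfg):
        raise AssemblyError(
            f"dropout reporter still present on {product.id}", report)
    labels = [_part_label(prom, ("promoter",)),
              _part_label(gene, ("CDS",)),
              _part_label(term, ("terminator",))]
    if not _in_cyclic_order(product, labels):
        raise AssemblyError(
            f"TU features {labels} not in promoter-gene-terminator order", report)
    for key in ("HA", "marker"):
        if not product.features_by_key(key):
            raise AssemblyError(f"product lost its {key} features", report)
    return product.with_id(f"{empty_lvl1.id}-{labels[1]}")


def _donor_sublevel(donor: DnaMolecule) -> int:
    name = parse_name(donor.id.split("-", 1)[0])
    if name.level != 1:
        raise AssemblyError(f"{donor.id}: Lvl2 donors must be Lvl1 plasmids")
    return name.sublevel


def assemble_lvl2(empty_lvl2: DnaMolecule, lvl1_donors: Sequence[DnaMolecule],
                  config: SyntaxConfig | None = None) -> DnaMolecule:
    """Combine Lvl1 transcription units into a multi-TU Lvl2 vector.

    The Lvl2 sublevel states the TU capacity (2 or 3); each donor's own
    sublevel fixes its position, so the donor set must be {1.1, 1.2} or
    {1.1, 1.2, 1.3} with no duplicates.  Position validation happens before
    any digestion.
    """
    cfg = config or default_config()
    acceptor = parse_name(empty_lvl2.id.split("-", 1)[0])
    if acceptor.level != 2:
        raise AssemblyError(f"{empty_lvl2.id} is not a Lvl2 acceptor")
    capacity = acceptor.sublevel
    if len(lvl1_donors) != capacity:
        raise AssemblyError(
            f"{empty_lvl2.id} takes {capacity} TUs, got {len(lvl1_donors)} donors")
    subs = [_donor_sublevel(m) for m in lvl1_donors]
    if sorted(subs) != list(range(1, capacity + 1)):
        raise AssemblyError(
            f"donor sublevels {sorted(subs)} must be exactly "
            f"{list(range(1, capacity + 1))} (duplicate or missing position)")
    ordered = [m for _, m in sorted(zip(subs, lvl1_donors), key=lambda t: t[0])]
    enz = cfg.lvl2_enzyme
    report = golden_gate([empty_lvl2, *ordered], enz)
    product = _single_stable(report, f"Lvl2 assembly into {empty_lvl2.id}")
    if not dropout_check(product, cfg):
        raise AssemblyError(
            f"dropout reporter still present on {product.id}", report)
    gene_labels = []
    for donor in ordered:
        frag = _released_part(donor, enz)
        gene_labels.append(_part_label(frag, ("CDS",)))
    if not _in_cyclic_order(product, gene_labels):
        raise AssemblyError(
            f"TUs {gene_labels} are not in positional order", report)
    return product.with_id(f"{empty_lvl2.id}-{'-'.join(gene_labels)}")


# ---------------------------------------------------------------------------
# Pro and Del modules


def assemble_pro(pProUA_empty: DnaMolecule, promoter_amplicon: DnaMolecule,
                 config: SyntaxConfig | None = None) -> DnaMolecule:
    """Insert a promoter amplicon upstream of the resident hrGFP reporter.

    The RFP dropout (mScarlet) must leave with the reaction; a product that
    still carries it is rejected, which models the visual red/white screen.
    """
    cfg = config or default_config()
    enz = cfg.entry_enzyme
    a, b, _, _ = cfg.entry_junctions()
    prom = _require_junctions(promoter_amplicon, enz, (a, b), "promoter")
    report = golden_gate([pProUA_empty, promoter_amplicon], enz)
    product = _single_stable(report, f"Pro assembly into {pProUA_empty.id}")
    dropout = cfg.reporters["pro_dropout"]
    if dropout in feature_labels(product, "reporter"):
        raise AssemblyError(f"{dropout} reporter still present", report)
    prom_label = _part_label(prom, ("promoter",))
    pf = product.find_feature(prom_label)
    gf = product.find_feature("hrGFP")
    if pf is None or gf is None:
        raise AssemblyError("product lacks promoter or hrGFP feature", report)
    gap = (gf.interval.start - pf.interval.end) % len(product.seq)
    if gap > 20:  # the fusion-site scar; anything more means a stray insert
        raise AssemblyError(
            f"promoter is not immediately upstream of hrGFP (gap {gap} nt)",
            report)
    base = pProUA_empty.id.split("-", 1)[0]
    return product.with_id(f"{base}-{prom_label}")


def assemble_del(pDelUK_RG: DnaMolecule, ha_up_amplicon: DnaMolecule,
                 ha_down_amplicon: DnaMolecule,
                 config: SyntaxConfig | None = None) -> DnaMolecule:
    """Assemble a marker-based gene disruption construct.

    Both bacterial reporters of the empty vector (mScarlet and sfGFP) are
    substituted by the PCR-amplified homology arms flanking the target
    gene; retention of either reporter fails the assembly.
    """
    cfg = config or default_config()
    enz = cfg.entry_enzyme
    j1, j2, j3, j4 = cfg.entry_junctions()
    up = _require_junctions(ha_up_amplicon, enz, (j1, j2), "upstream arm")
    down = _require_junctions(ha_down_amplicon, enz, (j3, j4), "downstream arm")
    report = golden_gate([pDelUK_RG, ha_up_amplicon, ha_down_amplicon], enz)
    product = _single_stable(report, f"Del assembly into {pDelUK_RG.id}")
    retained = feature_labels(product, "reporter") & {
        cfg.reporters["del_dropout_up"], cfg.reporters["del_dropout_down"]}
    if retained:
        raise AssemblyError(f"reporters still present: {sorted(retained)}", report)
    if not product.features_by_key("marker"):
        raise AssemblyError("product lost the yeast marker cassette", report)
    up_label = _part_label(up, ("HA",))
    target = re.sub(r"_(up|dn|down)$", "", up_label)
    base = pDelUK_RG.id.split("-", 1)[0]
    return product.with_id(f"{base}-{target}")


# ---------------------------------------------------------------------------
# Int module: homology-arm exchange


@dataclass
class ExchangeResult:
    """Outcome of a one-pot AarI exchange between two vectors.

    ``product`` is the circle a cloning workflow would pick (the empty
    vector's backbone, homology arms and antibiotic resistance carrying the
    assembled vector's TU section, sfGFP gone); ``reciprocal`` is the
    complementary circle, returned flagged for completeness.
    """

    product: DnaMolecule
    reciprocal: DnaMolecule | None
    report: GGReport


def _expect_two_sites(mol: DnaMolecule, enzyme: Enzyme) -> None:
    n = _site_count(mol, enzyme)
    if n != 2:
        raise AssemblyError(
            f"{mol.id}: homology-arm exchange needs exactly 2 {enzyme.name} "
            f"sites, found {n}")


def _exchange_product_id(assembled: DnaMolecule, empty: DnaMolecule) -> str:
    parts = assembled.id.split("-", 1)
    suffix = parts[1] if len(parts) == 2 else ""
    try:
        base = parse_name(empty.id.split("-", 1)[0]).base
    except NameParseError:
        base = empty.id.split("-", 1)[0]
    return f"{base}-{suffix}" if suffix else f"{base}-exchanged"


def exchange_has(assembled_vector: DnaMolecule, empty_vector: DnaMolecule,
                 config: SyntaxConfig | None = None) -> ExchangeResult:
    """Swap the TU-bearing central section onto a new backbone with new
    homology arms (reversible Golden Gate part exchange).

    Both vectors keep their two AarI sites on the backbone side of the
    junctions, so the exchange products can be exchanged again; selection
    is therefore not site-loss but the emulated clone screen: the empty
    vector's antibiotic resistance plus loss of the sfGFP dropout.
    """
    cfg = config or default_config()
    enz = cfg.exchange_enzyme
    _expect_two_sites(assembled_vector, enz)
    _expect_two_sites(empty_vector, enz)
    # the same species twice is one species in the pot
    if molecules_equal(assembled_vector, empty_vector):
        report = golden_gate([assembled_vector], enz)
    else:
        report = golden_gate([assembled_vector, empty_vector], enz)
    want_res = _resistance_label(empty_vector)
    tu_genes = feature_labels(assembled_vector, "CDS") - {"hrGFP"} or \
        feature_labels(assembled_vector, "CDS")
    log.info("exchange selection: resistance=%s, dropout-negative, TUs=%s",
             want_res, sorted(tu_genes))
    candidates = [
        m for m in report.all_circles
        if feature_labels(m, "resistance") == {want_res}
        and dropout_check(m, cfg)
        and tu_genes <= feature_labels(m, "CDS")
    ]
    if len(candidates) > 1:
        slimmer = [m for m in candidates
                   if not molecules_equal(m, assembled_vector)]
        candidates = slimmer or candidates
    if len(candidates) != 1:
        raise AssemblyError(
            f"exchange between {assembled_vector.id} and {empty_vector.id} "
            f"did not resolve to one selectable product ({len(candidates)} "
            "candidates); use vectors with distinct bacterial resistances",
            report)
    product = candidates[0].with_id(
        _exchange_product_id(assembled_vector, empty_vector))
    recip_res = _resistance_label(assembled_vector)
    recips = [
        m for m in report.all_circles
        if feature_labels(m, "resistance") == {recip_res}
        and not dropout_check(m, cfg)
    ]
    reciprocal = recips[0] if recips else None
    return ExchangeResult(product, reciprocal, report)


def transfer_to_del(assembled_vector: DnaMolecule, pDel_assembled: DnaMolecule,
                    config: SyntaxConfig | None = None) -> DnaMolecule:
    """Irreversibly transfer a TU section into a disruption construct.

    The URA3 marker of the pDel plasmid is flanked by AarI sites pointing
    outward, so it drops out with both sites and the product — deletion
    homology arms around the TU section — is the unique stable circle.
    """
    cfg = config or default_config()
    enz = cfg.exchange_enzyme
    _expect_two_sites(assembled_vector, enz)
    _expect_two_sites(pDel_assembled, enz)
    report = golden_gate([assembled_vector, pDel_assembled], enz)
    product = _single_stable(
        report, f"transfer of {assembled_vector.id} into {pDel_assembled.id}")
    ha_labels = feature_labels(pDel_assembled, "HA")
    if not ha_labels <= feature_labels(product, "HA"):
        raise AssemblyError(
            f"product lost deletion homology arms {sorted(ha_labels)}", report)
    if not dropout_check(product, cfg):
        raise AssemblyError("dropout reporter still present", report)
    parts = assembled_vector.id.split("-", 1)
    suffix = parts[1] if len(parts) == 2 else assembled_vector.id
    return product.with_id(f"{pDel_assembled.id}::{suffix}")
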