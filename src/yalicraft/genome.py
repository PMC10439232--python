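"""Homology-arm design and simulation of HR-mediated genome integration.

Homologous recombination is modeled as an exact, unique, double-crossover
replacement: both 500-bp arms of a donor must match the genome exactly
once, in order, on one strand, and the genomic span between their inner
edges is replaced by the donor cassette.  For an intergenic insertion the
span is empty and the edit is a pure insertion.  Non-homologous end
joining, indels and integration efficiencies are selection biology, not
sequence arithmetic, and are not modeled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .model import DnaMolecule, Interval, SeqFeature, find_sites, revcomp

__all__ = [
    "GenomeLocus",
    "Donor",
    "IntegrationError",
    "JunctionReport",
    "design_has",
    "donor_from_plasmid",
    "simulate_integration",
    "simulate_disruption",
    "verify_junctions",
    "load_loci_tsv",
    "write_loci_tsv",
]

DEFAULT_ARM_LEN = 500


class IntegrationError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeLocus:
    """A named genomic position: an intergenic insertion point
    (``start == end``) or a target interval for disruption."""

    chromosome: str
    start: int
    end: int
    name: str
    intergenic: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"locus {self.name}: bad interval "
                             f"[{self.start}, {self.end})")


@dataclass(frozen=True)
class Donor:
    """An integration cassette flanked by two homology arms."""

    cassette: str
    left_arm: str
    right_arm: str
    marker_present: bool = False
    cassette_features: tuple[SeqFeature, ...] = ()
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.left_arm or not self.right_arm:
            raise ValueError("homology arms must be non-empty")


Genome = Mapping[str, DnaMolecule]


def _as_genome(genome: "Genome | DnaMolecule") -> dict[str, DnaMolecule]:
    if isinstance(genome, DnaMolecule):
        return {genome.id: genome}
    return dict(genome)


def design_has(genome: "Genome | DnaMolecule", locus: GenomeLocus,
               arm_len: int = DEFAULT_ARM_LEN) -> tuple[str, str]:
    """The ``arm_len`` bases immediately flanking a locus.

    For an insertion point the arms abut; for a disruption target they
    flank the interval to be removed.  Loci closer than ``arm_len`` to a
    chromosome end are rejected.
    """
    if arm_len < 1:
        raise ValueError("arm_len must be >= 1")
    chroms = _as_genome(genome)
    if locus.chromosome not in chroms:
        raise IntegrationError(f"unknown chromosome {locus.chromosome!r}")
    chrom = chroms[locus.chromosome]
    n = len(chrom.seq)
    if locus.start < arm_len or locus.end + arm_len > n:
        raise IntegrationError(
            f"locus {locus.name} is within {arm_len} bp of a chromosome end")
    left = chrom.seq[locus.start - arm_len:locus.start]
    right = chrom.seq[locus.end:locus.end + arm_len]
    return left, right


def donor_from_plasmid(plasmid: DnaMolecule) -> Donor:
    """Extract the HR donor from an integrative plasmid.

    The two HA features delimit the donor; the cassette is the arc between
    them that does *not* carry the bacterial backbone (origin/resistance).
    """
    has = plasmid.features_by_key("HA")
    if len(has) != 2:
        raise IntegrationError(
            f"{plasmid.id}: need exactly 2 HA features, found {len(has)}")
    if not plasmid.is_circular:
        raise IntegrationError(f"{plasmid.id}: donor plasmid must be circular")
    n = len(plasmid.seq)
    f1, f2 = has

    def arc(a: SeqFeature, b: SeqFeature) -> tuple[int, int]:
        """(start, length) of the span from a's end to b's start."""
        start = a.interval.end % n
        length = (b.interval.start - start) % n
        return start, length

    def backbone_in(start: int, length: int) -> bool:
        for f in plasmid.features:
            if f.key in ("origin", "resistance"):
                rel = (f.interval.start - start) % n
                if rel < length:
                    return True
        return False

    s12, l12 = arc(f1, f2)
    s21, l21 = arc(f2, f1)
    if backbone_in(s12, l12) and not backbone_in(s21, l21):
        left, right, cas_start, cas_len = f2, f1, s21, l21
    elif backbone_in(s21, l21) and not backbone_in(s12, l12):
        left, right, cas_start, cas_len = f1, f2, s12, l12
    else:
        raise IntegrationError(
            f"{plasmid.id}: cannot orient the donor (backbone features "
            "missing or on both arcs)")
    cassette = plasmid.region(cas_start, cas_start + cas_len)
    feats = []
    for f in plasmid.features:
        iv = f.interval
        flen = iv.length(n)
        rel = (iv.start - cas_start) % n
        if rel + flen <= cas_len:
            feats.append(replace(f, interval=Interval(rel, rel + flen)))
    marker = any(f.key == "marker" for f in feats)
    return Donor(
        cassette=cassette,
        left_arm=plasmid.feature_seq(replace(left, strand="+")),
        right_arm=plasmid.feature_seq(replace(right, strand="+")),
        marker_present=marker,
        cassette_features=tuple(feats),
        source_id=plasmid.id,
    )


def _locate_arm(chroms: dict[str, DnaMolecule], arm: str,
                which: str) -> tuple[str, int, str]:
    hits = [(cid, pos, strand)
            for cid, chrom in chroms.items()
            for pos, strand in find_sites(chrom, arm)]
    if not hits:
        raise IntegrationError(f"{which} homology arm absent from the genome")
    if len(hits) > 1:
        raise IntegrationError(
            f"{which} homology arm matches {len(hits)} genomic positions")
    return hits[0]


def simulate_integration(genome: "Genome | DnaMolecule", donor: Donor,
                         locus: GenomeLocus | None = None) -> dict[str, DnaMolecule]:
    """Integrate a donor by double-crossover homologous recombination.

    Returns a new genome in which the span between the arm inner edges is
    replaced by the cassette.  ``locus``, when given, is cross-checked
    against the matched arm positions.  Distinct errors flag absent,
    ambiguous and inverted arms.
    """
    chroms = _as_genome(genome)
    lc, lp, ls = _locate_arm(chroms, donor.left_arm, "left")
    rc, rp, rs = _locate_arm(chroms, donor.right_arm, "right")
    if lc != rc:
        raise IntegrationError("homology arms match different chromosomes")
    if ls != rs:
        raise IntegrationError("homology arms inverted (opposite strands)")
    if ls == "-":
        flipped = Donor(revcomp(donor.cassette), revcomp(donor.right_arm),
                        revcomp(donor.left_arm), donor.marker_present,
                        _flip_features(donor.cassette_features,
                                       len(donor.cassette)),
                        donor.source_id)
        return simulate_integration(genome, flipped, locus)
    left_end = lp + len(donor.left_arm)
    right_start = rp
    if right_start < left_end:
        raise IntegrationError("homology arms inverted (right arm before left)")
    chrom = chroms[lc]
    if locus is not None:
        if locus.chromosome != lc or locus.start != left_end or locus.end != right_start:
            raise IntegrationError(
                f"arms match {lc}:[{left_end},{right_start}) but locus "
                f"{locus.name} is {locus.chromosome}:[{locus.start},{locus.end})")
    edited = _splice(chrom, left_end, right_start, donor.cassette,
                     donor.cassette_features)
    out = dict(chroms)
    out[lc] = edited
    return out


def _flip_features(feats: Iterable[SeqFeature], n: int) -> tuple[SeqFeature, ...]:
    out = []
    for f in feats:
        iv = f.interval
        out.append(replace(f, interval=Interval(n - iv.end, n - iv.start),
                           strand="-" if f.strand == "+" else "+"))
    return tuple(out)


def _splice(chrom: DnaMolecule, start: int, end: int, insert: str,
            insert_features: Iterable[SeqFeature] = ()) -> DnaMolecule:
    """Replace chrom[start:end) by ``insert`` on a linear molecule, keeping
    features outside the edit and dropping features that overlap it."""
    delta = len(insert) - (end - start)
    feats: list[SeqFeature] = []
    for f in chrom.features:
        iv = f.interval
        if iv.end <= start:
            feats.append(f)
        elif iv.start >= end:
            feats.append(replace(
                f, interval=Interval(iv.start + delta, iv.end + delta)))
        # overlapping the replaced span: dropped (the edit destroyed it)
    for f in insert_features:
        iv = f.interval
        feats.append(replace(
            f, interval=Interval(iv.start + start, iv.end + start)))
    seq = chrom.seq[:start] + insert + chrom.seq[end:]
    return DnaMolecule(chrom.id, seq, chrom.topology, feats)


def simulate_disruption(genome: "Genome | DnaMolecule",
                        pdel_construct: DnaMolecule) -> dict[str, DnaMolecule]:
    """Disrupt the gene between a deletion construct's homology arms.

    The construct's arms flank the target ORF; after integration the ORF
    feature is gone from the edited genome and the construct's payload
    (URA3 cassette, or a lox72 scar for a marker-free donor) sits in its
    place.
    """
    donor = donor_from_plasmid(pdel_construct)
    chroms = _as_genome(genome)
    before = {cid: {f.label for f in c.features if f.key == "CDS"}
              for cid, c in chroms.items()}
    edited = simulate_integration(chroms, donor)
    after = {cid: {f.label for f in c.features if f.key == "CDS"}
             for cid, c in edited.items()}
    removed = {cid: before[cid] - after[cid] for cid in chroms}
    if not any(removed.values()):
        # arms flanked nothing (adjacent): pure marker insertion, allowed
        pass
    return edited


@dataclass
class JunctionReport:
    """In-silico stand-in for junction colony PCR."""

    left_count: int
    right_count: int
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def verify_junctions(edited_genome: "Genome | DnaMolecule", donor: Donor,
                     locus: GenomeLocus | None = None,
                     probe_len: int = 20) -> JunctionReport:
    """Confirm both arm/cassette junction sequences occur exactly once.

    Each probe spans ``probe_len`` bases on either side of a junction; a
    count of zero means the integration is absent, more than one flags a
    multiple-insertion event.
    """
    chroms = _as_genome(edited_genome)
    if donor.cassette:
        left_probe = donor.left_arm[-probe_len:] + donor.cassette[:probe_len]
        right_probe = donor.cassette[-probe_len:] + donor.right_arm[:probe_len]
    else:
        left_probe = donor.left_arm[-probe_len:] + donor.right_arm[:probe_len]
        right_probe = left_probe
    counts = []
    for probe in (left_probe, right_probe):
        hits = sum(len(find_sites(c, probe)) for c in chroms.values())
        counts.append(hits)
    failures = []
    for name, cnt in zip(("left", "right"), counts):
        if cnt == 0:
            failures.append(f"{name} junction absent")
        elif cnt > 1:
            failures.append(f"{name} junction present {cnt} times "
                            "(multiple insertion?)")
    return JunctionReport(counts[0], counts[1], failures)


# ---------------------------------------------------------------------------
# BED-like locus tables (chrom, start, end, name; 0-based half-open)


def load_loci_tsv(path: str | Path) -> list[GenomeLocus]:
    loci = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            chrom, start, end, name = row[:4]
            intergenic = len(row) < 5 or row[4] != "orf"
            loci.append(GenomeLocus(chrom, int(start), int(end), name,
                                    intergenic))
    return loci


def write_loci_tsv(loci: Iterable[GenomeLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for loc in loci:
            writer.writerow([loc.chromosome, loc.start, loc.end, loc.name,
                             "intergenic" if loc.intergenic else "orf"])
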