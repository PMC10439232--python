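"""GenBank and FASTA readers/writers for :class:`~yalicraft.model.DnaMolecule`.

GenBank is the primary interchange format (LOCUS topology is honored).
FASTA carries sequence only: records read from FASTA are linear unless
circularity is supplied explicitly.

Free-text GenBank feature labels are mapped onto the package's controlled
feature vocabulary.  The mapping is table-driven and logged, never silent:
round-tripped files carry the vocabulary key in a ``/note`` qualifier, and
foreign files fall back to a user-extensible heuristic table.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    FeatureLocation,
    SeqFeature as BioFeature,
)
from Bio.SeqRecord import SeqRecord

from .model import CONTROLLED_KEYS, DnaMolecule, Interval, SeqFeature

__all__ = [
    "ParseError",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "LABEL_HEURISTICS",
]

log = logging.getLogger("yalicraft.io")


class ParseError(ValueError):
    """Raised when a sequence file cannot be parsed."""


_NOTE_PREFIX = "yalicraft_key:"

# vocabulary key -> GenBank feature key used on output
_KEY_TO_GB = {
    "promoter": "promoter",
    "CDS": "CDS",
    "terminator": "terminator",
    "marker": "misc_feature",
    "HA": "misc_feature",
    "lox_site": "misc_recomb",
    "overhang_junction": "misc_feature",
    "reporter": "CDS",
    "origin": "rep_origin",
    "resistance": "CDS",
    "sgRNA_cassette": "misc_RNA",
    "misc": "misc_feature",
}

# Heuristics for foreign files: (label regex, vocabulary key).  Deposited
# toolkit files may use nonstandard feature keys, so the table is ordered
# and user-extensible via the ``extra_heuristics`` argument.
LABEL_HEURISTICS: list[tuple[str, str]] = [
    (r"lox(p|66|71|72)", "lox_site"),
    (r"(ura3|leu2|trp1|his3|nat|nourseothricin|hph|hygromycin)", "marker"),
    (r"(gfp|rfp|mscarlet|mcherry|bfp|venus)", "reporter"),
    (r"(_up|_dn|_ha\b|ha_|homology|flank|zeta)", "HA"),
    (r"(amp|kan|spec|chlor|strep)[a-z]*[_-]?(r\b|res)?", "resistance"),
    (r"(ori\b|origin|ars|cen)", "origin"),
    (r"(sgrna|grna|crrna|tracr)", "sgRNA_cassette"),
    (r"(terminator|term\b|^t[A-Z])", "terminator"),
    (r"(promoter|^p[A-Z])", "promoter"),
]

_GB_KEY_FALLBACK = {
    "promoter": "promoter",
    "terminator": "terminator",
    "CDS": "CDS",
    "rep_origin": "origin",
    "misc_recomb": "lox_site",
    "misc_RNA": "sgRNA_cassette",
}


def _classify(gb_key: str, label: str, qualifiers: dict,
              extra: Iterable[tuple[str, str]] = ()) -> str:
    for note in qualifiers.get("note", []):
        if note.startswith(_NOTE_PREFIX):
            key = note[len(_NOTE_PREFIX):]
            if key in CONTROLLED_KEYS:
                return key
    for pattern, key in list(extra) + LABEL_HEURISTICS:
        if re.search(pattern, label, flags=re.IGNORECASE):
            log.info("feature %r: key %r mapped heuristically to %r",
                     label, gb_key, key)
            return key
    if gb_key in _GB_KEY_FALLBACK:
        return _GB_KEY_FALLBACK[gb_key]
    log.info("feature %r: key %r not recognised, mapped to 'misc'", label, gb_key)
    return "misc"


def _feature_label(bio_feat: BioFeature) -> str:
    for qual in ("label", "gene", "product", "standard_name", "note"):
        values = bio_feat.qualifiers.get(qual)
        if values:
            return str(values[0])
    return bio_feat.type


def _from_biopython(record: SeqRecord, path: str,
                    extra_heuristics: Iterable[tuple[str, str]] = ()) -> DnaMolecule:
    topology = record.annotations.get("topology", "linear")
    seq = str(record.seq).upper()
    n = len(seq)
    feats: list[SeqFeature] = []
    for bf in record.features:
        if bf.type == "source":
            continue
        label = _feature_label(bf)
        key = _classify(bf.type, label, bf.qualifiers, extra_heuristics)
        strand = "-" if bf.location.strand == -1 else "+"
        loc = bf.location
        if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
            p1, p2 = loc.parts
            if int(p1.end) == n and int(p2.start) == 0:
                feats.append(SeqFeature(key, label,
                                        Interval(int(p1.start), int(p2.end), wraps=True),
                                        strand))
                continue
            log.warning("%s: unsupported compound location for %r, skipped",
                        path, label)
            continue
        start, end = int(loc.start), int(loc.end)
        if end <= start:
            continue
        feats.append(SeqFeature(key, label, Interval(start, end), strand))
    mol_id = record.id if record.id not in ("", "<unknown id>", ".") else record.name
    return DnaMolecule(mol_id, seq, topology, feats)


def read_genbank(path: str | Path,
                 extra_heuristics: Iterable[tuple[str, str]] = ()) -> list[DnaMolecule]:
    """Read all records of a GenBank flat file.

    Topology is taken from the LOCUS line; features are mapped onto the
    controlled vocabulary (mapping decisions are logged).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ParseError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no GenBank records in {path}")
    out = []
    for i, rec in enumerate(records, 1):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.name or i} has no sequence")
        out.append(_from_biopython(rec, str(path), extra_heuristics))
    return out


def _to_biopython(mol: DnaMolecule) -> SeqRecord:
    n = len(mol.seq)
    record = SeqRecord(Seq(mol.seq), id=mol.id, name=_locus_name(mol.id),
                       description=mol.id)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = mol.topology
    record.annotations["data_file_division"] = "SYN"
    # fixed date keeps output byte-identical across runs
    record.annotations["date"] = "01-JAN-1980"
    for f in mol.features:
        iv = f.interval
        strand = -1 if f.strand == "-" else 1
        if iv.wraps:
            loc = CompoundLocation([
                FeatureLocation(iv.start, n, strand),
                FeatureLocation(0, iv.end, strand),
            ])
        else:
            loc = FeatureLocation(iv.start, iv.end, strand)
        record.features.append(BioFeature(
            loc, type=_KEY_TO_GB[f.key],
            qualifiers={"label": [f.label], "note": [_NOTE_PREFIX + f.key]},
        ))
    return record


def _locus_name(mol_id: str) -> str:
    return re.sub(r"\s+", "_", mol_id)


def write_genbank(molecule: DnaMolecule | Iterable[DnaMolecule],
                  path: str | Path) -> None:
    """Write one or several molecules as a GenBank flat file.

    The output round-trips: :func:`read_genbank` restores sequence,
    topology and features exactly.
    """
    mols = [molecule] if isinstance(molecule, DnaMolecule) else list(molecule)
    records = [_to_biopython(m) for m in mols]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def read_fasta(path: str | Path, circular: bool = False) -> list[DnaMolecule]:
    """Read FASTA; records are linear unless ``circular`` is set."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise ParseError(f"malformed FASTA file {path}: {exc}") from exc
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    topo = "circular" if circular else "linear"
    return [DnaMolecule(r.id, str(r.seq), topo) for r in records]


def write_fasta(molecules: DnaMolecule | Iterable[DnaMolecule],
                path: str | Path, width: int = 70) -> None:
    mols = [molecules] if isinstance(molecules, DnaMolecule) else list(molecules)
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f">{m.id}\n")
            for i in range(0, len(m.seq), width):
                fh.write(m.seq[i:i + width] + "\n")
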