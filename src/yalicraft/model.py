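"""Sequence data model: annotated DNA molecules with circular or linear topology.

The :class:`DnaMolecule` is the universal currency of every operation in the
package: plasmids, chromosomes, amplicons and assembly products are all
molecules.  Coordinates are 0-based half-open throughout; positions on
circular molecules are reduced modulo the length.  Circular molecules are
compared via their canonical form, the lexicographically minimal rotation
over both strands, which makes product comparison deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "Interval",
    "SeqFeature",
    "DnaMolecule",
    "revcomp",
    "iupac_regex",
    "find_sites",
    "molecules_equal",
    "canonical_key",
    "CONTROLLED_KEYS",
]

# Degenerate codes are allowed in search patterns (enzymes and PAMs need
# them) but molecule sequences are restricted to {A,C,G,T,N}.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CONTROLLED_KEYS = frozenset({
    "promoter", "CDS", "terminator", "marker", "HA", "lox_site",
    "overhang_junction", "reporter", "origin", "resistance",
    "sgRNA_cassette", "misc",
})

_SEQ_RE = re.compile(r"^[ACGTN]+$")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (complement of R is Y, etc.)."""
    return seq.translate(_COMP)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into a regular expression."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        exp = IUPAC[ch]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a molecule.

    ``wraps`` marks origin-spanning spans on circular molecules; a wrapping
    interval covers ``[start, L) + [0, end)``.
    """

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError("interval coordinates must be non-negative")
        if not self.wraps and self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )

    def length(self, seq_len: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if seq_len is None:
            raise ValueError("length of a wrapping interval needs seq_len")
        return seq_len - self.start + self.end


@dataclass(frozen=True)
class SeqFeature:
    """An annotation on a molecule.

    ``key`` is drawn from the controlled vocabulary (or ``misc``); ``label``
    carries the part identity (hrGFP, URA3, lox66, ...).
    """

    key: str
    label: str
    interval: Interval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.key not in CONTROLLED_KEYS:
            raise ValueError(f"feature key {self.key!r} not in vocabulary")
        if not self.label:
            raise ValueError("feature label must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class DnaMolecule:
    id: str
    seq: str
    topology: str = "circular"
    features: list[SeqFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"molecule {self.id!r}: empty sequence")
        if not _SEQ_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"molecule {self.id!r}: non-ACGTN symbols {bad}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        n = len(self.seq)
        for f in self.features:
            iv = f.interval
            if iv.start >= n or (not iv.wraps and iv.end > n) or (iv.wraps and iv.end > n):
                raise ValueError(
                    f"molecule {self.id!r}: feature {f.label!r} interval "
                    f"outside [0, {n})"
                )
            if iv.wraps and self.topology == "linear":
                raise ValueError(
                    f"molecule {self.id!r}: wrapping feature on linear molecule"
                )

    # -- basics -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def region(self, start: int, end: int) -> str:
        """Subsequence [start, end); modular on circular molecules.

        ``end`` may exceed the length on circular molecules (the read wraps).
        """
        n = len(self.seq)
        if self.is_circular:
            start %= n
            if end < start:
                end += n
            # a read may span the full circle plus an overhang (single-cut
            # digests), but never more than two turns
            if end - start > 2 * n:
                raise ValueError("region longer than two molecule turns")
            tripled = self.seq + self.seq + self.seq
            return tripled[start:end]
        if start < 0 or end > n or end < start:
            raise ValueError(f"region [{start}, {end}) outside linear molecule")
        return self.seq[start:end]

    def feature_seq(self, feat: SeqFeature) -> str:
        iv = feat.interval
        end = iv.end + len(self.seq) if iv.wraps else iv.end
        s = self.region(iv.start, end)
        return revcomp(s) if feat.strand == "-" else s

    # -- transforms -------------------------------------------------------

    def rotated(self, offset: int) -> "DnaMolecule":
        """Rotate a circular molecule so old position ``offset`` becomes 0."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear molecule")
        n = len(self.seq)
        offset %= n
        seq = self.seq[offset:] + self.seq[:offset]
        feats = []
        for f in self.features:
            iv = f.interval
            length = iv.length(n)
            s = (iv.start - offset) % n
            e = s + length
            if e <= n:
                feats.append(replace(f, interval=Interval(s, e)))
            else:
                feats.append(replace(f, interval=Interval(s, e - n, wraps=True)))
        return DnaMolecule(self.id, seq, "circular", feats)

    def reverse_complement(self) -> "DnaMolecule":
        n = len(self.seq)
        feats = []
        for f in self.features:
            iv = f.interval
            length = iv.length(n)
            # old interval start s maps to new position n - (s + length)
            s = (n - (iv.start + length)) % n if self.is_circular else n - iv.end
            if self.is_circular and iv.wraps:
                s = (n - (iv.start + length)) % n
            e = s + length
            strand = "-" if f.strand == "+" else "+"
            if e <= n:
                feats.append(replace(f, interval=Interval(s, e), strand=strand))
            else:
                feats.append(
                    replace(f, interval=Interval(s, e - n, wraps=True), strand=strand)
                )
        return DnaMolecule(self.id, revcomp(self.seq), self.topology, feats)

    def canonicalized(self) -> "DnaMolecule":
        """Rotate (and possibly flip) a circular molecule to canonical form."""
        if not self.is_circular:
            return self
        fwd_i = _least_rotation(self.seq)
        rc = revcomp(self.seq)
        rev_i = _least_rotation(rc)
        fwd = self.seq[fwd_i:] + self.seq[:fwd_i]
        rev = rc[rev_i:] + rc[:rev_i]
        if fwd <= rev:
            return self.rotated(fwd_i)
        return self.reverse_complement().rotated(rev_i)

    def with_id(self, new_id: str) -> "DnaMolecule":
        return DnaMolecule(new_id, self.seq, self.topology, list(self.features))

    def features_by_key(self, key: str) -> list[SeqFeature]:
        return [f for f in self.features if f.key == key]

    def find_feature(self, label: str) -> SeqFeature | None:
        for f in self.features:
            if f.label == label:
                return f
        return None


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_key(mol_or_seq: "DnaMolecule | str", topology: str = "circular") -> str:
    """Canonical comparison string: minimal rotation over both strands
    (circular), or min(seq, revcomp) for linear molecules."""
    if isinstance(mol_or_seq, DnaMolecule):
        seq, topology = mol_or_seq.seq, mol_or_seq.topology
    else:
        seq = mol_or_seq.upper()
    rc = revcomp(seq)
    if topology == "linear":
        return min(seq, rc)
    i = _least_rotation(seq)
    j = _least_rotation(rc)
    return min(seq[i:] + seq[:i], rc[j:] + rc[:j])


def find_sites(molecule: DnaMolecule, pattern: str) -> list[tuple[int, str]]:
    """All occurrences of an IUPAC ``pattern`` on both strands.

    Positions are 0-based starts of the matched span on the + strand;
    origin-spanning matches on circular molecules are found once.  A pattern
    longer than the molecule yields an empty list.
    """
    n = len(molecule.seq)
    m = len(pattern)
    if m == 0:
        raise ValueError("empty pattern")
    if m > n:
        return []
    hits: set[tuple[int, str]] = set()
    search_space = molecule.seq + molecule.seq[: m - 1] if molecule.is_circular else molecule.seq
    fwd = iupac_regex(pattern)
    for match in re.finditer(f"(?={fwd.pattern})", search_space):
        hits.add((match.start() % n, "+"))
    rev = iupac_regex(revcomp(pattern))
    for match in re.finditer(f"(?={rev.pattern})", search_space):
        hits.add((match.start() % n, "-"))
    return sorted(hits)


def molecules_equal(a: DnaMolecule, b: DnaMolecule) -> bool:
    """Sequence-level identity up to rotation and strand.

    Circular molecules are equal iff one is a rotation (or a rotation of the
    reverse complement) of the other; linear molecules iff exact or
    reverse-complement match.  Annotations are not compared.
    """
    if a.topology != b.topology or len(a.seq) != len(b.seq):
        return False
    return canonical_key(a) == canonical_key(b)
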