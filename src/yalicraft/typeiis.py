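"""Type IIS restriction digestion and sticky-end ligation.

Type IIS enzymes (AarI, BsaI, BsmBI, ...) cut at a fixed offset *outside*
their non-palindromic recognition sequence, leaving short programmable 5'
overhangs ("fusion sites").  Because the recognition site leaves with one of
the fragments, digestion and ligation can cycle in a single pot until
products lacking sites accumulate: this is the basis of Golden Gate
assembly, and the reason :func:`golden_gate` classifies enumerated circular
products into *stable* (site-free, the assembly outcome) and *unstable*
(re-ligations that are cut again).

Fragments are represented by their top strand including overhang bases; a
left overhang is the single-stranded prefix of the top strand, a right
overhang is the bottom-strand extension written in top-strand coordinates.
Two ends are therefore compatible exactly when their stored overhang
strings are equal.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .model import (
    DnaMolecule,
    Interval,
    SeqFeature,
    canonical_key,
    find_sites,
    revcomp,
)

__all__ = [
    "Enzyme",
    "Overhang",
    "Fragment",
    "DigestResult",
    "GGReport",
    "UnresolvableCutError",
    "digest",
    "ligate_cyclic",
    "golden_gate",
    "fidelity_check",
    "AARI",
    "BSAI",
    "BSMBI",
]


class UnresolvableCutError(ValueError):
    """Two recognition sites whose cut windows overlap."""


@dataclass(frozen=True)
class Enzyme:
    """A Type IIS enzyme definition.

    ``cut_offset_top``/``cut_offset_bottom`` count nucleotides downstream of
    the recognition sequence on the top/bottom strand; AarI is CACCTGC(4/8),
    i.e. a 4-nt 5' overhang eight bases downstream of the site.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if self.recognition.upper() == revcomp(self.recognition.upper()):
            raise ValueError(
                f"{self.name}: palindromic recognition sequence is not Type IIS"
            )
        if self.cut_offset_top < 0 or self.cut_offset_bottom < 0:
            raise ValueError(f"{self.name}: cut offsets must be >= 0 (outside site)")

    @property
    def overhang_len(self) -> int:
        return abs(self.cut_offset_bottom - self.cut_offset_top)


AARI = Enzyme("AarI", "CACCTGC", 4, 8)
BSAI = Enzyme("BsaI", "GGTCTC", 1, 5)
BSMBI = Enzyme("BsmBI", "CGTCTC", 1, 5)


@dataclass(frozen=True)
class Overhang:
    """A single-stranded extension, written on the top strand."""

    seq: str
    end: str = "five_prime"
    side: str = "left"

    def __len__(self) -> int:
        return len(self.seq)

    def matches(self, other: "Overhang") -> bool:
        """True when this (right) end can ligate to ``other`` (left) end."""
        return len(self.seq) > 0 and self.seq == other.seq


@dataclass(frozen=True)
class Fragment:
    """A linear piece with typed sticky ends.

    ``seq`` is the full top-strand span including both overhang regions,
    so the left overhang is a prefix and the right overhang a suffix.
    Feature coordinates are relative to ``seq``.
    """

    seq: str
    left: Overhang
    right: Overhang
    parent_id: str = ""
    features: tuple[SeqFeature, ...] = ()

    def __post_init__(self) -> None:
        if self.left.seq and not self.seq.startswith(self.left.seq):
            raise ValueError("left overhang is not a prefix of the fragment")
        if self.right.seq and not self.seq.endswith(self.right.seq):
            raise ValueError("right overhang is not a suffix of the fragment")

    def __len__(self) -> int:
        return len(self.seq)

    def flipped(self) -> "Fragment":
        n = len(self.seq)
        feats = []
        for f in self.features:
            iv = f.interval
            feats.append(replace(
                f,
                interval=Interval(n - iv.end, n - iv.start),
                strand="-" if f.strand == "+" else "+",
            ))
        return Fragment(
            revcomp(self.seq),
            Overhang(revcomp(self.right.seq), self.right.end, "left"),
            Overhang(revcomp(self.left.seq), self.left.end, "right"),
            self.parent_id,
            tuple(feats),
        )

    def has_site(self, enzyme: Enzyme) -> bool:
        mol = DnaMolecule("frag", self.seq, "linear")
        return bool(find_sites(mol, enzyme.recognition))


@dataclass
class DigestResult:
    fragments: list[Fragment]
    undigested: DnaMolecule | None = None

    @property
    def was_cut(self) -> bool:
        return self.undigested is None


def _cut_windows(molecule: DnaMolecule, enzyme: Enzyme) -> list[int]:
    """Start positions (top strand) of the overhang windows for every site."""
    rec_len = len(enzyme.recognition)
    n = len(molecule.seq)
    starts = []
    for pos, strand in find_sites(molecule, enzyme.recognition):
        if strand == "+":
            a = pos + rec_len + enzyme.cut_offset_top
        else:
            a = pos - enzyme.cut_offset_bottom
        if molecule.is_circular:
            a %= n
        starts.append(a)
    return sorted(starts)


def _clip_features(molecule: DnaMolecule, start: int, length: int) -> tuple[SeqFeature, ...]:
    """Features of a (possibly wrapping) window [start, start+length),
    re-based to the window and truncated at its edges."""
    n = len(molecule.seq)
    out = []
    for f in molecule.features:
        iv = f.interval
        flen = iv.length(n)
        rel = (iv.start - start) % n if molecule.is_circular else iv.start - start
        if rel < 0 or rel >= length:
            # feature may still reach into the window from "before" its start
            # only in the linear case; modular arithmetic covers circular
            if molecule.is_circular or rel + flen <= 0:
                continue
            flen += rel
            rel = 0
        end = min(rel + flen, length)
        if end - rel >= 1:
            out.append(replace(f, interval=Interval(rel, end)))
    return tuple(out)


def digest(molecule: DnaMolecule, enzyme: Enzyme) -> DigestResult:
    """Digest a molecule with a Type IIS enzyme.

    A circular molecule with *k* sites yields exactly *k* fragments; a
    linear molecule with *k* usable sites yields *k+1* (outer ends blunt).
    A circular molecule with no sites is returned undigested, flagged via
    :attr:`DigestResult.undigested`.  Overlapping cut windows raise
    :class:`UnresolvableCutError`.
    """
    n = len(molecule.seq)
    ov = enzyme.overhang_len
    windows = _cut_windows(molecule, enzyme)

    if molecule.is_circular:
        if not windows:
            return DigestResult([], undigested=molecule)
        for a, b in zip(windows, windows[1:] + [windows[0] + n]):
            if b - a < ov:
                raise UnresolvableCutError(
                    f"{molecule.id}: {enzyme.name} cut windows at {a} and {b % n} overlap"
                )
        frags = []
        k = len(windows)
        for i in range(k):
            a = windows[i]
            b = windows[(i + 1) % k]
            span = (b - a) % n or n
            length = span + ov
            seq = molecule.region(a, a + length)
            frags.append(Fragment(
                seq,
                Overhang(seq[:ov], side="left"),
                Overhang(seq[-ov:] if ov else "", side="right"),
                molecule.id,
                _clip_features(molecule, a, length),
            ))
        return DigestResult(frags)

    # linear: discard cuts whose windows fall off either end
    windows = [a for a in windows if 0 <= a and a + ov <= n]
    if not windows:
        return DigestResult([], undigested=molecule)
    for a, b in zip(windows, windows[1:]):
        if b - a < ov:
            raise UnresolvableCutError(
                f"{molecule.id}: {enzyme.name} cut windows at {a} and {b} overlap"
            )
    bounds = [0] + windows + [n]
    frags = []
    for i in range(len(bounds) - 1):
        a = bounds[i]
        is_last = i + 1 == len(bounds) - 1
        end = n if is_last else bounds[i + 1] + ov
        seq = molecule.seq[a:end]
        left = Overhang(seq[:ov], side="left") if i > 0 else Overhang("", side="left")
        right = Overhang("", side="right") if is_last else Overhang(seq[-ov:] if ov else "", side="right")
        frags.append(Fragment(seq, left, right, molecule.id,
                              _clip_features(molecule, a, end - a)))
    return DigestResult(frags)


def _product_id(seq: str) -> str:
    return "asm_" + hashlib.sha1(canonical_key(seq).encode()).hexdigest()[:10]


def ligate_cyclic(fragments: Sequence[Fragment], *, allow_blunt: bool = False,
                  max_copies: int = 1) -> list[DnaMolecule]:
    """Enumerate every distinct circular molecule formable from the pool.

    Fragments join through complementary overhang pairs; each fragment is
    used at most ``max_copies`` times per product (1 by default, so
    multimeric circles are not enumerated).  Junction bases appear once in
    the product.  Products are returned in canonical form, deduplicated,
    sorted by length then sequence.
    """
    frags = list(fragments)
    products: dict[str, DnaMolecule] = {}

    def joinable(right: Overhang, left: Overhang) -> bool:
        if len(right.seq) == 0 and len(left.seq) == 0:
            return allow_blunt
        return right.seq == left.seq

    def close_chain(chain: list[Fragment]) -> None:
        if not joinable(chain[-1].right, chain[0].left):
            return
        seq_parts: list[str] = []
        feats: list[SeqFeature] = []
        offset = 0
        for frag in chain:
            trimmed = len(frag.seq) - len(frag.right.seq)
            seq_parts.append(frag.seq[:trimmed])
            for f in frag.features:
                iv = f.interval
                end = min(iv.end, trimmed)
                if end - iv.start >= 1 and iv.start < trimmed:
                    feats.append(replace(
                        f, interval=Interval(offset + iv.start, offset + end)))
            offset += trimmed
        seq = "".join(seq_parts)
        if not seq:
            return
        mol = DnaMolecule(_product_id(seq), seq, "circular", feats).canonicalized()
        products.setdefault(canonical_key(mol), mol)

    def extend(chain: list[Fragment], used: list[int], min_index: int) -> None:
        close_chain(chain)
        for j in range(min_index, len(frags)):
            if used[j] >= max_copies:
                continue
            for cand in (frags[j], frags[j].flipped()):
                if joinable(chain[-1].right, cand.left):
                    used[j] += 1
                    extend(chain + [cand], used, min_index)
                    used[j] -= 1

    for i, frag in enumerate(frags):
        used = [0] * len(frags)
        used[i] = 1
        # fixing the lowest-index fragment as the chain start (in either
        # orientation) enumerates each cycle at least once; duplicates are
        # removed by canonical form
        for cand in (frag, frag.flipped()):
            extend([cand], used, i)

    return sorted(products.values(), key=lambda m: (len(m.seq), m.seq))


def fidelity_check(overhangs: Iterable[str]) -> list[str]:
    """Warnings about an overhang set: duplicates, palindromes, and
    reverse-complement collisions between non-partner junctions."""
    ovs = [o.upper() for o in overhangs]
    warnings = []
    seen: set[str] = set()
    for o in ovs:
        if o in seen:
            warnings.append(f"duplicated overhang {o}")
        seen.add(o)
    for o in sorted(seen):
        if o == revcomp(o):
            warnings.append(f"palindromic (self-complementary) overhang {o}")
    for o in sorted(seen):
        rc = revcomp(o)
        if rc in seen and rc != o and o < rc:
            warnings.append(f"reverse-complement collision between {o} and {rc}")
    return warnings


@dataclass
class GGReport:
    """Outcome of a one-pot Golden Gate reaction."""

    stable: list[DnaMolecule] = field(default_factory=list)
    unstable: list[DnaMolecule] = field(default_factory=list)
    undigested: list[DnaMolecule] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    intended: list[str] = field(default_factory=list)
    fragments: list[Fragment] = field(default_factory=list)

    @property
    def products(self) -> list[DnaMolecule]:
        return self.stable

    @property
    def all_circles(self) -> list[DnaMolecule]:
        return self.stable + self.unstable


def golden_gate(plasmids: Sequence[DnaMolecule], enzyme: Enzyme, *,
                allow_blunt: bool = False, max_copies: int = 1,
                intended: Sequence[str] = ()) -> GGReport:
    """Simulate a one-pot Golden Gate reaction.

    All inputs are digested, every circular ligation product is enumerated,
    and products are split into stable circles (no recognition site of the
    enzyme left: these accumulate under reaction cycling and are the
    assembly outcome) and unstable re-ligations.  Overhang-fidelity
    warnings cover the ends of site-free fragments, i.e. the junctions that
    persist in stable products.
    """
    if not plasmids:
        raise ValueError("golden_gate needs at least one input molecule")
    report = GGReport(intended=list(intended))
    pool: list[Fragment] = []
    for mol in plasmids:
        res = digest(mol, enzyme)
        if res.undigested is not None:
            report.undigested.append(res.undigested)
            report.warnings.append(
                f"input {mol.id} has no {enzyme.name} site and was not digested")
        pool.extend(res.fragments)
    report.fragments = pool

    persistent_ends = [
        ov.seq for f in pool if not f.has_site(enzyme)
        for ov in (f.left, f.right) if ov.seq
    ]
    report.warnings.extend(fidelity_check(sorted(set(persistent_ends))))
    counts: dict[str, int] = {}
    for seq in persistent_ends:
        counts[seq] = counts.get(seq, 0) + 1
    for seq, cnt in sorted(counts.items()):
        if cnt > 2:
            report.warnings.append(
                f"overhang {seq} present on {cnt} persistent fragment ends "
                "(competing junctions)")

    for mol in ligate_cyclic(pool, allow_blunt=allow_blunt, max_copies=max_copies):
        if find_sites(mol, enzyme.recognition):
            report.unstable.append(mol)
        else:
            report.stable.append(mol)
    if not report.stable and not report.undigested:
        report.warnings.append("no stable circular product can form")
    return report
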