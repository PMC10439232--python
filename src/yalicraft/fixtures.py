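"""Deterministic synthetic mini-toolkit and genome generator.

The generator emulates the structure of a physical modular-cloning toolkit
— Lvl0 entry vectors with parts, the empty Lvl1/Lvl2 vector series for a
set of named intergenic loci, the promoter-assay vector, the deletion
vector, the empty Cas9 helper — together with a six-chromosome toy genome
carrying those loci and planted aminotransferase-like ORFs for disruption
tests.  Everything derives from a single integer seed: the same seed gives
byte-identical files.

Sequence hygiene: every random element is scrubbed of all configured
Type IIS recognition sequences (both strands) and is padded with ``AA`` at
element boundaries.  None of the recognition sequences contains ``AA`` or
starts/ends with ``A``, so no concatenation of clean padded elements can
ever create a recognition site across a boundary; enzyme-site counts on
every construct are therefore exactly the designed ones (and are asserted
at build time).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cas import verify_helper
from .config import SyntaxConfig, default_config
from .grammar import VectorName, enumerate_empty_vectors, format_name
from .genome import DEFAULT_ARM_LEN, GenomeLocus, design_has, write_loci_tsv
from .io import write_fasta, write_genbank
from .model import DnaMolecule, Interval, SeqFeature, find_sites, revcomp

__all__ = [
    "FixtureSpec",
    "FixtureGenome",
    "FixtureToolkit",
    "build_fixture_genome",
    "build_fixture_toolkit",
    "make_promoter_amplicon",
    "make_ha_amplicon",
]

PAD = "AA"
_BASES = np.array(list("ACGT"))

PROMOTER_NAMES = ("TEF1", "ALK1", "RPL25", "TDH1")
GENE_NAMES = ("hrGFP", "ARO4", "ARO7", "HPD1")
TERMINATOR_NAMES = ("Tsyn1", "Tsyn2")
ORF_NAMES = ("ARO8", "ARO9", "AAT1", "AAT2")
CHROMOSOMES = "ABCDEF"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic toolkit; one seed fixes everything."""

    seed: int = 0
    n_loci: int = 16
    arm_len: int = DEFAULT_ARM_LEN
    chrom_len: int = 8000
    n_promoters: int = 3
    n_genes: int = 4
    n_terminators: int = 2
    orf_len: int = 600
    syntax: SyntaxConfig | None = None

    def config(self) -> SyntaxConfig:
        return self.syntax or default_config()


# ---------------------------------------------------------------------------
# random sequence hygiene


def _forbidden(cfg: SyntaxConfig) -> list[str]:
    pats = []
    for enz in cfg.enzymes.values():
        pats.append(enz.recognition)
        pats.append(revcomp(enz.recognition))
    return sorted(set(pats))


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _scrub(seq: str, rng: np.random.Generator, patterns: list[str]) -> str:
    buf = list(seq)
    for _ in range(10000):
        s = "".join(buf)
        hit = None
        for pat in patterns:
            idx = s.find(pat)
            if idx >= 0 and (hit is None or idx < hit[0]):
                hit = (idx, len(pat))
        if hit is None:
            return s
        idx, ln = hit
        for i in range(idx, idx + ln):
            buf[i] = str(_BASES[rng.integers(0, 4)])
    raise RuntimeError("could not scrub sequence of recognition sites")


def _clean_seq(rng: np.random.Generator, n: int, patterns: list[str]) -> str:
    return _scrub(_rand_bases(rng, n), rng, patterns)


def _part(rng: np.random.Generator, n: int, patterns: list[str]) -> str:
    """A clean random element with AA boundary pads."""
    if n < 6:
        raise ValueError("parts must be at least 6 nt")
    return PAD + _clean_seq(rng, n - 4, patterns) + PAD


def _orf_seq(rng: np.random.Generator, inner_len: int,
             patterns: list[str]) -> str:
    """ATG...stop open reading frame, clean as a whole (the fixed start and
    stop codons can complete a recognition site with an unlucky interior)."""
    for _ in range(100):
        core = "ATG" + _clean_seq(rng, inner_len, patterns) + "TAA"
        if not any(p in core for p in patterns):
            return core
    raise RuntimeError("could not draw a clean ORF")


# ---------------------------------------------------------------------------
# genome


@dataclass
class FixtureGenome:
    chromosomes: dict[str, DnaMolecule]
    loci: list[GenomeLocus]
    orfs: list[GenomeLocus]

    def locus(self, name: str) -> GenomeLocus:
        for loc in itertools.chain(self.loci, self.orfs):
            if loc.name == name:
                return loc
        raise KeyError(f"no locus named {name!r}")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        order = sorted(self.chromosomes)
        write_fasta([self.chromosomes[c] for c in order], out / "genome.fasta")
        write_loci_tsv(self.loci + self.orfs, out / "loci.tsv")


def _locus_counts(n_loci: int) -> list[int]:
    base, extra = divmod(n_loci, len(CHROMOSOMES))
    return [base + (1 if i < extra else 0) for i in range(len(CHROMOSOMES))]


def build_fixture_genome(spec: FixtureSpec) -> FixtureGenome:
    """Six toy chromosomes with named intergenic loci and planted ORFs.

    Loci (IntA1, IntA2, ... by chromosome) are insertion points at least
    ``arm_len`` from every chromosome end; the four aminotransferase-like
    ORFs are planted downstream of the loci, one per chromosome.
    """
    cfg = spec.config()
    patterns = _forbidden(cfg)
    rng = np.random.default_rng([spec.seed, 0])
    margin = spec.arm_len + 50
    if spec.chrom_len < 2 * margin + spec.orf_len + 200:
        raise ValueError("chromosomes too short for the requested arms/ORFs")
    chroms: dict[str, DnaMolecule] = {}
    loci: list[GenomeLocus] = []
    orfs: list[GenomeLocus] = []
    counts = _locus_counts(spec.n_loci)
    for ci, chrom_name in enumerate(CHROMOSOMES):
        seq = _clean_seq(rng, spec.chrom_len, patterns)
        feats = []
        # plant one ORF per chromosome while names last
        if ci < len(ORF_NAMES):
            orf_name = ORF_NAMES[ci]
            orf_seq = _orf_seq(rng, spec.orf_len - 6, patterns)
            pos = int(spec.chrom_len * 0.75)
            window = PAD + orf_seq + PAD
            seq = seq[:pos] + window + seq[pos + len(window):]
            start = pos + len(PAD)
            feats.append(SeqFeature("CDS", orf_name,
                                    Interval(start, start + len(orf_seq))))
            orfs.append(GenomeLocus(chrom_name, start, start + len(orf_seq),
                                    orf_name, intergenic=False))
        k = counts[ci]
        span_end = int(spec.chrom_len * 0.65)
        for j in range(k):
            point = margin + (j + 1) * (span_end - margin) // (k + 1)
            loci.append(GenomeLocus(chrom_name, point, point,
                                    f"Int{chrom_name}{j + 1}"))
        chroms[chrom_name] = DnaMolecule(chrom_name, seq, "linear", feats)
    return FixtureGenome(chroms, loci, orfs)


# ---------------------------------------------------------------------------
# plasmid construction


class _Builder:
    """Accumulates padded sequence elements and their features."""

    def __init__(self, mol_id: str):
        self.id = mol_id
        self.chunks: list[str] = []
        self.feats: list[SeqFeature] = []
        self.pos = 0

    def add(self, seq: str, key: str | None = None, label: str | None = None,
            pad: bool = True) -> "_Builder":
        if pad and self.chunks:
            self.chunks.append(PAD)
            self.pos += len(PAD)
        if key:
            self.feats.append(SeqFeature(key, label or key,
                                         Interval(self.pos, self.pos + len(seq))))
        self.chunks.append(seq)
        self.pos += len(seq)
        return self

    def molecule(self, topology: str = "circular") -> DnaMolecule:
        return DnaMolecule(self.id, "".join(self.chunks), topology, self.feats)


def _scars(cfg: SyntaxConfig):
    """Fixed scar strings for the three enzymes."""
    e1, e2, ex = cfg.entry_enzyme, cfg.lvl2_enzyme, cfg.exchange_enzyme
    s1, s2, sx = cfg.spacers["entry"], cfg.spacers["lvl2"], cfg.spacers["exchange"]
    return {
        "entry_fwd": e1.recognition + s1,    # cut window follows
        "entry_rev": s1 + revcomp(e1.recognition),
        "lvl2_fwd": e2.recognition + s2,
        "lvl2_rev": s2 + revcomp(e2.recognition),
        "ex_fwd": ex.recognition + sx,
        "ex_rev": sx + revcomp(ex.recognition),
    }


def _entry_slot(cfg: SyntaxConfig, ovl: str, filler_seq: str,
                filler_label: str, ovr: str, b: _Builder) -> None:
    """Acceptor slot: dropout ``filler`` flanked by outward entry sites so
    digestion leaves the cut windows exactly on ``ovl``/``ovr``."""
    sc = _scars(cfg)
    b.add(ovl + sc["entry_rev"], pad=True)
    b.add(filler_seq, "reporter", filler_label)
    b.add(sc["entry_fwd"] + ovr)


@dataclass
class _Catalog:
    """Raw building-block sequences (with their AA pads)."""

    parts: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> str:
        return self.parts[key]

    def __setitem__(self, key: str, value: str) -> None:
        self.parts[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self.parts


def _build_catalog(spec: FixtureSpec, cfg: SyntaxConfig,
                   rng: np.random.Generator) -> _Catalog:
    pats = _forbidden(cfg)
    cat = _Catalog()
    for name in PROMOTER_NAMES[:spec.n_promoters]:
        cat[f"promoter:{name}"] = _part(rng, 300, pats)
    for name in GENE_NAMES[:spec.n_genes]:
        cat[f"gene:{name}"] = PAD + _orf_seq(rng, 500, pats) + PAD
    for name in TERMINATOR_NAMES[:spec.n_terminators]:
        cat[f"terminator:{name}"] = _part(rng, 150, pats)
    for name in ("sfGFP", "mScarlet"):
        cat[f"reporter:{name}"] = _part(rng, 400, pats)
    for letter, marker in cfg.markers.items():
        cat[f"marker:{marker}"] = _part(rng, 400, pats)
    for letter, res in cfg.resistances.items():
        cat[f"resistance:{res}"] = _part(rng, 350, pats)
    cat["ori"] = _part(rng, 250, pats)
    cat["ARS68"] = _part(rng, 200, pats)
    cat["entry_backbone"] = _part(rng, 300, pats)
    cat["Zeta_up"] = _part(rng, spec.arm_len + 4, pats)
    cat["Zeta_dn"] = _part(rng, spec.arm_len + 4, pats)
    cat["UAS1B8-TEF"] = _part(rng, 136 + 4, pats)
    cat["Cas9-SV40NLS"] = PAD + _orf_seq(rng, 700, pats) + PAD
    cat["Cas9_term"] = _part(rng, 120, pats)
    cat["SCR1p-tRNAGly"] = _part(rng, 150, pats)
    cat["tracrRNA"] = _part(rng, 80, pats)
    cat["rpsL-kanR"] = _part(rng, 500, pats)
    cat["filler"] = _part(rng, 60, pats)
    return cat


def _unpadded(seq: str) -> tuple[str, int]:
    """Strip the AA pads for feature annotation: (core, offset)."""
    return seq[len(PAD):-len(PAD)], len(PAD)


class _PlasmidFactory:
    def __init__(self, spec: FixtureSpec, cfg: SyntaxConfig, cat: _Catalog,
                 genome: FixtureGenome):
        self.spec = spec
        self.cfg = cfg
        self.cat = cat
        self.genome = genome
        self.sc = _scars(cfg)

    # -- helpers ---------------------------------------------------------

    def _add_core(self, b: _Builder, cat_key: str, key: str, label: str) -> None:
        """Add a catalog element, annotating only the unpadded core."""
        seq = self.cat[cat_key]
        core, off = _unpadded(seq)
        if b.chunks:
            b.chunks.append(PAD)
            b.pos += len(PAD)
        b.feats.append(SeqFeature(key, label,
                                  Interval(b.pos + off, b.pos + off + len(core))))
        b.chunks.append(seq)
        b.pos += len(seq)

    def _add_ha(self, b: _Builder, arm: str, label: str) -> None:
        b.add(PAD, pad=True)
        b.add(arm, "HA", label, pad=False)
        b.add(PAD, pad=False)

    def _marker_cassette(self, b: _Builder, marker: str) -> None:
        lox = self.cfg.lox
        b.add(lox.lox71_seq, "lox_site", "lox71")
        self._add_core(b, f"marker:{marker}", "marker", marker)
        b.add(lox.lox66_seq, "lox_site", "lox66")

    # -- vectors ---------------------------------------------------------

    def entry_vector(self, part_type: str, name: str,
                     junctions: tuple[str, str]) -> DnaMolecule:
        key = {"promoter": "promoter", "gene": "CDS",
               "terminator": "terminator"}[part_type]
        b = _Builder(f"pL0-{name}")
        self._add_core(b, "ori", "origin", "ori")
        self._add_core(b, "resistance:chloramphenicol", "resistance",
                       "chloramphenicol")
        b.add(self.sc["entry_fwd"] + junctions[0], pad=True)
        self._add_core(b, f"{part_type}:{name}", key, name)
        b.add(junctions[1] + self.sc["entry_rev"])
        return b.molecule()

    def _exchange_open(self, b: _Builder) -> None:
        b.add(self.sc["ex_fwd"] + self.cfg.junction("exchange_left"), pad=True)

    def _exchange_close(self, b: _Builder) -> None:
        b.add(self.cfg.junction("exchange_right") + self.sc["ex_rev"], pad=True)

    def empty_vector(self, vname: VectorName) -> DnaMolecule:
        cfg = self.cfg
        marker = cfg.markers[vname.yeast_marker]
        res = cfg.resistances[vname.bacterial_resistance]
        if vname.chromosome == "Z":
            up, dn = self.cat["Zeta_up"], self.cat["Zeta_dn"]
            up, _ = _unpadded(up)
            dn, _ = _unpadded(dn)
            up_label, dn_label = "Zeta_up", "Zeta_dn"
        else:
            locus = self.genome.locus(
                f"Int{vname.chromosome}{vname.locus_number}")
            up, dn = design_has(self.genome.chromosomes, locus,
                                self.spec.arm_len)
            up_label, dn_label = f"{locus.name}_up", f"{locus.name}_dn"
        b = _Builder(format_name(vname))
        self._add_core(b, "ori", "origin", "ori")
        self._add_core(b, f"resistance:{res}", "resistance", res)
        self._add_ha(b, up, up_label)
        self._exchange_open(b)
        self._marker_cassette(b, marker)
        a, bb, c, d = cfg.entry_junctions()
        sfgfp = self.cat["reporter:sfGFP"]
        if vname.level == 1:
            p_l = cfg.position_junction(vname.sublevel - 1)
            p_r = cfg.position_junction(vname.sublevel)
            b.add(self.sc["lvl2_fwd"] + p_l + PAD + a + self.sc["entry_rev"],
                  pad=True)
            self._add_core(b, "reporter:sfGFP", "reporter", "sfGFP")
            b.add(self.sc["entry_fwd"] + d + PAD + p_r + self.sc["lvl2_rev"])
        else:
            p_l = cfg.position_junction(0)
            p_r = cfg.position_junction(vname.sublevel)
            b.add(p_l + self.sc["lvl2_rev"], pad=True)
            self._add_core(b, "reporter:sfGFP", "reporter", "sfGFP")
            b.add(self.sc["lvl2_fwd"] + p_r)
        self._exchange_close(b)
        self._add_ha(b, dn, dn_label)
        return b.molecule()

    def pro_vector(self) -> DnaMolecule:
        cfg = self.cfg
        a, bb, c, d = cfg.entry_junctions()
        locus = self._pro_locus()
        up, dn = design_has(self.genome.chromosomes, locus, self.spec.arm_len)
        b = _Builder("pProUA-mScarlet")
        self._add_core(b, "ori", "origin", "ori")
        self._add_core(b, "resistance:ampicillin", "resistance", "ampicillin")
        self._add_ha(b, up, f"{locus.name}_up")
        self._exchange_open(b)
        self._marker_cassette(b, cfg.markers["U"])
        b.add(self.sc["lvl2_fwd"] + cfg.position_junction(0) + PAD
              + a + self.sc["entry_rev"], pad=True)
        self._add_core(b, "reporter:mScarlet", "reporter", "mScarlet")
        b.add(self.sc["entry_fwd"] + bb)
        self._add_core(b, "gene:hrGFP", "CDS", "hrGFP")
        b.add(c, pad=True)
        self._add_core(b, f"terminator:{TERMINATOR_NAMES[0]}", "terminator",
                       TERMINATOR_NAMES[0])
        b.add(d + PAD + cfg.position_junction(1) + self.sc["lvl2_rev"],
              pad=True)
        self._exchange_close(b)
        self._add_ha(b, dn, f"{locus.name}_dn")
        return b.molecule()

    def _pro_locus(self) -> GenomeLocus:
        try:
            return self.genome.locus("IntC2")
        except KeyError:
            return self.genome.loci[0]

    def del_vector(self) -> DnaMolecule:
        cfg = self.cfg
        j1, j2, j3, j4 = cfg.entry_junctions()
        b = _Builder("pDelUK-RG")
        self._add_core(b, "ori", "origin", "ori")
        self._add_core(b, "resistance:kanamycin", "resistance", "kanamycin")
        _entry_slot(cfg, j1, self.cat["reporter:mScarlet"], "mScarlet", j2, b)
        self._exchange_close_open_marker(b)
        _entry_slot(cfg, j3, self.cat["reporter:sfGFP"], "sfGFP", j4, b)
        return b.molecule()

    def _exchange_close_open_marker(self, b: _Builder) -> None:
        """URA3 between outward-pointing AarI sites: the marker drops out
        with both sites during TU transfer."""
        cfg = self.cfg
        b.add(cfg.junction("exchange_left") + self.sc["ex_rev"], pad=True)
        self._marker_cassette(b, cfg.markers["U"])
        b.add(self.sc["ex_fwd"] + cfg.junction("exchange_right"))

    def cas_helper(self) -> DnaMolecule:
        b = _Builder("pCasNA-RK")
        self._add_core(b, "ori", "origin", "ori")
        self._add_core(b, "resistance:ampicillin", "resistance", "ampicillin")
        self._add_core(b, "ARS68", "origin", "ARS68")
        self._add_core(b, "UAS1B8-TEF", "promoter", "UAS1B8-TEF")
        self._add_core(b, "Cas9-SV40NLS", "CDS", "Cas9-SV40NLS")
        self._add_core(b, "Cas9_term", "terminator", "Cas9_term")
        self._add_core(b, "marker:NAT", "marker", "NAT")
        # sgRNA cassette: the promoter feature must directly abut the spacer
        # slot (the 9-nt 5' linker of earlier helper designs was removed),
        # so the four elements are annotated over their padded spans with
        # zero gaps between features
        b.add(self.cat["SCR1p-tRNAGly"], "promoter", "SCR1p-tRNAGly",
              pad=True)
        b.add(self.cat["rpsL-kanR"], "marker", "rpsL-kanR", pad=False)
        b.add(self.cat["tracrRNA"], "sgRNA_cassette", "tracrRNA", pad=False)
        b.add("TTTTTTT", "terminator", "polyT_terminator", pad=False)
        return b.molecule()


# ---------------------------------------------------------------------------
# toolkit


@dataclass
class FixtureToolkit:
    spec: FixtureSpec
    config: SyntaxConfig
    genome: FixtureGenome
    molecules: dict[str, DnaMolecule]
    catalog: _Catalog

    def __getitem__(self, mol_id: str) -> DnaMolecule:
        return self.molecules[mol_id]

    def entry(self, name: str) -> DnaMolecule:
        return self.molecules[f"pL0-{name}"]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "plasmids").mkdir(parents=True, exist_ok=True)
        self.genome.write(out / "genome")
        self.config.write_yaml(out / "syntax.yaml")
        for mol_id in sorted(self.molecules):
            write_genbank(self.molecules[mol_id],
                          out / "plasmids" / f"{mol_id}.gb")


def _selfcheck(mol: DnaMolecule, cfg: SyntaxConfig,
               expected: dict[str, int]) -> None:
    for role, count in expected.items():
        enz = cfg.enzymes[role]
        got = len(find_sites(mol, enz.recognition))
        if got != count:
            raise AssertionError(
                f"{mol.id}: expected {count} {enz.name} sites, found {got}")


def build_fixture_toolkit(spec: FixtureSpec | None = None) -> FixtureToolkit:
    """Build the complete synthetic toolkit for a fixture spec.

    Includes entry vectors for every catalog part, the five empty
    Lvl1/Lvl2 variants per genomic locus plus the Zeta series, the Pro,
    Del and Cas vectors, and the toy genome.  Every plasmid is verified
    against its designed enzyme-site counts before it is returned.
    """
    spec = spec or FixtureSpec()
    cfg = spec.config()
    warnings = cfg.validate()
    if warnings:
        raise AssertionError(f"syntax configuration unsafe: {warnings}")
    genome = build_fixture_genome(spec)
    rng = np.random.default_rng([spec.seed, 1])
    cat = _build_catalog(spec, cfg, rng)
    fac = _PlasmidFactory(spec, cfg, cat, genome)
    mols: dict[str, DnaMolecule] = {}

    a, b, c, d = cfg.entry_junctions()
    for name in PROMOTER_NAMES[:spec.n_promoters]:
        mols[f"pL0-{name}"] = fac.entry_vector("promoter", name, (a, b))
    for name in GENE_NAMES[:spec.n_genes]:
        mols[f"pL0-{name}"] = fac.entry_vector("gene", name, (b, c))
    for name in TERMINATOR_NAMES[:spec.n_terminators]:
        mols[f"pL0-{name}"] = fac.entry_vector("terminator", name, (c, d))

    locus_names = [loc.name for loc in genome.loci]
    for vname in enumerate_empty_vectors(locus_names):
        mols[format_name(vname)] = fac.empty_vector(vname)
    for vname in enumerate_empty_vectors(["Zeta"], resistance="A"):
        mols[format_name(vname)] = fac.empty_vector(vname)

    mols["pProUA-mScarlet"] = fac.pro_vector()
    mols["pDelUK-RG"] = fac.del_vector()
    mols["pCasNA-RK"] = fac.cas_helper()

    for mol_id, mol in mols.items():
        if mol_id.startswith("pL0-"):
            _selfcheck(mol, cfg, {"entry": 2, "lvl2": 0, "exchange": 0})
        elif mol_id == "pProUA-mScarlet":
            _selfcheck(mol, cfg, {"entry": 2, "lvl2": 2, "exchange": 2})
        elif mol_id == "pDelUK-RG":
            _selfcheck(mol, cfg, {"entry": 4, "lvl2": 0, "exchange": 2})
        elif mol_id == "pCasNA-RK":
            _selfcheck(mol, cfg, {"entry": 0, "lvl2": 0, "exchange": 0})
        else:
            level = int(mol_id.split(".")[0][-1])
            _selfcheck(mol, cfg, {"entry": 2 if level == 1 else 0,
                                  "lvl2": 2, "exchange": 2})
    report = verify_helper(mols["pCasNA-RK"], cfg)
    if not report.ok:
        raise AssertionError(f"pCasNA-RK fails verification: {report.errors}")
    return FixtureToolkit(spec, cfg, genome, mols, cat)


# ---------------------------------------------------------------------------
# "PCR" amplicons: primer concatenation, no thermodynamics


def _amplicon(cfg: SyntaxConfig, insert: str, junctions: tuple[str, str],
              mol_id: str, feature: SeqFeature | None) -> DnaMolecule:
    sc = _scars(cfg)
    prefix = sc["entry_fwd"] + junctions[0] + PAD
    seq = prefix + insert + PAD + junctions[1] + sc["entry_rev"]
    feats = []
    if feature is not None:
        iv = feature.interval
        feats.append(SeqFeature(feature.key, feature.label,
                                Interval(iv.start + len(prefix),
                                         iv.end + len(prefix))))
    return DnaMolecule(mol_id, seq, "linear", feats)


def make_promoter_amplicon(toolkit: FixtureToolkit, name: str) -> DnaMolecule:
    """A promoter 'PCR product' with entry sites and promoter junctions."""
    cfg = toolkit.config
    core, _ = _unpadded(toolkit.catalog[f"promoter:{name}"])
    a, b, _, _ = cfg.entry_junctions()
    return _amplicon(
        cfg, PAD + core, (a, b), f"amp-{name}",
        SeqFeature("promoter", name, Interval(len(PAD), len(PAD) + len(core))))


def make_ha_amplicon(toolkit: FixtureToolkit, target: str,
                     which: str) -> DnaMolecule:
    """A homology-arm 'PCR product' for a deletion construct.

    ``target`` names a planted ORF; ``which`` is ``up`` or ``down``.
    The up arm carries the first two entry junctions, the down arm the
    last two, matching the two reporter slots of the deletion vector.
    """
    cfg = toolkit.config
    locus = toolkit.genome.locus(target)
    up, dn = design_has(toolkit.genome.chromosomes, locus,
                        toolkit.spec.arm_len)
    j1, j2, j3, j4 = cfg.entry_junctions()
    if which == "up":
        arm, junctions, suffix = up, (j1, j2), "up"
    elif which == "down":
        arm, junctions, suffix = dn, (j3, j4), "dn"
    else:
        raise ValueError("which must be 'up' or 'down'")
    return _amplicon(
        cfg, PAD + arm, junctions, f"amp-{target}_{suffix}",
        SeqFeature("HA", f"{target}_{suffix}",
                   Interval(len(PAD), len(PAD) + len(arm))))
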