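"""The toolkit grammar as data: part types, junction overhangs, enzymes,
reporter/marker vocabularies.

The concrete overhang sequences are configuration, not code.  The default
set below is internally consistent (it passes :func:`fidelity_check` and
creates no stray recognition sites at part boundaries), but every entry can
be overridden from a YAML file, so a user can drop in the fusion sites of
an existing physical toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model import revcomp
from .typeiis import AARI, BSAI, BSMBI, Enzyme, fidelity_check

__all__ = ["LoxConfig", "SyntaxConfig", "default_config", "ConfigError"]


class ConfigError(ValueError):
    pass


# Literature sequences of the mutant Cre sites: 13-nt arms around the
# asymmetric 8-nt spacer that defines directionality.  lox66 carries the
# right-arm mutation, lox71 the left-arm one; lox66 x lox71 recombination
# leaves the poorly re-recombinable double-mutant lox72.
_LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"
_LOX66 = "ATAACTTCGTATAATGTATGCTATACGAACGGTA"
_LOX71 = "TACCGTTCGTATAATGTATGCTATACGAAGTTAT"
_LOX72 = "TACCGTTCGTATAATGTATGCTATACGAACGGTA"


@dataclass(frozen=True)
class LoxConfig:
    lox66_seq: str = _LOX66
    lox71_seq: str = _LOX71
    lox72_seq: str = _LOX72
    loxP_seq: str = _LOXP
    arm_len: int = 13
    spacer_len: int = 8
    # which hybrid site the retained (marker-free) backbone should carry;
    # realised by placing lox71 upstream and lox66 downstream of the marker
    retained_hybrid: str = "lox72"

    def __post_init__(self) -> None:
        expect = 2 * self.arm_len + self.spacer_len
        for name in ("lox66_seq", "lox71_seq", "lox72_seq", "loxP_seq"):
            s = getattr(self, name)
            if len(s) != expect:
                raise ConfigError(f"{name} must be {expect} nt, got {len(s)}")
        spacers = {
            s[self.arm_len:self.arm_len + self.spacer_len]
            for s in (self.lox66_seq, self.lox71_seq, self.lox72_seq, self.loxP_seq)
        }
        if len(spacers) != 1:
            raise ConfigError("all lox sites must share the asymmetric spacer")

    def split(self, site_seq: str) -> tuple[str, str, str]:
        """(left arm, spacer, right arm) of a 34-nt site sequence."""
        a, s = self.arm_len, self.spacer_len
        return site_seq[:a], site_seq[a:a + s], site_seq[a + s:]


PART_TYPES = (
    "promoter", "gene", "terminator", "left_HA", "right_HA",
    "yeast_marker", "bacterial_resistance", "backbone", "reporter",
)

_DEFAULT_JUNCTIONS = {
    # entry (Lvl0 -> Lvl1 / Pro / Del) fusion sites
    "pre_promoter": "GGAG",
    "promoter_gene": "AATG",
    "gene_terminator": "GCTT",
    "post_terminator": "CGCT",
    # TU position sites for the Lvl1 -> Lvl2 reaction
    "pos0": "TGCC",
    "pos1": "GCAA",
    "pos2": "ACTA",
    "pos3": "TTAC",
    # AarI homology-arm exchange sites (Int module)
    "exchange_left": "AGGT",
    "exchange_right": "CGTT",
}

# the deletion-construct junctions reuse the entry fusion sites
_DEL_JUNCTIONS = ("pre_promoter", "promoter_gene", "gene_terminator", "post_terminator")


@dataclass
class SyntaxConfig:
    """The complete assembly grammar of a toolkit instance."""

    part_types: tuple[str, ...] = PART_TYPES
    junction_overhangs: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_JUNCTIONS))
    enzymes: dict[str, Enzyme] = field(default_factory=lambda: {
        "entry": BSAI, "lvl2": BSMBI, "exchange": AARI})
    reporters: dict[str, str] = field(default_factory=lambda: {
        "assembly_dropout": "sfGFP",
        "pro_dropout": "mScarlet",
        "del_dropout_up": "mScarlet",
        "del_dropout_down": "sfGFP",
    })
    markers: dict[str, str] = field(default_factory=lambda: {
        "U": "URA3", "L": "LEU2", "N": "NAT", "H": "hph"})
    resistances: dict[str, str] = field(default_factory=lambda: {
        "S": "spectinomycin", "K": "kanamycin", "A": "ampicillin",
        "C": "chloramphenicol"})
    lox: LoxConfig = field(default_factory=LoxConfig)
    counter_select: str = "rpsL-kanR"
    # short fixed spacers between a recognition sequence and its cut window
    spacers: dict[str, str] = field(default_factory=lambda: {
        "entry": "A", "lvl2": "A", "exchange": "TAGA"})

    # -- accessors --------------------------------------------------------

    @property
    def entry_enzyme(self) -> Enzyme:
        return self.enzymes["entry"]

    @property
    def lvl2_enzyme(self) -> Enzyme:
        return self.enzymes["lvl2"]

    @property
    def exchange_enzyme(self) -> Enzyme:
        return self.enzymes["exchange"]

    def junction(self, name: str) -> str:
        return self.junction_overhangs[name]

    def entry_junctions(self) -> list[str]:
        return [self.junction(j) for j in _DEL_JUNCTIONS]

    def position_junction(self, index: int) -> str:
        return self.junction(f"pos{index}")

    def dropout_labels(self) -> set[str]:
        return set(self.reporters.values())

    def spacer(self, role: str, enzyme: Enzyme | None = None) -> str:
        s = self.spacers[role]
        want = (enzyme or self.enzymes[role]).cut_offset_top
        if len(s) != want:
            raise ConfigError(
                f"spacer for {role!r} must be {want} nt for enzyme offsets")
        return s

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Check internal consistency; returns warnings, raises on errors."""
        warnings: list[str] = []
        groups = {
            "entry": [self.junction(j) for j in _DEL_JUNCTIONS],
            "lvl2": [self.position_junction(i) for i in range(4)],
            "exchange": [self.junction("exchange_left"),
                         self.junction("exchange_right")],
        }
        for role, ovs in groups.items():
            enzyme = self.enzymes[role]
            for o in ovs:
                if len(o) != enzyme.overhang_len:
                    raise ConfigError(
                        f"{role} junction overhang {o} does not match "
                        f"{enzyme.name} overhang length {enzyme.overhang_len}")
            problems = fidelity_check(ovs)
            if problems:
                raise ConfigError(f"{role} junction set fails fidelity: {problems}")
        # fixed scar context (recognition + spacer + overhang) must not
        # create recognition sites beyond the intentional one
        def count(pat: str, s: str) -> int:
            return sum(s[i:i + len(pat)] == pat
                       for i in range(len(s) - len(pat) + 1))

        for role, ovs in groups.items():
            enzyme = self.enzymes[role]
            sp = self.spacers[role]
            for o in ovs:
                for w in (enzyme.recognition + sp + o,
                          o + sp + revcomp(enzyme.recognition)):
                    for other in self.enzymes.values():
                        rec = other.recognition
                        expected = 1 if other is enzyme else 0
                        if count(rec, w) + count(revcomp(rec), w) != expected:
                            warnings.append(
                                f"scar window {w} creates a stray "
                                f"{other.name} site")
        self.spacer("entry")
        self.spacer("lvl2")
        self.spacer("exchange")
        return warnings

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "part_types": list(self.part_types),
            "junction_overhangs": dict(self.junction_overhangs),
            "enzymes": {
                role: {
                    "name": e.name,
                    "recognition": e.recognition,
                    "cut_offset_top": e.cut_offset_top,
                    "cut_offset_bottom": e.cut_offset_bottom,
                } for role, e in self.enzymes.items()
            },
            "reporters": dict(self.reporters),
            "markers": dict(self.markers),
            "resistances": dict(self.resistances),
            "lox": {
                "lox66_seq": self.lox.lox66_seq,
                "lox71_seq": self.lox.lox71_seq,
                "lox72_seq": self.lox.lox72_seq,
                "loxP_seq": self.lox.loxP_seq,
                "arm_len": self.lox.arm_len,
                "spacer_len": self.lox.spacer_len,
                "retained_hybrid": self.lox.retained_hybrid,
            },
            "counter_select": self.counter_select,
            "spacers": dict(self.spacers),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntaxConfig":
        base = cls()
        try:
            enzymes = {
                role: Enzyme(d["name"], d["recognition"],
                             int(d["cut_offset_top"]), int(d["cut_offset_bottom"]))
                for role, d in data.get("enzymes", {}).items()
            } or base.enzymes
            cfg = cls(
                part_types=tuple(data.get("part_types", base.part_types)),
                junction_overhangs={**base.junction_overhangs,
                                    **data.get("junction_overhangs", {})},
                enzymes={**base.enzymes, **enzymes},
                reporters={**base.reporters, **data.get("reporters", {})},
                markers={**base.markers, **data.get("markers", {})},
                resistances={**base.resistances, **data.get("resistances", {})},
                lox=LoxConfig(**data["lox"]) if "lox" in data else base.lox,
                counter_select=data.get("counter_select", base.counter_select),
                spacers={**base.spacers, **data.get("spacers", {})},
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad syntax configuration: {exc}") from exc
        cfg.validate()
        return cfg

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntaxConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not hold a configuration mapping")
        return cls.from_dict(data)


def default_config() -> SyntaxConfig:
    cfg = SyntaxConfig()
    cfg.validate()
    return cfg
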