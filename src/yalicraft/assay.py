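"""Normalization and summarization of promoter-strength measurements.

Raw fluorescence from a plate reader or flow cytometer is on an arbitrary,
instrument-specific scale.  Promoter strengths are therefore reported
relative to two anchors measured in the same medium on the same
instrument: the parent strain without reporter defines 0% (blank) and the
TEF1 promoter defines 100%:

    strength = 100 * (F_sample - F_blank) / (F_TEF1 - F_blank)

This makes the result invariant to affine rescaling of the raw units
(detector gain and offset) and preserves the within-batch ranking of
promoters.  Values below 0% or above 100% are perfectly legal readings and
are reported as-is, flagged rather than clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FluorRecord",
    "LibrarySummary",
    "normalize_strength",
    "summarize_library",
    "BLANK_PROMOTER",
    "REFERENCE_PROMOTER",
]

BLANK_PROMOTER = "parent"       # parent strain without the reporter (S234-like)
REFERENCE_PROMOTER = "TEF1"


@dataclass(frozen=True)
class FluorRecord:
    """One fluorescence measurement of one transformant."""

    strain: str
    promoter: str
    medium: str
    replicate: int
    fluorescence: float
    instrument: str = "plate_reader"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if not math.isfinite(self.fluorescence):
            raise ValueError("fluorescence must be finite")


def normalize_strength(f_sample: float, f_blank: float, f_ref: float) -> float:
    """Promoter strength in percent of the reference promoter.

    The blank maps to 0%, the reference to 100%; values outside [0, 100]
    are meaningful and returned unchanged.  A reference indistinguishable
    from the blank leaves the scale undefined and is an error.
    """
    if f_ref <= f_blank:
        raise ValueError(
            f"reference ({f_ref}) must exceed blank ({f_blank}): "
            "reference indistinguishable from blank")
    return 100.0 * (f_sample - f_blank) / (f_ref - f_blank)


@dataclass
class LibrarySummary:
    """Per-promoter normalized strengths plus rejected-batch messages."""

    table: pd.DataFrame
    rejected: list[str] = field(default_factory=list)


def _to_frame(records: "Iterable[FluorRecord] | pd.DataFrame") -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    required = {"promoter", "medium", "replicate", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    if "instrument" not in df.columns:
        df["instrument"] = "plate_reader"
    return df


def summarize_library(records: "Iterable[FluorRecord] | pd.DataFrame",
                      blank: str = BLANK_PROMOTER,
                      reference: str = REFERENCE_PROMOTER) -> LibrarySummary:
    """Normalize a promoter library batch-wise and average replicates.

    A batch is one (medium, instrument) combination; raw values are only
    comparable within a batch, so each batch needs its own blank and
    reference rows and batches missing either are rejected with a message.
    Replicates are normalized individually (against the batch-mean blank
    and reference) and then averaged.
    """
    df = _to_frame(records)
    rows = []
    rejected = []
    for (medium, instrument), batch in df.groupby(["medium", "instrument"],
                                                  sort=True):
        blanks = batch.loc[batch.promoter == blank, "fluorescence"]
        refs = batch.loc[batch.promoter == reference, "fluorescence"]
        if blanks.empty or refs.empty:
            what = "blank" if blanks.empty else "reference"
            rejected.append(
                f"batch ({medium}, {instrument}) rejected: no {what} rows")
            continue
        f_blank, f_ref = blanks.mean(), refs.mean()
        try:
            normalize_strength(f_ref, f_blank, f_ref)
        except ValueError as exc:
            rejected.append(f"batch ({medium}, {instrument}) rejected: {exc}")
            continue
        for promoter, group in batch.groupby("promoter", sort=True):
            group = group.sort_values("replicate")
            values = [normalize_strength(v, f_blank, f_ref)
                      for v in group.fluorescence]
            row = {
                "promoter": promoter,
                "medium": medium,
                "instrument": instrument,
                "n_replicates": len(values),
                "mean_percent": sum(values) / len(values),
                "below_blank": any(v < 0 for v in values),
            }
            for i, v in enumerate(values, 1):
                row[f"rep{i}"] = v
            rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        lead = ["promoter", "medium", "instrument", "n_replicates"]
        reps = sorted((c for c in table.columns if c.startswith("rep")),
                      key=lambda c: int(c[3:]))
        table = table[lead + reps + ["mean_percent", "below_blank"]]
        table = table.sort_values(["medium", "instrument", "promoter"],
                                  ignore_index=True)
    return LibrarySummary(table, rejected)
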