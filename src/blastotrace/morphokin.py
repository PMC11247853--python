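"""Morphokinetic interval variables derived from annotated event times.

All times are hours post-insemination (hpi).  Derived intervals follow the
standard cleavage-timing nomenclature: the second cell cycle ECC2 = t4 - t2,
the third cell cycle ECC3 = t8 - t4, division synchronicities s2 = t4 - t3
and s3 = t8 - t5, plus the blastulation intervals tB - tSB and tSB - t8.
Missing annotations propagate as missing; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = ["MorphokineticAnnotation", "derive_intervals", "derive_intervals_table"]

_ORDERED = ("t2", "t3", "t4", "t5", "t8")

INTERVALS = {
    "ECC2": ("t4", "t2"),
    "ECC3": ("t8", "t4"),
    "s2": ("t4", "t3"),
    "s3": ("t8", "t5"),
    "tB_minus_tSB": ("tB", "tSB"),
    "tSB_minus_t8": ("tSB", "t8"),
}


@dataclass
class MorphokineticAnnotation:
    """Annotated event times (hpi); any field may be missing (None)."""

    t0: float | None = None
    tPNa: float | None = None
    tPNf: float | None = None
    t2: float | None = None
    t3: float | None = None
    t4: float | None = None
    t5: float | None = None
    t6: float | None = None
    t7: float | None = None
    t8: float | None = None
    tSB: float | None = None
    tB: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{f.name} must be a non-negative finite time")
        present = [
            (name, getattr(self, name))
            for name in _ORDERED
            if getattr(self, name) is not None
        ]
        for (n1, v1), (n2, v2) in zip(present, present[1:]):
            if v1 > v2 + 1e-9:
                raise ValueError(f"ordering violation: {n1}={v1} > {n2}={v2}")
        if self.tSB is not None and self.tB is not None and self.tSB > self.tB + 1e-9:
            raise ValueError(f"ordering violation: tSB={self.tSB} > tB={self.tB}")


def derive_intervals(ann: MorphokineticAnnotation) -> dict[str, float | None]:
    """Interval set {ECC2, ECC3, s2, s3, tB_minus_tSB, tSB_minus_t8} in
    hours; an interval is missing (None) unless both operands are present."""
    out: dict[str, float | None] = {}
    for name, (hi, lo) in INTERVALS.items():
        a, b = getattr(ann, hi), getattr(ann, lo)
        out[name] = None if a is None or b is None else float(a - b)
    return out


def derive_intervals_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived interval columns to an annotation table (columns in
    hpi, NaN for missing).  Rows with ordering violations raise."""
    out = df.copy()
    for i in df.index:
        row = df.loc[i]
        ann = MorphokineticAnnotation(
            **{
                f.name: (None if pd.isna(row.get(f.name)) else float(row[f.name]))
                for f in fields(MorphokineticAnnotation)
                if f.name in df.columns
            }
        )
        for name, val in derive_intervals(ann).items():
            out.loc[i, name] = np.nan if val is None else val
    return out
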