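"""Ploidy classification from per-chromosome aberration fractions.

Implements the PGT-A threshold logic used on low-pass NGS copy-number
profiles: a segment is aneuploid when its aberrant-cell fraction exceeds
70%, euploid when it falls below a chromosome-specific lower limit (30% for
chromosomes 13, 16, 18 and 21; 50% for chromosome 19; 40% otherwise), and
mosaic in between.  Aneuploid embryos are subtyped into monosomy, trisomy,
fragment (segmental) deletion and fragment duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Segment",
    "CopyNumberProfile",
    "PloidyCall",
    "classify_segment",
    "classify_embryo_ploidy",
    "classify_profiles_table",
    "ANEUPLOID_THRESHOLD",
    "euploid_lower_limit",
]

logger = logging.getLogger(__name__)

ANEUPLOID_THRESHOLD = 0.70

_CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
_LOW_LIMIT_030 = {"13", "16", "18", "21"}

LABELS = ("euploid", "mosaic", "aneuploid", "no_result")
SUBTYPES = ("fragment_deletion", "fragment_duplication", "monosomy", "trisomy")


def _norm_chrom(chromosome: str) -> str:
    c = str(chromosome).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if c.upper() in ("X", "Y") else c
    if c not in _CHROMOSOMES:
        raise ValueError(f"unknown chromosome name: {chromosome!r}")
    return c


def euploid_lower_limit(chromosome: str) -> float:
    """Chromosome-specific euploid upper bound on the aberrant fraction.
    Sex chromosomes use the general 40% limit."""
    c = _norm_chrom(chromosome)
    if c in _LOW_LIMIT_030:
        return 0.30
    if c == "19":
        return 0.50
    return 0.40


def classify_segment(chromosome: str, aberrant_fraction: float) -> str:
    """euploid / mosaic / aneuploid call for one segment.

    Boundary convention: strictly greater than 70% is aneuploid, strictly
    below the lower limit is euploid; the closed band in between is mosaic.
    """
    if not 0.0 <= aberrant_fraction <= 1.0:
        raise ValueError(f"aberrant_fraction {aberrant_fraction} outside [0, 1]")
    low = euploid_lower_limit(chromosome)
    if aberrant_fraction > ANEUPLOID_THRESHOLD:
        return "aneuploid"
    if aberrant_fraction < low:
        return "euploid"
    return "mosaic"


@dataclass(frozen=True)
class Segment:
    chromosome: str
    span: str  # whole_chromosome | segmental
    direction: str  # gain | loss
    aberrant_fraction: float

    def __post_init__(self) -> None:
        _norm_chrom(self.chromosome)
        if self.span not in ("whole_chromosome", "segmental"):
            raise ValueError(f"unknown span {self.span!r}")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0.0 <= self.aberrant_fraction <= 1.0:
            raise ValueError("aberrant_fraction outside [0, 1]")


@dataclass
class CopyNumberProfile:
    """Per-embryo list of copy-number segments.  At most one
    whole-chromosome segment per chromosome and direction."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        seen = set()
        for s in self.segments:
            if s.span == "whole_chromosome":
                key = (_norm_chrom(s.chromosome), s.direction)
                if key in seen:
                    raise ValueError(
                        f"duplicate whole-chromosome {s.direction} on chr{key[0]}"
                    )
                seen.add(key)


@dataclass
class PloidyCall:
    label: str
    subtype: str | None = None
    complex_aneuploidy: bool = False

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.subtype is not None) != (self.label == "aneuploid"):
            raise ValueError("subtype present iff label is aneuploid")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


def classify_embryo_ploidy(profile: CopyNumberProfile | None) -> PloidyCall:
    """Embryo-level call from a copy-number profile.

    A missing profile (amplification failure) yields ``no_result``.  The
    embryo is aneuploid when any segment is aneuploid, else mosaic when any
    segment is mosaic, else euploid (an empty segment list is euploid by
    definition).  Aneuploid subtypes: monosomy for a whole-chromosome loss,
    trisomy for a whole-chromosome gain (whole-chromosome events take
    precedence over fragment classes); otherwise fragment deletion for
    segmental losses only, fragment duplication for segmental gains only
    (mixed segmental events fall to the loss class and are flagged complex).
    An embryo with both whole-chromosome loss and gain takes the subtype of
    the first-listed whole-chromosome event and is flagged complex.
    """
    if profile is None:
        return PloidyCall("no_result")
    if not profile.segments:
        logger.info("empty segment list: euploid by definition")
        return PloidyCall("euploid")
    calls = [
        (s, classify_segment(s.chromosome, s.aberrant_fraction))
        for s in profile.segments
    ]
    aneu = [s for s, c in calls if c == "aneuploid"]
    if not aneu:
        if any(c == "mosaic" for _, c in calls):
            return PloidyCall("mosaic")
        return PloidyCall("euploid")
    whole = [s for s in aneu if s.span == "whole_chromosome"]
    if whole:
        directions = {s.direction for s in whole}
        subtype = "monosomy" if whole[0].direction == "loss" else "trisomy"
        return PloidyCall("aneuploid", subtype, complex_aneuploidy=len(directions) > 1)
    directions = {s.direction for s in aneu}
    if directions == {"loss"}:
        return PloidyCall("aneuploid", "fragment_deletion")
    if directions == {"gain"}:
        return PloidyCall("aneuploid", "fragment_duplication")
    return PloidyCall("aneuploid", "fragment_deletion", complex_aneuploidy=True)


def classify_profiles_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Classify a long-format profiles table (embryo_id, chromosome, span,
    direction, aberrant_fraction) into one call row per embryo."""
    rows = []
    for eid, grp in profiles.groupby("embryo_id", sort=True):
        segs = [
            Segment(
                str(r.chromosome), str(r.span), str(r.direction),
                float(r.aberrant_fraction),
            )
            for r in grp.itertuples()
        ]
        call = classify_embryo_ploidy(CopyNumberProfile(segs))
        rows.append((eid, call.label, call.subtype, call.complex_aneuploidy))
    return pd.DataFrame(
        rows, columns=["embryo_id", "label", "subtype", "complex_aneuploidy"]
    )
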