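"""Collapse-event detection and quantification on cavity-area traces.

A blastocyst collapse is an uninterrupted reduction of the blastocoel-cavity
area followed by (possible) re-expansion.  On the 10-min frame grid an event
is a maximal non-increasing run of cavity area containing at least one strict
decrease, whose total relative drop from the pre-fall reference reaches
``min_drop``.  A rise of any size ends the run (two falls separated by a rise
are two events); a flat plateau does not.

Quantities per event:

* ``shrinkage`` — fraction of the reference area lost at the minimum.
  Before full blastocyst formation (tB) the reference is the cavity area on
  the last frame before the fall; after tB it is the area inside the zona
  pellucida at the time of the minimum.  The raw remaining-area ratio is kept
  alongside as ``area_ratio`` (= 1 - shrinkage).
* ``recovery_duration_h`` — time from the minimum-area frame to the first
  frame whose cavity area returns to ``recovery_frac`` of the pre-collapse
  cavity area; censored (None) when the trace ends first.
* ``phase`` — ``before_tB`` / ``after_tB``, assigned from the event start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .segment import AreaTrace

__all__ = [
    "CollapseEvent",
    "CollapseSummary",
    "detect_collapses",
    "shrinkage",
    "recovery_duration",
    "summarize_embryo",
    "DEFAULT_MIN_DROP",
    "DEFAULT_RECOVERY_FRAC",
]

#: default trigger: total relative drop required to call a collapse.
#: Chosen to mirror the published criterion of an embryo:ZP area ratio <= 90%.
DEFAULT_MIN_DROP = 0.10
#: default recovery criterion: return to 90% of the pre-collapse cavity area.
DEFAULT_RECOVERY_FRAC = 0.90

PHASE_BEFORE = "before_tB"
PHASE_AFTER = "after_tB"


@dataclass
class CollapseEvent:
    """One detected collapse.

    ``start_hpi`` is the last frame at the reference area before the fall,
    ``tmin_hpi`` the first frame attaining the minimum area.  Times in hours
    post-insemination.
    """

    start_hpi: float
    tmin_hpi: float
    recovery_hpi: float | None
    shrinkage: float
    area_ratio: float
    recovery_duration_h: float | None
    phase: str
    start_idx: int = 0
    tmin_idx: int = 0
    censored: bool = False
    flagged: bool = False  # missing frames inside the event window
    invalid: bool = False  # undefined reference area

    def __post_init__(self) -> None:
        if not self.start_hpi < self.tmin_hpi:
            raise ValueError("event start must precede its minimum")
        if self.recovery_hpi is not None and not self.recovery_hpi > self.tmin_hpi:
            raise ValueError("recovery must follow the minimum")
        if not self.invalid and not (0.0 <= self.shrinkage < 1.0):
            raise ValueError(f"shrinkage {self.shrinkage} outside [0, 1)")
        if self.phase not in (PHASE_BEFORE, PHASE_AFTER):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class CollapseSummary:
    """Per-embryo collapse behaviour."""

    n_before_tB: int
    n_after_tB: int
    category: str  # none | before_only | after_only | both
    multi_after_tB: bool
    first_event_before: CollapseEvent | None = None
    first_event_after: CollapseEvent | None = None

    def __post_init__(self) -> None:
        expected = _category(self.n_before_tB, self.n_after_tB)
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with counts "
                f"({self.n_before_tB}, {self.n_after_tB})"
            )
        if self.multi_after_tB != (self.n_after_tB >= 2):
            raise ValueError("multi_after_tB inconsistent with n_after_tB")


def _category(n_before: int, n_after: int) -> str:
    if n_before == 0 and n_after == 0:
        return "none"
    if n_after == 0:
        return "before_only"
    if n_before == 0:
        return "after_only"
    return "both"


def _phase_of(start_hpi: float, tB: float | None) -> str:
    if tB is None:
        return PHASE_BEFORE
    return PHASE_AFTER if start_hpi >= tB else PHASE_BEFORE


def detect_collapses(
    trace: AreaTrace,
    tB: float | None = None,
    min_drop: float = DEFAULT_MIN_DROP,
    recovery_frac: float = DEFAULT_RECOVERY_FRAC,
    tSB: float | None = None,
) -> list[CollapseEvent]:
    """Detect collapse events on an analyzable cavity-area trace.

    The search window starts at tSB (annotation, argument, or the trace
    start): pre-blastulation area fluctuations are never events.  Events are
    returned in time order and never overlap.  Events spanning missing frames
    are retained but flagged.  Traces shorter than 3 frames are rejected.
    """
    if trace.n_frames < 3:
        raise ValueError("trace too short for event detection (< 3 frames)")
    if not 0.0 <= min_drop < 1.0:
        raise ValueError("min_drop must be in [0, 1)")
    if tB is None:
        tB = trace.tB_hpi
    if tSB is None:
        tSB = trace.tSB_hpi

    t = trace.time_hpi
    a = trace.cavity_area.copy()
    a[trace.quality_flag != "ok"] = np.nan
    window = np.ones(trace.n_frames, dtype=bool)
    if tSB is not None:
        window &= t >= tSB - 1e-9
    finite = np.isfinite(a) & window
    idx = np.where(finite)[0]
    if idx.size < 2:
        return []
    av, orig = a[idx], idx  # compressed finite series with original indices

    events: list[CollapseEvent] = []
    i = 0
    n = av.size
    while i < n - 1:
        if av[i + 1] < av[i]:
            s = i
            e = i + 1
            while e + 1 < n and av[e + 1] <= av[e]:
                e += 1
            amin = float(av[s + 1 : e + 1].min())
            tmin_rel = s + 1 + int(np.argmin(av[s + 1 : e + 1]))
            ref = float(av[s])
            gap = bool(np.any(np.diff(orig[s : e + 1]) > 1))
            drop = 1.0 - amin / ref if ref > 0 else np.nan
            if np.isfinite(drop) and drop >= min_drop - 1e-12:
                si, mi = int(orig[s]), int(orig[tmin_rel])
                ev = CollapseEvent(
                    start_hpi=float(t[si]),
                    tmin_hpi=float(t[mi]),
                    recovery_hpi=None,
                    shrinkage=0.0,
                    area_ratio=1.0,
                    recovery_duration_h=None,
                    phase=_phase_of(float(t[si]), tB),
                    start_idx=si,
                    tmin_idx=mi,
                    flagged=gap,
                )
                ev = shrinkage(ev, trace, tB, as_event=True)
                ev = recovery_duration(ev, trace, recovery_frac, as_event=True)
                events.append(ev)
            i = e
        else:
            i += 1
    return events


def shrinkage(
    event: CollapseEvent,
    trace: AreaTrace,
    tB: float | None = None,
    as_event: bool = False,
):
    """Shrinkage fraction of a collapse event.

    Computes r = A_min / A_ref with A_ref the cavity area at the event start
    (phase ``before_tB``) or the ZP-interior area at the time of the minimum
    (phase ``after_tB``), and reports shrinkage = 1 - r.  The raw ratio r is
    kept on the event as ``area_ratio``.  A zero/undefined reference marks the
    event invalid rather than producing a number.
    """
    amin = float(trace.cavity_area[event.tmin_idx])
    if event.phase == PHASE_BEFORE:
        ref = float(trace.cavity_area[event.start_idx])
    else:
        ref = float(trace.zp_interior_area[event.tmin_idx])
    if not np.isfinite(ref) or ref <= 0:
        ev = replace(event, invalid=True)
        return ev if as_event else np.nan
    r = min(max(amin / ref, 0.0), 1.0)
    ev = replace(event, shrinkage=1.0 - r, area_ratio=r)
    return ev if as_event else 1.0 - r


def recovery_duration(
    event: CollapseEvent,
    trace: AreaTrace,
    recovery_frac: float = DEFAULT_RECOVERY_FRAC,
    as_event: bool = False,
):
    """Hours from the minimum-area frame to the first frame whose cavity area
    reaches ``recovery_frac`` of the pre-collapse cavity area.

    Granularity is the frame interval.  When the trace ends before recovery
    the duration is missing and the event is marked censored.
    """
    ref = float(trace.cavity_area[event.start_idx])
    threshold = recovery_frac * ref
    a = trace.cavity_area
    after = np.arange(event.tmin_idx + 1, trace.n_frames)
    rec_idx = None
    for j in after:
        if np.isfinite(a[j]) and a[j] >= threshold - 1e-9:
            rec_idx = int(j)
            break
    if rec_idx is None:
        ev = replace(event, recovery_hpi=None, recovery_duration_h=None, censored=True)
        return ev if as_event else None
    rec_t = float(trace.time_hpi[rec_idx])
    dur = rec_t - event.tmin_hpi
    ev = replace(
        event, recovery_hpi=rec_t, recovery_duration_h=dur, censored=False
    )
    return ev if as_event else dur


def summarize_embryo(
    events: list[CollapseEvent], tB: float | None = None
) -> CollapseSummary:
    """Collapse behaviour of one embryo: phase counts, four-way category
    (none / before_only / after_only / both) and the multiple-collapse flag
    (>= 2 collapses after tB).  First events per phase are retained for
    first-collapse characterisation."""
    before = [e for e in events if e.phase == PHASE_BEFORE]
    after = [e for e in events if e.phase == PHASE_AFTER]
    return CollapseSummary(
        n_before_tB=len(before),
        n_after_tB=len(after),
        category=_category(len(before), len(after)),
        multi_after_tB=len(after) >= 2,
        first_event_before=min(before, key=lambda e: e.start_hpi, default=None),
        first_event_after=min(after, key=lambda e: e.start_hpi, default=None),
    )
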