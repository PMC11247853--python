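"""Collapse detection: frozen toy traces, brute-force oracle equivalence,
shrinkage/recovery arithmetic and per-embryo summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastotrace.events import (
    CollapseEvent,
    detect_collapses,
    recovery_duration,
    shrinkage,
    summarize_embryo,
)


def brute_force_events(areas, min_drop):
    """Independent oracle: maximal non-increasing runs found via the sign
    pattern of first differences, filtered by total relative drop."""
    a = np.asarray(areas, dtype=float)
    d = np.diff(a)
    out = []
    k = 0
    for nonpos, grp in itertools.groupby(range(d.size), key=lambda i: d[i] <= 0):
        idxs = list(grp)
        if nonpos:
            strict = [i for i in idxs if d[i] < 0]
            if strict:
                s = strict[0]  # last frame at the reference level
                end = idxs[-1] + 1
                seg = a[s + 1 : end + 1]
                tmin = s + 1 + int(np.argmin(seg))
                drop = 1 - seg.min() / a[s] if a[s] > 0 else np.nan
                if np.isfinite(drop) and drop >= min_drop - 1e-12:
                    out.append((s, tmin))
        k += len(idxs)
    return out


class TestDetect:
    def test_monotone_trace_has_no_events(self, toy_trace):
        tr = toy_trace(np.linspace(100, 200, 12))
        assert detect_collapses(tr, tB=0.0) == []

    def test_single_uninterrupted_fall(self, toy_trace):
        # plateau start, fall through 80 to a 60-plateau, then re-expansion:
        # one event from the last 100-frame to the first 60-frame
        tr = toy_trace([100, 100, 80, 60, 60, 75, 95, 100])
        evs = detect_collapses(tr, tB=0.0, min_drop=0.10)
        assert len(evs) == 1
        (e,) = evs
        assert (e.start_idx, e.tmin_idx) == (1, 3)
        assert e.phase == "after_tB"

    def test_rise_splits_two_falls(self, toy_trace):
        # a rise between two dips interrupts: two events, not one
        tr = toy_trace([100, 90, 95, 85, 95])
        evs = detect_collapses(tr, tB=0.0, min_drop=0.10)
        assert [(e.start_idx, e.tmin_idx) for e in evs] == [(0, 1), (2, 3)]

    def test_min_drop_filters_shallow_dips(self, toy_trace):
        tr = toy_trace([100, 95, 100, 60, 100])
        evs = detect_collapses(tr, tB=0.0, min_drop=0.10)
        assert [(e.start_idx, e.tmin_idx) for e in evs] == [(2, 3)]

    def test_short_trace_rejected(self, toy_trace):
        with pytest.raises(ValueError, match="3 frames"):
            detect_collapses(toy_trace([100, 90]))

    def test_search_window_starts_at_tSB(self, toy_trace):
        # the dip before blastulation onset is never an event
        tr = toy_trace([100, 50, 100, 100, 60, 100], tSB_hpi=2 * 10 / 60.0)
        evs = detect_collapses(tr, tB=100.0)
        assert [(e.start_idx, e.tmin_idx) for e in evs] == [(3, 4)]

    def test_gap_inside_event_is_flagged(self, toy_trace):
        areas = np.array([100.0, 90, np.nan, 60, 100, 100])
        tr = toy_trace(areas)
        evs = detect_collapses(tr, tB=0.0)
        assert len(evs) == 1 and evs[0].flagged

    def test_events_ordered_and_disjoint(self, toy_trace):
        tr = toy_trace([100, 80, 100, 70, 100, 60, 100])
        evs = detect_collapses(tr, tB=0.0)
        assert len(evs) == 3
        for e1, e2 in zip(evs, evs[1:]):
            assert e1.tmin_hpi <= e2.start_hpi

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        areas=st.lists(
            st.sampled_from([60.0, 80.0, 90.0, 100.0]), min_size=3, max_size=12
        ),
        min_drop=st.sampled_from([0.0, 0.05, 0.10, 0.25]),
    )
    def test_matches_brute_force_oracle(self, areas, min_drop):
        tr = trace = None
        from conftest import trace_from_areas

        trace = trace_from_areas(areas)
        evs = detect_collapses(trace, tB=0.0, min_drop=min_drop)
        assert [(e.start_idx, e.tmin_idx) for e in evs] == brute_force_events(
            areas, min_drop
        )

    def test_exhaustive_small_traces_match_oracle(self):
        from conftest import trace_from_areas

        for areas in itertools.product([60.0, 80.0, 100.0], repeat=6):
            trace = trace_from_areas(areas)
            evs = detect_collapses(trace, tB=0.0, min_drop=0.10)
            assert [
                (e.start_idx, e.tmin_idx) for e in evs
            ] == brute_force_events(areas, 0.10), areas


class TestShrinkage:
    def test_before_tb_uses_start_cavity_reference(self, toy_trace):
        tr = toy_trace([100, 70, 100, 100])
        (e,) = detect_collapses(tr, tB=1e9)
        assert e.phase == "before_tB"
        assert e.shrinkage == pytest.approx(0.30)
        assert e.area_ratio == pytest.approx(0.70)

    def test_after_tb_uses_zp_interior_reference(self, toy_trace):
        zp = np.full(4, 120.0)
        tr = toy_trace([110, 90, 110, 110], zp=zp)
        (e,) = detect_collapses(tr, tB=0.0)
        assert e.phase == "after_tB"
        assert e.shrinkage == pytest.approx(1 - 90 / 120)

    def test_zero_reference_marks_event_invalid(self, toy_trace):
        tr = toy_trace([110, 90, 110], zp=np.full(3, 120.0))
        (e,) = detect_collapses(tr, tB=0.0)
        tr.zp_interior_area[e.tmin_idx] = 0.0
        e2 = shrinkage(e, tr, tB=0.0, as_event=True)
        assert e2.invalid

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=1000.0))
    def test_invariant_under_uniform_area_rescaling(self, scale):
        from conftest import trace_from_areas

        base = np.array([100.0, 100, 55, 70, 100, 100])
        t1 = trace_from_areas(base)
        t2 = trace_from_areas(base * scale, zp=t1.zp_interior_area * scale)
        for tB in (0.0, 1e9):
            e1 = detect_collapses(t1, tB=tB)
            e2 = detect_collapses(t2, tB=tB)
            assert len(e1) == len(e2) == 1
            assert e1[0].shrinkage == pytest.approx(e2[0].shrinkage)


class TestRecovery:
    def test_recovery_counts_frames_to_threshold(self, toy_trace):
        # recovery to 95% of reference three frames after the minimum
        tr = toy_trace([100, 60, 70, 80, 95, 100])
        (e,) = detect_collapses(tr, tB=0.0, recovery_frac=0.90)
        assert e.recovery_duration_h == pytest.approx(0.5)
        assert e.recovery_hpi == pytest.approx(e.tmin_hpi + 0.5)

    def test_unrecovered_event_is_censored(self, toy_trace):
        tr = toy_trace([100, 60, 62, 64, 66])
        (e,) = detect_collapses(tr, tB=0.0)
        assert e.censored and e.recovery_duration_h is None

    def test_recovery_frac_changes_the_criterion(self, toy_trace):
        tr = toy_trace([100, 60, 85, 95, 100])
        (e_loose,) = detect_collapses(tr, tB=0.0, recovery_frac=0.80)
        (e_tight,) = detect_collapses(tr, tB=0.0, recovery_frac=0.99)
        assert e_loose.recovery_duration_h < e_tight.recovery_duration_h


class TestSummary:
    def _ev(self, start, tB_ref):
        phase = "after_tB" if start >= tB_ref else "before_tB"
        return CollapseEvent(start, start + 0.17, None, 0.2, 0.8, None, phase)

    def test_no_events_is_category_none(self):
        s = summarize_embryo([], tB=110.0)
        assert (s.category, s.multi_after_tB) == ("none", False)

    def test_straddling_counts_by_phase(self):
        evs = [self._ev(100.0, 110.0), self._ev(125.0, 110.0)]
        s = summarize_embryo(evs, tB=110.0)
        assert (s.category, s.n_before_tB, s.n_after_tB, s.multi_after_tB) == (
            "both", 1, 1, False,
        )
        assert s.first_event_before.start_hpi == 100.0
        assert s.first_event_after.start_hpi == 125.0

    def test_three_after_tb_is_multi(self):
        evs = [self._ev(t, 110.0) for t in (112.0, 120.0, 130.0)]
        s = summarize_embryo(evs, tB=110.0)
        assert (s.category, s.multi_after_tB) == ("after_only", True)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        starts=st.lists(st.floats(min_value=90, max_value=140), max_size=6),
    )
    def test_phase_counts_partition_all_events(self, starts):
        evs = [self._ev(s, 110.0) for s in starts]
        s = summarize_embryo(evs, tB=110.0)
        assert s.n_before_tB + s.n_after_tB == len(evs)
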