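"""Generator contracts: trace construction, ground-truth consistency,
rendering geometry, cohort simulation and reproducibility."""

import numpy as np
import pytest
from scipy import stats as sps

from blastotrace import (
    CohortParams,
    CollapseSpec,
    SceneSpec,
    make_area_trace,
    render_frames,
    simulate_cohort,
)
from blastotrace.events import detect_collapses
from blastotrace.synthgen import (
    PAPER_CATEGORY_PREVALENCE,
    FirstCollapseLaws,
    sample_scene,
    simulate_profiles,
)


class TestSceneSpec:
    def test_time_ordering_enforced(self):
        with pytest.raises(ValueError, match="tSB"):
            SceneSpec(tSB_hpi=110, tB_hpi=100, end_hpi=150)

    def test_overlapping_collapse_windows_rejected_with_pair(self):
        with pytest.raises(ValueError, match="collapse 0 .* collapse 1"):
            SceneSpec(
                collapses=[CollapseSpec(120, 0.3, 2.0), CollapseSpec(120.5, 0.3, 2.0)]
            )

    def test_bad_collapse_parameters_rejected(self):
        with pytest.raises(ValueError):
            CollapseSpec(120, 1.2, 1.0)
        with pytest.raises(ValueError):
            CollapseSpec(-5, 0.3, 1.0)


class TestMakeAreaTrace:
    def test_no_collapse_trace_is_monotone_with_empty_truth(self):
        trace, truth = make_area_trace(SceneSpec())
        assert truth == []
        assert np.all(np.diff(trace.cavity_area) >= -1e-9)

    def test_dip_ratio_forced_by_construction(self):
        scene = SceneSpec(
            tSB_hpi=100, tB_hpi=115, end_hpi=150,
            collapses=[CollapseSpec(112.0, 0.30, 1.0)],
        )
        trace, truth = make_area_trace(scene)
        (ev,) = truth
        assert ev.phase == "before_tB"
        i = ev.tmin_idx
        ref = trace.cavity_area[ev.start_idx]
        assert trace.cavity_area[i] / ref == pytest.approx(0.70, abs=1e-9)

    def test_truth_shrinkage_reproduced_by_detector(self):
        scene = SceneSpec(
            collapses=[CollapseSpec(113.0, 0.22, 0.5), CollapseSpec(125.0, 0.4, 2.0)]
        )
        trace, truth = make_area_trace(scene)
        evs = detect_collapses(trace, min_drop=0.01)
        assert len(evs) == len(truth) == 2
        for det, gt in zip(evs, truth):
            assert det.shrinkage == pytest.approx(gt.shrinkage, abs=1e-9)
            assert det.start_hpi == gt.start_hpi
            # recovery quantised up to one frame-grid step
            assert (
                gt.recovery_duration_h
                <= det.recovery_duration_h
                <= gt.recovery_duration_h + trace.frame_interval_min / 60 + 1e-9
            )

    def test_first_collapse_start_calibration(self):
        # programmed post-tB starts follow the 121.3 +/- 11.1 hpi law
        starts = []
        for k in range(1000):
            rng = np.random.default_rng(k)
            scene = sample_scene(rng, n_after=1, tSB_hpi=98.0, tB_hpi=110.0)
            starts.append(scene.collapses[0].start_hpi)
        assert abs(np.mean(starts) - 121.3) < 1.0

    def test_cavity_never_exceeds_zp_interior(self):
        scene = SceneSpec(collapses=[CollapseSpec(120.0, 0.1, 0.2)])
        trace, _ = make_area_trace(scene)
        assert np.all(trace.cavity_area <= trace.zp_interior_area + 1e-9)


class TestRenderFrames:
    def test_cavity_mask_pixel_count_matches_disc_area(self):
        r = 50.0
        scene = SceneSpec(tSB_hpi=100, tB_hpi=110, end_hpi=111)
        trace, _ = make_area_trace(scene)
        trace.cavity_area[:] = np.pi * r**2
        stack, masks = render_frames(trace, scene, seed=0)
        count = (masks[0] == 3).sum()
        assert abs(count - np.pi * r**2) / (np.pi * r**2) < 0.02

    def test_no_shrinkage_masks_nondecreasing(self):
        scene = SceneSpec(tSB_hpi=100, tB_hpi=106, end_hpi=112)
        trace, _ = make_area_trace(scene)
        _, masks = render_frames(trace, scene, seed=0)
        counts = (masks == 3).sum(axis=(1, 2))
        assert np.all(np.diff(counts) >= 0)

    def test_deterministic_given_seed(self):
        scene = SceneSpec(tSB_hpi=100, tB_hpi=106, end_hpi=108, noise_sd=5.0)
        trace, _ = make_area_trace(scene)
        s1, m1 = render_frames(trace, scene, seed=9)
        s2, m2 = render_frames(trace, scene, seed=9)
        assert np.array_equal(s1, s2) and np.array_equal(m1, m2)

    def test_cavity_exceeding_zp_rejected(self):
        scene = SceneSpec(tSB_hpi=100, tB_hpi=106, end_hpi=108)
        trace, _ = make_area_trace(scene)
        trace.cavity_area[0] = trace.zp_interior_area[0] * 1.2
        with pytest.raises(ValueError, match="exceeds ZP inner radius"):
            render_frames(trace, scene, seed=0)


class TestSimulateCohort:
    def test_reproducible_given_seed(self):
        p = CohortParams(n_cycles=50, seed=4)
        a, b = simulate_cohort(p), simulate_cohort(p)
        assert a.equals(b)

    def test_category_prevalence_recovered_at_n3000(self):
        p = CohortParams(n_cycles=1300, embryos_per_cycle_mean=2.4, seed=0)
        df = simulate_cohort(p)
        props = df["category"].value_counts(normalize=True)
        for cat, target in zip(
            ("none", "before_only", "after_only", "both"), PAPER_CATEGORY_PREVALENCE
        ):
            assert abs(props.get(cat, 0.0) - target) < 0.015

    def test_null_effect_gives_flat_aneuploidy(self):
        p = CohortParams(
            n_cycles=1700, embryos_per_cycle_mean=3.0, seed=1,
            beta_multicollapse=0.0, beta_collapse1=0.0, cycle_sd=0.0,
            p_no_result=0, p_mosaic=0, p_imaging_abnormal=0, p_off_frame=0,
        )
        df = simulate_cohort(p)
        groups = np.minimum(df["n_after_tB"], 2)
        tab = (
            df.assign(g=groups)
            .groupby("g")["aneuploid"]
            .agg([lambda s: s.sum(), "size"])
            .to_numpy()
        )
        tab = np.column_stack([tab[:, 0], tab[:, 1] - tab[:, 0]]).astype(float)
        _, pval, _, _ = sps.chi2_contingency(tab)
        assert pval > 0.01

    def test_saturating_effect_drives_rate_to_one(self):
        p = CohortParams(
            n_cycles=700, embryos_per_cycle_mean=3.0, seed=2,
            beta_multicollapse=10.0, cycle_sd=0.0,
            p_no_result=0, p_mosaic=0, p_imaging_abnormal=0, p_off_frame=0,
        )
        df = simulate_cohort(p)
        multi = df[df["n_after_tB"] >= 2]
        assert len(multi) > 50
        assert multi["aneuploid"].mean() > 0.99

    def test_random_effect_requires_multiple_cycles(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            CohortParams(n_cycles=1, cycle_sd=0.5)

    def test_outcomes_only_on_euploid_transfers(self):
        df = simulate_cohort(CohortParams(n_cycles=200, seed=6))
        tr = df[df["transferred"]]
        assert len(tr) > 50
        # transfers are analysable euploid embryos only
        assert (~tr[["no_result", "mosaic", "imaging_abnormal", "off_frame"]]).all().all()
        assert (~tr["aneuploid"].astype(bool)).all()
        assert df.loc[~df["transferred"], "pregnant"].isna().all()
        assert (tr["live_birth"] <= tr["pregnant"]).all()
        from blastotrace.stats import compare_outcome_rates

        out = compare_outcome_rates(tr, "pregnant", "category")
        assert out.loc[out["group"] == "none", "n"].iloc[0] > 0

    def test_morphokinetic_ordering_holds(self):
        df = simulate_cohort(CohortParams(n_cycles=80, seed=3))
        for a, b in [("t2", "t3"), ("t3", "t4"), ("t4", "t5"), ("t5", "t8"),
                     ("t8", "tSB"), ("tSB", "tB")]:
            assert (df[a] <= df[b] + 1e-9).all()


class TestProfiles:
    def test_profiles_consistent_with_labels(self):
        from blastotrace.ploidy import classify_profiles_table

        cohort = simulate_cohort(CohortParams(n_cycles=60, seed=5))
        profiles = simulate_profiles(cohort, seed=5)
        calls = classify_profiles_table(profiles).set_index("embryo_id")
        merged = cohort.set_index("embryo_id").join(calls)
        measured = merged[~merged["no_result"]]
        aneu = measured["aneuploid"].astype("boolean")
        assert ((measured["label"] == "mosaic") == measured["mosaic"]).all()
        ok = ~measured["mosaic"]
        assert ((measured.loc[ok, "label"] == "aneuploid") == aneu[ok]).all()


class TestFirstCollapseLaws:
    def test_symmetric_truncation_keeps_printed_mean(self):
        rng = np.random.default_rng(0)
        laws = FirstCollapseLaws()
        draws = laws.draw_shrinkage(rng, "after_tB", size=200_000)
        assert abs(draws.mean() - 0.250) < 0.002
        assert draws.min() > 0.0 and draws.max() < 1.0

    def test_recovery_law_is_right_skewed_with_unit_mean(self):
        rng = np.random.default_rng(0)
        laws = FirstCollapseLaws()
        d = laws.draw_recovery(rng, "after_tB", size=200_000)
        assert abs(d.mean() - 1.0) < 0.02
        assert np.median(d) < d.mean()  # right skew
        assert (d > 0).all()
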