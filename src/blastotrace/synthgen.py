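"""Synthetic embryo generator: area traces, rendered frame stacks, cohorts.

Three fidelity levels, each with exact ground truth:

1. **Area traces** (`make_area_trace`): cavity and ZP-interior areas on the
   10-min frame grid.  The cavity baseline follows logistic growth between
   blastulation onset (tSB) and full blastocyst formation (tB) and equals the
   ZP-interior area after tB (fully expanded blastocyst); the ZP thins
   linearly after tB.  Collapses are piecewise-linear dips with configurable
   start, shrinkage and recovery duration.
2. **Rendered frames** (`render_frames`): schematic grayscale frames — a
   bright ZP annulus, a trophectoderm ring and a darker cavity disc whose
   pixel area matches the trace — with per-frame ground-truth masks.
3. **Cohorts** (`simulate_cohort`): per-embryo collapse categories, counts,
   covariates, cycle membership and a ploidy label drawn from a logistic
   model with a cycle-level Gaussian random intercept.

All randomness flows from one master seed; embryo k uses an independent
substream so it is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import CollapseEvent, PHASE_AFTER, PHASE_BEFORE
from .segment import AreaTrace

__all__ = [
    "CollapseSpec",
    "SceneSpec",
    "CohortParams",
    "make_area_trace",
    "render_frames",
    "simulate_cohort",
    "simulate_profiles",
    "sample_scene",
    "simulate_trace_cohort",
    "truncated_normal",
    "PAPER_CATEGORY_PREVALENCE",
]

#: published four-way prevalence of collapse categories
#: (none, before_only, after_only, both)
PAPER_CATEGORY_PREVALENCE = (0.719, 0.056, 0.194, 0.031)

#: ground-truth recovery convention: a collapse "recovers" when the cavity
#: regains this fraction of its pre-collapse area (same as the detector).
RECOVERY_FRAC_TRUTH = 0.90


@dataclass
class CollapseSpec:
    """One programmed collapse: start time (hpi), fraction of the reference
    area lost at the minimum, and hours from the minimum back to the
    recovered baseline."""

    start_hpi: float
    shrinkage_frac: float
    recovery_duration_h: float

    def __post_init__(self) -> None:
        if self.start_hpi <= 0:
            raise ValueError("start_hpi must be > 0")
        if not 0.0 < self.shrinkage_frac < 1.0:
            raise ValueError("shrinkage_frac must lie in (0, 1)")
        if self.recovery_duration_h < 0:
            raise ValueError("recovery_duration_h must be >= 0")


@dataclass
class SceneSpec:
    """Geometry and timeline of one synthetic embryo.

    Times in hours post-insemination, radii in pixels, areas in px².
    ``expansion_steepness`` spans the logistic cavity growth over
    (tSB, tB); ``zp_thinning_px_per_h`` is the post-tB inner-radius growth.
    """

    tSB_hpi: float = 98.0
    tB_hpi: float = 110.0
    end_hpi: float = 150.0
    start_hpi: float | None = None  # default: tSB - 2 h
    frame_interval_min: float = 10.0
    zp_inner_radius_px: float = 75.0
    zp_outer_radius_px: float = 85.0
    zp_thinning_px_per_h: float = 0.4
    expansion_steepness: float = 10.0
    cavity_floor_frac: float = 0.02
    frame_px: int = 200
    noise_sd: float = 0.0  # additive grayscale noise in rendered frames
    debris: bool = False  # render confounding debris blobs
    collapses: list[CollapseSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_hpi is None:
            self.start_hpi = self.tSB_hpi - 2.0
        if not (self.start_hpi < self.tSB_hpi < self.tB_hpi < self.end_hpi):
            raise ValueError("require start < tSB < tB < end (hpi)")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if not 0 < self.zp_inner_radius_px < self.zp_outer_radius_px:
            raise ValueError("require 0 < zp inner radius < outer radius")
        if self.zp_outer_radius_px * 2 + 10 > self.frame_px:
            raise ValueError("frame_px too small for the ZP outer radius")
        self._check_overlaps()

    @property
    def dt_h(self) -> float:
        return self.frame_interval_min / 60.0

    def collapse_window(self, c: CollapseSpec) -> tuple[float, float]:
        """[start, end] of the trace segment perturbed by collapse ``c``."""
        return (c.start_hpi, c.start_hpi + self.dt_h + c.recovery_duration_h + 2 * self.dt_h)

    def _check_overlaps(self) -> None:
        wins = sorted(
            ((self.collapse_window(c), i) for i, c in enumerate(self.collapses)),
            key=lambda w: w[0][0],
        )
        for (w1, i1), (w2, i2) in zip(wins, wins[1:]):
            if w2[0] < w1[1]:
                raise ValueError(
                    f"collapse windows overlap: collapse {i1} "
                    f"[{w1[0]:.2f}, {w1[1]:.2f}] hpi and collapse {i2} "
                    f"[{w2[0]:.2f}, {w2[1]:.2f}] hpi"
                )


# ---------------------------------------------------------------- baselines


def zp_interior_area(scene: SceneSpec, t: np.ndarray) -> np.ndarray:
    """Area inside the ZP; the inner radius grows linearly after tB as the
    zona thins (outer radius fixed, thickness floored at 1 px)."""
    t = np.asarray(t, dtype=float)
    r_in = scene.zp_inner_radius_px + scene.zp_thinning_px_per_h * np.maximum(
        t - scene.tB_hpi, 0.0
    )
    r_in = np.minimum(r_in, scene.zp_outer_radius_px - 1.0)
    return np.pi * r_in**2


def zp_thickness(scene: SceneSpec, t: np.ndarray) -> np.ndarray:
    r_in = np.sqrt(zp_interior_area(scene, t) / np.pi)
    return scene.zp_outer_radius_px - r_in


def cavity_baseline(scene: SceneSpec, t: np.ndarray) -> np.ndarray:
    """Collapse-free cavity area: 0 before tSB, normalised logistic growth
    over (tSB, tB), equal to the ZP-interior area from tB on."""
    t = np.asarray(t, dtype=float)
    zpa = zp_interior_area(scene, t)
    k = scene.expansion_steepness / (scene.tB_hpi - scene.tSB_hpi)
    mid = 0.5 * (scene.tSB_hpi + scene.tB_hpi)

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-k * (x - mid)))

    g0, g1 = logistic(np.array(scene.tSB_hpi)), logistic(np.array(scene.tB_hpi))
    g = (logistic(t) - g0) / (g1 - g0)
    eps = scene.cavity_floor_frac
    frac = np.clip(eps + (1 - eps) * g, 0.0, 1.0)
    out = zpa * frac
    out[t < scene.tSB_hpi] = 0.0
    out[t >= scene.tB_hpi] = zpa[t >= scene.tB_hpi]
    return out


# ------------------------------------------------------------------- traces


def make_area_trace(scene: SceneSpec) -> tuple[AreaTrace, list[CollapseEvent]]:
    """Sample the scene on its frame grid and return the trace plus the
    ground-truth event list.

    Collapse starts are snapped to the frame grid; the fall to the minimum
    takes one frame interval and the recovery ramp reaches the recovery
    criterion (90% of the pre-collapse cavity area) exactly
    ``recovery_duration_h`` after the minimum, then rejoins the baseline.
    The programmed shrinkage uses the phase-appropriate reference: cavity
    area at the start before tB, ZP-interior area at the minimum after tB.
    """
    dt = scene.dt_h
    n = int(np.floor((scene.end_hpi - scene.start_hpi) / dt + 1e-9)) + 1
    t = scene.start_hpi + dt * np.arange(n)
    base = cavity_baseline(scene, t)
    zpa = zp_interior_area(scene, t)
    area = base.copy()
    truth: list[CollapseEvent] = []

    for c in sorted(scene.collapses, key=lambda c: c.start_hpi):
        si = int(round((c.start_hpi - scene.start_hpi) / dt))
        si = min(max(si, 0), n - 2)
        t_s = float(t[si])
        t_min = t_s + dt
        phase = PHASE_AFTER if t_s >= scene.tB_hpi else PHASE_BEFORE
        ref_cav = float(base[si])
        if ref_cav <= 0:
            raise ValueError(
                f"collapse at {c.start_hpi:.2f} hpi precedes cavity formation"
            )
        if phase == PHASE_AFTER:
            ref = float(np.interp(t_min, t, zpa))
        else:
            ref = ref_cav
        a_min = (1.0 - c.shrinkage_frac) * ref
        a_min = min(a_min, ref_cav)  # dips cannot rise above the baseline
        rec_level = RECOVERY_FRAC_TRUTH * ref_cav
        t_rec = t_min + c.recovery_duration_h
        t_end = t_rec + 2 * dt
        bp_t = [t_s, t_min, max(t_rec, t_min + 1e-9), t_end]
        bp_a = [ref_cav, a_min, max(rec_level, a_min), float(np.interp(t_end, t, base))]
        sel = (t > t_s) & (t < t_end)
        area[sel] = np.minimum(np.interp(t[sel], bp_t, bp_a), base[sel])

        amin_sampled = float(area[si + 1])
        shr = 1.0 - amin_sampled / ref
        truth.append(
            CollapseEvent(
                start_hpi=t_s,
                tmin_hpi=t_min,
                recovery_hpi=None,
                shrinkage=max(shr, 0.0),
                area_ratio=1.0 - max(shr, 0.0),
                recovery_duration_h=c.recovery_duration_h,
                phase=phase,
                start_idx=si,
                tmin_idx=si + 1,
            )
        )

    trace = AreaTrace(
        time_hpi=t,
        cavity_area=area,
        zp_interior_area=zpa,
        zp_thickness=zp_thickness(scene, t),
        frame_interval_min=scene.frame_interval_min,
        tSB_hpi=scene.tSB_hpi,
        tB_hpi=scene.tB_hpi,
    )
    return trace, truth


# ------------------------------------------------------------------ frames


def render_frames(
    trace: AreaTrace, scene: SceneSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render a schematic grayscale stack from a trace.

    Returns ``(stack, masks)``: uint8 frames of shape (n, H, W) and label
    masks (0 background, 1 ZP annulus, 2 trophectoderm/interior, 3 cavity).
    Deterministic given the seed.  Rejects traces whose cavity would exceed
    the ZP inner radius.
    """
    rng = np.random.default_rng(seed)
    npx = scene.frame_px
    yy, xx = np.mgrid[0:npx, 0:npx]
    cy = cx = (npx - 1) / 2.0
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)

    n = trace.n_frames
    stack = np.empty((n, npx, npx), dtype=np.uint8)
    masks = np.empty((n, npx, npx), dtype=np.uint8)
    r_out = scene.zp_outer_radius_px
    for i in range(n):
        zpa = trace.zp_interior_area[i]
        cav = trace.cavity_area[i]
        r_in = np.sqrt(zpa / np.pi)
        r_cav = np.sqrt(max(cav, 0.0) / np.pi)
        if r_cav > r_in + 1e-9:
            raise ValueError(
                f"frame {i}: cavity radius {r_cav:.1f} px exceeds ZP inner "
                f"radius {r_in:.1f} px"
            )
        img = np.full((npx, npx), 40.0)
        msk = np.zeros((npx, npx), dtype=np.uint8)
        zp_ring = (rr <= r_out) & (rr > r_in)
        interior = rr <= r_in
        cavity = rr <= r_cav
        img[zp_ring] = 230.0
        img[interior] = 150.0
        img[cavity] = 80.0
        msk[zp_ring] = 1
        msk[interior & ~cavity] = 2
        msk[cavity] = 3
        if scene.debris:
            # a few bright blobs in the perivitelline gap, the confounder
            # that degrades segmentation on real videos
            for _ in range(3):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(r_cav + 2, max(r_in - 2, r_cav + 3))
                by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                blob = (yy - by) ** 2 + (xx - bx) ** 2 <= rng.uniform(2, 5) ** 2
                img[blob] = 210.0
        if scene.noise_sd > 0:
            img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
        stack[i] = np.clip(img, 0, 255).astype(np.uint8)
        masks[i] = msk
    return stack, masks


# ------------------------------------------------------------------ cohorts


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size=None
) -> np.ndarray:
    """Draw from a normal truncated to (low, high).  A degenerate SD pins
    the draw at the mean."""
    if sd < 1e-8:
        return np.full(size, float(mean)) if size is not None else float(mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_mean(rng, mean: float, sigma_log: float, size=None):
    mu = np.log(mean) - sigma_log**2 / 2.0
    return rng.lognormal(mu, sigma_log, size=size)


@dataclass
class FirstCollapseLaws:
    """Calibration of programmed collapses, per phase.

    Defaults follow the published first-collapse characteristics: starts
    106.6 ± 8.2 hpi (before tB) and 121.3 ± 11.1 hpi (after tB); shrinkage
    23.9 ± 4.5% / 25.0 ± 15.2%; durations 0.9 h / 1.0 h.  Shrinkage draws
    are truncated symmetrically about the mean (within (0, 1)) so the
    truncated law keeps the printed mean; recovery durations are log-normal
    with the printed mean and a right-skew sigma_log of 0.8.
    """

    start_mean_before: float = 106.6
    start_sd_before: float = 8.2
    start_mean_after: float = 121.3
    start_sd_after: float = 11.1
    shrink_mean_before: float = 0.239
    shrink_sd_before: float = 0.045
    shrink_mean_after: float = 0.250
    shrink_sd_after: float = 0.152
    recovery_mean_before_h: float = 0.9
    recovery_mean_after_h: float = 1.0
    recovery_sigma_log: float = 0.8
    shrink_floor: float = 0.02

    def draw_shrinkage(self, rng, phase: str, size=None):
        m, s = (
            (self.shrink_mean_before, self.shrink_sd_before)
            if phase == PHASE_BEFORE
            else (self.shrink_mean_after, self.shrink_sd_after)
        )
        lo = self.shrink_floor
        hi = min(2 * m - lo, 0.98)  # symmetric about the mean
        return truncated_normal(rng, m, s, lo, hi, size=size)

    def draw_recovery(self, rng, phase: str, size=None):
        m = (
            self.recovery_mean_before_h
            if phase == PHASE_BEFORE
            else self.recovery_mean_after_h
        )
        return _lognormal_mean(rng, m, self.recovery_sigma_log, size=size)


def sample_scene(
    rng: np.random.Generator,
    n_before: int = 0,
    n_after: int = 0,
    laws: FirstCollapseLaws | None = None,
    tSB_hpi: float | None = None,
    tB_hpi: float | None = None,
    end_hpi: float = 150.0,
    max_tries: int = 500,
    **scene_kwargs,
) -> SceneSpec:
    """Draw a SceneSpec with the requested number of collapses per phase.

    Start times follow the first-collapse laws truncated to the phase span;
    events are rejection-sampled until their windows do not overlap.
    Recovery durations are clamped so every event completes before the trace
    ends.
    """
    laws = laws or FirstCollapseLaws()
    if tSB_hpi is None:
        tSB_hpi = float(truncated_normal(rng, 98.0, 4.0, 88.0, 108.0))
    if tB_hpi is None:
        tB_hpi = float(tSB_hpi + truncated_normal(rng, 12.0, 3.0, 5.0, 24.0))
    scene = SceneSpec(
        tSB_hpi=tSB_hpi, tB_hpi=tB_hpi, end_hpi=end_hpi, **scene_kwargs
    )
    dt = scene.dt_h
    specs: list[CollapseSpec] = []
    for phase, count in ((PHASE_BEFORE, n_before), (PHASE_AFTER, n_after)):
        if phase == PHASE_BEFORE:
            lo, hi = tSB_hpi + 4 * dt, tB_hpi - 2 * dt
            m, s = laws.start_mean_before, laws.start_sd_before
        else:
            lo, hi = tB_hpi + 2 * dt, end_hpi - 6 * dt
            m, s = laws.start_mean_after, laws.start_sd_after
        # truncate the start law symmetrically about its mean when the phase
        # span allows it, so the programmed starts keep the printed mean
        lo2, hi2 = max(lo, 2 * m - hi), min(hi, 2 * m - lo)
        if hi2 - lo2 < 4 * dt:
            lo2, hi2 = lo, hi
        for _ in range(count):
            for attempt in range(max_tries):
                # late attempts widen back to the full phase span and cap
                # recovery so crowded phases can still be packed
                crowded = attempt >= max_tries // 2
                a, b = (lo, hi) if crowded else (lo2, hi2)
                start = float(truncated_normal(rng, m, s, a, b))
                shr = float(laws.draw_shrinkage(rng, phase))
                rec = float(laws.draw_recovery(rng, phase))
                if crowded:
                    rec = min(rec, max((hi - lo) / (2 * count + 1) - 3 * dt, 0.05))
                rec = min(rec, (end_hpi - 4 * dt) - (start + dt), 30.0)
                rec = max(rec, 0.0)
                cand = CollapseSpec(start, shr, rec)
                w = scene.collapse_window(cand)
                if all(
                    w[1] <= scene.collapse_window(o)[0] or w[0] >= scene.collapse_window(o)[1]
                    for o in specs
                ):
                    specs.append(cand)
                    break
            else:
                raise RuntimeError(
                    f"could not place {count} non-overlapping collapses in phase {phase}"
                )
    return replace(scene, collapses=specs)


@dataclass
class CohortParams:
    """Cohort-level generative parameters.

    The ploidy label follows
    ``logit P(aneuploid) = -baseline_euploid_logit + log(1.100)·1[count == 1]
    + beta_multicollapse·1[count >= 2] + covariate terms + cycle intercept``
    with a N(0, cycle_sd²) intercept per treatment cycle.  Category
    prevalences and the adjusted multiple-collapse effect default to the
    published calibration (prevalences 71.9 / 5.6 / 19.4 / 3.1% and
    OR 2.597 for >= 2 post-tB collapses).
    """

    n_cycles: int = 450
    embryos_per_cycle_mean: float = 2.38
    category_prevalence: tuple[float, float, float, float] = PAPER_CATEGORY_PREVALENCE
    #: distribution of post-tB collapse counts 1..6 given >= 1 (free knob;
    #: consistent with 183/560 embryos collapsing more than once)
    post_tb_count_probs: tuple[float, ...] = (0.673, 0.20, 0.075, 0.030, 0.015, 0.007)
    before_count_probs: tuple[float, ...] = (0.75, 0.20, 0.05)  # counts 1..3
    baseline_euploid_logit: float = 0.07
    beta_collapse1: float = float(np.log(1.100))
    beta_multicollapse: float = float(np.log(2.597))
    cycle_sd: float = 0.5
    seed: int = 0
    #: exclusion probabilities, defaults from the published cohort counts
    p_no_result: float = 43 / 3288
    p_mosaic: float = 416 / 3245
    p_imaging_abnormal: float = 57 / 3288
    p_off_frame: float = 276 / 3288
    #: single-embryo-transfer simulation among analysable euploid embryos
    #: (~494 transfers out of ~1196 euploid); outcome rates at typical
    #: vitrified-warmed euploid values
    p_transfer: float = 494 / 1196
    p_pregnant: float = 0.60
    p_live_birth_given_pregnant: float = 0.82
    p_miscarriage_given_pregnant: float = 0.12

    def __post_init__(self) -> None:
        if abs(sum(self.category_prevalence) - 1.0) > 1e-9:
            raise ValueError("category_prevalence must sum to 1")
        if self.cycle_sd < 0:
            raise ValueError("cycle_sd must be >= 0")
        if self.n_cycles < 2 and self.cycle_sd > 0:
            raise ValueError(
                "n_cycles must be >= 2 when cycle_sd > 0 "
                "(cycle random effect unidentifiable)"
            )
        for name in ("post_tb_count_probs", "before_count_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or not np.isfinite(p).all() or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")


CATEGORIES = ("none", "before_only", "after_only", "both")

#: covariate effects on the aneuploidy log-odds (centered covariates),
#: calibrated to the published adjusted odds ratios
DEFAULT_COVARIATE_BETAS = {
    "t8": np.log(0.976),
    "tSB": np.log(0.955),
    "tB": np.log(1.063),
    "ECC3": np.log(1.046),
    "s3": np.log(0.949),
    "infertility_years": np.log(1.105),
    "amh_100": np.log(1.031),
    "biopsy_day6": np.log(1.168),
    "icm_B": np.log(1.414),
    "te_B": np.log(1.297),
    "te_C": np.log(2.567),
}


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a cohort table: one row per biopsied embryo.

    Columns include cycle membership, the collapse category and post-tB
    count, morphokinetic annotations and derived intervals, patient/cycle
    covariates, grades, exclusion flags (no_result / mosaic /
    imaging_abnormal / off_frame) and the aneuploid label for analysable
    embryos.  Reproducible given ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed), 0x27C]))
    n_per = 1 + rng.poisson(max(p.embryos_per_cycle_mean - 1.0, 0.0), size=p.n_cycles)
    cycle_id = np.repeat(np.arange(p.n_cycles), n_per)
    n = cycle_id.size
    b_cycle = rng.normal(0.0, p.cycle_sd, size=p.n_cycles)

    cat_idx = rng.choice(4, size=n, p=np.asarray(p.category_prevalence))
    category = np.array(CATEGORIES, dtype=object)[cat_idx]
    n_before = np.zeros(n, dtype=int)
    n_after = np.zeros(n, dtype=int)
    before_mask = (category == "before_only") | (category == "both")
    after_mask = (category == "after_only") | (category == "both")
    n_before[before_mask] = rng.choice(
        np.arange(1, len(p.before_count_probs) + 1),
        size=int(before_mask.sum()),
        p=np.asarray(p.before_count_probs),
    )
    n_after[after_mask] = rng.choice(
        np.arange(1, len(p.post_tb_count_probs) + 1),
        size=int(after_mask.sum()),
        p=np.asarray(p.post_tb_count_probs),
    )

    # patient / cycle covariates (cycle-constant), realistic clinic ranges
    age_c = truncated_normal(rng, 32.0, 4.6, 20.0, 45.0, size=p.n_cycles)
    bmi_c = truncated_normal(rng, 22.0, 3.0, 16.0, 35.0, size=p.n_cycles)
    inf_c = _lognormal_mean(rng, 3.5, 0.6, size=p.n_cycles)
    fsh_c = truncated_normal(rng, 7.0, 2.0, 2.0, 15.0, size=p.n_cycles)
    amh_c = _lognormal_mean(rng, 3.5, 0.7, size=p.n_cycles)
    stim_c = truncated_normal(rng, 10.0, 2.0, 5.0, 18.0, size=p.n_cycles)

    # morphokinetics built from non-negative increments so ordering holds;
    # post-tB collapses delay tB and stretch s3 (delayed development)
    t2 = truncated_normal(rng, 26.0, 2.5, 18.0, 36.0, size=n)
    s2 = np.abs(rng.normal(1.0, 0.8, size=n)) + 0.1
    t3 = t2 + truncated_normal(rng, 11.0, 2.0, 4.0, 20.0, size=n)
    t4 = t3 + s2
    t5 = t4 + truncated_normal(rng, 11.0, 2.0, 4.0, 20.0, size=n)
    s3 = truncated_normal(rng, 7.0, 2.5, 0.5, 20.0, size=n) + 0.2 * n_after
    t8 = t5 + s3
    tSB = t8 + truncated_normal(rng, 42.0, 5.0, 20.0, 60.0, size=n)
    tB = tSB + truncated_normal(rng, 12.0, 3.0, 4.0, 24.0, size=n) + 0.8 * n_after

    biopsy_day = np.where(tB <= 112.0, 5, 6)
    icm = rng.choice(np.array(["A", "B"], dtype=object), size=n, p=[0.45, 0.55])
    te_probs = np.column_stack(
        [
            np.full(n, 0.30) - 0.03 * np.minimum(n_after, 2),
            np.full(n, 0.50),
            np.full(n, 0.20) + 0.03 * np.minimum(n_after, 2),
        ]
    )
    te_u = rng.random(n)
    te_cum = np.cumsum(te_probs, axis=1)
    te = np.array(["A", "B", "C"], dtype=object)[
        (te_u[:, None] > te_cum).sum(axis=1)
    ]

    # exclusion flags
    no_result = rng.random(n) < p.p_no_result
    mosaic = ~no_result & (rng.random(n) < p.p_mosaic)
    imaging_abnormal = rng.random(n) < p.p_imaging_abnormal
    off_frame = ~imaging_abnormal & (rng.random(n) < p.p_off_frame)

    # ploidy via the logistic model on centered covariates
    eta = np.full(n, -p.baseline_euploid_logit)
    eta += p.beta_collapse1 * (n_after == 1)
    eta += p.beta_multicollapse * (n_after >= 2)
    cov = {
        "t8": t8 - t8.mean(),
        "tSB": tSB - tSB.mean(),
        "tB": tB - tB.mean(),
        "ECC3": (t8 - t4) - (t8 - t4).mean(),
        "s3": s3 - s3.mean(),
        "infertility_years": inf_c[cycle_id] - inf_c.mean(),
        "amh_100": (amh_c[cycle_id] - amh_c.mean()) / 100.0,
        "biopsy_day6": (biopsy_day == 6).astype(float),
        "icm_B": (icm == "B").astype(float),
        "te_B": (te == "B").astype(float),
        "te_C": (te == "C").astype(float),
    }
    for name, beta in DEFAULT_COVARIATE_BETAS.items():
        eta += beta * cov[name]
    eta += b_cycle[cycle_id]
    aneuploid = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    df = pd.DataFrame(
        {
            "embryo_id": [f"E{i:05d}" for i in range(n)],
            "cycle_id": cycle_id,
            "category": category,
            "n_before_tB": n_before,
            "n_after_tB": n_after,
            "multi_after_tB": n_after >= 2,
            "age": age_c[cycle_id],
            "bmi": bmi_c[cycle_id],
            "infertility_years": inf_c[cycle_id],
            "fsh": fsh_c[cycle_id],
            "amh": amh_c[cycle_id],
            "stimulation_days": stim_c[cycle_id],
            "t2": t2,
            "t3": t3,
            "t4": t4,
            "t5": t5,
            "t8": t8,
            "tSB": tSB,
            "tB": tB,
            "ECC2": t4 - t2,
            "ECC3": t8 - t4,
            "s2": s2,
            "s3": s3,
            "biopsy_day": biopsy_day,
            "icm_grade": icm,
            "te_grade": te,
            "no_result": no_result,
            "mosaic": mosaic,
            "imaging_abnormal": imaging_abnormal,
            "off_frame": off_frame,
            "aneuploid": pd.array(aneuploid, dtype="boolean"),
            "true_cycle_logit": b_cycle[cycle_id],
        }
    )
    df.loc[no_result | mosaic, "aneuploid"] = pd.NA

    # vitrified-warmed single embryo transfers: euploid analysable only
    analysable = ~(no_result | mosaic | imaging_abnormal | off_frame)
    euploid = analysable & ~np.where(no_result | mosaic, True, aneuploid)
    transferred = euploid & (rng.random(n) < p.p_transfer)
    pregnant = transferred & (rng.random(n) < p.p_pregnant)
    live = pregnant & (rng.random(n) < p.p_live_birth_given_pregnant)
    misc = pregnant & ~live & (rng.random(n) < p.p_miscarriage_given_pregnant / (1 - p.p_live_birth_given_pregnant))
    for name, col in (("pregnant", pregnant), ("live_birth", live),
                      ("miscarriage", misc)):
        s = pd.array(col, dtype="boolean")
        s[~transferred] = pd.NA
        df[name] = s
    df["transferred"] = transferred
    return df


def simulate_profiles(cohort: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Draw per-chromosome copy-number profiles consistent with each
    embryo's ploidy label (one CSV row per aberrant segment; euploid embryos
    get low-level segments below every chromosome's lower limit)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A1]))
    chroms = [str(c) for c in range(1, 23)] + ["X", "Y"]
    lower = {c: 0.40 for c in chroms}
    lower.update({c: 0.30 for c in ("13", "16", "18", "21")})
    lower["19"] = 0.50
    rows = []
    for _, r in cohort.iterrows():
        eid = r["embryo_id"]
        if r["no_result"]:
            continue
        chrom = chroms[rng.integers(len(chroms))]
        if r["mosaic"]:
            frac = rng.uniform(lower[chrom] + 0.02, 0.68)
            rows.append((eid, chrom, "whole_chromosome", "loss", frac))
        elif bool(r["aneuploid"]):
            kind = rng.choice(
                ["monosomy", "trisomy", "fragment_deletion", "fragment_duplication"],
                p=[0.3, 0.3, 0.2, 0.2],
            )
            frac = rng.uniform(0.75, 1.0)
            span = "whole_chromosome" if kind in ("monosomy", "trisomy") else "segmental"
            direction = "loss" if kind in ("monosomy", "fragment_deletion") else "gain"
            rows.append((eid, chrom, span, direction, frac))
        else:
            frac = rng.uniform(0.0, lower[chrom] - 0.05)
            rows.append((eid, chrom, "segmental", "loss", frac))
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "chromosome", "span", "direction", "aberrant_fraction"],
    )


def simulate_trace_cohort(
    n_embryos: int,
    seed: int = 0,
    category_prevalence: tuple[float, float, float, float] = PAPER_CATEGORY_PREVALENCE,
    post_tb_count_probs: tuple[float, ...] = CohortParams.post_tb_count_probs,
    before_count_probs: tuple[float, ...] = CohortParams.before_count_probs,
    laws: FirstCollapseLaws | None = None,
):
    """Yield ``(embryo_index, scene, trace, truth_events)`` for a cohort of
    synthetic embryos with categories drawn from ``category_prevalence``.

    Embryo k uses substream (seed, k), so any embryo is reproducible alone.
    """
    master = np.random.SeedSequence(int(seed))
    cat_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA7]))
    cats = cat_rng.choice(4, size=n_embryos, p=np.asarray(category_prevalence))
    for k in range(n_embryos):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1 + k]))
        cat = CATEGORIES[cats[k]]
        nb = na = 0
        if cat in ("before_only", "both"):
            nb = int(
                rng.choice(np.arange(1, len(before_count_probs) + 1),
                           p=np.asarray(before_count_probs))
            )
        if cat in ("after_only", "both"):
            na = int(
                rng.choice(np.arange(1, len(post_tb_count_probs) + 1),
                           p=np.asarray(post_tb_count_probs))
            )
        scene = sample_scene(rng, n_before=nb, n_after=na, laws=laws)
        trace, truth = make_area_trace(scene)
        yield k, scene, trace, truth
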