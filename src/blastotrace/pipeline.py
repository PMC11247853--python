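"""Reproducible generate → detect → classify → analyse pipeline.

Each stage is independently invocable and writes plain-text artifacts
(CSV/JSON) into the output directory; ``run_pipeline`` chains them and
writes a manifest with the config hash, seed, package versions and exact
per-stage exclusion accounting.  Same config + seed ⇒ identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import detect_collapses, summarize_embryo
from .experiments import CLOSURE_MIN_DROP
from .ploidy import classify_profiles_table
from .stats import (
    apply_exclusions,
    chisq_partitioned,
    fit_mixed_logit,
    group_euploidy_rates,
    mh_trend,
)
from .synthgen import CohortParams, simulate_cohort, simulate_profiles

__all__ = ["PipelineConfig", "run_pipeline", "stage_generate", "stage_detect",
           "stage_classify", "stage_analyse"]


@dataclass
class PipelineConfig:
    """Single structured configuration for a pipeline run.

    ``n_trace_embryos`` embryos additionally get full synthetic area traces
    (CSV per embryo) that the detect stage re-measures; the rest carry their
    generated collapse summaries directly.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_trace_embryos: int = 0
    min_drop: float = CLOSURE_MIN_DROP
    recovery_frac: float = 0.90
    alpha: float = 0.008
    n_quad: int = 15
    fit_model: bool = False
    cohort: dict = field(default_factory=dict)  # CohortParams overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path is
        environmental and excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _out(config: PipelineConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_generate(config: PipelineConfig) -> dict:
    out = _out(config)
    params = CohortParams(seed=config.seed, **config.cohort)
    cohort = simulate_cohort(params)
    cohort.to_csv(out / "cohort.csv", index=False)
    profiles = simulate_profiles(cohort, seed=config.seed)
    profiles.to_csv(out / "profiles.csv", index=False)
    n_traces = min(config.n_trace_embryos, len(cohort))
    if n_traces:
        from .synthgen import make_area_trace, sample_scene

        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        # traces are consistent with each cohort row's collapse counts
        for k, row in cohort.head(n_traces).iterrows():
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed), 0x7A, int(k)])
            )
            scene = sample_scene(
                rng,
                n_before=int(row["n_before_tB"]),
                n_after=int(row["n_after_tB"]),
            )
            trace, _ = make_area_trace(scene)
            trace.to_csv(tdir / f"{row['embryo_id']}.csv")
    return {"embryos_generated": len(cohort), "traces_written": n_traces}


def stage_detect(config: PipelineConfig) -> dict:
    """Re-measure collapse events on every written trace."""
    out = _out(config)
    tdir = out / "traces"
    ev_rows, sm_rows = [], []
    n_unanalyzable = 0
    if tdir.exists():
        from .segment import AreaTrace

        for path in sorted(tdir.glob("*.csv")):
            eid = path.stem
            trace = AreaTrace.from_csv(path)
            if not trace.analyzable:
                n_unanalyzable += 1
                continue
            events = detect_collapses(
                trace, min_drop=config.min_drop, recovery_frac=config.recovery_frac
            )
            for e in events:
                ev_rows.append(
                    (eid, e.start_hpi, e.tmin_hpi, e.recovery_hpi, e.shrinkage,
                     e.recovery_duration_h, e.phase)
                )
            s = summarize_embryo(events, tB=trace.tB_hpi)
            sm_rows.append(
                (eid, s.n_before_tB, s.n_after_tB, s.category, s.multi_after_tB)
            )
    pd.DataFrame(
        ev_rows,
        columns=["embryo_id", "start_hpi", "tmin_hpi", "recovery_hpi",
                 "shrinkage", "recovery_duration_h", "phase"],
    ).to_csv(out / "events.csv", index=False)
    pd.DataFrame(
        sm_rows,
        columns=["embryo_id", "n_before_tB", "n_after_tB", "category",
                 "multi_after_tB"],
    ).to_csv(out / "summaries.csv", index=False)
    return {
        "traces_measured": len(sm_rows),
        "traces_unanalyzable": n_unanalyzable,
        "events_detected": len(ev_rows),
    }


def stage_classify(config: PipelineConfig) -> dict:
    out = _out(config)
    profiles = pd.read_csv(out / "profiles.csv")
    calls = classify_profiles_table(profiles)
    calls.to_csv(out / "ploidy_calls.csv", index=False)
    return {
        "profiles_classified": len(calls),
        **{f"calls_{k}": int(v) for k, v in calls["label"].value_counts().items()},
    }


def stage_analyse(config: PipelineConfig) -> dict:
    out = _out(config)
    cohort = pd.read_csv(out / "cohort.csv")
    kept, counts = apply_exclusions(cohort)
    kept = kept.copy()
    kept["aneuploid"] = kept["aneuploid"].astype("boolean")

    rates = group_euploidy_rates(kept, "category")
    rates.to_csv(out / "euploidy_rates_category.csv", index=False)
    table = rates.set_index("group")[["n_euploid"]].assign(
        n_aneuploid=rates.set_index("group")["n"] - rates.set_index("group")["n_euploid"]
    )
    part = chisq_partitioned(table, alpha=config.alpha)
    count_rates = group_euploidy_rates(kept, "post_tb_count")
    count_rates.to_csv(out / "euploidy_rates_post_tb_count.csv", index=False)
    trend_tab = count_rates[["n_euploid"]].assign(
        n_aneuploid=count_rates["n"] - count_rates["n_euploid"]
    ).to_numpy()
    trend_z, trend_p = mh_trend(trend_tab)

    results = {
        "exclusion_counts": counts,
        "partitioned_chi2": {
            "overall_chi2": part.overall_chi2,
            "overall_p": part.overall_p,
            "alpha": part.alpha,
            "n_significant_pairs": sum(c.significant for c in part.pairwise),
        },
        "mh_trend": {"z": trend_z, "p": trend_p},
    }
    if config.fit_model:
        fit = fit_mixed_logit(kept, n_quad=config.n_quad)
        fit.params.round(6).to_csv(out / "mixed_logit_fit.csv")
        results["mixed_logit"] = {
            "or_collapse_ge2": float(fit.params.loc["collapse_ge2", "or_"]),
            "sigma": fit.sigma,
            "converged": fit.converged,
        }
    with open(out / "analysis.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=float)
    return results


STAGES = {
    "generate": stage_generate,
    "detect": stage_detect,
    "classify": stage_classify,
    "analyse": stage_analyse,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and write the run manifest.

    The manifest records the config hash, master seed, package versions and
    per-stage counts so the exclusion accounting
    (analysed = generated − no_result − mosaic − unusable imaging) is exact
    and auditable.  A stage failure halts the run; the manifest then names
    the failed stage and keeps the counts of completed stages.
    """
    out = _out(config)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"blastotrace": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
        "status": "ok",
    }
    try:
        for name, fn in STAGES.items():
            manifest["stages"][name] = fn(config)
    except Exception as exc:  # halt with the stage name; partial outputs marked
        manifest["status"] = f"failed at stage {name!r}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        raise
    counts = manifest["stages"]["analyse"]["exclusion_counts"]
    manifest["accounting"] = {
        "generated": counts["biopsied"],
        "analysable": counts["analysable"],
        "identity_holds": counts["analysable"]
        == counts["biopsied"]
        - sum(counts[f"excluded_{f}"] for f in
              ("no_result", "mosaic", "imaging_abnormal", "off_frame")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
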