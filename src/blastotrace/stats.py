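"""Cohort-level statistics: euploidy-rate tables, partitioned chi-squared
comparisons, the Mantel–Haenszel linear-by-linear trend test, outcome-rate
comparisons with exact tests, a univariate euploid-vs-aneuploid screen, and
the two-level mixed-effects logistic regression relating multiple post-tB
collapses to aneuploidy.

Mosaic and no-result embryos are excluded from every ploidy association
(the analyses contrast euploid vs aneuploid only), as are embryos whose
time-lapse recording was unusable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mixedlogit import ConvergenceError, MixedLogitResult, fit_mixed_logit_arrays

__all__ = [
    "apply_exclusions",
    "group_euploidy_rates",
    "chisq_partitioned",
    "mh_trend",
    "compare_outcome_rates",
    "fit_mixed_logit",
    "univariate_screen",
    "ADJUSTED_MODEL_PREDICTORS",
    "ConvergenceError",
]

EXCLUSION_FLAGS = ("no_result", "mosaic", "imaging_abnormal", "off_frame")


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the analysability cascade and return (analysable subset, counts).

    Embryos drop out, in order, for: amplification failure (no_result),
    a mosaic ploidy call, an imaging abnormality, and moving off-frame.
    The counts dictionary records the cohort size at each step.
    """
    counts = {"biopsied": len(cohort)}
    kept = cohort
    for flag in EXCLUSION_FLAGS:
        if flag in kept.columns:
            removed = int(kept[flag].fillna(False).astype(bool).sum())
            kept = kept[~kept[flag].fillna(False).astype(bool)]
        else:
            removed = 0
        counts[f"excluded_{flag}"] = removed
    counts["analysable"] = len(kept)
    if "aneuploid" in kept.columns:
        aneu = kept["aneuploid"].astype("boolean")
        counts["euploid"] = int((~aneu).sum())
        counts["aneuploid"] = int(aneu.sum())
    return kept, counts


def _post_tb_bin(n: int) -> str:
    return str(n) if n < 4 else ">=4"


def _grouping_column(cohort: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "category":
        order = ["none", "before_only", "after_only", "both"]
        return pd.Categorical(cohort["category"], categories=order, ordered=True)
    if grouping == "post_tb_count":
        vals = cohort["n_after_tB"].map(_post_tb_bin)
        return pd.Categorical(vals, categories=["0", "1", "2", "3", ">=4"], ordered=True)
    if grouping == "multi":
        sub = cohort["n_after_tB"]
        vals = np.where(sub >= 2, ">1", np.where(sub == 1, "1", "0"))
        return pd.Categorical(vals, categories=["0", "1", ">1"], ordered=True)
    raise ValueError(f"unknown grouping {grouping!r}")


def group_euploidy_rates(cohort: pd.DataFrame, grouping: str = "category") -> pd.DataFrame:
    """Euploidy rate per collapse group.

    ``grouping`` is one of ``category`` (four-way), ``post_tb_count``
    (0/1/2/3/>=4) or ``multi`` (0 / 1 / >1 post-tB collapses).  Expects an
    already-filtered euploid/aneuploid cohort (see :func:`apply_exclusions`).
    Empty groups report a missing rate, never zero.
    """
    aneu = cohort["aneuploid"].astype("boolean")
    if aneu.isna().any():
        raise ValueError("cohort contains embryos without a euploid/aneuploid label")
    g = _grouping_column(cohort, grouping)
    df = pd.DataFrame({"group": g, "euploid": ~aneu.astype(bool)})
    out = (
        df.groupby("group", observed=False)["euploid"]
        .agg(n="size", n_euploid="sum")
        .reset_index()
    )
    out["rate"] = np.where(out["n"] > 0, out["n_euploid"] / out["n"].where(out["n"] > 0), np.nan)
    return out


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    chi2: float
    p: float
    significant: bool
    min_expected: float


@dataclass
class PartitionedChisq:
    overall_chi2: float
    overall_p: float
    overall_df: int
    alpha: float
    pairwise: list[PairwiseComparison]
    warnings: list[str] = field(default_factory=list)
    excluded_rows: list[str] = field(default_factory=list)


def _pearson_chi2(table: np.ndarray) -> tuple[float, float, int, np.ndarray]:
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(dof), expected


def chisq_partitioned(
    table: pd.DataFrame | np.ndarray, alpha: float = 0.008
) -> PartitionedChisq:
    """Overall Pearson chi-squared on an R x 2 count table plus all pairwise
    2 x 2 partitions, each flagged significant iff P < ``alpha`` (0.008,
    i.e. 0.05 Bonferroni-corrected over the six pairs of four groups).
    Zero-margin rows are excluded with a diagnostic; expected counts below 5
    raise a warning entry.
    """
    if isinstance(table, pd.DataFrame):
        labels = [str(i) for i in table.index]
        arr = table.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
        labels = [str(i) for i in range(arr.shape[0])]
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an R x 2 count table")
    keep = arr.sum(axis=1) > 0
    excluded = [labels[i] for i in np.flatnonzero(~keep)]
    arr, labels = arr[keep], [l for l, k in zip(labels, keep) if k]
    if arr.shape[0] < 2:
        raise ValueError("fewer than 2 non-empty rows")
    notes: list[str] = []
    chi2, p, dof, expected = _pearson_chi2(arr)
    if expected.min() < 5:
        notes.append(f"overall table: min expected count {expected.min():.2f} < 5")
    pairs = []
    for i in range(arr.shape[0]):
        for j in range(i + 1, arr.shape[0]):
            sub = arr[[i, j]]
            if np.any(sub.sum(axis=0) == 0):
                c2, pv, mine = 0.0, 1.0, 0.0
            else:
                c2, pv, _, exp = _pearson_chi2(sub)
                mine = float(exp.min())
                if mine < 5:
                    notes.append(
                        f"pair ({labels[i]}, {labels[j]}): min expected {mine:.2f} < 5"
                    )
            pairs.append(
                PairwiseComparison(labels[i], labels[j], c2, pv, pv < alpha, mine)
            )
    return PartitionedChisq(chi2, p, dof, alpha, pairs, notes, excluded)


def mh_trend(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Mantel–Haenszel linear-by-linear association test on an ordered
    R x 2 table with integer row scores.

    Returns ``(z, p)`` where z = sign(association) * sqrt(M²) with
    M² = (N - 1) r² on 1 df and r the Pearson correlation between the row
    score and the column indicator.  Requires at least 3 rows (with 2 rows
    the trend test degenerates to the 2 x 2 comparison).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an R x 2 count table")
    if arr.shape[0] < 3:
        raise ValueError("trend test requires at least 3 ordered rows")
    n = arr.sum()
    if n <= 1:
        raise ValueError("empty table")
    scores = np.arange(1, arr.shape[0] + 1, dtype=float)
    col = np.array([0.0, 1.0])
    w = arr / n
    mx = (scores[:, None] * w).sum()
    my = (col[None, :] * w).sum()
    sxx = ((scores[:, None] - mx) ** 2 * w).sum()
    syy = ((col[None, :] - my) ** 2 * w).sum()
    sxy = ((scores[:, None] - mx) * (col[None, :] - my) * w).sum()
    if sxx <= 0 or syy <= 0:
        return 0.0, 1.0
    r = sxy / np.sqrt(sxx * syy)
    m2 = (n - 1) * r**2
    z = float(np.sign(r) * np.sqrt(m2))
    p = float(sps.chi2.sf(m2, df=1))
    return z, p


def compare_outcome_rates(
    cohort: pd.DataFrame,
    outcome: str,
    grouping: str = "category",
    reference: str = "none",
) -> pd.DataFrame:
    """Per-group outcome rates among transferred euploid embryos, with
    Fisher's exact test of each group against the no-collapse reference.

    ``outcome`` is a binary column (e.g. pregnant / live_birth /
    miscarriage); rows with a missing outcome are not transfers and are
    dropped.  Groups with zero transfers are omitted with a note column.
    """
    sub = cohort[cohort[outcome].notna()].copy()
    g = _grouping_column(sub, grouping)
    y = sub[outcome].astype(bool)
    rows = []
    cats = list(g.categories)
    counts = {
        c: (int((np.asarray(g) == c).sum()), int(y[np.asarray(g) == c].sum()))
        for c in cats
    }
    if reference not in cats or counts[reference][0] == 0:
        raise ValueError(f"reference group {reference!r} has no transfers")
    n_ref, k_ref = counts[reference]
    for c in cats:
        n, k = counts[c]
        if n == 0:
            rows.append((c, 0, 0, np.nan, np.nan, "omitted: no transfers"))
            continue
        if c == reference:
            rows.append((c, n, k, k / n, np.nan, "reference"))
            continue
        tab = [[k, n - k], [k_ref, n_ref - k_ref]]
        _, pv = sps.fisher_exact(tab, alternative="two-sided")
        rows.append((c, n, k, k / n, float(pv), ""))
    return pd.DataFrame(
        rows, columns=["group", "n", "n_events", "rate", "fisher_p", "note"]
    )


#: Predictor set for the adjusted aneuploidy model: post-tB collapse
#: count (0 reference / 1 / >=2), biopsy day 6 vs 5, ICM B vs A, TE B and C
#: vs A, and the continuous confounders.
ADJUSTED_MODEL_PREDICTORS = (
    "collapse_1",
    "collapse_ge2",
    "biopsy_day6",
    "icm_B",
    "te_B",
    "te_C",
    "t8",
    "tSB",
    "tB",
    "ECC3",
    "s3",
    "infertility_years",
    "amh_100",
)

_CONTINUOUS = {"t8", "tSB", "tB", "ECC3", "s3", "infertility_years", "amh_100"}


def _build_design(cohort: pd.DataFrame, predictors) -> tuple[np.ndarray, list[str]]:
    cols = {"intercept": np.ones(len(cohort))}
    for name in predictors:
        if name == "collapse_1":
            cols[name] = (cohort["n_after_tB"] == 1).to_numpy(float)
        elif name == "collapse_ge2":
            cols[name] = (cohort["n_after_tB"] >= 2).to_numpy(float)
        elif name == "biopsy_day6":
            cols[name] = (cohort["biopsy_day"] == 6).to_numpy(float)
        elif name == "icm_B":
            cols[name] = (cohort["icm_grade"] == "B").to_numpy(float)
        elif name in ("te_B", "te_C"):
            cols[name] = (cohort["te_grade"] == name[-1]).to_numpy(float)
        elif name == "amh_100":
            cols[name] = cohort["amh"].to_numpy(float) / 100.0
        elif name in _CONTINUOUS:
            cols[name] = cohort[name].to_numpy(float)
        else:
            cols[name] = cohort[name].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def fit_mixed_logit(
    cohort: pd.DataFrame,
    outcome: str = "aneuploid",
    predictors=ADJUSTED_MODEL_PREDICTORS,
    cluster: str = "cycle_id",
    n_quad: int = 15,
    fix_sigma: float | None = None,
) -> MixedLogitResult:
    """Adjusted aneuploidy model: two-level mixed-effects logistic
    regression (level one embryo, level two cycle) on complete-case rows.

    The default predictor set encodes the post-tB collapse count as 0
    (reference) / 1 / >= 2 indicators plus the morphology, timing and
    patient confounders.  Returns odds ratios with Wald 95% CIs; raises
    :class:`ConvergenceError` on failure and warns on suspected separation.
    """
    needed = {outcome, cluster, "n_after_tB", "biopsy_day", "icm_grade", "te_grade"}
    needed |= {c for c in predictors if c in cohort.columns}
    sub = cohort.dropna(subset=[c for c in needed if c in cohort.columns]).copy()
    y = sub[outcome].astype("boolean")
    sub = sub[y.notna()]
    y = sub[outcome].astype("boolean").astype(bool).to_numpy()
    X, names = _build_design(sub, predictors)
    result = fit_mixed_logit_arrays(
        X, y, sub[cluster].to_numpy(), names=names, n_quad=n_quad, fix_sigma=fix_sigma
    )
    for msg in result.separation_warnings:
        warnings.warn(msg, stacklevel=2)
    return result


def univariate_screen(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variable euploid-vs-aneuploid comparison.

    Continuous variables use the Mann–Whitney U test; categorical variables
    use the chi-squared test (Fisher's exact on 2 x 2 tables with small
    expected counts).  Constant or all-missing variables are skipped with a
    note.
    """
    if variables is None:
        variables = [
            "age", "bmi", "infertility_years", "fsh", "amh", "stimulation_days",
            "t2", "t3", "t4", "t5", "t8", "tSB", "tB", "ECC2", "ECC3", "s2", "s3",
            "biopsy_day", "icm_grade", "te_grade",
        ]
    aneu = cohort["aneuploid"].astype("boolean")
    mask = aneu.notna()
    rows = []
    for var in variables:
        if var not in cohort.columns:
            rows.append((var, "missing", np.nan, "skipped: column absent"))
            continue
        x = cohort.loc[mask, var]
        grp = aneu[mask].astype(bool)
        if x.isna().all():
            rows.append((var, "missing", np.nan, "skipped: all missing"))
            continue
        ok = x.notna()
        x, grp_ok = x[ok], grp[ok]
        if x.nunique() <= 1:
            rows.append((var, "constant", np.nan, "skipped: constant"))
            continue
        if pd.api.types.is_numeric_dtype(x) and x.nunique() > 5:
            u, p = sps.mannwhitneyu(
                x[~grp_ok], x[grp_ok], alternative="two-sided"
            )
            rows.append((var, "mann_whitney", float(p), ""))
        else:
            tab = pd.crosstab(x, grp_ok).to_numpy()
            if tab.shape == (2, 2) and sps.chi2_contingency(tab)[3].min() < 5:
                _, p = sps.fisher_exact(tab)
                rows.append((var, "fisher", float(p), ""))
            else:
                _, p, _, _ = sps.chi2_contingency(tab, correction=False)
                rows.append((var, "chi2", float(p), ""))
    return pd.DataFrame(rows, columns=["variable", "test", "p", "note"])
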