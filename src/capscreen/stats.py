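"""Two-stage screen statistics: toxicity exclusion, rescue index, hit
calling, percent-of-control lengths, and normality-gated group comparison
with post-hoc power.

The rescue index (RI) of a treated group is the fraction of axons grown
beyond the horizontal myoseptum divided by that fraction in the plate's
DMSO-mutant internal control; compounds reaching RI >= 2.5 are first-stage
hits.  Group comparisons are gated on per-group Shapiro-Wilk normality at
alpha = 0.05: parametric (t-test / one-way ANOVA with Dunnett's or Tukey's
post hoc) when every group passes, otherwise rank-based (Mann-Whitney /
Kruskal-Wallis with Dunn's post hoc).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower, FTestAnovaPower

__all__ = ["StatReport", "exclude_toxic", "rescue_index", "call_hits",
           "analyze_screen", "percent_of_control", "compare_groups",
           "posthoc_power", "screen_summary"]

RI_THRESHOLD = 2.5
CONTROL_ID = "DMSO-control"


# ---------------------------------------------------------------------------
# toxicity and rescue index
# ---------------------------------------------------------------------------

def exclude_toxic(records: pd.DataFrame, control_id: str = CONTROL_ID):
    """Drop compounds with a non-'none' toxicity state.

    ``records`` holds one row per embryo with columns ``compound_id`` and
    ``toxicity``.  Returns ``(kept_records, summary)`` where the summary
    counts excluded *compounds* per category and as percent of all
    compounds tested (the internal control is not a tested compound).
    """
    is_compound = records["compound_id"] != control_id
    by_compound = (records.loc[is_compound]
                   .groupby("compound_id")["toxicity"]
                   .agg(lambda s: next((t for t in s if t != "none"), "none")))
    n_total = len(by_compound)
    counts = {state: int((by_compound == state).sum())
              for state in ("death", "delayed", "malformed")}
    toxic_ids = set(by_compound.index[by_compound != "none"])
    kept = records[~records["compound_id"].isin(toxic_ids)].copy()
    n_excluded = len(toxic_ids)
    summary = dict(counts, n_total=n_total, n_excluded=n_excluded,
                   percent_excluded=(100.0 * n_excluded / n_total
                                     if n_total else 0.0))
    return kept, summary


def _counts(group) -> tuple[float, float]:
    """Sum (n_crossed, n_scored) over embryos of one group."""
    if isinstance(group, pd.DataFrame):
        arr = group[["n_crossed", "n_scored"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(group, dtype=float).reshape(-1, 2)
    return float(np.nansum(arr[:, 0])), float(np.nansum(arr[:, 1]))


def rescue_index(treated, control, method: str = "pooled") -> float:
    """Crossing fraction of the treated group normalised to the control.

    ``treated`` and ``control`` are sequences of per-embryo
    ``(n_crossed, n_scored)`` pairs (or DataFrames with those columns).
    ``method='pooled'`` (default) pools counts over embryos before taking
    the ratio; ``method='per-embryo'`` averages per-embryo fractions first.
    A control group with no crossing axons yields NaN with a warning
    (undefined, not infinite).
    """
    if method == "pooled":
        ct, st = _counts(treated)
        cc, sc = _counts(control)
        num = ct / st if st else math.nan
        den = cc / sc if sc else math.nan
    elif method == "per-embryo":
        def frac(g):
            if isinstance(g, pd.DataFrame):
                arr = g[["n_crossed", "n_scored"]].to_numpy(dtype=float)
            else:
                arr = np.asarray(g, dtype=float).reshape(-1, 2)
            arr = arr[~np.isnan(arr).any(axis=1)]
            return float(np.mean(arr[:, 0] / arr[:, 1])) if len(arr) else math.nan
        num, den = frac(treated), frac(control)
    else:
        raise ValueError("method must be 'pooled' or 'per-embryo'")
    if not den or math.isnan(den):
        warnings.warn("control crossing fraction is 0; rescue index undefined",
                      stacklevel=2)
        return math.nan
    return num / den


def call_hits(results: pd.DataFrame, threshold: float = RI_THRESHOLD
              ) -> pd.DataFrame:
    """Flag hits: rescue index at or above threshold and not excluded."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = results.copy()
    excluded = out.get("excluded_reason", pd.Series("", index=out.index))
    out["hit"] = ((out["rescue_index"] >= threshold)
                  & (excluded.fillna("") == "")
                  & out["rescue_index"].notna())
    return out


def analyze_screen(records: pd.DataFrame, threshold: float = RI_THRESHOLD,
                   ri_method: str = "pooled",
                   control_id: str = CONTROL_ID) -> pd.DataFrame:
    """Per-compound first-stage table: rescue index vs the same-plate
    internal control, toxicity exclusion, and hit flag."""
    rows = []
    controls_by_plate = {
        plate: g[g["compound_id"] == control_id]
        for plate, g in records.groupby("plate")
    }
    for cid, g in records[records["compound_id"] != control_id].groupby(
            "compound_id"):
        tox = next((t for t in g["toxicity"] if t != "none"), "none")
        plate = g["plate"].iloc[0]
        ctrl = controls_by_plate.get(plate)
        if tox != "none":
            ri = math.nan
            reason = f"toxic:{tox}"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ri = rescue_index(g, ctrl, method=ri_method)
            reason = ""
        rows.append(dict(compound_id=cid, plate=plate, rescue_index=ri,
                         toxicity=tox, excluded_reason=reason))
    return call_hits(pd.DataFrame(rows), threshold)


def percent_of_control(treated, control) -> float:
    """100 x mean(treated per-embryo means) / mean(control per-embryo means)."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    cm = float(np.mean(c))
    if cm == 0:
        warnings.warn("control mean is 0; percent-of-control undefined",
                      stacklevel=2)
        return math.nan
    return 100.0 * float(np.mean(t)) / cm


# ---------------------------------------------------------------------------
# group comparison with a normality gate
# ---------------------------------------------------------------------------

@dataclass
class StatReport:
    """Outcome of a normality-gated group comparison."""

    normality_p: list[float]
    parametric: bool
    test: str
    statistic: float
    p_value: float
    posthoc: list[dict] = field(default_factory=list)
    power: float = math.nan


def _dunn(groups: list[np.ndarray], comparisons: list[tuple[int, int]]):
    """Dunn's multiple-comparison test after Kruskal-Wallis.

    Standard rank-based z statistics with tie correction; each two-sided
    normal p-value is multiplied by the number of comparisons (the
    procedure's built-in adjustment), capped at 1.
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(comparisons)
    out = []
    for i, j in comparisons:
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se else math.nan
        p = min(1.0, m * 2.0 * sps.norm.sf(abs(z))) if se else math.nan
        out.append(dict(groups=(i, j), statistic=float(z), p_value=float(p)))
    return out


def compare_groups(groups, design: str = "vs-control",
                   alpha: float = 0.05) -> StatReport:
    """Normality-gated comparison of two or more groups of per-embryo values.

    Group 0 is the control for the 'vs-control' design.  Every group is
    Shapiro-Wilk tested at ``alpha``; if all pass, the parametric branch is
    used (two-sample t-test for two groups, one-way ANOVA with Dunnett's or
    Tukey's post hoc for more), otherwise the rank-based branch
    (Mann-Whitney U, or Kruskal-Wallis with Dunn's post hoc).
    """
    if design not in ("vs-control", "all-pairs"):
        raise ValueError("design must be 'vs-control' or 'all-pairs'")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 3:
            raise ValueError("each group needs n >= 3 for the normality gate")
    norm_p = [float(sps.shapiro(g).pvalue) for g in gs]
    parametric = all(p > alpha for p in norm_p)
    k = len(gs)
    if design == "vs-control":
        comparisons = [(0, j) for j in range(1, k)]
    else:
        comparisons = [(i, j) for i in range(k) for j in range(i + 1, k)]

    posthoc: list[dict] = []
    if parametric:
        if k == 2:
            res = sps.ttest_ind(gs[0], gs[1])
            report = StatReport(norm_p, True, "t-test",
                                float(res.statistic), float(res.pvalue))
        else:
            res = sps.f_oneway(*gs)
            if design == "vs-control":
                dn = sps.dunnett(*gs[1:], control=gs[0])
                posthoc = [dict(groups=(0, j + 1),
                                statistic=float(dn.statistic[j]),
                                p_value=float(dn.pvalue[j]))
                           for j in range(k - 1)]
                name = "one-way ANOVA + Dunnett"
            else:
                tk = sps.tukey_hsd(*gs)
                posthoc = [dict(groups=(i, j),
                                statistic=float(tk.statistic[i, j]),
                                p_value=float(tk.pvalue[i, j]))
                           for i, j in comparisons]
                name = "one-way ANOVA + Tukey"
            report = StatReport(norm_p, True, name, float(res.statistic),
                                float(res.pvalue), posthoc)
    else:
        if k == 2:
            res = sps.mannwhitneyu(gs[0], gs[1], alternative="two-sided")
            report = StatReport(norm_p, False, "Mann-Whitney U",
                                float(res.statistic), float(res.pvalue))
        else:
            res = sps.kruskal(*gs)
            posthoc = _dunn(gs, comparisons)
            report = StatReport(norm_p, False, "Kruskal-Wallis + Dunn",
                                float(res.statistic), float(res.pvalue),
                                posthoc)
    report.power = posthoc_power([float(g.mean()) for g in gs],
                                 [float(g.std(ddof=1)) for g in gs],
                                 [int(g.size) for g in gs], alpha=alpha)
    return report


def posthoc_power(means, sds, ns, alpha: float = 0.05) -> float:
    """Post-hoc (observed-effect) power at the observed effect size and n.

    Two groups: noncentral-t power of the two-sided two-sample t-test with
    Cohen's d from the pooled SD.  More groups: noncentral-F power of the
    one-way ANOVA with Cohen's f.  Observed-effect power describes the
    sensitivity of the design, not the evidence in the data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (means.size == sds.size == ns.size) or means.size < 2:
        raise ValueError("need aligned means, sds and ns for >= 2 groups")
    dof = ns - 1
    pooled_var = float((dof * sds ** 2).sum() / dof.sum())
    if pooled_var == 0:
        warnings.warn("zero pooled SD; power undefined", stacklevel=2)
        return math.nan
    sp = math.sqrt(pooled_var)
    if means.size == 2:
        d = abs(means[0] - means[1]) / sp
        return float(TTestIndPower().power(
            effect_size=d, nobs1=int(ns[0]), ratio=ns[1] / ns[0],
            alpha=alpha, alternative="two-sided"))
    grand = float((ns * means).sum() / ns.sum())
    f = math.sqrt(float((ns * (means - grand) ** 2).sum() / ns.sum())) / sp
    return float(FTestAnovaPower().power(
        effect_size=f, nobs=int(ns.sum()), alpha=alpha,
        k_groups=means.size))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def control_drift_check(records: pd.DataFrame,
                        control_id: str = CONTROL_ID) -> float:
    """Mann-Whitney p comparing first-wells vs last-wells control embryos,
    pooled over plates (non-blocking plate-drift diagnostic)."""
    ctrl = records[records["compound_id"] == control_id]
    first, last = [], []
    for _, g in ctrl.groupby("plate"):
        g = g.sort_values("well", key=lambda s: s.map(
            lambda w: (w[0], int(w[1:]))))
        wells = list(dict.fromkeys(g["well"]))
        first.extend(g[g["well"].isin(wells[:2])]["n_crossed"].dropna())
        last.extend(g[g["well"].isin(wells[-2:])]["n_crossed"].dropna())
    if len(first) < 3 or len(last) < 3 or (len(set(first)) == 1
                                           and set(first) == set(last)):
        return math.nan
    try:
        return float(sps.mannwhitneyu(first, last,
                                      alternative="two-sided").pvalue)
    except ValueError:
        return math.nan


def screen_summary(results: pd.DataFrame, toxicity_summary: dict | None = None,
                   n_stage2_confirmed: int | None = None) -> dict:
    """Human-readable screen arithmetic: hit counts and rates in percent.

    Hit rates are quoted against the full number of compounds tested
    (toxic compounds included in the denominator).
    """
    n_total = len(results)
    n_hits = int(results["hit"].sum())
    out = dict(
        n_compounds=n_total,
        n_hits=n_hits,
        first_stage_hit_rate_pct=100.0 * n_hits / n_total if n_total else 0.0,
    )
    if n_stage2_confirmed is not None:
        out["n_stage2_confirmed"] = int(n_stage2_confirmed)
        out["second_stage_hit_rate_pct"] = (100.0 * n_stage2_confirmed
                                            / n_total if n_total else 0.0)
    if toxicity_summary is not None:
        out["toxicity"] = dict(toxicity_summary)
    else:
        excl = results["excluded_reason"].fillna("")
        n_excl = int((excl != "").sum())
        out["toxicity"] = dict(
            n_total=n_total, n_excluded=n_excl,
            percent_excluded=100.0 * n_excl / n_total if n_total else 0.0,
            **{state: int((excl == f"toxic:{state}").sum())
               for state in ("death", "delayed", "malformed")})
    return out
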