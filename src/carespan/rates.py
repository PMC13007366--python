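"""Baseline care-state proportions, death rates, standardization, comparison.

All tables are tidy pandas DataFrames carrying an analytic variance column
so that standardized estimates and between-population comparisons can
propagate Wald-type uncertainty:

* proportions — Bernoulli variance ``p (1 - p) / n``;
* rates per 1000 person-years — Poisson variance ``1000^2 D / PY^2``.

Age standardization weights stratum-specific values by a reference age
structure, by default the combined two-population baseline cohort.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .cohort import Cohort, as_cohort
from .records import DAYS_PER_YEAR
from .states import EndReason, STATE_LABELS

Z95 = 1.96

AGE_GROUP_EDGES = (75.0, 80.0, 85.0, 90.0, 95.0, 100.0)


def age_group_labels(edges=AGE_GROUP_EDGES) -> list[str]:
    labels = [f"{int(a)}-{int(b) - 1}" for a, b in zip(edges, edges[1:])]
    labels.append(f"{int(edges[-1])}+")
    return labels


def assign_age_groups(ages: np.ndarray, edges=AGE_GROUP_EDGES) -> np.ndarray:
    """Half-open 5-year groups [75,80), ..., [100, inf); below range -> None."""
    labels = age_group_labels(edges)
    idx = np.digitize(ages, edges) - 1
    out = np.array([labels[i] if i >= 0 else None for i in idx], dtype=object)
    return out


def baseline_month_states(cohort: Cohort, baseline_date: date) -> np.ndarray:
    """State in the calendar month before the baseline month, vectorized.

    Returns -1 for persons not under observation during that month.  Panel
    months are assumed to align with the calendar months of ``obs_start``.
    """
    start_month = cohort.obs_start.astype("datetime64[M]")
    ref_month = np.datetime64(f"{baseline_date.year:04d}-{baseline_date.month:02d}", "M") - 1
    m = (ref_month - start_month).astype(np.int64)
    valid = (m >= 0) & (m < cohort.n_months)
    out = np.full(len(cohort), -1, dtype=np.int64)
    rows = np.flatnonzero(valid)
    out[rows] = cohort.states[rows, m[rows]]
    return out


def _at_risk_at_baseline(cohort: Cohort, baseline_date: date) -> np.ndarray:
    b = np.datetime64(baseline_date, "D")
    return (cohort.obs_start <= b) & (cohort.obs_end > b)


def _wald_proportion_ci(p: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    se = np.sqrt(p * (1 - p) / n)
    return np.clip(p - Z95 * se, 0, 1), np.clip(p + Z95 * se, 0, 1)


def baseline_proportions(data, baseline_date: date,
                         edges=AGE_GROUP_EDGES) -> pd.DataFrame:
    """Proportion of the at-risk baseline population in each care state.

    One row per population x sex x 5-year age group x state, with count,
    denominator, proportion, analytic variance and Wald 95% CI (clipped to
    [0, 1]).  Cells with zero denominator are not emitted.
    """
    cohort = as_cohort(data)
    at_risk = _at_risk_at_baseline(cohort, baseline_date)
    states = baseline_month_states(cohort, baseline_date)
    keep = at_risk & (states >= 0)
    ages = cohort.age_at(baseline_date)
    groups = assign_age_groups(ages, edges)
    keep &= np.array([g is not None for g in groups])

    df = pd.DataFrame({
        "population": cohort.population[keep],
        "sex": cohort.sex[keep],
        "age_group": groups[keep],
        "state": [STATE_LABELS[int(s)] for s in states[keep]],
    })
    counts = (df.value_counts(["population", "sex", "age_group", "state"])
                .rename("count").reset_index())
    full = _complete_states(counts)
    denom = (full.groupby(["population", "sex", "age_group"])["count"]
                 .transform("sum"))
    full["denominator"] = denom
    full = full[full["denominator"] > 0].copy()
    p = full["count"] / full["denominator"]
    full["proportion"] = p
    full["var"] = p * (1 - p) / full["denominator"]
    full["lower"], full["upper"] = _wald_proportion_ci(
        p.to_numpy(), full["denominator"].to_numpy())
    return full.sort_values(["population", "sex", "age_group", "state"],
                            ignore_index=True)


def _complete_states(counts: pd.DataFrame) -> pd.DataFrame:
    """Ensure every observed cell lists all three transient states."""
    state_labels = [STATE_LABELS[i] for i in range(3)]
    cells = counts[["population", "sex", "age_group"]].drop_duplicates()
    grid = cells.merge(pd.DataFrame({"state": state_labels}), how="cross")
    out = grid.merge(counts, on=["population", "sex", "age_group", "state"],
                     how="left")
    out["count"] = out["count"].fillna(0).astype(np.int64)
    return out


def proportion_from_counts(count: int, denominator: int) -> dict[str, float]:
    """Closed-form proportion with Bernoulli Wald 95% CI from printed counts."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    p = count / denominator
    se = np.sqrt(p * (1 - p) / denominator)
    return {
        "proportion": p,
        "lower": max(p - Z95 * se, 0.0),
        "upper": min(p + Z95 * se, 1.0),
        "var": p * (1 - p) / denominator,
    }


def death_rates(data, baseline_date: date, follow_up_years: float,
                edges=AGE_GROUP_EDGES, include_total: bool = False) -> pd.DataFrame:
    """Death rates per 1000 person-years by baseline care state.

    The state is fixed at baseline (deaths after a later care change still
    count in the baseline state's cell) and exposure runs from baseline to
    death, censoring, or baseline + follow-up.  Wald 95% CI uses Poisson
    variance; zero-death cells get a degenerate (0, 0) interval and are
    flagged ``low_information``.  With ``include_total`` an extra
    ``state='all'`` stratum pools the care states.
    """
    cohort = as_cohort(data)
    at_risk = _at_risk_at_baseline(cohort, baseline_date)
    states = baseline_month_states(cohort, baseline_date)
    keep = at_risk & (states >= 0)
    ages = cohort.age_at(baseline_date)
    groups = assign_age_groups(ages, edges)
    keep &= np.array([g is not None for g in groups])

    b = np.datetime64(baseline_date, "D")
    days = (cohort.obs_end - b).astype(float)
    window = follow_up_years * DAYS_PER_YEAR
    py = np.clip(days, 0, window) / DAYS_PER_YEAR
    dead = (cohort.end_reason == EndReason.DEATH) & (days <= window)

    df = pd.DataFrame({
        "population": cohort.population[keep],
        "sex": cohort.sex[keep],
        "age_group": groups[keep],
        "state": [STATE_LABELS[int(s)] for s in states[keep]],
        "deaths": dead[keep].astype(np.int64),
        "person_years": py[keep],
    })
    frames = [df]
    if include_total:
        total = df.copy()
        total["state"] = "all"
        frames.append(total)
    out = (pd.concat(frames)
             .groupby(["population", "sex", "age_group", "state"], as_index=False)
             .agg(deaths=("deaths", "sum"), person_years=("person_years", "sum")))
    out = out[out["person_years"] > 0].copy()
    rate = 1000.0 * out["deaths"] / out["person_years"]
    se = 1000.0 * np.sqrt(out["deaths"]) / out["person_years"]
    out["rate"] = rate
    out["var"] = se**2
    out["lower"] = np.maximum(rate - Z95 * se, 0.0)
    out["upper"] = rate + Z95 * se
    out["low_information"] = out["deaths"] == 0
    return out.sort_values(["population", "sex", "age_group", "state"],
                           ignore_index=True)


def standard_weights(proportions: pd.DataFrame,
                     by: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Reference age structure of the combined populations.

    Weights are combined-cohort baseline count shares per age group within
    each ``by`` stratum (``('sex',)`` for the total population,
    ``('sex', 'state')`` to stratify by baseline care state as well); they
    sum to 1 within each stratum.
    """
    cols = list(by) + ["age_group"]
    counts = proportions.groupby(cols, as_index=False)["count"].sum()
    total = counts.groupby(list(by))["count"].transform("sum")
    counts["weight"] = counts["count"] / total
    return counts[cols + ["weight"]]


def standardize(table: pd.DataFrame, weights: pd.DataFrame,
                value: str = "rate") -> pd.DataFrame:
    """Age-standardize a rate or proportion table.

    ``value`` names the estimate column; the table must carry a matching
    ``var`` column.  Every age group present in the table must have a
    weight (hard error listing any missing groups).  Returns one row per
    remaining stratum with ``age_group='standardized'``, the weighted
    estimate, variance ``sum w^2 var`` and Wald 95% CI.
    """
    join = [c for c in weights.columns if c not in ("age_group", "weight", "count")]
    merged = table.merge(weights, on=join + ["age_group"], how="left")
    missing = merged[merged["weight"].isna()]["age_group"].unique().tolist()
    if missing:
        raise ValueError(f"no standard weight for age groups: {missing}")
    group_cols = [c for c in ("population", "sex", "state") if c in table.columns]
    rows = []
    for key, grp in merged.groupby(group_cols):
        w = grp["weight"].to_numpy()
        est = float((w * grp[value]).sum())
        var = float((w**2 * grp["var"]).sum())
        se = np.sqrt(var)
        rows.append(dict(zip(group_cols, key if isinstance(key, tuple) else (key,)),
                         age_group="standardized", **{value: est},
                         var=var, lower=est - Z95 * se, upper=est + Z95 * se))
    return pd.DataFrame(rows)


def compare(table_a: pd.DataFrame, table_b: pd.DataFrame,
            mode: str = "difference", value: str = "rate",
            label: str | None = None) -> pd.DataFrame:
    """Stratum-wise difference (A - B) or ratio (A / B) with Wald 95% CIs.

    The population-order convention is explicit: the first table is the
    minuend/numerator, and the ``comparison`` column echoes it.  Difference
    CIs are on the natural scale with summed variances; ratio CIs are Wald
    intervals on the log scale.  Ratios with a zero denominator are emitted
    as missing with ``undefined=True``.
    """
    if mode not in ("difference", "ratio"):
        raise ValueError("mode must be 'difference' or 'ratio'")
    keys = [c for c in ("sex", "age_group", "state") if c in table_a.columns
            and c in table_b.columns]
    la = table_a["population"].iloc[0] if "population" in table_a.columns else "A"
    lb = table_b["population"].iloc[0] if "population" in table_b.columns else "B"
    cols = keys + [value, "var"]
    merged = table_a[cols].merge(table_b[cols], on=keys, suffixes=("_a", "_b"))
    a, b = merged[f"{value}_a"], merged[f"{value}_b"]
    va, vb = merged["var_a"], merged["var_b"]
    out = merged[keys].copy()
    if mode == "difference":
        est = a - b
        se = np.sqrt(va + vb)
        out["difference"] = est
        out["lower"] = est - Z95 * se
        out["upper"] = est + Z95 * se
        out["comparison"] = label or f"{la}-{lb}"
    else:
        undefined = b == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            est = np.where(undefined, np.nan, a / b)
            var_log = va / a**2 + vb / b**2
            lo = est * np.exp(-Z95 * np.sqrt(var_log))
            hi = est * np.exp(Z95 * np.sqrt(var_log))
        out["ratio"] = est
        out["lower"] = np.where(undefined, np.nan, lo)
        out["upper"] = np.where(undefined, np.nan, hi)
        out["undefined"] = undefined
        out["comparison"] = label or f"{la}/{lb}"
    return out
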