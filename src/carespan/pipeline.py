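"""End-to-end pipeline: simulate/load, estimate, life table, rates, decompose.

Produces plain-CSV report tables (baseline composition, life expectancy,
proportions by age, death rates with standardized comparisons, and the
mortality decomposition), a human-readable text summary, and a JSON
manifest with the seed, package versions and a config hash — enough to
reproduce every report byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import BootstrapSpec, bootstrap
from .cohort import Cohort, as_cohort
from .decomposition import decompose_table
from .estimation import count_transitions, smooth_probabilities
from .lifetable import state_expectancies
from .rates import (baseline_proportions, compare, death_rates,
                    standard_weights, standardize)
from .records import follow_up_end, read_panel
from .simulate import ScenarioConfig, default_scenario, scenario_from_dict, \
    scenario_to_dict, simulate_cohort

log = logging.getLogger("carespan.pipeline")

REPORT_FILES = (
    "baseline_composition.csv",
    "life_expectancy.csv",
    "proportions_by_age.csv",
    "death_rates.csv",
    "decomposition.csv",
)


@dataclass
class RunConfig:
    """Configuration for one full analysis run."""

    scenario: ScenarioConfig
    out_dir: Path
    panel_path: Path | None = None          # analyse an existing panel instead
    index_age: float = 75.0
    bootstrap_replicates: int = 100
    bootstrap_seed: int | None = None
    comparison: tuple[str, str] | None = None  # (minuend, subtrahend)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.comparison is None:
            # default: second-listed population minus first-listed
            self.comparison = (self.scenario.populations[1],
                               self.scenario.populations[0])
        if self.bootstrap_seed is None:
            self.bootstrap_seed = self.scenario.seed + 1

    @property
    def baseline_date(self) -> date:
        return self.scenario.baseline_date

    @property
    def follow_up_years(self) -> float:
        return self.scenario.follow_up_years

    def to_dict(self) -> dict:
        return {
            "scenario": scenario_to_dict(self.scenario),
            "panel_path": str(self.panel_path) if self.panel_path else None,
            "index_age": self.index_age,
            "bootstrap_replicates": self.bootstrap_replicates,
            "bootstrap_seed": self.bootstrap_seed,
            "comparison": list(self.comparison),
        }

    @classmethod
    def from_dict(cls, data: dict, out_dir) -> "RunConfig":
        return cls(
            scenario=scenario_from_dict(data["scenario"]),
            out_dir=out_dir,
            panel_path=Path(data["panel_path"]) if data.get("panel_path") else None,
            index_age=float(data.get("index_age", 75.0)),
            bootstrap_replicates=int(data.get("bootstrap_replicates", 100)),
            bootstrap_seed=data.get("bootstrap_seed"),
            comparison=tuple(data["comparison"]) if data.get("comparison") else None,
        )

    @classmethod
    def from_yaml(cls, path, out_dir) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), out_dir)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def life_expectancy_statistic(index_age: float, window_end=None):
    """Statistic: smoothed-surface LE vector (total + 3 states) for a stratum.

    The initial distribution is the observed state distribution among those
    at risk within a year of the index age, recomputed per (re)sample.
    ``window_end`` is the administrative end of follow-up, passed through to
    the transition counter.
    """

    def stat(cohort: Cohort) -> np.ndarray:
        counts = count_transitions(cohort, window_end=window_end)
        surface = smooth_probabilities(counts)
        init = counts.observed_initial_distribution(index_age, window=1.0)
        res = state_expectancies(surface, index_age, init)
        return np.concatenate([[res.total], res.by_state])

    return stat


def _le_table(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    rows = []
    window = follow_up_end(config.baseline_date, config.follow_up_years)
    stat = life_expectancy_statistic(config.index_age, window_end=window)
    for (pop, sex), mask in cohort.strata():
        sub = cohort.subset(np.flatnonzero(mask))
        if config.bootstrap_replicates >= 2:
            spec = BootstrapSpec(n_replicates=config.bootstrap_replicates,
                                 strata=(), seed=config.bootstrap_seed)
            res = bootstrap(sub, stat, spec)
            point, lo, hi = np.asarray(res.point), res.lower, res.upper
        else:
            point = stat(sub)
            lo = hi = np.full(4, np.nan)
        for name, i in (("total", 0), ("no_care", 1), ("home_care", 2),
                        ("care_home", 3)):
            rows.append({"population": pop, "sex": sex,
                         "index_age": config.index_age, "quantity": name,
                         "estimate": point[i], "lower": lo[i], "upper": hi[i]})
    return pd.DataFrame(rows)


def _decomposition_with_ci(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    pop_a, pop_b = config.comparison

    def tables(c: Cohort):
        props = baseline_proportions(c, config.baseline_date)
        rates = death_rates(c, config.baseline_date, config.follow_up_years)
        weights = standard_weights(props, by=("sex",))
        return props, rates, weights

    props, rates, weights = tables(cohort)
    table = decompose_table(rates, props, pop_a, pop_b, weights=weights)
    value_cols = [c for c in table.columns if c not in ("sex", "age_group",
                                                        "comparison")]
    if config.bootstrap_replicates >= 2:
        key = table.set_index(["sex", "age_group"]).index

        def stat(c: Cohort) -> np.ndarray:
            p, r, w = tables(c)
            t = decompose_table(r, p, pop_a, pop_b, weights=w)
            t = t.set_index(["sex", "age_group"]).reindex(key)
            return t[value_cols].to_numpy(dtype=float).ravel()

        spec = BootstrapSpec(n_replicates=config.bootstrap_replicates,
                             seed=config.bootstrap_seed + 1)
        res = bootstrap(cohort, stat, spec)
        lo = np.asarray(res.lower).reshape(len(table), len(value_cols))
        hi = np.asarray(res.upper).reshape(len(table), len(value_cols))
        for j, col in enumerate(value_cols):
            table[f"{col}_lower"] = lo[:, j]
            table[f"{col}_upper"] = hi[:, j]
    return table


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Returns a mapping from report name to written path.  Reruns with the
    same config produce byte-identical reports.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if config.panel_path is not None:
        log.info("loading panel from %s", config.panel_path)
        cohort = as_cohort(read_panel(config.panel_path))
    else:
        log.info("simulating scenario (seed=%d)", config.scenario.seed)
        cohort = simulate_cohort(config.scenario)
    log.info("cohort: %d individuals", len(cohort))

    stage = "baseline composition"
    try:
        props = baseline_proportions(cohort, config.baseline_date)
        props.to_csv(out / "baseline_composition.csv", index=False)
        written["baseline_composition"] = out / "baseline_composition.csv"

        stage = "life expectancy"
        le = _le_table(cohort, config)
        le.to_csv(out / "life_expectancy.csv", index=False)
        written["life_expectancy"] = out / "life_expectancy.csv"

        stage = "proportions by age"
        weights_sex = standard_weights(props, by=("sex",))
        std_props = standardize(props, weights_sex, value="proportion")
        pop_a, pop_b = config.comparison
        prop_diff = compare(std_props[std_props["population"] == pop_a],
                            std_props[std_props["population"] == pop_b],
                            mode="difference", value="proportion")
        props_report = pd.concat([props, std_props], ignore_index=True)
        props_report.to_csv(out / "proportions_by_age.csv", index=False)
        prop_diff.to_csv(out / "proportion_differences.csv", index=False)
        written["proportions_by_age"] = out / "proportions_by_age.csv"

        stage = "death rates"
        rates = death_rates(cohort, config.baseline_date, config.follow_up_years,
                            include_total=True)
        weights_state = standard_weights(props, by=("sex", "state"))
        weights_state_all = standard_weights(props, by=("sex",)).assign(state="all")
        w_all = pd.concat([weights_state, weights_state_all], ignore_index=True)
        std_rates = standardize(rates, w_all, value="rate")
        rate_diff = compare(std_rates[std_rates["population"] == pop_a],
                            std_rates[std_rates["population"] == pop_b],
                            mode="difference")
        rate_ratio = compare(std_rates[std_rates["population"] == pop_a],
                             std_rates[std_rates["population"] == pop_b],
                             mode="ratio")
        rates_report = pd.concat([rates, std_rates], ignore_index=True)
        rates_report.to_csv(out / "death_rates.csv", index=False)
        pd.concat([rate_diff, rate_ratio], ignore_index=True).to_csv(
            out / "rate_comparisons.csv", index=False)
        written["death_rates"] = out / "death_rates.csv"

        stage = "decomposition"
        decomp = _decomposition_with_ci(cohort, config)
        decomp.to_csv(out / "decomposition.csv", index=False)
        written["decomposition"] = out / "decomposition.csv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.scenario.seed,
        "bootstrap_seed": config.bootstrap_seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "n_individuals": int(len(cohort)),
        "reports": sorted(p.name for p in written.values()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = out / "manifest.json"

    summary = _text_summary(le, std_rates, decomp, config)
    (out / "summary.txt").write_text(summary)
    written["summary"] = out / "summary.txt"
    log.info("wrote %d report files to %s", len(written), out)
    return written


def _text_summary(le: pd.DataFrame, std_rates: pd.DataFrame,
                  decomp: pd.DataFrame, config: RunConfig) -> str:
    pop_a, pop_b = config.comparison
    lines = [
        "carespan pipeline summary",
        f"seed={config.scenario.seed}  follow_up={config.follow_up_years}y  "
        f"baseline={config.baseline_date.isoformat()}",
        "",
        f"Remaining life expectancy at age {config.index_age} (years):",
    ]
    for _, r in le[le["quantity"] == "total"].iterrows():
        lines.append(f"  {r['population']:>3} {r['sex']:<7} "
                     f"{r['estimate']:6.2f}  [{r['lower']:.2f}, {r['upper']:.2f}]")
    lines.append("")
    lines.append(f"Age-standardized death rates per 1000 PY and decomposition "
                 f"({pop_a} - {pop_b}):")
    std = decomp[decomp["age_group"] == "standardized"]
    for _, r in std.iterrows():
        lines.append(
            f"  {r['sex']:<7} total diff {r['total_difference']:+8.2f}  "
            f"composition {r['composition']:+8.2f}  "
            f"no_care {r['rate_no_care']:+8.2f}  "
            f"home_care {r['rate_home_care']:+8.2f}  "
            f"care_home {r['rate_care_home']:+8.2f}"
        )
    lines.append("")
    return "\n".join(lines) + "\n"


def demo_config(out_dir, seed: int = 0, cohort_size: int = 2000,
                bootstrap_replicates: int = 0) -> RunConfig:
    """Small, quick default run used by the CLI demo and smoke tests."""
    return RunConfig(
        scenario=default_scenario(seed=seed, cohort_size=cohort_size),
        out_dir=out_dir,
        bootstrap_replicates=bootstrap_replicates,
    )
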