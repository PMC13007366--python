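"""Percentile bootstrap over individuals, stratified by population and sex.

The resampling unit is the whole individual trajectory, preserving
within-person serial dependence; per-stratum sample sizes are kept exactly.
Replicate seeds are derived from the master seed through a counter stream,
so results are reproducible and independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, as_cohort


@dataclass
class BootstrapSpec:
    n_replicates: int = 1000
    strata: tuple[str, ...] = ("population", "sex")
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    max_failure_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("percentiles must be strictly ordered within (0, 100)")


@dataclass
class BootstrapResult:
    """Point estimate with percentile confidence bounds.

    ``point``, ``lower`` and ``upper`` are scalars, arrays or Series
    matching the statistic's output; ``replicates`` stacks the per-replicate
    values (failures excluded).
    """

    point: object
    lower: object
    upper: object
    replicates: np.ndarray
    n_failed: int
    index: object = None
    failures: list[str] = field(default_factory=list)

    def interval(self, name=None) -> tuple[float, float]:
        if name is None:
            return float(np.asarray(self.lower).ravel()[0]), \
                   float(np.asarray(self.upper).ravel()[0])
        i = list(self.index).index(name)
        return float(np.asarray(self.lower)[i]), float(np.asarray(self.upper)[i])


def _stratum_indices(cohort: Cohort, strata: tuple[str, ...]) -> list[np.ndarray]:
    if not strata:
        return [np.arange(len(cohort))]
    keys = [getattr(cohort, s) for s in strata]
    combined = np.array(list(zip(*(k.tolist() for k in keys))), dtype=object)
    seen: dict[tuple, list[int]] = {}
    for i, key in enumerate(map(tuple, combined)):
        seen.setdefault(key, []).append(i)
    return [np.asarray(v) for v in seen.values()]


def _as_vector(value):
    if isinstance(value, pd.Series):
        return value.to_numpy(dtype=float), value.index
    arr = np.asarray(value, dtype=float)
    return np.atleast_1d(arr), None


def bootstrap(data, statistic, spec: BootstrapSpec | None = None) -> BootstrapResult:
    """Percentile-bootstrap CI for a pure statistic of a cohort.

    ``statistic`` maps a cohort to a scalar, 1-D array or Series.  Persons
    are resampled with replacement within each stratum; the statistic is
    recomputed per replicate and the CI taken as empirical percentiles.
    Replicates on which the statistic raises are dropped with a warning as
    long as they stay under ``max_failure_fraction``; otherwise a hard error
    reports the failure mode.
    """
    spec = spec or BootstrapSpec()
    cohort = as_cohort(data)
    point_raw = statistic(cohort)
    point_vec, index = _as_vector(point_raw)
    groups = _stratum_indices(cohort, spec.strata)

    reps = []
    failures: list[str] = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, r])
        idx = np.concatenate([g[rng.integers(0, len(g), size=len(g))] for g in groups])
        try:
            value, _ = _as_vector(statistic(cohort.subset(idx)))
            if value.shape != point_vec.shape:
                raise ValueError("statistic changed shape across replicates")
            reps.append(value)
        except Exception as exc:  # noqa: BLE001 - failure bookkeeping by contract
            failures.append(f"replicate {r}: {type(exc).__name__}: {exc}")
    allowed = max(1, int(spec.max_failure_fraction * spec.n_replicates))
    if failures:
        if len(failures) > allowed:
            raise RuntimeError(
                f"statistic failed on {len(failures)}/{spec.n_replicates} bootstrap "
                f"replicates (> {allowed} allowed); first failure: {failures[0]}"
            )
        warnings.warn(
            f"excluded {len(failures)} failed bootstrap replicate(s); "
            f"first: {failures[0]}",
            stacklevel=2,
        )
    rep_arr = np.vstack(reps)
    lo, hi = np.percentile(rep_arr, spec.percentiles, axis=0)
    if index is not None:
        return BootstrapResult(point=point_raw, lower=pd.Series(lo, index=index),
                               upper=pd.Series(hi, index=index),
                               replicates=rep_arr, n_failed=len(failures),
                               index=index, failures=failures)
    if np.isscalar(point_raw) or np.asarray(point_raw).ndim == 0:
        return BootstrapResult(point=float(point_vec[0]), lower=float(lo[0]),
                               upper=float(hi[0]), replicates=rep_arr,
                               n_failed=len(failures), failures=failures)
    return BootstrapResult(point=point_vec, lower=lo, upper=hi,
                           replicates=rep_arr, n_failed=len(failures),
                           failures=failures)
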