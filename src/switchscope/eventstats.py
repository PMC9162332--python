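"""Dependency statistics for switching events across microfluidic traps.

Events per trap are counted under three schemes of decreasing granularity:

1. every synchronous mother-daughter switching pair is an independent event;
2. pairs connected through uninterrupted chains of switching cells (direct
   patterns, including the four-cell pattern) merge into one event;
3. pairs that share an ancestor within the trap pedigree (mixed-fate
   pedigrees) also merge.

The null model is a Poisson rate per trap estimated solely from the
zero-event class, lambda = -ln(n0 / N); goodness of fit uses a Pearson
chi-squared statistic with a Monte-Carlo p-value from multinomial draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, DataError
from .lineage import SwitchGroup, parent_name

__all__ = [
    "TrapEventTable", "PoissonNull", "GofResult",
    "count_events", "estimate_lambda", "poisson_expected",
    "gof_monte_carlo", "sector_frequency",
]

SCHEMES = (1, 2, 3)


@dataclass
class TrapEventTable:
    """Per-trap switching-event counts under one counting scheme."""

    counts: pd.Series          # index: trap_id, values: nonnegative ints
    scheme: int

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        if (self.counts < 0).any():
            raise DataError("event counts must be nonnegative")
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown counting scheme: {self.scheme!r}")

    @property
    def n_traps(self) -> int:
        return len(self.counts)

    @property
    def n_zero(self) -> int:
        return int((self.counts == 0).sum())

    def class_counts(self, k_max: int) -> np.ndarray:
        """Observed counts per event-number class, pooling k >= k_max."""
        out = np.zeros(k_max + 1, dtype=int)
        for c in self.counts:
            out[min(c, k_max)] += 1
        return out


def _merge_groups_scheme3(groups: list[SwitchGroup]) -> int:
    """Number of ancestor-sharing clusters among switching groups.

    Two groups merge iff any of their cells share a common ancestor within
    the recorded pedigree (i.e. their dotted names share a leading token).
    """
    reps = [g.cells[0].split(".")[0] for g in groups]
    return len(set(reps))


def count_events(groups_by_trap: dict[str, list[SwitchGroup]],
                 scheme: int) -> TrapEventTable:
    """Count switching events per trap under one scheme.

    ``groups_by_trap`` maps every trap (including event-free ones, with an
    empty list) to its switching groups from
    :func:`~switchscope.lineage.group_switching_cells`.  Scheme 1 counts
    synchronous mother-daughter pairs (a group detected without any
    complete pair still counts one event); scheme 2 counts connected
    groups; scheme 3 counts ancestor-sharing clusters of groups.
    """
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown counting scheme: {scheme!r}")
    counts = {}
    for trap_id, groups in groups_by_trap.items():
        if scheme == 1:
            n = sum(max(len(g.pairs), 1) for g in groups)
        elif scheme == 2:
            n = len(groups)
        else:
            n = _merge_groups_scheme3(groups) if groups else 0
        counts[trap_id] = n
    series = pd.Series(counts, name=f"scheme{scheme}").sort_index()
    series.index.name = "trap_id"
    return TrapEventTable(counts=series, scheme=scheme)


@dataclass
class PoissonNull:
    """Poisson expectation over pooled event-number classes."""

    lam: float
    n_traps: int
    expected: np.ndarray       # class counts for k = 0..k_max-1, tail pooled

    @property
    def k_max(self) -> int:
        return len(self.expected) - 1

    @property
    def probs(self) -> np.ndarray:
        return self.expected / self.n_traps


def estimate_lambda(n_zero: int, n_total: int) -> float:
    """Zero-class Poisson rate estimate, lambda = -ln(n0 / N).

    This is the maximum-likelihood rate given only the zero/nonzero
    dichotomy of traps.
    """
    if not (0 < n_zero <= n_total):
        raise DataError(
            f"zero-class estimator requires 0 < n_zero <= n_total, "
            f"got ({n_zero}, {n_total})")
    return -math.log(n_zero / n_total)


def poisson_expected(lam: float, n_traps: int, k_max: int = 4) -> PoissonNull:
    """Expected class counts n * P(K = k), pooling k >= k_max into a tail."""
    if lam < 0:
        raise DataError("lambda must be >= 0")
    if k_max < 1:
        raise ConfigError("k_max must be >= 1")
    k = np.arange(k_max)
    pmf = stats.poisson.pmf(k, lam)
    tail = 1.0 - pmf.sum()
    probs = np.concatenate([pmf, [max(tail, 0.0)]])
    probs = probs / probs.sum()
    return PoissonNull(lam=lam, n_traps=n_traps, expected=probs * n_traps)


class GofResult(NamedTuple):
    statistic: float
    p_value: float
    reps: int
    dof_classes: int


def gof_monte_carlo(observed: TrapEventTable, null: PoissonNull,
                    reps: int = 2000,
                    seed: Optional[int] = None) -> GofResult:
    """Chi-squared goodness of fit with a Monte-Carlo p-value.

    The Pearson statistic compares observed class counts to the Poisson
    expectation; the p-value is (1 + #{simulated >= observed}) / (reps + 1)
    over multinomial draws of ``n_traps`` traps from the null class
    probabilities (add-one estimator, never exactly zero).
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if observed.n_traps != null.n_traps:
        raise DataError("observed table and null cover different trap totals")
    rng = np.random.default_rng(seed)
    obs = observed.class_counts(null.k_max).astype(float)
    exp = null.expected
    if np.any(exp <= 0):
        keep = exp > 0
        if np.any(obs[~keep] > 0):
            raise DataError("observed events in a zero-probability class")
        obs, exp = obs[keep], exp[keep]
    stat = float(np.sum((obs - exp) ** 2 / exp))
    sims = rng.multinomial(null.n_traps, exp / exp.sum(), size=reps)
    sim_stats = np.sum((sims - exp) ** 2 / exp, axis=1)
    p = (1.0 + float(np.sum(sim_stats >= stat - 1e-12))) / (reps + 1.0)
    return GofResult(statistic=stat, p_value=p, reps=reps,
                     dof_classes=len(exp))


class SectorFrequency(NamedTuple):
    proportion: float
    std_error: float
    n: int


def sector_frequency(n_sectored: int, n_colonies: int) -> SectorFrequency:
    """Plate-assay switching frequency with its sample-proportion SE.

    p_hat = k/n and SE = sqrt(p_hat (1 - p_hat) / n).
    """
    if n_colonies <= 0:
        raise DataError("n_colonies must be > 0")
    if not (0 <= n_sectored <= n_colonies):
        raise DataError("n_sectored must be between 0 and n_colonies")
    p = n_sectored / n_colonies
    se = math.sqrt(p * (1.0 - p) / n_colonies)
    return SectorFrequency(p, se, n_colonies)
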