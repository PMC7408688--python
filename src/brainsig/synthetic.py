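"""Seeded generators for every input the pipeline consumes.

The study's actual inputs (a reanalyzed microarray matrix and the METABRIC
survival cohort) are not publicly deposited, so all stages are exercised
on synthetic data with the statistical structure the analysis assumes:

* a 9-sample log2 expression matrix with planted RG-specific up/down
  genes.  The seven MSG lines carry independent between-line biological
  variation (``noise_sd``); the two RG lines are generated as
  near-replicates of a common RG expression state whose within-pair
  scatter is ``rg_inconsistency_sd`` — consistency of the rapid-growth
  pair is the premise of the within-RG logFC filter, and planting it in
  the generator makes recovery of the planted sets a sharp oracle;
* exponential tumor-growth radiance series with group-dependent doubling
  times and multiplicative lognormal measurement noise;
* a right-censored proportional-hazards cohort whose event hazard depends
  log-linearly on selected gene expressions.

Every generator takes a single seed and touches no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .expression import (
    DEFAULT_CELL_LINES,
    ExpressionMatrix,
    GroupAssignment,
    default_group_assignment,
)
from .growth import BioluminescenceSeries
from .survival import SurvivalCohort


@dataclass
class SyntheticExpressionSpec:
    """Planted-signature expression simulation parameters.

    effect_delta is the log2 shift applied to the RG pair for planted
    genes; noise_sd the between-MSG-line log2 sd; rg_inconsistency_sd the
    residual scatter between the two RG lines; baselines are drawn
    uniformly from baseline_mean_range (log2 intensity units).
    """

    n_genes: int = 2000
    n_up: int = 40
    n_down: int = 40
    effect_delta: float = 2.5
    noise_sd: float = 0.3
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    rg_inconsistency_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise FormatError("planted counts exceed n_genes")
        if min(self.noise_sd, self.rg_inconsistency_sd) < 0:
            raise FormatError("standard deviations must be >= 0")
        if self.n_genes < 1:
            raise FormatError("n_genes must be positive")


@dataclass
class SyntheticCohortSpec:
    """Proportional-hazards survival cohort parameters.

    ``genes`` maps gene name -> log hazard ratio per SD of expression
    (0 = null gene).  Times are in months: exponential baseline hazard,
    independent exponential censoring, administrative censoring at
    horizon_months.
    """

    n_patients: int = 400
    genes: Mapping[str, float] = field(default_factory=lambda: {"GENE_1": 0.7})
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.004
    horizon_months: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise FormatError("n_patients must be >= 4")
        if min(self.baseline_hazard, self.censoring_rate) <= 0:
            raise FormatError("rates must be positive")
        if self.horizon_months <= 0:
            raise FormatError("horizon must be positive")


@dataclass
class SyntheticGrowthSpec:
    """Exponential bioluminescence growth parameters.

    ``doubling_times`` maps cell line -> doubling time in days;
    ``n_mice`` maps cell line -> number of mice (defaults to the study's
    design: 4 for HCC-1419 and HCC-2218, 3 otherwise).  noise_cv is the
    coefficient of variation of the multiplicative lognormal measurement
    noise, applied at every day including day 0.
    """

    doubling_times: Mapping[str, float] = field(
        default_factory=lambda: {
            line: (3.5 if line in ("UACC-893", "MDA-MB-453") else 14.0)
            for line in DEFAULT_CELL_LINES
        }
    )
    n_mice: Mapping[str, int] | int = field(
        default_factory=lambda: {
            line: (4 if line in ("HCC-1419", "HCC-2218") else 3)
            for line in DEFAULT_CELL_LINES
        }
    )
    days: Sequence[int] = (0, 7, 14, 21, 28)
    radiance0: float = 1e5
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(dt <= 0 for dt in self.doubling_times.values()):
            raise FormatError("doubling times must be positive")
        mice = self.mice_per_line()
        if any(n < 1 for n in mice.values()):
            raise FormatError("n_mice must be >= 1")
        if self.noise_cv < 0:
            raise FormatError("noise_cv must be >= 0")
        if self.radiance0 <= 0:
            raise FormatError("radiance0 must be positive")

    def mice_per_line(self) -> dict[str, int]:
        if isinstance(self.n_mice, int):
            return {line: self.n_mice for line in self.doubling_times}
        return {line: int(self.n_mice.get(line, 3)) for line in self.doubling_times}


def simulate_expression(
    spec: SyntheticExpressionSpec,
) -> tuple[ExpressionMatrix, GroupAssignment, dict[str, frozenset]]:
    """Simulate the nine-cell-line matrix with planted RG up/down genes.

    Returns the gene-level matrix (samples named as the nine cell lines,
    RG = UACC-893 and MDA-MB-453), the group assignment, and the planted
    truth ``{"up": ..., "down": ...}``.  Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    groups = default_group_assignment()
    rg, msg = groups.rg, groups.msg
    n = spec.n_genes
    feats = np.array([f"GENE_{i + 1:05d}" for i in range(n)])
    planted_sign = np.zeros(n)
    idx = rng.permutation(n)
    up_idx = idx[: spec.n_up]
    down_idx = idx[spec.n_up : spec.n_up + spec.n_down]
    planted_sign[up_idx] = 1.0
    planted_sign[down_idx] = -1.0

    lo, hi = spec.baseline_mean_range
    baseline = rng.uniform(lo, hi, n)
    rg_level = baseline + planted_sign * spec.effect_delta
    rg_vals = rg_level[:, None] + rng.normal(0, spec.rg_inconsistency_sd, (n, len(rg)))
    msg_vals = baseline[:, None] + rng.normal(0, spec.noise_sd, (n, len(msg)))
    data = pd.DataFrame(
        np.hstack([rg_vals, msg_vals]), index=feats, columns=rg + msg
    )[list(DEFAULT_CELL_LINES)]
    data.index.name = "feature"
    truth = {
        "up": frozenset(feats[up_idx]),
        "down": frozenset(feats[down_idx]),
    }
    return ExpressionMatrix(data, level="gene"), groups, truth


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[SurvivalCohort, dict[str, float]]:
    """Simulate a right-censored proportional-hazards cohort.

    Expression is iid standard normal per gene; the event time is
    exponential with rate baseline_hazard * exp(sum beta_g x_g); the
    censoring time is the minimum of an exponential(censoring_rate) draw
    and the administrative horizon.  Deterministic under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    betas = np.array([spec.genes[g] for g in genes], dtype=float)
    n = spec.n_patients
    X = rng.standard_normal((n, len(genes)))
    rate = spec.baseline_hazard * np.exp(X @ betas) if genes else np.full(
        n, spec.baseline_hazard
    )
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.minimum(
        rng.exponential(1.0 / spec.censoring_rate, n), spec.horizon_months
    )
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard the cohort invariant time > 0 against underflow at extreme rates
    time = np.maximum(time, np.finfo(float).tiny)
    data = pd.DataFrame(X, columns=genes)
    data.insert(0, "event", event)
    data.insert(0, "time", time)
    data.index = pd.Index([f"P{i + 1:05d}" for i in range(n)], name="id")
    return SurvivalCohort(data), dict(zip(genes, betas))


def simulate_bioluminescence(
    spec: SyntheticGrowthSpec,
) -> tuple[list[BioluminescenceSeries], dict[str, float]]:
    """Simulate per-mouse radiance series with exponential growth.

    radiance(t) = radiance0 * 2^(t / doubling_time) * exp(eps) with
    eps ~ N(0, sigma), sigma chosen so the multiplicative noise has the
    requested coefficient of variation; noise applies at day 0 too.
    Returns the series plus the per-line doubling-time truth.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    days = np.asarray(spec.days, dtype=int)
    series = []
    mice = spec.mice_per_line()
    for line, dt in spec.doubling_times.items():
        for m in range(mice[line]):
            clean = spec.radiance0 * 2.0 ** (days / dt)
            eps = rng.normal(0.0, sigma, len(days)) if sigma > 0 else 0.0
            series.append(
                BioluminescenceSeries(
                    cell_line=line,
                    mouse_id=f"{line}-m{m + 1}",
                    days=days,
                    radiance=clean * np.exp(eps),
                )
            )
    return series, {line: float(dt) for line, dt in spec.doubling_times.items()}
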