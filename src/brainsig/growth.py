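"""In vivo growth quantification from longitudinal bioluminescence.

Each intracranially injected mouse is imaged every seven days; per-mouse
radiance is normalized to its day-0 value (the growth ratio), cell lines
are summarized by the log10 of the mean day-28 ratio over their mice, and
the lines are split into a rapid-growth group (RG) and a medium-to-slow
group (MSG).  The numeric cutoff between the groups is not an a-priori
constant: the default classifier places it at the midpoint of the largest
gap in the sorted summaries, which is parameter-free and reproduces a clear
bimodal separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)


@dataclass
class BioluminescenceSeries:
    """Radiance of one mouse over days post-injection.

    Days must be strictly increasing and include day 0; radiance is the
    instrument's average-radiance readout and must be positive.
    """

    cell_line: str
    mouse_id: str
    days: np.ndarray
    radiance: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.radiance = np.asarray(self.radiance, dtype=float)
        if self.days.shape != self.radiance.shape or self.days.ndim != 1:
            raise FormatError("days and radiance must be 1-D and equally long")
        if len(self.days) == 0:
            raise FormatError("empty series")
        if not np.all(np.diff(self.days) > 0):
            raise FormatError("days must be strictly increasing")
        if self.days[0] != 0:
            raise FormatError(
                f"{self.cell_line}/{self.mouse_id}: day 0 measurement required"
            )
        if np.any(self.days < 0):
            raise FormatError("days must be non-negative")
        if np.any(self.radiance <= 0) or not np.all(np.isfinite(self.radiance)):
            raise FormatError("radiance must be positive and finite")


@dataclass
class GrowthRatioSeries:
    """Per-mouse radiance normalized to day 0 (ratio at day 0 is exactly 1)."""

    cell_line: str
    mouse_id: str
    days: np.ndarray
    ratio: np.ndarray


@dataclass
class GrowthClassification:
    """RG/MSG labels per cell line plus the log10-ratio threshold used."""

    labels: dict[str, str]
    threshold_used: float
    method: str

    @property
    def rg(self) -> list[str]:
        return sorted(l for l, g in self.labels.items() if g == "RG")

    @property
    def msg(self) -> list[str]:
        return sorted(l for l, g in self.labels.items() if g == "MSG")


def growth_ratio(s: BioluminescenceSeries) -> GrowthRatioSeries:
    """Normalize a radiance series to its day-0 value."""
    return GrowthRatioSeries(
        cell_line=s.cell_line,
        mouse_id=s.mouse_id,
        days=s.days.copy(),
        ratio=s.radiance / s.radiance[0],
    )


def summarize_growth(
    series: Iterable[GrowthRatioSeries],
    day: int = 28,
    aggregate: str = "mean",
) -> pd.Series:
    """Per cell line, log10 of the mean growth ratio at ``day`` over mice.

    ``aggregate='geometric'`` averages on the log scale instead of the
    arithmetic mean of ratios.  Every mouse of every line must have a
    measurement at the requested day.
    """
    if aggregate not in ("mean", "geometric"):
        raise FormatError(f"unknown aggregate {aggregate!r}")
    per_line: dict[str, list[float]] = {}
    for s in series:
        hits = np.flatnonzero(s.days == day)
        if hits.size == 0:
            raise FormatError(
                f"cell line {s.cell_line!r} mouse {s.mouse_id!r} has no day-{day} measurement"
            )
        per_line.setdefault(s.cell_line, []).append(float(s.ratio[hits[0]]))
    if not per_line:
        raise FormatError("no series provided")
    out = {}
    for line, ratios in per_line.items():
        if aggregate == "mean":
            out[line] = float(np.log10(np.mean(ratios)))
        else:
            out[line] = float(np.mean(np.log10(ratios)))
    return pd.Series(out, name=f"log10_mean_ratio_day{day}")


def classify_growth(
    summary: pd.Series,
    method: str = "max_gap",
    threshold: float | None = None,
) -> GrowthClassification:
    """Split cell lines into RG (fast) and MSG (slow) on the 1-D summary.

    ``max_gap`` sorts the log10 summaries, splits at the largest adjacent
    gap and labels the upper part RG, reporting the gap midpoint as the
    threshold.  ``fixed_threshold`` labels RG iff summary > threshold.
    """
    if len(summary) < 2:
        raise DegenerateInputError("need at least 2 cell lines to classify")
    if method == "fixed_threshold":
        if threshold is None:
            raise FormatError("fixed_threshold requires a threshold")
        cut = float(threshold)
    elif method == "max_gap":
        vals = summary.sort_values()
        gaps = np.diff(vals.to_numpy())
        if np.all(gaps == 0):
            raise DegenerateInputError(
                "all growth summaries equal; no valid RG/MSG split"
            )
        k = int(np.argmax(gaps))  # first largest gap on ties
        cut = float((vals.iloc[k] + vals.iloc[k + 1]) / 2)
    else:
        raise FormatError(f"unknown classification method {method!r}")
    labels = {line: ("RG" if v > cut else "MSG") for line, v in summary.items()}
    if method == "max_gap" and (
        all(g == "RG" for g in labels.values())
        or all(g == "MSG" for g in labels.values())
    ):  # cannot happen for a strictly positive max gap, kept as a guard
        raise DegenerateInputError("degenerate split")
    return GrowthClassification(labels=labels, threshold_used=cut, method=method)


def in_vitro_growth(
    counts: Mapping[str, float | Sequence[float]],
    n0: float = 1.5e5,
) -> pd.Series:
    """log2(N(4)/N0) per cell line; replicate counts are averaged after log2.

    ``n0`` is the number of cells seeded on day 0 (1.5e5 in the study's
    protocol); N(4) is the count on day 4.
    """
    if n0 <= 0:
        raise FormatError("n0 must be positive")
    out = {}
    for line, c in counts.items():
        arr = np.atleast_1d(np.asarray(c, dtype=float))
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise FormatError(f"cell counts for {line!r} must be positive and finite")
        out[line] = float(np.mean(np.log2(arr / n0)))
    return pd.Series(out, name="log2_n4_over_n0")


def marker_level(intensities: Mapping[str, float]) -> pd.Series:
    """log10 of a raw-integrated-density band quantification per cell line."""
    out = {}
    for line, v in intensities.items():
        if v <= 0 or not np.isfinite(v):
            raise FormatError(f"band intensity for {line!r} must be positive")
        out[line] = float(np.log10(v))
    return pd.Series(out, name="log10_rawintden")


def correlate_growth_with_covariate(
    summary: pd.Series,
    covariate: pd.Series,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlate in vivo growth with a per-line covariate.

    Pairs are joined on cell line; lines present in only one input are
    dropped with a warning.  Returns (coefficient, two-sided p-value).
    """
    shared = summary.index.intersection(covariate.index)
    dropped = set(summary.index).symmetric_difference(covariate.index)
    if dropped:
        logger.warning("correlation: dropping unmatched cell lines %s", sorted(dropped))
    if len(shared) < 3:
        raise DegenerateInputError(
            f"need >= 3 shared cell lines, found {len(shared)}"
        )
    x = summary.loc[shared].to_numpy(dtype=float)
    y = covariate.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise FormatError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def read_bioluminescence(path) -> list[BioluminescenceSeries]:
    """Read a long-format CSV with columns cell_line, mouse_id, day, radiance."""
    df = pd.read_csv(path)
    required = {"cell_line", "mouse_id", "day", "radiance"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    out = []
    for (line, mouse), grp in df.groupby(["cell_line", "mouse_id"], sort=False):
        grp = grp.sort_values("day")
        out.append(
            BioluminescenceSeries(
                cell_line=str(line),
                mouse_id=str(mouse),
                days=grp["day"].to_numpy(),
                radiance=grp["radiance"].to_numpy(),
            )
        )
    return out


def write_bioluminescence(series: Iterable[BioluminescenceSeries], path) -> None:
    rows = [
        {"cell_line": s.cell_line, "mouse_id": s.mouse_id, "day": int(d), "radiance": r}
        for s in series
        for d, r in zip(s.days, s.radiance)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
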