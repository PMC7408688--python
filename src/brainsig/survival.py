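"""Prognostic screening of signature genes in a survival cohort.

For each gene, the cohort is split into high- and low-expression groups,
the two survivor functions are estimated by the Kaplan-Meier product-limit
method with Greenwood variances and log(-log)-transformed 95% confidence
bands, the groups are compared with the two-sample log-rank test, and
"mean survival" is reported as the restricted mean survival time (RMST) —
the area under the survivor curve up to a horizon — since an unrestricted
mean is undefined under right censoring.

The dichotomization rule is a first-class parameter because published
high/low group sizes vary gene to gene, which no single fixed split can
produce.  The default scans candidate cuts on a quantile grid (0.10-0.90,
step 0.05) and picks the cut minimizing the log-rank p-value; this
selection inflates the type-I error, so the scan is reported alongside the
result and flagged.

Conventions: subjects censored at an event time are still counted at risk
at that time; p-values come from the chi-square(1) reference distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

_Z95 = sps.norm.ppf(0.975)


@dataclass
class SurvivalCohort:
    """Right-censored cohort with per-patient gene expression.

    ``data`` is indexed by patient id with columns ``time`` (months, > 0),
    ``event`` (1 = death observed, 0 = censored) and one column per gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise FormatError(f"cohort missing column {col!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate patient ids")
        t = self.data["time"].to_numpy(dtype=float)
        e = self.data["event"].to_numpy()
        if len(t) == 0:
            raise FormatError("empty cohort")
        if np.any(t <= 0) or not np.all(np.isfinite(t)):
            raise FormatError("times must be positive and finite")
        if not np.isin(e, (0, 1)).all():
            raise FormatError("event flags must be 0 or 1")
        expr = self.expression.to_numpy(dtype=float)
        if expr.size and not np.isfinite(expr).all():
            raise FormatError("expression values must be finite")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    @property
    def expression(self) -> pd.DataFrame:
        return self.data[self.genes]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class Dichotomy:
    """A high/low expression split of the cohort for one gene."""

    gene: str
    strategy: str
    cut: float
    labels: pd.Series  # per patient, "high" or "low"
    n_high: int
    n_low: int
    scan: pd.DataFrame | None = None  # optimal_logrank: the full cut scan
    selection_biased: bool = False

    @property
    def high_mask(self) -> np.ndarray:
        return (self.labels == "high").to_numpy()


@dataclass
class KMCurve:
    """Product-limit survivor estimate at the distinct event times."""

    event_times: np.ndarray
    n_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): 1 before the first event, then the step value."""
        j = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if j < 0 else float(self.survival[j])

    def ci_at(self, t: float) -> tuple[float, float]:
        j = np.searchsorted(self.event_times, t, side="right") - 1
        if j < 0:
            return 1.0, 1.0
        return float(self.ci_lower[j]), float(self.ci_upper[j])


@dataclass
class LogRankResult:
    """Two-sample log-rank test (1 df)."""

    statistic: float
    p_value: float
    observed: tuple[float, float]  # events in (A, B)
    expected: tuple[float, float]


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance and log(-log) 95% CI.

    Subjects censored exactly at an event time remain in the risk set at
    that time.  With no events the curve is identically 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise FormatError("km_estimate: empty input")
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    death_times = ts[es == 1]
    ut, d = np.unique(death_times, return_counts=True)
    # at risk: subjects with time >= ut_j (censored-at-event-time stay at risk)
    n = len(ts) - np.searchsorted(ts, ut, side="left")
    frac = 1.0 - d / n
    S = np.cumprod(frac)
    # Greenwood: var(S_j) = S_j^2 * sum_{i<=j} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
        var = S**2 * np.cumsum(terms)
        var = np.where(S == 0.0, 0.0, var)
        # log(-log) transform CI, clipped to [0, 1]
        se_loglog = np.sqrt(var) / np.abs(S * np.log(S))
        theta = np.exp(_Z95 * se_loglog)
        lower = S**theta
        upper = S ** (1.0 / theta)
    degenerate = (S == 0.0) | (S == 1.0)
    lower = np.where(degenerate, S, lower)
    upper = np.where(degenerate, S, upper)
    return KMCurve(
        event_times=ut,
        n_risk=n.astype(int),
        deaths=d.astype(int),
        survival=S,
        variance=var,
        ci_lower=np.clip(lower, 0.0, 1.0),
        ci_upper=np.clip(upper, 0.0, 1.0),
    )


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Standard two-sample log-rank test.

    At each distinct pooled event time, the expected number of deaths in
    group A is n_Aj d_j / n_j with the hypergeometric variance
    n_Aj n_Bj d_j (n_j - d_j) / (n_j^2 (n_j - 1)); the statistic is
    (sum O_A - sum E_A)^2 / sum V with a chi-square(1) p-value.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise FormatError("logrank: both groups must be non-empty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    if e.sum() == 0:
        raise DegenerateInputError("logrank: no events in either group")
    ut, d = np.unique(t[e == 1], return_counts=True)
    ts = np.sort(t)
    tas = np.sort(ta)
    n = len(t) - np.searchsorted(ts, ut, side="left")
    n_a = len(ta) - np.searchsorted(tas, ut, side="left")
    # observed deaths in A at each pooled event time
    uta, da = np.unique(ta[ea == 1], return_counts=True)
    d_a = np.zeros_like(d, dtype=float)
    d_a[np.searchsorted(ut, uta)] = da
    expected_a = n_a * d / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(
            n > 1, d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1.0), 0.0
        )
    V = v.sum()
    if V == 0:
        raise DegenerateInputError("logrank: zero variance; groups not comparable")
    O_a, E_a = float(d_a.sum()), float(expected_a.sum())
    total = float(d.sum())
    chi2 = (O_a - E_a) ** 2 / V
    p = float(sps.chi2.sf(chi2, df=1))
    return LogRankResult(
        statistic=float(chi2),
        p_value=p,
        observed=(O_a, total - O_a),
        expected=(E_a, total - E_a),
    )


def mean_survival(k: KMCurve, horizon: float) -> float:
    """Restricted mean survival time: area under S from 0 to ``horizon``."""
    if horizon <= 0:
        raise FormatError("horizon must be positive")
    ts = k.event_times
    S = k.survival
    keep = ts < horizon
    knots = np.concatenate([[0.0], ts[keep], [horizon]])
    heights = np.concatenate([[1.0], S[keep]])
    return float(np.sum(np.diff(knots) * heights))


_QUANTILE_GRID = np.round(np.arange(0.10, 0.9001, 0.05), 2)


def dichotomize(
    cohort: SurvivalCohort,
    gene: str,
    strategy: str = "optimal_logrank",
    param: float | None = None,
) -> Dichotomy:
    """Split the cohort into high/low expression groups for one gene.

    Strategies: ``median`` (high iff expression > median), ``zscore_cut``
    (high iff the standardized expression > ``param``) and
    ``optimal_logrank`` (scan cuts at expression quantiles 0.10-0.90 in
    steps of 0.05, keep the cut minimizing the log-rank p-value; the scan
    is attached and the result flagged as selection-biased).
    """
    if gene not in cohort.genes:
        raise FormatError(f"gene {gene!r} not in cohort")
    if len(cohort) < 4:
        raise DegenerateInputError("dichotomization needs at least 4 patients")
    x = cohort.data[gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"gene {gene!r} has constant expression")

    def split_at(cut: float) -> np.ndarray:
        return x > cut

    scan = None
    biased = False
    if strategy == "median":
        cut = float(np.median(x))
        high = split_at(cut)
    elif strategy == "zscore_cut":
        if param is None:
            raise FormatError("zscore_cut requires a param (the z cutoff)")
        z = (x - x.mean()) / x.std(ddof=1)
        cut = float(x.mean() + param * x.std(ddof=1))
        high = z > param
    elif strategy == "optimal_logrank":
        rows = []
        best = None
        t, e = cohort.time, cohort.event
        for q in _QUANTILE_GRID:
            c = float(np.quantile(x, q))
            h = split_at(c)
            if h.all() or not h.any():
                continue
            try:
                res = logrank(t[h], e[h], t[~h], e[~h])
            except DegenerateInputError:
                continue
            rows.append(
                {"quantile": q, "cut": c, "n_high": int(h.sum()),
                 "n_low": int((~h).sum()), "p_value": res.p_value}
            )
            if best is None or res.p_value < best[0]:
                best = (res.p_value, c, h)
        if best is None:
            raise DegenerateInputError(
                f"gene {gene!r}: no valid cut on the quantile grid"
            )
        scan = pd.DataFrame(rows)
        biased = True
        logger.info(
            "optimal_logrank cut for %s selected from %d candidates; "
            "reported p-value is selection-biased",
            gene, len(rows),
        )
        _, cut, high = best
    else:
        raise FormatError(f"unknown dichotomization strategy {strategy!r}")

    if high.all() or not high.any():
        raise DegenerateInputError(
            f"gene {gene!r}: degenerate split (one group empty)"
        )
    labels = pd.Series(
        np.where(high, "high", "low"), index=cohort.data.index, name=gene
    )
    return Dichotomy(
        gene=gene,
        strategy=strategy,
        cut=cut,
        labels=labels,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        scan=scan,
        selection_biased=biased,
    )


def survival_screen(
    cohort: SurvivalCohort,
    genes,
    strategy: str = "optimal_logrank",
    alpha: float = 0.05,
    param: float | None = None,
    horizon: float | None = None,
) -> pd.DataFrame:
    """Screen genes for survival association, one row per gene.

    ``genes`` may be an iterable of gene names or a SignatureResult (its
    up and down sets are pooled).  Each gene is dichotomized, tested with
    the log-rank test, and summarized by the RMST of each group up to
    ``horizon`` (default: the largest observed time in the cohort).  Rows
    are flagged ``adverse-high`` when the high-expression group survives
    shorter (high RMST < low RMST) at p < alpha, and ``adverse-low`` for
    the reverse, mirroring a raw-p prognostic table; Benjamini-Hochberg
    q-values are reported alongside but do not drive the flag.  Genes that
    fail (constant expression, degenerate splits) are logged and skipped.
    """
    if hasattr(genes, "up") and hasattr(genes, "down"):
        gene_list = sorted(genes.up) + sorted(genes.down)
    else:
        gene_list = list(genes)
    if horizon is None:
        horizon = float(np.max(cohort.time)) if len(cohort) else None
    rows = []
    for gene in gene_list:
        try:
            di = dichotomize(cohort, gene, strategy=strategy, param=param)
            h = di.high_mask
            t, e = cohort.time, cohort.event
            res = logrank(t[h], e[h], t[~h], e[~h])
            high_mean = mean_survival(km_estimate(t[h], e[h]), horizon)
            low_mean = mean_survival(km_estimate(t[~h], e[~h]), horizon)
        except (DegenerateInputError, FormatError) as exc:
            logger.warning("survival_screen: skipping %s (%s)", gene, exc)
            continue
        if res.p_value < alpha:
            flag = "adverse-high" if high_mean < low_mean else "adverse-low"
        else:
            flag = "ns"
        rows.append(
            {
                "gene": gene,
                "strategy": di.strategy,
                "cut": di.cut,
                "n_high": di.n_high,
                "n_low": di.n_low,
                "p_value": res.p_value,
                "high_mean": high_mean,
                "low_mean": low_mean,
                "flag": flag,
                "selection_biased": di.selection_biased,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "strategy", "cut", "n_high", "n_low", "p_value",
            "high_mean", "low_mean", "flag", "selection_biased",
        ],
    )
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def read_cohort(path) -> SurvivalCohort:
    """Read a cohort CSV: columns id, time_months, event, then gene columns."""
    df = pd.read_csv(path)
    required = {"id", "time_months", "event"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    df = df.set_index("id").rename(columns={"time_months": "time"})
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    genes = [c for c in df.columns if c not in ("time", "event")]
    df[genes] = df[genes].astype(float)
    return SurvivalCohort(df)


def write_cohort(cohort: SurvivalCohort, path) -> None:
    out = cohort.data.rename(columns={"time": "time_months"})
    out.index.name = "id"
    out.to_csv(path, float_format="%.17g")
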