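"""Brain-colonization signature extraction.

The filtering procedure works on a log2 expression matrix of the nine cell
lines.  Each gene is standardized to a z-score across all nine samples;
three per-gene statistics then drive the filters:

* ``rg_logfc`` — within-RG consistency: the log2 fold-change between the
  two rapid-growth samples (MDA-MB-453 minus UACC-893),
* ``rg_msg_logfc`` — differential expression: mean log2 expression of the
  RG samples minus the mean of the MSG samples,
* ``rg_z`` / ``msg_z`` — the group means of the per-sample z-scores.

Four Venn sets characterize direction and group (RG up/down constrained to
consistent RG pairs, MSG up/down on the MSG z-score alone), and the
signature itself is the conjunction: consistent within RG
(|rg_logfc| < 1), differential versus MSG (rg_msg_logfc beyond +/-1) and
extreme z (rg_z beyond +/-1), with concordant signs.  All inequalities are
strict, exactly as the criteria are stated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, FormatError
from .expression import ExpressionMatrix, GroupAssignment

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Cutoffs for the three filtering criteria (all strict, all > 0).

    z_cut bounds the group-mean z-score, rg_consistency_cut bounds the
    absolute within-RG logFC, rg_msg_cut bounds the absolute RG-vs-MSG
    logFC.  The study uses 1.0 for all three.
    """

    z_cut: float = 1.0
    rg_consistency_cut: float = 1.0
    rg_msg_cut: float = 1.0

    def __post_init__(self) -> None:
        if min(self.z_cut, self.rg_consistency_cut, self.rg_msg_cut) <= 0:
            raise FormatError("thresholds must be positive")


@dataclass
class GeneStats:
    """Per-gene statistics feeding the filters.

    ``z`` holds the per-sample z-score matrix (features x samples);
    ``table`` has one row per feature with columns rg_z, msg_z, rg_logfc
    and rg_msg_logfc.
    """

    z: pd.DataFrame
    table: pd.DataFrame
    rg_order: tuple[str, str]

    @property
    def features(self) -> list:
        return self.table.index.tolist()


@dataclass
class VennSets:
    """The four direction/group sets used for the Venn diagram view."""

    rg_up: frozenset
    rg_down: frozenset
    msg_up: frozenset
    msg_down: frozenset

    def sizes(self) -> dict[str, int]:
        return {
            "rg_up": len(self.rg_up),
            "rg_down": len(self.rg_down),
            "msg_up": len(self.msg_up),
            "msg_down": len(self.msg_down),
        }


@dataclass
class SignatureResult:
    """Up/down signature gene sets plus their statistics."""

    up: frozenset
    down: frozenset
    stats: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)

    def sizes(self) -> dict[str, int]:
        return {"up": len(self.up), "down": len(self.down), "total": len(self.up) + len(self.down)}


@dataclass
class ClusteringResult:
    """Row dendrogram of the signature z-score submatrix."""

    leaf_order: list
    linkage_matrix: np.ndarray
    features: list


def zscore_matrix(m: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Standardize each feature across samples.

    Uses the sample (n-1) standard deviation by default.  Zero-variance
    rows map to all-zero z-scores; their count is logged.
    """
    if m.shape[1] < 2:
        raise DegenerateInputError("z-scores need at least 2 samples")
    vals = m.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.info("zscore_matrix: %d constant rows set to z=0", int(constant.sum()))
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / sd_safe
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=m.data.index, columns=m.data.columns)


def compute_gene_stats(
    m: ExpressionMatrix,
    groups: GroupAssignment,
    rg_order: tuple[str, str] | None = None,
    ddof: int = 1,
) -> GeneStats:
    """Compute the filtering statistics for every feature.

    ``rg_order`` fixes the orientation of the within-RG logFC as second
    minus first; it defaults to the assignment's RG samples in order, i.e.
    MDA-MB-453 minus UACC-893 in the study's configuration.
    """
    missing = [s for s in groups.samples if s not in m.data.columns]
    if missing:
        raise FormatError(f"samples missing from matrix: {missing}")
    rg = groups.rg
    msg = groups.msg
    if rg_order is None:
        rg_order = tuple(rg)
    if len(rg) != 2 or set(rg_order) != set(rg) or len(rg_order) != 2:
        raise FormatError(
            "within-RG logFC requires exactly 2 RG samples and a matching rg_order"
        )
    z = zscore_matrix(m, ddof=ddof)
    table = pd.DataFrame(
        {
            "rg_z": z[list(rg)].mean(axis=1),
            "msg_z": z[list(msg)].mean(axis=1),
            "rg_logfc": m.data[rg_order[1]] - m.data[rg_order[0]],
            "rg_msg_logfc": m.data[list(rg)].mean(axis=1) - m.data[list(msg)].mean(axis=1),
        }
    )
    return GeneStats(z=z, table=table, rg_order=tuple(rg_order))


def _rg_consistent(stats: GeneStats, cut: float) -> pd.Series:
    return stats.table["rg_logfc"].abs() < cut


def _rg_extreme(stats: GeneStats, cut: float, sign: int, mode: str) -> pd.Series:
    """Genes whose RG z-score exceeds ``cut`` in direction ``sign``.

    ``mode='mean'`` tests the group-mean z; ``mode='both'`` requires each
    RG sample's z individually beyond the cut.
    """
    if mode == "mean":
        return sign * stats.table["rg_z"] > cut
    if mode == "both":
        zrg = sign * stats.z[list(stats.rg_order)]
        return (zrg > cut).all(axis=1)
    raise FormatError(f"unknown rg_z mode {mode!r}")


def venn_partition(
    stats: GeneStats,
    thresholds: Thresholds | None = None,
    rg_z_mode: str = "mean",
) -> VennSets:
    """The four Venn criteria sets (strict inequalities throughout)."""
    t = thresholds or Thresholds()
    tab = stats.table
    consistent = _rg_consistent(stats, t.rg_consistency_cut)
    rg_up = consistent & _rg_extreme(stats, t.z_cut, +1, rg_z_mode)
    rg_down = consistent & _rg_extreme(stats, t.z_cut, -1, rg_z_mode)
    msg_up = tab["msg_z"] > t.z_cut
    msg_down = tab["msg_z"] < -t.z_cut
    idx = tab.index
    return VennSets(
        rg_up=frozenset(idx[rg_up]),
        rg_down=frozenset(idx[rg_down]),
        msg_up=frozenset(idx[msg_up]),
        msg_down=frozenset(idx[msg_down]),
    )


def extract_signature(
    stats: GeneStats,
    thresholds: Thresholds | None = None,
    rg_z_mode: str = "mean",
) -> SignatureResult:
    """Apply the dual logFC + z-score conjunction to every feature.

    Up: |rg_logfc| < consistency cut, rg_msg_logfc > fc cut, rg_z > z cut.
    Down: the mirror image.  The two sets are disjoint by construction.
    """
    t = thresholds or Thresholds()
    tab = stats.table
    consistent = _rg_consistent(stats, t.rg_consistency_cut)
    up = (
        consistent
        & (tab["rg_msg_logfc"] > t.rg_msg_cut)
        & _rg_extreme(stats, t.z_cut, +1, rg_z_mode)
    )
    down = (
        consistent
        & (tab["rg_msg_logfc"] < -t.rg_msg_cut)
        & _rg_extreme(stats, t.z_cut, -1, rg_z_mode)
    )
    selected = up | down
    return SignatureResult(
        up=frozenset(tab.index[up]),
        down=frozenset(tab.index[down]),
        stats=tab.loc[selected].copy(),
        thresholds=t,
    )


def cluster_signature(
    z: pd.DataFrame,
    linkage: str = "complete",
    distance: str = "euclidean",
) -> ClusteringResult:
    """Agglomerative clustering of signature rows for heatmap ordering.

    Rows (features) are clustered; columns are left in their fixed group
    order.  Defaults match the usual heatmap conventions: complete linkage
    on Euclidean distances.  ``distance='correlation'`` uses 1 - Pearson r.
    Leaf order follows the standard left-before-right dendrogram reading;
    SciPy's deterministic tie handling (by input order) applies.
    """
    if z.shape[0] < 2:
        raise DegenerateInputError("clustering needs at least 2 signature features")
    if linkage not in ("complete", "average"):
        raise FormatError(f"unsupported linkage {linkage!r}")
    if distance not in ("euclidean", "correlation"):
        raise FormatError(f"unsupported distance {distance!r}")
    d = pdist(z.to_numpy(dtype=float), metric=distance)
    Z = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(Z).tolist()
    return ClusteringResult(
        leaf_order=[z.index[i] for i in order],
        linkage_matrix=Z,
        features=z.index.tolist(),
    )
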