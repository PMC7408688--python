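"""Expression-matrix I/O and probe-to-gene collapsing.

The pipeline consumes a log2-scale expression matrix (features x samples,
tab-separated) together with a two-group assignment of the nine cell-line
samples into a rapid-growth group (RG) and a medium-to-slow-growth group
(MSG).  Values are assumed already log2-transformed and normalized; only
finiteness is validated here.  Gene sets are exchanged in the GMT format
used throughout the gene-set ecosystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

RG = "RG"
MSG = "MSG"
VALID_GROUPS = (RG, MSG)

#: The nine cell lines, rapid-growth pair first.
DEFAULT_CELL_LINES = (
    "UACC-893",
    "MDA-MB-453",
    "HCC-2218",
    "BT-474",
    "ZR-75-1",
    "UACC-812",
    "MDA-MB-361",
    "HCC-202",
    "HCC-1419",
)
DEFAULT_RG_LINES = ("UACC-893", "MDA-MB-453")


@dataclass
class ExpressionMatrix:
    """Log2-intensity matrix, features in rows, samples in columns.

    ``level`` records whether rows are microarray probes or collapsed gene
    symbols.  Feature and sample identifiers must be unique and every value
    finite.
    """

    data: pd.DataFrame
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise FormatError(f"level must be 'probe' or 'gene', got {self.level!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise FormatError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.empty:
            raise FormatError("expression matrix has no rows or no columns")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(vals).all():
            n_bad = int((~np.isfinite(vals)).sum())
            raise FormatError(f"expression matrix contains {n_bad} non-finite values")

    @property
    def feature_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GroupAssignment:
    """Total mapping of sample ids to the RG/MSG dichotomy."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)
        bad = {s: g for s, g in self.mapping.items() if g not in VALID_GROUPS}
        if bad:
            raise FormatError(f"unknown group labels (expected RG or MSG): {bad}")
        if not self.rg or not self.msg:
            raise FormatError("both RG and MSG must be non-empty")

    @property
    def rg(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == RG]

    @property
    def msg(self) -> list[str]:
        return [s for s, g in self.mapping.items() if g == MSG]

    @property
    def samples(self) -> list[str]:
        return list(self.mapping)

    def __getitem__(self, sample: str) -> str:
        return self.mapping[sample]


def default_group_assignment() -> GroupAssignment:
    """The study's configuration: UACC-893 and MDA-MB-453 form the RG."""
    return GroupAssignment(
        {line: (RG if line in DEFAULT_RG_LINES else MSG) for line in DEFAULT_CELL_LINES}
    )


def read_expression_matrix(path, level: str = "probe") -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Expects a header row of sample ids, feature ids in the first column and
    a numeric body.  Duplicate ids, non-numeric cells (reported with their
    row/column coordinates) and empty files are rejected.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if raw.empty:
        raise FormatError(f"{path}: expression file has no data rows or columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values in expression body")
    # astype parses correctly rounded (to_numeric's fast path is 1-2 ulp off)
    return ExpressionMatrix(raw.astype(float), level=level)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV with full (round-trippable) float precision."""
    m.data.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_groups(path) -> GroupAssignment:
    """Read a two-column TSV (``sample_id<TAB>group``, with header)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty group file") from exc
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, found {df.shape[1]}")
    sample_col, group_col = df.columns
    if df[sample_col].duplicated().any():
        dups = sorted(df.loc[df[sample_col].duplicated(), sample_col].tolist())
        raise FormatError(f"{path}: samples assigned more than once: {dups}")
    return GroupAssignment(dict(zip(df[sample_col], df[group_col])))


def write_sample_groups(groups: GroupAssignment, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.mapping), "group": list(groups.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def collapse_probes(
    m: ExpressionMatrix,
    probe_map: Mapping[str, str],
    method: str = "max_mean",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    ``max_mean`` keeps, for each gene, the probe with the highest mean
    intensity across samples (the common microarray convention); ``mean``
    averages all probes mapping to the gene.  The map must cover every
    probe in the matrix.
    """
    if m.level != "probe":
        raise FormatError("collapse_probes requires a probe-level matrix")
    if method not in ("max_mean", "mean"):
        raise FormatError(f"unknown collapse method {method!r}")
    missing = [p for p in m.feature_ids if p not in probe_map]
    if missing:
        raise FormatError(f"probe map missing {len(missing)} probe ids: {missing[:10]}")
    genes = pd.Series({p: probe_map[p] for p in m.feature_ids}, name="gene")
    if method == "mean":
        collapsed = m.data.groupby(genes, sort=False).mean()
    else:
        row_means = m.data.mean(axis=1)
        best = row_means.groupby(genes, sort=False).idxmax()
        collapsed = m.data.loc[best]
        collapsed.index = best.index
    collapsed.index.name = m.data.index.name
    return ExpressionMatrix(collapsed, level="gene")


def write_gene_sets(sig, path, description: str = "brain-colonizing signature") -> None:
    """Write the up/down signature sets as a two-record GMT file.

    Records are named ``RG_UP`` and ``RG_DOWN``; empty sets produce valid
    zero-member records.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in (("RG_UP", sig.up), ("RG_DOWN", sig.down)):
            fields = [name, description, *sorted(members)]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_gene_sets(path) -> dict[str, frozenset]:
    """Parse a GMT file into ``{set name: frozenset of members}``."""
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: GMT record with fewer than 2 fields")
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets
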