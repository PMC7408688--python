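"""End-to-end orchestration: growth classification, signature extraction
and survival screening from declared file inputs, with one results bundle.

The bundle is a pure function of (inputs, config): stages consume only the
paths named in the config, every tunable lives in the config, and the JSON
artifacts are written with sorted keys and fixed float formatting so that
repeated runs are byte-identical.  Wall-clock timestamps therefore go to
the run log only, never into the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._version import __version__
from .errors import BrainsigError
from .expression import (
    read_expression_matrix,
    read_sample_groups,
    write_gene_sets,
)
from .growth import classify_growth, growth_ratio, read_bioluminescence, summarize_growth
from .signature import (
    Thresholds,
    cluster_signature,
    compute_gene_stats,
    extract_signature,
    venn_partition,
)
from .survival import read_cohort, survival_screen

logger = logging.getLogger(__name__)


class PipelineStageError(BrainsigError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat configuration mirroring the CLI flags."""

    expression: str | None = None
    groups: str | None = None
    series: str | None = None
    cohort: str | None = None
    expression_level: str = "gene"
    z_cut: float = 1.0
    rg_consistency_cut: float = 1.0
    rg_msg_cut: float = 1.0
    rg_z_mode: str = "mean"
    growth_method: str = "max_gap"
    growth_threshold: float | None = None
    growth_day: int = 28
    linkage: str = "complete"
    distance: str = "euclidean"
    strategy: str = "optimal_logrank"
    alpha: float = 0.05
    out_dir: str = "brainsig_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise BrainsigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            z_cut=self.z_cut,
            rg_consistency_cut=self.rg_consistency_cut,
            rg_msg_cut=self.rg_msg_cut,
        )


@dataclass
class ResultsBundle:
    """Everything the pipeline computed, plus provenance."""

    growth: dict | None
    signature: dict
    venn: dict
    clustering: dict | None
    survival: list | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        skipped = {"skipped": True}
        return {
            "growth": self.growth if self.growth is not None else skipped,
            "signature": self.signature,
            "venn": self.venn,
            "clustering": self.clustering if self.clustering is not None else skipped,
            "survival": self.survival if self.survival is not None else skipped,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _round10(x: float) -> float:
    """Stabilize float formatting in JSON artifacts."""
    return float(f"{x:.10g}")


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Execute the configured stages in order and write the bundle.

    Growth classification runs if a bioluminescence series file is given,
    signature extraction always (expression + groups are required), and
    the survival screen if a cohort file is given.  On stage failure the
    partial outputs are removed and a stage-tagged error raised.
    """
    if cfg.expression is None or cfg.groups is None:
        raise BrainsigError("expression and groups inputs are required")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    stage = "setup"
    try:
        growth_result = None
        if cfg.series is not None:
            stage = "classify-growth"
            logger.info("stage %s: %s", stage, cfg.series)
            series = read_bioluminescence(cfg.series)
            ratios = [growth_ratio(s) for s in series]
            summary = summarize_growth(ratios, day=cfg.growth_day)
            cls = classify_growth(
                summary, method=cfg.growth_method, threshold=cfg.growth_threshold
            )
            summary.round(10).to_csv(track(out / "growth_summary.csv"))
            growth_result = {
                "labels": dict(sorted(cls.labels.items())),
                "threshold_used": _round10(cls.threshold_used),
                "method": cls.method,
                "day": cfg.growth_day,
                "summary": {k: _round10(v) for k, v in sorted(summary.items())},
            }

        stage = "extract-signature"
        logger.info("stage %s: %s", stage, cfg.expression)
        matrix = read_expression_matrix(cfg.expression, level=cfg.expression_level)
        groups = read_sample_groups(cfg.groups)
        stats = compute_gene_stats(matrix, groups)
        thresholds = cfg.thresholds()
        venn = venn_partition(stats, thresholds, rg_z_mode=cfg.rg_z_mode)
        sig = extract_signature(stats, thresholds, rg_z_mode=cfg.rg_z_mode)
        stats_out = stats.table.copy()
        stats_out["flag"] = [
            "up" if f in sig.up else ("down" if f in sig.down else "")
            for f in stats_out.index
        ]
        stats_out.round(10).to_csv(track(out / "gene_stats.tsv"), sep="\t")
        write_gene_sets(sig, track(out / "signature.gmt"))
        signature_result = {
            "up": sorted(sig.up),
            "down": sorted(sig.down),
            "sizes": sig.sizes(),
            "thresholds": dataclasses.asdict(thresholds),
            "rg_z_mode": cfg.rg_z_mode,
        }
        venn_result = {"sizes": venn.sizes()}

        clustering_result = None
        members = sorted(sig.up) + sorted(sig.down)
        if len(members) >= 2:
            z_sub = stats.z.loc[members]
            clus = cluster_signature(z_sub, linkage=cfg.linkage, distance=cfg.distance)
            (out / "clustering_order.tsv").write_text(
                "\n".join(str(f) for f in clus.leaf_order) + "\n", encoding="utf-8"
            )
            track(out / "clustering_order.tsv")
            clustering_result = {
                "leaf_order": [str(f) for f in clus.leaf_order],
                "linkage": cfg.linkage,
                "distance": cfg.distance,
            }

        survival_result = None
        if cfg.cohort is not None:
            stage = "survival"
            logger.info("stage %s: %s", stage, cfg.cohort)
            cohort = read_cohort(cfg.cohort)
            present = [g for g in members if g in cohort.genes]
            table = survival_screen(
                cohort, present, strategy=cfg.strategy, alpha=cfg.alpha
            )
            table.round(10).to_csv(track(out / "survival_screen.csv"), index=False)
            survival_result = json.loads(
                table.round(10).to_json(orient="records")
            )

        stage = "bundle"
        bundle = ResultsBundle(
            growth=growth_result,
            signature=signature_result,
            venn=venn_result,
            clustering=clustering_result,
            survival=survival_result,
            provenance={
                "package": "brainsig",
                "version": __version__,
                "seed": cfg.seed,
                "config": dataclasses.asdict(cfg),
            },
        )
        (out / "results.json").write_text(bundle.to_json() + "\n", encoding="utf-8")
        return bundle
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc
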