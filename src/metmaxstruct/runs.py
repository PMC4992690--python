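"""Reproducible analysis runs: configuration, orchestration, result bundles.

A run compares a query collection against a target collection over an (α, β)
grid and writes every derived artifact — per-grid-point profiles, cumulative
curves, an optional retained matrix, top-k tables, a fraction-exceeding
summary, figures, and a manifest (config echo + seeds + software version +
input checksums) sufficient to reproduce the run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import (
    SweepResult,
    cumulative_curve,
    named_hits_above,
    sweep,
    top_k_hits,
)
from .fingerprints import Collection, load_collection
from .mwmatch import build_match_plan, mw_matched_subsample
from .tversky import TverskyParams, alpha_grid

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a comparison run."""

    query_path: str
    target_path: str
    query_format: str | None = None
    target_format: str | None = None
    grid_family: str = "sum1"
    grid_points: int = 11
    explicit_grid: list[tuple[float, float]] | None = None
    thresholds: list[float] = field(default_factory=lambda: [0.8])
    top_k: int = 20
    mw_match_bin_width: float | None = None  # None = MW matching off
    mw_match_seed: int = 0
    output_dir: str = "results"
    exclude_self: bool = False
    keep_matrices: bool = False
    plots: bool = True

    def __post_init__(self) -> None:
        for t in self.thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold {t} outside [0, 1]")
        if self.explicit_grid is not None:
            for a, b in self.explicit_grid:
                if a < 0 or b < 0:
                    raise ValueError("explicit grid weights must be non-negative")

    def grid(self) -> list[TverskyParams]:
        if self.explicit_grid is not None:
            return [TverskyParams(a, b) for a, b in self.explicit_grid]
        return alpha_grid(self.grid_family, self.grid_points)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, extra: dict) -> None:
    manifest = {
        "software": {"name": "metmaxstruct", "version": __version__},
        "config": dataclasses.asdict(config),
        "input_checksums": {
            "queries": _sha256(config.query_path),
            "targets": _sha256(config.target_path),
        },
        **extra,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_inputs(config: RunConfig) -> tuple[Collection, Collection]:
    queries = load_collection(config.query_path, config.query_format, "queries")
    targets = load_collection(config.target_path, config.target_format, "targets")
    for name, coll in (("queries", queries), ("targets", targets)):
        for rej in coll.rejected:
            logger.warning("%s: rejected %s (%s)", name, rej.identifier, rej.reason)
    return queries, targets


def _write_sweep_outputs(
    result: SweepResult,
    queries: Collection,
    targets: Collection,
    config: RunConfig,
    outdir: Path,
) -> None:
    from .plotting import plot_cumulative_curves, plot_fraction_vs_alpha, plot_heatmap

    for params, profile in zip(result.grid, result.profiles):
        profile.to_dataframe().to_csv(
            outdir / f"profile_{params.label}.csv", index=False
        )
        cumulative_curve(profile).round(6).to_csv(
            outdir / f"curve_{params.label}.csv", index=False
        )
        rows = []
        for i, rec in enumerate(queries.records):
            for rank, (tid, s) in enumerate(
                top_k_hits(
                    (rec, queries.fingerprint(i)), targets, params, config.top_k
                ),
                start=1,
            ):
                rows.append(
                    {
                        "query_id": rec.id,
                        "rank": rank,
                        "target_id": tid,
                        "similarity": round(s, 6),
                        "alpha": params.alpha,
                        "beta": params.beta,
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / f"top{config.top_k}_{params.label}.csv", index=False)

    if result.matrices:
        for m in result.matrices:
            m.to_csv(outdir / f"matrix_{m.params.label}.csv")

    summary = result.summary_table(config.thresholds)
    summary.round(6).to_csv(outdir / "summary_fraction_exceeding.csv", index=False)

    if config.plots:
        plot_cumulative_curves(result, outdir / "cumulative_curves.png")
        for t in config.thresholds:
            plot_fraction_vs_alpha(
                summary, t, outdir / f"fraction_gt_{t:g}_vs_alpha.png"
            )
        if result.matrices:
            for m in result.matrices:
                plot_heatmap(m, outdir / f"heatmap_{m.params.label}.png")


def run_compare(config: RunConfig) -> SweepResult:
    """Full comparison run: load, (optionally MW-match), sweep, write bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    queries, targets = _load_inputs(config)

    mw_plan_info = {}
    if config.mw_match_bin_width is not None:
        classes = {"queries": queries, "targets": targets}
        plan = build_match_plan(
            classes, bin_width=config.mw_match_bin_width, seed=config.mw_match_seed
        )
        plan.to_json(outdir / "mw_match_plan.json")
        matched = mw_matched_subsample(classes, plan)
        queries, targets = matched["queries"], matched["targets"]
        mw_plan_info = {
            "mw_match": {
                "n_per_class": plan.n_sampled_per_class,
                "bin_width": config.mw_match_bin_width,
                "seed": config.mw_match_seed,
            }
        }

    result = sweep(
        queries,
        targets,
        config.grid(),
        keep_matrices=config.keep_matrices,
        exclude_self=config.exclude_self,
    )
    _write_sweep_outputs(result, queries, targets, config, outdir)
    _write_manifest(
        config,
        outdir,
        {"n_queries": len(queries), "n_targets": len(targets), **mw_plan_info},
    )
    return result


def run_interrogate(
    config: RunConfig, query_id: str, named_threshold: float = 0.85
) -> dict:
    """Ranked hit report for one interrogatory molecule across the grid."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    queries, targets = _load_inputs(config)
    i = queries.index_of(query_id)  # raises KeyError for an unknown id
    query = (queries.records[i], queries.fingerprint(i))
    single = queries.subset([i])

    report: dict = {"query_id": query_id, "grid": []}
    for params in config.grid():
        hits = top_k_hits(query, targets, params, config.top_k)
        named = named_hits_above(single, targets, params, named_threshold)
        report["grid"].append(
            {
                "alpha": params.alpha,
                "beta": params.beta,
                "top_hits": [
                    {"target_id": t, "similarity": round(s, 6)} for t, s in hits
                ],
                "named_hits_at_or_above": [
                    {"target_id": t, "similarity": round(s, 6)} for _, t, s in named
                ],
                "named_threshold": named_threshold,
            }
        )
    with open(outdir / f"interrogate_{query_id}.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(config, outdir, {"interrogated_query": query_id})
    return report


def fraction_above_threshold_report(
    queries: Collection,
    target_classes: dict[str, Collection],
    grid: list[TverskyParams],
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Fraction of queries above a threshold against each target class, per grid point.

    The library-profiling summary: rows are (α, β) grid points, one column per
    target class holding the fraction of queries whose best hit in that class
    is strictly greater than the threshold.
    """
    frames = {}
    for label, targets in target_classes.items():
        result = sweep(queries, targets, grid)
        frames[label] = result.summary_table([threshold])[f"frac_gt_{threshold:g}"]
    out = pd.DataFrame(
        {"alpha": [p.alpha for p in grid], "beta": [p.beta for p in grid], **frames}
    )
    return out
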