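"""Molecular-weight-matched subsampling of compound classes.

Fingerprint similarity on binary keys is confounded by molecular size: bigger
molecules set more bits and tend to score higher against anything.  To compare
classes (drugs, endogenous metabolites, natural products, screening libraries)
on an equal footing, each class is randomly subsampled so that all classes
share the same molecular-weight histogram.

Procedure: histogram all classes on a common Da grid (default 50 Da bins
spanning the union MW range); the per-bin quota is the minimum count across
classes — the unique rule that equalizes the distributions exactly without
replacement.  Bins where any class is empty get quota 0, which "clips" the
heavy tail of wide-ranged classes.  Draws are uniform without replacement and
fully determined by the plan's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fingerprints import Collection


@dataclass
class MWMatchPlan:
    """A reproducible recipe for MW-matched subsampling."""

    bin_edges: np.ndarray  # ascending, Da
    per_bin_quota: np.ndarray  # one quota per bin
    seed: int
    reference_class: str | None = None
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.per_bin_quota = np.asarray(self.per_bin_quota, dtype=int)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly ascending")
        if self.per_bin_quota.size != self.bin_edges.size - 1:
            raise ValueError("need one quota per bin")
        if (self.per_bin_quota < 0).any():
            raise ValueError("quotas must be non-negative")

    @property
    def n_sampled_per_class(self) -> int:
        return int(self.per_bin_quota.sum())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "bin_edges": self.bin_edges.tolist(),
                    "per_bin_quota": self.per_bin_quota.tolist(),
                    "seed": self.seed,
                    "reference_class": self.reference_class,
                    "class_labels": self.class_labels,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "MWMatchPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.array(d["bin_edges"]),
            np.array(d["per_bin_quota"]),
            d["seed"],
            d.get("reference_class"),
            d.get("class_labels", []),
        )


def _bin_indices(mws: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per molecule; the top edge is inclusive, out-of-range is -1."""
    idx = np.searchsorted(edges, mws, side="right") - 1
    idx[mws == edges[-1]] = edges.size - 2
    idx[(mws < edges[0]) | (mws > edges[-1])] = -1
    return idx


def build_match_plan(
    classes: dict[str, Collection],
    bin_width: float = 50.0,
    seed: int = 0,
    reference_class: str | None = None,
) -> MWMatchPlan:
    """Histogram all classes on a shared grid and set per-bin quotas.

    Quota = the minimum count across classes in that bin (restricted further
    to the reference class's count when one is named), so every class can
    fill every quota.  Bins missing from any class get quota 0.
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to match")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    for label, coll in classes.items():
        if len(coll) == 0:
            raise ValueError(f"class {label!r} is empty")
        if not np.all(coll.mol_weights > 0):
            raise ValueError(f"class {label!r} has non-positive molecular weights")
    if reference_class is not None and reference_class not in classes:
        raise ValueError(f"reference class {reference_class!r} not among classes")

    all_mw = np.concatenate([c.mol_weights for c in classes.values()])
    lo = np.floor(all_mw.min() / bin_width) * bin_width
    hi = np.ceil(all_mw.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)

    labels = sorted(classes)
    counts = np.stack(
        [
            np.bincount(
                _bin_indices(classes[lab].mol_weights, edges), minlength=edges.size - 1
            )[: edges.size - 1]
            for lab in labels
        ]
    )
    quota = counts.min(axis=0)
    if reference_class is not None:
        ref_counts = counts[labels.index(reference_class)]
        quota = np.minimum(quota, ref_counts)
    return MWMatchPlan(edges, quota, seed, reference_class, labels)


def mw_matched_subsample(
    classes: dict[str, Collection], plan: MWMatchPlan
) -> dict[str, Collection]:
    """Draw each class's per-bin quota uniformly without replacement.

    Deterministic in (plan, inputs): classes are visited in sorted-label
    order and bins in ascending order, each drawing from one generator
    seeded by the plan.  Per-bin counts after sampling are identical across
    classes by construction.
    """
    rng = np.random.default_rng(plan.seed)
    out: dict[str, Collection] = {}
    for label in sorted(classes):
        coll = classes[label]
        idx = _bin_indices(coll.mol_weights, plan.bin_edges)
        chosen: list[int] = []
        for b, q in enumerate(plan.per_bin_quota):
            members = np.flatnonzero(idx == b)
            if q > members.size:
                raise ValueError(
                    f"plan quota {q} exceeds class {label!r} count "
                    f"{members.size} in bin {b}"
                )
            if q > 0:
                chosen.extend(rng.choice(members, size=int(q), replace=False))
        if not chosen:
            raise ValueError(f"plan selects no molecules from class {label!r}")
        out[label] = coll.subset(sorted(chosen))
    return out


def max_cdf_gap(mw_x: np.ndarray, mw_y: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov distance between MW distributions."""
    x, y = np.sort(mw_x), np.sort(mw_y)
    both = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, both, side="right") / x.size
    cdf_y = np.searchsorted(y, both, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())
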