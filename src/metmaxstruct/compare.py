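"""Query-vs-target similarity matrices and their aggregate statistics.

The central object is the similarity matrix between an interrogatory (query)
collection and an interrogated (target) collection at one (α, β) point.  From
it derive the statistics used to profile a library:

- the max-similarity profile (each query's nearest target and its score),
- the cumulative rank curve (profile sorted descending vs rank fraction),
- the fraction of queries whose best hit exceeds a threshold (strict ">"),
- top-k ranked hit tables for a single query,
- named best hits at or above a threshold ("≥").

Sweeps repeat the analysis over an (α, β) grid.  Ties in every ranking are
broken by target input order, so runs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprints import Collection, Fingerprint, MoleculeRecord, pair_counts_matrix
from .tversky import TverskyParams, tversky_matrix

#: row-block size for the streaming profile pass
_CHUNK = 256


@dataclass
class SimilarityMatrix:
    """Rows = interrogatory queries (A), columns = interrogated targets (B)."""

    query_ids: list[str]
    target_ids: list[str]
    values: np.ndarray
    params: TverskyParams
    key_dialect: str = "MACCS166"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.query_ids), len(self.target_ids)):
            raise ValueError("matrix shape does not match id lists")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("similarities must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.query_ids, columns=self.target_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().round(6).to_csv(path, index_label="id")


@dataclass
class SimilarityProfile:
    """Per-query maximum similarity over a target collection, with the argmax target."""

    query_ids: list[str]
    max_similarity: np.ndarray
    best_target_id: list[str]
    params: TverskyParams

    def __post_init__(self) -> None:
        self.max_similarity = np.asarray(self.max_similarity, dtype=np.float64)
        n = len(self.query_ids)
        if self.max_similarity.shape != (n,) or len(self.best_target_id) != n:
            raise ValueError("profile field lengths disagree")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query_id": self.query_ids,
                "best_target_id": self.best_target_id,
                "similarity": np.round(self.max_similarity, 6),
                "alpha": self.params.alpha,
                "beta": self.params.beta,
            }
        )


@dataclass
class SweepResult:
    """One profile (and optionally the full matrix) per (α, β) grid point."""

    grid: list[TverskyParams]
    profiles: list[SimilarityProfile]
    matrices: list[SimilarityMatrix] | None = None

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.grid):
            raise ValueError("one profile required per grid point")

    def profile_for(self, params: TverskyParams) -> SimilarityProfile:
        for p, prof in zip(self.grid, self.profiles):
            if p.alpha == params.alpha and p.beta == params.beta:
                return prof
        raise KeyError(f"no grid point ({params.alpha}, {params.beta})")

    def summary_table(self, thresholds: list[float]) -> pd.DataFrame:
        """Fraction-exceeding table: one row per grid point, one column per threshold."""
        rows = []
        for params, prof in zip(self.grid, self.profiles):
            row = {"alpha": params.alpha, "beta": params.beta}
            for t in thresholds:
                row[f"frac_gt_{t:g}"] = fraction_exceeding(prof, t)
            rows.append(row)
        return pd.DataFrame(rows)


def similarity_matrix(
    queries: Collection, targets: Collection, params: TverskyParams
) -> SimilarityMatrix:
    """Dense Tversky similarity matrix, queries × targets."""
    if len(queries) == 0 or len(targets) == 0:
        raise ValueError("empty collection")
    a, b, c = pair_counts_matrix(queries, targets)
    values = tversky_matrix(a, b, c, params)
    return SimilarityMatrix(
        queries.ids, targets.ids, values, params, queries.key_dialect
    )


def max_profile(matrix: SimilarityMatrix) -> SimilarityProfile:
    """Row maxima and their argmax targets; ties go to the earliest target."""
    if not matrix.query_ids:
        raise ValueError("empty matrix")
    best = matrix.values.argmax(axis=1)  # argmax returns the first maximum
    return SimilarityProfile(
        matrix.query_ids,
        matrix.values[np.arange(len(matrix.query_ids)), best],
        [matrix.target_ids[j] for j in best],
        matrix.params,
    )


def _streamed_profile(
    queries: Collection,
    targets: Collection,
    params: TverskyParams,
    exclude_self: bool = False,
) -> SimilarityProfile:
    """Profile without materializing the full matrix (row blocks of _CHUNK).

    With ``exclude_self`` a target sharing the query's id is ignored (for the
    degenerate same-collection-both-sides use); a query whose only target is
    itself gets similarity 0.0 and an empty best-target id.
    """
    target_ids = targets.ids
    maxima = np.empty(len(queries))
    best = np.empty(len(queries), dtype=np.intp)
    for lo in range(0, len(queries), _CHUNK):
        rows = range(lo, min(lo + _CHUNK, len(queries)))
        block = queries.subset(rows)
        a, b, c = pair_counts_matrix(block, targets)
        vals = tversky_matrix(a, b, c, params)
        if exclude_self:
            for r, qi in enumerate(rows):
                qid = queries.records[qi].id
                for j, tid in enumerate(target_ids):
                    if tid == qid:
                        vals[r, j] = -1.0
        idx = vals.argmax(axis=1)
        best[lo : lo + vals.shape[0]] = idx
        maxima[lo : lo + vals.shape[0]] = vals[np.arange(vals.shape[0]), idx]
    best_ids = [target_ids[j] for j in best]
    if exclude_self:
        lone = maxima < 0
        maxima[lone] = 0.0
        best_ids = ["" if m else t for m, t in zip(lone, best_ids)]
    return SimilarityProfile(queries.ids, maxima, best_ids, params)


def cumulative_curve(profile: SimilarityProfile) -> pd.DataFrame:
    """Max similarities sorted descending against rank fraction rank/N ∈ (0, 1]."""
    n = len(profile.query_ids)
    if n == 0:
        raise ValueError("empty profile")
    sims = np.sort(profile.max_similarity)[::-1]
    return pd.DataFrame(
        {"rank_fraction": np.arange(1, n + 1) / n, "similarity": sims}
    )


def fraction_exceeding(profile: SimilarityProfile, threshold: float) -> float:
    """Fraction of queries whose best hit is strictly greater than the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return float(np.mean(profile.max_similarity > threshold))


def top_k_hits(
    query: tuple[MoleculeRecord, Fingerprint] | Fingerprint,
    targets: Collection,
    params: TverskyParams,
    k: int,
) -> list[tuple[str, float]]:
    """The k most similar targets to one query, descending; ties by input order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(targets) == 0:
        raise ValueError("empty target collection")
    fp = query[1] if isinstance(query, tuple) else query
    rec = query[0] if isinstance(query, tuple) else MoleculeRecord("query", "", 1.0)
    single = Collection([rec], fp.bits[None, :], fp.key_dialect)
    a, b, c = pair_counts_matrix(single, targets)
    row = tversky_matrix(a, b, c, params)[0]
    # stable mergesort on -row keeps input order among ties
    order = np.argsort(-row, kind="stable")[:k]
    return [(targets.ids[j], float(row[j])) for j in order]


def sweep(
    queries: Collection,
    targets: Collection,
    grid: list[TverskyParams],
    keep_matrices: bool = False,
    exclude_self: bool = False,
) -> SweepResult:
    """Run the profile analysis at every grid point.

    With ``keep_matrices=False`` (default) profiles are computed in a
    streaming row-block pass, so desk-scale sweeps (thousands × tens of
    thousands) never hold more than one block of the matrix.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    profiles, matrices = [], []
    for params in grid:
        if keep_matrices and not exclude_self:
            m = similarity_matrix(queries, targets, params)
            matrices.append(m)
            profiles.append(max_profile(m))
        else:
            if keep_matrices:
                matrices.append(similarity_matrix(queries, targets, params))
            profiles.append(
                _streamed_profile(queries, targets, params, exclude_self)
            )
    return SweepResult(grid, profiles, matrices if keep_matrices else None)


def named_hits_above(
    queries: Collection,
    targets: Collection,
    params: TverskyParams,
    threshold: float,
) -> list[tuple[str, str, float]]:
    """(query, best target) pairs with max similarity ≥ threshold, descending.

    This is the restriction of the max profile to rows passing the threshold
    (inclusive, unlike the strict ``fraction_exceeding``).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    prof = _streamed_profile(queries, targets, params)
    keep = np.flatnonzero(prof.max_similarity >= threshold)
    order = keep[np.argsort(-prof.max_similarity[keep], kind="stable")]
    return [
        (prof.query_ids[i], prof.best_target_id[i], float(prof.max_similarity[i]))
        for i in order
    ]
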