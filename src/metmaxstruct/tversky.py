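"""The Tversky similarity family on fingerprint bit counts.

For a pair of binary fingerprints summarized by counts ``(a, b, c)`` — keys on
only in the interrogatory molecule A, only in the interrogated molecule B, and
in both — the Tversky similarity with non-negative weights α, β is

    Tv(A, B; α, β) = c / (α·a + β·b + c)

α weights the keys unique to A and β those unique to B, so the measure is
asymmetric: at small α the score rewards B being contained in A as a
substructure, at large α it rewards A being contained in B.  Two special cases
are exact: α = β = 1 is the Tanimoto (Jaccard) similarity c/(a+b+c), and
α = β = 0.5 is the Dice coefficient 2c/(a+b+2c).

Parameter sweeps conventionally hold the sum α+β fixed at 1 or 2 (the
Tanimoto point lives on the α+β = 2 family).

Degenerate denominators: whenever c = 0 — including both-empty fingerprints
and the α = 0, b = 0 case where the denominator vanishes — the similarity is
defined as 0.0.  No shared key is no evidence of similarity, and one fixed
convention keeps NaN out of rankings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .fingerprints import BitCounts

logger = logging.getLogger(__name__)

_warned_empty = False


@dataclass(frozen=True)
class TverskyParams:
    """An (α, β) weight pair, optionally tagged with its constraint family."""

    alpha: float
    beta: float
    constraint_family: str = "free"  # {"sum1", "sum2", "free"}

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("Tversky weights must be non-negative")
        s = self.alpha + self.beta
        if self.constraint_family == "sum1" and abs(s - 1.0) > 1e-9:
            raise ValueError(f"sum1 family requires alpha+beta=1, got {s}")
        if self.constraint_family == "sum2" and abs(s - 2.0) > 1e-9:
            raise ValueError(f"sum2 family requires alpha+beta=2, got {s}")
        if self.constraint_family not in ("sum1", "sum2", "free"):
            raise ValueError(f"unknown constraint family {self.constraint_family!r}")

    @property
    def label(self) -> str:
        """Stable short label for filenames and table headers, e.g. ``a0.3_b0.7``."""
        return f"a{self.alpha:g}_b{self.beta:g}"

    def swapped(self) -> "TverskyParams":
        return TverskyParams(self.beta, self.alpha, self.constraint_family)


TANIMOTO = TverskyParams(1.0, 1.0, "sum2")
DICE = TverskyParams(0.5, 0.5, "sum1")


def _warn_empty_once() -> None:
    global _warned_empty
    if not _warned_empty:
        warnings.warn(
            "empty fingerprint encountered; similarity to anything is 0.0 "
            "under the degenerate-denominator convention",
            stacklevel=3,
        )
        _warned_empty = True


def tversky(counts: BitCounts, params: TverskyParams) -> float:
    """Tv = c / (α·a + β·b + c), with the c = 0 → 0.0 convention.

    Always in [0, 1]: the denominator is ≥ c for non-negative weights.
    """
    a, b, c = counts
    if min(a, b, c) < 0:
        raise ValueError(f"negative bit counts {counts}")
    if c == 0:
        if a == 0 and b == 0:
            _warn_empty_once()
        return 0.0
    return c / (params.alpha * a + params.beta * b + c)


def tanimoto(counts: BitCounts) -> float:
    """Tanimoto (Jaccard) similarity c/(a+b+c); identical to ``tversky`` at α=β=1."""
    return tversky(counts, TANIMOTO)


def dice(counts: BitCounts) -> float:
    """Dice coefficient 2c/(a+b+2c); identical to ``tversky`` at α=β=0.5."""
    return tversky(counts, DICE)


def tversky_matrix(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, params: TverskyParams
) -> np.ndarray:
    """Vectorized Tversky over parallel (a, b, c) count arrays.

    Computed in double precision from the integer counts; cells with c = 0
    get 0.0 per the degenerate convention.
    """
    c = np.asarray(c, dtype=np.float64)
    denom = params.alpha * np.asarray(a, dtype=np.float64) + params.beta * np.asarray(
        b, dtype=np.float64
    ) + c
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(c > 0, c / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def alpha_grid(family: str, n_points: int = 11) -> list[TverskyParams]:
    """Evenly spaced α over a fixed-sum family, β = s − α, endpoints included.

    ``family`` is "sum1" (s = 1) or "sum2" (s = 2).  Grid values are computed
    from integer ratios and rounded so that decimal labels (0.1, 0.2, ...)
    round-trip exactly through output files.
    """
    sums = {"sum1": 1.0, "sum2": 2.0}
    if family not in sums:
        raise ValueError(f"unknown constraint family {family!r}")
    if n_points < 2:
        raise ValueError("grid needs at least 2 points")
    s = sums[family]
    grid = []
    for i in range(n_points):
        alpha = round(s * i / (n_points - 1), 12)
        beta = round(s - alpha, 12)
        grid.append(TverskyParams(alpha, beta, family))
    return grid
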