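"""Network degree distributions and their moments.

In a degree-based (heterogeneous) mean-field epidemic model, nodes are grouped
by degree k and the only network quantities the dynamics see are the degree
law p(k) on 1..M and its first two moments: the edge-coupling term theta is
weighted by k p(k) / <k>, and the epidemic threshold scales with <k^2>/<k>.

Two normalisation conventions are supported for a truncated power law
p(k) ~ k^(-s):

* ``renormalized`` — masses are rescaled so the truncated support sums to 1
  (a proper distribution; the default).
* ``zeta_truncated`` — masses are exactly k^(-s)/zeta(s), i.e. the
  infinite-support normalisation restricted to 1..M, so the retained mass is
  strictly below 1.  This mirrors the common literature convention of writing
  p(k) = 1/(zeta(3) k^3) while simulating a finite network.

The two conventions differ in <k^2>/<k> by the truncated tail mass; the
renormalized mode is preferred wherever exact moment identities matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import zeta as _zeta

__all__ = [
    "RENORMALIZED",
    "ZETA_TRUNCATED",
    "DegreeDistribution",
    "truncated_power_law",
    "moment",
]

RENORMALIZED = "renormalized"
ZETA_TRUNCATED = "zeta_truncated"

_NORM_MODES = (RENORMALIZED, ZETA_TRUNCATED)


@dataclass(frozen=True)
class DegreeDistribution:
    """A discrete degree law on the support 1..M with cached moments.

    Parameters
    ----------
    degrees
        Strictly increasing integer degrees starting at 1.
    probabilities
        Per-degree mass p(k), non-negative.  Must sum to 1 (within 1e-12)
        in ``renormalized`` mode; may sum to less than 1 in
        ``zeta_truncated`` mode.
    normalization_mode
        One of ``"renormalized"`` or ``"zeta_truncated"``.
    """

    degrees: np.ndarray
    probabilities: np.ndarray
    normalization_mode: str = RENORMALIZED
    _moment_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        degrees = np.asarray(self.degrees, dtype=np.int64)
        probs = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "degrees", degrees)
        object.__setattr__(self, "probabilities", probs)
        if degrees.ndim != 1 or probs.ndim != 1 or degrees.size != probs.size:
            raise ValueError("degrees and probabilities must be 1-d of equal length")
        if degrees.size == 0:
            raise ValueError("empty support")
        if degrees[0] != 1 or np.any(np.diff(degrees) <= 0):
            raise ValueError("degrees must be strictly increasing and start at 1")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if self.normalization_mode not in _NORM_MODES:
            raise ValueError(f"unknown normalization_mode {self.normalization_mode!r}")
        total = math.fsum(probs.tolist())
        if self.normalization_mode == RENORMALIZED:
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"renormalized masses must sum to 1, got {total!r}")
        else:
            if total > 1.0 + 1e-12:
                raise ValueError("zeta_truncated masses must not exceed 1")
        if self.moment(1) <= 0:
            raise ValueError("mean degree must be positive")

    @property
    def max_degree(self) -> int:
        return int(self.degrees[-1])

    def moment(self, order: int) -> float:
        """Return sum_k k^order p(k) over the retained support.

        Order 0 is the total retained mass (1 in renormalized mode).
        Results are cached; the cache is keyed on the immutable arrays.
        """
        order = int(order)
        if order < 0:
            raise ValueError("moment order must be a non-negative integer")
        cached = self._moment_cache.get(order)
        if cached is None:
            k = self.degrees.astype(np.float64)
            cached = float(np.dot(k**order, self.probabilities))
            self._moment_cache[order] = cached
        return cached

    @property
    def mean_degree(self) -> float:
        """First moment <k>."""
        return self.moment(1)

    @property
    def second_moment(self) -> float:
        """Second moment <k^2>."""
        return self.moment(2)

    @property
    def moment_ratio(self) -> float:
        """<k^2>/<k>, the degree-heterogeneity factor in the threshold."""
        return self.second_moment / self.mean_degree

    def edge_weights(self) -> np.ndarray:
        """g(k) = k p(k) / <k>: degree law of the node at the end of an edge."""
        return self.degrees * self.probabilities / self.mean_degree

    def to_csv(self, path) -> None:
        """Write the distribution as a two-column CSV (degree, probability)."""
        import pandas as pd

        pd.DataFrame(
            {"degree": self.degrees, "probability": self.probabilities}
        ).to_csv(path, index=False)


def truncated_power_law(
    exponent: float, max_degree: int, normalization_mode: str = RENORMALIZED
) -> DegreeDistribution:
    """Power-law degree distribution p(k) ~ k^(-exponent) on 1..max_degree.

    With ``zeta_truncated`` normalisation the masses are exactly
    k^(-exponent)/zeta(exponent) (for exponent 3 this is the familiar
    1/(zeta(3) k^3)); with ``renormalized`` they are rescaled to sum to 1.
    """
    exponent = float(exponent)
    max_degree = int(max_degree)
    if not exponent > 1:
        raise ValueError("exponent must exceed 1 for a summable power law")
    if max_degree < 1:
        raise ValueError("max_degree must be a positive integer")
    k = np.arange(1, max_degree + 1, dtype=np.float64)
    weights = k ** (-exponent)
    if normalization_mode == ZETA_TRUNCATED:
        probs = weights / float(_zeta(exponent, 1))
    elif normalization_mode == RENORMALIZED:
        probs = weights / math.fsum(weights.tolist())
    else:
        raise ValueError(f"unknown normalization_mode {normalization_mode!r}")
    return DegreeDistribution(
        degrees=np.arange(1, max_degree + 1, dtype=np.int64),
        probabilities=probs,
        normalization_mode=normalization_mode,
    )


def moment(dist: DegreeDistribution, order: int) -> float:
    """Module-level alias for :meth:`DegreeDistribution.moment`."""
    return dist.moment(order)
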