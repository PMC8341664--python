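"""Exact counts of the class-proportional sampling space.

The number of distinct class-proportional subsamples is a product of
per-class binomial coefficients; already for three classes of 50 drawn at
half it reaches ~2e42, which is why the method searches a seeded trial set
instead of enumerating.  All arithmetic is arbitrary-precision integer.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, List, Sequence, Tuple


@dataclasses.dataclass(frozen=True)
class CombinationCount:
    exact: int
    log10: float

    @classmethod
    def from_exact(cls, exact: int) -> "CombinationCount":
        if exact < 1:
            raise ValueError("count must be >= 1")
        return cls(exact=exact, log10=math.log10(exact))


def count_pairwise_distances(n: int) -> int:
    """Number of unique pairwise distances among n points: n (n - 1) / 2."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * (n - 1) // 2


def _per_class_draws(class_sizes: Sequence[int], fraction: float) -> List[int]:
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    sizes = list(class_sizes)
    if not sizes:
        raise ValueError("class_sizes must be non-empty")
    if any(s < 1 for s in sizes):
        raise ValueError("class sizes must be positive")
    # nearest integer, ties to even — documented counting convention
    return [int(round(fraction * s)) for s in sizes]


def count_class_proportional_combinations(
    class_sizes: Sequence[int], fraction: float
) -> CombinationCount:
    """Product over classes of C(class_size, round(fraction * class_size)).

    Sampling none or all of the data gives exactly one combination; the
    count peaks at fraction 1/2 for symmetric class sizes.
    """
    draws = _per_class_draws(class_sizes, fraction)
    exact = 1
    for size, r in zip(class_sizes, draws):
        exact *= math.comb(size, r)
    return CombinationCount.from_exact(exact)


def combination_curve(
    class_sizes: Sequence[int], fractions: Iterable[float]
) -> List[Tuple[float, float]]:
    """log10 combination counts along a grid of sampled fractions."""
    return [
        (f, count_class_proportional_combinations(class_sizes, f).log10)
        for f in fractions
    ]
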