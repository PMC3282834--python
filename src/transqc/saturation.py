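"""Gene-discovery saturation by read subsampling.

Nested (cumulative) random subsets of the reads at increasing fractions are
scored with a caller-supplied ``evaluate`` function (on real data: assemble
and deduplicate; on synthetic data: count distinct true source genes).
Nesting makes the discovery curve non-decreasing by construction whenever
``evaluate`` is monotone in its input set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["SaturationPoint", "subsample", "discovery_curve", "DEFAULT_FRACTIONS"]

DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass(frozen=True)
class SaturationPoint:
    fraction: float
    n_sampled: int
    n_unique: int
    max_product_length: int | None = None


def _sample_size(fraction: float, total: int) -> int:
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0,1]")
    return round(fraction * total)


def subsample(ids: Sequence[str], fraction: float, seed: int) -> list[str]:
    """Uniform sample without replacement of size round(fraction * N).

    Deterministic for a given seed.
    """
    n = _sample_size(fraction, len(ids))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in idx]


def discovery_curve(
    ids: Sequence[str],
    evaluate: Callable[[Sequence[str]], int],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> list[SaturationPoint]:
    """One :class:`SaturationPoint` per fraction over nested subsets.

    A single seeded permutation of the ids is drawn; the subset at each
    fraction is a prefix of it, so every larger subset contains the smaller.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    points = []
    for fraction in sorted(fractions):
        n = _sample_size(fraction, len(ids))
        subset = [ids[i] for i in order[:n]]
        try:
            n_unique = evaluate(subset)
        except Exception as exc:
            raise RuntimeError(
                f"evaluate failed at fraction {fraction}: {exc}"
            ) from exc
        points.append(
            SaturationPoint(fraction=fraction, n_sampled=n, n_unique=n_unique)
        )
    return points
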