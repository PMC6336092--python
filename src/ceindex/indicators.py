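"""Optional indicator helpers: community diversity and weighted rare species.

Most service indicators (wave energy reduction, bivalve filtration, COD
purification, visitor counts, ...) come from field models and enter the
assessment as precomputed values. The two indicators fully determined by
survey tables are computed here: the Shannon-Wiener diversity index H' and a
threatened-species count weighted by endangerment category.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import stats

from .errors import EmptyCommunityError


def shannon_diversity(counts: Mapping[str, float]) -> float:
    """Shannon-Wiener H' = -sum p_k ln p_k over species proportions.

    Natural logarithm; zero-count species are ignored.
    """
    c = np.asarray([v for v in counts.values()], dtype=float)
    if (c < 0).any():
        raise ValueError("negative abundance count")
    total = c.sum()
    if total == 0:
        raise EmptyCommunityError("all abundance counts are zero")
    return float(stats.entropy(c[c > 0]))


def weighted_rare_species(
    count_by_category: Mapping[str, float],
    weights: Mapping[str, float],
) -> float:
    """Sum of category counts weighted by endangerment category.

    Weights (e.g. CR > EN > VU) are user configuration; every category
    appearing in the counts must carry a weight.
    """
    total = 0.0
    for cat, n in count_by_category.items():
        if cat not in weights:
            raise KeyError(f"no weight configured for category {cat!r}")
        if n < 0:
            raise ValueError(f"negative count for category {cat!r}")
        total += weights[cat] * n
    return total
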