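"""Nonparametric group-comparison helpers.

Kruskal–Wallis comes from scipy; the Dunn all-pairs post-hoc test (joint
ranking, tie-corrected standard errors, optional Bonferroni adjustment) is
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["DunnResult", "dunn_test"]


@dataclass
class DunnResult:
    z: dict[tuple[str, str], float]
    p_raw: dict[tuple[str, str], float]
    p_adjusted: dict[tuple[str, str], float]
    mean_ranks: dict[str, float]


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> DunnResult:
    """Dunn's all-pairs comparison on jointly ranked data.

    For groups i, j with mean joint ranks R_i, R_j:

        z_ij = (R_i - R_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where ``T = sum(t^3 - t)`` over tie groups. Two-sided normal p-values,
    optionally Bonferroni-adjusted over the number of pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    if min(sizes.values()) < 1:
        raise ValueError("every group needs at least one observation")
    n = values.size
    ranks = sps.rankdata(values)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = float(ranks[start : start + sizes[g]].mean())
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n * (n + 1) / 12.0 - (tie_term / (12.0 * (n - 1)) if n > 1 else 0.0)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    z, p_raw, p_adj = {}, {}, {}
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        zz = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pp = 2.0 * sps.norm.sf(abs(zz))
        z[(a, b)] = float(zz)
        p_raw[(a, b)] = float(pp)
        if adjust == "bonferroni":
            p_adj[(a, b)] = float(min(1.0, pp * m))
        elif adjust in (None, "none"):
            p_adj[(a, b)] = float(pp)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    return DunnResult(z=z, p_raw=p_raw, p_adjusted=p_adj, mean_ranks=mean_ranks)
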