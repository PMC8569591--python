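"""Hypergeometric over-representation tests with Benjamini-Hochberg control.

The "one-dimensional" Fisher's exact test here is the upper-tail
hypergeometric probability P(X >= k) of drawing at least the observed
overlap k between a hit list (n of N universe proteins) and a candidate set
(K of N): the standard enrichment-only form. Odds ratios come from the 2x2
table with a Haldane 0.5 correction when any cell is empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .solubility import significance_stars


@dataclass
class EnrichmentResult:
    universe_N: int
    hits_n: int
    set_K: int
    overlap_k: int
    odds_ratio: float
    p: float
    q: Optional[float] = None
    label: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "N": self.universe_N,
            "n": self.hits_n,
            "K": self.set_K,
            "k": self.overlap_k,
            "odds_ratio": self.odds_ratio,
            "p": self.p,
            "q": self.q,
            "stars": significance_stars(self.q if self.q is not None else self.p),
        }


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    # 2x2: [k, n-k; K-k, N-n-K+k], Haldane correction on empty cells
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def hypergeom_enrichment(
    universe: Set[str], hits: Set[str], candidate: Set[str], label: Optional[str] = None
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of hit/candidate overlap.

    ``hits`` must be a subset of ``universe``; the candidate set is
    intersected with the universe before testing.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits:
        raise ValueError("empty hit list")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    cand = candidate & universe
    N, n, K = len(universe), len(hits), len(cand)
    k = len(hits & cand)
    # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(p, 1.0)
    return EnrichmentResult(N, n, K, k, _odds_ratio(k, n, K, N), p, label=label)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def module_hit_enrichment(
    module_members: Mapping[int, Set[str]],
    universe: Set[str],
    hits: Set[str],
) -> pd.DataFrame:
    """One enrichment test per module, BH-corrected across modules.

    The universe is the full network input (assigned plus unassigned
    proteins); each module's member set is the candidate. Empty modules are
    skipped with a warning.
    """
    results: list[EnrichmentResult] = []
    for label, members in sorted(module_members.items()):
        if not members:
            warnings.warn(f"module {label} is empty; skipped", stacklevel=2)
            continue
        res = hypergeom_enrichment(universe, hits, members, label=f"M{label}")
        results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["label", "N", "n", "K", "k", "odds_ratio", "p", "q", "stars"]
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return pd.DataFrame([r.as_dict() for r in results])
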