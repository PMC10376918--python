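"""Running-sum set enrichment over miRNAs ranked by age correlation.

miRNAs are sorted by descending age correlation within one fraction; for
each category the unweighted running sum gains (N - K) at every member hit
and loses K at every miss, terminating at exactly 0. The enrichment score is
the maximum absolute deviation of the running sum. Significance comes from
shuffling category labels over list positions; all nominal p-values are
reported (p-value threshold of 1) and Benjamini-Hochberg adjusted across
categories. The EV-vs-fc contrast flags categories whose p-values differ by
at least a given number of orders of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "set_enrichment",
    "fraction_contrast",
    "rank_by_correlation",
    "read_gmt",
]


@dataclass
class EnrichmentResult:
    """Per-category running-sum enrichment outcome."""

    category: str
    size: int  # K, members found in the ranked list
    n: int  # N, ranked list length
    es: float  # max |running sum|
    running_sum: np.ndarray = field(repr=False)
    p_value: float = float("nan")
    q_value: float = float("nan")
    n_dropped: int = 0  # members absent from the ranked list


def rank_by_correlation(correlations: pd.Series) -> list[str]:
    """Order feature ids by descending age correlation (NaN dropped)."""
    s = correlations.dropna().sort_values(ascending=False, kind="stable")
    return s.index.tolist()


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT category sets: per line, id <tab> description <tab> members..."""
    categories: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            categories[parts[0]] = set(parts[2:])
    return categories


def _running_sum(hits: np.ndarray, n: int, k: int) -> np.ndarray:
    steps = np.where(hits, n - k, -k)
    return np.cumsum(steps)


def set_enrichment(
    ranked: Sequence[str],
    categories: Mapping[str, Set[str]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Score every category against a ranked miRNA list.

    p = (b + 1) / (B + 1) where b counts label-shuffled permutations with
    ES >= observed. Every category is reported regardless of p; q-values are
    Benjamini-Hochberg across the reported categories.
    """
    ranked = list(ranked)
    n = len(ranked)
    if n == 0:
        raise ValueError("empty ranked list")
    if not categories:
        raise ValueError("empty category table")
    if len(set(ranked)) != n:
        raise ValueError("ranked list contains duplicates")
    pos = {f: i for i, f in enumerate(ranked)}
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    for cat, members in categories.items():
        inside = [m for m in members if m in pos]
        dropped = len(members) - len(inside)
        if dropped:
            warnings.warn(f"category {cat}: {dropped} member(s) absent from ranked list",
                          stacklevel=2)
        k = len(inside)
        if k == 0:
            warnings.warn(f"category {cat}: no members in ranked list, skipped", stacklevel=2)
            continue
        hits = np.zeros(n, dtype=bool)
        hits[[pos[m] for m in inside]] = True
        rs = _running_sum(hits, n, k)
        es = float(np.abs(rs).max()) if k < n else 0.0

        # permutation null: random placement of the k labels
        null = np.empty(n_permutations)
        if k < n:
            order = np.argsort(rng.random((n_permutations, n)), axis=1)
            perm_hits = order < k
            steps = np.where(perm_hits, n - k, -k)
            null = np.abs(np.cumsum(steps, axis=1)).max(axis=1).astype(float)
        else:
            null[:] = 0.0
        p = (int((null >= es).sum()) + 1) / (n_permutations + 1)
        results.append(
            EnrichmentResult(
                category=cat,
                size=k,
                n=n,
                es=es,
                running_sum=rs,
                p_value=float(p),
                n_dropped=dropped,
            )
        )
    if results:
        pvals = [r.p_value for r in results]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    return results


def fraction_contrast(
    results_ev: Sequence[EnrichmentResult],
    results_fc: Sequence[EnrichmentResult],
    magnitude: float = 3.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Contrast per-category significance between the EV and fc fractions.

    A category is EV-specific when p_fc / p_EV >= 10**magnitude, fc-specific
    for the reverse ratio, and shared-significant when its BH-adjusted q is
    below ``alpha`` in both fractions. Categories present in only one result
    list are excluded with a warning.
    """
    ev = {r.category: r for r in results_ev}
    fc = {r.category: r for r in results_fc}
    only = set(ev) ^ set(fc)
    if only:
        warnings.warn(f"categories present in one fraction only, excluded: {sorted(only)}",
                      stacklevel=2)
    rows = []
    for cat in sorted(set(ev) & set(fc)):
        p_ev, p_fc = ev[cat].p_value, fc[cat].p_value
        ratio = 10.0**magnitude
        flag = ""
        if p_fc / p_ev >= ratio:
            flag = "EV_specific"
        elif p_ev / p_fc >= ratio:
            flag = "fc_specific"
        rows.append(
            {
                "category": cat,
                "p_ev": p_ev,
                "p_fc": p_fc,
                "q_ev": ev[cat].q_value,
                "q_fc": fc[cat].q_value,
                "flag": flag,
                "shared_significant": bool(ev[cat].q_value < alpha and fc[cat].q_value < alpha),
            }
        )
    return pd.DataFrame(rows)
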