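"""Principal-variance-component-style attribution of expression variance.

The standardized sample x feature matrix is decomposed into principal
components; components are retained until their cumulative explained
variance reaches a threshold. For each retained component and each factor
(age, fraction, mouse, ...), a one-way random-effects variance component is
estimated by method of moments (negative estimates truncated at 0). Per-
component attributions are averaged with eigenvalue weights and normalized,
including the residual, to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError

__all__ = ["VarianceAttribution", "variance_attribution"]

DEFAULT_FACTORS = ("age_months", "fraction", "mouse_id")


@dataclass
class VarianceAttribution:
    """Factor -> proportion of eigenvalue-weighted variance (sums to 1)."""

    proportions: dict[str, float]
    n_components: int
    pc_variance_threshold: float
    estimator: str = "method_of_moments"

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, name="proportion")


def _one_way_component(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Method-of-moments between/within variance components for one factor."""
    levels, idx = np.unique(groups, return_inverse=True)
    n = y.size
    G = len(levels)
    grand = y.mean()
    ssb = ssw = 0.0
    sizes = np.bincount(idx)
    for g in range(G):
        yg = y[idx == g]
        ssb += yg.size * (yg.mean() - grand) ** 2
        ssw += ((yg - yg.mean()) ** 2).sum()
    msb = ssb / (G - 1)
    msw = ssw / (n - G) if n > G else 0.0
    n0 = (n - (sizes**2).sum() / n) / (G - 1)
    sigma_between = max((msb - msw) / n0, 0.0) if n0 > 0 else 0.0
    return sigma_between, msw


def _partition(values: np.ndarray) -> set[frozenset[int]]:
    levels = {}
    for i, v in enumerate(values):
        levels.setdefault(v, []).append(i)
    return {frozenset(ix) for ix in levels.values()}


def variance_attribution(
    x: ExpressionMatrix,
    samples: pd.DataFrame,
    factors: Sequence[str] = DEFAULT_FACTORS,
    pc_variance_threshold: float = 0.6,
) -> VarianceAttribution:
    """Attribute expression variance to experimental factors, PVCA-style.

    Parameters
    ----------
    x :
        Expression matrix (features x samples).
    samples :
        Sample sheet; must contain a column per requested factor.
    factors :
        Factor columns; each needs >= 2 levels among the matrix samples, and
        no two factors may induce the identical sample grouping.
    pc_variance_threshold :
        Retain principal components until cumulative explained variance
        reaches this threshold (at least one component).
    """
    meta = samples.set_index("sample_id").loc[list(x.sample_ids)]
    factor_values = {}
    for f in factors:
        if f not in meta.columns:
            raise ValidationError(f"factor {f!r} not in sample sheet")
        vals = meta[f].to_numpy()
        if len(np.unique(vals)) < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 levels")
        factor_values[f] = vals
    for i, f1 in enumerate(factors):
        for f2 in list(factors)[i + 1 :]:
            if _partition(factor_values[f1]) == _partition(factor_values[f2]):
                raise ValidationError(f"factors {f1!r} and {f2!r} are confounded 1:1")

    v = x.values()
    sd = v.std(axis=1, ddof=0)
    keep = sd > 0
    z = (v[keep] - v[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    X = z.T  # samples x features, standardized
    n = X.shape[0]

    # principal components via SVD of the centered sample matrix
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / max(n - 1, 1)
    eigvals = eigvals[eigvals > 1e-12]
    explained = eigvals / eigvals.sum()
    n_keep = int(np.searchsorted(np.cumsum(explained), pc_variance_threshold) + 1)
    n_keep = min(max(n_keep, 1), len(eigvals))
    scores = U[:, :n_keep] * S[:n_keep]

    weighted = {f: 0.0 for f in factors}
    weighted["residual"] = 0.0
    for c in range(n_keep):
        y = scores[:, c]
        total_var = y.var(ddof=1)
        comps = {}
        for f in factors:
            sigma_b, _ = _one_way_component(y, factor_values[f])
            comps[f] = sigma_b
        resid = max(total_var - sum(comps.values()), 0.0)
        denom = sum(comps.values()) + resid
        if denom <= 0:
            continue
        w = eigvals[c]
        for f in factors:
            weighted[f] += w * comps[f] / denom
        weighted["residual"] += w * resid / denom

    total = sum(weighted.values())
    if total <= 0:
        raise ValidationError("no variance to attribute")
    proportions = {k: v / total for k, v in weighted.items()}
    return VarianceAttribution(
        proportions=proportions,
        n_components=n_keep,
        pc_variance_threshold=pc_variance_threshold,
    )
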