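"""Per-feature age-trajectory statistics and cross-fraction comparisons.

Each feature gets a linear Pearson correlation with age and a (nonlinear)
distance correlation with age. A cubic regression spline of distance
correlation on Pearson correlation, fitted across features at a fixed number
of degrees of freedom, separates predominantly nonlinear features: those
whose distance correlation deviates at least ``threshold`` from the spline.

Cross-fraction concordance is summarized by the sign quadrants of the paired
Pearson correlations, tested against the uniform 25%-per-quadrant null, and
by a permutation test on the mean-correlation shift between fractions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .core_io import ExpressionMatrix, ValidationError

__all__ = [
    "age_correlation",
    "pearson_by_feature",
    "distance_correlation",
    "classify_nonlinear",
    "QuadrantTable",
    "quadrant_concordance",
    "MeanShiftResult",
    "mean_shift_permutation_test",
    "baseline_relative_expression",
]


def age_correlation(values: np.ndarray, ages: np.ndarray) -> float:
    """Pearson product-moment correlation of a feature with age.

    Returns NaN (the "undefined" flag, excluded downstream) when the feature
    has zero variance. Requires at least 3 samples and non-constant ages.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape:
        raise ValueError(f"length mismatch: {values.shape} vs {ages.shape}")
    if values.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(ages) == 0:
        raise ValueError("ages are all equal")
    if np.ptp(values) == 0:
        return float("nan")
    return float(stats.pearsonr(values, ages).statistic)


def pearson_by_feature(x: ExpressionMatrix, ages: np.ndarray) -> pd.Series:
    """Vectorized per-feature Pearson correlation with age (NaN if constant)."""
    v = x.values()
    ages = np.asarray(ages, dtype=float)
    if v.shape[1] != ages.size:
        raise ValueError("ages do not match matrix samples")
    vc = v - v.mean(axis=1, keepdims=True)
    vs = np.sqrt((vc**2).sum(axis=1))
    ac = ages - ages.mean()
    an = np.sqrt((ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ ac) / (vs * an)
    r[vs == 0] = np.nan
    return pd.Series(r, index=x.feature_ids, name="pearson_r")


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation of two real vectors, in [0, 1].

    Pairwise Euclidean distance matrices are double-centred; the statistic is
    dCov / sqrt(dVar_x * dVar_y). By convention returns 0 when either
    distance variance is 0 (e.g. a constant argument).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    dcor2 = dcov2 / np.sqrt(dvarx * dvary)
    return float(np.sqrt(max(dcor2, 0.0)))


def dcor_by_feature(x: ExpressionMatrix, ages: np.ndarray) -> pd.Series:
    """Per-feature distance correlation with age."""
    ages = np.asarray(ages, dtype=float)
    vals = x.values()
    out = np.array([distance_correlation(row, ages) for row in vals])
    return pd.Series(out, index=x.feature_ids, name="dcor")


def trajectory_stats(x: ExpressionMatrix, ages: np.ndarray) -> pd.DataFrame:
    """Pearson r and distance correlation with age for every feature."""
    return pd.concat([pearson_by_feature(x, ages), dcor_by_feature(x, ages)], axis=1)


def _spline_fit(r: np.ndarray, d: np.ndarray, df: int) -> np.ndarray:
    """Least-squares cubic spline of d on r with ``df`` basis functions.

    Internal knots are placed at quantiles of r; ``df`` coefficients give the
    stated equivalent degrees of freedom. Fitted values are returned at r.
    """
    order = np.argsort(r, kind="stable")
    rs, ds = r[order], d[order]
    k = 3
    n_internal = df - (k + 1)
    if n_internal > 0:
        qs = np.linspace(0, 1, n_internal + 2)[1:-1]
        internal = np.unique(np.quantile(rs, qs))
        # knots must sit strictly inside the data range
        internal = internal[(internal > rs[0]) & (internal < rs[-1])]
    else:
        internal = np.array([])
    t = np.concatenate([[rs[0]] * (k + 1), internal, [rs[-1]] * (k + 1)])
    spl = interpolate.make_lsq_spline(rs, ds, t, k=k)
    fitted = np.empty_like(r)
    fitted[order] = spl(rs)
    return fitted


def classify_nonlinear(
    stats_df: pd.DataFrame, df: int = 7, threshold: float = 0.15
) -> pd.DataFrame:
    """Flag predominantly nonlinear features via the spline-residual rule.

    Fits a cubic spline of distance correlation on Pearson correlation across
    features (``df`` degrees of freedom, default 7), then flags features with
    |dcor - spline| >= ``threshold``. Flagged features are categorized
    ``nonlinear_positive`` when their Pearson r is positive and
    ``nonlinear_negative`` otherwise; all remaining features are ``linear``.

    Parameters
    ----------
    stats_df :
        DataFrame with columns ``pearson_r`` and ``dcor`` indexed by feature.
        Rows with undefined (NaN) statistics are returned with empty category.
    """
    out = stats_df.copy()
    defined = out[["pearson_r", "dcor"]].notna().all(axis=1)
    n_def = int(defined.sum())
    if n_def < df + 2:
        raise ValidationError(f"need at least {df + 2} features with defined stats, got {n_def}")
    r = out.loc[defined, "pearson_r"].to_numpy()
    d = out.loc[defined, "dcor"].to_numpy()
    fitted = _spline_fit(r, d, df)
    residual = d - fitted
    flagged = np.abs(residual) >= threshold
    category = np.where(
        flagged, np.where(r > 0, "nonlinear_positive", "nonlinear_negative"), "linear"
    )
    out.loc[defined, "spline_fit"] = fitted
    out.loc[defined, "residual"] = residual
    out["category"] = ""
    out.loc[defined, "category"] = category
    return out


@dataclass
class QuadrantTable:
    """Cross-fraction sign-concordance quadrant counts and the 25% null test.

    Quadrant keys are (EV sign, fc sign) pairs. ``p_value`` is a chi-square
    goodness-of-fit test against (1/4, 1/4, 1/4, 1/4), replaced by an exact
    multinomial test when any expected count is below 5.
    """

    counts: dict[tuple[str, str], int]
    fractions: dict[tuple[str, str], float]
    n_excluded: int
    chi2_stat: float
    p_value: float
    method: str = "chi2"

    QUADRANTS = (("+", "+"), ("+", "-"), ("-", "+"), ("-", "-"))


def _exact_multinomial_gof(counts: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p against equal cell probabilities.

    p = P(pmf(X) <= pmf(observed)) over all count vectors with the same total.
    Only used for small totals (expected cell count < 5).
    """
    n = int(counts.sum())
    k = len(counts)
    probs = np.full(k, 1.0 / k)
    obs_p = stats.multinomial.pmf(counts, n, probs)
    total = 0.0
    for c in itertools.product(range(n + 1), repeat=k - 1):
        if sum(c) > n:
            continue
        vec = list(c) + [n - sum(c)]
        p = stats.multinomial.pmf(vec, n, probs)
        if p <= obs_p * (1 + 1e-12):
            total += p
    return float(min(total, 1.0))


def quadrant_concordance(r_ev: pd.Series, r_fc: pd.Series) -> QuadrantTable:
    """Tabulate the four cross-fraction correlation-sign quadrants.

    Features with zero or undefined correlation in either fraction are
    excluded and counted in ``n_excluded``. Under independent equiprobable
    signs each quadrant is expected to hold 25% of features.
    """
    r_ev, r_fc = r_ev.align(r_fc, join="inner")
    ev = r_ev.to_numpy(dtype=float)
    fc = r_fc.to_numpy(dtype=float)
    valid = np.isfinite(ev) & np.isfinite(fc) & (ev != 0) & (fc != 0)
    n_excluded = int((~valid).sum())
    ev, fc = ev[valid], fc[valid]
    if ev.size == 0:
        raise ValidationError("no features with defined non-zero correlations in both fractions")
    counts = {}
    for qe, qf in QuadrantTable.QUADRANTS:
        mask = ((ev > 0) == (qe == "+")) & ((fc > 0) == (qf == "+"))
        counts[(qe, qf)] = int(mask.sum())
    total = ev.size
    fractions = {k: v / total for k, v in counts.items()}
    arr = np.array([counts[q] for q in QuadrantTable.QUADRANTS])
    expected = total / 4.0
    if expected < 5:
        chi2 = float(((arr - expected) ** 2 / expected).sum())
        p = _exact_multinomial_gof(arr)
        method = "exact_multinomial"
    else:
        chi2, p = stats.chisquare(arr)
        chi2, p = float(chi2), float(p)
        method = "chi2"
    return QuadrantTable(
        counts=counts,
        fractions=fractions,
        n_excluded=n_excluded,
        chi2_stat=chi2,
        p_value=p,
        method=method,
    )


@dataclass
class MeanShiftResult:
    """Permutation test of the cross-fraction mean-correlation shift."""

    observed_mean_ev: float
    observed_mean_fc: float
    observed_difference: float
    null_means: np.ndarray = field(repr=False)
    p_value: float = float("nan")
    p_normal: float = float("nan")
    n_permutations: int = 0
    seed: int = 0


def _mean_pearson(values: np.ndarray, ages: np.ndarray) -> float:
    vc = values - values.mean(axis=1, keepdims=True)
    vs = np.sqrt((vc**2).sum(axis=1))
    ac = ages - ages.mean()
    an = np.sqrt((ac**2).sum())
    ok = vs > 0
    if not ok.any():
        return float("nan")
    r = (vc[ok] @ ac) / (vs[ok] * an)
    return float(r.mean())


def mean_shift_permutation_test(
    matrix_ev: ExpressionMatrix,
    matrix_fc: ExpressionMatrix,
    ages_ev: np.ndarray,
    ages_fc: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> MeanShiftResult:
    """Test whether the mean per-feature age correlation differs by fraction.

    The observed statistic is the difference of the mean per-feature Pearson
    correlation (EV minus fc). The null is built by shuffling age labels
    across samples within each fraction, keeping feature values fixed — this
    preserves the correlation structure among features while breaking the age
    signal. Two-sided p with add-one correction: p = (b + 1) / (B + 1).
    Zero-variance features are excluded (undefined correlation).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    shared = matrix_ev.feature_ids.intersection(matrix_fc.feature_ids)
    if len(shared) == 0:
        raise ValidationError("matrices share no features")
    v_ev = matrix_ev.subset_features(shared).values()
    v_fc = matrix_fc.subset_features(shared).values()
    ages_ev = np.asarray(ages_ev, dtype=float)
    ages_fc = np.asarray(ages_fc, dtype=float)
    if v_ev.shape[1] < 3 or v_fc.shape[1] < 3:
        raise ValidationError("need at least 3 samples per fraction")

    mean_ev = _mean_pearson(v_ev, ages_ev)
    mean_fc = _mean_pearson(v_fc, ages_fc)
    observed = mean_ev - mean_fc

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = _mean_pearson(v_ev, rng.permutation(ages_ev)) - _mean_pearson(
            v_fc, rng.permutation(ages_fc)
        )
    exceed = int((np.abs(null) >= abs(observed) - 1e-15).sum())
    p = (exceed + 1) / (n_permutations + 1)
    # normal-approximation p, clearly labelled as such
    mu, sd = null.mean(), null.std(ddof=1)
    p_norm = float(2 * stats.norm.sf(abs(observed - mu) / sd)) if sd > 0 else float("nan")
    return MeanShiftResult(
        observed_mean_ev=mean_ev,
        observed_mean_fc=mean_fc,
        observed_difference=observed,
        null_means=null,
        p_value=float(p),
        p_normal=p_norm,
        n_permutations=n_permutations,
        seed=seed,
    )


def baseline_relative_expression(
    x: ExpressionMatrix,
    samples: pd.DataFrame,
    features: pd.DataFrame,
    baseline_age: int = 2,
) -> pd.DataFrame:
    """Log2 class-total expression per age relative to the baseline age.

    For each RNA class and fraction, total class RPM is averaged over samples
    of each age and divided by the baseline-age value, then log2-transformed.
    The baseline column is exactly 0; classes with zero baseline expression
    get NaN (undefined) rather than +/- infinity.
    """
    meta = samples.set_index("sample_id")
    if baseline_age not in set(meta["age_months"]):
        raise ValidationError(f"baseline age {baseline_age} not present in cohort")
    classes = features.set_index("feature_id")["rna_class"]
    cls_of = classes.loc[x.feature_ids]
    ages = sorted(meta["age_months"].unique())
    rows = {}
    for frac in sorted(meta["fraction"].unique()):
        for cls in sorted(cls_of.unique()):
            feats = x.feature_ids[cls_of == cls]
            vals = {}
            for age in ages:
                cols = meta.index[(meta["fraction"] == frac) & (meta["age_months"] == age)]
                cols = [c for c in cols if c in x.sample_ids]
                if not cols:
                    vals[age] = np.nan
                    continue
                vals[age] = x.data.loc[feats, cols].sum(axis=0).mean()
            base = vals.get(baseline_age, np.nan)
            if not np.isfinite(base) or base <= 0:
                warnings.warn(f"class {cls}/{frac}: zero baseline expression", stacklevel=2)
                rows[(cls, frac)] = {a: np.nan for a in ages}
            else:
                rows[(cls, frac)] = {
                    a: (np.log2(v / base) if np.isfinite(v) and v > 0 else np.nan)
                    for a, v in vals.items()
                }
    out = pd.DataFrame(rows).T
    out.index.names = ["rna_class", "fraction"]
    return out
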