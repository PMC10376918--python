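"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design: five age groups across the lifespan
(2, 6, 8, 12, 18 months), two plasma fractions (EV, FC), a small number of
replicates per group and fraction, ten RNA classes, planted linear and purely
nonlinear age trajectories with fraction-specific sign structure, and
overdispersed (gamma-Poisson, i.e. negative-binomial) count noise.

Age-group truth follows the grouping young = 2 months, middle = 6-8 months,
old = 12-18 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import DEFAULT_RNA_CLASSES, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "age_group_label",
    "simulate_cohort",
    "simulate_target_atlas",
    "simulate_qpcr",
]

AGE_GROUPS: dict[str, tuple[int, ...]] = {
    "young": (2,),
    "middle": (6, 8),
    "old": (12, 18),
}


def age_group_label(age_months: int, groups: Mapping[str, Sequence[int]] = AGE_GROUPS) -> str:
    """Map an age in months to its young/middle/old group label."""
    for label, months in groups.items():
        if age_months in months:
            return label
    raise ValueError(f"age {age_months} not covered by group definition {dict(groups)}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` is the planted mean shift, in within-group standard
    deviations (on the log scale), across the full age range. ``dispersion``
    is the gamma-Poisson overdispersion parameter (variance = mu + phi*mu^2).
    """

    n_features_per_class: int = 50
    class_labels: tuple[str, ...] = DEFAULT_RNA_CLASSES
    age_groups: tuple[int, ...] = (2, 6, 8, 12, 18)
    replicates_per_group_per_fraction: int = 4
    linear_fraction: float = 0.4
    nonlinear_fraction: float = 0.1
    discordant_fraction: float = 0.2
    effect_size: float = 2.0
    dispersion: float = 0.05
    fraction_effect: float = 0.0
    #: plant discrete per-age-group mean shifts with independent per-feature
    #: group profiles instead of trends continuous in months. This yields
    #: three affinely independent group centroids — the three-archetype
    #: structure the group classifier assumes (collinear centroids make the
    #: middle archetype a convex combination of the outer two and soften P)
    group_structure: bool = False
    base_log_mean: float = float(np.log(300.0))
    base_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features_per_class < 1 or not self.class_labels:
            raise ValueError("degenerate config: no features")
        if self.replicates_per_group_per_fraction < 1 or not self.age_groups:
            raise ValueError("degenerate config: no samples")
        for name in ("linear_fraction", "nonlinear_fraction", "discordant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.linear_fraction + self.nonlinear_fraction > 1.0 + 1e-12:
            raise ValueError("linear_fraction + nonlinear_fraction must be <= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    @property
    def n_features(self) -> int:
        return self.n_features_per_class * len(self.class_labels)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort.

    ``features`` has columns planted_shape (flat/linear_up/linear_down/
    nonlinear), planted_sign_ev and planted_sign_fc (+/-/0), indexed by
    feature id. ``sample_groups`` maps sample id to young/middle/old.
    """

    features: pd.DataFrame
    sample_groups: pd.Series
    config: SimulationConfig = field(repr=False, default=None)


def _linear_covariate(ages: np.ndarray) -> np.ndarray:
    """Centered age, scaled so the full range spans 1."""
    a = ages.astype(float)
    return (a - a.mean()) / (a.max() - a.min())


def _quadratic_covariate(ages: np.ndarray) -> np.ndarray:
    """Quadratic age shape orthogonalized against the linear trend.

    By construction the sample Pearson correlation with age is exactly 0 on
    the design points, while the curvature is non-zero; scaled to max |.| = 1.
    """
    a = ages.astype(float)
    q = (a - a.mean()) ** 2
    lin = a - a.mean()
    q = q - q.mean() - (q @ lin) / (lin @ lin) * lin
    return q / np.abs(q).max()


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate a seeded synthetic cohort.

    Returns the raw count matrix, sample sheet, feature sheet and the planted
    truth. Deterministic for a fixed config (independent RNG streams for the
    planted structure and the count noise are spawned from the master seed).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    # -- samples: same age design in both fractions, mice shared across fractions
    rows = []
    for frac in ("EV", "FC"):
        for age in cfg.age_groups:
            for rep in range(1, cfg.replicates_per_group_per_fraction + 1):
                rows.append(
                    {
                        "sample_id": f"{frac}_{age}m_r{rep}",
                        "mouse_id": f"m{age}_{rep}",
                        "age_months": age,
                        "fraction": frac,
                    }
                )
    samples = pd.DataFrame(rows)
    ages = samples["age_months"].to_numpy()
    is_ev = (samples["fraction"] == "EV").to_numpy()

    u_lin = np.empty(len(samples))
    u_quad = np.empty(len(samples))
    for mask in (is_ev, ~is_ev):
        u_lin[mask] = _linear_covariate(ages[mask])
        u_quad[mask] = _quadratic_covariate(ages[mask])
    group_idx = np.array(
        [("young", "middle", "old").index(age_group_label(a)) for a in ages]
    )

    # -- features
    m = cfg.n_features
    feature_ids = [
        f"{cls}_{i:05d}" for cls in cfg.class_labels for i in range(cfg.n_features_per_class)
    ]
    features = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "rna_class": np.repeat(list(cfg.class_labels), cfg.n_features_per_class),
        }
    )

    draw = rng_struct.random(m)
    shape = np.where(
        draw < cfg.linear_fraction,
        "linear",
        np.where(draw < cfg.linear_fraction + cfg.nonlinear_fraction, "nonlinear", "flat"),
    )
    if cfg.effect_size == 0:  # zero amplitude plants no trajectory at all
        shape = np.full(m, "flat")
    lin_sign = rng_struct.choice([-1.0, 1.0], size=m)
    quad_sign = rng_struct.choice([-1.0, 1.0], size=m)
    discordant = rng_struct.random(m) < cfg.discordant_fraction
    base = rng_struct.normal(cfg.base_log_mean, cfg.base_log_sd, size=m)
    # per-feature fraction coefficient: a global shift would cancel under RPM
    # normalization, so the planted fraction effect varies across features
    frac_coef = rng_struct.normal(0.0, 1.0, size=m)

    sigma = float(np.sqrt(cfg.dispersion))  # approx. within-group log-scale sd
    amp = cfg.effect_size * sigma

    sign_ev = np.where(shape == "linear", lin_sign, 0.0)
    sign_fc = np.where(discordant, -sign_ev, sign_ev)

    shape_label = np.where(
        shape == "linear",
        np.where(lin_sign > 0, "linear_up", "linear_down"),
        shape,
    )
    truth_features = pd.DataFrame(
        {
            "planted_shape": shape_label,
            "planted_sign_ev": np.where(sign_ev > 0, "+", np.where(sign_ev < 0, "-", "0")),
            "planted_sign_fc": np.where(sign_fc > 0, "+", np.where(sign_fc < 0, "-", "0")),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    # -- planted log-scale means
    is_lin = (shape == "linear").astype(float)
    is_quad = (shape == "nonlinear").astype(float)
    slope = np.where(is_ev[None, :], sign_ev[:, None], sign_fc[:, None])
    if cfg.group_structure:
        group_profiles = rng_struct.normal(0.0, 1.0, size=(m, 3))
        age_term = amp * is_lin[:, None] * group_profiles[:, group_idx]
    else:
        age_term = (
            amp * is_lin[:, None] * slope * u_lin[None, :]
            # nonlinear amplitude x2.5: the orthogonalized quadratic has lower
            # variance than a full-range linear trend at equal max amplitude
            + 2.5 * amp * is_quad[:, None] * quad_sign[:, None] * u_quad[None, :]
        )
    log_mu = (
        base[:, None]
        + age_term
        + cfg.fraction_effect * sigma * frac_coef[:, None] * np.where(is_ev[None, :], 0.5, -0.5)
    )
    mu = np.exp(log_mu)

    # -- gamma-Poisson counts
    g = rng_noise.gamma(shape=1.0 / cfg.dispersion, scale=cfg.dispersion, size=mu.shape)
    counts = rng_noise.poisson(mu * g).astype(float)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=samples["sample_id"]),
        unit="raw_counts",
    )
    sample_groups = pd.Series(
        [age_group_label(a) for a in samples["age_months"]],
        index=samples["sample_id"],
        name="age_group",
    )
    truth = SimulationTruth(features=truth_features, sample_groups=sample_groups, config=cfg)
    return matrix, samples, features, truth


def simulate_target_atlas(
    n_mirnas: int,
    n_genes: int,
    n_tissues: int,
    repression_strength: float,
    seed: int = 0,
    ages: Sequence[int] = (2, 6, 8, 12, 18),
    noise_sd: float = 0.1,
    strong_fraction: float = 0.8,
    max_regulators: int = 3,
    ensure_hubs: bool = True,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame, dict]:
    """Generate a miRNA->gene target atlas with planted repression.

    Each gene's age trend equals ``-repression_strength`` times the sum of
    its regulators' planted slopes, plus Gaussian noise. Edge evidence labels
    are strong with probability ``strong_fraction``, weak otherwise.

    Returns (edge table, per-tissue gene-by-age tables, miRNA-by-age table,
    truth dict with planted slopes and regulator assignments).
    """
    if n_mirnas < 1 or n_genes < 1 or n_tissues < 1:
        raise ValueError("n_mirnas, n_genes and n_tissues must be positive")
    if repression_strength < 0:
        raise ValueError("repression_strength must be >= 0")
    if ensure_hubs and max_regulators >= 3 and n_mirnas < 3:
        raise ValueError("hub guarantee needs at least 3 miRNAs")
    rng = np.random.default_rng(seed)
    a = np.asarray(ages, dtype=float)
    u = _linear_covariate(a)

    mirna_ids = [f"miR-{i:03d}" for i in range(n_mirnas)]
    gene_ids = [f"Gene{i:04d}" for i in range(n_genes)]
    # alternate planted slope signs so both sign pools are populated
    signs = np.where(np.arange(n_mirnas) % 2 == 0, 1.0, -1.0)
    mirna_slopes = rng.uniform(0.5, 1.0, size=n_mirnas) * signs

    # each gene's regulators share a slope sign, so the planted repression
    # gives every target an unambiguous expected age trend
    pools = {
        s: [i for i in range(n_mirnas) if signs[i] == s] for s in (1.0, -1.0) if (signs == s).any()
    }
    regulators: dict[str, list[str]] = {}
    edge_rows = []
    for gi, gene in enumerate(gene_ids):
        if ensure_hubs and gi == 0:
            # first gene drawn from the larger pool with up to 3 regulators
            pool = max(pools.values(), key=len)
            n_reg = min(3, len(pool))
        else:
            pool = pools[rng.choice(sorted(pools))]
            n_reg = int(rng.integers(1, min(max_regulators, len(pool)) + 1))
        regs = rng.choice(pool, size=n_reg, replace=False)
        regulators[gene] = [mirna_ids[r] for r in regs]
        for r in regs:
            evidence = "strong" if rng.random() < strong_fraction else "weak"
            edge_rows.append({"mirna_id": mirna_ids[r], "gene_id": gene, "evidence": evidence})
    edges = pd.DataFrame(edge_rows)

    reg_slope_sum = np.array(
        [sum(mirna_slopes[mirna_ids.index(r)] for r in regulators[g]) for g in gene_ids]
    )
    gene_slopes = -repression_strength * reg_slope_sum + rng.normal(0, noise_sd, size=n_genes)

    mirna_expr = pd.DataFrame(
        10.0 + np.outer(mirna_slopes, u) + rng.normal(0, noise_sd, size=(n_mirnas, len(a))),
        index=mirna_ids,
        columns=[str(int(x)) for x in a],
    )
    tissues = {}
    for t in range(n_tissues):
        tissues[f"tissue_{t:02d}"] = pd.DataFrame(
            10.0 + np.outer(gene_slopes, u) + rng.normal(0, noise_sd, size=(n_genes, len(a))),
            index=gene_ids,
            columns=[str(int(x)) for x in a],
        )
    truth = {
        "mirna_slopes": pd.Series(mirna_slopes, index=mirna_ids),
        "gene_slopes": pd.Series(gene_slopes, index=gene_ids),
        "regulators": regulators,
    }
    return edges, tissues, mirna_expr, truth


def simulate_qpcr(
    n_young: int,
    n_old: int,
    true_log2fc: Mapping[str, float],
    control_ct: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    control_assays: tuple[str, str] = ("miR-191a", "let-7a"),
) -> pd.DataFrame:
    """Generate a long-format Ct table with planted old-vs-young fold changes.

    Target Ct drops by ``true_log2fc`` cycles in the old group (one cycle =
    one doubling); control assays stay at ``control_ct`` up to noise.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("group sizes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    groups = [("young", i) for i in range(n_young)] + [("old", i) for i in range(n_old)]
    for group, i in groups:
        sample = f"{group}_{i + 1}"
        for assay in control_assays:
            rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "assay_id": assay,
                    "ct": control_ct + rng.normal(0, noise_sd),
                }
            )
        for assay, fc in true_log2fc.items():
            ct = control_ct - fc * (group == "old") + rng.normal(0, noise_sd)
            rows.append({"sample_id": sample, "group": group, "assay_id": assay, "ct": ct})
    return pd.DataFrame(rows)
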