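"""Pipeline orchestration: stage ordering, per-class splitting, manifests.

Stages run in dependency order (io -> trajectory -> nmf / clustering /
variance -> enrichment / network -> qpcr). The constrained-NMF classifier
runs once per RNA class and fraction (the per-class split of the expression
matrix); classes with too few features are skipped with a logged reason.
Every output file lands in the manifest with a SHA-256 checksum, so a rerun
with the same config and master seed is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age_nmf, clustering, enrichment, qpcr, target_network, trajectory, variance
from .core_io import (
    ExpressionMatrix,
    ValidationError,
    filter_expressed,
    normalize_rpm,
    read_expression,
)
from .synthetic import SimulationConfig, age_group_label, simulate_cohort, simulate_qpcr, \
    simulate_target_atlas

logger = logging.getLogger("evcargo")

__all__ = ["PipelineConfig", "run_pipeline", "generate_fixtures", "sha256_file"]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


@dataclass
class PipelineConfig:
    """Flat, file-loadable configuration of a full pipeline run."""

    matrix_path: str = ""
    sample_sheet_path: str = ""
    feature_sheet_path: str = ""
    categories_path: str = ""  # optional GMT
    target_edges_path: str = ""  # optional miRNA->gene TSV
    ct_table_path: str = ""  # optional qPCR Ct TSV
    out_dir: str = "results"
    seed: int = 0
    min_rpm: float = 5.0
    spline_df: int = 7
    nonlinear_threshold: float = 0.15
    nmf_restarts: int = 10
    nmf_k: int = 3
    cut_factor: float = 1.25
    n_permutations: int = 1000
    hub_threshold: int = 3
    enrichment_magnitude: float = 3.0
    min_class_features: int = 10
    young_months: tuple[int, ...] = (2,)
    middle_months: tuple[int, ...] = (6, 8)
    old_months: tuple[int, ...] = (12, 18)

    def __post_init__(self) -> None:
        sets = [set(self.young_months), set(self.middle_months), set(self.old_months)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValidationError(
                        f"age-group month sets overlap: {sorted(sets[i] & sets[j])}"
                    )
        if not 0 < self.min_rpm < 1e6 and self.min_rpm != 0:
            raise ValidationError("min_rpm out of range")
        if self.nonlinear_threshold < 0 or self.cut_factor <= 1:
            raise ValidationError("threshold parameters out of documented range")

    @property
    def age_groups(self) -> dict[str, tuple[int, ...]]:
        return {
            "young": tuple(self.young_months),
            "middle": tuple(self.middle_months),
            "old": tuple(self.old_months),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("young_months", "middle_months", "old_months"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("young_months", "middle_months", "old_months"):
            d[key] = list(d[key])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class Manifest:
    config: dict
    completed: list[str] = field(default_factory=list)
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    error: str | None = None

    def record(self, stage: str, files: list[Path]) -> None:
        self.outputs[stage] = {str(p): sha256_file(p) for p in files}
        self.completed.append(stage)
        logger.info("stage=%s outputs=%d", stage, len(files))

    def write(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _fraction_ages(samples: pd.DataFrame, x: ExpressionMatrix, frac: str):
    meta = samples.set_index("sample_id")
    cols = [s for s in x.sample_ids if meta.loc[s, "fraction"] == frac]
    ages = meta.loc[cols, "age_months"].to_numpy(dtype=float)
    return cols, ages


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Execute all stages over a cohort; returns the run manifest.

    Any stage error aborts the run; the manifest (with the stages completed
    so far and the error message) is still written before the exception
    propagates.
    """
    out = Path(config.out_dir)
    manifest = Manifest(config=asdict(config))
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:  # record partial progress, then re-raise
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: Manifest) -> None:
    rng_seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_perm, seed_nmf, seed_enrich, _ = (int(s.generate_state(1)[0]) for s in rng_seeds)

    # ---- io ----
    matrix, samples, features = read_expression(
        config.matrix_path, config.sample_sheet_path, config.feature_sheet_path
    )
    rpm = normalize_rpm(matrix)
    expressed = filter_expressed(rpm, min_rpm=config.min_rpm)
    manifest.record("io", [])

    meta = samples.set_index("sample_id")
    classes = features.set_index("feature_id")["rna_class"]
    fractions = sorted(meta.loc[list(expressed.sample_ids), "fraction"].unique())

    # ---- trajectory ----
    stats_files = []
    stats_by_fraction: dict[str, pd.DataFrame] = {}
    corr_by_fraction: dict[str, pd.Series] = {}
    for frac in fractions:
        cols, ages = _fraction_ages(samples, expressed, frac)
        sub = expressed.subset_samples(cols)
        stats = trajectory.trajectory_stats(sub, ages)
        try:
            stats = trajectory.classify_nonlinear(
                stats, df=config.spline_df, threshold=config.nonlinear_threshold
            )
        except ValidationError as exc:
            manifest.warnings.append(f"trajectory/{frac}: nonlinearity skipped ({exc})")
        stats_by_fraction[frac] = stats
        corr_by_fraction[frac] = stats["pearson_r"]
        stats_files.append(_write_tsv(stats, out / f"trajectory_{frac}.tsv"))

    if {"EV", "FC"} <= set(fractions):
        quad = trajectory.quadrant_concordance(corr_by_fraction["EV"], corr_by_fraction["FC"])
        quad_df = pd.DataFrame(
            [
                {
                    "quadrant": f"EV{qe}/fc{qf}",
                    "count": quad.counts[(qe, qf)],
                    "fraction": quad.fractions[(qe, qf)],
                }
                for qe, qf in quad.QUADRANTS
            ]
        )
        quad_df["n_excluded"] = quad.n_excluded
        quad_df["chi2_p"] = quad.p_value
        stats_files.append(_write_tsv(quad_df, out / "quadrants_all.tsv", index=False))
        # per-class quadrant tables
        qc_rows = []
        for cls in sorted(classes.loc[expressed.feature_ids].unique()):
            feats = expressed.feature_ids[classes.loc[expressed.feature_ids] == cls]
            if len(feats) < 4:
                continue
            try:
                q = trajectory.quadrant_concordance(
                    corr_by_fraction["EV"].loc[corr_by_fraction["EV"].index.isin(feats)],
                    corr_by_fraction["FC"].loc[corr_by_fraction["FC"].index.isin(feats)],
                )
            except ValidationError:
                continue
            for qe, qf in q.QUADRANTS:
                qc_rows.append(
                    {
                        "rna_class": cls,
                        "quadrant": f"EV{qe}/fc{qf}",
                        "count": q.counts[(qe, qf)],
                        "fraction": q.fractions[(qe, qf)],
                        "chi2_p": q.p_value,
                    }
                )
        if qc_rows:
            stats_files.append(
                _write_tsv(pd.DataFrame(qc_rows), out / "quadrants_by_class.tsv", index=False)
            )

        ev_cols, ev_ages = _fraction_ages(samples, expressed, "EV")
        fc_cols, fc_ages = _fraction_ages(samples, expressed, "FC")
        shift = trajectory.mean_shift_permutation_test(
            expressed.subset_samples(ev_cols),
            expressed.subset_samples(fc_cols),
            ev_ages,
            fc_ages,
            n_permutations=config.n_permutations,
            seed=seed_perm,
        )
        logger.info(
            "mean_shift seed=%d n_permutations=%d p=%g",
            seed_perm, config.n_permutations, shift.p_value,
        )
        shift_df = pd.DataFrame(
            [
                {
                    "mean_ev": shift.observed_mean_ev,
                    "mean_fc": shift.observed_mean_fc,
                    "difference": shift.observed_difference,
                    "p_value": shift.p_value,
                    "p_normal_approx": shift.p_normal,
                    "n_permutations": shift.n_permutations,
                    "seed": shift.seed,
                }
            ]
        )
        stats_files.append(_write_tsv(shift_df, out / "mean_shift.tsv", index=False))
    manifest.record("trajectory", stats_files)

    # ---- nmf (per class x fraction) ----
    nmf_files = []
    nmf_rows = []
    sample_rows = []
    for frac in fractions:
        cols, _ = _fraction_ages(samples, expressed, frac)
        truth = [
            age_group_label(int(meta.loc[s, "age_months"]), config.age_groups) for s in cols
        ]
        for cls in sorted(classes.loc[expressed.feature_ids].unique()):
            feats = expressed.feature_ids[classes.loc[expressed.feature_ids] == cls]
            if len(feats) < config.min_class_features:
                manifest.warnings.append(
                    f"nmf/{cls}/{frac}: skipped ({len(feats)} < {config.min_class_features} features)"
                )
                continue
            D = expressed.subset_features(feats).subset_samples(cols).values()
            if D.max() <= 0:
                continue
            fit = age_nmf.fit_age_nmf(
                age_nmf.normalize_max(D),
                k=config.nmf_k,
                n_restarts=config.nmf_restarts,
                seed=seed_nmf,
            )
            fit = age_nmf.classify_and_score(fit, truth)
            nmf_rows.append(
                {
                    "rna_class": cls,
                    "fraction": frac,
                    "accuracy": fit.accuracy,
                    "objective": fit.objective,
                    "seed": seed_nmf,
                }
            )
            for j, s in enumerate(cols):
                row = {"sample_id": s, "rna_class": cls, "fraction": frac, "truth": truth[j]}
                for g in range(fit.k):
                    row[f"P{g + 1}"] = fit.P[g, j]
                row["predicted"] = fit.permutation_used[fit.labels[j]]
                sample_rows.append(row)
    if nmf_rows:
        nmf_files.append(_write_tsv(pd.DataFrame(nmf_rows), out / "nmf_summary.tsv", index=False))
        nmf_files.append(
            _write_tsv(pd.DataFrame(sample_rows), out / "nmf_samples.tsv", index=False)
        )
    manifest.record("nmf", nmf_files)

    # ---- clustering ----
    cluster_files = []
    if {"EV", "FC"} <= set(fractions):
        ev_cols, _ = _fraction_ages(samples, expressed, "EV")
        fc_cols, _ = _fraction_ages(samples, expressed, "FC")
        res_ev = clustering.cluster_features(
            expressed.subset_samples(ev_cols), min_rpm=config.min_rpm,
            cut_factor=config.cut_factor,
        )
        res_fc = clustering.cluster_features(
            expressed.subset_samples(fc_cols), min_rpm=config.min_rpm,
            cut_factor=config.cut_factor,
        )
        res_ev, res_fc, overlap = clustering.summarize_and_map(
            res_ev, res_fc, stats_by_fraction["EV"], stats_by_fraction["FC"]
        )
        cluster_files.append(
            _write_tsv(res_ev.assignments.to_frame(), out / "clusters_EV.tsv")
        )
        cluster_files.append(
            _write_tsv(res_fc.assignments.to_frame(), out / "clusters_FC.tsv")
        )
        cluster_files.append(_write_tsv(res_ev.summary, out / "cluster_summary_EV.tsv"))
        cluster_files.append(_write_tsv(res_fc.summary, out / "cluster_summary_FC.tsv"))
        cluster_files.append(_write_tsv(overlap, out / "cluster_overlap.tsv"))
    manifest.record("clustering", cluster_files)

    # ---- variance attribution (per class) ----
    var_files = []
    var_rows = []
    for cls in sorted(classes.loc[expressed.feature_ids].unique()):
        feats = expressed.feature_ids[classes.loc[expressed.feature_ids] == cls]
        if len(feats) < 2:
            continue
        try:
            attr = variance.variance_attribution(expressed.subset_features(feats), samples)
        except ValidationError as exc:
            manifest.warnings.append(f"variance/{cls}: skipped ({exc})")
            continue
        for factor, prop in attr.proportions.items():
            var_rows.append({"rna_class": cls, "factor": factor, "proportion": prop})
    if var_rows:
        var_files.append(
            _write_tsv(pd.DataFrame(var_rows), out / "variance_attribution.tsv", index=False)
        )
    manifest.record("variance", var_files)

    # ---- enrichment (miRNAs ranked by age correlation) ----
    enrich_files = []
    if config.categories_path:
        categories = enrichment.read_gmt(config.categories_path)
        results = {}
        for frac in fractions:
            mirna_feats = expressed.feature_ids[
                classes.loc[expressed.feature_ids] == "miRNA"
            ]
            corr = corr_by_fraction[frac].loc[
                corr_by_fraction[frac].index.isin(mirna_feats)
            ]
            if corr.dropna().empty:
                manifest.warnings.append(f"enrichment/{frac}: no ranked miRNAs")
                continue
            ranked = enrichment.rank_by_correlation(corr)
            res = enrichment.set_enrichment(
                ranked, categories, n_permutations=config.n_permutations, seed=seed_enrich
            )
            results[frac] = res
            df = pd.DataFrame(
                [
                    {
                        "category": r.category,
                        "size": r.size,
                        "es": r.es,
                        "p_value": r.p_value,
                        "q_value": r.q_value,
                    }
                    for r in res
                ]
            )
            enrich_files.append(_write_tsv(df, out / f"enrichment_{frac}.tsv", index=False))
        if {"EV", "FC"} <= set(results):
            contrast = enrichment.fraction_contrast(
                results["EV"], results["FC"], magnitude=config.enrichment_magnitude
            )
            enrich_files.append(
                _write_tsv(contrast, out / "enrichment_contrast.tsv", index=False)
            )
    manifest.record("enrichment", enrich_files)

    # ---- target network ----
    net_files = []
    if config.target_edges_path and "EV" in corr_by_fraction:
        edges = target_network.read_edge_table(config.target_edges_path)
        mirna_feats = expressed.feature_ids[classes.loc[expressed.feature_ids] == "miRNA"]
        corr = corr_by_fraction["EV"].loc[corr_by_fraction["EV"].index.isin(mirna_feats)]
        net = target_network.build_network(
            edges, corr.dropna().to_dict(), hub_threshold=config.hub_threshold
        )
        edge_rows = [
            {"mirna_id": u, "gene_id": v, "evidence": d["evidence"],
             "hub": v in net.hub_genes}
            for u, v, d in net.graph.edges(data=True)
        ]
        net_files.append(
            _write_tsv(
                pd.DataFrame(edge_rows, columns=["mirna_id", "gene_id", "evidence", "hub"]),
                out / "network_edges.tsv",
                index=False,
            )
        )
    manifest.record("network", net_files)

    # ---- qpcr ----
    qpcr_files = []
    if config.ct_table_path:
        table = pd.read_csv(config.ct_table_path, sep="\t")
        controls = ("miR-191a", "let-7a")
        assays = sorted(set(table["assay_id"]) - set(controls) - set(qpcr.SPIKE_IN_ASSAYS))
        rows = []
        for assay in assays:
            res = qpcr.delta_delta_ct(table, assay, controls)
            rows.append(
                {
                    "assay": assay,
                    "log2_fold_change": res.log2_fold_change,
                    "n_reference": res.n_reference,
                    "n_comparison": res.n_comparison,
                }
            )
        if rows:
            qpcr_files.append(_write_tsv(pd.DataFrame(rows), out / "qpcr.tsv", index=False))
    manifest.record("qpcr", qpcr_files)


# ---------------------------------------------------------------------------
# fixture generation

PRESETS: dict[str, dict] = {
    "tiny": dict(n_features_per_class=5, replicates_per_group_per_fraction=2),
    "default": dict(),
    "stress": dict(n_features_per_class=200, replicates_per_group_per_fraction=4),
}


def generate_fixtures(preset: str, seed: int, out_dir: str | Path) -> Path:
    """Write a complete, internally consistent input set for tests and docs.

    Produces expression/sample/feature TSVs, planted-truth tables, a target
    atlas (edge table + per-tissue expression + miRNA table), a Ct table, a
    GMT category file and a ready-to-run pipeline config.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r} (choose from {sorted(PRESETS)})")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed, **PRESETS[preset])
    matrix, samples, features, truth = simulate_cohort(cfg)

    _write_tsv(matrix.data.rename_axis("feature_id"), out / "expression.tsv")
    _write_tsv(samples, out / "samples.tsv", index=False)
    _write_tsv(features, out / "features.tsv", index=False)
    _write_tsv(truth.features, out / "truth_features.tsv")
    _write_tsv(truth.sample_groups.to_frame(), out / "truth_samples.tsv")

    rng = np.random.default_rng(seed)
    edges, tissues, mirna_expr, _ = simulate_target_atlas(
        n_mirnas=8, n_genes=30, n_tissues=3, repression_strength=1.0, seed=seed
    )
    # tie atlas miRNA ids to cohort miRNA features so the network stage can
    # annotate them with cohort age correlations
    cohort_mirnas = features.loc[features["rna_class"] == "miRNA", "feature_id"].tolist()
    rename = {
        old: cohort_mirnas[i % len(cohort_mirnas)]
        for i, old in enumerate(mirna_expr.index)
    }
    edges = edges.assign(mirna_id=edges["mirna_id"].map(rename))
    edges = edges.drop_duplicates(subset=["mirna_id", "gene_id"])
    mirna_expr = mirna_expr.rename(index=rename)
    mirna_expr = mirna_expr[~mirna_expr.index.duplicated()]
    _write_tsv(edges, out / "targets.tsv", index=False)
    _write_tsv(mirna_expr.rename_axis("mirna_id"), out / "mirna_atlas.tsv")
    for tissue, table in tissues.items():
        _write_tsv(table.rename_axis("gene_id"), out / f"{tissue}.tsv")

    ct = simulate_qpcr(4, 2, {"miR-29a-3p": 1.5, "miR-455-5p": -1.0}, noise_sd=0.2, seed=seed)
    _write_tsv(ct, out / "ct.tsv", index=False)

    # random GMT categories over the simulated miRNA features
    mirna_ids = features.loc[features["rna_class"] == "miRNA", "feature_id"].tolist()
    with open(out / "categories.gmt", "w", encoding="utf-8") as fh:
        for i in range(5):
            size = max(3, len(mirna_ids) // 5)
            members = rng.choice(mirna_ids, size=min(size, len(mirna_ids)), replace=False)
            fh.write("\t".join([f"category_{i:02d}", "synthetic"] + sorted(members)) + "\n")

    pconf = PipelineConfig(
        matrix_path=str(out / "expression.tsv"),
        sample_sheet_path=str(out / "samples.tsv"),
        feature_sheet_path=str(out / "features.tsv"),
        categories_path=str(out / "categories.gmt"),
        target_edges_path=str(out / "targets.tsv"),
        ct_table_path=str(out / "ct.tsv"),
        out_dir=str(out / "results"),
        seed=seed,
        n_permutations=100 if preset == "tiny" else 1000,
        min_class_features=5 if preset == "tiny" else 10,
    )
    pconf.to_yaml(out / "config.yaml")
    return out
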