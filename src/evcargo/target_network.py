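"""miRNA -> gene target network construction and target-age concordance.

Edges come from a miRTarBase-like table with an evidence level; the network
is restricted to strong-evidence (experimentally validated) interactions by
default. Hub genes are those targeted by at least ``hub_threshold`` miRNAs.
Two concordance views: (1) per tissue, the mean age correlation of the
target genes of each miRNA sign group (expectation under repression: miRNAs
up with age have targets down with age, and vice versa); (2) the direct
miRNA-target expression correlation across shared samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd

from .trajectory import age_correlation

__all__ = [
    "TargetNetwork",
    "build_network",
    "target_age_concordance",
    "direct_target_correlation",
    "read_edge_table",
    "sign_groups",
]

EVIDENCE_LEVELS = ("strong", "weak")

#: Example mapping from source-database evidence vocabulary to the internal
#: two-level enum; configurable on read.
DEFAULT_EVIDENCE_MAP = {
    "Functional MTI": "strong",
    "Functional MTI (Weak)": "weak",
    "Non-Functional MTI": "weak",
    "strong": "strong",
    "weak": "weak",
}


def read_edge_table(
    path, evidence_map: Mapping[str, str] = DEFAULT_EVIDENCE_MAP
) -> pd.DataFrame:
    """Read a miRNA->gene edge TSV, mapping source evidence labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "gene_id", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    df = df.copy()
    df["evidence"] = df["evidence"].map(lambda e: evidence_map.get(e, e))
    bad = set(df["evidence"]) - set(EVIDENCE_LEVELS)
    if bad:
        raise ValueError(f"unmapped evidence labels: {sorted(bad)}")
    return df


@dataclass
class TargetNetwork:
    """Bipartite miRNA -> gene network with age annotation and hubs."""

    graph: nx.DiGraph = field(repr=False)
    hub_genes: set[str] = field(default_factory=set)
    hub_threshold: int = 3

    @property
    def mirnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "mirna"}

    @property
    def genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"}

    def targets_of(self, mirna: str) -> set[str]:
        if mirna not in self.graph:
            return set()
        return set(self.graph.successors(mirna))


def build_network(
    edges: pd.DataFrame,
    mirna_age_corr: Mapping[str, float],
    evidence_filter: str | None = "strong",
    hub_threshold: int = 3,
    min_abs_corr: float = 0.0,
) -> TargetNetwork:
    """Build the evidence-filtered bipartite network.

    miRNAs without an age-correlation annotation are dropped with a warning;
    ``min_abs_corr`` optionally restricts the network to miRNAs whose
    absolute age correlation reaches the inclusion threshold. An empty
    post-filter network is returned (with a warning), not raised.
    """
    g = nx.DiGraph()
    dropped = set()
    for row in edges.itertuples(index=False):
        if not row.mirna_id or not row.gene_id:
            raise ValueError("empty node id in edge table")
        if evidence_filter is not None and row.evidence != evidence_filter:
            continue
        if row.mirna_id not in mirna_age_corr:
            dropped.add(row.mirna_id)
            continue
        corr = mirna_age_corr[row.mirna_id]
        if not np.isfinite(corr) or abs(corr) < min_abs_corr:
            continue
        g.add_node(row.mirna_id, kind="mirna", age_corr=float(corr))
        g.add_node(row.gene_id, kind="gene")
        g.add_edge(row.mirna_id, row.gene_id, evidence=row.evidence)
    if dropped:
        warnings.warn(f"miRNAs without age correlation dropped: {sorted(dropped)}", stacklevel=2)
    if g.number_of_edges() == 0:
        warnings.warn("empty network after evidence filtering", stacklevel=2)
    hubs = {
        n
        for n, d in g.nodes(data=True)
        if d.get("kind") == "gene" and g.in_degree(n) >= hub_threshold
    }
    return TargetNetwork(graph=g, hub_genes=hubs, hub_threshold=hub_threshold)


def sign_groups(
    corr_ev: Mapping[str, float] | None = None,
    corr_fc: Mapping[str, float] | None = None,
) -> dict[str, set[str]]:
    """Partition miRNAs into up/down sign groups per fraction."""
    groups: dict[str, set[str]] = {}
    for label, corr in (("EV", corr_ev), ("fc", corr_fc)):
        if corr is None:
            continue
        groups[f"{label}_up"] = {m for m, r in corr.items() if np.isfinite(r) and r > 0}
        groups[f"{label}_down"] = {m for m, r in corr.items() if np.isfinite(r) and r < 0}
    return groups


def _gene_age_corr(table: pd.DataFrame, gene: str, ages: np.ndarray) -> float:
    if gene not in table.index:
        return float("nan")
    return age_correlation(table.loc[gene].to_numpy(dtype=float), ages)


def target_age_concordance(
    net: TargetNetwork,
    tissue_expression: Mapping[str, pd.DataFrame],
    mirna_groups: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Mean target-gene age correlation per tissue and miRNA sign group.

    Tissue tables are gene x age (column labels parse as months); gene age
    correlation is computed on the per-age means, needing >= 3 ages. Groups
    with no targets in a tissue are flagged undefined (NaN) with n_targets 0.
    """
    rows = []
    for tissue, table in tissue_expression.items():
        ages = np.array([float(c) for c in table.columns])
        if ages.size < 3:
            raise ValueError(f"tissue {tissue}: need >= 3 ages")
        for group, mirnas in mirna_groups.items():
            targets = set()
            for m in mirnas:
                targets |= net.targets_of(m)
            present = sorted(targets & set(table.index))
            if not present:
                rows.append(
                    {"tissue": tissue, "group": group, "mean_corr": np.nan, "n_targets": 0}
                )
                continue
            corrs = [_gene_age_corr(table, g, ages) for g in present]
            corrs = [c for c in corrs if np.isfinite(c)]
            rows.append(
                {
                    "tissue": tissue,
                    "group": group,
                    "mean_corr": float(np.mean(corrs)) if corrs else np.nan,
                    "n_targets": len(present),
                }
            )
    return pd.DataFrame(rows)


def direct_target_correlation(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    net: TargetNetwork,
) -> pd.DataFrame:
    """Per-miRNA distribution of miRNA-target correlations, sorted by mean.

    Correlations are computed across samples shared by the two tables
    (>= 3 required). Output is long format (mirna_id, gene_id, correlation)
    with miRNAs ordered by ascending mean correlation, so the most
    consistent target downregulation comes first.
    """
    shared = [s for s in mirna_expr.columns if s in set(gene_expr.columns)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    rows = []
    for mirna in sorted(net.mirnas):
        if mirna not in mirna_expr.index:
            continue
        mv = mirna_expr.loc[mirna, shared].to_numpy(dtype=float)
        for gene in sorted(net.targets_of(mirna)):
            if gene not in gene_expr.index:
                continue
            gv = gene_expr.loc[gene, shared].to_numpy(dtype=float)
            if np.ptp(mv) == 0 or np.ptp(gv) == 0:
                corr = float("nan")
            else:
                corr = float(np.corrcoef(mv, gv)[0, 1])
            rows.append({"mirna_id": mirna, "gene_id": gene, "correlation": corr})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    order = df.groupby("mirna_id")["correlation"].mean().sort_values().index
    df["mirna_id"] = pd.Categorical(df["mirna_id"], categories=order, ordered=True)
    return df.sort_values(["mirna_id", "gene_id"], kind="stable").reset_index(drop=True)
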