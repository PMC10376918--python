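import numpy as np
import pandas as pd
import pytest

from evcargo.synthetic import simulate_target_atlas
from evcargo.target_network import (
    build_network,
    direct_target_correlation,
    read_edge_table,
    sign_groups,
    target_age_concordance,
)


def _edges(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "evidence"])


class TestBuildNetwork:
    def test_three_strong_mirnas_make_hub(self):
        edges = _edges(
            [(f"mir{i}", "g1", "strong") for i in range(3)]
            + [("mir0", "g2", "strong")]
        )
        corr = {f"mir{i}": 0.5 for i in range(3)}
        net = build_network(edges, corr)
        assert net.hub_genes == {"g1"}

    def test_weak_edges_do_not_count_toward_hub(self):
        edges = _edges(
            [("mir0", "g1", "strong"), ("mir1", "g1", "strong")]
            + [(f"mir{i}", "g1", "weak") for i in range(2, 7)]
        )
        corr = {f"mir{i}": 0.5 for i in range(7)}
        net = build_network(edges, corr)
        assert net.graph.in_degree("g1") == 2
        assert net.hub_genes == set()

    def test_empty_edge_table_warns_not_raises(self):
        with pytest.warns(UserWarning, match="empty network"):
            net = build_network(_edges([]), {})
        assert net.graph.number_of_edges() == 0

    def test_missing_correlation_drops_mirna_with_warning(self):
        edges = _edges([("mir0", "g1", "strong"), ("mir1", "g1", "strong")])
        with pytest.warns(UserWarning, match="mir1"):
            net = build_network(edges, {"mir0": 0.6})
        assert "mir1" not in net.mirnas

    def test_evidence_filter_never_increases_degree(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"mir{rng.integers(5)}", f"g{rng.integers(10)}", rng.choice(["strong", "weak"]))
            for _ in range(60)
        ]
        edges = _edges(rows).drop_duplicates(["mirna_id", "gene_id"])
        corr = {f"mir{i}": 0.5 for i in range(5)}
        all_net = build_network(edges, corr, evidence_filter=None)
        strong_net = build_network(edges, corr, evidence_filter="strong")
        for g in strong_net.genes:
            assert strong_net.graph.in_degree(g) <= all_net.graph.in_degree(g)

    def test_hub_set_monotone_in_threshold(self):
        edges = _edges(
            [(f"mir{i}", "g1", "strong") for i in range(5)]
            + [(f"mir{i}", "g2", "strong") for i in range(3)]
        )
        corr = {f"mir{i}": 0.4 for i in range(5)}
        hubs_prev = None
        for thr in (1, 3, 5, 6):
            net = build_network(edges, corr, hub_threshold=thr)
            if hubs_prev is not None:
                assert net.hub_genes <= hubs_prev
            hubs_prev = net.hub_genes

    def test_min_abs_corr_inclusion_threshold(self):
        edges = _edges([("mir0", "g1", "strong"), ("mir1", "g2", "strong")])
        net = build_network(edges, {"mir0": 0.6, "mir1": 0.1}, min_abs_corr=0.5)
        assert net.mirnas == {"mir0"}

    def test_read_edge_table_maps_source_vocabulary(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "mirna_id\tgene_id\tevidence\nmir0\tg1\tFunctional MTI\n"
            "mir1\tg1\tFunctional MTI (Weak)\n"
        )
        df = read_edge_table(path)
        assert list(df["evidence"]) == ["strong", "weak"]


class TestTargetAgeConcordance:
    def test_planted_repression_sign_recovery(self):
        edges, tissues, _, truth = simulate_target_atlas(
            8, 40, 4, repression_strength=1.0, seed=1, noise_sd=0.05
        )
        corr = {
            m: (1.0 if s > 0 else -1.0) for m, s in truth["mirna_slopes"].items()
        }
        net = build_network(edges, corr, evidence_filter=None)
        groups = sign_groups(corr_ev=corr)
        table = target_age_concordance(net, tissues, groups)
        for tissue, grp in table.groupby("tissue"):
            up = grp.loc[grp["group"] == "EV_up", "mean_corr"].iloc[0]
            down = grp.loc[grp["group"] == "EV_down", "mean_corr"].iloc[0]
            assert up < 0
            assert down > 0

    def test_null_strength_centred_at_zero(self):
        means = []
        for seed in range(8):
            edges, tissues, _, truth = simulate_target_atlas(
                6, 40, 1, repression_strength=0.0, seed=seed, noise_sd=0.3
            )
            corr = {m: np.sign(s) for m, s in truth["mirna_slopes"].items()}
            net = build_network(edges, corr, evidence_filter=None)
            table = target_age_concordance(net, tissues, sign_groups(corr_ev=corr))
            means.extend(table["mean_corr"].dropna())
        assert abs(np.mean(means)) < 0.25

    def test_sign_symmetry_under_negation(self):
        edges, tissues, _, truth = simulate_target_atlas(
            5, 25, 2, repression_strength=1.0, seed=3, noise_sd=0.01
        )
        corr = {m: float(np.sign(s)) for m, s in truth["mirna_slopes"].items()}
        net = build_network(edges, corr, evidence_filter=None)
        table = target_age_concordance(net, tissues, sign_groups(corr_ev=corr))
        # reflect each gene trajectory about its mean: exact sign flip of every
        # age correlation
        negated = {
            t: df.rsub(2 * df.mean(axis=1), axis=0) for t, df in tissues.items()
        }
        table_neg = target_age_concordance(net, negated, sign_groups(corr_ev=corr))
        merged = table.merge(table_neg, on=["tissue", "group"], suffixes=("", "_neg"))
        ok = merged.dropna(subset=["mean_corr", "mean_corr_neg"])
        np.testing.assert_allclose(ok["mean_corr"], -ok["mean_corr_neg"], atol=1e-9)

    def test_group_without_targets_undefined(self):
        edges = _edges([("mir0", "g1", "strong")])
        net = build_network(edges, {"mir0": 0.5})
        tissues = {
            "t1": pd.DataFrame(
                [[1.0, 2.0, 3.0]], index=["g1"], columns=["2", "8", "18"]
            )
        }
        table = target_age_concordance(net, tissues, {"empty": set()})
        row = table.iloc[0]
        assert row["n_targets"] == 0
        assert np.isnan(row["mean_corr"])

    def test_too_few_ages(self):
        edges = _edges([("mir0", "g1", "strong")])
        net = build_network(edges, {"mir0": 0.5})
        tissues = {"t1": pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["2", "8"])}
        with pytest.raises(ValueError):
            target_age_concordance(net, tissues, {"g": {"mir0"}})


class TestDirectTargetCorrelation:
    def test_perfect_anticorrelation(self):
        edges = _edges([("mir0", "g1", "strong")])
        net = build_network(edges, {"mir0": 0.5})
        mirna = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["mir0"], columns=list("abcd"))
        gene = pd.DataFrame([[-1.0, -2.0, -3.0, -4.0]], index=["g1"], columns=list("abcd"))
        out = direct_target_correlation(mirna, gene, net)
        assert out.loc[0, "correlation"] == pytest.approx(-1.0)

    def test_sort_contract(self):
        edges = _edges(
            [("neg", "g1", "strong"), ("neg", "g2", "strong"),
             ("pos", "g3", "strong"), ("pos", "g4", "strong")]
        )
        net = build_network(edges, {"neg": 0.5, "pos": 0.5})
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mirna = pd.DataFrame([x, x], index=["neg", "pos"], columns=list("abcde"))
        gene = pd.DataFrame(
            [-x, -2 * x, x, 2 * x], index=["g1", "g2", "g3", "g4"], columns=list("abcde")
        )
        out = direct_target_correlation(mirna, gene, net)
        assert list(out["mirna_id"].unique()) == ["neg", "pos"]

    def test_planted_repressors_most_negative(self):
        edges, tissues, mirna_expr, truth = simulate_target_atlas(
            6, 30, 1, repression_strength=1.5, seed=4, noise_sd=0.05
        )
        corr = {m: float(np.sign(s)) for m, s in truth["mirna_slopes"].items()}
        net = build_network(edges, corr, evidence_filter=None)
        gene_expr = next(iter(tissues.values()))
        out = direct_target_correlation(mirna_expr, gene_expr, net)
        means = out.groupby("mirna_id", observed=True)["correlation"].mean()
        # every miRNA's targets are repressed, so all means should be negative
        assert (means < 0).all()

    def test_insufficient_shared_samples(self):
        edges = _edges([("mir0", "g1", "strong")])
        net = build_network(edges, {"mir0": 0.5})
        mirna = pd.DataFrame([[1.0, 2.0]], index=["mir0"], columns=["a", "b"])
        gene = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a", "b"])
        with pytest.raises(ValueError):
            direct_target_correlation(mirna, gene, net)
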