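import numpy as np
import pandas as pd
import pytest

from matriscore.io_formats import ExpressionMatrix, SurvivalTable
from matriscore.screening_network import (
    correlation_network,
    gene_hub_screen,
    hub_ranking,
    intersect_prognostic,
    jaccard_index,
    prognostic_screen,
)


def _surv(t, e, index):
    return SurvivalTable(pd.DataFrame({"os_time": t, "os_event": e}, index=index))


class TestPrognosticScreen:
    def test_null_calibration(self):
        rng = np.random.default_rng(40)
        fracs = []
        for _ in range(8):
            n = 150
            samples = [f"S{j}" for j in range(n)]
            scores = pd.DataFrame(rng.normal(size=(100, n)),
                                  index=[f"P{i}" for i in range(100)],
                                  columns=samples)
            t = rng.exponential(10, n)
            e = (t <= np.quantile(t, 0.75)).astype(int)
            tab = prognostic_screen(scores, _surv(np.minimum(t, np.quantile(t, 0.75)), e, samples))
            fracs.append((tab["classification"] != "non-prognostic").mean())
        assert 0.02 <= np.mean(fracs) <= 0.08

    def test_planted_risk_pathway_detected(self):
        rng = np.random.default_rng(41)
        hits = 0
        for _ in range(20):
            n = 400
            samples = [f"S{j}" for j in range(n)]
            planted = rng.normal(size=n)
            decoys = rng.normal(size=(20, n))
            scores = pd.DataFrame(np.vstack([planted, decoys]),
                                  index=["PLANTED"] + [f"D{i}" for i in range(20)],
                                  columns=samples)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * planted)))
            c = np.quantile(t, 0.7)
            tab = prognostic_screen(
                scores, _surv(np.minimum(t, c), (t <= c).astype(int), samples))
            hits += tab.loc["PLANTED", "classification"] == "risk"
        assert hits >= 19

    def test_constant_row_flagged_degenerate(self):
        rng = np.random.default_rng(42)
        n = 50
        samples = [f"S{j}" for j in range(n)]
        scores = pd.DataFrame(
            np.vstack([np.ones(n), rng.normal(size=n)]),
            index=["CONST", "OK"], columns=samples)
        t = rng.exponential(10, n)
        tab = prognostic_screen(scores, _surv(t, np.ones(n, dtype=int), samples))
        assert tab.loc["CONST", "classification"] == "non-prognostic"
        assert bool(tab.loc["CONST", "degenerate"])
        assert not bool(tab.loc["OK", "degenerate"])


class TestIntersectProgostic:
    def _screen(self, classes):
        return pd.DataFrame(
            {"classification": list(classes.values()),
             "hr": [2.0 if c == "risk" else 0.5 if c == "favorable" else 1.0
                    for c in classes.values()]},
            index=pd.Index(classes.keys(), name="pathway"))

    def test_set_intersection(self):
        s1 = self._screen({"A": "risk", "B": "risk", "C": "favorable", "D": "non-prognostic"})
        s2 = self._screen({"A": "non-prognostic", "B": "risk", "C": "favorable", "D": "risk"})
        inter = intersect_prognostic([s1, s2])
        assert set(inter.index) == {"B", "C"}

    def test_direction_discordant_flagged_but_kept(self):
        s1 = self._screen({"A": "risk"})
        s2 = self._screen({"A": "favorable"})
        inter = intersect_prognostic([s1, s2])
        assert list(inter.index) == ["A"]
        assert bool(inter.loc["A", "direction_discordant"])

    def test_self_intersection_identity(self):
        s = self._screen({"A": "risk", "B": "non-prognostic", "C": "favorable"})
        inter = intersect_prognostic([s, s])
        assert set(inter.index) == {"A", "C"}
        assert not inter["direction_discordant"].any()

    def test_all_non_prognostic_empty(self):
        s1 = self._screen({"A": "non-prognostic"})
        s2 = self._screen({"A": "risk"})
        assert len(intersect_prognostic([s1, s2])) == 0


class TestCorrelationNetwork:
    def test_duplicated_rows_connected(self):
        rng = np.random.default_rng(43)
        row = rng.normal(size=30)
        scores = pd.DataFrame([row, row, rng.normal(size=30)],
                              index=["A", "B", "C"])
        g = correlation_network(scores, 0.5)
        assert g.has_edge("A", "B")
        assert g.edges["A", "B"]["rho"] == pytest.approx(1.0)

    def test_null_has_no_edges(self):
        rng = np.random.default_rng(44)
        empty = 0
        for _ in range(25):
            scores = pd.DataFrame(rng.normal(size=(20, 200)))
            empty += correlation_network(scores, 0.5).number_of_edges() == 0
        assert empty >= 24

    def test_planted_chain_degrees(self):
        # consecutive rows share one latent factor each (corr ~0.45, the
        # strongest equal-correlation chain a shared-latent construction
        # allows); non-adjacent pairs are independent
        rng = np.random.default_rng(45)
        n = 400
        c = 0.45
        latents = rng.normal(size=(4, n))
        rows = [
            np.sqrt(c) * latents[0] + np.sqrt(1 - c) * rng.normal(size=n),
            np.sqrt(c) * latents[0] + np.sqrt(c) * latents[1]
            + np.sqrt(1 - 2 * c) * rng.normal(size=n),
            np.sqrt(c) * latents[1] + np.sqrt(c) * latents[2]
            + np.sqrt(1 - 2 * c) * rng.normal(size=n),
            np.sqrt(c) * latents[2] + np.sqrt(c) * latents[3]
            + np.sqrt(1 - 2 * c) * rng.normal(size=n),
            np.sqrt(c) * latents[3] + np.sqrt(1 - c) * rng.normal(size=n),
        ]
        scores = pd.DataFrame(rows, index=list("ABCDE"))
        g = correlation_network(scores, 0.3)
        degs = [g.degree[x] for x in "ABCDE"]
        assert degs == [1, 2, 2, 2, 1]

    def test_constant_row_isolated_with_warning(self):
        rng = np.random.default_rng(46)
        scores = pd.DataFrame([np.ones(20), rng.normal(size=20),
                               rng.normal(size=20)], index=["K", "A", "B"])
        with pytest.warns(UserWarning, match="constant"):
            g = correlation_network(scores, 0.3)
        assert g.degree["K"] == 0

    def test_symmetry_and_degree_sum(self):
        rng = np.random.default_rng(47)
        scores = pd.DataFrame(rng.normal(size=(8, 50))
                              + rng.normal(size=(1, 50)))
        g = correlation_network(scores, 0.2)
        assert sum(dict(g.degree()).values()) == 2 * g.number_of_edges()

    def test_rank_invariance_under_monotone_sample_transform(self):
        rng = np.random.default_rng(48)
        scores = pd.DataFrame(rng.normal(size=(6, 40)))
        g1 = correlation_network(scores, 0.2)
        g2 = correlation_network(np.exp(scores), 0.2)
        assert set(g1.edges) == set(g2.edges)


class TestHubRanking:
    def _star(self, center="H", leaves="ABC"):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from([center, *leaves])
        for leaf in leaves:
            g.add_edge(center, leaf, rho=0.9)
        return g

    def test_star_center_is_top_hub(self):
        ranking = hub_ranking({"c1": self._star()}, k=1)
        assert ranking.per_cohort_top["c1"] == ["H"]
        assert ranking.mean_degree.index[0] == "H"

    def test_identical_cohorts_intersection_is_topk(self):
        ranking = hub_ranking({"c1": self._star(), "c2": self._star()}, k=2)
        assert ranking.intersection == set(ranking.per_cohort_top["c1"])

    def test_k_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            ranking = hub_ranking({"c1": self._star()}, k=99)
        assert ranking.k == 4


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({"a", "b"}, {"b", "c"}, 1 / 3),
    ])
    def test_closed_forms(self, a, b, expected):
        assert jaccard_index(a, b) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            jaccard_index(set(), {"a"})


class TestGeneHubScreen:
    def test_planted_hub_and_risk_gene(self):
        rng = np.random.default_rng(49)
        top1 = 0
        risk_first = 0
        reps = 5
        for _ in range(reps):
            n = 300
            n_genes = 30
            hub_latent = rng.normal(size=n)
            X = rng.normal(size=(n_genes, n))
            X[0] = hub_latent + 0.4 * rng.normal(size=n)       # hub gene
            for i in range(1, 9):                               # 8 partners
                X[i] = 0.7 * hub_latent + 0.7 * rng.normal(size=n)
            risk = rng.normal(size=n)
            X[9] = risk                                         # prognostic gene
            genes = [f"G{i}" for i in range(n_genes)]
            samples = [f"S{j}" for j in range(n)]
            expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))
            t = rng.exponential(1.0 / (0.05 * np.exp(0.6 * risk)))
            c = np.quantile(t, 0.75)
            surv = _surv(np.minimum(t, c), (t <= c).astype(int), samples)
            table, hubs = gene_hub_screen(expr, surv, rho_threshold=0.5, k=10)
            top1 += hubs.mean_degree.index[0] == "G0"
            risk_first += table.index[0] == "G9"
        assert top1 >= 4
        assert risk_first >= 4

    def test_independent_genes_no_shared_hubs(self, multi_sim):
        rng = np.random.default_rng(50)
        empties = 0
        reps = 5
        for _ in range(reps):
            genes = [f"G{i}" for i in range(15)]
            cohorts = {}
            for c in range(3):
                samples = [f"C{c}S{j}" for j in range(120)]
                cohorts[f"c{c}"] = ExpressionMatrix(
                    pd.DataFrame(rng.normal(size=(15, 120)), index=genes,
                                 columns=samples),
                    pd.Series(f"c{c}", index=samples))
            nets = {lab: correlation_network(em.values, 0.5)
                    for lab, em in cohorts.items()}
            ranking = hub_ranking(nets, k=3)
            # with no real edges, ties resolve lexicographically everywhere,
            # so compare degree-positive hubs only
            positive = {lab: [u for u in top if nets[lab].degree[u] > 0]
                        for lab, top in ranking.per_cohort_top.items()}
            shared = set.intersection(*(set(v) for v in positive.values())) \
                if all(positive.values()) else set()
            empties += len(shared) == 0
        assert empties >= 4
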