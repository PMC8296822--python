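"""Spearman statistics, DCG classification and differential-network assembly."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dcnet import (
    build_dn,
    build_wdrn,
    classify_edges,
    filter_ppi,
    spearman_pvalue,
    spearman_rho,
)
from dcnet.dcg import _classify, correlations_to_frame, write_dn
from dcnet.wdrn import PPINetwork

from conftest import make_matrix


def brute_force_exact_p(x, y) -> float:
    """Independent oracle: two-sided permutation p via scipy's rho per ordering."""
    n = len(x)
    obs = abs(stats.spearmanr(x, y).statistic)
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(stats.spearmanr(x, perm).statistic) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestSpearmanRho:
    def test_monotone_and_antitone_extremes(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        # ranks u=(1,2,3), v=(2,1,3): S_uv=0.5, S_u²=S_v²=1
        assert spearman_rho([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_constant_vector_undefined(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_tie_handling_matches_scipy(self, rng):
        for _ in range(25):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.normal(size=8)
            if len(set(x)) < 2:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )

    @pytest.mark.parametrize("x,y", [([1, 2], [1, 2]), ([1, 2, 3], [1, 2])])
    def test_bad_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            spearman_rho(x, y)


class TestSpearmanPvalue:
    def test_perfect_correlation_n3_exact(self):
        # 2 of the 6 orderings reach |rho| >= 1
        assert spearman_pvalue(1.0, 3, "exact") == pytest.approx(1 / 3)

    def test_zero_correlation_exact_is_one(self):
        assert spearman_pvalue(0.0, 5, "exact") == pytest.approx(1.0)

    def test_exact_p_always_positive(self):
        for n in (3, 5, 7):
            assert spearman_pvalue(1.0, n, "exact") > 0

    def test_t_approx_saturated_rho_gives_smallest_positive(self):
        p = spearman_pvalue(1.0, 10, "t_approx")
        assert 0 < p <= 5e-324

    def test_t_approx_matches_textbook_formula(self):
        rho, n = 0.6, 20
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        expected = 2 * stats.t.sf(abs(t), df=n - 2)
        assert spearman_pvalue(rho, n, "t_approx") == pytest.approx(expected)

    def test_exact_matches_brute_force_enumeration(self, rng):
        for n in (5, 6, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho = spearman_rho(x, y)
            assert spearman_pvalue(rho, n, "exact") == pytest.approx(
                brute_force_exact_p(x, y)
            )

    def test_exact_with_ties_conditions_on_tie_pattern(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = rng.normal(size=5)
        rho = spearman_rho(x, y)
        p = spearman_pvalue(rho, 5, "exact", x=x, y=y)
        assert p == pytest.approx(brute_force_exact_p(x, y))

    def test_auto_switches_on_size_and_ties(self):
        # small untied: exact; large n: t approximation
        assert spearman_pvalue(1.0, 3, "auto") == pytest.approx(1 / 3)
        assert spearman_pvalue(0.9, 30, "auto") == pytest.approx(
            spearman_pvalue(0.9, 30, "t_approx")
        )

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            spearman_pvalue(0.5, 5, "bootstrap")


class TestClassification:
    @pytest.mark.parametrize(
        "p_h,p_d,expected",
        [
            (0.50, 0.01, "gained"),
            (0.01, 0.50, "lost"),
            (0.01, 0.01, "none"),
            (0.20, 0.20, "none"),
            (float("nan"), 0.01, "none"),
        ],
    )
    def test_status_rule(self, p_h, p_d, expected):
        assert _classify(p_h, p_d, 0.05) == expected

    def test_alpha_bounds_enforced(self, tiny_ppi):
        wdrn = build_wdrn(tiny_ppi, {"A"})
        matrix = make_matrix({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4]}, n_healthy=2)
        with pytest.raises(ValueError, match="alpha"):
            classify_edges(wdrn, matrix.subset("healthy"), matrix.subset("disease"), alpha=1.5)

    def test_missing_gene_skipped_with_warning(self, caplog):
        wdrn = build_wdrn(
            PPINetwork.from_edges([("A", "B", 950), ("A", "C", 950)]), {"A"}
        )
        m = make_matrix(
            {"A": [1, 2, 3, 4, 5, 6, 7, 8], "B": [2, 1, 4, 3, 6, 5, 8, 7]},
            n_healthy=4,
        )
        with caplog.at_level("WARNING"):
            out = classify_edges(wdrn, m.subset("healthy"), m.subset("disease"))
        assert [(e.gene_a, e.gene_b) for e in out] == [("A", "B")]
        assert "A–C" in caplog.text or "skipped" in caplog.text

    def test_constant_gene_gives_none_status(self):
        wdrn = build_wdrn(PPINetwork.from_edges([("A", "B", 950)]), {"A"})
        m = make_matrix(
            {"A": [5, 5, 5, 5, 5, 5, 5, 5], "B": [1, 2, 3, 4, 8, 7, 6, 5]},
            n_healthy=4,
        )
        (ec,) = classify_edges(wdrn, m.subset("healthy"), m.subset("disease"))
        assert ec.status == "none"
        assert math.isnan(ec.rho_healthy) and math.isnan(ec.p_healthy)

    def test_label_symmetry_swaps_gained_and_lost(self, default_fixture):
        ppi, healthy, disease, truth = default_fixture
        wdrn = build_wdrn(filter_ppi(ppi), truth.true_degs)
        fwd = classify_edges(wdrn, healthy, disease, method="exact")
        rev = classify_edges(wdrn, disease, healthy, method="exact")
        flip = {"gained": "lost", "lost": "gained", "none": "none"}
        for a, b in zip(fwd, rev):
            assert (a.gene_a, a.gene_b) == (b.gene_a, b.gene_b)
            assert flip[a.status] == b.status
            assert a.perturbation == pytest.approx(-b.perturbation, nan_ok=True)


class TestDifferentialNetwork:
    def test_empty_when_no_dcg_edges(self, tiny_ppi):
        wdrn = build_wdrn(tiny_ppi, {"A"})
        dn = build_dn([], wdrn)
        assert dn.n_nodes == 0 and dn.n_edges == 0

    def test_subset_of_wdrn_with_deg_adjacency(self, default_fixture):
        ppi, healthy, disease, truth = default_fixture
        wdrn = build_wdrn(filter_ppi(ppi), truth.true_degs)
        dn = build_dn(classify_edges(wdrn, healthy, disease), wdrn)
        assert dn.n_edges <= wdrn.n_edges
        degs = {n for n, d in dn.graph.nodes(data=True) if d["is_deg"]}
        for u, v in dn.graph.edges:
            assert wdrn.graph.has_edge(u, v)
            assert u in degs or v in degs  # every edge touches a DEG

    def test_edge_attributes_and_sign_convention(self, default_fixture):
        ppi, healthy, disease, truth = default_fixture
        wdrn = build_wdrn(filter_ppi(ppi), truth.true_degs)
        dn = build_dn(classify_edges(wdrn, healthy, disease), wdrn)
        assert dn.n_edges > 0
        for _, _, d in dn.graph.edges(data=True):
            assert d["status"] in ("gained", "lost")
            assert d["sign"] == (1 if d["status"] == "gained" else -1)
            assert d["magnitude"] == pytest.approx(abs(d["perturbation"]))

    def test_outputs_round_trip(self, default_fixture, tmp_path):
        ppi, healthy, disease, truth = default_fixture
        wdrn = build_wdrn(filter_ppi(ppi), truth.true_degs, "heart")
        ecs = classify_edges(wdrn, healthy, disease)
        dn = build_dn(ecs, wdrn)
        paths = write_dn(dn, ecs, tmp_path)
        frame = correlations_to_frame(ecs)
        assert len(frame) == wdrn.n_edges
        assert paths["sif"].read_text().count("\tdcg\t") == dn.n_edges
        import networkx as nx

        g = nx.read_graphml(paths["graphml"])
        assert g.number_of_edges() == dn.n_edges
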