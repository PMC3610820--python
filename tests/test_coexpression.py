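"""Pairwise co-expression, enrichment tests and party/date hub calls."""

import numpy as np
import pandas as pd
import pytest

from circanet import (
    classify_hub,
    coexpression_enrichment,
    degree_vs_rhythmicity_tests,
    pair_pcc,
)
from circanet.coexpression import rhythmicity_enrichment
from circanet.network import InteractionNetwork

from conftest import cosine_profile

T48 = np.arange(48.0)


def textbook_pcc(x, y):
    x, y = np.asarray(x), np.asarray(y)
    return float(
        np.sum((x - x.mean()) * (y - y.mean()))
        / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    )


def frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows, index=T48).T


class TestPairPcc:
    def test_identical_profiles(self):
        expr = frame({"a": cosine_profile(3.0), "b": cosine_profile(3.0)})
        res = pair_pcc(expr, [("a", "b")])
        assert res["pcc"].iloc[0] == pytest.approx(1.0)

    def test_antiphase_profiles(self):
        expr = frame({"a": cosine_profile(0.0), "b": cosine_profile(12.0)})
        assert pair_pcc(expr, [("a", "b")])["pcc"].iloc[0] == pytest.approx(-1.0)

    def test_quadrature_profiles_uncorrelated(self):
        expr = frame({"a": cosine_profile(0.0), "b": cosine_profile(6.0)})
        assert pair_pcc(expr, [("a", "b")])["pcc"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(0)
        expr = frame({f"g{i}": 50 + rng.normal(0, 10, 48) for i in range(6)})
        pairs = [(f"g{i}", f"g{j}") for i in range(6) for j in range(i + 1, 6)]
        res = pair_pcc(expr, pairs)
        for row in res.itertuples(index=False):
            oracle = textbook_pcc(expr.loc[row.id_a], expr.loc[row.id_b])
            assert row.pcc == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_constant_flagging(self):
        expr = frame({"a": cosine_profile(0.0), "flat": np.full(48, 7.0)})
        res = pair_pcc(expr, [("a", "flat"), ("flat", "a")])
        assert not res["testable"].any()
        assert res["pcc"].isna().all()


class TestCoexpressionEnrichment:
    def test_null_construction_fractions_agree(self):
        rng = np.random.default_rng(1)
        expr = frame({f"g{i}": 100 + rng.normal(0, 10, 48) for i in range(40)})
        pairs = [(f"g{2*i}", f"g{2*i+1}") for i in range(20)]
        res = coexpression_enrichment(expr, pairs, n_random=2000, seed=2)
        assert res.p > 0.05
        assert abs(res.observed_fraction - res.random_fraction) < 0.25

    def test_planted_cophase_pairs_enriched(self):
        rng = np.random.default_rng(3)
        cols = {}
        pairs = []
        for i in range(30):  # co-phase interacting pairs
            ph = rng.uniform(0, 24)
            cols[f"a{i}"] = cosine_profile(ph) + rng.normal(0, 2, 48)
            cols[f"b{i}"] = cosine_profile(ph) + rng.normal(0, 2, 48)
            pairs.append((f"a{i}", f"b{i}"))
        for i in range(100):  # flat noisy background genes
            cols[f"n{i}"] = 100 + rng.normal(0, 10, 48)
        res = coexpression_enrichment(frame(cols), pairs, n_random=5000, seed=4)
        assert res.observed_fraction > res.random_fraction + 0.5
        assert res.p < 1e-6

    def test_boundary_value_not_coexpressed(self):
        """PCC exactly at the threshold counts as not co-expressed (strict >)."""
        from circanet.coexpression import PCC_COEXPRESSION_THRESHOLD

        assert not (PCC_COEXPRESSION_THRESHOLD > PCC_COEXPRESSION_THRESHOLD)
        rng = np.random.default_rng(5)
        expr = frame({f"g{i}": 100 + rng.normal(0, 10, 48) for i in range(10)})
        res = coexpression_enrichment(expr, [("g0", "g1")], n_random=1000, seed=6,
                                      threshold=1.0)  # nothing exceeds PCC 1.0 strictly
        assert res.observed_fraction == 0.0
        assert res.random_fraction == 0.0

    def test_requires_enough_random_pairs(self):
        expr = frame({"a": cosine_profile(0.0), "b": cosine_profile(1.0)})
        with pytest.raises(ValueError):
            coexpression_enrichment(expr, [("a", "b")], n_random=10)


def star_net(hub, leaves):
    return InteractionNetwork.from_edges(
        pd.DataFrame([{"id_a": hub, "id_b": v, "source": "Y2H"} for v in leaves])
    )


class TestClassifyHub:
    def test_phase_locked_partners_are_party(self):
        rng = np.random.default_rng(7)
        cols = {"hub": cosine_profile(5.0)}
        leaves = []
        for i in range(8):
            cols[f"p{i}"] = cosine_profile(5.0) + rng.normal(0, 1, 48)
            leaves.append(f"p{i}")
        for i in range(60):
            cols[f"bg{i}"] = 100 + rng.normal(0, 10, 48)
        net = star_net("hub", leaves)
        c = classify_hub("hub", net, frame(cols), n_background=500, seed=8)
        assert c.label == "party"
        assert c.mean_partner_pcc > 0.9
        assert c.fdr_high < 0.01

    def test_antiphase_partners_are_date(self):
        rng = np.random.default_rng(9)
        cols = {"hub": cosine_profile(0.0)}
        leaves = []
        for i in range(8):
            cols[f"p{i}"] = cosine_profile(12.0) + rng.normal(0, 1, 48)
            leaves.append(f"p{i}")
        # background pool of rhythmic genes at random phases: random sets score ~0
        for i in range(60):
            cols[f"bg{i}"] = cosine_profile(rng.uniform(0, 24)) + rng.normal(0, 1, 48)
        net = star_net("hub", leaves)
        c = classify_hub("hub", net, frame(cols), n_background=500, seed=10)
        assert c.label == "date"
        assert c.mean_partner_pcc < -0.9
        assert c.fdr_low < 0.01

    def test_random_partners_mostly_unclassified(self):
        rng = np.random.default_rng(11)
        cols = {f"g{i}": cosine_profile(rng.uniform(0, 24)) + rng.normal(0, 1, 48)
                for i in range(40)}
        cols["hub"] = cosine_profile(rng.uniform(0, 24))
        labels = []
        for seed in range(40):
            leaves = list(rng.choice([f"g{i}" for i in range(40)], size=6, replace=False))
            c = classify_hub("hub", star_net("hub", leaves), frame(cols),
                             n_background=300, seed=seed)
            labels.append(c.label)
        assert labels.count("unclassified") >= 0.9 * len(labels)

    def test_partial_background_mode_runs(self):
        rng = np.random.default_rng(12)
        cols = {"hub": cosine_profile(0.0)}
        leaves = [f"p{i}" for i in range(6)]
        for name in leaves:
            cols[name] = cosine_profile(0.0) + rng.normal(0, 1, 48)
        for i in range(30):
            cols[f"bg{i}"] = 100 + rng.normal(0, 10, 48)
        c = classify_hub("hub", star_net("hub", leaves), frame(cols),
                         n_background=200, seed=13, background="partial")
        assert c.protein == "hub"
        assert np.isfinite(c.mean_partner_pcc)

    def test_too_few_partners_raise(self):
        cols = {"hub": cosine_profile(0.0), "p0": cosine_profile(1.0)}
        with pytest.raises(ValueError):
            classify_hub("hub", star_net("hub", ["p0"]), frame(cols), n_background=50)


class TestDegreeVsRhythmicity:
    @staticmethod
    def _net_and_calls(planted: bool, seed: int):
        rng = np.random.default_rng(seed)
        import networkx as nx

        g = nx.barabasi_albert_graph(120, 3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(120)})
        net = InteractionNetwork(g)
        deg = net.degree()
        if planted:  # rhythmicity concentrated on high-degree nodes
            prob = 0.15 + 0.7 * (deg > deg.median()).astype(float)
        else:
            prob = pd.Series(0.4, index=deg.index)
        calls = pd.DataFrame(
            {"is_rhythmic": rng.random(len(deg)) < prob.to_numpy()}, index=deg.index
        )
        return net, calls

    def test_null_assignment_not_significant(self):
        pvals = []
        for seed in range(5):
            net, calls = self._net_and_calls(planted=False, seed=seed)
            r = degree_vs_rhythmicity_tests(net, calls)
            pvals.extend([r.wilcoxon_p, r.chi2_p])
        assert np.median(pvals) > 0.05

    def test_planted_association_detected(self):
        net, calls = self._net_and_calls(planted=True, seed=1)
        r = degree_vs_rhythmicity_tests(net, calls)
        assert r.wilcoxon_p < 0.01
        assert r.chi2_p < 0.01

    def test_label_swap_flips_statistic_sign(self):
        net, calls = self._net_and_calls(planted=True, seed=2)
        r = degree_vs_rhythmicity_tests(net, calls)
        swapped = calls.copy()
        swapped["is_rhythmic"] = ~swapped["is_rhythmic"].astype(bool)
        r2 = degree_vs_rhythmicity_tests(net, swapped)
        assert np.sign(r2.wilcoxon_statistic) == -np.sign(r.wilcoxon_statistic)
        assert r2.wilcoxon_p == pytest.approx(r.wilcoxon_p, rel=1e-9)

    def test_empty_stratum_raises(self):
        net, calls = self._net_and_calls(planted=False, seed=3)
        calls["is_rhythmic"] = True
        with pytest.raises(ValueError):
            degree_vs_rhythmicity_tests(net, calls)


class TestRhythmicityEnrichment:
    def test_enriched_subset_detected(self):
        idx = [f"g{i}" for i in range(200)]
        calls = pd.DataFrame({"is_rhythmic": [i < 60 for i in range(200)]}, index=idx)
        sub_frac, bg_frac, chi2, p = rhythmicity_enrichment(calls, idx[:50])
        assert sub_frac == 1.0
        assert sub_frac > bg_frac
        assert p < 1e-6
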