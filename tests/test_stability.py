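"""Bootstrap CIs, case-dropping stability, CS-coefficient, focal bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symptomnet.ggm import ebic_glasso
from symptomnet.stability import (
    CaseDropResult,
    bootstrap_predictive_betweenness,
    case_dropping,
    cs_coefficient,
    edge_difference_test,
    nonparametric_bootstrap,
)
from symptomnet.synthetic_data import make_ground_truth
from conftest import sample_latent


def latent_estimator(frame: pd.DataFrame):
    """Continuous-data pipeline used throughout: Pearson + EBIC glasso."""
    return ebic_glasso(
        np.corrcoef(frame.to_numpy().T), n=len(frame),
        nodes=list(frame.columns), n_lambdas=15, min_ratio=0.05, tol=1e-3,
    )


def edge_stats(frame: pd.DataFrame) -> pd.Series:
    net = latent_estimator(frame)
    out = {}
    for i in range(net.p):
        for j in range(i + 1, net.p):
            out[f"edge::{net.nodes[i]}--{net.nodes[j]}"] = net.weights[i, j]
    return pd.Series(out)


def two_edge_truth(w1, w2):
    comm = {v: "c" for v in "ABCD"}
    return make_ground_truth(
        4, comm, 0.0, seed=0,
        fixed_edges=[("A", "B", w1), ("C", "D", w2)] if w2 else [("A", "B", w1)],
    )


class TestNonparametricBootstrap:
    def test_constant_table_gives_degenerate_cis(self):
        frame = pd.DataFrame({"x": np.full(40, 2.0), "y": np.full(40, -1.0)})
        boot = nonparametric_bootstrap(frame, lambda df: df.mean(), B=30, seed=0)
        ci = boot.ci()
        assert (ci["lower"] == ci["upper"]).all()
        assert ci.loc["x", "lower"] == 2.0

    def test_same_seed_reproduces_exactly(self, small_truth):
        frame = sample_latent(small_truth, 300, seed=1)
        b1 = nonparametric_bootstrap(frame, edge_stats, B=20, seed=42)
        b2 = nonparametric_bootstrap(frame, edge_stats, B=20, seed=42)
        pd.testing.assert_frame_equal(b1.samples, b2.samples)

    def test_ci_contains_replicate_median(self, small_truth):
        frame = sample_latent(small_truth, 300, seed=2)
        boot = nonparametric_bootstrap(frame, edge_stats, B=40, seed=0)
        ci = boot.ci()
        assert (ci["lower"] <= ci["median"] + 1e-12).all()
        assert (ci["median"] <= ci["upper"] + 1e-12).all()

    def test_failed_replicates_counted_not_imputed(self):
        calls = {"n": 0}

        def flaky(df):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("unlucky resample")
            return df.mean()

        frame = pd.DataFrame({"x": np.arange(30.0)})
        boot = nonparametric_bootstrap(frame, flaky, B=12, seed=1)
        assert boot.n_failed == 4
        assert len(boot.samples) == 8

    def test_ci_widens_as_sample_shrinks(self, small_truth):
        widths = {}
        for n in (200, 1000, 5000):
            frame = sample_latent(small_truth, n, seed=3)
            boot = nonparametric_bootstrap(frame, edge_stats, B=40, seed=7)
            ci = boot.ci()
            widths[n] = float((ci["upper"] - ci["lower"]).loc["edge::A--B"])
        assert widths[200] >= widths[5000]


class TestEdgeDifferenceTest:
    def test_edge_vs_itself_never_significant(self, small_truth):
        frame = sample_latent(small_truth, 300, seed=4)
        boot = nonparametric_bootstrap(frame, edge_stats, B=30, seed=0)
        assert edge_difference_test(boot, ("A", "B"), ("A", "B")) is False

    def test_separated_weights_significant(self):
        truth = two_edge_truth(0.5, None)
        frame = sample_latent(truth, 2000, seed=5)
        boot = nonparametric_bootstrap(frame, edge_stats, B=200, seed=1)
        assert edge_difference_test(boot, ("A", "B"), ("C", "D")) is True

    def test_overlapping_weights_not_significant(self):
        truth = two_edge_truth(0.30, 0.29)
        frame = sample_latent(truth, 200, seed=6)
        boot = nonparametric_bootstrap(frame, edge_stats, B=200, seed=2)
        assert edge_difference_test(boot, ("A", "B"), ("C", "D")) is False

    def test_unknown_edge_raises(self, small_truth):
        frame = sample_latent(small_truth, 200, seed=7)
        boot = nonparametric_bootstrap(frame, edge_stats, B=10, seed=0)
        with pytest.raises(KeyError):
            edge_difference_test(boot, ("A", "B"), ("A", "Z"))


class TestCaseDropping:
    def test_negligible_drop_gives_perfect_correlation(self, small_truth):
        frame = sample_latent(small_truth, 400, seed=8)
        drop = case_dropping(
            frame, latent_estimator, proportions=(0.01,), B=5, seed=0
        )
        corr = drop.records["correlation"]
        assert (corr > 0.95).all()

    def test_redundant_rows_are_stable(self, small_truth):
        base = sample_latent(small_truth, 500, seed=9)
        frame = pd.concat([base] * 4, ignore_index=True)
        drop = case_dropping(
            frame, latent_estimator, proportions=(0.5,), B=8, seed=1
        )
        assert drop.records["correlation"].median() > 0.9

    def test_too_small_subsets_skipped_with_warning(self, small_truth):
        frame = sample_latent(small_truth, 20, seed=10)
        with pytest.warns(UserWarning, match="skipped"):
            drop = case_dropping(
                frame, latent_estimator, proportions=(0.75,), B=3, seed=0
            )
        assert drop.skipped == (0.75,)
        assert drop.records.empty


def fabricate_casedrop(correlations_by_q, index="expected_influence"):
    rows = [
        (q, i, index, r)
        for q, rs in correlations_by_q.items()
        for i, r in enumerate(rs)
    ]
    return CaseDropResult(
        records=pd.DataFrame(rows, columns=["proportion", "replicate", "index", "correlation"]),
        proportions=tuple(correlations_by_q),
        indices=(index,),
        skipped=(),
        n=100,
        seed=0,
    )


GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


class TestCsCoefficient:
    def test_perfect_stability_hits_grid_maximum(self):
        result = fabricate_casedrop({q: [1.0] * 20 for q in GRID})
        assert cs_coefficient(result)["expected_influence"] == 0.75

    def test_no_stability_gives_zero(self):
        result = fabricate_casedrop({q: [0.0] * 20 for q in GRID})
        assert cs_coefficient(result)["expected_influence"] == 0.0

    def test_partial_stability_by_definition(self):
        result = fabricate_casedrop(
            {q: ([0.9] * 20 if q <= 0.25 else [0.5] * 20) for q in GRID}
        )
        assert cs_coefficient(result)["expected_influence"] == 0.25

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_threshold_and_probability(self, seed):
        rng = np.random.default_rng(seed)
        result = fabricate_casedrop(
            {q: rng.uniform(-0.2, 1.0, size=12).tolist() for q in GRID}
        )
        loose = cs_coefficient(result, cor_threshold=0.5, prob=0.8)
        tight_cor = cs_coefficient(result, cor_threshold=0.8, prob=0.8)
        tight_prob = cs_coefficient(result, cor_threshold=0.5, prob=0.99)
        assert tight_cor["expected_influence"] <= loose["expected_influence"]
        assert tight_prob["expected_influence"] <= loose["expected_influence"]


class TestPredictiveBetweennessBootstrap:
    def test_star_truth_concentrates_at_zero(self):
        comm = {v: "c" for v in "FABCD"}
        truth = make_ground_truth(
            5, comm, 0.0, seed=0,
            fixed_edges=[("F", v, 0.3) for v in "ABCD"],
        )
        frame = sample_latent(truth, 2000, seed=11)
        pb = bootstrap_predictive_betweenness(
            frame, "F", latent_estimator, B=30, seed=0
        )
        summary = pb.summary()
        assert (summary["median"] == 0).all()

    def test_chain_gateway_scores_highest(self):
        # focal -- V -- {rest}: V lies on every focal-anchored path
        comm = {v: "c" for v in "FVABC"}
        truth = make_ground_truth(
            5, comm, 0.0, seed=0,
            fixed_edges=[("F", "V", 0.4), ("V", "A", 0.3), ("V", "B", 0.3),
                         ("V", "C", 0.3)],
        )
        frame = sample_latent(truth, 2000, seed=12)
        pb = bootstrap_predictive_betweenness(
            frame, "F", latent_estimator, B=30, seed=1
        )
        summary = pb.summary()
        assert summary["median"].idxmax() == "V"
        assert summary.loc["V", "point"] == 3.0

    def test_same_seed_identical_summaries(self, small_truth):
        frame = sample_latent(small_truth, 300, seed=13)
        a = bootstrap_predictive_betweenness(frame, "C", latent_estimator, B=15, seed=9)
        b = bootstrap_predictive_betweenness(frame, "C", latent_estimator, B=15, seed=9)
        pd.testing.assert_frame_equal(a.summary(), b.summary())


def test_strong_edge_ci_covers_truth():
    """Bootstrap CI coverage of a strong edge across seeded cohorts."""
    truth = two_edge_truth(0.5, 0.3)
    true_w = truth.partials[0, 1]
    covered = 0
    for seed in range(20):
        frame = sample_latent(truth, 1000, seed=100 + seed)
        boot = nonparametric_bootstrap(frame, edge_stats, B=50, seed=seed)
        ci = boot.ci()
        lo, hi = ci.loc["edge::A--B", ["lower", "upper"]]
        covered += lo <= true_w <= hi
    assert covered >= 16
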