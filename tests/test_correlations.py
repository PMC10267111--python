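"""Polychoric/polyserial estimators, mixed dispatch, PSD repair."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

from symptomnet.correlations import (
    CorrelationMatrix,
    bvn_cdf,
    mixed_matrix,
    nearest_psd,
    polychoric,
    polyserial,
)
from symptomnet.synthetic_data import (
    GeneratorConfig,
    NodeSpec,
    generate_cohort,
    make_ground_truth,
)


def bivariate_ordinal(rho, n, cuts, seed):
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
    z = rng.standard_normal((n, 2)) @ chol.T
    return np.searchsorted(cuts, z[:, 0]), np.searchsorted(cuts, z[:, 1])


class TestBvnCdf:
    def test_matches_scipy_quadrature(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            h, k = rng.normal(size=2) * 1.5
            rho = rng.uniform(-0.95, 0.95)
            ref = multivariate_normal.cdf([h, k], cov=[[1, rho], [rho, 1]])
            assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-8)

    def test_independence_factorises(self):
        assert float(bvn_cdf(0.7, -0.3, 0.0)) == pytest.approx(
            norm.cdf(0.7) * norm.cdf(-0.3), abs=1e-12
        )

    def test_infinite_limits(self):
        assert float(bvn_cdf(np.inf, 0.5, 0.4)) == pytest.approx(norm.cdf(0.5), abs=1e-10)
        assert float(bvn_cdf(-np.inf, 0.5, 0.4)) == pytest.approx(0.0, abs=1e-10)


class TestPolychoric:
    def test_self_correlation_at_bound(self):
        x = np.tile([0, 1, 2, 3, 4], 100)
        fit = polychoric(x, x)
        assert fit.rho >= 0.99
        assert fit.at_bound

    def test_balanced_2x2_is_independent(self):
        x = np.repeat([0, 0, 1, 1], 2500)
        y = np.tile(np.repeat([0, 1], 2500), 2)
        assert abs(polychoric(x, y).rho) < 0.01

    def test_recovers_generating_rho(self):
        cuts = np.array([-1.5, -0.5, 0.5, 1.5])
        x, y = bivariate_ordinal(0.5, 20_000, cuts, seed=42)
        fit = polychoric(x, y)
        assert fit.rho == pytest.approx(0.5, abs=0.02)
        # two-step thresholds approximate the generating cut points
        assert np.abs(fit.thresholds_x - cuts).max() < 0.05

    def test_tetrachoric_is_two_category_special_case(self):
        x, y = bivariate_ordinal(0.4, 20_000, np.array([0.0]), seed=1)
        assert polychoric(x, y).rho == pytest.approx(0.4, abs=0.03)

    def test_single_category_names_offender(self):
        with pytest.raises(ValueError, match="suicide_plan"):
            polychoric(np.zeros(100), np.tile([0, 1], 50), name_x="suicide_plan")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_relabeling(self, seed):
        cuts = np.array([-1.0, 0.0, 1.0, 1.8])
        x, y = bivariate_ordinal(0.35, 500, cuts, seed=seed)
        relabel = np.array([0, 1, 5, 7, 20])  # strictly increasing recode
        assert polychoric(relabel[x], y).rho == pytest.approx(
            polychoric(x, y).rho, abs=1e-9
        )


class TestPolyserial:
    def test_recovers_generating_rho(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((20_000, 2))
        latent = 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]
        ordinal = np.searchsorted([-1.0, 0.0, 1.0], latent)
        assert polyserial(ordinal, z[:, 0]) == pytest.approx(0.6, abs=0.03)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        ordinal = rng.integers(0, 4, size=20_000)
        assert abs(polyserial(ordinal, rng.normal(size=20_000))) < 0.03

    def test_degenerate_inputs_fail(self):
        with pytest.raises(ValueError, match="categories"):
            polyserial(np.zeros(100, dtype=int), np.random.default_rng(0).normal(size=100))
        with pytest.raises(ValueError, match="variance"):
            polyserial(np.tile([0, 1], 50), np.ones(100))


class TestMixedMatrix:
    def test_all_continuous_reduces_to_pearson(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        got = mixed_matrix(frame, type_map={c: "continuous" for c in "abc"})
        assert np.allclose(got.values, np.corrcoef(frame.to_numpy().T), atol=1e-10)
        assert all(m == "pearson" for m in got.method_map.values())

    def test_recovers_latent_correlations_from_cohort(self):
        comm = {"A": "c", "B": "c", "C": "c", "D": "c"}
        truth = make_ground_truth(
            4, comm, 0.0, seed=0,
            fixed_edges=[("A", "B", 0.35), ("B", "C", 0.3), ("C", "D", 0.3)],
        )
        cuts = (-1.0, -0.2, 0.6, 1.4)
        spec = {
            "A": NodeSpec(kind="ordinal", community="c", thresholds=cuts),
            "B": NodeSpec(kind="binary", community="c", threshold=0.4),
            "C": NodeSpec(kind="continuous", community="c"),
            "D": NodeSpec(kind="ordinal", community="c", thresholds=cuts),
        }
        table = generate_cohort(truth, GeneratorConfig(n=5000, node_spec=spec, seed=8))
        got = mixed_matrix(table, continuous_transform="rank")
        latent = truth.latent_correlation
        assert np.abs(got.values - latent).max() < 0.05
        # untransformed lognormal margins attenuate the continuous pairs
        raw = mixed_matrix(table)
        assert np.abs(raw.values[2] - latent[2]).max() > np.abs(got.values[2] - latent[2]).max()

    def test_output_is_psd(self):
        comm = {f"V{i}": "c" for i in range(5)}
        truth = make_ground_truth(5, comm, sparsity=0.5, seed=2)
        cuts = (-0.8, 0.0, 0.8, 1.6)
        spec = {
            f"V{i}": NodeSpec(kind="ordinal", community="c", thresholds=cuts)
            for i in range(5)
        }
        table = generate_cohort(truth, GeneratorConfig(n=200, node_spec=spec, seed=3))
        got = mixed_matrix(table)
        assert np.linalg.eigvalsh(got.values).min() >= -1e-8
        assert np.allclose(np.diag(got.values), 1.0)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame({
            "x": rng.integers(0, 5, 400),
            "y": rng.integers(0, 2, 400),
            "z": rng.normal(size=400),
        })
        tm = {"x": "ordinal", "y": "binary", "z": "continuous"}
        a = mixed_matrix(frame, type_map=tm).to_dataframe()
        b = mixed_matrix(frame[["z", "x", "y"]], type_map=tm).to_dataframe()
        pd.testing.assert_frame_equal(a, b.loc[a.index, a.columns], atol=1e-9, rtol=0)

    def test_failures_reported_with_pair_names(self):
        frame = pd.DataFrame({"ok": np.tile([0, 1, 2], 20), "bad": np.zeros(60, int)})
        tm = {"ok": "ordinal", "bad": "ordinal"}
        with pytest.raises(ValueError, match="ok--bad"):
            mixed_matrix(frame, type_map=tm)

    def test_bare_dataframe_requires_type_map(self):
        with pytest.raises(ValueError, match="type_map"):
            mixed_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


class TestNearestPsd:
    def test_identity_is_fixed_point(self):
        out = nearest_psd(np.eye(4))
        assert np.array_equal(out.values, np.eye(4))

    def test_psd_input_unchanged(self):
        M = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(nearest_psd(M).values, M)

    def test_indefinite_input_repaired(self):
        M = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(M).min() < 0
        out = nearest_psd(M).values
        assert np.linalg.eigvalsh(out).min() >= -1e-10
        assert np.allclose(np.diag(out), 1.0)
        assert np.allclose(out, out.T)
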