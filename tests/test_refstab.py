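"""geNorm and NormFinder stability, each validated against an independent
brute-force oracle, plus the ANOVA screen's calibration and power."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opcflux import simulate
from opcflux.matrix import ExpressionMatrix
from opcflux.refstab import (
    anova_screen,
    genorm_m_values,
    genorm_rank,
    normfinder_stability,
    stability_table,
)

from conftest import preprocessed, random_matrix


def brute_force_genorm(data: pd.DataFrame) -> dict[str, float]:
    """Double-loop pairwise log2-ratio SD oracle."""
    out = {}
    for j in data.index:
        vs = []
        for k in data.index:
            if k == j:
                continue
            ratios = np.log2(data.loc[j].to_numpy() / data.loc[k].to_numpy())
            mean = ratios.mean()
            vs.append(math.sqrt(((ratios - mean) ** 2).sum() / (len(ratios) - 1)))
        out[j] = sum(vs) / len(vs)
    return out


class TestGeNormM:
    def test_three_gene_worked_example(self, toy_matrix):
        """g1=(1,2,4), g2=(2,4,8), g3=(1,1,1): M = 0.5, 0.5, 1.0."""
        m = genorm_m_values(toy_matrix)
        assert m["g1"] == pytest.approx(0.5)
        assert m["g2"] == pytest.approx(0.5)
        assert m["g3"] == pytest.approx(1.0)

    def test_proportional_pair_has_zero_m(self):
        data = pd.DataFrame(
            {"s1": [1.0, 3.0], "s2": [2.0, 6.0], "s3": [5.0, 15.0]},
            index=["a", "b"],
        )
        m = genorm_m_values(
            ExpressionMatrix(data, pd.Series("c", index=data.columns))
        )
        assert np.allclose(m, 0.0, atol=1e-12)

    def test_invariant_to_per_sample_scaling(self):
        m0 = random_matrix(np.random.default_rng(0), n_genes=5, n_samples=6)
        scaled = m0.copy_with(m0.data * np.array([10.0, 1, 1, 1, 1, 1]))
        assert np.allclose(
            genorm_m_values(m0), genorm_m_values(scaled), rtol=1e-10
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        m = random_matrix(np.random.default_rng(seed), n_genes=5, n_samples=6)
        got = genorm_m_values(m)
        want = brute_force_genorm(m.data)
        for g in m.feature_ids:
            assert got[g] == pytest.approx(want[g], rel=1e-10)

    def test_needs_two_candidates_and_samples(self, toy_matrix):
        with pytest.raises(ValueError, match="candidate"):
            genorm_m_values(toy_matrix, ["g1"])
        one_sample = ExpressionMatrix(
            toy_matrix.data[["s1"]], toy_matrix.design[["s1"]]
        )
        with pytest.raises(ValueError, match="sample"):
            genorm_m_values(one_sample)


class TestGeNormRank:
    def test_worked_example_exclusion_and_tied_top_pair(self, toy_matrix):
        table = genorm_rank(toy_matrix)
        assert table.loc["g3", "genorm_rank"] == 2
        assert table.loc["g1", "genorm_rank"] == 1
        assert table.loc["g2", "genorm_rank"] == 1
        # reported M for the final pair comes from the two-gene set
        assert table.loc["g1", "genorm_M"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["g3", "genorm_M"] == pytest.approx(1.0)

    def test_all_proportional_ties_break_lexicographically(self):
        base = np.array([1.0, 2.0, 5.0, 3.0])
        data = pd.DataFrame(
            {f"s{i}": base[i] * np.ones(4) for i in range(4)},
            index=["d", "b", "c", "a"],
        )
        m = ExpressionMatrix(data, pd.Series("x", index=data.columns))
        table = genorm_rank(m)
        # all M = 0; lexicographically greatest excluded first
        assert table.loc["d", "genorm_rank"] == 3
        assert table.loc["c", "genorm_rank"] == 2
        assert table.loc["a", "genorm_rank"] == 1
        assert table.loc["b", "genorm_rank"] == 1

    def test_default_scenario_ranks_stable_references_on_top(self, zero_noise_run):
        scenario, merged, _, _ = zero_noise_run
        table = genorm_rank(merged, list(scenario.candidate_references))
        stable = table.loc[list(simulate.STABLE_REFERENCES), "genorm_rank"]
        unstable = table.loc[list(simulate.UNSTABLE_REFERENCES), "genorm_rank"]
        assert stable.max() < unstable.min()


def brute_force_normfinder(data: pd.DataFrame, design: pd.Series) -> dict[str, float]:
    """Loop implementation of the model-based stability value."""
    logs = np.log2(data)
    logs = logs - logs.mean(axis=0)  # sample centering
    genes = list(data.index)
    groups = list(dict.fromkeys(design))
    I, G = len(genes), len(groups)
    a = np.zeros((I, G))
    s2 = np.zeros((I, G))
    n = np.zeros(G)
    for j, grp in enumerate(groups):
        cols = design.index[design == grp]
        n[j] = len(cols)
        for i, g in enumerate(genes):
            vals = logs.loc[g, cols].to_numpy()
            a[i, j] = vals.mean()
            s2[i, j] = vals.var(ddof=1)
    sigma2 = np.zeros((I, G))
    for j in range(G):
        tot = s2[:, j].sum()
        for i in range(I):
            sigma2[i, j] = max((s2[i, j] - tot / (I * (I - 1))) * I / (I - 2), 0.0)
    d = a - a.mean(axis=1, keepdims=True)
    c = sigma2 / n
    gamma2 = max((d**2).sum() / ((I - 1) * (G - 1)) - c.mean(), 0.0)
    rho = {}
    for i, g in enumerate(genes):
        total = 0.0
        for j in range(G):
            shrunk = d[i, j] * gamma2 / (gamma2 + c[i, j]) if gamma2 > 0 else 0.0
            total += abs(shrunk) + math.sqrt(c[i, j])
        rho[g] = total / G
    return rho


class TestNormFinder:
    def test_all_constant_candidates_score_zero(self):
        data = pd.DataFrame(np.full((4, 6), 7.0), index=list("abcd"),
                            columns=[f"s{i}" for i in range(6)])
        design = pd.Series(["x"] * 3 + ["y"] * 3, index=data.columns)
        rho = normfinder_stability(ExpressionMatrix(data, design))
        assert np.allclose(rho, 0.0, atol=1e-12)

    def test_group_shift_scores_worse_than_iid_noise(self):
        """A gene whose variance is all intergroup must score less stable
        than one with the same total variance spread as i.i.d. noise."""
        rng = np.random.default_rng(0)
        n = 4
        samples = [f"s{i}" for i in range(2 * n)]
        design = pd.Series(["x"] * n + ["y"] * n, index=samples)
        shift = np.array([0.5] * n + [-0.5] * n)  # pure group effect, var 0.25
        iid = rng.normal(0.0, 0.5, size=2 * n)
        rows = {
            "shifted": 2.0 ** (10 + shift),
            "noisy": 2.0 ** (10 + iid),
        }
        for i in range(4):  # calm panel context
            rows[f"ref{i}"] = 2.0 ** (10 + rng.normal(0, 0.02, size=2 * n))
        data = pd.DataFrame(rows).T
        data.columns = samples
        rho = normfinder_stability(ExpressionMatrix(data, design))
        assert rho["shifted"] > rho["noisy"]

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            m = random_matrix(
                np.random.default_rng(seed), n_genes=6, n_samples=8, n_groups=2
            )
            got = normfinder_stability(m)
            want = brute_force_normfinder(m.data, m.design)
            for g in m.feature_ids:
                assert got[g] == pytest.approx(want[g], rel=1e-10)

    def test_invariant_to_per_sample_shift_on_log_scale(self):
        m = random_matrix(np.random.default_rng(5), n_genes=5, n_samples=8)
        scaled = m.copy_with(m.data * np.array([4.0, 1, 1, 1, 1, 1, 1, 1]))
        assert np.allclose(
            normfinder_stability(m), normfinder_stability(scaled), atol=1e-12
        )

    def test_requires_three_candidates_and_group_replication(self):
        m = random_matrix(np.random.default_rng(1), n_genes=2, n_samples=6)
        with pytest.raises(ValueError, match="candidate"):
            normfinder_stability(m)
        data = pd.DataFrame(np.ones((3, 3)) * 2.0, index=list("abc"),
                            columns=["s0", "s1", "s2"])
        design = pd.Series(["x", "x", "y"], index=data.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            normfinder_stability(ExpressionMatrix(data, design))

    def test_separates_stable_from_unstable_on_scenarios(self):
        """Zero-group-effect genes with small noise outrank genes with
        injected group effects in nearly all seeds."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(8)]
            design = pd.Series(["x"] * 4 + ["y"] * 4, index=samples)
            rows = {}
            for i in range(3):
                rows[f"stable{i}"] = 2.0 ** rng.normal(8, 0.05, 8)
            for i in range(2):
                effect = np.array([0.6] * 4 + [-0.6] * 4)
                rows[f"unstable{i}"] = 2.0 ** (8 + effect + rng.normal(0, 0.05, 8))
            data = pd.DataFrame(rows).T
            data.columns = samples
            rho = normfinder_stability(ExpressionMatrix(data, design))
            stable = max(rho[f"stable{i}"] for i in range(3))
            unstable = min(rho[f"unstable{i}"] for i in range(2))
            wins += stable < unstable
        assert wins >= 0.95 * n_seeds


class TestAnovaScreen:
    def test_two_group_worked_example(self):
        """log2 groups (1,2,3) and (2,3,4): F = 1.5 on (1,4) df, p ≈ 0.288."""
        data = pd.DataFrame(
            [2.0 ** np.array([1, 2, 3, 2, 3, 4.0])], index=["g"],
            columns=[f"s{i}" for i in range(6)],
        )
        design = pd.Series(["a"] * 3 + ["b"] * 3, index=data.columns)
        p = anova_screen(ExpressionMatrix(data, design))
        assert p["g"] == pytest.approx(0.2878, abs=2e-4)

    def test_null_type_one_error_calibrated(self):
        """2000 zero-effect genes: rejection rate at alpha 0.05 within
        2 SE of 0.05."""
        rng = np.random.default_rng(123)
        n_genes = 2000
        samples = [f"s{i}" for i in range(12)]
        design = pd.Series([f"c{i // 4}" for i in range(12)], index=samples)
        data = pd.DataFrame(
            2.0 ** rng.normal(8, 0.3, size=(n_genes, 12)),
            index=[f"g{i}" for i in range(n_genes)], columns=samples,
        )
        p = anova_screen(ExpressionMatrix(data, design))
        rate = float((p < 0.05).mean())
        se = math.sqrt(0.05 * 0.95 / n_genes)
        assert abs(rate - 0.05) < 2 * se + 1e-12

    def test_power_on_halved_expression(self):
        """Effect 0.5x in one of two conditions, noise 0.1, n=4: detected
        (p < 0.05) in at least 99% of 500 simulated genes."""
        rng = np.random.default_rng(7)
        n_genes = 500
        samples = [f"s{i}" for i in range(8)]
        design = pd.Series(["ctrl"] * 4 + ["trt"] * 4, index=samples)
        logs = rng.normal(0, 0.1, size=(n_genes, 8)) + 8.0
        logs[:, 4:] += math.log2(0.5)
        data = pd.DataFrame(2.0 ** logs, index=[f"g{i}" for i in range(n_genes)],
                            columns=samples)
        p = anova_screen(ExpressionMatrix(data, design))
        assert float((p < 0.05).mean()) >= 0.99


def test_stability_table_shape_and_ranks(zero_noise_run):
    scenario, merged, _, _ = zero_noise_run
    table = stability_table(merged, list(scenario.candidate_references))
    assert set(table.columns) == {
        "genorm_M", "genorm_rank", "normfinder_value", "normfinder_rank", "anova_p"
    }
    assert sorted(table.index) == sorted(scenario.candidate_references)
    assert table["normfinder_rank"].min() == 1
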