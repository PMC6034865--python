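import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import islandveg.ordination as ordn
from conftest import coenocline


def frame(arr, prefix_r="p", prefix_c="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix_r}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix_c}{j}" for j in range(arr.shape[1])],
    )


class TestTotalInertia:
    def test_identity_two_by_two(self):
        assert ordn.total_inertia(frame(np.eye(2))) == pytest.approx(1.0)

    def test_rank_one_table_has_zero_inertia(self):
        r = np.array([0.2, 0.3, 0.5])
        c = np.array([0.4, 0.6])
        assert ordn.total_inertia(frame(np.outer(r, c))) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_equals_chi_square_statistic_over_total(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(0, 20, size=(8, 6)).astype(float)
        Y[Y.sum(axis=1) == 0, 0] = 1
        chi2 = chi2_contingency(Y + 1e-12, correction=False)[0]
        assert ordn.total_inertia(frame(Y)) == pytest.approx(
            chi2 / Y.sum(), rel=1e-6
        )

    def test_zero_rows_dropped_with_warning(self):
        Y = frame([[1.0, 2.0], [0.0, 0.0], [2.0, 1.0]])
        with pytest.warns(UserWarning, match="empty plots"):
            ti = ordn.total_inertia(Y)
        assert ti == pytest.approx(ordn.total_inertia(Y.iloc[[0, 2]]))


class TestCA:
    def test_identity_matrix_single_unit_eigenvalue(self):
        res = ordn.ca(frame(np.eye(2)))
        assert res.eigenvalues == pytest.approx([1.0])

    def test_block_diagonal_leading_eigenvalue_is_one(self):
        Y = np.zeros((4, 4))
        Y[:2, :2] = [[2.0, 1.0], [1.0, 2.0]]
        Y[2:, 2:] = [[3.0, 1.0], [1.0, 3.0]]
        res = ordn.ca(frame(Y))
        assert res.eigenvalues[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_total_inertia(self):
        Y = coenocline(15, 10, span=3.0, seed=2)
        res = ordn.ca(Y)
        assert res.eigenvalues.sum() == pytest.approx(
            res.total_inertia, abs=1e-10
        )

    def test_degenerate_matrix_errors(self):
        with pytest.raises(ValueError):
            ordn.ca(frame([[1.0, 2.0]]))


class TestCCA:
    def test_perfectly_separating_indicator_recovers_ca_axis(self):
        # two plot groups with disjoint species: CA axis 1 is the group split
        Y = np.zeros((6, 6))
        rng = np.random.default_rng(0)
        Y[:3, :3] = rng.uniform(0.5, 1.0, (3, 3))
        Y[3:, 3:] = rng.uniform(0.5, 1.0, (3, 3))
        m = frame(Y)
        groups = pd.DataFrame({"g": [0.0] * 3 + [1.0] * 3}, index=m.index)
        full_ca = ordn.ca(m)
        constrained = ordn.cca(m, groups)
        assert constrained.canonical_eigenvalues[0] == pytest.approx(
            full_ca.eigenvalues[0], abs=1e-10
        )

    def test_noise_constraint_explains_little(self):
        Y = coenocline(60, 30, span=3.0, seed=4)
        rng = np.random.default_rng(9)
        noise = pd.DataFrame({"z": rng.normal(size=60)}, index=Y.index)
        res = ordn.cca(Y, noise)
        assert res.canonical_inertia < 0.05 * res.total_inertia

    def test_zero_constraints_give_empty_canonical_set(self):
        Y = coenocline(10, 8, span=2.0, seed=0)
        res = ordn.cca(Y, None)
        assert res.canonical_eigenvalues.size == 0
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-10)

    def test_collinear_constraints_error_names_dependency(self):
        Y = coenocline(12, 8, span=2.0, seed=0)
        env = pd.DataFrame(
            {"a": np.arange(12.0), "b": 2 * np.arange(12.0)}, index=Y.index
        )
        with pytest.raises(ValueError, match="collinear"):
            ordn.cca(Y, env)

    def test_nesting_canonical_inertia_nondecreasing(self):
        Y = coenocline(30, 20, span=3.0, seed=5)
        rng = np.random.default_rng(5)
        env = pd.DataFrame(
            rng.normal(size=(30, 3)), columns=["a", "b", "c"], index=Y.index
        )
        inertias = [
            ordn.cca(Y, env[cols]).canonical_inertia
            for cols in (["a"], ["a", "b"], ["a", "b", "c"])
        ]
        assert inertias[0] <= inertias[1] + 1e-12 <= inertias[2] + 2e-12

    def test_matches_vegan_reference(self, tmp_path):
        """Canonical eigenvalues agree with the independent R vegan fit."""
        Y = coenocline(20, 12, span=4.0, seed=42)
        rng = np.random.default_rng(7)
        env = pd.DataFrame(
            {"e1": np.linspace(0, 4, 20) + rng.normal(0, 0.5, 20),
             "e2": rng.normal(size=20)},
            index=Y.index,
        )
        ours = ordn.cca(Y, env)
        part = ordn.cca(Y, env[["e1"]], env[["e2"]])
        Y.to_csv(tmp_path / "Y.csv", index=False)
        env.to_csv(tmp_path / "E.csv", index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            Y <- read.csv('{tmp_path}/Y.csv'); E <- read.csv('{tmp_path}/E.csv')
            f <- cca(Y ~ e1 + e2, data=E)
            p <- cca(Y ~ e1 + Condition(e2), data=E)
            cat(f$tot.chi, f$CCA$eig, p$CCA$eig, p$pCCA$tot.chi, sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = [float(v) for v in out.stdout.split()]
        assert ours.total_inertia == pytest.approx(ref[0], rel=1e-6)
        assert ours.canonical_eigenvalues == pytest.approx(ref[1:3], rel=1e-5)
        assert part.canonical_eigenvalues[0] == pytest.approx(ref[3], rel=1e-5)
        assert part.covariable_inertia == pytest.approx(ref[4], rel=1e-5)


class TestPartialCCA:
    def test_self_partialling_leaves_no_canonical_inertia(self):
        Y = coenocline(20, 12, span=3.0, seed=1)
        x = np.linspace(0, 1, 20)
        env = pd.DataFrame({"x": x}, index=Y.index)
        cov = pd.DataFrame({"same_values": x}, index=Y.index)
        res = ordn.cca(Y, env, cov)
        assert res.canonical_inertia == pytest.approx(0.0, abs=1e-12)

    def test_empty_covariables_reduce_to_cca(self):
        Y = coenocline(20, 12, span=3.0, seed=1)
        env = pd.DataFrame({"x": np.linspace(0, 1, 20)}, index=Y.index)
        a = ordn.cca(Y, env)
        b = ordn.pcca(Y, env, None)
        assert a.canonical_eigenvalues == pytest.approx(b.canonical_eigenvalues)

    def test_constraint_named_as_covariable_errors(self):
        Y = coenocline(10, 8, span=2.0, seed=0)
        env = pd.DataFrame({"x": np.arange(10.0)}, index=Y.index)
        with pytest.raises(ValueError, match="covariables"):
            ordn.cca(Y, env, env)

    def test_mass_orthogonal_covariable_leaves_eigenvalues_unchanged(self):
        # equal row sums make masses uniform; use orthogonal contrasts
        rng = np.random.default_rng(3)
        Y = rng.uniform(0.5, 1.0, size=(8, 10))
        Y = Y / Y.sum(axis=1, keepdims=True)  # uniform plot masses
        m = frame(Y)
        x = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        z = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])  # orthogonal to x
        env = pd.DataFrame({"x": x}, index=m.index)
        cov = pd.DataFrame({"z": z}, index=m.index)
        plain = ordn.cca(m, env)
        partial = ordn.cca(m, env, cov)
        assert partial.canonical_eigenvalues == pytest.approx(
            plain.canonical_eigenvalues, rel=1e-8
        )


class TestPseudoF:
    def test_formula_against_independent_evaluation(self):
        Y = coenocline(25, 15, span=3.0, seed=6)
        env = pd.DataFrame(
            {"x": np.linspace(0, 1, 25), "w": np.cos(np.arange(25.0))},
            index=Y.index,
        )
        res = ordn.cca(Y, env)
        can = res.canonical_inertia
        expected = (can / 2) / ((res.total_inertia - can) / (25 - 2 - 1))
        assert ordn.pseudo_f(res) == pytest.approx(expected, rel=1e-12)

    def test_unconstrained_fit_errors(self):
        Y = coenocline(10, 8, span=2.0, seed=0)
        with pytest.raises(ValueError):
            ordn.pseudo_f(ordn.cca(Y, None))


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        Y = coenocline(12, 8, span=3.0, seed=0)
        env = pd.DataFrame({"x": np.linspace(0, 1, 12)}, index=Y.index)
        _, p = ordn.permutation_test(Y, env, n_perm=9, seed=0)
        assert p >= 1.0 / 10.0

    def test_seeded_determinism(self):
        Y = coenocline(15, 10, span=3.0, seed=2)
        env = pd.DataFrame({"x": np.linspace(0, 1, 15)}, index=Y.index)
        p1 = ordn.permutation_test(Y, env, n_perm=99, seed=7)
        p2 = ordn.permutation_test(Y, env, n_perm=99, seed=7)
        assert p1 == p2

    def test_structured_gradient_detected(self):
        Y = coenocline(30, 20, span=4.0, noise=0.1, seed=3)
        env = pd.DataFrame({"x": np.linspace(0, 4, 30)}, index=Y.index)
        _, p = ordn.permutation_test(Y, env, n_perm=199, seed=0)
        assert p <= 0.01


class TestFdr:
    def test_single_p_unchanged(self):
        assert ordn.fdr_bh([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        adj = ordn.fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = ordn.fdr_bh(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ordn.fdr_bh([1.2])


class TestForwardSelect:
    def test_true_driver_kept_noise_dropped(self):
        hits = 0
        n_sims = 20
        for seed in range(n_sims):
            Y = coenocline(25, 15, span=4.0, noise=0.3, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            env = pd.DataFrame(
                {"driver": np.linspace(0, 4, 25) + rng.normal(0, 0.3, 25),
                 "noise": rng.normal(size=25)},
                index=Y.index,
            )
            res = ordn.forward_select(
                Y, env, ["driver", "noise"], alpha=0.05, n_perm=199, seed=seed
            )
            if res.selected == ["driver"]:
                hits += 1
        assert hits >= 0.9 * n_sims

    def test_identical_seed_identical_selection(self):
        Y = coenocline(20, 12, span=3.0, seed=0)
        rng = np.random.default_rng(5)
        env = pd.DataFrame(
            rng.normal(size=(20, 3)), columns=["a", "b", "c"], index=Y.index
        )
        r1 = ordn.forward_select(Y, env, ["a", "b", "c"], n_perm=99, seed=3)
        r2 = ordn.forward_select(Y, env, ["a", "b", "c"], n_perm=99, seed=3)
        assert r1.order == r2.order and r1.p_values == r2.p_values

    def test_empty_candidate_set_errors(self):
        Y = coenocline(10, 8, span=2.0, seed=0)
        with pytest.raises(ValueError):
            ordn.forward_select(Y, pd.DataFrame(index=Y.index), [], seed=0)


class TestVariancePartition:
    def test_single_set_without_covariables_takes_all_emv(self):
        Y = coenocline(20, 12, span=3.0, seed=1)
        env = pd.DataFrame({"x": np.linspace(0, 1, 20)}, index=Y.index)
        part = ordn.variance_partition(Y, {"only": ["x"]}, env)
        row = part.set_index("set").loc["only"]
        assert row["gross_emv_pct"] == pytest.approx(100.0)
        assert row["gross_etv_pct"] == pytest.approx(
            part.attrs["full_model_etv_pct"]
        )

    def test_net_at_most_gross_with_correlated_drivers(self):
        Y = coenocline(40, 25, span=4.0, noise=0.3, seed=8)
        grad = np.linspace(0, 4, 40)
        rng = np.random.default_rng(8)
        env = pd.DataFrame(
            {"x1": grad + rng.normal(0, 0.4, 40),
             "x2": grad + rng.normal(0, 0.4, 40)},
            index=Y.index,
        )
        part = ordn.variance_partition(
            Y, {"s1": ["x1"], "s2": ["x2"]}, env
        ).set_index("set")
        assert part.loc["s1", "net_etv_pct"] <= part.loc["s1", "gross_etv_pct"] + 1e-9
        assert part.loc["s2", "net_etv_pct"] <= part.loc["s2", "gross_etv_pct"] + 1e-9

    def test_unselected_set_reported_not_significant(self):
        Y = coenocline(20, 12, span=3.0, seed=1)
        env = pd.DataFrame({"x": np.linspace(0, 1, 20)}, index=Y.index)
        part = ordn.variance_partition(Y, {"s": ["x"], "empty": []}, env)
        row = part.set_index("set").loc["empty"]
        assert row["variables"] == "n.s." and np.isnan(row["gross_etv_pct"])


class TestDCA:
    def test_duplicated_plots_have_no_gradient(self):
        row = np.array([0.2, 0.4, 0.1, 0.3])
        Y = frame(np.tile(row, (6, 1)))
        assert ordn.dca_gradient_length(Y) == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_matrix_errors(self):
        with pytest.raises(ValueError):
            ordn.dca_gradient_length(frame(np.eye(2)))

    def test_matches_vegan_decorana_roughly(self, tmp_path):
        Y = coenocline(60, 80, span=4.0, margin=1.0, seed=7)
        Y.to_csv(tmp_path / "Y.csv", index=False)
        script = (
            "suppressMessages(library(vegan));"
            f"Y<-read.csv('{tmp_path}/Y.csv');"
            "d<-decorana(Y); sc<-scores(d,display='sites',choices=1);"
            "cat(max(sc)-min(sc))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = float(out.stdout.strip())
        ours = ordn.dca_gradient_length(Y)
        assert ours == pytest.approx(ref, rel=0.2)


class TestSpeciesWeights:
    def test_downweighting_reduces_rare_species_contribution(self):
        Y = coenocline(20, 15, span=3.0, seed=9)
        w = pd.Series(1.0, index=Y.columns)
        assert ordn.total_inertia(Y, w) == pytest.approx(ordn.total_inertia(Y))
        w.iloc[0] = 0.25
        assert ordn.total_inertia(Y, w) < ordn.total_inertia(Y)
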