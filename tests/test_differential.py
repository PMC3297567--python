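"""Per-gene depletion model, q-values, profiles, Venn and primary-RNase."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnasetiling.datatypes import ExpressionMatrix
from rnasetiling.differential import (
    DepletionModel,
    DifferentialConfig,
    assign_primary_rnase,
    call_profiles,
    compute_qvalues,
    fit_gene_models,
    overlap_sets,
)
from rnasetiling.simulate import simulate_gene_matrix


def _matrix_from_rows(rows: dict, samples) -> ExpressionMatrix:
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples.index)
    return ExpressionMatrix(values=values, samples=samples)


class TestFitGeneModels:
    def test_hand_computed_t_statistic(self, main_samples):
        """wt {5.0,5.1}, rny {7.0,7.1}, others as wt: delta_Y = 2, pooled
        s^2 = 0.005 on 4 dof, t = 2/sqrt(0.005) ~ 28.28, p < 1e-4."""
        rows = {"g": [5.0, 5.1, 5.0, 5.1, 5.0, 5.1, 7.0, 7.1]}
        fits = fit_gene_models(_matrix_from_rows(rows, main_samples))
        assert fits.delta.at["g", "Y"] == pytest.approx(2.0)
        assert fits.sigma_hat["g"] ** 2 == pytest.approx(0.005)
        assert fits.dof == 4
        t = fits.delta.at["g", "Y"] / np.sqrt(0.005 * (0.5 + 0.5))
        assert t == pytest.approx(28.2843, abs=1e-3)
        assert fits.pvalues.at["g", "Y"] < 1e-4

    def test_zero_variance_flagged_not_zero_p(self, main_samples):
        rows = {"g": [5.0] * 8}
        fits = fit_gene_models(_matrix_from_rows(rows, main_samples))
        assert (fits.delta.loc["g"] == 0).all()
        assert fits.pvalues.loc["g"].isna().all()
        assert "g" in fits.qc["zero_variance"]

    def test_agrees_with_statsmodels_ols(self, main_samples):
        """Dual route: the vectorised fit matches a statsmodels OLS with a
        condition factor, gene by gene."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        rows = {f"g{i}": rng.normal(8, 0.5, 8) for i in range(5)}
        matrix = _matrix_from_rows(rows, main_samples)
        fits = fit_gene_models(matrix)
        conds = main_samples["condition"].to_numpy()
        for gene in rows:
            df = pd.DataFrame({"y": matrix.values.loc[gene].to_numpy(), "cond": conds})
            ols = smf.ols("y ~ C(cond, Treatment('wt'))", data=df).fit()
            for rnase, cond in (("III", "rnc"), ("J1", "rnjA"), ("Y", "rny")):
                term = f"C(cond, Treatment('wt'))[T.{cond}]"
                assert fits.delta.at[gene, rnase] == pytest.approx(ols.params[term])
                assert fits.pvalues.at[gene, rnase] == pytest.approx(ols.pvalues[term])

    def test_null_type_one_error_calibrated(self):
        """Raw p at alpha=0.05 rejects ~5% of truly null genes."""
        matrix, _ = simulate_gene_matrix(2000, 0, 1.0, 0.2, seed=11)
        fits = fit_gene_models(matrix)
        rate = (fits.pvalues.to_numpy() < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / fits.pvalues.size)
        assert abs(rate - 0.05) < 3 * se

    def test_missing_replicates_rejected(self, main_samples):
        short = main_samples.iloc[:-1]
        values = pd.DataFrame(
            np.ones((3, 7)), index=list("abc"), columns=short.index
        )
        with pytest.raises(ValueError, match="replicates"):
            fit_gene_models(ExpressionMatrix(values=values, samples=short))


class TestQValues:
    def test_single_p_identity(self):
        assert compute_qvalues([0.03]) == pytest.approx([0.03])

    def test_step_up_formula_example(self):
        np.testing.assert_allclose(
            compute_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_nan_excluded_from_m(self):
        q = compute_qvalues([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_qvalues([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60)
    )
    def test_matches_naive_step_up_and_dominates_p(self, pvals):
        """Property: q >= p element-wise, q monotone in p, and equal to a
        naive min-over-j evaluation of the step-up formula."""
        p = np.array(pvals)
        q = compute_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

        m = len(p)
        naive = np.empty(m)
        ranked = np.sort(p)
        for i in range(m):
            naive[i] = min(min(ranked[j] * m / (j + 1) for j in range(i, m)), 1.0)
        back = np.empty(m)
        back[order] = naive
        np.testing.assert_allclose(q, back, atol=1e-12)

    def test_matches_statsmodels_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(compute_qvalues(p), q_sm, atol=1e-12)


class TestProfiles:
    def _table(self, delta, q, main_samples):
        rows = {"g": [5.0, 5.1, 5.0, 5.1, 5.0, 5.1, 5.0, 5.1]}
        fits = fit_gene_models(_matrix_from_rows(rows, main_samples))
        fits.delta.loc["g"] = delta
        qdf = pd.DataFrame({r: [q] for r in ("III", "J1", "Y")}, index=["g"])
        return call_profiles(fits, qdf)

    def test_above_both_thresholds(self, main_samples):
        t = self._table(1.2, 0.05, main_samples)
        assert t.at["g", "profile_Y_2"] == "U"
        assert t.at["g", "profile_Y_1p5"] == "U"

    def test_between_thresholds(self, main_samples):
        t = self._table(0.8, 0.05, main_samples)
        assert t.at["g", "profile_Y_2"] == "-"
        assert t.at["g", "profile_Y_1p5"] == "U"

    def test_fdr_gate_blocks_large_delta(self, main_samples):
        t = self._table(3.0, 0.2, main_samples)
        assert t.at["g", "profile_Y_2"] == "-"
        assert t.at["g", "profile_Y_1p5"] == "-"

    def test_down_direction(self, main_samples):
        t = self._table(-1.2, 0.01, main_samples)
        assert t.at["g", "profile_J1_2"] == "D"


def _profile_frame(entries):
    """entries: {gene: (profile_III, profile_J1, profile_Y, deltas)}"""
    rows = {}
    for gene, (p3, pj, py, deltas) in entries.items():
        rows[gene] = {
            "profile_III_2": p3,
            "profile_J1_2": pj,
            "profile_Y_2": py,
            "delta_III": deltas[0],
            "delta_J1": deltas[1],
            "delta_Y": deltas[2],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


class TestVennAndPrimary:
    def test_single_gene_placement(self):
        table = _profile_frame({"g": ("-", "U", "U", (0, 1, 1))})
        venn = overlap_sets(table)
        assert venn.region("J1", "Y", direction="up") == 1
        assert venn.total_affected == 1

    def test_partition_identity(self):
        rng = np.random.default_rng(3)
        entries = {}
        for i in range(200):
            codes = rng.choice(["U", "D", "-"], size=3, p=[0.3, 0.2, 0.5])
            entries[f"g{i}"] = (*codes, (1.0, 1.0, 1.0))
        table = _profile_frame(entries)
        venn = overlap_sets(table)
        total_regions = sum(venn.up.values()) + sum(venn.down.values()) + venn.mixed
        affected = (table.filter(like="profile") != "-").any(axis=1).sum()
        assert total_regions == venn.total_affected == affected

    def test_ground_truth_recovery(self):
        """Planted disjoint target sets are recovered region by region."""
        matrix, truth = simulate_gene_matrix(300, 90, 2.0, 0.05, seed=21)
        results = DepletionModel(matrix).fit()
        venn = results.venn()
        planted = {"III": set(), "J1": set(), "Y": set()}
        for gene, rnase in truth:
            planted[rnase].add(gene)
        for rnase in ("III", "J1", "Y"):
            assert venn.region(rnase, direction="up") == len(planted[rnase])

    def test_primary_rnase_rules(self):
        table = _profile_frame(
            {
                "max_sig": ("-", "U", "U", (0.5, 1.5, 2.2)),
                "down_only": ("D", "-", "-", (-2.0, 0, 0)),
                "tie": ("-", "U", "U", (0, 1.5, 1.5)),
                "none": ("-", "-", "-", (0, 0, 0)),
            }
        )
        labels = assign_primary_rnase(table)
        assert labels["max_sig"] == "Y"
        assert labels["down_only"] == "down"
        assert labels["tie"] == "Y"  # fixed Y > J1 > III tie-break
        assert labels["none"] is None


class TestCalibration:
    def test_fdr_controlled_on_mixture(self):
        """Empirical FDP at q <= 0.1 stays at/below 0.1 on a null+effect mix."""
        fdps = []
        for seed in range(5):
            matrix, truth = simulate_gene_matrix(2000, 500, 1.0, 0.2, seed=100 + seed)
            results = DepletionModel(matrix).fit()
            q = results.qvalues
            called = [
                (g, r) for r in q.columns for g in q.index[q[r] <= 0.1]
            ]
            false = sum(1 for pair in called if pair not in truth)
            fdps.append(false / max(len(called), 1))
        assert np.mean(fdps) <= 0.1 + 0.02

    def test_power_monotone_in_effect_size(self):
        """Detection power grows with the planted |delta| at fixed noise."""
        powers = []
        for delta in (0.9, 1.1, 1.4):
            hits = 0
            matrix, truth = simulate_gene_matrix(500, 150, delta, 0.2, seed=int(delta * 100))
            results = DepletionModel(matrix).fit()
            q = results.qvalues
            for gene, rnase in truth:
                if q.at[gene, rnase] <= 0.1:
                    hits += 1
            powers.append(hits / len(truth))
        assert powers[0] < powers[1] < powers[2]


class TestResultsSurface:
    def test_summary_and_supplementary_table(self):
        matrix, _ = simulate_gene_matrix(100, 30, 1.5, 0.1, seed=33)
        results = DepletionModel(matrix).fit()
        text = results.summary()
        assert "RNase" in text and "dof" in text
        table = results.supplementary_table()
        for col in (
            "WT",
            "dRNase Y",
            "Qval_RNase J1",
            "Pval_RNase III",
            "Profile Y (2)",
            "Profile Y (1.5)",
        ):
            assert col in table.columns
        assert set(table["Profile Y (2)"].unique()) <= {"U", "D", "-"}

    def test_from_dataframe_constructor(self, main_samples):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(8, 0.3, (10, 8)),
            index=[f"g{i}" for i in range(10)],
            columns=main_samples.index,
        )
        results = DepletionModel.from_dataframe(values, main_samples).fit()
        assert results.table.shape[0] == 10
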