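import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somhub import diff_expression as de
from somhub.coexpr_network import HubRanking
from somhub.io_formats import TIMEPOINTS, ValidationError

from conftest import make_matrix


def two_group_matrix(rng, n_genes, effects=None, sd=0.3):
    """log2 matrix, 3 control + 3 ko per timepoint; ``effects`` maps
    (gene_row, timepoint) -> log2 shift in ko."""
    values = rng.normal(8.0, 0.0, size=(n_genes, 30)) + rng.normal(
        0.0, sd, size=(n_genes, 30)
    )
    matrix = make_matrix(2.0**values, genotypes=("control", "ko"))
    log2 = np.log2(matrix.data.to_numpy())
    if effects:
        for (row, tp), shift in effects.items():
            cols = [
                i
                for i, s in enumerate(matrix.samples)
                if s.genotype == "ko" and s.timepoint == tp
            ]
            log2[row, cols] += shift
    matrix.data.iloc[:, :] = 2.0**log2
    from somhub.preprocess import log2_transform

    return log2_transform(matrix)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        matrix = two_group_matrix(rng, 50)
        _, table = de.fit_moderated_t(matrix, "P7", prior_df_override=0.0)
        ctrl = matrix.data[matrix.columns_for("control", "P7")].to_numpy()
        ko = matrix.data[matrix.columns_for("ko", "P7")].to_numpy()
        for g in range(50):
            t_ref, p_ref = stats.ttest_ind(ko[g], ctrl[g], equal_var=True)
            assert table["t"].iloc[g] == pytest.approx(t_ref, abs=1e-9)
            assert table["p"].iloc[g] == pytest.approx(p_ref, abs=1e-9)

    def test_d0_infinite_equals_fixed_variance_statistic(self):
        rng = np.random.default_rng(1)
        matrix = two_group_matrix(rng, 50)
        fit, table = de.fit_moderated_t(matrix, "P14", prior_df_override=math.inf)
        ctrl = matrix.data[matrix.columns_for("control", "P14")].to_numpy()
        ko = matrix.data[matrix.columns_for("ko", "P14")].to_numpy()
        s0 = math.sqrt(fit.prior_var)
        expected = (ko.mean(axis=1) - ctrl.mean(axis=1)) / (
            s0 * math.sqrt(1 / 3 + 1 / 3)
        )
        np.testing.assert_allclose(table["t"].to_numpy(), expected, atol=1e-9)

    def test_prior_recovery_inverse_gamma(self):
        """(d0, s0^2) recovered within 25% over 20 seeds."""
        d0_true, s0_sq_true, df = 8.0, 0.04, 4.0
        d0_estimates, s0_estimates = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            # scaled inverse chi-square variances, then chi-square s2
            sigma2 = d0_true * s0_sq_true / rng.chisquare(d0_true, size=200)
            s2 = sigma2 * rng.chisquare(df, size=200) / df
            d0_hat, s0_sq_hat = de.estimate_prior(s2, df)
            d0_estimates.append(d0_hat)
            s0_estimates.append(s0_sq_hat)
        d0_gm = float(np.exp(np.mean(np.log(d0_estimates))))
        s0_gm = float(np.exp(np.mean(np.log(s0_estimates))))
        assert abs(d0_gm - d0_true) / d0_true <= 0.25
        assert abs(s0_gm - s0_sq_true) / s0_sq_true <= 0.25

    def test_posterior_variance_between_extremes(self):
        rng = np.random.default_rng(2)
        matrix = two_group_matrix(rng, 100)
        fit, _ = de.fit_moderated_t(matrix, "P1")
        lo = np.minimum(fit.s2, fit.prior_var)
        hi = np.maximum(fit.s2, fit.prior_var)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()

    def test_genotype_swap_negates_fold_changes(self):
        rng = np.random.default_rng(3)
        matrix = two_group_matrix(rng, 30, effects={(0, "P7"): 1.0})
        _, table = de.fit_moderated_t(matrix, "P7")
        swapped = make_matrix(
            2.0 ** matrix.data.to_numpy(), genotypes=("control", "ko")
        )
        # swap genotype labels by reordering columns: ko block first
        data = matrix.data.copy()
        ko_cols = [s.sample_id for s in matrix.samples if s.genotype == "ko"]
        ctrl_cols = [s.sample_id for s in matrix.samples if s.genotype == "control"]
        renamed = pd.concat(
            [
                data[ko_cols].set_axis(ctrl_cols, axis=1),
                data[ctrl_cols].set_axis(ko_cols, axis=1),
            ],
            axis=1,
        )
        swapped.data.iloc[:, :] = 2.0 ** renamed[swapped.data.columns].to_numpy()
        from somhub.preprocess import log2_transform

        _, table_swapped = de.fit_moderated_t(log2_transform(swapped), "P7")
        np.testing.assert_allclose(
            table_swapped["log2_fc"].to_numpy(),
            -table["log2_fc"].to_numpy(),
            atol=1e-9,
        )

    def test_single_replicate_rejected(self):
        rng = np.random.default_rng(4)
        matrix = two_group_matrix(rng, 10)
        single = matrix.subset_samples()
        keep = [
            s for s in single.samples
            if not (s.genotype == "ko" and s.timepoint == "P7" and s.replicate > 1)
        ]
        cols = [s.sample_id for s in keep]
        from somhub.io_formats import ExpressionMatrix

        reduced = ExpressionMatrix(single.data[cols], keep)
        with pytest.raises(ValidationError):
            de.fit_moderated_t(reduced, "P7")

    def test_null_pvalues_uniform(self):
        """Pooled KS test across 10 seeds on 2000 null genes each."""
        pooled = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            matrix = two_group_matrix(rng, 200)
            _, table = de.fit_moderated_t(matrix, "P30")
            pooled.append(table["p"].to_numpy())
        ks = stats.kstest(np.concatenate(pooled), "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """All-thresholds FDR step-up: q_i = min over thresholds t >= p_i of
    m * t / #{p_j <= t}."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [
            m * t / (p <= t).sum() for t in p if t >= pi
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(de.bh_adjust([1.0] * 5), [1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            de.bh_adjust([0.5, 1.5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 13))
            np.testing.assert_allclose(de.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        q = de.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_property_matches_oracle_hypothesis(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=50, deadline=None)
        @given(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12
            )
        )
        def check(p):
            np.testing.assert_allclose(de.bh_adjust(p), bh_oracle(p), atol=1e-12)

        check()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(de.bh_adjust(p), q_ref, atol=1e-12)


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------


class TestCallDe:
    def _table(self, p, fc):
        return pd.DataFrame(
            {
                "log2_fc": np.log2(fc),
                "fold_change": fc,
                "t": np.zeros(len(p)),
                "p": p,
            },
            index=[f"g{i}" for i in range(len(p))],
        )

    def test_rule_examples(self):
        table = de.call_de(self._table([0.00001, 0.00001], [2.0, 1.4]), 0.01, 1.5)
        assert table["call"].tolist() == ["up_in_ko", "ns"]

    def test_down_call(self):
        table = de.call_de(self._table([0.0001], [0.5]), 0.01, 1.5)
        assert table["call"].tolist() == ["down_in_ko"]

    def test_q_dominates_p(self):
        rng = np.random.default_rng(8)
        table = de.call_de(self._table(rng.uniform(size=50), np.full(50, 2.0)))
        assert (table["q"] >= table["p"] - 1e-12).all()


# ---------------------------------------------------------------------------
# intersection and consistency
# ---------------------------------------------------------------------------


def _de_tables(genes, calls):
    """calls: {(gene, tp): (call, fc)}"""
    tables = {}
    for tp in TIMEPOINTS:
        rows = []
        for g in genes:
            call, fc = calls.get((g, tp), ("ns", 1.0))
            rows.append({"log2_fc": np.log2(fc), "fold_change": fc,
                         "t": 0.0, "p": 1.0, "q": 1.0, "call": call})
        tables[tp] = pd.DataFrame(rows, index=pd.Index(genes, name="gene"))
    return tables


def _hub(genes, hub_genes, cluster=0):
    table = pd.DataFrame(
        {
            "mean_rank": np.arange(1, len(genes) + 1, dtype=float),
            "sd_rank": np.zeros(len(genes)),
            "hub": [g in hub_genes for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return {cluster: HubRanking(table=table, beta=6)}


class TestIntersectDeHubs:
    def test_empty_when_no_de_hubs(self):
        genes = ["a", "b", "c"]
        tables = _de_tables(genes, {("b", "P7"): ("up_in_ko", 2.0)})
        result = de.intersect_de_hubs(tables, _hub(genes, {"a"}))
        assert result.empty

    def test_de_hub_row_with_fold_change(self):
        genes = ["a", "b", "c"]
        tables = _de_tables(genes, {("a", "P7"): ("down_in_ko", 0.4)})
        result = de.intersect_de_hubs(tables, _hub(genes, {"a"}))
        assert len(result) == 1
        assert result.iloc[0]["gene"] == "a"
        assert result.iloc[0]["fc_P7"] == pytest.approx(0.4)
        assert np.isnan(result.iloc[0]["fc_P1"])

    def test_non_hub_de_genes_excluded(self):
        genes = ["a", "b"]
        tables = _de_tables(genes, {("b", "P1"): ("up_in_ko", 3.0)})
        result = de.intersect_de_hubs(tables, _hub(genes, {"a"}))
        assert result.empty

    def test_not_determined_cluster_skipped(self):
        genes = ["a"]
        tables = _de_tables(genes, {("a", "P1"): ("up_in_ko", 3.0)})
        result = de.intersect_de_hubs(tables, {0: None})
        assert result.empty


class TestConsistentDe:
    def test_all_five_up(self):
        genes = ["a", "b"]
        calls = {("a", tp): ("up_in_ko", 2.0) for tp in TIMEPOINTS}
        up, down = de.consistent_de(_de_tables(genes, calls))
        assert up == ["a"] and down == []

    def test_four_of_five_excluded(self):
        genes = ["a"]
        calls = {("a", tp): ("up_in_ko", 2.0) for tp in TIMEPOINTS[:4]}
        up, down = de.consistent_de(_de_tables(genes, calls))
        assert up == [] and down == []

    def test_missing_timepoint_rejected(self):
        genes = ["a"]
        tables = _de_tables(genes, {})
        del tables["P60"]
        with pytest.raises(ValidationError):
            de.consistent_de(tables)

    def test_planted_consistent_sets_recovered(self):
        """9 all-age up + 2 all-age down recovered in >= 90% of 20 seeds.

        Runs on the generator's per-gene signal probes (log2) so the
        check validates DE calling against generator truth.
        """
        from somhub import preprocess as pp
        from somhub import synthetic as syn
        from somhub.io_formats import ExpressionMatrix

        up_genes = [f"G{i:05d}" for i in range(1, 10)]
        down_genes = ["G00020", "G00021"]
        effects = tuple(
            syn.KoEffect(g, tp, 2.0) for g in up_genes for tp in TIMEPOINTS
        ) + tuple(
            syn.KoEffect(g, tp, 0.4) for g in down_genes for tp in TIMEPOINTS
        )
        ok = 0
        for seed in range(20):
            config = syn.SimulationConfig(
                n_genes=120,
                n_negative_controls=10,
                ko_effects=effects,
                noise_sd_log2=0.15,
                seed=seed,
            )
            matrices, _, _ = syn.generate_expression(config)
            genes = [f"G{i:05d}" for i in range(1, 121)]
            probes = [f"ILMN_{g}" for g in genes]
            frames = []
            for m in matrices.values():
                frame = m.data.loc[probes].copy()
                frame.index = genes
                frames.append(frame)
            combined = ExpressionMatrix(
                pd.concat(frames, axis=1),
                [s for m in matrices.values() for s in m.samples],
            )
            tables = de.de_all_timepoints(pp.log2_transform(combined))
            up, down = de.consistent_de(tables)
            ok += sorted(up) == sorted(up_genes) and sorted(down) == sorted(down_genes)
        assert ok >= 18
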