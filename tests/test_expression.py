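import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cazymap.expression import (
    CONTROL,
    call_induction,
    cluster_coexpression_branches,
    compute_contrasts,
    core_induced_set,
    family_induction_matrix,
    fold_change_contrast,
    induced_gene_set,
    max_induction_profile,
    moderated_t_p,
    moderated_variance,
    trigamma_inverse,
)
from cazymap.synthetic import gen_expression_dataset


class TestFoldChange:
    def make_dataset(self, induced, control):
        from cazymap.expression import ExpressionDataset

        rows, cols = [], {}
        for i, v in enumerate(induced):
            sid = f"SO_b1_t17_r{i+1}"
            rows.append({"sample_id": sid, "substrate": "SO", "time_h": 17,
                         "replicate": i + 1, "batch": 1})
            cols[sid] = [v]
        for i, v in enumerate(control):
            sid = f"CONTROL_b1_t17_r{i+1}"
            rows.append({"sample_id": sid, "substrate": CONTROL, "time_h": 17,
                         "replicate": i + 1, "batch": 1})
            cols[sid] = [v]
        values = pd.DataFrame(cols, index=["g1"])
        return ExpressionDataset(values=values, sheet=pd.DataFrame(rows))

    @pytest.mark.parametrize(
        "induced, control, expected",
        [
            ([10, 10, 10, 10], [8, 8, 8, 8], 2.0),
            ([9, 9, 9, 9], [9, 9, 9, 9], 0.0),
            # arithmetic oracle: mean 9.1 - mean 8.0 = 1.1
            ([9.1, 9.3, 8.9, 9.1], [8.0, 8.2, 7.8, 8.0], 1.1),
        ],
    )
    def test_mean_difference(self, induced, control, expected):
        data = self.make_dataset(induced, control)
        assert fold_change_contrast(data, "g1", "SO", 17) == pytest.approx(expected)

    def test_missing_stratum_named(self):
        data = self.make_dataset([9, 9, 9, 9], [8, 8, 8, 8])
        with pytest.raises(KeyError, match="time_h=41"):
            fold_change_contrast(data, "g1", "SO", 41)


class TestModeratedVariance:
    def test_identical_variances_full_shrinkage(self):
        d0, s0 = moderated_variance([0.25] * 10, df_per_gene=6)
        assert math.isinf(d0) and s0 == pytest.approx(0.25)

    def test_parameter_recovery_scaled_inv_chisq(self):
        # draws from the assumed prior: recover (d0, s0^2) within 10 %
        rng = np.random.default_rng(12345)
        d0_true, s0_true, dg, n = 4.0, 1.0, 6, 10_000
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        d0, s0 = moderated_variance(s2, dg)
        assert d0 == pytest.approx(d0_true, rel=0.10)
        assert s0 == pytest.approx(s0_true, rel=0.10)

    def test_two_spread_variances_weak_shrinkage(self):
        # direct evaluation of the moment equations: excess log-variance far
        # above the sampling term gives a small finite d0
        d0, s0 = moderated_variance([0.1, 10.0], df_per_gene=6)
        assert math.isfinite(d0) and 0 < d0 < 4
        assert s0 > 0

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (1e-5, 0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)

    def test_needs_two_positive_variances(self):
        with pytest.raises(ValueError):
            moderated_variance([0.5], df_per_gene=6)


def classical_pooled_t(x1, x2):
    """Textbook pooled two-sample t with n1 + n2 - 2 df."""
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (n1 + n2 - 2)
    t = (np.mean(x1) - np.mean(x2)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return t, p


class TestModeratedT:
    x1 = np.array([9.1, 9.3, 8.9, 9.1])
    x2 = np.array([8.0, 8.2, 7.8, 8.0])

    def test_d0_zero_is_classical_pooled_t(self):
        t, p = moderated_t_p(self.x1, self.x2, d0=0.0, s0_sq=0.0)
        t_ref, p_ref = classical_pooled_t(self.x1, self.x2)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_d0_inf_uses_prior_variance_exactly(self):
        s0_sq = 0.04
        t, p = moderated_t_p(self.x1, self.x2, d0=math.inf, s0_sq=s0_sq)
        diff = self.x1.mean() - self.x2.mean()
        t_ref = diff / math.sqrt(s0_sq * 0.5)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(t_ref)), abs=1e-12)

    def test_finite_d0_matches_direct_formula(self):
        d0, s0_sq = 4.0, 0.09
        t, p = moderated_t_p(self.x1, self.x2, d0=d0, s0_sq=s0_sq)
        n1 = n2 = 4
        dg = n1 + n2 - 2
        sg2 = (np.sum((self.x1 - self.x1.mean()) ** 2)
               + np.sum((self.x2 - self.x2.mean()) ** 2)) / dg
        st2 = (d0 * s0_sq + dg * sg2) / (d0 + dg)
        t_ref = (self.x1.mean() - self.x2.mean()) / math.sqrt(st2 * (1 / n1 + 1 / n2))
        p_ref = 2 * stats.t.sf(abs(t_ref), df=d0 + dg)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_posterior_variance_warns_p_zero(self):
        with pytest.warns(RuntimeWarning):
            t, p = moderated_t_p([1.0, 1.0], [0.0, 0.0], d0=0.0, s0_sq=0.0)
        assert p == 0.0 and math.isinf(t)


class TestInductionCall:
    @pytest.mark.parametrize(
        "p, lfc, expected",
        [
            (0.005, 0.5, 1),
            (0.005, 0.4, 0),    # lfc boundary strict
            (0.05, 3.0, 0),     # p boundary
            (0.01, 0.5, 0),     # p boundary strict
            (0.005, -0.5, -1),
        ],
    )
    def test_dual_threshold(self, p, lfc, expected):
        assert call_induction(lfc, p) == expected

    @given(lfc=st.floats(-5, 5), p=st.floats(0, 1))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_antisymmetric_in_lfc(self, lfc, p):
        assert call_induction(-lfc, p) == -call_induction(lfc, p)


def make_calls(records):
    return pd.DataFrame(records, columns=["gene_id", "substrate", "time_h", "lfc", "t_stat", "p_value", "call"])


class TestInducedSets:
    def test_single_positive_call_included(self):
        calls = make_calls([
            ("g1", "SO", 17, 2.0, 5.0, 1e-4, 1),
            ("g2", "SO", 17, -2.0, -5.0, 1e-4, -1),
            ("g3", "XO", 6, 0.1, 0.5, 0.7, 0),
        ])
        assert induced_gene_set(calls) == {"g1"}

    def test_all_zero_empty(self):
        calls = make_calls([("g1", "SO", 17, 0.0, 0.0, 1.0, 0)])
        assert induced_gene_set(calls) == set()

    def test_monotone_adding_calls(self):
        base = make_calls([("g1", "SO", 17, 2.0, 5.0, 1e-4, 1)])
        more = pd.concat(
            [base, make_calls([("g2", "XO", 6, 2.0, 5.0, 1e-4, 1)])], ignore_index=True
        )
        assert induced_gene_set(base) <= induced_gene_set(more)

    def test_core_set_rules(self):
        substrates = ["BO", "BS", "BE", "XO", "XB", "AV1", "AV0.75", "WH", "SP", "SO"]
        class_map = {"AV1": "cellulose", "AV0.75": "cellulose", "SP": "cellulose",
                     "SO": "cellulose", "XO": "xylan", "XB": "xylan",
                     "BO": "other", "BS": "other", "BE": "other", "WH": "other"}
        # gene a: induced on all 10; gene b: 8 substrates, no xylan;
        # gene c: exactly 7 including AV1 (cellulose) and XO (xylan)
        records = []
        for s in substrates:
            records.append(("a", s, 17, 2.0, 5.0, 1e-4, 1))
        for s in ["BO", "BS", "BE", "AV1", "AV0.75", "WH", "SP", "SO"]:
            records.append(("b", s, 17, 2.0, 5.0, 1e-4, 1))
        for s in ["BO", "BS", "BE", "AV1", "XO", "WH", "SP"]:
            records.append(("c", s, 17, 2.0, 5.0, 1e-4, 1))
        # every substrate must appear in the table for the 70 % denominator
        for s in substrates:
            records.append(("d", s, 17, 0.0, 0.0, 1.0, 0))
        calls = make_calls(records)
        assert core_induced_set(calls, class_map, fraction=0.70) == {"a", "c"}

    def test_core_set_missing_class_map_entry(self):
        calls = make_calls([("g1", "SO", 17, 2.0, 5.0, 1e-4, 1)])
        with pytest.raises(KeyError):
            core_induced_set(calls, {})


class TestFamilyMatrix:
    def test_zero_matrix_for_no_calls(self):
        calls = make_calls([("g1", "SO", 17, 0.0, 0.0, 1.0, 0)])
        matrix, margins = family_induction_matrix(calls, {"g1": "GH7"})
        assert matrix.to_numpy().sum() == 0
        assert margins["n_genes_induced"].sum() == 0

    def test_single_cell(self):
        calls = make_calls([
            ("g1", "SO", 17, 2.0, 5.0, 1e-4, 1),
            ("g1", "SO", 41, 2.5, 5.0, 1e-4, 1),  # same gene, same substrate: one
            ("g2", "SO", 17, 0.0, 0.0, 1.0, 0),
        ])
        matrix, margins = family_induction_matrix(calls, {"g1": "GH7", "g2": "GH5"})
        assert matrix.loc["GH7", "SO"] == 1
        assert margins.loc["SO", "n_genes_induced"] == 1
        assert margins.loc["SO", "n_families_induced"] == 1

    def test_planted_contingency_table(self):
        rng = np.random.default_rng(5)
        families = {f"g{i}": f"GH{1 + i % 4}" for i in range(40)}
        substrates = ["SO", "XO", "AV1"]
        records, expected = [], {}
        for g, fam in families.items():
            for s in substrates:
                hit = bool(rng.integers(2))
                records.append((g, s, 17, 2.0 if hit else 0.0, 0.0, 1e-4 if hit else 1.0, int(hit)))
                if hit:
                    expected[(fam, s)] = expected.get((fam, s), 0) + 1
        matrix, _ = family_induction_matrix(make_calls(records), families)
        for (fam, s), n in expected.items():
            assert matrix.loc[fam, s] == n
        assert matrix.to_numpy().sum() == sum(expected.values())

    def test_unannotated_counted_unassigned(self):
        calls = make_calls([("mystery", "SO", 17, 2.0, 5.0, 1e-4, 1)])
        with pytest.warns(RuntimeWarning):
            matrix, _ = family_induction_matrix(calls, {})
        assert matrix.loc["UNASSIGNED", "SO"] == 1


class TestMaxInductionProfile:
    def test_max_over_time(self):
        calls = make_calls([
            ("g1", "SO", 0, 0.1, 0, 1, 0),
            ("g1", "SO", 6, 2.3, 0, 1, 0),
            ("g1", "SO", 17, 1.0, 0, 1, 0),
            ("g2", "SO", 6, -1.0, 0, 1, 0),
            ("g2", "SO", 17, -2.0, 0, 1, 0),
            ("g3", "XO", 6, 0.7, 0, 1, 0),
        ])
        profile = max_induction_profile(calls)
        assert profile.loc["g1", "SO"] == 2.3
        assert profile.loc["g2", "SO"] == -1.0  # maximum even when all negative
        assert profile.loc["g3", "XO"] == 0.7


class TestBranches:
    def test_k1_single_branch(self):
        matrix = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                              index=[f"g{i}" for i in range(5)])
        labels, _ = cluster_coexpression_branches(matrix, k=1)
        assert set(labels.values()) == {"A"}

    def test_well_separated_groups_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(10, 6))
        b = rng.normal(5.0, 0.1, size=(10, 6))
        matrix = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(20)])
        labels, _ = cluster_coexpression_branches(matrix, k=2)
        first = {labels[f"g{i}"] for i in range(10)}
        second = {labels[f"g{i}"] for i in range(10, 20)}
        assert first == {"A"} and second == {"B"}

    def test_duplicate_rows_co_branch(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 4))
        matrix = pd.DataFrame(np.vstack([base, base[:1]]),
                              index=[f"g{i}" for i in range(7)])
        labels, _ = cluster_coexpression_branches(matrix, k=3)
        assert labels["g0"] == labels["g6"]

    def test_partition_invariant_to_row_permutation(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(12, 5)),
                              index=[f"g{i}" for i in range(12)])
        labels, _ = cluster_coexpression_branches(matrix, k=3)
        perm = rng.permutation(12)
        shuffled = matrix.iloc[perm]
        labels2, _ = cluster_coexpression_branches(shuffled, k=3)
        def parts(lab):
            groups = {}
            for g, b in lab.items():
                groups.setdefault(b, set()).add(g)
            return {frozenset(v) for v in groups.values()}
        assert parts(labels) == parts(labels2)

    def test_invalid_k(self):
        matrix = pd.DataFrame(np.zeros((3, 2)), index=list("abc"))
        with pytest.raises(ValueError):
            cluster_coexpression_branches(matrix, k=0)
        with pytest.raises(ValueError):
            cluster_coexpression_branches(matrix, k=4)


class TestContrastPipeline:
    def test_planted_effect_called_induced(self):
        data, truth = gen_expression_dataset(
            100, 0.2, 2.0, 0.5, substrates=("SO",), timepoints=(0, 17), seed=0
        )
        calls = compute_contrasts(data)
        at17 = calls[(calls["substrate"] == "SO") & (calls["time_h"] == 17)]
        called = set(at17.loc[at17["call"] == 1, "gene_id"])
        assert set(truth.induced_genes) <= called

    def test_no_effect_at_time_zero(self):
        data, truth = gen_expression_dataset(
            100, 0.2, 2.0, 0.5, substrates=("SO",), timepoints=(0, 17), seed=0
        )
        calls = compute_contrasts(data)
        at0 = calls[(calls["substrate"] == "SO") & (calls["time_h"] == 0)]
        # planted induction starts after substrate addition; time 0 is null
        assert (at0["call"] != 0).mean() < 0.1

    def test_null_p_values_approximately_uniform(self):
        # with the prior estimated from the data, moderated p-values under
        # the null stay close to uniform (Kolmogorov-Smirnov distance < 0.05)
        for seed in range(5):
            data, _ = gen_expression_dataset(
                2000, 0.0, 0.0, 0.2, substrates=("SO",), timepoints=(17,), seed=seed
            )
            calls = compute_contrasts(data)
            ks = stats.kstest(calls["p_value"], "uniform").statistic
            assert ks < 0.05
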