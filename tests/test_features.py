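import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drivergnn.features import (
    BLOCK_SIZES,
    CONVERSION_CLASSES,
    FEATURE_SCHEMA,
    attach_covariates,
    base_conversion_counts,
    cnv_rate,
    de_significance_flag,
    expression_fold_change,
    gene_outlier_count,
    gene_vaf,
    grubbs_critical_value,
    methylation_fold_change,
    mutation_frequency,
    normalize_features,
    outlier_matrix,
)
from drivergnn.io import CNVMatrix, CovariateTable, MethylationMatrix, MutationTable
from conftest import make_expression


def make_meth(values, tumor, normal):
    e = make_expression(values, tumor, normal)
    return MethylationMatrix(values=e.values, group=e.group)


def make_cnv(values, tumor, normal):
    e = make_expression(values, tumor, normal)
    return CNVMatrix(values=e.values, group=e.group)


def muts_from_rows(rows):
    df = pd.DataFrame(rows, columns=["gene", "sample", "ref", "alt", "alt_depth", "total_depth"])
    df["is_snv"] = (
        df["ref"].isin(list("ACGT")) & df["alt"].isin(list("ACGT")) & (df["ref"] != df["alt"])
    )
    return MutationTable(records=df)


class TestFoldChanges:
    def test_methylation_ratio(self):
        m = make_meth([[0.6, 0.6, 0.3, 0.3]], 2, 2)
        assert methylation_fold_change(m).iloc[0] == pytest.approx(2.0, abs=1e-4)

    def test_methylation_identity(self):
        m = make_meth([[0.4, 0.4, 0.4, 0.4]], 2, 2)
        assert methylation_fold_change(m).iloc[0] == pytest.approx(1.0)

    def test_methylation_zero_normal_finite_via_pseudocount(self):
        m = make_meth([[0.5, 0.5, 0.0, 0.0]], 2, 2)
        v = methylation_fold_change(m).iloc[0]
        assert np.isfinite(v)
        assert v == pytest.approx((0.5 + 1e-6) / 1e-6, rel=1e-3)

    def test_expression_log2(self):
        e = make_expression([[5, 5, 5, 5], [8, 8, 2, 2]], 2, 2)
        fc = expression_fold_change(e)
        assert fc.iloc[0] == pytest.approx(0.0, abs=1e-5)
        assert fc.iloc[1] == pytest.approx(2.0, abs=1e-5)

    def test_unmeasured_gene_is_zero(self):
        e = make_expression([[np.nan, np.nan, 3, 4]], 2, 2)
        assert expression_fold_change(e).iloc[0] == 0.0


class TestDEFlag:
    def test_forced_directions(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=(2, 40))
        up = np.concatenate([base[0, :20] + 50, base[0, 20:]])
        down = np.concatenate([base[1, :20] - 50, base[1, 20:]])
        e = make_expression(np.vstack([up, down]), 20, 20)
        flags = de_significance_flag(e)
        assert flags.iloc[0] == 1 and flags.iloc[1] == -1

    def test_null_mostly_zero(self):
        rng = np.random.default_rng(42)
        e = make_expression(rng.normal(5, 1, size=(1000, 40)), 20, 20)
        flags = de_significance_flag(e, alpha=0.05)
        assert (flags == 0).mean() >= 0.90


class TestGrubbs:
    def test_matches_direct_t_quantile_formula(self):
        n, alpha = 10, 0.05
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        assert grubbs_critical_value(n, alpha) == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_n(self):
        vals = [grubbs_critical_value(n) for n in range(3, 201)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_monotone_in_alpha(self):
        assert grubbs_critical_value(20, 0.01) > grubbs_critical_value(20, 0.05)

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            grubbs_critical_value(2)


class TestOutliers:
    def test_planted_outlier_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 1, size=(1, 50))
        x[0, 7] = 10 + 6 * x.std(ddof=1)
        e = make_expression(np.hstack([x, rng.normal(10, 1, size=(1, 5))]), 50, 5)
        om = outlier_matrix(e)
        assert om.values.iloc[0, 7] == 1
        assert om.values.iloc[0].sum() == 1

    def test_constant_gene_all_zero(self):
        e = make_expression([[3.0] * 10 + [1.0] * 2], 10, 2)
        assert outlier_matrix(e).values.sum().sum() == 0

    def test_low_outlier_not_flagged_one_sided(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 1, size=(1, 50))
        x[0, 3] = 10 - 8 * 1.0
        e = make_expression(np.hstack([x, rng.normal(10, 1, (1, 5))]), 50, 5)
        assert outlier_matrix(e).values.iloc[0, 3] == 0

    def test_outlier_count_is_row_sum(self):
        rng = np.random.default_rng(3)
        from drivergnn.features import OutlierMatrix

        m = (rng.random((20, 30)) < 0.3).astype(int)
        om = OutlierMatrix(values=pd.DataFrame(m))
        np.testing.assert_array_equal(gene_outlier_count(om).to_numpy(), m.sum(axis=1))


class TestMutationFeatures:
    def test_frequency_distinct_sample_rule(self):
        rows = [("A", f"S{i}", "C", "T", 10, 100) for i in range(3)]
        rows += [("B", "S0", "C", "T", 10, 100)] * 5
        samples = [f"S{i}" for i in range(10)]
        mf = mutation_frequency(muts_from_rows(rows), samples, ["A", "B", "C"])
        assert mf["A"] == pytest.approx(0.3)
        assert mf["B"] == pytest.approx(0.1)
        assert mf["C"] == 0.0

    def test_vaf_mean_over_records(self):
        rows = [("A", "S0", "C", "T", 30, 100), ("A", "S1", "C", "T", 50, 100)]
        v = gene_vaf(muts_from_rows(rows), ["A", "B"])
        assert v["A"] == pytest.approx(0.4)
        assert v["B"] == 0.0

    def test_conversion_counts(self):
        rows = [
            ("A", "S0", "C", "T", 1, 10),
            ("A", "S1", "C", "T", 1, 10),
            ("A", "S2", "A", "G", 1, 10),
            ("A", "S3", "AC", "A", 1, 10),  # indel: ignored
        ]
        t = base_conversion_counts(muts_from_rows(rows), ["A"])
        assert t.shape[1] == 12
        assert t.loc["A", "conv_C_T"] == 2
        assert t.loc["A", "conv_A_G"] == 1
        assert t.loc["A"].sum() == 3

    def test_conversion_column_order_fixed(self):
        t = base_conversion_counts(muts_from_rows([("A", "S0", "C", "T", 1, 10)]), ["A"])
        assert list(t.columns) == [f"conv_{c.replace('>', '_')}" for c in CONVERSION_CLASSES]


class TestCNVRate:
    def test_direct_formula(self):
        c = make_cnv([[2, 2, 1, 1]], 2, 2)
        assert cnv_rate(c).iloc[0] == pytest.approx(2.0)

    def test_symmetry(self):
        c = make_cnv([[1, 1, 1, 1]], 2, 2)
        assert cnv_rate(c).iloc[0] == pytest.approx(1.0)

    def test_pseudo_event_on_zero_normals(self):
        c = make_cnv([[2, 1, 0, 0]], 2, 2)
        assert cnv_rate(c).iloc[0] == pytest.approx(3.0)


class TestCovariates:
    def test_present_gene_passthrough_and_median_imputation(self):
        rng = np.random.default_rng(4)
        table = CovariateTable(
            values=pd.DataFrame(rng.normal(size=(5, 11)), index=list("abcde"))
        )
        out = attach_covariates(table, ["a", "zz"])
        np.testing.assert_allclose(out.loc["a"], table.values.loc["a"])
        np.testing.assert_allclose(out.loc["zz"], table.values.median(axis=0))
        assert out.shape[1] == 11

    def test_wrong_width_hard_error(self):
        with pytest.raises(ValueError, match="11"):
            CovariateTable(values=pd.DataFrame(np.zeros((3, 10))))


class TestNormalization:
    def test_minmax(self):
        df = pd.DataFrame({"f": [0.0, 5.0, 10.0]})
        np.testing.assert_allclose(normalize_features(df)["f"], [0, 0.5, 1])

    def test_constant_column_zero(self):
        df = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
        assert (normalize_features(df)["f"] == 0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((30, 4)), columns=list("wxyz"))
        once = normalize_features(df)
        pd.testing.assert_frame_equal(once, normalize_features(once))

    def test_non_finite_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "bad": [np.inf, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            normalize_features(df)


class TestAssembly:
    def test_schema_partition(self, default_features):
        assert default_features.values.shape[1] == 36
        counts = {}
        for _, block in FEATURE_SCHEMA:
            counts[block] = counts.get(block, 0) + 1
        assert counts == BLOCK_SIZES == {
            "genomic": 26,
            "transcriptomic": 3,
            "epigenomic": 1,
            "network": 6,
        }

    def test_all_values_unit_interval(self, default_features):
        v = default_features.values.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_missing_block_is_hard_error(self, small_sim):
        from drivergnn.features import assemble_feature_matrix

        with pytest.raises((ValueError, TypeError)):
            assemble_feature_matrix(
                mut_freq=pd.Series(dtype=float),
                vaf=pd.Series(dtype=float),
                covariates=pd.DataFrame(),
                conversions=pd.DataFrame(),
                cnv=pd.Series(dtype=float),
                expr_fc=pd.Series(dtype=float),
                de_flag=pd.Series(dtype=float),
                outlier_count=pd.Series(dtype=float),
                meth_fc=pd.Series(dtype=float),
                network=None,
            )


def test_sample_order_invariance(small_sim):
    """Permuting sample columns leaves every feature unchanged."""
    from drivergnn.features import compute_feature_matrix
    from drivergnn.io import ExpressionMatrix, MethylationMatrix, CNVMatrix, OmicsBundle

    b = small_sim.bundle
    rng = np.random.default_rng(9)
    perm = rng.permutation(b.expression.sample_ids).tolist()

    def permute(m, cls):
        return cls(values=m.values[perm], group=dict(m.group))

    b2 = OmicsBundle(
        expression=permute(b.expression, ExpressionMatrix),
        methylation=permute(b.methylation, MethylationMatrix),
        mutations=b.mutations,
        cnv=permute(b.cnv, CNVMatrix),
        covariates=b.covariates,
    )
    f1 = compute_feature_matrix(b, small_sim.ppi, small_sim.cprg)
    f2 = compute_feature_matrix(b2, small_sim.ppi, small_sim.cprg)
    pd.testing.assert_frame_equal(f1.values, f2.values)
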