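import numpy as np
import pandas as pd
import pytest

from imodkit import SyntheticSpec, generate_activities
from imodkit.activities import (
    activity_correlation_clusters,
    count_dima_per_condition,
    dima,
    fit_dima_null,
    fit_dima_nulls,
    sample_profile_clusters,
)
from imodkit.compendium_io import SampleMetadata


@pytest.fixture(scope="module")
def null_activities():
    """115-component activity matrix with replicate structure and no condition effects."""
    spec = SyntheticSpec(
        n_genes=100, n_modules=115, module_size_min=8, module_size_max=8,
        n_projects=50, conditions_per_project=3, replicates_per_condition=4,
        activity_scale=0.0, replicate_noise_sd=1.0, seed=5,
    )
    A, meta = generate_activities(spec)
    return A, meta


class TestDimaNull:
    def test_identical_replicates_degenerate_scale(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(20)],
                    "project": ["P"] * 20,
                    "condition": [f"c{i // 2}" for i in range(20)],
                    "replicate_group": [f"c{i // 2}" for i in range(20)],
                    "is_reference": [i < 2 for i in range(20)],
                }
            )
        )
        a_row = pd.Series(np.repeat(np.arange(10.0), 2), index=[f"s{i}" for i in range(20)])
        null = fit_dima_null(a_row, meta)
        assert null.scale < 1e-4  # epsilon floor, no crash

    def test_fitted_tail_self_consistent_on_lognormal_diffs(self):
        """MLE fit recovers the tail when the differences really are log-normal."""
        from scipy.stats import lognorm

        rng = np.random.default_rng(10)
        diffs = lognorm.rvs(0.8, scale=1.5, size=2000, random_state=rng)
        samples = ["s0", "s1"]
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "project": ["P", "P"],
                    "condition": ["c", "c"],
                    "replicate_group": ["c", "c"],
                    "is_reference": [True, True],
                }
            )
        )
        a_row = pd.Series([0.0, 0.0], index=samples)
        null = fit_dima_null(a_row, meta, extra_diffs=diffs)
        fitted_q95 = lognorm.ppf(0.95, null.shape, scale=null.scale)
        empirical_q95 = np.quantile(diffs, 0.95)
        assert abs(fitted_q95 - empirical_q95) / empirical_q95 < 0.15

    def test_fitted_tail_conservative_on_gaussian_replicate_noise(self):
        """On half-normal differences the log-normal fit overestimates the tail
        (conservative p-values), but not absurdly so."""
        rng = np.random.default_rng(10)
        n_groups = 200
        samples = [f"s{i}" for i in range(2 * n_groups)]
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "project": ["P"] * len(samples),
                    "condition": [f"c{i // 2}" for i in range(len(samples))],
                    "replicate_group": [f"c{i // 2}" for i in range(len(samples))],
                    "is_reference": [i < 2 for i in range(len(samples))],
                }
            )
        )
        a_row = pd.Series(rng.normal(0, 1.0, len(samples)), index=samples)
        null = fit_dima_null(a_row, meta)
        diffs = np.abs(a_row.to_numpy()[::2] - a_row.to_numpy()[1::2])
        from scipy.stats import lognorm

        fitted_q95 = lognorm.ppf(0.95, null.shape, scale=null.scale)
        empirical_q95 = np.quantile(diffs, 0.95)
        assert empirical_q95 <= fitted_q95 <= 2.0 * empirical_q95

    def test_scale_ordering_preserved(self, null_activities):
        A, meta = null_activities
        null_1 = fit_dima_null(A.iloc[0], meta)
        null_2 = fit_dima_null(A.iloc[0] * 2.0, meta)
        assert null_2.scale > null_1.scale

    def test_too_few_pairs_advises_pooling(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "project": ["P", "P"],
                    "condition": ["c", "c"],
                    "replicate_group": ["c", "c"],
                    "is_reference": [True, True],
                }
            )
        )
        a_row = pd.Series([0.0, 1.0], index=["s1", "s2"])
        with pytest.raises(ValueError, match="pooling"):
            fit_dima_null(a_row, meta)


class TestDima:
    def test_identical_groups_nothing_significant(self, null_activities):
        A, meta = null_activities
        nulls = fit_dima_nulls(A, meta)
        group = A.columns[:4].tolist()
        res = dima(A, group, group, nulls)
        assert (res["delta"] == 0).all()
        assert not res["significant"].any()

    def test_symmetry_in_group_order(self, null_activities):
        A, meta = null_activities
        nulls = fit_dima_nulls(A, meta)
        g1, g2 = A.columns[:4].tolist(), A.columns[8:12].tolist()
        r12 = dima(A, g1, g2, nulls)
        r21 = dima(A, g2, g1, nulls)
        assert np.allclose(r12["delta"], r21["delta"])
        assert np.allclose(r12["p"], r21["p"])
        assert (r12["significant"] == r21["significant"]).all()

    def test_conjunction_rule_enforced(self, null_activities):
        """A delta above min_delta is not significant unless q also clears alpha."""
        A, meta = null_activities
        nulls = fit_dima_nulls(A, meta)
        tbl = meta.table
        sub = tbl[tbl["project"] == "P01"]
        ref = sub[sub["is_reference"]]["sample_id"].tolist()
        grp = sub.loc[sub["condition"] == "P01_c1", "sample_id"].tolist()
        A2 = A.copy()
        A2.loc["mod01", grp] += 6.0  # above min_delta=5 but weak vs 115-way BH
        res = dima(A2, grp, ref, nulls, min_delta=5.0, alpha=1e-12).set_index("component_id")
        row = res.loc["mod01"]
        assert row["delta"] > 5.0
        assert not row["significant"]  # q >= alpha blocks the call

    def test_planted_shifts_recovered_exactly(self):
        spec = SyntheticSpec(
            n_genes=100, n_modules=30, module_size_min=8, module_size_max=8,
            n_projects=50, conditions_per_project=3, replicates_per_condition=4,
            activity_scale=0.0, replicate_noise_sd=1.0, seed=17,
        )
        A, meta = generate_activities(spec)
        nulls = fit_dima_nulls(A, meta)
        tbl = meta.table
        sub = tbl[tbl["project"] == "P01"]
        ref = sub[sub["is_reference"]]["sample_id"].tolist()
        grp = sub.loc[sub["condition"] == "P01_c1", "sample_id"].tolist()
        shifted = ["mod01", "mod05", "mod10"]
        A.loc[shifted, grp] += 20.0
        res = dima(A, grp, ref, nulls)
        assert sorted(res.loc[res["significant"], "component_id"]) == sorted(shifted)


class TestCountPerCondition:
    def test_null_compendium_near_zero_median(self, null_activities):
        A, meta = null_activities
        nulls = fit_dima_nulls(A, meta)
        counts, median = count_dima_per_condition(A, meta, nulls)
        assert len(counts) == 100  # 50 projects x 2 non-reference conditions
        assert median == 0.0

    def test_reference_condition_not_compared(self, null_activities):
        A, meta = null_activities
        nulls = fit_dima_nulls(A, meta)
        counts, _ = count_dima_per_condition(A, meta, nulls)
        ref_conditions = set(
            meta.table.loc[meta.table["is_reference"], "condition"]
        )
        assert not (counts["condition"].isin(ref_conditions)).any()


class TestClustering:
    def test_shared_latent_factor_components_cluster_together(self):
        spec = SyntheticSpec(
            n_genes=100, n_modules=6, module_size_min=8, module_size_max=8,
            n_projects=10, conditions_per_project=4, replicates_per_condition=2,
            activity_scale=1.0, stimulon_groups=(((0, 1), 10.0),),
            replicate_noise_sd=0.2, seed=23,
        )
        A, _ = generate_activities(spec)
        clustering = activity_correlation_clusters(A, threshold=0.3)
        assert clustering.assignments["mod01"] == clustering.assignments["mod02"]
        assert clustering.correlation.loc["mod01", "mod02"] > 0.9

    def test_duplicated_row_r_is_one(self):
        rng = np.random.default_rng(2)
        A = pd.DataFrame(rng.normal(0, 1, size=(3, 30)), index=["a", "b", "c"])
        A.loc["c"] = A.loc["a"]
        clustering = activity_correlation_clusters(A, threshold=0.5)
        assert clustering.correlation.loc["a", "c"] == pytest.approx(1.0)

    def test_correlation_matrix_properties(self, null_activities):
        A, _ = null_activities
        clustering = activity_correlation_clusters(A.iloc[:20], threshold=0.5)
        corr = clustering.correlation.to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert (corr <= 1 + 1e-12).all() and (corr >= -1 - 1e-12).all()

    def test_constant_row_excluded_with_warning(self):
        A = pd.DataFrame(
            np.vstack([np.zeros(20), np.random.default_rng(0).normal(size=(2, 20))]),
            index=["flat", "a", "b"],
        )
        with pytest.warns(UserWarning, match="constant"):
            clustering = activity_correlation_clusters(A, threshold=0.5)
        assert "flat" not in clustering.assignments.index

    def test_project_programs_separate_sample_clusters(self):
        # two projects driven by different module programs
        spec = SyntheticSpec(
            n_genes=100, n_modules=4, module_size_min=8, module_size_max=8,
            n_projects=2, conditions_per_project=4, replicates_per_condition=2,
            activity_scale=0.1, replicate_noise_sd=0.05, seed=31,
        )
        A, meta = generate_activities(spec)
        # overwrite with strong project-specific programs
        p1 = meta.table.loc[meta.table["project"] == "P01", "sample_id"]
        p2 = meta.table.loc[meta.table["project"] == "P02", "sample_id"]
        A.loc[["mod01", "mod02"], p1] += 20.0
        A.loc[["mod03", "mod04"], p2] += 20.0
        clustering = sample_profile_clusters(A, meta, threshold=0.8)
        groups = meta.table.drop_duplicates("replicate_group").set_index("replicate_group")["project"]
        labels = clustering.assignments
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(groups.loc[labels.index], labels)
        assert ari >= 0.9

    def test_replicate_averaging_idempotent_for_singletons(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(6)]
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "project": ["P"] * 6,
                    "condition": samples,
                    "replicate_group": samples,  # singletons
                    "is_reference": [True] + [False] * 5,
                }
            )
        )
        A = pd.DataFrame(rng.normal(0, 1, size=(4, 6)), columns=samples)
        clustering = sample_profile_clusters(A, meta, threshold=0.5)
        assert set(clustering.correlation.index) == set(samples)
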