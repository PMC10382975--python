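import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diaspeclib import synth
from diaspeclib.cohort import (
    GridSpec,
    QuantMatrix,
    differential_expression,
    grid_search,
    missing_profile,
    rank_features,
)
from diaspeclib.errors import ValidationError


def toy_matrix(values, labels, proteins=None):
    proteins = proteins or [f"P{i}" for i in range(np.asarray(values).shape[1])]
    samples = [f"s{i}" for i in range(len(labels))]
    return QuantMatrix(
        data=pd.DataFrame(values, index=samples, columns=proteins),
        labels=pd.Series(labels, index=samples),
    )


class TestMissingProfile:
    def test_complete_matrix_has_no_missing(self):
        m = toy_matrix(np.ones((3, 4)), ["a", "a", "b"])
        prof = missing_profile(m)
        assert prof.n_missing == 0 and prof.fraction == 0.0

    def test_planted_holes_located(self):
        values = np.ones((3, 3))
        values[0, 1] = np.nan
        values[2, 2] = np.nan
        prof = missing_profile(toy_matrix(values, ["a", "a", "b"]))
        assert prof.n_missing == 2
        assert prof.per_sample.tolist() == [1, 0, 1]
        assert prof.per_protein.tolist() == [0, 1, 1]
        assert prof.per_sample.sum() == prof.per_protein.sum() == 2

    def test_mcar_rate_recovered_on_synthetic_cohort(self):
        spec = synth.SynthSpec(
            seed=13, cohort_n_per_class=(50, 50), cohort_n_proteins=200, mcar_rate=0.2
        )
        qm, _ = synth.generate_cohort(spec)
        prof = missing_profile(qm)
        assert prof.fraction == pytest.approx(0.2, abs=0.02)


class TestDifferentialExpression:
    def test_identical_groups_are_ns(self):
        block = np.tile([[8.0, 16.0]], (5, 1)) + np.outer(
            np.linspace(0, 1, 5), [1.0, 1.0]
        )
        values = np.vstack([block, block])  # class b repeats class a exactly
        m = toy_matrix(values, ["a"] * 5 + ["b"] * 5)
        table = differential_expression(m)
        assert table["log2_fold_change"].tolist() == [0.0, 0.0]
        assert set(table["status"]) == {"ns"}

    def test_exact_fourfold_change_gives_lfc_two(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(100, 200, size=5)
        values = np.vstack([np.tile(base, (5, 1)) * 4.0, np.tile(base, (5, 1))])
        m = toy_matrix(values, ["tumor"] * 5 + ["benign"] * 5)
        table = differential_expression(m)  # tumor over benign
        assert np.allclose(table["log2_fold_change"], 2.0)

    def test_swapping_class_roles_negates_every_lfc(self):
        spec = synth.SynthSpec(seed=19, cohort_n_proteins=50, de_fraction=0.2)
        qm, _ = synth.generate_cohort(spec)
        ab = differential_expression(qm, class1="tumor", class2="benign")
        ba = differential_expression(qm, class1="benign", class2="tumor")
        assert np.allclose(
            ab["log2_fold_change"], -ba["log2_fold_change"], equal_nan=True
        )

    def test_adjusted_p_monotone_in_raw_p(self):
        spec = synth.SynthSpec(seed=23, cohort_n_proteins=300, de_fraction=0.1)
        qm, _ = synth.generate_cohort(spec)
        table = differential_expression(qm).dropna(subset=["raw_p"])
        ordered = table.sort_values("raw_p")
        assert (table["adjusted_p"] >= table["raw_p"] - 1e-12).all()
        assert ordered["adjusted_p"].is_monotonic_increasing

    def test_welch_p_matches_direct_scipy_call(self):
        spec = synth.SynthSpec(seed=29, cohort_n_proteins=20, de_fraction=0.0)
        qm, _ = synth.generate_cohort(spec)
        table = differential_expression(qm)
        prot = qm.data.columns[3]
        log2 = np.log2(qm.data[prot])
        x1 = log2[qm.labels == "tumor"]
        x2 = log2[qm.labels == "benign"]
        expected = stats.ttest_ind(x1, x2, equal_var=False).pvalue
        assert table.loc[prot, "raw_p"] == pytest.approx(expected, rel=1e-12)

    def test_global_null_yields_no_calls(self):
        spec = synth.SynthSpec(
            seed=17, cohort_n_per_class=(20, 20), cohort_n_proteins=2000, de_fraction=0.0
        )
        qm, _ = synth.generate_cohort(spec)
        table = differential_expression(qm)
        assert ((table["status"] == "up") | (table["status"] == "down")).sum() == 0

    def test_proteins_with_too_few_observations_reported_untested(self):
        values = np.ones((6, 2)) * 100.0
        values[:5, 0] = np.nan  # only one observed value in class a
        m = toy_matrix(values, ["a"] * 3 + ["b"] * 3)
        table = differential_expression(m)
        assert table.iloc[0]["status"] == "untested"
        assert np.isnan(table.iloc[0]["adjusted_p"])

    def test_single_class_rejected(self):
        m = toy_matrix(np.ones((4, 2)), ["a"] * 4)
        with pytest.raises(ValidationError):
            differential_expression(m)

    def test_planted_effects_recovered_with_high_recall_low_fdp(self):
        recalls, fdps = [], []
        for seed in range(10):
            spec = synth.SynthSpec(
                seed=500 + seed,
                cohort_n_per_class=(20, 20),
                cohort_n_proteins=300,
                de_fraction=0.1,
                log2fc_effect=2.0,
                cohort_noise_sd=0.5,
            )
            qm, truth = synth.generate_cohort(spec)
            table = differential_expression(qm)
            called = set(table.index[(table["status"] == "up") | (table["status"] == "down")])
            planted = set(truth.index[truth["is_de"]])
            recalls.append(len(called & planted) / len(planted))
            fdps.append(len(called - planted) / max(len(called), 1))
        assert np.mean(recalls) > 0.9
        assert np.mean(fdps) < 0.05

    def test_estimated_lfc_close_to_planted_effect(self):
        spec = synth.SynthSpec(
            seed=31, cohort_n_per_class=(20, 20), cohort_n_proteins=200,
            de_fraction=0.1, log2fc_effect=2.0, cohort_noise_sd=0.5,
        )
        qm, truth = synth.generate_cohort(spec)
        table = differential_expression(qm)
        planted = truth[truth["is_de"]]
        est = table.loc[planted.index, "log2_fold_change"]
        err = np.abs(est - planted["true_log2fc"])
        # SE of a mean difference at n=20/20, sigma=0.5 is ~0.16
        assert err.mean() < 0.2
        assert (err < 0.5).all()


class TestRankFeatures:
    def test_perfect_separator_ranked_first(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(1000, 10, size=(20, 9))
        separator = np.concatenate([np.full(10, 100.0), np.full(10, 10000.0)])
        values = np.column_stack([noise[:, :4], separator, noise[:, 4:]])
        m = toy_matrix(values, ["a"] * 10 + ["b"] * 10)
        ranked = rank_features(m)
        assert ranked[0] == "P4"

    def test_ties_broken_lexicographically_and_stable(self):
        values = np.tile(np.linspace(100, 200, 8)[:, None], (1, 5))
        m = toy_matrix(values, ["a"] * 4 + ["b"] * 4)
        first = rank_features(m)
        assert first == sorted(first) and first == rank_features(m)

    def test_planted_effect_gradient_respected(self):
        rng = np.random.default_rng(19)
        n = 40
        effects = np.linspace(4.0, 0.4, 10)
        base = rng.normal(15, 0.5, size=(n, 10))
        base[n // 2 :, :] += effects
        values = np.power(2.0, base)
        m = toy_matrix(values, ["a"] * (n // 2) + ["b"] * (n // 2))
        ranked = rank_features(m)
        plant_order = [f"P{i}" for i in range(10)]
        rho = stats.spearmanr(
            [plant_order.index(p) for p in ranked], range(10)
        ).statistic
        assert rho > 0.8

    def test_model_importance_mode_runs_and_is_deterministic(self):
        spec = synth.SynthSpec(seed=37, cohort_n_proteins=30, de_fraction=0.2,
                               cohort_n_per_class=(15, 15))
        qm, _ = synth.generate_cohort(spec)
        a = rank_features(qm, method="model_importance", seed=7)
        b = rank_features(qm, method="model_importance", seed=7)
        assert a == b
        assert set(a) == set(qm.data.columns)


class TestGridSearch:
    def small_cohort(self, seed=23, separable=True):
        spec = synth.SynthSpec(
            seed=seed,
            cohort_n_per_class=(20, 20),
            cohort_n_proteins=12,
            de_fraction=0.5,
            log2fc_effect=6.0 if separable else 0.0,
            cohort_noise_sd=0.3,
        )
        qm, _ = synth.generate_cohort(spec)
        return qm

    SMALL = GridSpec(
        eta_values=(0.3,),
        subsample_values=(1.0,),
        gamma_values=(0.1,),
        n_features_values=(5,),
        n_validation_iterations=1,
        validation_size=8,
    )

    def test_singleton_grid_trains_exactly_one_model(self):
        result = grid_search(self.small_cohort(), self.SMALL, test_size=8, seed=1)
        assert result.n_models == 1
        assert len(result.results) == 1

    def test_model_count_is_grid_product_times_iterations(self):
        spec = GridSpec(
            eta_values=(0.2, 0.3),
            subsample_values=(0.9, 1.0),
            gamma_values=(0.05,),
            n_features_values=(5, 6, 7),
            n_validation_iterations=2,
            validation_size=8,
        )
        assert spec.n_models == 2 * 2 * 1 * 3 * 2
        result = grid_search(self.small_cohort(), spec, test_size=8, seed=2)
        assert result.n_models == 24

    def test_separable_cohort_selects_every_model(self):
        spec = GridSpec(
            eta_values=(0.25,),
            subsample_values=(1.0,),
            gamma_values=(0.05, 0.2),
            n_features_values=(5, 8),
            n_validation_iterations=2,
            validation_size=10,
        )
        result = grid_search(self.small_cohort(separable=True), spec, test_size=8, seed=3)
        assert result.results["selected"].all()
        assert (result.results["val_acc"] == 1.0).all()
        assert result.selected["test_acc"].notna().all()

    def test_fixed_seed_reproduces_everything(self):
        qm = self.small_cohort()
        a = grid_search(qm, self.SMALL, test_size=8, seed=11)
        b = grid_search(qm, self.SMALL, test_size=8, seed=11)
        pd.testing.assert_frame_equal(a.results, b.results)
        assert a.train_samples == b.train_samples
        assert a.test_samples == b.test_samples

    def test_train_test_partition_is_disjoint_and_complete(self):
        qm = self.small_cohort()
        result = grid_search(qm, self.SMALL, test_size=8, seed=5)
        train, test = set(result.train_samples), set(result.test_samples)
        assert not train & test
        assert train | test == set(qm.data.index)
        assert len(test) == 8

    def test_infeasible_splits_rejected_before_training(self):
        qm = self.small_cohort()
        with pytest.raises(ValidationError):
            grid_search(qm, self.SMALL, test_size=40, seed=1)
        with pytest.raises(ValidationError):
            grid_search(qm, GridSpec(validation_size=100), test_size=8, seed=1)
        wide = GridSpec(n_features_values=(500,), validation_size=8)
        with pytest.raises(ValidationError):
            grid_search(qm, wide, test_size=8, seed=1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            GridSpec(eta_values=())


class TestQuantMatrixIO:
    def test_tsv_round_trip_with_missing_cells(self, tmp_path):
        spec = synth.SynthSpec(seed=41, cohort_n_proteins=20, mcar_rate=0.1,
                               cohort_n_per_class=(5, 5))
        qm, _ = synth.generate_cohort(spec)
        path = tmp_path / "cohort.tsv"
        qm.to_tsv(path)
        back = QuantMatrix.from_tsv(path)
        assert back.labels.tolist() == qm.labels.tolist()
        assert np.allclose(back.data.fillna(-1), qm.data.fillna(-1), rtol=1e-6)

    def test_default_grid_spec_enumerates_9600_models(self):
        assert GridSpec().n_models == 9600
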