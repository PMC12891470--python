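"""Augmentation tests: SMOTE geometry, GAN quality gates, leakage guard."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from gaitstab.augment import (SYNTH_COL, augment_training_split,
                              fit_tabular_generator, smote)
from gaitstab.errors import ParameterError
from gaitstab.prep import TablePreprocessor
from gaitstab.synthetic import (STABILITY_FEATURES, CohortSpec,
                                simulate_classification_cohort)


@pytest.fixture(scope="module")
def standardized_cohort():
    feats, _, _ = simulate_classification_cohort(CohortSpec(seed=11))
    cols = list(STABILITY_FEATURES)
    prep = TablePreprocessor(columns=cols)
    z = prep.fit_transform(feats[cols])
    table = z.copy()
    table["group"] = feats["group"].to_numpy()
    return table, cols


class TestSmote:
    def test_rows_lie_on_minority_segments(self):
        """Brute-force convexity oracle: every synthetic row is a convex
        combination of two minority rows."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 5))
        S = smote(X, n_synth=20, seed=1)
        for srow in S:
            on_segment = False
            for i in range(len(X)):
                for j in range(len(X)):
                    if i == j:
                        continue
                    d = X[j] - X[i]
                    u = (srow - X[i]) @ d / (d @ d)
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                            X[i] + u * d, srow, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_zero_requested_rows(self):
        assert smote(np.random.default_rng(0).standard_normal((10, 3)),
                     n_synth=0).shape == (0, 3)

    def test_minority_39_balanced_to_100(self):
        """39 minority rows balanced to 100 require exactly 61 synthetics."""
        X = np.random.default_rng(0).standard_normal((39, 4))
        assert smote(X, n_synth=100 - 39, seed=0).shape[0] == 61

    def test_seeded_determinism(self):
        X = np.random.default_rng(0).standard_normal((20, 4))
        np.testing.assert_array_equal(smote(X, 10, seed=5), smote(X, 10, seed=5))

    def test_small_minority_reduces_k(self):
        X = np.random.default_rng(0).standard_normal((4, 3))
        with pytest.warns(UserWarning, match="reducing k"):
            out = smote(X, 5, k=5, seed=0)
        assert out.shape == (5, 3)


class TestTabularGan:
    def test_sample_count_and_finiteness(self, standardized_cohort):
        table, cols = standardized_cohort
        gen = fit_tabular_generator(table[cols], table["group"], kind="gan", seed=0)
        S = gen.sample(1000, "HC")
        assert S.shape == (1000, len(cols))
        assert np.isfinite(S).all()

    def test_marginal_ks_quality(self, standardized_cohort):
        """Per-feature KS distance between synthetic and training marginals
        stays below 0.3 on the default cohort."""
        table, cols = standardized_cohort
        gen = fit_tabular_generator(table[cols], table["group"], kind="gan", seed=0)
        Xc = table.loc[table.group == "PwS", cols].to_numpy()
        S = gen.sample(500, "PwS", seed=1)
        ks = [ks_2samp(S[:, j], Xc[:, j]).statistic for j in range(len(cols))]
        assert max(ks) <= 0.3

    def test_conditional_generator_separates_classes(self, standardized_cohort):
        table, cols = standardized_cohort
        gen = fit_tabular_generator(table[cols], table["group"], kind="ctgan", seed=0)
        hc = gen.sample(300, "HC", seed=2).mean(axis=0)
        pws = gen.sample(300, "PwS", seed=3).mean(axis=0)
        j = cols.index("RMS_VT")
        assert pws[j] > hc[j]  # injected group shift survives generation

    def test_single_row_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 3)))
        labels = np.array(["A", "A", "A", "A", "B"])
        with pytest.raises(ParameterError):
            fit_tabular_generator(X, labels, kind="gan")

    def test_unknown_kind_rejected(self, standardized_cohort):
        table, cols = standardized_cohort
        with pytest.raises(ParameterError):
            fit_tabular_generator(table[cols], table["group"], kind="vae")


class TestAugmentSplit:
    def test_balance100_class_counts(self, standardized_cohort):
        table, cols = standardized_cohort
        out = augment_training_split(table, "smote", "balance100", seed=0,
                                     feature_cols=cols)
        counts = out["group"].value_counts().to_dict()
        assert counts == {"HC": 100, "PwS": 71}

    def test_real_rows_pass_through_unchanged(self, standardized_cohort):
        table, cols = standardized_cohort
        out = augment_training_split(table, "smote", "balance100", seed=0,
                                     feature_cols=cols)
        real = out[~out[SYNTH_COL]].drop(columns=SYNTH_COL).reset_index(drop=True)
        pd.testing.assert_frame_equal(real, table.reset_index(drop=True))

    def test_provenance_flags_on_all_synthetics(self, standardized_cohort):
        table, cols = standardized_cohort
        out = augment_training_split(table, "smote", "N200", seed=0,
                                     feature_cols=cols)
        assert out[SYNTH_COL].sum() == 200
        n_real = (~out[SYNTH_COL]).sum()
        assert n_real == len(table)

    def test_total_budget_equalizes_classes_first(self, standardized_cohort):
        table, cols = standardized_cohort
        out = augment_training_split(table, "smote", "N1000", seed=0,
                                     feature_cols=cols)
        counts = out["group"].value_counts()
        assert counts.sum() == len(table) + 1000
        assert abs(counts["HC"] - counts["PwS"]) <= 1

    def test_leakage_guard_differential(self, standardized_cohort):
        """Fitting the augmenter with extra (test) rows present changes the
        synthetic stream: withholding them is an active guard, not a no-op."""
        table, cols = standardized_cohort
        train, test = table.iloc[:80], table.iloc[80:]
        with_train = augment_training_split(train, "smote", "N100", seed=0,
                                            feature_cols=cols)
        contaminated = augment_training_split(pd.concat([train, test]),
                                              "smote", "N100", seed=0,
                                              feature_cols=cols)
        synth_a = with_train.loc[with_train[SYNTH_COL], cols].to_numpy()
        synth_b = contaminated.loc[contaminated[SYNTH_COL], cols].to_numpy()
        assert synth_a.shape != synth_b.shape or not np.allclose(synth_a, synth_b)
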