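"""CPM normalization, DE filter, Spearman signature, clustering, classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.svm import LinearSVC

from pdopharm import (
    Direction,
    HingeLinearClassifier,
    MICROTUBULE_DRUGS,
    SignatureSelector,
    apply_classifier,
    cluster_pdos,
    differential_expression,
    normalize_counts,
    spearman_filter,
    train_classifier,
)
from pdopharm.io import ValidationError
from pdopharm.signature import SignatureGene
from pdopharm.simulate import simulate_expression


class TestNormalizeCounts:
    def test_identical_samples_identical_columns(self):
        counts = pd.DataFrame({"s1": [10, 20, 70], "s2": [10, 20, 70]},
                              index=["g1", "g2", "g3"])
        expr = normalize_counts(counts)
        np.testing.assert_allclose(expr["s1"], expr["s2"])

    def test_library_doubling_invariance(self):
        counts = pd.DataFrame({"s1": [10, 20, 70], "s2": [20, 40, 140]},
                              index=["g1", "g2", "g3"])
        expr = normalize_counts(counts)
        np.testing.assert_allclose(expr["s1"], expr["s2"], rtol=1e-12)

    def test_hand_computed_cpm(self):
        # library 100 -> CPM = (10, 20, 70) * 1e4; log2(CPM + 1)
        counts = pd.DataFrame({"s1": [10, 20, 70], "s2": [1, 1, 98]},
                              index=["g1", "g2", "g3"])
        expr = normalize_counts(counts)
        np.testing.assert_allclose(
            expr["s1"], np.log2(np.array([1e5, 2e5, 7e5]) + 1), rtol=1e-12)

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValidationError, match="empty"):
            normalize_counts(counts)


class TestDifferentialExpression:
    @staticmethod
    def _groups(n_sens, n_res):
        cols = [f"s{i}" for i in range(n_sens + n_res)]
        return cols, pd.Series(["pan_sensitive"] * n_sens +
                               ["pan_resistant"] * n_res, index=cols)

    def test_null_genes_have_flat_fold_change_and_high_q(self):
        rng = np.random.default_rng(0)
        cols, groups = self._groups(10, 10)
        expr = pd.DataFrame(rng.normal(8, 1, size=(200, 20)),
                            index=[f"g{i}" for i in range(200)], columns=cols)
        de = differential_expression(expr, groups)
        assert abs(de["log2fc"].mean()) < 0.1
        assert (de["q"] <= 0.01).sum() == 0

    def test_planted_fourfold_gene_passes_thresholds(self):
        rng = np.random.default_rng(1)
        cols, groups = self._groups(10, 10)
        X = rng.normal(8, 0.3, size=(50, 20))
        X[0, :10] += 2.0  # 4-fold in the sensitive lines
        de = differential_expression(pd.DataFrame(X, columns=cols), groups)
        assert de.iloc[0]["q"] <= 0.01 and abs(de.iloc[0]["log2fc"]) >= 1.0

    def test_small_fold_change_fails_fc_filter_regardless_of_q(self):
        rng = np.random.default_rng(2)
        cols, groups = self._groups(20, 20)
        X = rng.normal(8, 0.05, size=(10, 40))
        X[0, :20] += np.log2(1.5)
        de = differential_expression(pd.DataFrame(X, columns=cols), groups)
        assert de.iloc[0]["q"] <= 0.01           # highly significant
        assert abs(de.iloc[0]["log2fc"]) < 1.0   # but fails FC >= 2

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(3)
        cols, groups = self._groups(5, 5)
        expr = pd.DataFrame(rng.normal(8, 1, size=(100, 10)), columns=cols)
        de = differential_expression(expr, groups).sort_values("p")
        assert (np.diff(de["q"].values) >= -1e-12).all()

    def test_small_group_raises(self):
        cols, groups = self._groups(2, 5)
        expr = pd.DataFrame(np.ones((5, 7)), columns=cols)
        with pytest.raises(ValidationError, match=">= 3"):
            differential_expression(expr, groups)


def _de_frame(genes, log2fc, q):
    return pd.DataFrame({"log2fc": log2fc, "p": q, "q": q}, index=genes)


def _mt_table(log10_summary, pdos):
    rng = np.random.default_rng(9)
    return pd.DataFrame(
        {d: 10.0 ** (np.asarray(log10_summary)) for d in MICROTUBULE_DRUGS},
        index=pdos)


class TestSpearmanFilter:
    def test_perfect_anticorrelation_kept_as_up_in_sensitive(self):
        pdos = [f"P{i}" for i in range(8)]
        ic50 = np.linspace(-7, -5, 8)
        expr = pd.DataFrame({p: [8.0 - i] for i, p in enumerate(pdos)},
                            index=["g1"])
        sig = spearman_filter(_de_frame(["g1"], [2.0], [0.001]), expr,
                              _mt_table(ic50, pdos))
        assert len(sig) == 1
        assert sig[0].rho == pytest.approx(-1.0)
        assert sig[0].direction is Direction.UP_IN_SENSITIVE

    def test_weak_correlation_excluded(self):
        rng = np.random.default_rng(4)
        pdos = [f"P{i}" for i in range(30)]
        ic50 = np.linspace(-7, -5, 30)
        # shuffle expression so |rho| is small
        x = rng.permutation(np.arange(30.0))
        rho = stats.spearmanr(x, ic50).statistic
        assert abs(rho) <= 0.3
        expr = pd.DataFrame([x], index=["g1"], columns=pdos)
        sig = spearman_filter(_de_frame(["g1"], [-2.0], [0.001]), expr,
                              _mt_table(ic50, pdos))
        assert sig == []

    def test_sign_inconsistent_gene_excluded(self):
        # up-in-sensitive gene that *positively* tracks IC50 is dropped
        pdos = [f"P{i}" for i in range(8)]
        ic50 = np.linspace(-7, -5, 8)
        expr = pd.DataFrame({p: [float(i)] for i, p in enumerate(pdos)},
                            index=["g1"])
        sig = spearman_filter(_de_frame(["g1"], [2.0], [0.001]), expr,
                              _mt_table(ic50, pdos))
        assert sig == []

    def test_tied_values_match_average_rank_oracle(self):
        def rank_avg(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2.0
                i = j
            return ranks

        def spearman_oracle(x, y):
            rx, ry = rank_avg(x), rank_avg(y)
            return np.corrcoef(rx, ry)[0, 1]

        rng = np.random.default_rng(5)
        pdos = [f"P{i}" for i in range(12)]
        ic50 = rng.choice([-7.0, -6.0, -5.0], size=12)  # heavy ties
        x = rng.choice([1.0, 2.0, 3.0, 4.0], size=12)   # tied expression
        expr = pd.DataFrame([x], index=["g1"], columns=pdos)
        expected = spearman_oracle(x, _mt_table(ic50, pdos).median(axis=1)
                                   .pipe(np.log10).values)
        sig = spearman_filter(_de_frame(["g1"], [-2.0], [1e-4]), expr,
                              _mt_table(ic50, pdos), rho_min=0.0)
        if sig:
            assert sig[0].rho == pytest.approx(expected, abs=1e-12)
        else:  # excluded only for sign/threshold reasons, not rho mismatch
            scipy_rho = stats.spearmanr(
                x, np.log10(_mt_table(ic50, pdos).median(axis=1))).statistic
            assert scipy_rho == pytest.approx(expected, abs=1e-12)

    def test_too_few_paired_samples(self):
        pdos = [f"P{i}" for i in range(4)]
        expr = pd.DataFrame([[1, 2, 3, 4.0]], index=["g1"], columns=pdos)
        with pytest.raises(ValidationError, match=">= 5"):
            spearman_filter(_de_frame(["g1"], [2.0], [0.001]), expr,
                            _mt_table(np.linspace(-7, -5, 4), pdos))


class TestClusterPDOs:
    @staticmethod
    def _signature(genes_up, genes_down):
        return [SignatureGene(g, Direction.UP_IN_SENSITIVE, 2.0, 1e-3, -0.8)
                for g in genes_up] + \
               [SignatureGene(g, Direction.DOWN_IN_SENSITIVE, -2.0, 1e-3, 0.8)
                for g in genes_down]

    def test_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(6)
        up = [f"u{i}" for i in range(5)]
        down = [f"d{i}" for i in range(5)]
        n = 12
        sensitive = np.arange(n) < 6
        X = rng.normal(0, 0.3, size=(n, 10))
        X[:, :5] += np.where(sensitive, 3.0, 0.0)[:, None]
        X[:, 5:] += np.where(sensitive, 0.0, 3.0)[:, None]
        expr = pd.DataFrame(X, index=[f"P{i}" for i in range(n)],
                            columns=up + down)
        groups = cluster_pdos(expr, self._signature(up, down))
        assert (groups[sensitive] == "sensitive_class").all()
        assert (groups[~sensitive] == "non_sensitive").all()

    def test_duplicated_profiles_share_cluster(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, size=(3, 4))
        X = np.vstack([base, base[0]])  # P3 duplicates P0
        expr = pd.DataFrame(X, index=["P0", "P1", "P2", "P3"],
                            columns=["u0", "u1", "d0", "d1"])
        groups = cluster_pdos(expr, self._signature(["u0", "u1"],
                                                    ["d0", "d1"]))
        assert groups["P0"] == groups["P3"]

    def test_two_pdos_one_per_cluster(self):
        expr = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["P0", "P1"],
                            columns=["u0", "d0"])
        groups = cluster_pdos(expr, self._signature(["u0"], ["d0"]))
        assert set(groups) == {"sensitive_class", "non_sensitive"}
        assert groups["P0"] == "sensitive_class"

    def test_constant_profile_raises(self):
        expr = pd.DataFrame([[1.0, 1.0], [0.0, 1.0]], index=["P0", "P1"],
                            columns=["u0", "d0"])
        with pytest.raises(ValidationError, match="constant"):
            cluster_pdos(expr, self._signature(["u0"], ["d0"]))


class TestHingeClassifier:
    def test_separable_data_trains_to_perfect_accuracy(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(-2, 0.3, size=(20, 5)),
                       rng.normal(2, 0.3, size=(20, 5))])
        y = np.array(["neg"] * 20 + ["pos"] * 20)
        clf = HingeLinearClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_symmetric_two_point_boundary_at_midpoint(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([0, 1])
        clf = HingeLinearClassifier(n_epochs=2000).fit(X, y)
        assert clf.decision_function([[1.0]])[0] == pytest.approx(0.0, abs=1e-6)
        assert clf.predict([[0.4]])[0] == 0 and clf.predict([[1.6]])[0] == 1

    def test_agrees_with_reference_svm_on_separated_classes(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(-1.5, 0.5, size=(40, 8)),
                       rng.normal(1.5, 0.5, size=(40, 8))])
        y = np.array([0] * 40 + [1] * 40)
        ours = HingeLinearClassifier().fit(X, y).predict(X)
        ref = LinearSVC().fit(X, y).predict(X)
        assert (ours == ref).mean() == 1.0

    def test_heldout_accuracy_on_planted_classes(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(-1, 0.7, size=(60, 10)),
                       rng.normal(1, 0.7, size=(60, 10))])
        y = np.array([0] * 60 + [1] * 60)
        idx = rng.permutation(120)
        train, test = idx[:80], idx[80:]
        clf = HingeLinearClassifier().fit(X[train], y[train])
        assert (clf.predict(X[test]) == y[test]).mean() >= 0.9

    def test_one_class_raises(self):
        with pytest.raises(ValidationError):
            HingeLinearClassifier().fit(np.ones((4, 2)), np.zeros(4))

    def test_determinism(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        a = HingeLinearClassifier().fit(X, y)
        b = HingeLinearClassifier().fit(X, y)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_

    def test_apply_classifier_imputes_missing_genes(self):
        expr = pd.DataFrame(np.random.default_rng(12).normal(size=(10, 3)),
                            columns=["g1", "g2", "g3"])
        labels = pd.Series((expr["g1"] > 0).map({True: "a", False: "b"}).values,
                           index=expr.index)
        model = train_classifier(expr, labels)
        new = expr.drop(columns=["g3"]).iloc[:4]
        preds = apply_classifier(model, new)
        assert set(preds) <= {"a", "b"} and len(preds) == 4


class TestSelectorEndToEnd:
    def test_planted_signature_recovered_from_counts(self):
        counts, truth = simulate_expression(
            n_genes=600, n_pdos=20, n_signature=40, effect_log2fc=2.0,
            seed=21, dispersion=0.05)
        expr = normalize_counts(counts)
        groups = pd.Series(truth.pdo_latent.set_index("pdo_id")["group"]
                           .values, index=truth.pdo_latent["pdo_id"])
        sel = SignatureSelector().fit(expr.T, groups, truth.mt_ic50)
        planted = set(truth.genes.loc[truth.genes["is_signature"], "gene_id"])
        found = set(sel.gene_ids_)
        assert len(found & planted) / len(planted) >= 0.9
        # every emitted gene satisfies all three thresholds
        for g in sel.signature_:
            assert g.fdr_q <= 0.01
            assert abs(g.log2fc) >= 1.0
            assert abs(g.rho) > 0.3

    def test_selector_determinism(self):
        counts, truth = simulate_expression(n_genes=300, n_pdos=16,
                                            n_signature=20, seed=22)
        expr = normalize_counts(counts)
        groups = pd.Series(truth.pdo_latent.set_index("pdo_id")["group"]
                           .values, index=truth.pdo_latent["pdo_id"])
        a = SignatureSelector().fit(expr.T, groups, truth.mt_ic50)
        b = SignatureSelector().fit(expr.T, groups, truth.mt_ic50)
        assert a.gene_ids_ == b.gene_ids_
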