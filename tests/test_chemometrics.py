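import numpy as np
import pandas as pd
import pytest

from progmet import (
    SynthConfig,
    simulate_cohort,
    average_replicates,
    autoscale,
    pca,
    group_dummy,
    osc_filter,
    plsda,
    oplsda,
    OplsDa,
    pcls_select,
    intersect_selections,
)
from progmet.chemometrics import OplsResults


class TestAutoscale:
    def test_hand_scaling(self):
        z = autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z1 = autoscale(rng.normal(size=(10, 4)))
        z2 = autoscale(z1.values)
        np.testing.assert_allclose(z2.values, z1.values, atol=1e-12)

    def test_constant_column_centred_and_flagged(self):
        z = autoscale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        np.testing.assert_allclose(z.values[:, 1], 0.0)
        assert z.constant.tolist() == [False, True]

    def test_column_moments(self):
        rng = np.random.default_rng(1)
        z = autoscale(rng.normal(3, 2, size=(30, 8)))
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0,
                                   atol=1e-10)


class TestPca:
    def test_rank_one_matrix(self):
        u = np.arange(1.0, 6.0)[:, None]
        v = np.array([[1.0, 2.0, 3.0]])
        scores, loadings, varfrac = pca(u @ v, k=1)
        assert varfrac[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        _, loadings, _ = pca(autoscale(rng.normal(size=(12, 6))), k=4)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(4),
                                   atol=1e-10)

    def test_matches_covariance_eigendecomposition(self):
        """Oracle: eigendecomposition of the covariance matrix (up to sign)."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))
        Xc = X - X.mean(axis=0)
        scores, loadings, varfrac = pca(Xc, k=3)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(3):
            dot = abs(loadings[:, j] @ evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(varfrac, evals[:3] / evals.sum(), atol=1e-8)

    def test_excessive_k_rejected(self):
        with pytest.raises(ValueError):
            pca(np.ones((3, 5)), k=4)


class TestOsc:
    def _data(self, seed=0, n=40, p=60):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        labels = np.array(["slow"] * (n // 2) + ["rapid"] * (n // 2),
                          dtype=object)
        Y, _ = group_dummy(labels)
        return X, Y, labels

    def test_removed_scores_orthogonal_to_dummies(self):
        X, Y, _ = self._data()
        _, comps = osc_filter(autoscale(X), Y, n_osc=3)
        for t, _, _ in comps:
            for j in range(Y.shape[1]):
                denom = np.linalg.norm(t) * np.linalg.norm(Y[:, j])
                assert abs(t @ Y[:, j]) / denom <= 1e-8

    def test_orthogonal_case_preserves_zero_class_correlation(self):
        """Data uncorrelated with class: OSC removes dominant variance but
        the class correlation of the corrected matrix stays ~0."""
        rng = np.random.default_rng(5)
        n = 60
        nuisance = rng.normal(size=n)
        nuisance -= nuisance.mean()
        labels = np.array(["slow", "rapid"] * (n // 2), dtype=object)
        Y, _ = group_dummy(labels)
        # project nuisance orthogonal to class so the construction is exact
        nuisance -= Y @ np.linalg.lstsq(Y, nuisance, rcond=None)[0]
        X = np.outer(nuisance, rng.normal(size=30)) + 0.1 * rng.normal(
            size=(n, 30))
        Z = autoscale(X)
        Xc, comps = osc_filter(Z, Y, n_osc=1)
        t = comps[0][0]
        # the removed component captures the dominant nuisance direction
        r_t = abs(np.corrcoef(t, nuisance)[0, 1])
        assert r_t > 0.95
        before = np.abs(Y[:, 0] @ Z.values) / (
            np.linalg.norm(Y[:, 0]) * np.linalg.norm(Z.values, axis=0))
        after_norm = np.linalg.norm(Xc, axis=0)
        after = np.abs(Y[:, 0] @ Xc) / (np.linalg.norm(Y[:, 0]) * after_norm)
        assert after.max() < 0.5  # still essentially uncorrelated with class

    def test_osc_improves_separation_under_nuisance(self):
        """A strong class-orthogonal nuisance factor: PLS t1 separation with
        OSC >= without, paired over seeds."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 40, 100
            labels = np.array(["slow"] * 20 + ["rapid"] * 20, dtype=object)
            Y, _ = group_dummy(labels)
            y = (labels == "rapid").astype(float) - 0.5
            nuisance = rng.normal(size=n)
            nuisance -= nuisance.mean()
            nuisance -= y * (nuisance @ y) / (y @ y)
            X = (0.3 * np.outer(y, rng.normal(size=p) > 0)
                 + 2.0 * np.outer(nuisance, rng.normal(size=p))
                 + rng.normal(size=(n, p)))
            Z = autoscale(X)

            def smd(model):
                t1 = model.T[:, 0]
                a, b = t1[labels == "slow"], t1[labels == "rapid"]
                pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
                return abs(a.mean() - b.mean()) / pooled

            plain = smd(plsda(Z, Y, n_comp=1))
            Xc, _ = osc_filter(Z, Y, n_osc=1)
            corrected = smd(plsda(Xc, Y, n_comp=1))
            diffs.append(corrected - plain)
        assert np.mean(diffs) > 0
        assert np.sum(np.array(diffs) >= 0) >= 15


class TestPlsda:
    def test_one_component_weight_is_normalised_zty(self):
        """NIPALS closed form for a single binary response."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 50))
        y = np.array([1.0] * 15 + [0.0] * 15)
        y = y - y.mean()
        model = plsda(autoscale(X), y[:, None], n_comp=1)
        Z = autoscale(X).values
        w_oracle = Z.T @ y
        w_oracle /= np.linalg.norm(w_oracle)
        dot = abs(model.W[:, 0] @ w_oracle)
        assert dot == pytest.approx(1.0, abs=1e-8)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 40))
        labels = np.array(["slow"] * 12 + ["rapid"] * 13, dtype=object)
        Y, _ = group_dummy(labels)
        model = plsda(autoscale(X), Y, n_comp=4)
        T = model.T
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() / np.diag(G).max() <= 1e-8

    def test_r2_fractions_bounded(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 30))
        labels = np.array(["slow"] * 10 + ["rapid"] * 10, dtype=object)
        Y, _ = group_dummy(labels)
        model = plsda(autoscale(X), Y, n_comp=5)
        assert (model.r2x >= 0).all() and model.r2x.sum() <= 1 + 1e-9
        assert (model.r2y >= 0).all() and model.r2y.sum() <= 1 + 1e-9

    def test_planted_difference_separates_scores(self, small_cohort):
        table, meta, _ = small_cohort
        res = oplsda(average_replicates(table), meta, ["slow", "rapid"],
                     n_osc=0)
        assert res.t1_separation() >= 2.0


class TestOplsda:
    def test_zero_osc_equals_plain_plsda(self, small_cohort):
        table, meta, _ = small_cohort
        avg = average_replicates(table)
        res0 = oplsda(avg, meta, ["slow", "rapid"], n_osc=0)
        model = OplsDa(avg, meta, ["slow", "rapid"], n_osc=0)
        Z = autoscale(model.X)
        Y, _ = group_dummy(model.labels, ["slow", "rapid"])
        direct = plsda(Z, Y, n_comp=2)
        np.testing.assert_allclose(res0.fit_.T, direct.T, atol=1e-10)

    def test_relabelled_identical_groups_show_no_real_separation(self):
        """Null case: random labels on one homogeneous group; the t1
        separation must fall within the permutation-null range."""
        cfg = SynthConfig(n_features=150,
                          n_per_group={"control": 0, "slow": 40, "rapid": 40},
                          n_effect_features=0, n_modules=0, module_size=0,
                          seed=11)
        table, meta, _ = simulate_cohort(cfg)
        avg = average_replicates(table)
        res = oplsda(avg, meta, ["slow", "rapid"], n_osc=0)
        # resubstitution SMD of PLS t1 is optimistically biased; compare to
        # the permutation-null distribution of the same statistic
        rng = np.random.default_rng(0)
        null = []
        for _ in range(20):
            meta_perm = meta.copy()
            meta_perm["group"] = rng.permutation(meta["group"].to_numpy())
            null.append(oplsda(avg, meta_perm, ["slow", "rapid"],
                               n_osc=0).t1_separation())
        assert res.t1_separation() <= max(null) * 1.5

    def test_score_plot_separates_planted_cohort(self, small_cohort):
        """Midpoint threshold on t1 misclassifies <= 10% at resubstitution."""
        table, meta, _ = small_cohort
        res = oplsda(average_replicates(table), meta, ["slow", "rapid"])
        frame = res.scores_frame()
        t1 = frame["t1"].to_numpy()
        g = frame["group"].to_numpy()
        mid = (t1[g == "slow"].mean() + t1[g == "rapid"].mean()) / 2
        sign = 1.0 if t1[g == "rapid"].mean() > mid else -1.0
        pred = np.where(sign * (t1 - mid) > 0, "rapid", "slow")
        assert (pred != g).mean() <= 0.10


class TestPcls:
    def _stub_results(self, Z, T, P, feature_ids):
        """Assemble a minimal fitted-results object for selector tests."""
        from types import SimpleNamespace
        scaled = SimpleNamespace(values=Z)
        fit = SimpleNamespace(T=T, P=P)
        model = SimpleNamespace(feature_id=np.array(feature_ids, dtype=object))
        res = OplsResults.__new__(OplsResults)
        res.model, res.fit_, res.scaled, res.X_corrected = model, fit, scaled, Z
        return res

    def test_feature_equal_to_score_has_unit_correlation(self):
        rng = np.random.default_rng(12)
        n = 50
        t1 = rng.normal(size=n)
        t2 = rng.normal(size=n)
        t2 -= t1 * (t2 @ t1) / (t1 @ t1)
        Z = np.column_stack([t1, rng.normal(size=(n, 4))])
        T = np.column_stack([t1, t2])
        P = rng.normal(size=(5, 2))
        res = self._stub_results(Z, T, P, [f"f{i}" for i in range(5)])
        sel = pcls_select(res, corr_threshold=0.95, top_fraction=0.2)
        row = sel.table.set_index("feature_id").loc["f0"]
        assert row["combined_R"] == pytest.approx(1.0, abs=1e-10)
        assert row["candidate"] and row["selected"]

    def test_pure_noise_stays_below_absolute_gate(self):
        """At n = 100 the null multiple correlation on two scores is far
        below 0.95."""
        rng = np.random.default_rng(13)
        n = 100
        T = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        Z = rng.normal(size=(n, 200))
        res = self._stub_results(Z, T, rng.normal(size=(200, 2)),
                                 [f"f{i}" for i in range(200)])
        sel = pcls_select(res)
        assert sel.table["combined_R"].max() < 0.95
        assert not sel.table["candidate"].any()

    def test_selection_count_and_modes(self):
        rng = np.random.default_rng(14)
        n = 60
        T = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        Z = np.column_stack([T @ rng.normal(size=(2, 10)),
                             rng.normal(size=(n, 90))])
        res = self._stub_results(Z, T, rng.normal(size=(100, 2)),
                                 [f"f{i}" for i in range(100)])
        sel_all = pcls_select(res, top_fraction=0.05, selection_within="all")
        assert sel_all.table["selected"].sum() == 5
        sel_cand = pcls_select(res, corr_threshold=0.9, top_fraction=0.5,
                               selection_within="candidates")
        assert sel_cand.selected_ids <= sel_cand.candidate_ids

    def test_selected_features_are_planted(self, small_cohort):
        table, meta, truth = small_cohort
        res = oplsda(average_replicates(table), meta, ["slow", "rapid"])
        sel = pcls_select(res)
        selected = sel.selected_ids
        assert len(selected) == round(0.05 * table.n_features)
        precision = len(selected & truth.effect_feature_ids) / len(selected)
        assert precision >= 0.8


class TestIntersect:
    @pytest.mark.parametrize(
        "a, b, expected, venn",
        [
            ({1, 2}, {3, 4}, set(), {"a_only": 2, "b_only": 2, "both": 0}),
            ({1, 2, 3}, {1, 2, 3}, {1, 2, 3},
             {"a_only": 0, "b_only": 0, "both": 3}),
            ({1, 2, 3}, {2, 3, 4}, {2, 3},
             {"a_only": 1, "b_only": 1, "both": 2}),
        ],
    )
    def test_intersections_and_venn_counts(self, a, b, expected, venn):
        both, counts = intersect_selections(a, b)
        assert both == expected and counts == venn
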