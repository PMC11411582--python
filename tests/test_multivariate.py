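"""PCA selection, penalized decoding, activation-pattern importance,
and cross-community predictive decoding."""

import numpy as np
import pandas as pd
import pytest

from eventseg import graph_sequences as gs
from eventseg import multivariate as mv
from eventseg import preprocessing as pp


class TestPCASelect:
    def test_rank_one_signal_dominant_component(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(200)
        v = rng.standard_normal(20)
        X = np.outer(u, v) * 5 + 0.01 * rng.standard_normal((200, 20))
        space, scores = mv.pca_select(X, seed=1)
        assert space.n_components == 1
        # scores align with the generating factor
        assert abs(np.corrcoef(scores[:, 0], u)[0, 1]) > 0.999

    def test_null_features_marchenko_pastur_share(self):
        """For standardized noise with p << n, about half the eigenvalues
        exceed 1 (the bulk is symmetric around 1 on this scale)."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((2000, 40))
        space, _ = mv.pca_select(X, seed=2)
        share = space.n_components / 40
        assert 0.35 < share < 0.65

    def test_imputation_distribution_matches_feature(self):
        rng = np.random.default_rng(3)
        X = np.tile(rng.normal(5.0, 2.0, size=300)[:, None], (1, 2))
        X[:, 1] = rng.normal(5.0, 2.0, size=300)
        draws = []
        for seed in range(200):
            Xm = X.copy()
            Xm[7, 0] = np.nan
            filled = mv.impute_gaussian(Xm, rng=np.random.default_rng(seed))
            draws.append(filled[7, 0])
        draws = np.asarray(draws)
        assert abs(draws.mean() - X[:, 0].mean()) < 0.5
        assert abs(draws.std() - np.nanstd(X[:, 0])) < 0.5
        assert np.all(np.abs(draws - X[:, 0].mean()) < 6 * X[:, 0].std())

    def test_all_missing_feature_raises(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        X[:, 2] = np.nan
        with pytest.raises(ValueError, match="feature 2"):
            mv.impute_gaussian(X)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            mv.pca_select(np.ones((1, 5)))


class TestLoadingTopography:
    def _spaces(self, pattern, n_participants=6, n_ch=8, n_f=6, seed=0, noise=0.1):
        rng = np.random.default_rng(seed)
        spaces = []
        for _ in range(n_participants):
            L = pattern[:, :, None] + noise * rng.standard_normal((n_ch, n_f, 3))
            spaces.append(
                mv.PCSpace(
                    loadings=L.reshape(n_ch * n_f, 3),
                    explained_variance=np.array([3.0, 2.0, 1.5]),
                    all_eigenvalues=np.ones(5),
                    mean=np.zeros(n_ch * n_f),
                    impute_mu=np.zeros(n_ch * n_f),
                    impute_sd=np.ones(n_ch * n_f),
                )
            )
        return spaces

    def test_zero_loadings_nothing_significant(self):
        ch = ["F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]
        freqs = np.array([4.0, 6.0, 10.0, 20.0, 40.0, 80.0])
        spaces = self._spaces(np.zeros((8, 6)), noise=0.0)
        out = mv.loading_topography(spaces, ch, freqs)
        assert not out["per_electrode"]["significant"].any()
        assert not out["per_frequency"]["significant"].any()

    def test_planted_structure_flagged(self):
        ch = ["F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]
        freqs = np.array([4.0, 6.0, 10.0, 20.0, 40.0, 80.0])
        pattern = np.zeros((8, 6))
        pattern[4:, 1] = 2.0  # posterior electrodes, 6 Hz
        out = mv.loading_topography(self._spaces(pattern), ch, freqs)
        per_f = out["per_frequency"]
        assert per_f.loc[per_f["freq_hz"] == 6.0, "significant"].all()
        per_e = out["per_electrode"].set_index("channel")
        assert per_e.loc[["P3", "P4", "O1", "O2"], "significant"].all()

    def test_fdr_calibration_on_uniform_p(self):
        """BH at q=.05 yields false discoveries in only a small share of
        null simulations (FWER-like bound holds under independence)."""
        rng = np.random.default_rng(4)
        any_disc = 0
        n_sim = 1000
        from statsmodels.stats.multitest import multipletests

        for _ in range(n_sim):
            p = rng.random(30)
            rej, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            any_disc += rej.any()
        assert any_disc / n_sim < 0.08


class TestClassification:
    def test_separable_contrast_high_auc(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat(["a", "b"], n // 2)
        X = rng.standard_normal((n, 10))
        X[y == "b", 0] += 4.0
        res = mv.classify_conditions(X, y, reduce=False, seed=1)
        assert res.auc > 0.9
        assert res.scheme == "leave-one-trial-out"
        assert set(res.per_penalty) == set(map(float, mv.DEFAULT_PENALTIES))

    def test_penalty_sweep_shrinks_weights_monotonically(self):
        """Larger ridge penalties shrink the coefficient norm monotonically
        (AUC itself is rank-based and need not move monotonically)."""
        rng = np.random.default_rng(1)
        n = 80
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 30))
        X[y == 1] += 0.15
        norms = [
            np.linalg.norm(mv._fit_logistic(X, y, lam).coef_)
            for lam in mv.DEFAULT_PENALTIES
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            mv.classify_conditions(X, np.repeat("a", 10))

    def test_min_trials_per_class(self):
        X = np.zeros((8, 2))
        y = np.array(["a"] * 6 + ["b"] * 2)
        with pytest.raises(ValueError, match=">= 5"):
            mv.classify_conditions(X, y)

    def test_univariate_perfect_threshold(self):
        vals = np.concatenate([np.zeros(10), np.ones(10) * 5])
        y = np.repeat(["a", "b"], 10)
        res = mv.univariate_classifier(vals, y, seed=0)
        assert res.auc == 1.0

    def test_auc_invariant_to_monotone_transform_of_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        s = rng.standard_normal(100)
        y = (s + rng.standard_normal(100) > 0).astype(int)
        a = roc_auc_score(y, s)
        b = roc_auc_score(y, np.exp(2.0 * s) + 5)
        assert a == pytest.approx(b, abs=1e-12)

    def test_loo_leakage_guard_with_duplicated_trial(self):
        """Fold-held imputation/PCA keeps null AUC near chance even when a
        trial is duplicated (a leaky pipeline would score its twin)."""
        rng = np.random.default_rng(3)
        n = 40
        X = rng.standard_normal((n, 60))
        y = np.array(["a", "b"] * (n // 2))
        X = np.vstack([X, X[:4]])
        y = np.concatenate([y, y[:4]])
        res = mv.classify_conditions(X, y, reduce=True, pooled_pca=False, seed=4)
        se = np.sqrt(1 / 12 * (1 / 22 + 1 / 22))  # rough null AUC SE
        assert res.auc < 0.5 + 3 * se + 0.08

    def test_permuted_labels_destroy_signal(self):
        rng = np.random.default_rng(5)
        n = 40
        y = np.repeat(["a", "b"], n // 2)
        X = rng.standard_normal((n, 5))
        X[y == "b", 0] += 3.0
        true = mv.classify_conditions(X, y, reduce=False, seed=6)
        null = mv.permuted_label_control(X, y, n_perm=30, seed=7, pooled_pca=False)
        assert true.auc > np.quantile(null, 0.975)
        assert abs(null.mean() - 0.5) < 0.06
        again = mv.permuted_label_control(X, y, n_perm=30, seed=7, pooled_pca=False)
        assert np.array_equal(null, again)  # bit-for-bit reproducible


class TestHaufe:
    def test_diagonal_covariance_closed_form(self):
        """With exactly diagonal feature covariance, A_i = var_i w_i / var_y."""
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((5000, 3))
        raw -= raw.mean(axis=0)
        # orthogonalize columns, then scale to known variances
        q, _ = np.linalg.qr(raw)
        sds = np.array([1.0, 2.0, 3.0])
        X = q / q.std(axis=0) * sds
        w = np.array([1.0, -0.5, 0.25])
        imp = mv.haufe_importance(X, w)
        expected = sds**2 * w / np.var(X @ w)
        assert np.allclose(imp.A, expected, rtol=1e-10)

    def test_recovers_generative_pattern(self):
        """In a two-class Gaussian, A aligns with the class-mean difference."""
        rng = np.random.default_rng(1)
        n, p = 2000, 20
        pattern = rng.standard_normal(p)
        y = np.repeat([0, 1], n // 2)
        noise_mix = rng.standard_normal((p, p)) * 0.5
        X = rng.standard_normal((n, p)) @ noise_mix
        X += np.outer(y - 0.5, pattern) * 2
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, max_iter=2000).fit(X, y)
        imp = mv.haufe_importance(X, clf.coef_)
        r = np.corrcoef(imp.A, pattern)[0, 1]
        assert r > 0.95
        # raw weights do not align as well (that is the point of the transform)
        assert r >= np.corrcoef(clf.coef_.ravel(), pattern)[0, 1] - 1e-6

    def test_scaling_leaves_direction_invariant(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((500, 4))
        w = rng.standard_normal(4)
        a = mv.haufe_importance(X, w).A
        b = mv.haufe_importance(3.0 * X, w).A
        cos = a @ b / np.linalg.norm(a) / np.linalg.norm(b)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_zero_output_variance_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            mv.haufe_importance(X, np.ones(2))


def _toy_power(graph, trials, patterns, n_f=3, noise=0.3, seed=0, n_t=21):
    """Time-resolved z-featured power with community patterns planted on
    boundary trials from 250 ms onward and inner trials throughout."""
    rng = np.random.default_rng(seed)
    n = len(trials)
    n_ch = patterns.shape[1]
    times = np.linspace(0.0, 1.0, n_t, endpoint=False)
    X = rng.standard_normal((n, n_ch, n_f, n_t)) * noise
    for i, node in enumerate(trials["node"]):
        comm = graph.community(node)
        if graph.role(node) == "inner":
            X[i, :, 0, :] += patterns[comm - 1][:, None]
        else:
            adj = graph.community(graph.external_neighbor(node))
            X[i, :, 0, times >= 0.25] += patterns[adj - 1][None, :]
    return pp.SpectralPower(
        power=X.astype(np.float32),
        freqs=np.array([6.0, 10.0, 20.0])[:n_f],
        ch_names=[f"ch{i}" for i in range(n_ch)],
        metadata=trials.reset_index(drop=True),
        times=times,
        sfreq=n_t / 1.0,
    )


class TestPredictiveDecode:
    @pytest.fixture(scope="class")
    def decode_setup(self, graph):
        trials = gs.build_parsing_sequence(graph, n_trials=600, seed=5)
        rng = np.random.default_rng(6)
        patterns = rng.standard_normal((3, 8))
        power = _toy_power(graph, trials, patterns, seed=7)
        return trials, power

    def test_planted_mixing_decoded_after_onset(self, graph, decode_setup):
        trials, power = decode_setup
        res = mv.predictive_decode(power, graph, penalties=np.logspace(-2, 2, 3))
        assert res.whole_epoch_auc > 0.8
        late = res.window_auc[res.window_starts >= 0.3]
        early = res.window_auc[res.window_starts + 0.1 <= 0.16]
        assert late.mean() > 0.8
        assert abs(early.mean() - 0.5) < 0.15

    def test_preboundary_control_near_chance(self, graph, decode_setup):
        trials, power = decode_setup
        res = mv.predictive_decode(
            power, graph, penalties=np.logspace(-2, 2, 3), test_on="preboundary"
        )
        assert abs(res.whole_epoch_auc - 0.5) < 0.2

    def test_recent_visit_filter(self, graph):
        """A boundary node revisited within two trials is excluded."""
        nodes = (
            list("ghighi") + list("lmnlmn")        # training inner trials
            + ["b", "a", "b", "a", "c", "d", "a", "e", "d", "e"]
        )
        trials = pd.DataFrame(
            {
                "trial_index": range(len(nodes)),
                "node": nodes,
                "manipulated": False,
                "block_kind": "walk",
                "transition_label": "",
            }
        )
        rng = np.random.default_rng(1)
        power = _toy_power(graph, trials, rng.standard_normal((3, 4)), seed=2)
        res = mv.predictive_decode(
            power, graph, penalties=np.array([1.0]), win_s=0.5, step_s=0.5
        )
        tested = res.trial_table
        tested_a = tested.loc[tested["node"] == "a", "epoch"].tolist()
        tested_e = tested.loc[tested["node"] == "e", "epoch"].tolist()
        # 'a' appears at epochs 13, 15, 18: the 15 visit (lag 2) is excluded;
        # 'e' appears at 19 and 21: the 21 visit (lag 2) is excluded
        assert tested_a == [13, 18]
        assert tested_e == [19]

    def test_rotation_relabeling_symmetry(self, graph, decode_setup):
        """Community relabeling permutes but does not change rotation AUCs."""
        trials, power = decode_setup
        res = mv.predictive_decode(power, graph, penalties=np.array([1.0]))
        # relabel communities by rotating node names one community forward
        mapping = dict(zip("abcdefghijklmno", "fghijklmnoabcde"))
        trials2 = trials.copy()
        trials2["node"] = trials["node"].map(mapping)
        power2 = pp.SpectralPower(
            power=power.power, freqs=power.freqs, ch_names=power.ch_names,
            metadata=trials2.reset_index(drop=True), times=power.times,
            sfreq=power.sfreq,
        )
        res2 = mv.predictive_decode(power2, graph, penalties=np.array([1.0]))
        a = sorted(r["whole_epoch_auc"] for r in res.per_rotation if not r.get("skipped"))
        b = sorted(r["whole_epoch_auc"] for r in res2.per_rotation if not r.get("skipped"))
        assert np.allclose(a, b, atol=1e-12)


class TestEarlyLate:
    def test_median_split_ties_to_early(self):
        table = pd.DataFrame(
            {
                "run_length": [2, 3, 5, 8],
                "label": [0, 1, 0, 1],
                "score": [0.1, 0.2, -0.1, 0.3],
            }
        )
        out = mv.early_late_split(table)
        assert out["median"] == 4.0
        # groups {2,3} and {5,8}: too few for AUC -> NaN, but split respected
        assert np.isnan(out["early"]) and np.isnan(out["late"])

    def test_split_with_enough_trials(self):
        rng = np.random.default_rng(0)
        n = 200
        run = rng.integers(1, 10, n)
        label = rng.integers(0, 2, n)
        # score informative only for long runs
        score = np.where(run > 4, label * 2.0 - 1.0, 0.0) + 0.3 * rng.standard_normal(n)
        out = mv.early_late_split(
            pd.DataFrame({"run_length": run, "label": label, "score": score})
        )
        assert out["late"] > out["early"]


def test_window_significance_flags_strong_windows():
    rng = np.random.default_rng(0)
    aucs = 0.5 + 0.01 * rng.standard_normal((12, 10))
    aucs[:, 4:7] += 0.2
    sig = mv.window_significance(aucs)
    assert sig["significant"].iloc[4:7].all()
    assert not sig["significant"].iloc[:3].any()
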