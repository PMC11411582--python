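"""Multivariate analyses: PCA feature selection with Kaiser retention,
L2-penalized logistic classification over a penalty sweep with
leave-one-trial-out AUC, covariance-based (activation-pattern) feature
importance, and cross-community predictive decoding in sliding windows.

Conventions
-----------
* Features are z-scored log-power values, one column per (channel,
  frequency); missing entries (rejected data) are imputed from a Gaussian
  with that feature's observed mean and SD.
* Principal components are retained by the Kaiser criterion (eigenvalue
  strictly greater than 1 on standardized features).
* The penalty sweep uses eight log-spaced regularization strengths
  lambda in [1e-4, 1e4] (ridge C = 1/lambda); reported AUC is the mean over
  the eight penalties.
* Feature importance follows the activation-pattern transform
  A = Sigma_x w / var(y), where Sigma_x is the feature covariance, w the
  classifier weights, and var(y) the variance of the linear classifier
  outputs; A is projected back to (channel, frequency) space through the PC
  loadings.
* By default imputation and PCA are fit inside each training fold
  (fold hygiene); ``pooled_pca=True`` reproduces the simpler fit-once
  pipeline in which components are estimated from all trials before
  cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from . import montage
from .graph_sequences import CommunityGraph
from .preprocessing import SpectralPower

logger = logging.getLogger(__name__)


def roc_auc(y_true, scores) -> float:
    """Rank-based AUC (Mann-Whitney closed form, average tie ranks)."""
    y = np.asarray(y_true).astype(bool)
    r = stats.rankdata(np.asarray(scores, float))
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))

DEFAULT_PENALTIES = np.logspace(-4, 4, 8)

#: Frequency bands implied by the spectral feature-selection topography.
BANDS = {
    "theta": (5.0, 7.0),
    "alpha": (9.0, 10.0),
    "beta": (17.0, 21.0),
    "gamma": (45.0, 80.0),
}


# ---------------------------------------------------------------------------
# Imputation + PCA feature selection
# ---------------------------------------------------------------------------

@dataclass
class PCSpace:
    """Retained principal-component space over (channel x frequency) features."""

    loadings: np.ndarray            # features x retained components (orthonormal)
    explained_variance: np.ndarray  # eigenvalues of retained components
    all_eigenvalues: np.ndarray
    mean: np.ndarray                # feature means removed before projection
    impute_mu: np.ndarray
    impute_sd: np.ndarray
    feature_index: list[tuple[str, float]] | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        X = impute_gaussian(X, self.impute_mu, self.impute_sd, rng)
        return (X - self.mean) @ self.loadings


def impute_gaussian(
    X: np.ndarray,
    mu: np.ndarray | None = None,
    sd: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fill missing cells with draws from each feature's observed Gaussian."""
    X = np.asarray(X, float)
    miss = np.isnan(X)
    if not miss.any():
        return X
    rng = np.random.default_rng(rng)
    if mu is None or sd is None:
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(X, axis=0)
            sd = np.nanstd(X, axis=0)
    if np.isnan(mu).any():
        bad = int(np.flatnonzero(np.isnan(mu))[0])
        raise ValueError(f"feature {bad} has no observed values to impute from")
    out = X.copy()
    rows, cols = np.nonzero(miss)
    out[rows, cols] = rng.normal(mu[cols], sd[cols])
    return out


def pca_select(
    X: np.ndarray,
    seed: int | np.random.Generator | None = None,
    feature_index: list[tuple[str, float]] | None = None,
    kaiser_threshold: float = 1.0,
) -> tuple[PCSpace, np.ndarray]:
    """Impute, fit PCA, and retain Kaiser components (eigenvalue > 1).

    Returns the fitted space and the trials x components score matrix.
    Requires at least 2 trials; features are assumed standardized so the
    Kaiser criterion applies to the covariance eigenvalues.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 trials for PCA")
    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
    Xi = impute_gaussian(X, mu, sd, rng)
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Xi)
    ev = pca.explained_variance_
    keep = ev > kaiser_threshold
    if not keep.any():
        keep = np.zeros_like(ev, bool)
        keep[0] = True  # degenerate input: keep the dominant component
    space = PCSpace(
        loadings=pca.components_[keep].T,
        explained_variance=ev[keep],
        all_eigenvalues=ev,
        mean=pca.mean_,
        impute_mu=mu,
        impute_sd=sd,
        feature_index=feature_index,
    )
    return space, scores[:, keep]


def loading_topography(
    spaces: list[PCSpace],
    ch_names: list[str],
    freqs: np.ndarray,
    signed: bool = True,
    weight: str | None = "variance",
    fdr_q: float = 0.05,
    montage_name: str = "biosemi64",
) -> dict:
    """Group-level electrode and frequency profiles of retained PC loadings.

    Per participant, retained-component loadings are combined across
    components — by default weighted by each component's explained variance,
    so the dominant (and deterministically signed) components carry the
    profile rather than being diluted by the many sign-indeterminate minor
    components — and then averaged across frequencies (per-electrode score)
    or electrodes (per-frequency score). Across participants, each
    electrode/frequency is tested against zero (one-sample t) with
    Benjamini-Hochberg FDR, and the electrode scores are aggregated into
    hemisphere x anterior/posterior ROIs for a 2x2 repeated-measures ANOVA.
    ``weight=None`` gives the unweighted mean; ``signed=False`` averages
    absolute loadings.
    """
    n_ch, n_f = len(ch_names), len(freqs)
    per_elec, per_freq = [], []
    for sp in spaces:
        L = sp.loadings.reshape(n_ch, n_f, sp.n_components)
        if not signed:
            L = np.abs(L)
        if weight == "variance":
            w = sp.explained_variance / sp.explained_variance.sum()
            comp_mean = (L * w).sum(axis=2)
        elif weight is None:
            comp_mean = L.mean(axis=2)
        else:
            raise ValueError("weight must be 'variance' or None")
        per_elec.append(comp_mean.mean(axis=1))
        per_freq.append(comp_mean.mean(axis=0))
    per_elec = np.asarray(per_elec)  # participants x channels
    per_freq = np.asarray(per_freq)

    def _group_test(M: np.ndarray) -> pd.DataFrame:
        t, p = stats.ttest_1samp(M, 0.0, axis=0)
        p = np.where(np.isnan(p), 1.0, p)  # degenerate (zero-variance) features
        rej, p_adj, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
        return pd.DataFrame(
            {"score": M.mean(axis=0), "t": t, "p": p, "p_fdr": p_adj,
             "significant": rej}
        )

    elec = _group_test(per_elec)
    elec.insert(0, "channel", ch_names)
    freq = _group_test(per_freq)
    freq.insert(0, "freq_hz", np.asarray(freqs))

    rois = montage.roi_membership(montage_name)
    roi_rows = []
    for s, scores in enumerate(per_elec):
        by_roi: dict[str, list[float]] = {}
        for c, ch in enumerate(ch_names):
            roi = rois.get(ch)
            if roi:
                by_roi.setdefault(roi, []).append(scores[c])
        for roi, vals in by_roi.items():
            roi_rows.append(
                {"participant": s, "hemisphere": roi[0], "ap": roi[1],
                 "score": float(np.mean(vals))}
            )
    roi_df = pd.DataFrame(roi_rows)
    roi_anova = pg.rm_anova(
        data=roi_df, dv="score", within=["hemisphere", "ap"],
        subject="participant",
    )
    return {
        "per_electrode": elec,
        "per_frequency": freq,
        "roi_table": roi_df,
        "roi_anova": roi_anova,
        "per_electrode_matrix": per_elec,
        "per_frequency_matrix": per_freq,
    }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    """AUC of a penalized logistic decoder (mean over the penalty sweep)."""

    auc: float
    per_penalty: dict[float, float]
    scheme: str
    classes: tuple
    n_trials: int
    scores: np.ndarray | None = None   # cross-validated decision values
    labels: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _fit_logistic(X, y, lam: float) -> LogisticRegression:
    # default penalty is ridge (L2); C is the inverse regularization strength.
    # balanced class weights keep leave-one-out folds calibrated: without
    # them the fold-dependent class prior biases the intercept against the
    # held-out trial's class, dragging null AUC below chance at small n.
    # newton-cholesky solves the same objective much faster when samples
    # outnumber features; its Hessian is p x p, so wide problems use lbfgs
    solver = "newton-cholesky" if X.shape[1] <= 200 else "lbfgs"
    clf = LogisticRegression(
        C=1.0 / lam, solver=solver, max_iter=2000, class_weight="balanced"
    )
    clf.fit(X, y)
    return clf


def classify_conditions(
    X: np.ndarray,
    y: np.ndarray,
    penalties: np.ndarray = DEFAULT_PENALTIES,
    pooled_pca: bool = False,
    reduce: bool = True,
    seed: int | np.random.Generator | None = None,
    min_per_class: int = 5,
) -> DecodingResult:
    """Leave-one-trial-out AUC of the penalty-swept L2 logistic decoder.

    ``reduce=True`` applies Gaussian imputation + Kaiser PCA; with the
    default ``pooled_pca=False`` the reduction is refit inside every training
    fold so the left-out trial never informs the feature space.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} trials per class, got {counts}"
        )
    rng = np.random.default_rng(seed)
    ybin = (y == classes[1]).astype(int)
    n = len(y)

    if reduce and pooled_pca:
        space, scores_all = pca_select(X, seed=rng)
        X_work = scores_all
        per_fold_reduce = False
    elif reduce:
        X_work = X
        per_fold_reduce = True
    else:
        X_work = impute_gaussian(X, rng=rng)
        per_fold_reduce = False

    dec = np.empty((n, len(penalties)))
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        if per_fold_reduce:
            space, Xtr = pca_select(X_work[tr], seed=rng)
            Xte = space.transform(X_work[i : i + 1], rng=rng)
        else:
            Xtr, Xte = X_work[tr], X_work[i : i + 1]
        for j, lam in enumerate(penalties):
            clf = _fit_logistic(Xtr, ybin[tr], lam)
            dec[i, j] = clf.decision_function(Xte)[0]
    per_penalty = {
        float(lam): float(roc_auc(ybin, dec[:, j]))
        for j, lam in enumerate(penalties)
    }
    return DecodingResult(
        auc=float(np.mean(list(per_penalty.values()))),
        per_penalty=per_penalty,
        scheme="leave-one-trial-out",
        classes=tuple(classes),
        n_trials=n,
        scores=dec.mean(axis=1),
        labels=ybin,
    )


def univariate_classifier(
    values: np.ndarray,
    y: np.ndarray,
    penalties: np.ndarray = DEFAULT_PENALTIES,
    seed: int | np.random.Generator | None = None,
) -> DecodingResult:
    """The same protocol on a single feature (e.g. Pz window amplitude)."""
    X = np.asarray(values, float).reshape(-1, 1)
    return classify_conditions(X, y, penalties=penalties, reduce=False, seed=seed)


def compare_aucs_paired(
    auc_a: np.ndarray, auc_b: np.ndarray, name: str = "auc_multivariate_vs_univariate"
):
    """Across-participant paired t test between two AUC vectors."""
    from .erp import StatsResult

    t = pg.ttest(np.asarray(auc_a, float), np.asarray(auc_b, float), paired=True)
    return StatsResult(
        name=name,
        statistic=float(t["T"].iloc[0]),
        df=float(t["dof"].iloc[0]),
        p=float(t["p_val"].iloc[0]),
        effect_size=float(t["cohen_d"].iloc[0]),
        effect_size_name="cohen_d",
    )


def permuted_label_control(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
    penalties: np.ndarray = DEFAULT_PENALTIES,
    pooled_pca: bool = True,
) -> np.ndarray:
    """Null AUC distribution from decoders trained on permuted labels.

    Labels are permuted within each cross-validation training fold before
    fitting; the left-out trial keeps its true label for scoring.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    ybin = (y == classes[1]).astype(int)
    n = len(y)
    if pooled_pca:
        _, X_work = pca_select(X, seed=rng) if X.shape[1] > 1 else (None, X)
    else:
        X_work = X
    aucs = np.empty(n_perm)
    for k in range(n_perm):
        dec = np.empty((n, len(penalties)))
        for i in range(n):
            tr = np.ones(n, bool)
            tr[i] = False
            yp = rng.permutation(ybin[tr])
            for j, lam in enumerate(penalties):
                clf = _fit_logistic(X_work[tr], yp, lam)
                dec[i, j] = clf.decision_function(X_work[i : i + 1])[0]
        aucs[k] = np.mean(
            [roc_auc(ybin, dec[:, j]) for j in range(len(penalties))]
        )
    return aucs


# ---------------------------------------------------------------------------
# Activation-pattern (covariance-based) importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceMap:
    A: np.ndarray                      # importance per classifier feature
    sigma_x: np.ndarray
    w: np.ndarray
    var_y: float
    channel_frequency: np.ndarray | None = None  # projected (n_ch, n_f)


def haufe_importance(
    X: np.ndarray,
    w: np.ndarray,
    y_scores: np.ndarray | None = None,
    space: PCSpace | None = None,
    n_channels: int | None = None,
) -> ImportanceMap:
    """Activation pattern A = Sigma_x w / var(y) from discriminative weights.

    ``y_scores`` defaults to the linear outputs X w. When ``space`` is given
    the PC-space importance is projected to (channel, frequency) features by
    loading-weighted combination.
    """
    X = np.asarray(X, float)
    w = np.asarray(w, float).ravel()
    if X.shape[1] != len(w):
        raise ValueError("weight length does not match feature count")
    if y_scores is None:
        y_scores = X @ w
    var_y = float(np.var(y_scores))
    if var_y == 0:
        raise ValueError("zero variance of classifier outputs")
    sigma = np.cov(X, rowvar=False, bias=True)  # ddof matches var(y_scores)
    sigma = np.atleast_2d(sigma)
    A = sigma @ w / var_y
    chfreq = None
    if space is not None:
        proj = space.loadings @ A  # back to original feature space
        if n_channels is None and space.feature_index is not None:
            n_channels = len({c for c, _ in space.feature_index})
        if n_channels:
            chfreq = proj.reshape(n_channels, -1)
    return ImportanceMap(
        A=A, sigma_x=sigma, w=w, var_y=var_y, channel_frequency=chfreq
    )


def aggregate_importance(
    chfreq: np.ndarray,
    ch_names: list[str],
    freqs: np.ndarray,
    bands: dict[str, tuple[float, float]] = BANDS,
    montage_name: str = "biosemi64",
) -> pd.DataFrame:
    """Mean importance per (band x anterior/posterior ROI) cell."""
    rois = montage.roi_membership(montage_name)
    freqs = np.asarray(freqs)
    rows = []
    for band, (lo, hi) in bands.items():
        fmask = (freqs >= lo) & (freqs <= hi)
        for ap, ap_name in (("A", "anterior"), ("P", "posterior")):
            chans = [i for i, ch in enumerate(ch_names)
                     if rois.get(ch, " ")[-1:] == ap]
            cols = np.flatnonzero(fmask)
            value = (
                float(chfreq[np.ix_(chans, cols)].mean())
                if chans and len(cols)
                else np.nan  # band outside the frequency axis, or no ROI members
            )
            rows.append({"band": band, "roi": ap_name, "importance": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Predictive cross-community decoding
# ---------------------------------------------------------------------------

@dataclass
class PredictiveResult:
    """Sliding-window cross-community decoding of boundary-node trials."""

    window_starts: np.ndarray          # seconds
    window_auc: np.ndarray             # mean over rotations and penalties
    whole_epoch_auc: float
    per_rotation: list[dict]           # rotation bookkeeping
    trial_table: pd.DataFrame          # per test trial: score, label, run length
    test_on: str = "boundary"

    @property
    def mean_window_auc(self) -> float:
        return float(np.nanmean(self.window_auc))


def _window_features(power: SpectralPower, lo: float, hi: float) -> np.ndarray:
    mask = (power.times >= lo - 1e-9) & (power.times < hi - 1e-9)
    n_ep = power.power.shape[0]
    return (
        power.power[:, :, :, mask].mean(axis=3).reshape(n_ep, -1).astype(np.float64)
    )


def predictive_decode(
    power: SpectralPower,
    graph: CommunityGraph,
    win_s: float = 0.1,
    step_s: float = 0.05,
    span: tuple[float, float] = (0.0, 1.0),
    penalties: np.ndarray = DEFAULT_PENALTIES,
    exclude_recent: int = 2,
    test_on: str = "boundary",
) -> PredictiveResult:
    """Train on inner nodes of two communities; test on held-out boundary nodes.

    For each of the three community rotations, classifiers are trained to
    discriminate (unmanipulated) inner-node trials of the two training
    communities, within each sliding window, and applied to the held-out
    community's boundary-node trials; the test label is the training
    community each boundary node abuts. Test trials are restricted to visits
    where the same boundary node was not visited within the previous
    ``exclude_recent`` trials. ``test_on="preboundary"`` instead tests on the
    held-out community's inner-node trials that immediately precede a
    boundary-node visit, labeled by the upcoming boundary node's adjacent
    community. Window AUCs are averaged over penalties and rotations;
    ``whole_epoch_auc`` decodes features averaged over the whole
    presentation span.
    """
    if not power.time_resolved:
        raise ValueError("predictive decoding needs time-resolved power")
    meta = power.metadata.reset_index(drop=True)
    nodes = meta["node"].to_numpy()
    manip = meta["manipulated"].to_numpy(bool) if "manipulated" in meta else np.zeros(len(meta), bool)
    comm = np.array([graph.community(n) for n in nodes])
    role = np.array([graph.role(n) for n in nodes])
    seq_pos = meta["trial_index"].to_numpy()
    from .synthetic import preceding_run_length

    run_len = preceding_run_length(comm)

    starts = np.arange(span[0], span[1] - win_s + 1e-9, step_s)
    # window features are rotation-independent: compute each once
    window_feats = [_window_features(power, lo, lo + win_s) for lo in starts]
    whole_feats = _window_features(power, span[0], span[1])
    communities = sorted(graph.communities())
    rotations = []
    window_aucs = np.full((len(communities), len(starts)), np.nan)
    whole_scores: list[np.ndarray] = []
    whole_labels: list[np.ndarray] = []
    trial_rows = []

    # positions of each node in the *sequence* for the recent-visit filter
    recent_ok = np.ones(len(meta), bool)
    node_by_pos = dict(zip(seq_pos, nodes))
    for i in range(len(meta)):
        p = seq_pos[i]
        for back in range(1, exclude_recent + 1):
            if node_by_pos.get(p - back) == nodes[i]:
                recent_ok[i] = False
                break

    for r, held in enumerate(communities):
        train_comms = [c for c in communities if c != held]
        train_mask = (
            (role == "inner") & ~manip & np.isin(comm, train_comms)
        )
        if test_on == "boundary":
            test_mask = (comm == held) & (role == "boundary") & ~manip & recent_ok
            test_ix = np.flatnonzero(test_mask)
            test_label = np.array(
                [graph.community(graph.external_neighbor(nodes[i])) for i in test_ix]
            )
        elif test_on == "preboundary":
            is_b = (role == "boundary")
            pre = np.zeros(len(meta), bool)
            pre[:-1] = is_b[1:] & (role[:-1] == "inner")
            # consecutive in the sequence, not merely in the retained epochs
            pre[:-1] &= np.diff(seq_pos) == 1
            test_mask = pre & (comm == held) & ~manip
            test_ix = np.flatnonzero(test_mask)
            test_label = np.array(
                [
                    graph.community(graph.external_neighbor(nodes[i + 1]))
                    for i in test_ix
                ]
            )
        else:
            raise ValueError("test_on must be 'boundary' or 'preboundary'")
        keep = np.isin(test_label, train_comms)
        test_ix, test_label = test_ix[keep], test_label[keep]
        if len(test_ix) == 0 or len(np.unique(test_label)) < 2:
            logger.info("rotation %d (held-out community %s): no usable test "
                        "trials; skipped", r, held)
            rotations.append({"held_out": held, "skipped": True})
            continue
        tr_ix = np.flatnonzero(train_mask)
        ytr = (comm[tr_ix] == train_comms[1]).astype(int)
        yte = (test_label == train_comms[1]).astype(int)

        for wi, F in enumerate(window_feats):
            aucs = []
            for lam in penalties:
                clf = _fit_logistic(F[tr_ix], ytr, lam)
                s = clf.decision_function(F[test_ix])
                aucs.append(roc_auc(yte, s))
            window_aucs[r, wi] = float(np.mean(aucs))

        Fw = whole_feats
        scores = np.zeros(len(test_ix))
        aucs = []
        for lam in penalties:
            clf = _fit_logistic(Fw[tr_ix], ytr, lam)
            s = clf.decision_function(Fw[test_ix])
            scores += s / len(penalties)
            aucs.append(roc_auc(yte, s))
        whole_scores.append(scores)
        whole_labels.append(yte)
        for k, i in enumerate(test_ix):
            trial_rows.append(
                {
                    "rotation": r,
                    "held_out": held,
                    "epoch": int(i),
                    "node": nodes[i],
                    "run_length": int(run_len[i]),
                    "label": int(yte[k]),
                    "score": float(scores[k]),
                }
            )
        rotations.append(
            {"held_out": held, "skipped": False, "n_train": int(train_mask.sum()),
             "n_test": len(test_ix), "whole_epoch_auc": float(np.mean(aucs))}
        )

    usable = [rot["whole_epoch_auc"] for rot in rotations if not rot.get("skipped")]
    return PredictiveResult(
        window_starts=starts,
        window_auc=np.nanmean(window_aucs, axis=0),
        whole_epoch_auc=float(np.mean(usable)) if usable else np.nan,
        per_rotation=rotations,
        trial_table=pd.DataFrame(trial_rows),
        test_on=test_on,
    )


def early_late_split(trial_table: pd.DataFrame) -> dict:
    """Median split of boundary test trials by preceding run length.

    Ties (run length equal to the median) go to the early group. Returns
    per-group AUC computed from the pooled cross-rotation scores.
    """
    df = trial_table
    med = df["run_length"].median()
    early = df[df["run_length"] <= med]
    late = df[df["run_length"] > med]
    out = {"median": float(med)}
    for name, grp in (("early", early), ("late", late)):
        if len(grp) < 3 or grp["label"].nunique() < 2:
            out[name] = np.nan
        else:
            out[name] = float(roc_auc(grp["label"], grp["score"]))
    return out


def window_significance(
    group_window_aucs: np.ndarray, alpha: float = 0.05, chance: float = 0.5
) -> pd.DataFrame:
    """Across-participant one-sample t per window vs chance, BH-FDR corrected."""
    M = np.asarray(group_window_aucs, float)
    t, p = stats.ttest_1samp(M, chance, axis=0, alternative="greater")
    rej, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"window": np.arange(M.shape[1]), "mean_auc": M.mean(axis=0),
         "t": t, "p": p, "p_fdr": p_adj, "significant": rej}
    )
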