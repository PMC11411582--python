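"""Event-related potential analyses: parietal window amplitudes, condition
contrasts, and brain-behavior correlations with a permutation contrast.

The P300-style measure is the mean preprocessed *voltage* at one electrode
(default Pz) in the 250-450 ms post-onset window (closed on the left, open
on the right in samples); an early 50-250 ms window runs through the same
code path. Group statistics are repeated-measures ANOVA and paired t tests
over per-participant condition means, a Pearson correlation between the
novel-nonboundary P300 difference and the corresponding parsing-probability
difference, and a seeded permutation test for the difference between the
novel and learned brain-behavior correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .preprocessing import EpochArray

P300_WINDOW = (0.25, 0.45)
EARLY_WINDOW = (0.05, 0.25)


@dataclass(frozen=True)
class ERPConfig:
    electrode: str = "Pz"
    window: tuple[float, float] = P300_WINDOW


@dataclass
class StatsResult:
    """One inferential test: statistic, df, p, effect size."""

    name: str
    statistic: float
    df: object
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    extra: dict | None = None

    def as_row(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": str(self.df),
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
        }


def window_amplitude(
    epochs: EpochArray,
    electrode: str = "Pz",
    window: tuple[float, float] = P300_WINDOW,
) -> pd.Series:
    """Per-epoch mean voltage at ``electrode`` over [window) seconds."""
    ix = epochs.pick(electrode)
    mask = epochs.time_window(*window)
    vals = epochs.data[:, ix, :][:, mask].mean(axis=1)
    return pd.Series(vals, index=epochs.metadata.index, name="amplitude")


def condition_means(
    epochs: EpochArray,
    electrode: str = "Pz",
    window: tuple[float, float] = P300_WINDOW,
    condition_col: str = "transition_label",
    min_epochs: int = 5,
) -> pd.Series:
    """Condition -> mean window amplitude over retained epochs.

    Conditions with fewer than ``min_epochs`` retained epochs are omitted.
    """
    retained = epochs.retained()
    amp = window_amplitude(retained, electrode, window)
    cond = retained.metadata[condition_col]
    counts = cond.value_counts()
    means = amp.groupby(cond).mean()
    return means[counts[means.index] >= min_epochs]


def condition_contrasts(per_participant: pd.DataFrame) -> list[StatsResult]:
    """Repeated-measures ANOVA plus pairwise paired t tests.

    ``per_participant``: rows = participants, columns = conditions, values =
    mean window amplitude. Participants missing any condition are dropped.
    """
    df = per_participant.dropna(axis=0)
    if len(df) < 2:
        raise ValueError("need at least 2 complete participants")
    long = df.reset_index(names="participant").melt(
        id_vars="participant", var_name="condition", value_name="amplitude"
    )
    aov = pg.rm_anova(
        data=long, dv="amplitude", within="condition", subject="participant",
        detailed=True,
    )
    row = aov.iloc[0]
    results = [
        StatsResult(
            name="anova_condition",
            statistic=float(row["F"]),
            df=(int(row["DF"]), int(aov.iloc[1]["DF"])),
            p=float(row["p_unc"]),
            effect_size=float(row.get("ng2", np.nan)),
            effect_size_name="eta_sq_generalized",
        )
    ]
    conds = list(df.columns)
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            a, b = df[conds[i]], df[conds[j]]
            t = pg.ttest(a, b, paired=True)
            results.append(
                StatsResult(
                    name=f"paired_t_{conds[i]}_vs_{conds[j]}",
                    statistic=float(t["T"].iloc[0]),
                    df=float(t["dof"].iloc[0]),
                    p=float(t["p_val"].iloc[0]),
                    effect_size=float(t["cohen_d"].iloc[0]),
                    effect_size_name="cohen_d",
                )
            )
    return results


def brain_behavior_correlation(
    delta_erp: np.ndarray, delta_parse: np.ndarray, name: str = "brain_behavior_r"
) -> StatsResult:
    """Pearson correlation between participant-level difference scores."""
    x = np.asarray(delta_erp, float)
    y = np.asarray(delta_parse, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return StatsResult(
        name=name,
        statistic=float(r),
        df=len(x) - 2,
        p=float(p),
        effect_size=float(r**2),
        effect_size_name="r_squared",
    )


def correlation_difference_permutation(
    novel_pairs: np.ndarray,
    learned_pairs: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> StatsResult:
    """Permutation test for r(novel) - r(learned) with within-participant swaps.

    ``novel_pairs`` and ``learned_pairs`` are (n, 2) arrays of per-participant
    (delta_ERP, delta_parse) pairs for each condition. Under the null, the
    condition labels of each participant's two pairs are exchangeable: each
    permutation independently swaps, per participant, which pair is called
    "novel". Two-tailed p = (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    import warnings as _warnings

    novel = np.asarray(novel_pairs, float)
    learned = np.asarray(learned_pairs, float)
    if novel.shape != learned.shape or novel.ndim != 2 or novel.shape[1] != 2:
        raise ValueError("expected matching (n, 2) arrays")
    if n_perm < 100:
        _warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    rng = np.random.default_rng(seed)
    n = len(novel)

    def rdiff(a: np.ndarray, b: np.ndarray) -> float:
        return float(
            np.corrcoef(a[:, 0], a[:, 1])[0, 1] - np.corrcoef(b[:, 0], b[:, 1])[0, 1]
        )

    observed = rdiff(novel, learned)
    null = np.empty(n_perm)
    for k in range(n_perm):
        swap = rng.random(n) < 0.5
        a = np.where(swap[:, None], learned, novel)
        b = np.where(swap[:, None], novel, learned)
        null[k] = rdiff(a, b)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return StatsResult(
        name="correlation_difference_permutation",
        statistic=observed,
        df=n,
        p=float(p),
        extra={"n_perm": n_perm},
    )


def results_frame(results: list[StatsResult]) -> pd.DataFrame:
    """Tidy one-row-per-test table for CSV/JSON export."""
    return pd.DataFrame([r.as_row() for r in results])
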