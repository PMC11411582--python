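"""Behavioral statistics: rotation-task sensitivity (d'), parsing rates and
RTs by transition condition, posttest scoring, and cross-measure correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .erp import StatsResult, condition_contrasts
from .graph_sequences import LEARNED, NONBOUNDARY, NOVEL

logger = logging.getLogger(__name__)


def dprime(hits: int, misses: int, fas: int, crs: int) -> float:
    """Signal-detection d' with the log-linear correction applied always.

    d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate), with 0.5 added to every
    cell (and 1 to every denominator) so perfect rates stay finite and the
    estimator is continuous. Raises if either stimulus class has no trials.
    """
    if min(hits, misses, fas, crs) < 0:
        raise ValueError("counts must be nonnegative")
    if hits + misses == 0 or fas + crs == 0:
        raise ValueError("each stimulus class needs at least one trial")
    hr = (hits + 0.5) / (hits + misses + 1.0)
    fr = (fas + 0.5) / (fas + crs + 1.0)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(fr))


def rotation_summary(behavior: pd.DataFrame) -> dict:
    """Exposure-phase rotation-task d' and RT, overall and by condition.

    ``behavior`` needs columns rotated, responded_rotated, rt_ms, condition.
    d' is computed overall and separately for trials whose incoming
    transition was a learned boundary vs nonboundary.
    """
    def _counts(df: pd.DataFrame) -> tuple[int, int, int, int]:
        rot = df["rotated"].to_numpy(bool)
        yes = df["responded_rotated"].to_numpy(bool)
        return (
            int((rot & yes).sum()), int((rot & ~yes).sum()),
            int((~rot & yes).sum()), int((~rot & ~yes).sum()),
        )

    out = {"dprime_overall": dprime(*_counts(behavior))}
    for cond in (LEARNED, NONBOUNDARY):
        sub = behavior[behavior["condition"] == cond]
        try:
            out[f"dprime_{cond}"] = dprime(*_counts(sub))
        except ValueError:
            out[f"dprime_{cond}"] = np.nan
            logger.info("rotation_summary: no trials for %s", cond)
        out[f"rt_{cond}"] = float(sub["rt_ms"].mean())
    return out


def parsing_summary(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-condition parse percentage and mean RT of parsed trials."""
    rows = []
    for cond in (NOVEL, LEARNED, NONBOUNDARY):
        sub = behavior[behavior["condition"] == cond]
        if len(sub) == 0:
            continue
        parsed = sub["parsed"].to_numpy(bool)
        rts = sub.loc[parsed, "rt_ms"]
        if parsed.sum() == 0:
            logger.info("parsing_summary: no parses in condition %s", cond)
        rows.append(
            {
                "condition": cond,
                "n_trials": len(sub),
                "parse_pct": 100.0 * parsed.mean(),
                "rt_ms": float(rts.mean()) if len(rts) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def parsing_group_stats(per_participant: pd.DataFrame) -> list[StatsResult]:
    """RM-ANOVA + pairwise t tests on participants x conditions values."""
    return condition_contrasts(per_participant)


def posttest_score(answers: pd.DataFrame) -> float:
    """Percent correct of a forced-choice posttest answer table."""
    if len(answers) == 0:
        raise ValueError("empty answer table")
    if answers["correct"].isna().any():
        logger.info("posttest_score: %d missing answers",
                    int(answers["correct"].isna().sum()))
    return float(100.0 * answers["correct"].dropna().astype(bool).mean())


def posttest_group_test(percent_correct: np.ndarray, chance: float = 50.0) -> StatsResult:
    """Across-participant Wilcoxon signed-rank test against chance."""
    x = np.asarray(percent_correct, float)
    res = pg.wilcoxon(x - chance)
    d = (x.mean() - chance) / x.std(ddof=1) if x.std(ddof=1) > 0 else np.nan
    return StatsResult(
        name="posttest_vs_chance_wilcoxon",
        statistic=float(res["W_val"].iloc[0]),
        df=len(x),
        p=float(res["p_val"].iloc[0]),
        effect_size=float(d),
        effect_size_name="cohen_d",
    )


def across_participant_correlation(
    x: np.ndarray, y: np.ndarray, name: str = "across_participant_r"
) -> StatsResult:
    """Pearson correlation with df = N - 2 and r^2 effect size."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return StatsResult(
        name=name, statistic=float(r), df=len(x) - 2, p=float(p),
        effect_size=float(r**2), effect_size_name="r_squared",
    )
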