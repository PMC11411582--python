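"""Representational pattern similarity across boundary conditions.

Pairs of inner-node epochs inside Hamiltonian blocks at an inter-item lag of
3, with no parse response anywhere in the closed span, are classified by the
transitions between them: a manipulated between-community transition makes
the pair *novel*, an unmanipulated one *learned*, and only within-community
transitions *nonboundary*. Similarity is the Pearson correlation over the
retained PC scores, Fisher r-to-z transformed and averaged within condition;
group contrasts use repeated-measures ANOVA and paired t tests.

A second analysis asks whether boundary-position representations are item-
or community-level: the similarity of epochs from the two true boundary
nodes of a transition (learned-learned) is compared with the similarity of a
true boundary node to the swapped-in inner node occupying the other boundary
position during manipulated blocks (learned-novel).
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd
import pingouin as pg

from .graph_sequences import LEARNED, NONBOUNDARY, NOVEL, CommunityGraph

logger = logging.getLogger(__name__)

_Z_CLIP = 1.0 - 1e-10


def find_pairs(
    trials: pd.DataFrame,
    behavior: pd.DataFrame | None,
    graph: CommunityGraph,
    lag: int = 3,
    parse_rule: str = "span",
) -> pd.DataFrame:
    """Lag-``lag`` inner-node epoch pairs within Hamiltonian blocks.

    Both endpoints must be inner nodes in the same Hamiltonian block.
    ``parse_rule="span"`` (default) excludes pairs with a parse response on
    any trial of the closed span [i, i+lag]; ``"endpoints"`` only checks the
    two endpoint trials. The pair condition is determined by the intervening
    transition labels: any novel label -> novel; else any learned label ->
    learned; else nonboundary.
    """
    if parse_rule not in ("span", "endpoints"):
        raise ValueError("parse_rule must be 'span' or 'endpoints'")
    df = trials.reset_index(drop=True)
    labels = df["transition_label"].to_numpy()
    kinds = df["block_kind"].to_numpy()
    nodes = df["node"].to_numpy()
    seq = df["trial_index"].to_numpy()
    parsed = np.zeros(len(df), bool)
    if behavior is not None and "parsed" in behavior:
        parse_by_pos = dict(zip(behavior["trial_index"], behavior["parsed"]))
        parsed = np.array([bool(parse_by_pos.get(p, False)) for p in seq])
    # Hamiltonian block id: running id over consecutive hamiltonian runs
    is_ham = kinds == "hamiltonian"
    bid = np.full(len(df), -1)
    cur = -1
    for i in range(len(df)):
        if is_ham[i] and (i == 0 or not is_ham[i - 1]):
            cur += 1
        if is_ham[i]:
            bid[i] = cur

    rows = []
    for i in range(len(df) - lag):
        j = i + lag
        if bid[i] < 0 or bid[i] != bid[j]:
            continue
        if seq[j] - seq[i] != lag:
            continue
        if graph.role(nodes[i]) != "inner" or graph.role(nodes[j]) != "inner":
            continue
        span = slice(i, j + 1) if parse_rule == "span" else [i, j]
        if np.any(parsed[span]):
            continue
        between = labels[i + 1 : j + 1]
        if NOVEL in between:
            cond = NOVEL
        elif LEARNED in between:
            cond = LEARNED
        else:
            cond = NONBOUNDARY
        rows.append(
            {"i": i, "j": j, "trial_i": int(seq[i]), "trial_j": int(seq[j]),
             "condition": cond, "block": int(bid[i])}
        )
    return pd.DataFrame(rows, columns=["i", "j", "trial_i", "trial_j",
                                       "condition", "block"])


def _fisher_z(r: np.ndarray) -> np.ndarray:
    r = np.clip(r, -_Z_CLIP, _Z_CLIP)
    return np.arctanh(r)


def pair_similarity(pc_scores: np.ndarray, pairs: pd.DataFrame) -> pd.DataFrame:
    """Fisher-z Pearson similarity per pair over retained PC scores.

    Rows of ``pc_scores`` index epochs in the same order as the ``i``/``j``
    columns of ``pairs``. |r| = 1 is clipped before the transform (logged).
    """
    X = np.asarray(pc_scores, float)
    rows = []
    n_clipped = 0
    for _, p in pairs.iterrows():
        a, b = X[int(p["i"])], X[int(p["j"])]
        sa, sb = a.std(), b.std()
        r = float(np.corrcoef(a, b)[0, 1]) if sa > 0 and sb > 0 else 0.0
        if abs(r) >= 1.0:
            n_clipped += 1
        rows.append({**p.to_dict(), "r": r, "z": float(_fisher_z(np.array(r)))})
    if n_clipped:
        logger.info("pair_similarity: clipped %d perfect correlations", n_clipped)
    return pd.DataFrame(rows)


def condition_summary(sim: pd.DataFrame) -> pd.Series:
    """Mean Fisher-z similarity per condition (one participant)."""
    return sim.groupby("condition")["z"].mean()


def group_contrasts(per_participant: pd.DataFrame) -> list:
    """RM-ANOVA and pairwise t tests over per-participant condition means."""
    from .erp import condition_contrasts

    return condition_contrasts(per_participant)


def boundary_item_similarity(
    pc_scores: np.ndarray,
    trials: pd.DataFrame,
    graph: CommunityGraph,
    max_pairs: int = 400,
    seed: int | np.random.Generator | None = 0,
) -> dict:
    """Learned-learned vs learned-novel boundary-position similarity.

    For each between-community transition (b1, b2): *learned-learned* pairs
    correlate epochs where b1 and b2 each display their own stimulus;
    *learned-novel* pairs correlate own-stimulus epochs of one true boundary
    node with epochs where the other boundary position shows the swapped-in
    inner stimulus (manipulated trials). Returns mean Fisher-z per condition.
    """
    rng = np.random.default_rng(seed)
    df = trials.reset_index(drop=True)
    nodes = df["node"].to_numpy()
    manip = df["manipulated"].to_numpy(bool)
    X = np.asarray(pc_scores, float)

    def _mean_sim(ix_a: np.ndarray, ix_b: np.ndarray) -> float | None:
        if len(ix_a) == 0 or len(ix_b) == 0:
            return None
        combos = [(a, b) for a, b in product(ix_a, ix_b) if a != b]
        if not combos:
            return None
        if len(combos) > max_pairs:
            sel = rng.choice(len(combos), size=max_pairs, replace=False)
            combos = [combos[s] for s in sel]
        zs = []
        for a, b in combos:
            u, v = X[a], X[b]
            if u.std() == 0 or v.std() == 0:
                continue
            zs.append(_fisher_z(np.array(np.corrcoef(u, v)[0, 1])))
        return float(np.mean(zs)) if zs else None

    ll, ln = [], []
    for edge in graph.between_edges():
        b1, b2 = sorted(edge)
        own1 = np.flatnonzero((nodes == b1) & ~manip)
        own2 = np.flatnonzero((nodes == b2) & ~manip)
        sw1 = np.flatnonzero((nodes == b1) & manip)
        sw2 = np.flatnonzero((nodes == b2) & manip)
        s = _mean_sim(own1, own2)
        if s is not None:
            ll.append(s)
        for own, swapped in ((own1, sw2), (own2, sw1)):
            s = _mean_sim(own, swapped)
            if s is not None:
                ln.append(s)
    if not ll or not ln:
        logger.info("boundary_item_similarity: insufficient epochs; dropped")
        return {"learned_learned": np.nan, "learned_novel": np.nan}
    return {
        "learned_learned": float(np.mean(ll)),
        "learned_novel": float(np.mean(ln)),
    }
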