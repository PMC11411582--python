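"""Temporal community graph and stimulus-sequence design.

The experimental paradigm organizes 15 abstract stimuli as nodes of an
undirected graph with three 5-node communities arranged in a ring. Inner
nodes connect to all four members of their community; each community's two
boundary nodes carry the single edge to an adjacent community (the two
boundary nodes of a community are not connected to each other). The graph is
degree-4 regular, so community membership is invisible to local transition
statistics.

This module builds the graph, generates exposure (random walk) and parsing
(pseudorandom walk / Hamiltonian path) sequences, applies the boundary-swap
manipulation that creates *novel* between-community transitions, labels every
transition, and constructs the forced-choice posttest.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CommunityGraph",
    "ManipulationSchedule",
    "build_graph",
    "random_walk",
    "pseudorandom_walk",
    "enumerate_hamiltonian_paths",
    "hamiltonian_path",
    "build_schedule",
    "build_exposure_sequence",
    "build_parsing_sequence",
    "apply_boundary_swap",
    "label_transitions",
    "build_posttest",
    "break_schedule",
    "write_events_tsv",
    "write_graph",
]

STIMULUS_DURATION_S = 1.25
#: Self-paced break positions (trial counts between breaks) per phase.
EXPOSURE_BREAK_EVERY = 350
PARSING_BREAKS_AFTER = (405, 390)

NONBOUNDARY = "nonboundary"
LEARNED = "learned_boundary"
NOVEL = "novel_boundary"


@dataclass(frozen=True)
class CommunityGraph:
    """15-node temporal community graph with node roles and stimulus map.

    Attributes
    ----------
    graph : networkx.Graph
        Undirected adjacency. Node attributes ``community`` (1-based int) and
        ``role`` (``"inner"`` or ``"boundary"``).
    stimulus : dict
        Node label -> displayed stimulus id (a permutation of a stimulus pool).
    """

    graph: nx.Graph
    stimulus: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def community(self, node: str) -> int:
        return self.graph.nodes[node]["community"]

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for n in self.graph.nodes:
            out.setdefault(self.community(n), []).append(n)
        return out

    def inner_nodes(self, community: int | None = None) -> list[str]:
        return [
            n
            for n in self.graph.nodes
            if self.role(n) == "inner"
            and (community is None or self.community(n) == community)
        ]

    def boundary_nodes(self, community: int | None = None) -> list[str]:
        return [
            n
            for n in self.graph.nodes
            if self.role(n) == "boundary"
            and (community is None or self.community(n) == community)
        ]

    def between_edges(self) -> list[frozenset[str]]:
        """The between-community (boundary) edges, one per community pair."""
        return [
            frozenset((u, v))
            for u, v in self.graph.edges
            if self.community(u) != self.community(v)
        ]

    def external_neighbor(self, node: str) -> str:
        """The single out-of-community neighbor of a boundary node."""
        if self.role(node) != "boundary":
            raise ValueError(f"{node!r} is not a boundary node")
        out = [m for m in self.neighbors(node) if self.community(m) != self.community(node)]
        assert len(out) == 1
        return out[0]


def build_graph(
    seed: int | None = None,
    n_communities: int = 3,
    community_size: int = 5,
    stimulus_pool: int = 74,
) -> CommunityGraph:
    """Build the ring-of-communities graph with the standard edge convention.

    Node labels are consecutive lowercase letters (``a``..``o`` for the
    default 3x5 layout). The first and last node of each community are its
    boundary nodes; consecutive communities are joined by a single edge
    between the last boundary node of one and the first boundary node of the
    next, closing into a ring.

    When ``seed`` is given, each node is assigned a stimulus id drawn
    uniformly without replacement from a pool of ``stimulus_pool`` ids;
    otherwise the stimulus id equals the node label.
    """
    n = n_communities * community_size
    labels = list(string.ascii_lowercase[:n])
    g = nx.Graph()
    comms: list[list[str]] = []
    for c in range(n_communities):
        members = labels[c * community_size : (c + 1) * community_size]
        comms.append(members)
        first, last = members[0], members[-1]
        for node in members:
            g.add_node(
                node,
                community=c + 1,
                role="boundary" if node in (first, last) else "inner",
            )
        # complete within-community graph minus the boundary-boundary edge
        for u, v in itertools.combinations(members, 2):
            if {u, v} != {first, last}:
                g.add_edge(u, v)
    for c in range(n_communities):
        # last boundary of community c joins first boundary of community c+1
        g.add_edge(comms[c][-1], comms[(c + 1) % n_communities][0])

    if seed is None:
        stim = {node: node for node in labels}
    else:
        rng = np.random.default_rng(seed)
        pool = [f"stim{i:02d}" for i in range(stimulus_pool)]
        chosen = rng.choice(len(pool), size=n, replace=False)
        stim = {node: pool[i] for node, i in zip(labels, chosen)}
    return CommunityGraph(graph=g, stimulus=stim)


def random_walk(
    graph: CommunityGraph,
    length: int,
    start: str | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Uniform random walk of ``length`` trials over the graph."""
    if length < 1:
        raise ValueError("walk length must be >= 1")
    rng = np.random.default_rng(seed)
    if start is None:
        start = graph.nodes[rng.integers(len(graph.nodes))]
    if start not in graph.graph:
        raise ValueError(f"start node {start!r} not in graph")
    walk = [start]
    for _ in range(length - 1):
        nbrs = graph.neighbors(walk[-1])
        walk.append(nbrs[rng.integers(len(nbrs))])
    return walk


def pseudorandom_walk(
    graph: CommunityGraph,
    length: int,
    start: str | None = None,
    force_after: int = 9,
    seed: int | np.random.Generator | None = None,
    run_in: int = 1,
) -> list[str]:
    """Random walk with forced community exits.

    Once ``force_after`` consecutive same-community stimuli have occurred,
    the next time the walk sits on a boundary node it must take its
    between-community edge. The run counter resets to 1 on every community
    change, forced or spontaneous. ``run_in`` seeds the counter for the start
    node (1 when the walk begins fresh; pass the ongoing run length when
    continuing a longer sequence).
    """
    if length < 1:
        raise ValueError("walk length must be >= 1")
    rng = np.random.default_rng(seed)
    if start is None:
        start = graph.nodes[rng.integers(len(graph.nodes))]
    if start not in graph.graph:
        raise ValueError(f"start node {start!r} not in graph")
    walk = [start]
    run = run_in
    for _ in range(length - 1):
        cur = walk[-1]
        if (
            np.isfinite(force_after)
            and run >= force_after
            and graph.role(cur) == "boundary"
        ):
            nxt = graph.external_neighbor(cur)
        else:
            nbrs = graph.neighbors(cur)
            nxt = nbrs[rng.integers(len(nbrs))]
        run = run + 1 if graph.community(nxt) == graph.community(cur) else 1
        walk.append(nxt)
    return walk


def enumerate_hamiltonian_paths(graph: CommunityGraph, start: str) -> list[list[str]]:
    """Exhaustively enumerate all Hamiltonian paths starting at ``start`` (DFS)."""
    n = len(graph.nodes)
    paths: list[list[str]] = []
    stack = [(start, [start], {start})]
    while stack:
        node, path, seen = stack.pop()
        if len(path) == n:
            paths.append(path)
            continue
        for nbr in graph.neighbors(node):
            if nbr not in seen:
                stack.append((nbr, path + [nbr], seen | {nbr}))
    return paths


def hamiltonian_path(
    graph: CommunityGraph,
    start: str,
    path_pool_size: int = 15,
    seed: int | np.random.Generator | None = None,
    _pool_cache: dict | None = None,
) -> list[str]:
    """Draw a Hamiltonian path from a pre-generated pool of paths from ``start``.

    A pool of ``path_pool_size`` distinct Hamiltonian paths rooted at
    ``start`` is generated by randomized depth-first search and one is drawn
    uniformly. Raises ``ValueError`` if the graph admits no Hamiltonian path
    from ``start`` (callers fall back to another origin).
    """
    if start not in graph.graph:
        raise ValueError(f"start node {start!r} not in graph")
    rng = np.random.default_rng(seed)
    if _pool_cache is not None and start in _pool_cache:
        pool = _pool_cache[start]
    else:
        pool = _hamiltonian_pool(graph, start, path_pool_size, rng)
        if _pool_cache is not None:
            _pool_cache[start] = pool
    return list(pool[rng.integers(len(pool))])


def _hamiltonian_pool(
    graph: CommunityGraph, start: str, size: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    n = len(graph.nodes)
    found: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(200 * size):
        path = _random_dfs_path(graph, start, n, rng)
        if path is not None and path not in seen:
            seen.add(path)
            found.append(path)
            if len(found) >= size:
                break
    if not found:
        raise ValueError(f"no Hamiltonian path starts at node {start!r}")
    return found


def _random_dfs_path(
    graph: CommunityGraph, start: str, n: int, rng: np.random.Generator
) -> tuple[str, ...] | None:
    """One randomized DFS attempt at a Hamiltonian path; None on dead end."""
    path = [start]
    visited = {start}
    stack: list[list[str]] = []
    nbrs = graph.neighbors(start)
    rng.shuffle(nbrs)
    stack.append(nbrs)
    while stack:
        if len(path) == n:
            return tuple(path)
        options = stack[-1]
        advanced = False
        while options:
            nxt = options.pop()
            if nxt not in visited:
                path.append(nxt)
                visited.add(nxt)
                nn = [m for m in graph.neighbors(nxt) if m not in visited]
                rng.shuffle(nn)
                stack.append(nn)
                advanced = True
                break
        if not advanced:
            stack.pop()
            visited.discard(path.pop())
    return None


# ---------------------------------------------------------------------------
# Manipulation schedule and sequence builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManipulationSchedule:
    """Which community transition is manipulated in each 200-trial block.

    ``transitions[b]`` is the between-community edge (frozenset of the two
    boundary nodes) manipulated during block ``b``; ``swap_partners[b]`` maps
    each of those boundary nodes to the randomly chosen inner node of its own
    community whose stimulus it displays during the block (bidirectional
    swap). Partners are constant within a block.
    """

    block_length: int
    transitions: tuple[frozenset[str], ...]
    swap_partners: tuple[dict[str, str], ...]

    @property
    def n_blocks(self) -> int:
        return len(self.transitions)

    def block_of(self, trial_index: int) -> int:
        return trial_index // self.block_length

    def swap_map(self, block: int) -> dict[str, str]:
        """Node -> node whose stimulus it displays during ``block`` (both ways)."""
        partners = self.swap_partners[block]
        out = {}
        for boundary, inner in partners.items():
            out[boundary] = inner
            out[inner] = boundary
        return out


def build_schedule(
    graph: CommunityGraph,
    n_trials: int = 1200,
    block_length: int = 200,
    seed: int | np.random.Generator | None = None,
) -> ManipulationSchedule:
    """Cycle the three community transitions across 200-trial blocks.

    The cycle order is a random permutation of the three between-community
    edges, repeated so that over the default six blocks each transition is
    manipulated exactly twice. Swap partners are redrawn each block.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    edges = sorted(graph.between_edges(), key=sorted)
    order = list(rng.permutation(len(edges)))
    n_blocks = -(-n_trials // block_length)  # final block may be partial
    transitions = []
    partners = []
    for b in range(n_blocks):
        edge = edges[order[b % len(edges)]]
        transitions.append(edge)
        pmap = {}
        for boundary in sorted(edge):
            inner = graph.inner_nodes(graph.community(boundary))
            pmap[boundary] = inner[rng.integers(len(inner))]
        partners.append(pmap)
    return ManipulationSchedule(
        block_length=block_length,
        transitions=tuple(transitions),
        swap_partners=tuple(partners),
    )


def _trials_frame(
    nodes: list[str],
    phase: str,
    block_kind: list[str] | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "trial_index": np.arange(len(nodes)),
            "node": nodes,
            "phase": phase,
        }
    )
    df["block_kind"] = block_kind if block_kind is not None else "walk"
    df["onset_s"] = df["trial_index"] * STIMULUS_DURATION_S
    df["duration_s"] = STIMULUS_DURATION_S
    return df


def build_exposure_sequence(
    graph: CommunityGraph,
    n_trials: int = 1400,
    rotate_prob: float = 0.25,
    seed: int | np.random.Generator | None = None,
    start: str | None = None,
) -> pd.DataFrame:
    """Exposure-phase sequence: a random walk with rotated-stimulus probes.

    Each trial is independently flagged as rotated with probability
    ``rotate_prob`` (the orientation task used to hold attention during
    learning). Transition labels are ``learned_boundary`` for
    between-community steps and ``nonboundary`` otherwise.
    """
    rng = np.random.default_rng(seed)
    nodes = random_walk(graph, n_trials, start=start, seed=rng)
    df = _trials_frame(nodes, "exposure")
    df["block_200"] = -1
    df["rotated"] = rng.random(n_trials) < rotate_prob
    df["stimulus"] = [graph.stimulus[n] for n in nodes]
    df["manipulated"] = False
    df["transition_label"] = label_transitions(df, graph, schedule=None)
    return df


def build_parsing_sequence(
    graph: CommunityGraph,
    n_trials: int = 1200,
    block: int = 15,
    schedule: ManipulationSchedule | None = None,
    seed: int | np.random.Generator | None = None,
    force_after: int = 9,
    ham_origin: str = "neighbor",
    start: str | None = None,
) -> pd.DataFrame:
    """Parsing-phase sequence: alternating pseudorandom walks and Hamiltonian paths.

    ``n_trials`` must be divisible by ``2 * block``: the sequence alternates
    walk blocks of ``block`` trials with Hamiltonian blocks of ``block``
    trials (40 + 40 by default). Each Hamiltonian path originates from the
    final node of the preceding walk: with ``ham_origin="neighbor"`` (default)
    the path starts at a uniformly drawn graph neighbor of that node, so the
    junction is an ordinary edge and every block contributes ``block`` fresh
    trials; with ``ham_origin="shared"`` the path's first node is the walk's
    final node itself and is not re-displayed (the Hamiltonian block then
    contributes ``block - 1`` trials and the total is shorter).

    The boundary-swap manipulation of ``schedule`` (built by default) is
    applied and all transitions labeled.
    """
    if n_trials % (2 * block):
        raise ValueError("n_trials must be divisible by 2*block")
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = build_schedule(graph, n_trials=n_trials, seed=rng)
    if schedule.block_length * schedule.n_blocks < n_trials:
        raise ValueError("schedule does not cover n_trials")
    if ham_origin not in ("neighbor", "shared"):
        raise ValueError("ham_origin must be 'neighbor' or 'shared'")

    n_pairs = n_trials // (2 * block)
    pool_cache: dict = {}
    nodes: list[str] = []
    kinds: list[str] = []
    cur = start if start is not None else graph.nodes[rng.integers(len(graph.nodes))]
    for _ in range(n_pairs):
        # each walk block is its own pseudorandom-walk program: the
        # nine-stimulus counter starts fresh at the block's first stimulus
        walk = pseudorandom_walk(
            graph, block, start=cur, force_after=force_after, seed=rng, run_in=1
        )
        nodes.extend(walk)
        kinds.extend(["walk"] * block)
        wfinal = walk[-1]
        if ham_origin == "neighbor":
            nbrs = graph.neighbors(wfinal)
            origin = nbrs[rng.integers(len(nbrs))]
            path = hamiltonian_path(graph, origin, seed=rng, _pool_cache=pool_cache)
        else:
            path = hamiltonian_path(graph, wfinal, seed=rng, _pool_cache=pool_cache)[1:]
        nodes.extend(path)
        kinds.extend(["hamiltonian"] * len(path))
        cur_nbrs = graph.neighbors(nodes[-1])
        cur = cur_nbrs[rng.integers(len(cur_nbrs))]

    df = _trials_frame(nodes, "parsing", block_kind=kinds)
    df["block_200"] = df["trial_index"] // schedule.block_length
    df["rotated"] = False
    df = apply_boundary_swap(df, graph, schedule)
    df["transition_label"] = label_transitions(df, graph, schedule)
    return df


def apply_boundary_swap(
    trials: pd.DataFrame,
    graph: CommunityGraph,
    schedule: ManipulationSchedule | None,
) -> pd.DataFrame:
    """Assign displayed stimuli, swapping boundary/inner pairs per block.

    Within a manipulated block, each boundary node of the block's manipulated
    transition displays its inner partner's stimulus and the partner displays
    the boundary node's stimulus; all other node->stimulus mappings are the
    identity. ``manipulated`` flags trials whose displayed stimulus differs
    from the node's own.
    """
    df = trials.copy()
    if schedule is None:
        df["stimulus"] = [graph.stimulus[n] for n in df["node"]]
        df["manipulated"] = False
        return df
    for boundary, inner in (
        (b, i) for partners in schedule.swap_partners for b, i in partners.items()
    ):
        if graph.role(inner) != "inner" or graph.community(inner) != graph.community(boundary):
            raise ValueError(
                f"swap partner {inner!r} is not an inner node of {boundary!r}'s community"
            )
    stim = []
    manip = []
    for idx, node in zip(df["trial_index"], df["node"]):
        swap = schedule.swap_map(schedule.block_of(idx))
        shown = swap.get(node, node)
        stim.append(graph.stimulus[shown])
        manip.append(shown != node)
    df["stimulus"] = stim
    df["manipulated"] = manip
    return df


def label_transitions(
    trials: pd.DataFrame,
    graph: CommunityGraph,
    schedule: ManipulationSchedule | None = None,
) -> pd.Series:
    """Label the transition *into* each trial.

    Within-community steps are ``nonboundary``; between-community steps are
    ``novel_boundary`` when they cross the manipulated transition of the
    destination trial's 200-trial block, else ``learned_boundary``. The first
    trial has no incoming transition (empty label). Walk/Hamiltonian
    junctions are ordinary graph steps under the default origination rule and
    are labeled by the same criterion.
    """
    nodes = trials["node"].to_numpy()
    idx = trials["trial_index"].to_numpy()
    labels = [""]
    for i in range(1, len(nodes)):
        prev, cur = nodes[i - 1], nodes[i]
        if graph.community(prev) == graph.community(cur):
            labels.append(NONBOUNDARY)
            continue
        edge = frozenset((prev, cur))
        if schedule is not None:
            block = schedule.block_of(idx[i])
            if block < schedule.n_blocks and schedule.transitions[block] == edge:
                labels.append(NOVEL)
                continue
        labels.append(LEARNED)
    return pd.Series(labels, index=trials.index, name="transition_label")


def build_posttest(
    graph: CommunityGraph, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Forced-choice posttest: every ordered same-community (cue, target) pair.

    Each of the 15 stimuli appears as cue once with each of its four
    same-community members as target (60 trials); the lure is drawn from a
    different community. Trial order is randomized.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cue in graph.nodes:
        c = graph.community(cue)
        for target in graph.communities()[c]:
            if target == cue:
                continue
            others = [n for n in graph.nodes if graph.community(n) != c]
            lure = others[rng.integers(len(others))]
            rows.append(
                {
                    "cue": graph.stimulus[cue],
                    "target": graph.stimulus[target],
                    "lure": graph.stimulus[lure],
                    "cue_node": cue,
                    "target_node": target,
                    "lure_node": lure,
                    "cue_community": c,
                    "lure_community": graph.community(lure),
                }
            )
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=rng).reset_index(drop=True)


def break_schedule(phase: str) -> pd.DataFrame:
    """Self-paced break positions and their elapsed viewing time in minutes.

    Exposure breaks occur every 350 stimuli (~7.3 min of viewing at 1.25 s
    per stimulus); parsing breaks after 405 (~8.4 min) and a further 390
    stimuli (~8.1 min).
    """
    if phase == "exposure":
        counts = [EXPOSURE_BREAK_EVERY] * (1400 // EXPOSURE_BREAK_EVERY - 1)
    elif phase == "parsing":
        counts = list(PARSING_BREAKS_AFTER)
    else:
        raise ValueError("phase must be 'exposure' or 'parsing'")
    after = np.cumsum(counts)
    return pd.DataFrame(
        {
            "break_index": np.arange(1, len(counts) + 1),
            "after_trial": after,
            "stimuli_since_last": counts,
            "minutes_since_last": np.asarray(counts) * STIMULUS_DURATION_S / 60.0,
        }
    )


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "onset_s",
    "duration_s",
    "trial_index",
    "node",
    "stimulus",
    "phase",
    "block_kind",
    "block_200",
    "rotated",
    "transition_label",
    "manipulated",
]


def write_events_tsv(trials: pd.DataFrame, path) -> None:
    """Write a trial table as tab-separated events (BIDS-events-like columns)."""
    trials[_EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_graph(graph: CommunityGraph, path) -> None:
    """Write the graph as an edge list preceded by a community/role header."""
    with open(path, "w") as fh:
        header = {
            "community": {n: graph.community(n) for n in graph.nodes},
            "role": {n: graph.role(n) for n in graph.nodes},
            "stimulus": graph.stimulus,
        }
        fh.write("# " + json.dumps(header) + "\n")
        for u, v in sorted(map(sorted, graph.graph.edges)):
            fh.write(f"{u}\t{v}\n")
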