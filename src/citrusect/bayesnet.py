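"""Score-based Gaussian Bayesian-network structure learning.

Linear-Gaussian node models, a decomposable BIC score on the
higher-is-better scale, greedy hill climbing and tabu search over
add/delete/reverse moves under an arc blacklist, bootstrap model
averaging with per-arc strength and direction confidence, and a
thresholded consensus network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NetworkStructure",
    "trait_blacklist",
    "bic_score",
    "hill_climb",
    "tabu_search",
    "bootstrap_average",
    "averaged_network",
]


@dataclass
class NetworkStructure:
    """A DAG stored as per-node parent sets."""

    nodes: tuple[str, ...]
    parents: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node names must be unique")
        for n in self.nodes:
            self.parents.setdefault(n, frozenset())
        if self._has_cycle():
            raise ValueError("structure contains a cycle")

    @classmethod
    def empty(cls, nodes) -> "NetworkStructure":
        return cls(tuple(nodes))

    def arcs(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c in self.nodes for p in self.parents[c])

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(self.nodes, dict(self.parents))

    def _reaches(self, src: str, dst: str) -> bool:
        """True if dst is reachable from src following child arcs."""
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for c in self.nodes:
            for p in self.parents[c]:
                children[p].append(c)
        stack, seen = [src], set()
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            if u in seen:
                continue
            seen.add(u)
            stack.extend(children[u])
        return False

    def _has_cycle(self) -> bool:
        order: dict[str, int] = {}
        WHITE, GRAY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.nodes, WHITE)

        def visit(u: str) -> bool:
            color[u] = GRAY
            for p in self.parents[u]:
                if color[p] == GRAY or (color[p] == WHITE and visit(p)):
                    return True
            color[u] = BLACK
            return False

        return any(color[n] == WHITE and visit(n) for n in self.nodes)

    def can_add(self, u: str, v: str) -> bool:
        """Adding u -> v keeps the graph acyclic."""
        return u != v and u not in self.parents[v] and not self._reaches(v, u)

    def with_arc(self, u: str, v: str) -> "NetworkStructure":
        s = self.copy()
        s.parents[v] = self.parents[v] | {u}
        return s

    def without_arc(self, u: str, v: str) -> "NetworkStructure":
        s = self.copy()
        s.parents[v] = self.parents[v] - {u}
        return s

    def to_adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for p, c in self.arcs():
            adj[p].append(c)
        return adj


def trait_blacklist(nodes, traits) -> set[tuple[str, str]]:
    """Forbid every arc leading away from a trait toward another node."""
    traits = {traits} if isinstance(traits, str) else set(traits)
    return {(t, n) for t in traits for n in nodes if n != t and t in nodes}


# ---------------------------------------------------------------------------
# scoring


class _Scorer:
    """Cached per-node Gaussian BIC terms (higher is better)."""

    def __init__(self, data: pd.DataFrame):
        self.data = data.astype(float)
        self.n = len(data)
        self.cols = {c: self.data[c].to_numpy() for c in data.columns}
        self.cache: dict[tuple[str, frozenset], float] = {}

    def node_score(self, node: str, parents: frozenset[str]) -> float:
        key = (node, parents)
        if key in self.cache:
            return self.cache[key]
        y = self.cols[node]
        n = self.n
        if parents:
            X = np.column_stack([np.ones(n)] + [self.cols[p] for p in sorted(parents)])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                self.cache[key] = -np.inf
                return -np.inf
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:
            resid = y - y.mean()
        s2 = float(resid @ resid) / n
        if s2 <= 0:
            self.cache[key] = -np.inf
            return -np.inf
        ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
        k = len(parents) + 2  # coefficients + intercept + variance
        val = ll - 0.5 * k * np.log(n)
        self.cache[key] = val
        return val

    def total(self, structure: NetworkStructure) -> float:
        return sum(self.node_score(v, structure.parents[v]) for v in structure.nodes)


def bic_score(structure: NetworkStructure, data: pd.DataFrame) -> float:
    """Decomposable Gaussian BIC of a structure; higher is better.

    Sum over nodes of the node's Gaussian log-likelihood given its parents
    minus (parameters / 2) * log n.
    """
    missing = [n for n in structure.nodes if n not in data.columns]
    if missing:
        raise KeyError(f"data lacks columns for nodes: {missing}")
    max_parents = max((len(structure.parents[v]) for v in structure.nodes), default=0)
    if len(data) <= max_parents + 1:
        raise ValueError("need n > max parent-set size + 1")
    return _Scorer(data).total(structure)


# ---------------------------------------------------------------------------
# search


def _legal_moves(s: NetworkStructure, blacklist: set[tuple[str, str]]):
    """All admissible (kind, u, v) moves in deterministic lexicographic order."""
    moves = []
    for u in s.nodes:
        for v in s.nodes:
            if u == v:
                continue
            if u in s.parents[v]:
                moves.append(("delete", u, v))
                if (v, u) not in blacklist and not s.without_arc(u, v)._reaches(u, v):
                    moves.append(("reverse", u, v))
            elif (u, v) not in blacklist and s.can_add(u, v):
                moves.append(("add", u, v))
    return sorted(moves)


def _move_delta(scorer: _Scorer, s: NetworkStructure, move) -> float:
    kind, u, v = move
    if kind == "add":
        return scorer.node_score(v, s.parents[v] | {u}) - scorer.node_score(v, s.parents[v])
    if kind == "delete":
        return scorer.node_score(v, s.parents[v] - {u}) - scorer.node_score(v, s.parents[v])
    # reverse u -> v into v -> u
    return (
        scorer.node_score(v, s.parents[v] - {u})
        - scorer.node_score(v, s.parents[v])
        + scorer.node_score(u, s.parents[u] | {v})
        - scorer.node_score(u, s.parents[u])
    )


def _apply(s: NetworkStructure, move) -> NetworkStructure:
    kind, u, v = move
    if kind == "add":
        return s.with_arc(u, v)
    if kind == "delete":
        return s.without_arc(u, v)
    return s.without_arc(u, v).with_arc(v, u)


def hill_climb(
    data: pd.DataFrame,
    blacklist: set[tuple[str, str]] | None = None,
    restarts: int = 1,
    rng: np.random.Generator | None = None,
    start: NetworkStructure | None = None,
) -> NetworkStructure:
    """Greedy BIC search from the empty graph over add/delete/reverse moves.

    Ties between equal-scoring moves break lexicographically so runs are
    deterministic; extra ``restarts`` begin from random blacklist-respecting
    graphs (seeded) and the best-scoring result is returned.
    """
    blacklist = blacklist or set()
    scorer = _Scorer(data)
    tie_rng = np.random.default_rng(rng) if rng is not None else None
    rng = np.random.default_rng(rng)
    nodes = tuple(data.columns)

    # Gaussian BIC is score-equivalent under single-arc reversal, so exact
    # ties are real; with an rng they break at random (deterministic under
    # seed), otherwise lexicographically.
    def climb(s: NetworkStructure) -> NetworkStructure:
        while True:
            best_delta, tied = 1e-10, []
            for move in _legal_moves(s, blacklist):
                d = _move_delta(scorer, s, move)
                if d > best_delta + 1e-9:
                    best_delta, tied = d, [move]
                elif tied and abs(d - best_delta) <= 1e-9:
                    tied.append(move)
            if not tied:
                return s
            if tie_rng is not None and len(tied) > 1:
                move = tied[int(tie_rng.integers(len(tied)))]
            else:
                move = tied[0]
            s = _apply(s, move)

    best = climb(start if start is not None else NetworkStructure.empty(nodes))
    best_score = scorer.total(best)
    for _ in range(max(restarts - 1, 0)):
        s = NetworkStructure.empty(nodes)
        for _ in range(len(nodes)):
            u, v = rng.choice(nodes, size=2, replace=False)
            if (u, v) not in blacklist and s.can_add(u, v):
                s = s.with_arc(u, v)
        cand = climb(s)
        if scorer.total(cand) > best_score:
            best, best_score = cand, scorer.total(cand)
    return best


def tabu_search(
    data: pd.DataFrame,
    blacklist: set[tuple[str, str]] | None = None,
    tabu_length: int = 10,
    max_stagnation: int = 10,
) -> NetworkStructure:
    """Hill climbing that may take non-improving moves while forbidding the
    reversal of recent moves; returns the best structure encountered."""
    blacklist = blacklist or set()
    scorer = _Scorer(data)
    s = NetworkStructure.empty(tuple(data.columns))
    best, best_score = s, scorer.total(s)
    current_score = best_score
    tabu: list[tuple] = []
    stagnation = 0

    _inverse = {"add": "delete", "delete": "add", "reverse": "reverse"}

    while True:
        candidates = []
        for move in _legal_moves(s, blacklist):
            kind, u, v = move
            sig = (kind, u, v)
            d = _move_delta(scorer, s, move)
            aspiration = current_score + d > best_score + 1e-10
            if sig in tabu and not aspiration:
                continue
            candidates.append((d, move))
        if not candidates:
            break
        d, move = max(candidates, key=lambda t: (t[0], tuple(map(str, t[1]))))
        if d <= 1e-10:
            if stagnation >= max_stagnation:
                break
            stagnation += 1
        s = _apply(s, move)
        current_score += d
        kind, u, v = move
        tabu.append((_inverse[kind], u, v) if kind != "reverse" else ("reverse", v, u))
        if tabu_length > 0:
            tabu = tabu[-tabu_length:]
        else:
            tabu = []
        if current_score > best_score + 1e-10:
            best, best_score = s, current_score
            stagnation = 0
    return best


# ---------------------------------------------------------------------------
# bootstrap averaging


def bootstrap_average(
    data: pd.DataFrame,
    algorithm: str = "hc",
    replicates: int = 5000,
    blacklist: set[tuple[str, str]] | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 10,
    structure_hook=None,
    **algo_kwargs,
) -> tuple[pd.DataFrame, int]:
    """Model averaging over bootstrap resamples.

    Strength of the undirected arc {u, v} is the fraction of replicates
    whose learned structure contains it in either direction; the direction
    confidence of u -> v is the fraction of those containing that
    orientation.  ``structure_hook`` (if given) is called with every
    accepted replicate structure, e.g. to audit blacklist compliance.
    Returns (arc table, number of retried replicates).
    """
    if algorithm not in ("hc", "tabu"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    rng = np.random.default_rng(rng)
    blacklist = blacklist or set()
    n = len(data)
    directed: dict[tuple[str, str], int] = {}
    failures = 0
    done = 0
    while done < replicates:
        idx = rng.integers(0, n, n)
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            if algorithm == "hc":
                s = hill_climb(boot, blacklist=blacklist,
                               rng=rng.integers(0, 2**31 - 1), **algo_kwargs)
            else:
                s = tabu_search(boot, blacklist=blacklist, **algo_kwargs)
        except Exception:
            failures += 1
            if failures > max_retries * replicates:
                raise
            continue
        if structure_hook is not None:
            structure_hook(s)
        for arc in s.arcs():
            directed[arc] = directed.get(arc, 0) + 1
        done += 1

    rows = []
    undirected: dict[frozenset, int] = {}
    for (u, v), c in directed.items():
        undirected[frozenset((u, v))] = undirected.get(frozenset((u, v)), 0) + c
    for (u, v), c in sorted(directed.items()):
        both = undirected[frozenset((u, v))]
        rows.append(
            {
                "from": u,
                "to": v,
                "strength": both / replicates,
                "direction_confidence": c / both,
            }
        )
    return pd.DataFrame(rows, columns=["from", "to", "strength", "direction_confidence"]), failures


def averaged_network(
    arcs: pd.DataFrame, threshold: float = 0.5
) -> NetworkStructure:
    """Threshold bootstrap strengths into a consensus DAG.

    Keeps undirected arcs with strength >= threshold, orients each by its
    majority direction, and breaks any residual cycle by removing the
    weakest arc in it.
    """
    import networkx as nx

    nodes = sorted(set(arcs["from"]) | set(arcs["to"])) if len(arcs) else ()
    chosen: dict[frozenset, tuple[str, str, float, float]] = {}
    for _, row in arcs.iterrows():
        key = frozenset((row["from"], row["to"]))
        if row["strength"] < threshold:
            continue
        cur = chosen.get(key)
        cand = (row["from"], row["to"], float(row["strength"]),
                float(row["direction_confidence"]))
        if cur is None or cand[3] > cur[3] or (cand[3] == cur[3] and (cand[0], cand[1]) < (cur[0], cur[1])):
            chosen[key] = cand
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v, s, d in chosen.values():
        g.add_edge(u, v, weight=s * d)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: g.edges[e[0], e[1]]["weight"])
        g.remove_edge(weakest[0], weakest[1])
    parents = {n: frozenset(g.predecessors(n)) for n in nodes}
    return NetworkStructure(tuple(nodes), parents)
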