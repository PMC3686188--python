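"""Dispersal-extinction-cladogenesis (DEC) ancestral range reconstruction.

The model is a continuous-time Markov chain on the nonempty subsets of a
small set of biogeographic areas.  Anagenetic moves are single-area gains
(dispersal, rate d per occupied-source x target pair, so S -> S ∪ {j} at
rate d·|S|) and single-area losses (local extinction, rate e per occupied
area; single-area ranges cannot be lost, keeping the chain on nonempty
subsets).  At each speciation event the ancestral range is partitioned
between the daughters by a cladogenesis scenario: identity inheritance for
single-area ranges, and for multi-area ranges either vicariance (one
daughter takes one area, the other the complement) or subset speciation
(one daughter takes one area, the other keeps the full range), all
scenarios equally weighted.

Likelihood uses Felsenstein pruning with dense matrix exponentials; the
state spaces involved (<= 8 areas, 255 states) stay comfortably dense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from rangearc.phylo_io import DatedTree

__all__ = [
    "AreaCoding",
    "DecModel",
    "SplitReconstruction",
    "build_state_space",
    "build_rate_matrix",
    "cladogenesis_events",
    "tree_likelihood",
    "tree_likelihood_bruteforce",
    "fit_dec",
    "ancestral_splits",
    "read_coding_tsv",
    "write_coding_tsv",
]

RATE_BOUNDS = (1e-8, 10.0)
_GRID_STARTS = [0.001, 0.01, 0.1]


def build_state_space(areas: list[str]) -> tuple[list[frozenset], dict]:
    """All nonempty subsets of ``areas``, ordered by size then lexicographic.

    Returns the state list and a state -> index map.
    """
    if not 1 <= len(areas) <= 8:
        raise ValueError("need between 1 and 8 areas")
    if len(set(areas)) != len(areas):
        raise ValueError("duplicate area codes")
    order = {a: i for i, a in enumerate(areas)}
    states: list[frozenset] = []
    for size in range(1, len(areas) + 1):
        subsets = [
            frozenset(combo)
            for combo in _combinations_sorted(areas, size)
        ]
        subsets.sort(key=lambda s: tuple(sorted(order[a] for a in s)))
        states.extend(subsets)
    return states, {s: i for i, s in enumerate(states)}


def _combinations_sorted(areas, size):
    from itertools import combinations

    return combinations(areas, size)


def state_label(state: frozenset, areas: list[str]) -> str:
    return "".join(a for a in areas if a in state)


@dataclass
class AreaCoding:
    """Presence/absence of each tip taxon over a named, ordered area set."""

    areas: list[str]
    tips: dict[str, tuple[int, ...]]

    def __post_init__(self):
        k = len(self.areas)
        if len(set(self.areas)) != k:
            raise ValueError("duplicate area codes")
        for taxon, vec in self.tips.items():
            vec = tuple(int(v) for v in vec)
            if len(vec) != k:
                raise ValueError(f"tip {taxon!r}: coding length != {k} areas")
            if not any(vec):
                raise ValueError(f"tip {taxon!r} occupies no area")
            if any(v not in (0, 1) for v in vec):
                raise ValueError(f"tip {taxon!r}: coding must be 0/1")
            self.tips[taxon] = vec

    def state_of(self, taxon: str) -> frozenset:
        vec = self.tips[taxon]
        return frozenset(a for a, v in zip(self.areas, vec) if v)


@dataclass
class DecModel:
    """A DEC model: areas, dispersal/extinction rates, state space, Q."""

    areas: list[str]
    d: float
    e: float
    root_prior: np.ndarray | None = None
    states: list[frozenset] = field(init=False, repr=False)
    index: dict = field(init=False, repr=False)
    Q: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")
        self.states, self.index = build_state_space(self.areas)
        self.Q = build_rate_matrix(self)
        if self.root_prior is None:
            self.root_prior = np.full(len(self.states), 1.0 / len(self.states))
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if self.root_prior.shape != (len(self.states),):
                raise ValueError("root prior length != number of states")
        self._events = _event_table(self.states, self.index)


def build_rate_matrix(m: DecModel) -> np.ndarray:
    """Instantaneous rate matrix over nonempty area subsets.

    Q[S, S ∪ {j}] = d·|S| for j outside S (any occupied area can seed the
    new one, uniform dispersal multipliers); Q[S, S \\ {j}] = e for j in S
    when |S| > 1.  Rows sum to zero.
    """
    if m.d < 0 or m.e < 0:
        raise ValueError("rates must be non-negative")
    states, index = build_state_space(m.areas)
    n = len(states)
    Q = np.zeros((n, n))
    all_areas = set(m.areas)
    for i, S in enumerate(states):
        for j in all_areas - S:
            Q[i, index[S | {j}]] += m.d * len(S)
        if len(S) > 1:
            for j in S:
                Q[i, index[S - {j}]] += m.e
        Q[i, i] = -Q[i].sum()
    return Q


def cladogenesis_events(state: frozenset) -> list[tuple[frozenset, frozenset, float]]:
    """Legal daughter-range pairs for an ancestral range, with weights.

    Single-area {A}: the one event ({A}, {A}).  Multi-area S: vicariance
    ({a}, S-{a}) and subset speciation ({a}, S) for every a in S, each in
    both daughter orders; weights uniform over the enumerated events.
    """
    if not state:
        raise ValueError("empty ancestral range")
    if len(state) == 1:
        return [(state, state, 1.0)]
    events: dict[tuple[frozenset, frozenset], None] = {}
    for a in sorted(state):
        single = frozenset({a})
        rest = state - single
        # for a 2-area range the two vicariance orders coincide across the
        # two choices of a; the dict keeps each ordered pair once
        events[(single, rest)] = None
        events[(rest, single)] = None
        events[(single, state)] = None
        events[(state, single)] = None
    w = 1.0 / len(events)
    return [(l, r, w) for l, r in events]


def _event_table(states, index) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flattened (ancestor, left, right, weight) index arrays over all states."""
    i_s, i_l, i_r, ws = [], [], [], []
    for i, S in enumerate(states):
        for L, R, w in cladogenesis_events(S):
            i_s.append(i)
            i_l.append(index[L])
            i_r.append(index[R])
            ws.append(w)
    return (
        np.array(i_s, dtype=np.intp),
        np.array(i_l, dtype=np.intp),
        np.array(i_r, dtype=np.intp),
        np.array(ws, dtype=float),
    )


def _tip_partial(model: DecModel, state: frozenset) -> np.ndarray:
    v = np.zeros(len(model.states))
    v[model.index[state]] = 1.0
    return v


def _branch_matrices(tree: DatedTree, model: DecModel) -> dict:
    """Transition matrix expm(Q t) for every non-root edge, cached by node."""
    mats = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None:
            mats[node] = expm(model.Q * node.edge.length)
    return mats


def _postorder_partials(
    tree: DatedTree, coding: AreaCoding, model: DecModel, mats: dict
) -> dict:
    """Conditional likelihood of the subtree below each node, by node state.

    For a tip the partial is the indicator of the coded range; for an
    internal node it sums over cladogenesis events of the product of the
    daughters' branch-propagated partials.
    """
    partials: dict = {}
    for node in tree.tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            taxon = node.taxon.label
            if taxon not in coding.tips:
                raise KeyError(f"tip {taxon!r} has no area coding")
            partials[node] = _tip_partial(model, coding.state_of(taxon))
            continue
        left, right = kids
        dl = mats[left] @ partials[left]
        dr = mats[right] @ partials[right]
        i_s, i_l, i_r, w = model._events
        v = np.zeros(len(model.states))
        np.add.at(v, i_s, w * dl[i_l] * dr[i_r])
        partials[node] = v
    return partials


def tree_likelihood(
    tree: DatedTree, coding: AreaCoding, model: DecModel
) -> float:
    """Log-likelihood of the tip area codings under the DEC model."""
    mats = _branch_matrices(tree, model)
    partials = _postorder_partials(tree, coding, model, mats)
    lik = float(model.root_prior @ partials[tree.tree.seed_node])
    if lik <= 0:
        return -math.inf
    return math.log(lik)


def tree_likelihood_bruteforce(
    tree: DatedTree, coding: AreaCoding, model: DecModel
) -> float:
    """Exhaustive-enumeration log-likelihood (oracle for tiny problems).

    Sums the joint probability over every explicit assignment of an
    ancestral range and a cladogenesis event to every internal node,
    multiplying branch transition probabilities from each daughter's
    inherited range to the state at the bottom of that branch.  Exponential
    in tree size; intended for <= 4 tips and <= 3 areas.
    """
    mats = _branch_matrices(tree, model)
    internals = [n for n in tree.tree.preorder_node_iter() if n.child_nodes()]
    choices = []
    for node in internals:
        node_choices = []
        for S in model.states:
            for L, R, w in cladogenesis_events(S):
                node_choices.append((S, L, R, w))
        choices.append(node_choices)
    total = 0.0
    for assignment in product(*choices):
        by_node = dict(zip(internals, assignment))
        prob = float(model.root_prior[model.index[by_node[internals[0]][0]]])
        for node, (S, L, R, w) in by_node.items():
            prob *= w
            for child, inherited in zip(node.child_nodes(), (L, R)):
                P = mats[child]
                if child.child_nodes():
                    S_child = by_node[child][0]
                    prob *= P[model.index[inherited], model.index[S_child]]
                else:
                    tip_state = coding.state_of(child.taxon.label)
                    prob *= P[model.index[inherited], model.index[tip_state]]
            if prob == 0.0:
                break
        total += prob
    if total <= 0:
        return -math.inf
    return math.log(total)


def fit_dec(
    tree: DatedTree,
    coding: AreaCoding,
    root_prior: np.ndarray | None = None,
    bounds: tuple[float, float] = RATE_BOUNDS,
) -> DecModel:
    """Maximum-likelihood dispersal and extinction rates.

    Screens a 3x3 log-spaced grid of (d, e) starts plus the default
    (0.01, 0.01), then runs L-BFGS-B in log-rate space from the best start.
    Flat likelihood surfaces (e.g. all tips identical single-area) return
    the boundary estimate the optimizer reaches, with a warning flag in
    ``fit_info``.
    """
    areas = coding.areas
    lo, hi = bounds

    def nll(log_rates):
        d, e = np.exp(log_rates)
        model = DecModel(areas, d, e, root_prior=root_prior)
        ll = tree_likelihood(tree, coding, model)
        return -ll if math.isfinite(ll) else 1e10

    starts = [(0.01, 0.01)] + [
        (d0, e0) for d0 in _GRID_STARTS for e0 in _GRID_STARTS
    ]
    start_vals = [(nll(np.log(s)), s) for s in starts]
    start_vals.sort(key=lambda t: t[0])
    best_start = start_vals[0][1]
    res = minimize(
        nll,
        np.log(best_start),
        method="L-BFGS-B",
        bounds=[(math.log(lo), math.log(hi))] * 2,
    )
    d_hat, e_hat = (float(v) for v in np.exp(res.x))
    # flat directions (e.g. all tips identical single-area: d unidentified)
    # are snapped to the boundary and flagged rather than left wherever the
    # optimizer stalled
    at_bound = False
    snapped = [d_hat, e_hat]
    for i in range(2):
        for bound in (lo, hi):
            trial = list(res.x)
            trial[i] = math.log(bound)
            if nll(np.array(trial)) <= res.fun + 1e-9:
                snapped[i] = bound
                at_bound = True
                break
    d_hat, e_hat = snapped
    model = DecModel(areas, d_hat, e_hat, root_prior=root_prior)
    model.fit_info = {
        "log_likelihood": -float(nll(np.log(snapped))),
        "converged": bool(res.success),
        "at_bound": at_bound,
        "n_starts": len(starts),
    }
    return model


@dataclass
class SplitReconstruction:
    """Ranked cladogenesis scenarios per internal node.

    ``scenarios[node_id]`` is a list of (left_range, right_range, relative
    likelihood) sorted by decreasing likelihood (ties broken by canonical
    state order and flagged); relative likelihoods sum to 1 per node.
    """

    areas: list[str]
    scenarios: dict[str, list[tuple[frozenset, frozenset, float]]]
    ties: dict[str, bool]

    def top(self, node_id: str) -> tuple[frozenset, frozenset, float]:
        return self.scenarios[node_id][0]

    def slash_label(self, node_id: str) -> str:
        """Fig-style "X/Y" label: upper daughter's range / lower daughter's."""
        L, R, _ = self.top(node_id)
        return f"{state_label(L, self.areas)}/{state_label(R, self.areas)}"


def ancestral_splits(
    tree: DatedTree,
    coding: AreaCoding,
    model: DecModel,
    node_ids: dict | None = None,
) -> SplitReconstruction:
    """Marginal relative likelihood of every split scenario at every node.

    For node v and scenario (S; L, R): the scenario's likelihood is the
    outside likelihood of range S at v times the event weight times the
    branch-propagated partials of the daughters restricted to L and R,
    marginalizing over all other nodes.  Computed with an outside (preorder)
    pass over the pruning partials; per node the scenario likelihoods are
    normalized to sum to 1.
    """
    mats = _branch_matrices(tree, model)
    partials = _postorder_partials(tree, coding, model, mats)
    n = len(model.states)

    # outside[v][S]: likelihood of data outside v's subtree, v in range S
    outside: dict = {tree.tree.seed_node: np.asarray(model.root_prior)}
    for node in tree.tree.preorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            continue
        left, right = kids
        dl = mats[left] @ partials[left]
        dr = mats[right] @ partials[right]
        i_s, i_l, i_r, w = model._events
        out_v = outside[node]
        contrib_l = np.zeros(n)  # by left-inherited range
        contrib_r = np.zeros(n)
        np.add.at(contrib_l, i_l, out_v[i_s] * w * dr[i_r])
        np.add.at(contrib_r, i_r, out_v[i_s] * w * dl[i_l])
        outside[left] = mats[left].T @ contrib_l
        outside[right] = mats[right].T @ contrib_r

    internals = [nd for nd in tree.tree.preorder_node_iter() if nd.child_nodes()]
    ages = {nd: tree.ages[nd] for nd in internals}
    internals.sort(
        key=lambda nd: (
            -ages[nd],
            str(sorted(leaf.taxon.label for leaf in nd.leaf_iter())),
        )
    )
    if node_ids is None:
        node_ids = {nd: (nd.label or f"n{i}") for i, nd in enumerate(internals)}

    order = {s: i for i, s in enumerate(model.states)}
    scenarios: dict[str, list] = {}
    ties: dict[str, bool] = {}
    for nd in internals:
        left, right = nd.child_nodes()
        dl = mats[left] @ partials[left]
        dr = mats[right] @ partials[right]
        out_v = outside[nd]
        rows = []
        for i, S in enumerate(model.states):
            if out_v[i] == 0.0:
                continue
            for L, R, w in cladogenesis_events(S):
                lik = out_v[i] * w * dl[model.index[L]] * dr[model.index[R]]
                if lik > 0:
                    rows.append((L, R, lik))
        total = sum(r[2] for r in rows)
        if total <= 0:
            raise ValueError(f"node {node_ids[nd]!r}: zero marginal likelihood")
        merged: dict[tuple, float] = {}
        for L, R, lik in rows:
            key = (order[L], order[R])
            merged[key] = merged.get(key, 0.0) + lik / total
        ranked = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
        scenarios[node_ids[nd]] = [
            (model.states[l], model.states[r], p) for (l, r), p in ranked
        ]
        ties[node_ids[nd]] = (
            len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) < 1e-12
        )
    return SplitReconstruction(model.areas, scenarios, ties)


def read_coding_tsv(path) -> AreaCoding:
    """Read a tip coding table: column taxon_id then one 0/1 column per area."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if header[0] != "taxon_id":
        raise ValueError("first column must be 'taxon_id'")
    areas = header[1:]
    tips = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        tips[parts[0]] = tuple(int(v) for v in parts[1:])
    return AreaCoding(areas, tips)


def write_coding_tsv(coding: AreaCoding, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\t" + "\t".join(coding.areas) + "\n")
        for taxon in sorted(coding.tips):
            fh.write(taxon + "\t" + "\t".join(map(str, coding.tips[taxon])) + "\n")
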