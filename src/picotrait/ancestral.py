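"""Ancestral history of a binary trait: weighted parsimony and Mk likelihood.

The trait is a two-state character (absent = 0, present = 1) evolving on a
rooted phylogeny.  Two inference routes are provided:

* :func:`sankoff_parsimony` — minimum-cost reconstruction under arbitrary
  gain (0→1) and loss (1→0) costs, reporting *every* state achieving the
  minimum at each node rather than breaking ties arbitrarily.
* :func:`mk_loglik` / :func:`fit_mk` / :func:`mk_marginal_ancestral_states`
  — the continuous-time Mk model, either symmetric (one rate, "Mk1") or
  asymmetric with separate gain rate ``q01`` and loss rate ``q10`` ("Mk2").
  Transition probabilities use the closed form for a 2-state chain, so no
  matrix exponentials are needed, and the pruning pass runs in plain floats.

Nested model comparison goes through :func:`likelihood_ratio_test`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .io import CharacterMatrix

__all__ = [
    "MkModel",
    "ParsimonyCosts",
    "AncestralReconstruction",
    "LrtResult",
    "sankoff_parsimony",
    "mk_loglik",
    "fit_mk",
    "mk_marginal_ancestral_states",
    "likelihood_ratio_test",
]

_INF = float("inf")


@dataclass
class MkModel:
    """Two-state Markov model with gain rate ``q01`` and loss rate ``q10``.

    Rates are events per unit branch length.  ``symmetric=True`` asserts
    ``q01 == q10`` (the one-parameter Mk1 model).
    """

    q01: float
    q10: float
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be >= 0")
        if self.symmetric and self.q01 != self.q10:
            raise ValueError("symmetric model requires q01 == q10")

    @property
    def stationary(self) -> tuple[float, float]:
        q = self.q01 + self.q10
        if q == 0:
            return (0.5, 0.5)
        return (self.q10 / q, self.q01 / q)


@dataclass
class ParsimonyCosts:
    cost_gain: float  # 0 -> 1
    cost_loss: float  # 1 -> 0

    def __post_init__(self) -> None:
        if not (self.cost_gain > 0 and math.isfinite(self.cost_gain)):
            raise ValueError("cost_gain must be finite and > 0")
        if not (self.cost_loss > 0 and math.isfinite(self.cost_loss)):
            raise ValueError("cost_loss must be finite and > 0")


@dataclass
class AncestralReconstruction:
    """Per-node reconstruction plus the objective it optimizes.

    ``node_states`` maps a dendropy node to either a frozenset of optimal
    states (parsimony) or a ``(p0, p1)`` marginal probability pair (ML).
    ``score`` is the minimum total cost (parsimony) or the log-likelihood.
    """

    node_states: dict = field(repr=False)
    score: float
    method: str = "parsimony"

    def states_by_label(self) -> dict[str, object]:
        out = {}
        for node, val in self.node_states.items():
            label = node.taxon.label if node.taxon else (node.label or f"node{id(node)}")
            out[label] = val
        return out


@dataclass
class LrtResult:
    lnl_null: float
    lnl_alt: float
    statistic: float
    df: int
    p: float


def _check_leaves(tree: dendropy.Tree, chars: CharacterMatrix) -> None:
    missing = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label not in chars.taxa
    ]
    if missing:
        raise ValueError(f"tree leaves absent from character matrix: {sorted(missing)}")


def sankoff_parsimony(
    tree: dendropy.Tree, chars: CharacterMatrix, costs: ParsimonyCosts
) -> AncestralReconstruction:
    """Weighted (Sankoff) parsimony for a binary character.

    Every leaf of ``tree`` must appear in ``chars``; leaves with missing state
    contribute zero cost for either assignment.  The result reports, per node,
    the full set of states attainable in *some* minimum-cost reconstruction.
    """
    _check_leaves(tree, chars)

    def edge_cost(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return costs.cost_gain if (i, j) == (0, 1) else costs.cost_loss

    # Bottom-up: S[v][s] = min cost of the subtree at v given v has state s.
    S: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = chars.state(node.taxon.label)
            if state is None:
                S[node] = [0.0, 0.0]
            else:
                S[node] = [0.0 if state == s else _INF for s in (0, 1)]
        else:
            tot = [0.0, 0.0]
            for child in node.child_nodes():
                for s in (0, 1):
                    tot[s] += min(edge_cost(s, t) + S[child][t] for t in (0, 1))
            S[node] = tot

    root = tree.seed_node
    best = min(S[root])

    # Top-down: T[v][s] = min cost of everything outside v's subtree given
    # v has state s; optimal states at v are argmin over S[v][s] + T[v][s].
    T: dict = {root: [0.0, 0.0]}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            sib_cost = [0.0, 0.0]
            for s in (0, 1):
                for sib in children:
                    if sib is not child:
                        sib_cost[s] += min(
                            edge_cost(s, t) + S[sib][t] for t in (0, 1)
                        )
            T[child] = [
                min(
                    T[node][s] + sib_cost[s] + edge_cost(s, t)
                    for s in (0, 1)
                )
                for t in (0, 1)
            ]

    node_states = {}
    for node in tree.preorder_node_iter():
        totals = [S[node][s] + T[node][s] for s in (0, 1)]
        node_states[node] = frozenset(
            s for s in (0, 1) if totals[s] <= best + 1e-9
        )
    return AncestralReconstruction(node_states=node_states, score=best, method="parsimony")


def _p_stay_leave(q01: float, q10: float, t: float) -> tuple[float, float, float, float]:
    """Closed-form 2x2 transition probabilities (P00, P01, P10, P11)."""
    q = q01 + q10
    if q == 0.0:
        return 1.0, 0.0, 0.0, 1.0
    e = math.exp(-q * t)
    pi0 = q10 / q
    pi1 = q01 / q
    return (
        pi0 + pi1 * e,
        pi1 * (1.0 - e),
        pi0 * (1.0 - e),
        pi1 + pi0 * e,
    )


def _postorder_plan(tree: dendropy.Tree):
    """Flatten the tree once so repeated likelihood passes avoid traversal."""
    nodes = list(tree.postorder_node_iter())
    index = {node: k for k, node in enumerate(nodes)}
    plan = []
    for k, node in enumerate(nodes):
        if node.is_leaf():
            plan.append((k, node.taxon.label, None))
        else:
            children = [
                (index[c], c.edge.length or 0.0) for c in node.child_nodes()
            ]
            plan.append((k, None, children))
    return plan


def _root_prior(model: MkModel, root_prior: str) -> tuple[float, float]:
    if root_prior == "equal":
        return (0.5, 0.5)
    if root_prior == "stationary":
        return model.stationary
    raise ValueError("root_prior must be 'equal' or 'stationary'")


def mk_loglik(
    tree: dendropy.Tree,
    chars: CharacterMatrix,
    model: MkModel,
    root_prior: str = "equal",
    _plan=None,
) -> float:
    """Felsenstein pruning log-likelihood of the tip states under ``model``.

    Missing tips carry flat partial likelihoods (1, 1) — they are retained,
    not dropped.  Branch lengths must be non-negative.
    """
    _check_leaves(tree, chars)
    if model.q01 == 0.0 and model.q10 == 0.0:
        raise ValueError("rates must not both be zero")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    plan = _plan if _plan is not None else _postorder_plan(tree)
    q01, q10 = model.q01, model.q10

    L0 = [0.0] * len(plan)
    L1 = [0.0] * len(plan)
    log_scale = 0.0
    for k, leaf_label, children in plan:
        if children is None:
            state = chars.state(leaf_label)
            if state is None:
                L0[k], L1[k] = 1.0, 1.0
            elif state == 0:
                L0[k], L1[k] = 1.0, 0.0
            else:
                L0[k], L1[k] = 0.0, 1.0
        else:
            a0, a1 = 1.0, 1.0
            for ck, t in children:
                p00, p01, p10, p11 = _p_stay_leave(q01, q10, t)
                c0, c1 = L0[ck], L1[ck]
                a0 *= p00 * c0 + p01 * c1
                a1 *= p10 * c0 + p11 * c1
            scale = a0 if a0 > a1 else a1
            if scale <= 0.0:
                return -_INF
            L0[k], L1[k] = a0 / scale, a1 / scale
            log_scale += math.log(scale)

    prior0, prior1 = _root_prior(model, root_prior)
    root_like = prior0 * L0[-1] + prior1 * L1[-1]
    if root_like <= 0.0:
        return -_INF
    return math.log(root_like) + log_scale


_GRID = [1e-4, 3e-3, 1e-1, 3e0, 1e3]  # 5x5 start grid in rate space
_BOUNDS = (math.log(1e-6), math.log(1e4))


def fit_mk(
    tree: dendropy.Tree,
    chars: CharacterMatrix,
    symmetric: bool = False,
    root_prior: str = "equal",
) -> tuple[MkModel, float]:
    """Maximum-likelihood Mk rates by bounded multi-start optimization.

    Searches in log-rate space from a fixed 5x5 grid (5 points when
    symmetric), refining the best starts with L-BFGS-B to an lnL tolerance
    of 1e-8.  Deterministic for a given input.
    """
    plan = _postorder_plan(tree)

    def negloglik(logrates) -> float:
        if symmetric:
            r = math.exp(logrates[0])
            model = MkModel(r, r, symmetric=True)
        else:
            model = MkModel(math.exp(logrates[0]), math.exp(logrates[1]))
        ll = mk_loglik(tree, chars, model, root_prior, _plan=plan)
        return -ll if math.isfinite(ll) else 1e12

    if symmetric:
        starts = [[math.log(r)] for r in _GRID]
    else:
        starts = [[math.log(a), math.log(b)] for a in _GRID for b in _GRID]
    scored = sorted(starts, key=negloglik)
    best_x, best_f = None, _INF
    last_err = None
    for x0 in scored[:3]:
        try:
            res = minimize(
                negloglik,
                x0,
                method="L-BFGS-B",
                bounds=[_BOUNDS] * len(x0),
                options={"ftol": 1e-12, "gtol": 1e-10},
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            last_err = exc
            continue
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    if best_x is None:
        raise RuntimeError(f"Mk optimization failed from all starts: {last_err}")
    # never worse than the best grid point
    grid_best = scored[0]
    if negloglik(grid_best) < best_f:
        best_x, best_f = grid_best, negloglik(grid_best)
    if symmetric:
        r = math.exp(best_x[0])
        model = MkModel(r, r, symmetric=True)
    else:
        model = MkModel(math.exp(best_x[0]), math.exp(best_x[1]))
    return model, -best_f


def mk_marginal_ancestral_states(
    tree: dendropy.Tree,
    chars: CharacterMatrix,
    model: MkModel,
    root_prior: str = "equal",
) -> AncestralReconstruction:
    """Marginal ancestral state probabilities via the up-down pass.

    Each node receives ``(P(state 0), P(state 1))`` conditional on all tip
    data; probabilities sum to one per node.
    """
    _check_leaves(tree, chars)
    q01, q10 = model.q01, model.q10
    if q01 == 0.0 and q10 == 0.0:
        raise ValueError("rates must not both be zero")

    # Down pass: D[v][s] = P(tip data below v | v in state s), rescaled.
    D: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = chars.state(node.taxon.label)
            if state is None:
                D[node] = (1.0, 1.0)
            else:
                D[node] = (1.0, 0.0) if state == 0 else (0.0, 1.0)
        else:
            a0, a1 = 1.0, 1.0
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                p00, p01, p10, p11 = _p_stay_leave(q01, q10, t)
                c0, c1 = D[child]
                a0 *= p00 * c0 + p01 * c1
                a1 *= p10 * c0 + p11 * c1
            s = max(a0, a1)
            if s <= 0:
                raise ValueError("zero likelihood: data incompatible with model")
            D[node] = (a0 / s, a1 / s)

    prior0, prior1 = _root_prior(model, root_prior)
    root = tree.seed_node

    # Up pass: U[v][s] proportional to P(data outside v's subtree, v = s).
    U: dict = {root: (prior0, prior1)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        # contribution of each sibling subtree, conditional on parent state
        sib_like = {}
        for child in children:
            t = child.edge.length or 0.0
            p00, p01, p10, p11 = _p_stay_leave(q01, q10, t)
            c0, c1 = D[child]
            sib_like[child] = (p00 * c0 + p01 * c1, p10 * c0 + p11 * c1)
        for child in children:
            t = child.edge.length or 0.0
            p00, p01, p10, p11 = _p_stay_leave(q01, q10, t)
            par0, par1 = U[node]
            for sib in children:
                if sib is not child:
                    par0 *= sib_like[sib][0]
                    par1 *= sib_like[sib][1]
            u0 = par0 * p00 + par1 * p10
            u1 = par0 * p01 + par1 * p11
            s = max(u0, u1)
            if s <= 0:
                raise ValueError("zero likelihood: data incompatible with model")
            U[child] = (u0 / s, u1 / s)

    node_states = {}
    for node in tree.preorder_node_iter():
        m0 = U[node][0] * D[node][0]
        m1 = U[node][1] * D[node][1]
        tot = m0 + m1
        node_states[node] = (m0 / tot, m1 / tot)
    lnl = mk_loglik(tree, chars, model, root_prior)
    return AncestralReconstruction(node_states=node_states, score=lnl, method="ml")


def likelihood_ratio_test(lnl_null: float, lnl_alt: float, df: int) -> LrtResult:
    """Chi-squared likelihood-ratio test of nested models.

    The statistic ``2 (lnL_alt - lnL_null)`` is reported even when negative
    (a warning is emitted and p is set to 1, since the null then fits at
    least as well as the alternative).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    statistic = 2.0 * (lnl_alt - lnl_null)
    if statistic < 0:
        warnings.warn(
            f"negative LRT statistic {statistic:.6g}: alternative fits worse "
            "than null; p set to 1",
            stacklevel=2,
        )
        p = 1.0
    else:
        p = float(chi2.sf(statistic, df))
    return LrtResult(lnl_null=lnl_null, lnl_alt=lnl_alt, statistic=statistic, df=df, p=p)
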