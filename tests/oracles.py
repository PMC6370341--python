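"""Independent brute-force reference implementations used only by tests.

These deliberately take the slow road (exhaustive enumeration, dense matrix
exponentials, naive agglomeration) so they share no code path with the
package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm


def internal_nodes(tree):
    return [n for n in tree.postorder_node_iter() if not n.is_leaf()]


def brute_sankoff_cost(tree, states, cost_gain, cost_loss):
    """Minimum total weighted parsimony cost by enumerating every internal
    assignment.  ``states`` maps leaf label -> 0/1/None."""
    internals = internal_nodes(tree)

    def edge_cost(i, j):
        if i == j:
            return 0.0
        return cost_gain if (i, j) == (0, 1) else cost_loss

    best = math.inf
    best_assignments = []
    leaf_choices = {}
    for leaf in tree.leaf_node_iter():
        s = states[leaf.taxon.label]
        leaf_choices[leaf] = (0, 1) if s is None else (s,)
    leaves = list(leaf_choices)
    for internal_combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, internal_combo))
        for leaf_combo in itertools.product(*leaf_choices.values()):
            assign.update(dict(zip(leaves, leaf_combo)))
            cost = 0.0
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    cost += edge_cost(assign[node.parent_node], assign[node])
            if cost < best - 1e-12:
                best = cost
                best_assignments = [dict(assign)]
            elif cost <= best + 1e-12:
                best_assignments.append(dict(assign))
    return best, best_assignments


def brute_mk_loglik(tree, states, q01, q10, prior=(0.5, 0.5)):
    """Mk log-likelihood by summing over all internal/root states, with
    transition probabilities from a dense matrix exponential."""
    Q = np.array([[-q01, q01], [q10, -q10]])
    internals = internal_nodes(tree)
    leaf_choices = {}
    for leaf in tree.leaf_node_iter():
        s = states[leaf.taxon.label]
        leaf_choices[leaf] = (0, 1) if s is None else (s,)
    leaves = list(leaf_choices)
    total = 0.0
    for internal_combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, internal_combo))
        for leaf_combo in itertools.product(*leaf_choices.values()):
            assign.update(dict(zip(leaves, leaf_combo)))
            prob = prior[assign[tree.seed_node]]
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                P = expm(Q * (node.edge.length or 0.0))
                prob *= P[assign[node.parent_node], assign[node]]
            total += prob
    return math.log(total)


def brute_mk_marginals(tree, states, q01, q10, prior=(0.5, 0.5)):
    """Per-node marginal state probabilities by joint enumeration."""
    Q = np.array([[-q01, q01], [q10, -q10]])
    internals = internal_nodes(tree)
    leaf_choices = {}
    for leaf in tree.leaf_node_iter():
        s = states[leaf.taxon.label]
        leaf_choices[leaf] = (0, 1) if s is None else (s,)
    leaves = list(leaf_choices)
    mass = {n: [0.0, 0.0] for n in tree.preorder_node_iter()}
    for internal_combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip(internals, internal_combo))
        for leaf_combo in itertools.product(*leaf_choices.values()):
            assign.update(dict(zip(leaves, leaf_combo)))
            prob = prior[assign[tree.seed_node]]
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                P = expm(Q * (node.edge.length or 0.0))
                prob *= P[assign[node.parent_node], assign[node]]
            for node, s in assign.items():
                mass[node][s] += prob
    out = {}
    for node, (m0, m1) in mass.items():
        out[node] = (m0 / (m0 + m1), m1 / (m0 + m1))
    return out


def brute_fitch_changes(tree, labels):
    """Minimum label-change count by enumerating internal assignments."""
    values = sorted(set(labels.values()))
    internals = internal_nodes(tree)
    best = math.inf
    for combo in itertools.product(values, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        for leaf in tree.leaf_node_iter():
            assign[leaf] = labels[leaf.taxon.label]
        changes = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
            and assign[node] != assign[node.parent_node]
        )
        best = min(best, changes)
    return best


def brute_average_linkage(dist: np.ndarray):
    """Naive average-linkage agglomeration returning merge heights.

    Cluster-to-cluster distance is the mean of all original pairwise
    distances between members (UPGMA on the raw matrix).
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def brute_average_linkage_cut(dist: np.ndarray, cutoff: float):
    """Flat clusters from naive average linkage cut at merge height <= cutoff."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        if d > cutoff:
            break
        clusters[a] = clusters.pop(a) + clusters.pop(b)
    return sorted(sorted(v) for v in clusters.values())


def hypergeom_tail_enumeration(N, K, n, k, upper=True):
    """P(X >= k) (or <= k) for draws of n from N with K successes, by
    exhaustive enumeration of all C(N, n) draws."""
    hits = 0
    total = 0
    items = list(range(N))
    successes = set(range(K))
    for draw in itertools.combinations(items, n):
        total += 1
        x = len(successes.intersection(draw))
        if (upper and x >= k) or (not upper and x <= k):
            hits += 1
    return hits / total
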