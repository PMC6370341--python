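"""Pairwise distances and phylogenetic population-divergence tests.

Two permutation tests ask whether sequences from two populations (e.g. two
ocean gyres) are phylogenetically segregated on a gene tree:

* unweighted UniFrac — the fraction of branch length leading exclusively to
  one population's leaves; large values mean the populations occupy distinct
  parts of the tree.
* the P-test — the Fitch parsimony count of population-label changes; few
  changes mean strong segregation.

Significance comes from permuting leaf labels while preserving group sizes,
with the (k+1)/(n+1) p-value estimator (never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import Alignment

__all__ = [
    "DistanceMatrix",
    "DivergenceTestResult",
    "percent_difference",
    "cluster_representatives",
    "subsample_populations",
    "unweighted_unifrac",
    "p_test",
    "permutation_significance",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class DivergenceTestResult:
    statistic: float
    p: float
    n_iters: int
    seed: int
    statistic_name: str
    replicate: int = 0


def _pair_distance_onegap(a: str, b: str) -> float:
    """mothur-style 'onegap' distance: a contiguous gap run in one sequence
    counts as a single difference and terminal gap overhangs are ignored."""
    chars_a, chars_b = a, b
    # overlap window: trim positions before both sequences start / after both end
    def span(s: str) -> tuple[int, int]:
        first = next((i for i, c in enumerate(s) if c != "-"), None)
        if first is None:
            raise ValueError("sequence is all gaps")
        last = len(s) - next(i for i, c in enumerate(reversed(s)) if c != "-") - 1
        return first, last

    fa, la = span(chars_a)
    fb, lb = span(chars_b)
    start, end = max(fa, fb), min(la, lb)
    diffs = 0
    length = 0
    in_gap = False
    for i in range(start, end + 1):
        ca, cb = chars_a[i], chars_b[i]
        if ca == "-" and cb == "-":
            continue
        if ca == "-" or cb == "-":
            if not in_gap:
                diffs += 1
                length += 1
                in_gap = True
            continue
        in_gap = False
        length += 1
        if ca != cb:
            diffs += 1
    if length == 0:
        raise ValueError("pair has zero comparable columns")
    return diffs / length


def _pair_distance_ignore(a: str, b: str) -> float:
    diffs = 0
    length = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        length += 1
        if ca != cb:
            diffs += 1
    if length == 0:
        raise ValueError("pair has zero comparable columns")
    return diffs / length


def percent_difference(aln: Alignment, gap_mode: str = "onegap") -> DistanceMatrix:
    """Pairwise proportion of differing positions.

    ``gap_mode='onegap'`` (default) treats a contiguous gap run as one
    difference and ignores terminal overhangs; ``'ignore'`` drops every
    column containing a gap in the pair.
    """
    if len(aln) < 2:
        raise ValueError("need >= 2 sequences")
    pair = {"onegap": _pair_distance_onegap, "ignore": _pair_distance_ignore}.get(gap_mode)
    if pair is None:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    n = len(aln)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pair(aln.seqs[i], aln.seqs[j])
            except ValueError as exc:
                raise ValueError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(aln.ids), values=values)


def cluster_representatives(
    aln: Alignment, cutoff: float = 0.01, gap_mode: str = "onegap"
) -> list[tuple[str, list[str]]]:
    """Average-linkage clusters cut at ``cutoff`` with one representative each.

    The representative is the member with minimum summed within-cluster
    distance (ties broken by lexicographic id).  Returns
    ``[(representative, members), ...]`` covering every input sequence.
    """
    dm = percent_difference(aln, gap_mode=gap_mode)
    if len(aln) == 1:
        return [(aln.ids[0], list(aln.ids))]
    Z = linkage(squareform(dm.values, checks=False), method="average")
    assignment = fcluster(Z, t=cutoff, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for idx, cl in enumerate(assignment):
        clusters.setdefault(int(cl), []).append(idx)
    out = []
    for cl in sorted(clusters):
        members = clusters[cl]
        sums = dm.values[np.ix_(members, members)].sum(axis=1)
        best = min(
            range(len(members)),
            key=lambda i: (sums[i], aln.ids[members[i]]),
        )
        rep = aln.ids[members[best]]
        out.append((rep, [aln.ids[i] for i in members]))
    out.sort(key=lambda item: item[0])
    return out


def subsample_populations(
    aln: Alignment,
    pops: dict[str, str],
    n_per_pop: int = 9,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[Alignment]:
    """Independent without-replacement subsamples of each population.

    Each replicate alignment holds exactly ``n_per_pop`` sequences per
    population (drawn independently across replicates).
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for sid in aln.ids:
        if sid in pops:
            groups.setdefault(pops[sid], []).append(sid)
    for pop, members in sorted(groups.items()):
        if len(members) < n_per_pop:
            raise ValueError(
                f"population {pop!r} has {len(members)} sequences, "
                f"fewer than n_per_pop={n_per_pop}"
            )
    replicates = []
    for _ in range(n_replicates):
        chosen: list[str] = []
        for pop in sorted(groups):
            members = groups[pop]
            picks = rng.choice(len(members), size=n_per_pop, replace=False)
            chosen.extend(members[i] for i in sorted(picks))
        replicates.append(aln.subset(chosen))
    return replicates


def _require_rooted_two_pops(tree: dendropy.Tree, pops: dict[str, str]):
    if not tree.is_rooted:
        raise ValueError("tree must be rooted; apply picotrait.io.midpoint_root first")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    unmapped = [l for l in leaves if l not in pops]
    if unmapped:
        raise ValueError(f"leaves missing from population map: {sorted(unmapped)}")
    return leaves


def unweighted_unifrac(tree: dendropy.Tree, pops: dict[str, str]) -> float:
    """Unweighted UniFrac distance between exactly two populations.

    Sum of branch lengths whose descendant leaves all belong to a single
    population, divided by the total branch length subtending mapped leaves.
    The root's own edge is excluded.
    """
    leaves = _require_rooted_two_pops(tree, pops)
    pop_names = sorted(set(pops[l] for l in leaves))
    if len(pop_names) != 2:
        raise ValueError(f"pairwise UniFrac requires exactly 2 populations, got {pop_names}")
    unique = 0.0
    total = 0.0
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {pops[node.taxon.label]}
        else:
            s = set()
            for child in node.child_nodes():
                s |= below[child]
            below[node] = s
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        total += length
        if len(below[node]) == 1:
            unique += length
    if total == 0:
        raise ValueError("tree has zero branch length below the root")
    return unique / total


def p_test(tree: dendropy.Tree, pops: dict[str, str]) -> int:
    """Minimum parsimony count of population-label changes on the tree.

    Uses the Fitch/Hartigan downpass, which also handles multifurcations:
    at each internal node the retained label set is the set of labels borne
    by the largest number of children, and the change count increments by
    (#children - that maximum).
    """
    leaves = _require_rooted_two_pops(tree, pops)
    if len(set(pops[l] for l in leaves)) == 1:
        return 0
    changes = 0
    state: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[node] = frozenset([pops[node.taxon.label]])
        else:
            counts: dict[str, int] = {}
            children = node.child_nodes()
            for child in children:
                for label in state[child]:
                    counts[label] = counts.get(label, 0) + 1
            m = max(counts.values())
            state[node] = frozenset(l for l, c in counts.items() if c == m)
            changes += len(children) - m
    return changes


def permutation_significance(
    tree: dendropy.Tree,
    pops: dict[str, str],
    statistic: str = "unifrac",
    n_iters: int = 1000,
    seed: int = 0,
    replicate: int = 0,
) -> DivergenceTestResult:
    """Permutation p-value for UniFrac or the P-test.

    Leaf-to-population labels are shuffled preserving group sizes; the
    p-value is ``(#permutations at least as extreme + 1) / (n_iters + 1)``
    where "extreme" means >= the observed UniFrac or <= the observed change
    count.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    stat_fns = {"unifrac": unweighted_unifrac, "ptest": p_test}
    if statistic not in stat_fns:
        raise ValueError(f"unknown statistic {statistic!r}")
    fn = stat_fns[statistic]
    observed = fn(tree, pops)
    leaves = _require_rooted_two_pops(tree, pops)
    labels = [pops[l] for l in leaves]
    rng = np.random.default_rng(seed)
    exceed = 0
    labels = np.array(labels)
    for _ in range(n_iters):
        perm = rng.permutation(labels)
        permuted = dict(zip(leaves, perm.tolist()))
        value = fn(tree, permuted)
        if statistic == "unifrac":
            if value >= observed - 1e-12:
                exceed += 1
        else:
            if value <= observed:
                exceed += 1
    p = (exceed + 1) / (n_iters + 1)
    return DivergenceTestResult(
        statistic=float(observed),
        p=p,
        n_iters=n_iters,
        seed=seed,
        statistic_name=statistic,
        replicate=replicate,
    )
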