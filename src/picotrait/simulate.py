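"""Synthetic data generators with the statistical structure the analyses assume.

Every generator is a pure function of its inputs and an integer seed, so
downstream modules can be exercised end-to-end without any external genome
data:

* Yule trees stand in for externally inferred phylogenies.
* A 2-state asymmetric Markov process simulates binary trait gain/loss
  along a tree, returning both tip states and the true internal history.
* Bernoulli gene retention emulates partial single-cell genome assemblies
  at a stated recovery fraction per genome.
* A ClonalFrame-style forward simulator evolves sequences under point
  mutation plus homologous-recombination imports parameterized by
  (R/theta, delta, nu), logging every event so realized r/m is measurable.
* Codon alignments evolve under GY94 site-class mixtures.
* Two-population trees with tunable phylogenetic segregation feed the
  beta-diversity tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .genecontent import GenePresenceTable
from .io import Alignment, CharacterMatrix
from .selection import CODONS, _ReversibleExp, gy94_generator

__all__ = [
    "simulate_yule_tree",
    "simulate_binary_trait",
    "simulate_partial_genomes",
    "simulate_clonalframe_alignment",
    "simulate_codon_alignment",
    "simulate_two_population_tree",
    "TraitHistory",
]

_NUC = "ACGT"
_TI_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _new_rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("seed is mandatory for every stochastic call")
    return np.random.default_rng(seed)


def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0, prefix: str = "t"
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with ``n_taxa`` extant leaves.

    Lineages split at exponential waiting times with total rate
    ``birth_rate * k``; after the last split all tips are extended to the
    present, so every root-to-tip path has equal length.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _new_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # active lineages as (node, birth_time of the node)
    t_now = 0.0
    root = tree.seed_node
    active = [(root, 0.0)]
    while len(active) < n_taxa:
        k = len(active)
        t_now += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t_now - born
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t_now))
        active.append((right, t_now))
    k = len(active)
    t_end = t_now + rng.exponential(1.0 / (birth_rate * k))
    for i, (node, born) in enumerate(active):
        node.edge.length = t_end - born
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"{prefix}{i + 1}")
    root.edge.length = 0.0
    return tree


@dataclass
class TraitHistory:
    """Tip states plus the true internal-node states of a trait simulation."""

    tips: CharacterMatrix
    node_states: dict  # dendropy node -> 0/1


def simulate_binary_trait(
    tree: dendropy.Tree,
    q01: float,
    q10: float,
    root_state="stationary",
    seed: int = 0,
) -> TraitHistory:
    """Continuous-time 2-state Markov evolution of a binary trait on a tree.

    ``q01`` is the gain rate (0 to 1) and ``q10`` the loss rate, per unit
    branch length.  ``root_state`` is 0, 1, or "stationary" (draw from the
    stationary distribution q01/(q01+q10)).
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be >= 0")
    rng = _new_rng(seed)
    if root_state == "stationary":
        if q01 + q10 == 0:
            raise ValueError("stationary root requires q01 + q10 > 0")
        pi1 = q01 / (q01 + q10)
        state0 = int(rng.random() < pi1)
    elif root_state in (0, 1):
        state0 = int(root_state)
    else:
        raise ValueError("root_state must be 0, 1, or 'stationary'")

    rates = {0: q01, 1: q10}
    node_states = {tree.seed_node: state0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        state = node_states[node.parent_node]
        t_left = node.edge.length or 0.0
        while True:
            rate = rates[state]
            if rate == 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= t_left:
                break
            state = 1 - state
            t_left -= wait
        node_states[node] = state

    taxa = []
    states = {}
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        states[leaf.taxon.label] = node_states[leaf]
    return TraitHistory(
        tips=CharacterMatrix(taxa=taxa, states=states), node_states=node_states
    )


def simulate_partial_genomes(
    full_table: GenePresenceTable, recovery_fractions, seed: int = 0
) -> GenePresenceTable:
    """Thin a complete gene presence table into partial assemblies.

    Each present gene is retained independently with probability equal to
    its genome's recovery fraction; absent genes stay absent.  The recovery
    fractions used are recorded on the output table.
    """
    rng = _new_rng(seed)
    rec = pd.Series(recovery_fractions).reindex(full_table.matrix.index)
    if rec.isna().any():
        raise ValueError("recovery fraction missing for some genomes")
    if ((rec <= 0) | (rec > 1)).any():
        raise ValueError("recovery fractions must be in (0, 1]")
    mat = full_table.matrix.to_numpy().copy()
    keep = rng.random(mat.shape) < rec.to_numpy()[:, None]
    thinned = (mat.astype(bool) & keep).astype(int)
    return GenePresenceTable(
        matrix=pd.DataFrame(
            thinned, index=full_table.matrix.index, columns=full_table.matrix.columns
        ),
        recovery=rec,
        marker=None if full_table.marker is None else full_table.marker.copy(),
    )


def _mutate_base(rng, base: str, kappa: float) -> str:
    """Draw a replacement base; transitions weighted by kappa."""
    others = [b for b in _NUC if b != base]
    weights = np.array(
        [kappa if b == _TI_PARTNER[base] else 1.0 for b in others]
    )
    weights /= weights.sum()
    return others[int(rng.choice(3, p=weights))]


def simulate_clonalframe_alignment(
    tree: dendropy.Tree,
    theta: float,
    R_over_theta: float,
    delta: float,
    nu: float,
    L: int,
    seed: int = 0,
    kappa: float = 1.0,
):
    """Forward sequence evolution with homologous-recombination imports.

    Along each branch of length t, point mutations arrive as a Poisson
    process at rate ``theta`` per site and import initiations at rate
    ``(R/theta) * theta`` per site.  Each import covers a geometric-length
    tract with mean ``delta`` (truncated at the linear sequence end), and
    every site in the tract is replaced with probability ``nu``.  Events on
    a branch are applied in time order, so overlapping imports are
    permitted and the last event wins.

    Returns ``(Alignment of the leaf sequences, event-log DataFrame)`` with
    one row per mutation and per import (start, tract length, substituted
    site count).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if delta < 1:
        raise ValueError("delta must be >= 1 (mean import length in bp)")
    if not (0 <= nu <= 0.75):
        raise ValueError("nu must be in [0, 0.75]")
    if theta < 0 or R_over_theta < 0:
        raise ValueError("rates must be >= 0")
    rng = _new_rng(seed)
    root_seq = rng.integers(0, 4, size=L)
    seqs = {tree.seed_node: root_seq}
    log_rows = []
    branch_id = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        branch_id += 1
        t = node.edge.length or 0.0
        seq = seqs[node.parent_node].copy()
        n_mut = rng.poisson(theta * t * L)
        n_imp = rng.poisson(R_over_theta * theta * t * L)
        events = [("mutation", float(u)) for u in rng.random(n_mut)]
        events += [("import", float(u)) for u in rng.random(n_imp)]
        events.sort(key=lambda e: e[1])
        for kind, when in events:
            if kind == "mutation":
                site = int(rng.integers(L))
                old = _NUC[seq[site]]
                seq[site] = _NUC.index(_mutate_base(rng, old, kappa))
                log_rows.append(
                    {
                        "branch": branch_id, "event": "mutation", "time": when * t,
                        "start": site, "tract_length": 1, "n_substituted": 1,
                    }
                )
            else:
                start = int(rng.integers(L))
                tract = int(rng.geometric(1.0 / delta))
                end = min(start + tract, L)
                n_sub = 0
                for site in range(start, end):
                    if rng.random() < nu:
                        old = _NUC[seq[site]]
                        seq[site] = _NUC.index(_mutate_base(rng, old, 1.0))
                        n_sub += 1
                log_rows.append(
                    {
                        "branch": branch_id, "event": "import", "time": when * t,
                        "start": start, "tract_length": end - start,
                        "n_substituted": n_sub,
                    }
                )
        seqs[node] = seq
    ids, out = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        out.append("".join(_NUC[b] for b in seqs[leaf]))
    log = pd.DataFrame(
        log_rows,
        columns=["branch", "event", "time", "start", "tract_length", "n_substituted"],
    )
    return Alignment(ids=ids, seqs=out), log


def simulate_codon_alignment(
    tree: dendropy.Tree,
    kappa: float,
    site_class_spec,
    L_codons: int,
    codon_freqs="uniform",
    seed: int = 0,
) -> Alignment:
    """Evolve a codon alignment under a GY94 site-class mixture.

    ``site_class_spec`` is a list of ``(proportion, omega)`` pairs summing
    to one; each codon site draws a class once and keeps it on every branch.
    Stop codons are never emitted (the state space is the 61 sense codons).
    """
    if L_codons < 1:
        raise ValueError("L_codons must be >= 1")
    props = np.array([p for p, _ in site_class_spec], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {props.sum()}, expected 1")
    if isinstance(codon_freqs, str):
        if codon_freqs != "uniform":
            raise ValueError("codon_freqs must be 'uniform' or an array")
        pi = np.full(61, 1.0 / 61.0)
    else:
        pi = np.asarray(codon_freqs, dtype=float)
    rng = _new_rng(seed)
    classes = rng.choice(len(site_class_spec), size=L_codons, p=props)
    states = {tree.seed_node: rng.choice(61, size=L_codons, p=pi)}
    decomps = [
        _ReversibleExp(gy94_generator(kappa, omega, pi), pi)
        for _, omega in site_class_spec
    ]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent = states[node.parent_node]
        child = np.empty(L_codons, dtype=int)
        for ci, dec in enumerate(decomps):
            mask = classes == ci
            if not mask.any():
                continue
            P = dec.expm(t)
            cum = P.cumsum(axis=1)
            idx = np.where(mask)[0]
            u = rng.random(len(idx))
            for pos, uu in zip(idx, u):
                child[pos] = int(np.searchsorted(cum[parent[pos]], uu))
        states[node] = child
    ids, seqs = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        seqs.append("".join(CODONS[s] for s in states[leaf]))
    return Alignment(ids=ids, seqs=seqs)


def simulate_two_population_tree(
    n_per_pop: int,
    segregation: str = "none",
    seed: int = 0,
    birth_rate: float = 1.0,
    pop_names: tuple[str, str] = ("popA", "popB"),
):
    """A labeled tree for two populations with tunable segregation.

    ``segregation='complete'`` joins two independent Yule clades (one per
    population) under the root, giving reciprocal monophyly;
    ``'none'`` grows a single Yule tree and assigns labels by random
    interleaving.  Returns ``(tree, {leaf: population})``.
    """
    if n_per_pop < 2:
        raise ValueError("n_per_pop must be >= 2")
    rng = _new_rng(seed)
    if segregation == "complete":
        sub_a = simulate_yule_tree(
            n_per_pop, birth_rate, seed=int(rng.integers(2**31)), prefix="a"
        )
        sub_b = simulate_yule_tree(
            n_per_pop, birth_rate, seed=int(rng.integers(2**31)), prefix="b"
        )
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.is_rooted = True
        for sub in (sub_a, sub_b):
            node = sub.seed_node
            node.edge.length = 1.0 / birth_rate
            tree.seed_node.add_child(node)
        pops = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            pop = pop_names[0] if label.startswith("a") else pop_names[1]
            leaf.taxon = taxa.new_taxon(label=label)
            pops[label] = pop
        tree.update_taxon_namespace()
        return tree, pops
    if segregation == "none":
        tree = simulate_yule_tree(
            2 * n_per_pop, birth_rate, seed=int(rng.integers(2**31))
        )
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        assignment = [pop_names[0]] * n_per_pop + [pop_names[1]] * n_per_pop
        perm = rng.permutation(2 * n_per_pop)
        pops = {labels[i]: assignment[k] for k, i in enumerate(perm)}
        return tree, pops
    raise ValueError("segregation must be 'none' or 'complete'")
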