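"""Readers, writers and shared tree utilities.

Sequence alignments travel as :class:`Alignment`, phylogenies as
:class:`dendropy.Tree`, binary trait data as :class:`CharacterMatrix`, and
leaf-to-population assignments as plain ``dict`` objects produced by
:func:`read_population_map`.  All tabular formats are TSV with a header row;
branch lengths are substitutions per site throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
from Bio import SeqIO

__all__ = [
    "Alignment",
    "CharacterMatrix",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "parse_newick",
    "read_nexus_characters",
    "read_population_map",
    "write_population_map",
    "midpoint_root",
]

@dataclass
class Alignment:
    """A gap-aware multiple sequence alignment.

    ids
        Unique sequence identifiers, in input order.
    seqs
        Equal-length gapped sequences over ``{A, C, G, T, -, N}`` (uppercase).
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment must contain at least one record")
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        length = len(self.seqs[0])
        if length < 1:
            raise ValueError("alignment length must be >= 1")
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length {len(seq)}, "
                    f"expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    def subset(self, keep_ids) -> "Alignment":
        keep = list(keep_ids)
        index = {sid: s for sid, s in zip(self.ids, self.seqs)}
        missing = [k for k in keep if k not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment(ids=keep, seqs=[index[k] for k in keep])


@dataclass
class CharacterMatrix:
    """Taxon x single-binary-trait states; ``None`` encodes missing data."""

    taxa: list[str]
    states: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa must be unique")
        for taxon, state in self.states.items():
            if state not in (0, 1, None):
                raise ValueError(
                    f"non-binary state {state!r} for taxon {taxon!r}; "
                    "this pipeline is binary-trait only"
                )
        for taxon in self.states:
            if taxon not in self.taxa:
                raise ValueError(f"state given for unknown taxon {taxon!r}")

    def state(self, taxon: str) -> Optional[int]:
        return self.states.get(taxon)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file, preserving order and uppercasing residues."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Quoted labels are supported; internal-node labels (e.g. RAxML support
    values) are preserved but unused downstream.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    _check_tree(tree)
    return tree


def read_newick(path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    """Newick serialization preserving lengths to 10 significant digits."""
    return (
        tree.as_string(
            schema="newick",
            real_value_format_specifier=".10g",
            suppress_rooting=True,
        ).strip()
        + "\n"
    )


def _check_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


_MISSING_SYMBOLS = {"?", "-"}  # Mesquite accepts both for missing


def read_nexus_characters(path):
    """Read a Mesquite-style NEXUS file with a binary character matrix.

    Returns ``(tree_or_None, CharacterMatrix)``.  The first tree of a TREES
    block, if any, is returned.  ``?`` and ``-`` both map to missing.
    """
    ds = dendropy.DataSet.get(path=str(path), schema="nexus", preserve_underscores=True)
    if not ds.char_matrices:
        raise ValueError(f"no CHARACTERS block in {path}")
    cm = ds.char_matrices[0]
    taxa: list[str] = []
    states: dict[str, Optional[int]] = {}
    for taxon in cm.taxon_namespace:
        if taxon not in cm:
            raise ValueError(
                f"taxon {taxon.label!r} declared in TAXA but absent from CHARACTERS"
            )
    for taxon in cm.taxon_namespace:
        taxa.append(taxon.label)
        symbols = [str(c) for c in cm[taxon].symbols_as_list()]
        if not symbols:
            raise ValueError(f"empty character row for taxon {taxon.label!r}")
        sym = symbols[0]  # single binary trait per taxon
        if sym in _MISSING_SYMBOLS:
            states[taxon.label] = None
        elif sym in ("0", "1"):
            states[taxon.label] = int(sym)
        else:
            raise ValueError(
                f"non-binary state {sym!r} for taxon {taxon.label!r}; "
                "this pipeline is binary-trait only"
            )
    tree = None
    if ds.tree_lists and len(ds.tree_lists[0]) > 0:
        tree = ds.tree_lists[0][0]
        _check_tree(tree)
    return tree, CharacterMatrix(taxa=taxa, states=states)


def read_population_map(path) -> dict[str, str]:
    """Read a two-column TSV (leaf label, population label) with a header."""
    pops: dict[str, str] = {}
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        leaf, pop = line.split("\t")[:2]
        pops[leaf] = pop
    return pops


def write_population_map(pops: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf\tpopulation\n")
        for leaf, pop in pops.items():
            fh.write(f"{leaf}\t{pop}\n")


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Returns a new rooted tree; the input is not modified.  Raises on trees
    whose total branch length is zero (midpoint undefined).
    """
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("midpoint rooting requires >= 2 leaves")
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total <= 0.0:
        raise ValueError("degenerate tree: all branch lengths zero")
    tree = tree.clone(depth=1)

    # depths and ancestor chains from the current (arbitrary) root
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[parent] + (node.edge.length or 0.0)
    leaves = tree.leaf_nodes()

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    chains = {leaf: ancestors(leaf) for leaf in leaves}
    best = (-1.0, None, None)
    for i, u in enumerate(leaves):
        anc_u = set(chains[u])
        for v in leaves[i + 1 :]:
            lca = next(n for n in chains[v] if n in anc_u)
            d = depth[u] + depth[v] - 2.0 * depth[lca]
            if d > best[0]:
                best = (d, u, v)
    dmax, u, v = best
    if dmax <= 0.0:
        raise ValueError("degenerate tree: longest leaf-to-leaf path is zero")
    target = dmax / 2.0

    # walk the u -> v path accumulating distance until the midpoint edge
    anc_u = set(chains[u])
    lca = next(n for n in chains[v] if n in anc_u)
    path = chains[u][: chains[u].index(lca) + 1]
    path += list(reversed(chains[v][: chains[v].index(lca)]))
    walked = 0.0
    for a, b in zip(path, path[1:]):
        child = a if a.parent_node is b else b
        step = child.edge.length or 0.0
        if walked + step >= target - 1e-12:
            offset = target - walked  # distance from node `a` into this edge
            from_child = offset if child is a else step - offset
            root_node = _split_edge(child, from_child)
            break
        walked += step
    else:  # numerically at the far end of the path
        root_node = path[-1]
    tree.reroot_at_node(root_node, update_bipartitions=False)
    tree.suppress_unifurcations()
    tree.is_rooted = True
    return tree


def _split_edge(child: dendropy.Node, from_child: float) -> dendropy.Node:
    """Insert (or reuse) a node on ``child``'s edge at ``from_child`` above it."""
    length = child.edge.length or 0.0
    if from_child <= 1e-12:
        return child
    if from_child >= length - 1e-12:
        return child.parent_node
    parent = child.parent_node
    new = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(new)
    new.edge.length = length - from_child
    new.add_child(child)
    child.edge.length = from_child
    return new


def tree_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-leaf path length per leaf label."""
    depths: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent_depth = getattr(node.parent_node, "_pt_depth", 0.0) if node.parent_node else 0.0
        node._pt_depth = parent_depth + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node._pt_depth
    return depths
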