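"""Distance-based phylogeny: Jukes-Cantor distances, neighbour joining,
bootstrap majority-rule consensus, outgroup rooting and clade assignment.

Trees are dendropy objects throughout; Newick serialisation carries branch
lengths and bootstrap support as internal node labels.  The Jukes-Cantor
model is applied with alphabet size 4 for nucleotides and its a = 20
generalisation for proteins, the way standard distance software treats
protein alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from isfamily.alignment import MSA


class SaturationError(ValueError):
    """Observed divergence at or beyond the Jukes-Cantor domain boundary."""


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances


def p_distance(row_i: str, row_j: str) -> float:
    """Mismatch fraction over columns where neither row has a gap."""
    if len(row_i) != len(row_j):
        raise PhylogenyError("aligned rows differ in length")
    kept = mism = 0
    for x, y in zip(row_i, row_j):
        if x == "-" or y == "-":
            continue
        kept += 1
        mism += x != y
    if kept == 0:
        raise PhylogenyError("no shared ungapped columns")
    return mism / kept


def jc_distance(p: float, alphabet_size: int = 4,
                cap: Optional[float] = None) -> float:
    """Jukes-Cantor distance -((a-1)/a) * ln(1 - a*p/(a-1)).

    Undefined for p >= (a-1)/a: raises SaturationError unless the caller
    opts into a finite ``cap`` (substitutions/site).
    """
    a = alphabet_size
    if p < 0:
        raise ValueError("p must be non-negative")
    limit = (a - 1) / a
    if p >= limit:
        if cap is not None:
            return cap
        raise SaturationError(f"p = {p:.4f} >= {(a - 1)}/{a}; distance saturated")
    d = -limit * np.log(1.0 - p / limit)
    if cap is not None:
        d = min(d, cap)
    return float(d)


def msa_distance(row_i: str, row_j: str,
                 model: Literal["p", "jc_nt", "jc_aa"] = "jc_aa",
                 cap: Optional[float] = None) -> float:
    """Distance between two aligned rows under the chosen model."""
    p = p_distance(row_i, row_j)
    if model == "p":
        return p
    a = 4 if model == "jc_nt" else 20
    return jc_distance(p, a, cap=cap)


def distance_matrix(msa: MSA, model: Literal["p", "jc_nt", "jc_aa"] = "jc_aa",
                    cap: Optional[float] = None) -> pd.DataFrame:
    """Pairwise model distances with per-pair gap-column deletion."""
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = msa_distance(msa.rows[i], msa.rows[j], model, cap)
    return pd.DataFrame(d, index=msa.names, columns=msa.names)


# ---------------------------------------------------------------------------
# neighbour joining


def _as_matrix(dm) -> tuple[np.ndarray, list[str]]:
    if isinstance(dm, pd.DataFrame):
        names = [str(c) for c in dm.columns]
        m = dm.to_numpy(dtype=float, copy=True)
    else:
        m = np.array(dm, dtype=float)
        names = [f"t{i}" for i in range(len(m))]
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise PhylogenyError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise PhylogenyError("distance matrix must be symmetric")
    if (m < 0).any():
        raise PhylogenyError("distance matrix has negative entries")
    return m, names


def nj(dm) -> dendropy.Tree:
    """Saitou-Nei neighbour joining.

    Q-criterion ties are broken by the smallest (i, j) index pair in the
    current matrix ordering, so repeated runs are identical.  Negative branch
    lengths are clamped to 0 with the deficit transferred to the sibling
    branch.  The returned tree is unrooted (trifurcating seed node).
    """
    d, names = _as_matrix(dm)
    n = len(names)
    if n < 3:
        raise PhylogenyError("neighbour joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(names)
    nodes = []
    for name in names:
        leaf = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(leaf)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among ties
        best = np.min(q)
        ties = np.argwhere(np.isclose(q, best, atol=1e-10))
        ai, aj = min((int(i), int(j)) for i, j in ties if i < j)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = li
        parent.add_child(nodes[j]); nodes[j].edge.length = lj
        nodes.append(parent)
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            d[new, ak] = d[ak, new] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        active = [a for a in active if a not in (i, j)] + [new]
    # final star join of the last three
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li, lj, lk = (max(v, 0.0) for v in (li, lj, lk))
    seed = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        seed.add_child(nodes[idx])
        nodes[idx].edge.length = length
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=seed)
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# bipartitions, Robinson-Foulds, consensus


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each encoded as the side not holding the
    alphabetically first leaf."""
    all_leaves = set(_leaf_labels(tree))
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else frozenset(all_leaves - below)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Symmetric-difference (RF) distance over non-trivial bipartitions."""
    la, lb = set(_leaf_labels(tree_a)), set(_leaf_labels(tree_b))
    if la != lb:
        raise PhylogenyError("trees are over different leaf sets")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


def _majority_consensus(bip_counts: dict[frozenset[str], int], n_trees: int,
                        leaves: list[str], taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Build the >50 % majority-rule consensus tree with support labels.

    Strict-majority bipartitions are pairwise compatible (two incompatible
    splits cannot each occur in more than half the trees), so on the rooted
    view anchored at the reference leaf any two clades are nested or
    disjoint and the consensus follows from the containment forest.
    """
    majority = [(set(b), c) for b, c in bip_counts.items() if c * 2 > n_trees]
    majority.sort(key=lambda bc: (-len(bc[0]), sorted(bc[0])))
    parent_of: list[Optional[int]] = [None] * len(majority)
    for i in range(len(majority)):
        for j in range(i - 1, -1, -1):  # nearest (smallest) container wins
            if majority[i][0] <= majority[j][0]:
                parent_of[i] = j
                break
    clade_nodes = []
    for side, count in majority:
        node = dendropy.Node()
        node.label = f"{100.0 * count / n_trees:.0f}"
        clade_nodes.append(node)
    seed = dendropy.Node()
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=seed)
    tree.is_rooted = False
    for i, node in enumerate(clade_nodes):
        holder = seed if parent_of[i] is None else clade_nodes[parent_of[i]]
        holder.add_child(node)
    for name in leaves:
        owners = [i for i, (side, _) in enumerate(majority) if name in side]
        holder = seed if not owners else clade_nodes[max(owners)]
        holder.add_child(dendropy.Node(taxon=taxa.get_taxon(name)))
    return tree


def bootstrap_consensus(msa: MSA, model: Literal["p", "jc_nt", "jc_aa"] = "jc_aa",
                        B: int = 100, seed: int = 0,
                        cap: Optional[float] = 5.0) -> dendropy.Tree:
    """Column bootstrap of the distance + NJ analysis, majority-rule summary.

    Draws ``B`` column resamples with replacement, runs NJ on each, and
    returns the >50 % majority-rule consensus with per-clade support labels
    (percent).  Identical seed gives identical output.  Saturated resampled
    distances are capped (default 5 substitutions/site) rather than fatal,
    since individual bootstrap pseudo-replicates routinely push p past the
    model boundary.
    """
    if B < 1:
        raise PhylogenyError("need at least one bootstrap replicate")
    if len(msa) < 4:
        raise PhylogenyError("bootstrap consensus needs at least 4 rows")
    rng = np.random.default_rng(seed)
    rows = np.array([list(r) for r in msa.rows])
    n, L = rows.shape
    gap = rows == "-"
    # per-pair per-column usable/mismatch masks, computed once
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    usable = np.array([~(gap[i] | gap[j]) for i, j in pair_idx])
    mismatch = np.array([(rows[i] != rows[j]) for i, j in pair_idx]) & usable
    a = {"p": None, "jc_nt": 4, "jc_aa": 20}[model]
    counts_all = rng.multinomial(L, np.full(L, 1.0 / L), size=B)
    bip_counts: dict[frozenset[str], int] = {}
    names = msa.names
    for b in range(B):
        w = counts_all[b].astype(float)
        kept = usable @ w
        mism = mismatch @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(kept > 0, mism / np.maximum(kept, 1.0), 0.75)
        d = np.zeros((n, n))
        for (pi, (i, j)) in enumerate(pair_idx):
            if a is None:
                d[i, j] = d[j, i] = p[pi]
            else:
                d[i, j] = d[j, i] = jc_distance(min(p[pi], (a - 1) / a), a, cap=cap)
        tree = nj(pd.DataFrame(d, index=names, columns=names))
        for bip in bipartitions(tree):
            bip_counts[bip] = bip_counts.get(bip, 0) + 1
    taxa = dendropy.TaxonNamespace(names)
    return _majority_consensus(bip_counts, B, sorted(names), taxa)


# ---------------------------------------------------------------------------
# rooting and clades


def root_at_outgroup(tree: dendropy.Tree, outgroup_leaf: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge, splitting its length equally."""
    clone = tree.clone(depth=1)
    leaf = None
    for l in clone.leaf_node_iter():
        if l.taxon.label == outgroup_leaf:
            leaf = l
            break
    if leaf is None:
        raise PhylogenyError(f"outgroup leaf {outgroup_leaf!r} not in tree")
    length = leaf.edge.length if leaf.edge.length is not None else 0.0
    clone.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0,
                         update_bipartitions=False)
    clone.is_rooted = True
    return clone


@dataclass
class CladeAssignment:
    """Reference-seeded clade labelling of a rooted tree's leaves."""

    clade_map: dict[str, list[str]]
    assignment: dict[str, str]           # leaf -> clade label or "solo"
    violations: list[str]


def assign_clades(tree: dendropy.Tree, clade_map: dict[str, Sequence[str]]) -> CladeAssignment:
    """Label leaves by the smallest reference-seeded MRCA subtree they fall in.

    Each clade is the rooted subtree spanned by the MRCA of its reference
    leaves.  Leaves inside no clade subtree are "solo".  Overlapping clade
    subtrees (one MRCA nested in or equal to another) are reported as
    monophyly violations; a contested leaf goes to the smallest subtree.
    """
    leaf_by_label = {l.taxon.label: l for l in tree.leaf_node_iter()}
    subtrees: dict[str, set[str]] = {}
    for label, refs in clade_map.items():
        missing = [r for r in refs if r not in leaf_by_label]
        if missing:
            raise PhylogenyError(f"clade {label}: reference leaves missing {missing}")
        if len(refs) == 1:
            subtrees[label] = {refs[0]}
            continue
        mrca = tree.mrca(taxa=[leaf_by_label[r].taxon for r in refs])
        subtrees[label] = {l.taxon.label for l in mrca.leaf_iter()}
    violations = []
    labels = sorted(subtrees)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            if subtrees[la] & subtrees[lb]:
                violations.append(f"clades {la} and {lb} overlap")
    assignment = {}
    for leaf in leaf_by_label:
        containing = [l for l in labels if leaf in subtrees[l]]
        if not containing:
            assignment[leaf] = "solo"
        else:
            assignment[leaf] = min(containing, key=lambda l: (len(subtrees[l]), l))
    return CladeAssignment({k: list(v) for k, v in clade_map.items()},
                           assignment, violations)
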