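"""phylogeny: JC closed forms, NJ correctness, bootstrap, rooting, clades."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from isfamily.alignment import MSA
from isfamily.phylogeny import (CladeAssignment, PhylogenyError, SaturationError,
                                assign_clades, bipartitions, bootstrap_consensus,
                                distance_matrix, jc_distance, msa_distance, nj,
                                p_distance, robinson_foulds, root_at_outgroup)


# --- distances -------------------------------------------------------------

def test_jc_closed_form_values():
    assert jc_distance(0.3, 4) == pytest.approx(0.38312, abs=5e-6)
    # a = 20 generalisation at p = 0.5: frozen from the closed form
    assert jc_distance(0.5, 20) == pytest.approx(0.70985, abs=5e-6)
    assert jc_distance(0.0, 4) == 0.0


def test_jc_small_p_limit_and_monotonicity():
    p = 1e-4
    assert abs(jc_distance(p, 4) - p) / p < 1e-3
    grid = np.linspace(0.01, 0.7, 30)
    vals = [jc_distance(float(x), 4) for x in grid]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert all(v >= g for v, g in zip(vals, grid))  # correction expands p


def test_jc_saturation_error_and_cap():
    with pytest.raises(SaturationError):
        jc_distance(0.95, 20)
    assert jc_distance(0.95, 20, cap=5.0) == 5.0
    with pytest.raises(SaturationError):
        jc_distance(0.75, 4)


def test_pairwise_gap_deletion():
    assert p_distance("AC-GT", "ACTGT") == 0.0
    assert p_distance("ACGGT", "AC-GA") == pytest.approx(0.25)
    assert msa_distance("AAAA", "AAAA", "jc_nt") == 0.0


# --- neighbour joining -----------------------------------------------------

def _leaf_edge_lengths(tree):
    return {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}


def test_nj_three_taxa_closed_form():
    names = list("ABC")
    d = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0]], index=names,
                     columns=names, dtype=float)
    tree = nj(d)
    lengths = _leaf_edge_lengths(tree)
    assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
    assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
    assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
    names = list("ABCD")
    d = pd.DataFrame([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
                     index=names, columns=names, dtype=float)
    tree = nj(d)
    assert bipartitions(tree) == {frozenset("CD")} or bipartitions(tree) == {frozenset("AB")}
    lengths = _leaf_edge_lengths(tree)
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)
    assert lengths["D"] == pytest.approx(1.0)


def _random_additive(n, rng):
    """Random binary topology with positive lengths; return (tree, distances)."""
    from dendropy.simulate import treesim

    taxa = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=tns,
        rng=rng)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = 0.2 + rng.random()
    pdm = tree.phylogenetic_distance_matrix()
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(taxa, 2):
        v = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
        d.loc[a, b] = d.loc[b, a] = v
    return tree, d


def _ls_best_topology(d):
    """Exhaustive least-squares tree over all unrooted topologies (n <= 6)."""
    names = list(d.columns)
    best = (None, np.inf)
    for bips, paths in _topology_catalog(len(names)):
        # paths: rows = leaf pairs, cols = edges, entries 0/1
        pairs = list(itertools.combinations(range(len(names)), 2))
        y = np.array([d.iloc[i, j] for i, j in pairs])
        x, *_ = np.linalg.lstsq(paths, y, rcond=None)
        sse = float(np.sum((paths @ x - y) ** 2))
        if sse < best[1] - 1e-12:
            best = (bips, sse)
    return {frozenset(names[i] for i in side) for side in best[0]}


def _topology_catalog(n):
    """Yield (internal bipartition sides, pair-edge incidence) for every
    unrooted binary topology on n leaves, by exhaustive leaf insertion on an
    explicit edge graph (15 topologies for n=5, 105 for n=6)."""
    pairs = list(itertools.combinations(range(n), 2))

    def topologies(edges, next_leaf, next_internal):
        if next_leaf == n:
            yield edges
            return
        for edge in list(edges):
            u, v = tuple(edge)
            w = next_internal
            new_edges = (edges - {edge}) | {frozenset((u, w)),
                                            frozenset((w, v)),
                                            frozenset((w, next_leaf))}
            yield from topologies(new_edges, next_leaf + 1, next_internal - 1)

    star = frozenset(frozenset((-1, i)) for i in range(3))
    for edges in topologies(set(star), 3, -2):
        adj = {}
        for e in edges:
            u, v = tuple(e)
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def side_of(edge):
            u, v = tuple(edge)
            comp, stack = set(), [u]
            while stack:
                node = stack.pop()
                if node in comp:
                    continue
                comp.add(node)
                for nb in adj[node]:
                    if frozenset((node, nb)) == edge or nb in comp:
                        continue
                    stack.append(nb)
            return frozenset(x for x in comp if x >= 0)

        edge_list = sorted(edges, key=sorted)
        sides = [side_of(e) for e in edge_list]
        inc = np.zeros((len(pairs), len(edge_list)))
        for r, (i, j) in enumerate(pairs):
            for c, side in enumerate(sides):
                if (i in side) != (j in side):
                    inc[r, c] = 1.0
        nontrivial = [s for s in sides if 1 < len(s) < n - 1]
        yield nontrivial, inc


def test_nj_matches_exhaustive_least_squares_on_additive_matrices():
    rng = np.random.default_rng(42)

    import random as _random
    py_rng = _random.Random(42)
    for n in (5, 6):
        for _ in range(5):
            true_tree, d = _random_additive(n, py_rng)
            got = nj(d)
            got_bips = bipartitions(got)
            want_bips = bipartitions(true_tree)
            assert got_bips == want_bips, "NJ must recover the additive tree"
            # and the generating topology is the least-squares optimum
            names = list(d.columns)

            def canon(bips):
                full = set(names)
                return {frozenset(min(b, frozenset(full - b), key=sorted)) for b in bips}

            ls = _ls_best_topology(d)
            assert canon(ls) == canon(want_bips)


def test_nj_additive_lengths_exact():
    """NJ on additive distances reproduces every patristic distance exactly
    (branch lengths, not just topology)."""
    import random as _random
    tree, d = _random_additive(6, _random.Random(9))
    got = nj(d)
    pdm = got.phylogenetic_distance_matrix()
    tns = got.taxon_namespace
    for a, b in itertools.combinations(d.columns, 2):
        v = pdm.distance(tns.get_taxon(a), tns.get_taxon(b))
        assert v == pytest.approx(d.loc[a, b], abs=1e-9)


def test_nj_deterministic_under_ties():
    names = list("ABCDE")
    d = pd.DataFrame(1.0, index=names, columns=names)
    np.fill_diagonal(d.values, 0.0)
    t1 = nj(d).as_string(schema="newick")
    t2 = nj(d).as_string(schema="newick")
    assert t1 == t2


def test_nj_input_validation():
    bad = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"),
                       dtype=float)
    with pytest.raises(PhylogenyError):
        nj(bad)
    neg = pd.DataFrame([[0, -1, 1], [-1, 0, 1], [1, 1, 0]], index=list("ABC"),
                       columns=list("ABC"), dtype=float)
    with pytest.raises(PhylogenyError):
        nj(neg)


def test_nj_agrees_with_skbio(small_records):
    """Independent implementation cross-check on a real distance matrix."""
    import io

    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    sub = small_records.subset(small_records.names[:8])
    msa = MSA([r.name for r in sub], [r.tnp for r in sub])
    d = distance_matrix(msa, "jc_aa")
    ours = nj(d)
    theirs_nwk = skbio_nj(DistanceMatrix(d.to_numpy(), ids=list(d.columns))
                          ).write(io.StringIO()).getvalue()
    theirs = dendropy.Tree.get(data=theirs_nwk, schema="newick",
                               preserve_underscores=True)
    assert robinson_foulds(ours, theirs) == 0


# --- bootstrap consensus ---------------------------------------------------

def _perfect_msa():
    # every column supports AB | CDE
    rows = ["AAAAAAAAAA", "AAAAAAAAAA", "TTTTTTTTTT", "TTTTTTTTGG", "TTTTTTTGGG"]
    return MSA(list("ABCDE"), rows)


def test_bootstrap_unanimous_split_gets_full_support():
    cons = bootstrap_consensus(_perfect_msa(), "p", B=50, seed=1)
    labels = {frozenset(l.taxon.label for l in n.leaf_iter()): n.label
              for n in cons.preorder_node_iter()
              if n.parent_node is not None and not n.is_leaf()}
    ab = frozenset("AB")
    matching = [v for k, v in labels.items() if k == ab or k == frozenset("CDE")]
    assert matching and all(v == "100" for v in matching)


def test_bootstrap_deterministic_for_fixed_seed(small_records):
    sub = small_records.subset(small_records.names[:6])
    msa = MSA([r.name for r in sub], [r.tnp for r in sub])
    a = bootstrap_consensus(msa, "jc_aa", B=30, seed=7).as_string(schema="newick")
    b = bootstrap_consensus(msa, "jc_aa", B=30, seed=7).as_string(schema="newick")
    assert a == b


def test_bootstrap_supports_are_majorities(small_records):
    sub = small_records.subset(small_records.names[:8])
    msa = MSA([r.name for r in sub], [r.tnp for r in sub])
    cons = bootstrap_consensus(msa, "jc_aa", B=40, seed=3)
    sups = [int(n.label) for n in cons.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf() and n.label]
    assert sups and all(50 < s <= 100 for s in sups)


def test_bootstrap_requires_enough_rows():
    msa = MSA(list("ABC"), ["AAAA", "AAAT", "AATT"])
    with pytest.raises(PhylogenyError):
        bootstrap_consensus(msa, "p", B=5, seed=0)


# --- rooting and clades ----------------------------------------------------

def test_rooting_preserves_bipartitions_and_halves_pendant_edge():
    names = list("ABCD")
    d = pd.DataFrame([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
                     index=names, columns=names, dtype=float)
    tree = nj(d)
    pendant = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}["C"]
    rooted = root_at_outgroup(tree, "C")
    assert rooted.is_rooted
    assert bipartitions(rooted) == bipartitions(tree)
    kids = rooted.seed_node.child_nodes()
    out_edge = [k for k in kids if k.is_leaf() and k.taxon.label == "C"]
    assert out_edge and out_edge[0].edge.length == pytest.approx(pendant / 2)
    other = [k for k in kids if k is not out_edge[0]]
    assert other[0].edge.length == pytest.approx(pendant / 2)


def test_rooting_with_either_outgroup_same_ingroup_topology(small_records):
    sub = small_records.subset(small_records.names[:8])
    msa = MSA([r.name for r in sub], [r.tnp for r in sub])
    tree = nj(distance_matrix(msa, "jc_aa"))
    r1 = root_at_outgroup(tree, sub.names[0])
    r2 = root_at_outgroup(tree, sub.names[5])
    ingroup = [n for n in sub.names if n not in (sub.names[0], sub.names[5])]

    def restricted(t):
        keep = set(ingroup)
        out = set()
        for bip in bipartitions(t):
            side = frozenset(bip & keep)
            if 1 < len(side) < len(keep) - 1:
                out.add(min(side, frozenset(keep - side), key=sorted))
        return out

    assert restricted(r1) == restricted(r2)


def test_root_missing_leaf():
    d = pd.DataFrame([[0, 1, 2], [1, 0, 2], [2, 2, 0]], index=list("ABC"),
                     columns=list("ABC"), dtype=float)
    with pytest.raises(PhylogenyError, match="nope"):
        root_at_outgroup(nj(d), "nope")


def test_assign_clades_planted_and_violations():
    nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);"
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    good = assign_clades(tree, {"left": ["A", "B"], "right": ["C", "D"]})
    assert good.violations == []
    assert good.assignment == {"A": "left", "B": "left", "C": "right",
                               "D": "right", "E": "solo", "F": "solo"}
    # references spanning two planted clades force an overlap report
    merged = assign_clades(tree, {"big": ["A", "C"], "small": ["C", "D"]})
    assert merged.violations
    # a single-reference clade is just that leaf
    single = assign_clades(tree, {"only": ["E"]})
    assert single.assignment["E"] == "only" and single.assignment["F"] == "solo"


def test_assign_clades_missing_reference():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
    with pytest.raises(PhylogenyError):
        assign_clades(tree, {"x": ["A", "ZZZ"]})


def test_topology_recovery_over_replicates():
    """NJ on the stacked aa alignment recovers the generating topology."""
    from isfamily.synthetic import SimulationConfig, simulate_family

    ok = 0
    for s in range(15):
        rs, truth = simulate_family(SimulationConfig(seed=300 + s, n_taxa=12,
                                                     isoform_pairs=0))
        msa = MSA([r.name for r in rs], [r.tnp for r in rs])
        tree = nj(distance_matrix(msa, "jc_aa"))
        ok += robinson_foulds(tree, truth.tree()) == 0
    assert ok >= 14
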