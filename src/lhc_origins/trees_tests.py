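"""Distance trees, topology tests, and parsimony character evolution.

Covers the tree-level analyses of the pipeline: neighbor-joining with
ML pairwise distances and nonparametric bootstrap, majority-rule
consensus, the Shimodaira-Hasegawa and expected-likelihood-weight
topology tests via RELL (resampling estimated log-likelihoods), and
unordered-parsimony reconstruction of family presence/absence characters
on a rooted species tree with inference of each family's origin node.

Parsimony uses the minimum-change (Fitch/Sankoff) criterion; the set of
states a node takes across *all* most-parsimonious reconstructions is
computed exactly, so ambiguity is reported rather than silently
resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .evolve_models import RateModel, ml_pair_distance
from .seqio import Alignment


@dataclass
class DistanceMatrix:
    taxa: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


@dataclass
class CharacterMatrix:
    taxa: list
    characters: list
    matrix: np.ndarray  # taxa x characters, entries in {0,1}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("character states must be 0/1")
        self.matrix = m

    def states(self, character: str) -> dict:
        j = self.characters.index(character)
        return {t: int(self.matrix[i, j]) for i, t in enumerate(self.taxa)}


@dataclass
class AncestralStates:
    tree: dendropy.Tree
    characters: list
    #: character -> node label -> frozenset of MPR states
    mpr: dict
    #: character -> node label -> resolved state (one optimal labeling)
    resolved: dict
    #: character -> parsimony score (minimum number of changes)
    scores: dict


def distance_matrix(alignment: Alignment, model: RateModel) -> DistanceMatrix:
    """All pairwise ML distances under the model's gamma mixture."""
    recs = alignment.records
    n = len(recs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ml_pair_distance(recs[i].residues, recs[j].residues, model)
            m[i, j] = m[j, i] = d
    return DistanceMatrix([r.id for r in recs], m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Negative branch-length estimates are clamped to zero with the
    deficit moved to the sister branch.  Ties in the Q criterion break on
    the lexicographically smallest label pair, so the result does not
    depend on input taxon order.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa_ns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes = []
    for label in dm.taxa:
        node = dendropy.Node(taxon=taxa_ns.get_taxon(label))
        nodes.append(node)
    labels = list(dm.taxa)
    d = dm.matrix.copy()
    active = list(range(n))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), (i, j))
            for i, j in cand if i < j
        )[1]
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        for child, ln in ((nodes[ai], li), (nodes[aj], lj)):
            parent.add_child(child)
            child.edge.length = ln
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (ai, aj):
                continue
            new_row[k] = max((d[ai, k] + d[aj, k] - dij) / 2, 0.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        labels.append(f"__internal{len(nodes)}")
        active = [k for k in active if k not in (ai, aj)] + [len(nodes) - 1]

    # join the final three nodes at an unrooted trifurcation
    x, y, z = active
    root = dendropy.Node()
    lx = (d[x, y] + d[x, z] - d[y, z]) / 2
    ly = (d[x, y] + d[y, z] - d[x, z]) / 2
    lz = (d[x, z] + d[y, z] - d[x, y]) / 2
    for idx, ln in ((x, lx), (y, ly), (z, lz)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa_ns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap and consensus
# ---------------------------------------------------------------------------

def _splits(tree: dendropy.Tree, ref: str) -> set:
    """Nontrivial bipartitions as frozensets of the side without *ref*."""
    all_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = frozenset(all_labels - side)
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side)
    return out


def bootstrap_support(alignment: Alignment, model: RateModel, B: int,
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree from ML distances, with bootstrap split support in percent.

    Columns are resampled with replacement B times; distances and the NJ
    tree are recomputed per replicate, and each internal bipartition of
    the full-data tree is annotated (node label) with its replicate
    frequency.
    """
    if len(alignment) < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    if B < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    tree0 = nj(distance_matrix(alignment, model))
    ref = alignment.ids()[0]
    counts: dict = {s: 0 for s in _splits(tree0, ref)}
    ncol = alignment.n_columns
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        rep_aln = alignment.subset_columns(list(cols))
        rep_tree = nj(distance_matrix(rep_aln, model))
        for s in _splits(rep_tree, ref):
            if s in counts:
                counts[s] += 1
    all_labels = {leaf.taxon.label for leaf in tree0.leaf_node_iter()}
    for node in tree0.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = frozenset(all_labels - side)
        if side in counts:
            node.label = f"{100.0 * counts[side] / B:.1f}"
    return tree0


def consensus(trees: list, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: splits with frequency strictly > threshold."""
    tip_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter())
                for t in trees]
    if len(set(tip_sets)) != 1:
        raise ValueError("trees must share an identical tip set")
    labels = sorted(tip_sets[0])
    ref = labels[0]
    counts: dict = {}
    for t in trees:
        for s in _splits(t, ref):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    kept = sorted(
        [(s, c / n) for s, c in counts.items() if c / n > threshold],
        key=lambda x: (-len(x[0]), sorted(x[0])))
    accepted: list = []
    for s, freq in kept:
        if all(s <= o or o <= s or not (s & o) for o, _ in accepted):
            accepted.append((s, freq))

    others = [l for l in labels if l != ref]

    def build(members: list, cands: list) -> str:
        parts = []
        used: set = set()
        for s, freq in cands:
            if set(s) <= set(members) and set(s) != set(members) and not (s & used):
                inner = [(s2, f2) for s2, f2 in cands if s2 < s]
                parts.append(build(sorted(s), inner) + f"{freq * 100:.0f}")
                used |= set(s)
        parts.extend(l for l in members if l not in used)
        return "(" + ",".join(parts) + ")"

    newick = "(" + ref + "," + build(others, accepted)[1:-1] + ");"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# RELL topology tests
# ---------------------------------------------------------------------------

def _rell_sums(site_logl: np.ndarray, B: int,
               rng: np.random.Generator) -> np.ndarray:
    """Per-replicate total log-likelihoods, shape (B, n_topologies)."""
    ntopo, nsites = site_logl.shape
    out = np.empty((B, ntopo))
    chunk = max(1, int(5e6 // max(nsites, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, nsites, size=(b, nsites))
        out[done:done + b] = site_logl[:, idx].sum(axis=2).T
        done += b
    return out


def sh_test(site_logl: np.ndarray, B: int = 10000, seed: int = 0) -> np.ndarray:
    """Shimodaira-Hasegawa p-values by RELL with centering.

    *site_logl* is (topologies x sites) of per-site log-likelihoods from
    the same data, each topology with branch lengths optimized.  The ML
    topology gets p = 1 by construction.
    """
    site_logl = np.asarray(site_logl, dtype=float)
    if site_logl.ndim != 2 or site_logl.shape[0] < 2:
        raise ValueError("need at least two topologies")
    rng = np.random.default_rng(seed)
    totals = site_logl.sum(axis=1)
    delta = totals.max() - totals
    reps = _rell_sums(site_logl, B, rng)
    centered = reps - reps.mean(axis=0, keepdims=True)
    stat = centered.max(axis=1, keepdims=True) - centered
    return (stat >= delta[None, :]).mean(axis=0)


def elw(site_logl: np.ndarray, B: int = 10000, seed: int = 0) -> np.ndarray:
    """Expected likelihood weights: mean softmax over RELL replicates."""
    site_logl = np.asarray(site_logl, dtype=float)
    if site_logl.ndim != 2 or site_logl.shape[0] < 1:
        raise ValueError("need at least one topology")
    if site_logl.shape[0] == 1:
        return np.array([1.0])
    rng = np.random.default_rng(seed)
    reps = _rell_sums(site_logl, B, rng)
    reps -= reps.max(axis=1, keepdims=True)
    w = np.exp(reps)
    w /= w.sum(axis=1, keepdims=True)
    return w.mean(axis=0)


# ---------------------------------------------------------------------------
# parsimony character evolution
# ---------------------------------------------------------------------------

def _node_label(node: dendropy.Node, i: int) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label if node.label else f"node{i}"


def fitch(tree: dendropy.Tree, chars: CharacterMatrix) -> AncestralStates:
    """Minimum-change ancestral states for unordered binary characters.

    Requires a rooted tree (root with exactly two children).  For every
    node the exact set of states over all most-parsimonious
    reconstructions is computed by dynamic programming over subtree and
    rest-of-tree costs; one optimal labeling (ties resolved toward the
    parent state) is also returned for change counting.
    """
    if tree.seed_node.num_child_nodes() != 2:
        raise ValueError("tree must be rooted (bifurcation at the root); "
                         "root it on the outgroup first")
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    if tips != set(chars.taxa):
        raise ValueError("tree tips and character-matrix taxa differ")

    post = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(post)}
    labels = {i: _node_label(n, i) for i, n in enumerate(post)}
    INF = 10 ** 9

    mpr_all: dict = {}
    resolved_all: dict = {}
    scores: dict = {}
    for character in chars.characters:
        obs = chars.states(character)
        down = np.zeros((len(post), 2), dtype=np.int64)
        for i, node in enumerate(post):
            if node.is_leaf():
                s = obs[node.taxon.label]
                down[i, 0] = 0 if s == 0 else INF
                down[i, 1] = 0 if s == 1 else INF
            else:
                for s in (0, 1):
                    total = 0
                    for c in node.child_nodes():
                        ci = index[id(c)]
                        total += min(down[ci, 0] + (s != 0),
                                     down[ci, 1] + (s != 1))
                    down[i, s] = total
        up = np.zeros((len(post), 2), dtype=np.int64)
        root_i = len(post) - 1
        up[root_i] = 0
        for node in tree.preorder_node_iter():
            i = index[id(node)]
            for c in node.child_nodes():
                ci = index[id(c)]
                sib_cost = {0: 0, 1: 0}
                for w in node.child_nodes():
                    if w is c:
                        continue
                    wi = index[id(w)]
                    for sp in (0, 1):
                        sib_cost[sp] += min(down[wi, 0] + (sp != 0),
                                            down[wi, 1] + (sp != 1))
                for sc in (0, 1):
                    up[ci, sc] = min(
                        up[i, sp] + (sp != sc) + sib_cost[sp]
                        for sp in (0, 1))
        total = down[root_i] + up[root_i]
        score = int(total.min())
        mpr = {}
        for i in range(len(post)):
            t = down[i] + up[i]
            mpr[labels[i]] = frozenset(s for s in (0, 1) if t[s] == score)
        # one optimal labeling, preferring the parent's state on ties
        resolved: dict = {}
        root_states = mpr[labels[root_i]]
        resolved[labels[root_i]] = min(root_states)
        for node in tree.preorder_node_iter():
            i = index[id(node)]
            ps = resolved[labels[i]]
            for c in node.child_nodes():
                ci = index[id(c)]
                costs = {s: down[ci, s] + (ps != s) for s in (0, 1)}
                best = min(costs.values())
                opts = [s for s in (0, 1) if costs[s] == best]
                resolved[labels[ci]] = ps if ps in opts else opts[0]
        mpr_all[character] = mpr
        resolved_all[character] = resolved
        scores[character] = score
    return AncestralStates(tree, list(chars.characters), mpr_all,
                           resolved_all, scores)


def infer_origins(states: AncestralStates) -> pd.DataFrame:
    """Per-character origin node and loss count.

    The origin is the most ancestral node whose MPR state set is exactly
    {present}; if several disjoint clades qualify the character has
    multiple origins and all are listed.  A character whose origin's
    parent is ambiguous ({0,1}) is flagged.
    """
    tree = states.tree
    post = list(tree.postorder_node_iter())
    labels = {id(n): _node_label(n, i) for i, n in enumerate(post)}
    rows = []
    for character in states.characters:
        mpr = states.mpr[character]
        resolved = states.resolved[character]
        present = {labels[id(n)] for n in post if mpr[labels[id(n)]] == frozenset({1})}
        keep = []
        ambiguous = False
        for node in tree.preorder_node_iter():
            lab = labels[id(node)]
            if lab not in present:
                continue
            parent = node.parent_node
            anc = set()
            p = parent
            while p is not None:
                anc.add(labels[id(p)])
                p = p.parent_node
            if anc & present:
                continue  # nested inside a more ancestral origin clade
            if parent is not None and mpr[labels[id(parent)]] == frozenset({0, 1}):
                ambiguous = True
            keep.append(lab)
        gains = losses = 0
        for node in tree.preorder_node_iter():
            p = node.parent_node
            if p is None:
                continue
            sp = resolved[labels[id(p)]]
            sc = resolved[labels[id(node)]]
            gains += sp == 0 and sc == 1
            losses += sp == 1 and sc == 0
        rows.append({"character": character,
                     "origin": "+".join(keep) if keep else "none",
                     "n_gains": int(gains), "n_losses": int(losses),
                     "score": states.scores[character],
                     "ambiguous": ambiguous})
    return pd.DataFrame(rows)
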