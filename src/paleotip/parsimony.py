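"""Parsimony scoring and heuristic tree search for unordered characters.

Tree length is computed with Hartigan's dynamic program, the
generalization of the Fitch pass to arbitrary (soft or hard) polytomies:
at each internal node, each candidate state receives one vote per child
whose state set contains it; the node keeps the majority states and pays
``(#children - #majority votes)`` steps.  Cells are *state sets*, so
missing data and polymorphisms are scored at no cost for any compatible
state.  Equal-weights (EW) and implied-weights (IW) optimality criteria
share the same per-character step counts; IW maximizes Goloboff's total
fit ``sum_i k/(k + h_i)`` with homoplasy ``h_i = s_i - m_i`` and
concavity ``k``.

Heuristic search is random-addition-sequence starting trees improved by
SPR and (optionally) TBR branch swapping until no improvement, returning
all distinct optimal topologies encountered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
from numba import njit

from .matrixio import CharacterMatrix
from .treesample import TreeSample

__all__ = [
    "ParsimonyScore",
    "tree_length",
    "implied_fit",
    "char_min_steps",
    "char_max_steps",
    "search",
    "bootstrap_support",
]


# ---------------------------------------------------------------------------
# scoring kernel


@njit(cache=True)
def _hartigan_steps(order, child_ptr, child_idx, tiprow, tipmasks, kmax, out):
    """Per-character parsimony steps by Hartigan's algorithm.

    order: all node ids in postorder; tiprow[v] >= 0 marks a leaf and its
    row in tipmasks; children of internal v are child_idx[child_ptr[v]:
    child_ptr[v+1]].  out receives integer steps per character.
    """
    n_nodes = order.shape[0]
    n_char = tipmasks.shape[1]
    masks = np.zeros(n_nodes, dtype=np.int64)
    for c in range(n_char):
        steps = 0
        for oi in range(n_nodes):
            v = order[oi]
            if tiprow[v] >= 0:
                masks[v] = tipmasks[tiprow[v], c]
            else:
                best = 0
                bestmask = 0
                for s in range(kmax):
                    cnt = 0
                    for ci in range(child_ptr[v], child_ptr[v + 1]):
                        if (masks[child_idx[ci]] >> s) & 1:
                            cnt += 1
                    if cnt > best:
                        best = cnt
                        bestmask = 1 << s
                    elif cnt == best and cnt > 0:
                        bestmask |= 1 << s
                masks[v] = bestmask
                steps += (child_ptr[v + 1] - child_ptr[v]) - best
        out[c] = steps
    return out


def _dendropy_arrays(tree: dendropy.Tree, matrix: CharacterMatrix):
    """Flatten a dendropy tree into kernel arrays."""
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder_node_iter())
    node_id = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    order = np.arange(n, dtype=np.int64)
    tiprow = np.full(n, -1, dtype=np.int64)
    child_ptr = np.zeros(n + 1, dtype=np.int64)
    kids = []
    for i, nd in enumerate(nodes):
        ch = nd.child_nodes()
        if not ch:
            label = nd.taxon.label
            if label not in taxon_index:
                raise ValueError(f"tree tip {label!r} absent from matrix")
            tiprow[i] = taxon_index[label]
        else:
            kids.extend(node_id[id(c)] for c in ch)
        child_ptr[i + 1] = len(kids)
    return order, child_ptr, np.array(kids, dtype=np.int64), tiprow


def char_steps(tree: dendropy.Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character parsimony steps of ``tree`` on ``matrix``."""
    order, child_ptr, child_idx, tiprow = _dendropy_arrays(tree, matrix)
    out = np.zeros(matrix.n_char, dtype=np.int64)
    _hartigan_steps(
        order, child_ptr, child_idx, tiprow,
        matrix.masks.astype(np.int64), int(matrix.n_states.max()), out,
    )
    return out


# ---------------------------------------------------------------------------
# per-character bounds


def _resolved_counts(matrix: CharacterMatrix, j: int) -> dict[int, int]:
    """Resolve non-missing cells of character j to single states.

    Polymorphic cells count under their most frequent compatible state
    (frequencies from unambiguous cells, ties to the lowest state) —
    the convention used for the worst-case step count g_i.
    """
    k = int(matrix.n_states[j])
    full = (1 << k) - 1
    cells = [int(m) for m in matrix.masks[:, j] if int(m) != full]
    freq = np.zeros(k, dtype=np.int64)
    for m in cells:
        if m & (m - 1) == 0:  # singleton
            freq[m.bit_length() - 1] += 1
    counts: dict[int, int] = {}
    for m in cells:
        members = [s for s in range(k) if m >> s & 1]
        s = max(members, key=lambda x: (freq[x], -x))
        counts[s] = counts.get(s, 0) + 1
    return counts


def char_min_steps(matrix: CharacterMatrix) -> np.ndarray:
    """Minimum conceivable steps m_i per character on any tree.

    With uncertainty-set cells this is (size of the smallest set of
    states hitting every non-missing cell) - 1, found exactly by subset
    enumeration over the (small) alphabet.
    """
    out = np.zeros(matrix.n_char, dtype=np.int64)
    for j in range(matrix.n_char):
        k = int(matrix.n_states[j])
        full = (1 << k) - 1
        cells = {int(m) for m in matrix.masks[:, j] if int(m) != full}
        if not cells:
            continue
        best = k
        for size in range(1, k + 1):
            found = False
            for combo in itertools.combinations(range(k), size):
                s = sum(1 << x for x in combo)
                if all(m & s for m in cells):
                    found = True
                    break
            if found:
                best = size
                break
        out[j] = best - 1
    return out


def char_max_steps(matrix: CharacterMatrix) -> np.ndarray:
    """Worst-tree steps g_i = (#scored taxa) - (frequency of the most
    common resolved state), the unordered-character bound."""
    out = np.zeros(matrix.n_char, dtype=np.int64)
    for j in range(matrix.n_char):
        counts = _resolved_counts(matrix, j)
        if counts:
            n_scored = sum(counts.values())
            out[j] = n_scored - max(counts.values())
    return out


@dataclass
class ParsimonyScore:
    """Tree length with ensemble statistics for one (tree, matrix) pair."""

    steps: np.ndarray  # s_i per character
    min_steps: np.ndarray  # m_i
    max_steps: np.ndarray  # g_i
    weights: np.ndarray | None = None  # character weights (bootstrap)

    @property
    def length(self) -> int:
        w = self.weights if self.weights is not None else 1
        return int(np.sum(self.steps * w))

    @property
    def homoplasy(self) -> np.ndarray:
        return self.steps - self.min_steps

    @property
    def ci(self) -> float:
        s = float(self.steps.sum())
        return float(self.min_steps.sum()) / s if s > 0 else 1.0

    @property
    def ri(self) -> float:
        g, m, s = (float(x.sum()) for x in (self.max_steps, self.min_steps, self.steps))
        return (g - s) / (g - m) if g > m else 1.0

    def fit(self, k: float) -> float:
        return implied_fit(self, k)


def tree_length(
    tree: dendropy.Tree, matrix: CharacterMatrix, weights: np.ndarray | None = None
) -> ParsimonyScore:
    """Parsimony score of a (possibly multifurcating) tree."""
    return ParsimonyScore(
        steps=char_steps(tree, matrix),
        min_steps=char_min_steps(matrix),
        max_steps=char_max_steps(matrix),
        weights=None if weights is None else np.asarray(weights, dtype=np.int64),
    )


def implied_fit(score: ParsimonyScore, k: float) -> float:
    """Goloboff's total fit sum_i k/(k + h_i); larger is better."""
    if k <= 0:
        raise ValueError("concavity k must be positive")
    w = score.weights if score.weights is not None else np.ones_like(score.steps)
    return float(np.sum(w * k / (k + score.homoplasy)))


# ---------------------------------------------------------------------------
# search trees: light mutable binary structure, leaf-rooted


class _N:
    __slots__ = ("children", "parent", "tip")

    def __init__(self, tip: int = -1):
        self.children: list["_N"] = []
        self.parent: "_N" | None = None
        self.tip = tip


def _link(p: _N, c: _N) -> None:
    p.children.append(c)
    c.parent = p


def _copy(root: _N) -> _N:
    new = _N(root.tip)
    for c in root.children:
        _link(new, _copy(c))
    return new


def _postorder(root: _N):
    stack, out = [root], []
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(v.children)
    return out[::-1]


def _arrays(root: _N):
    nodes = _postorder(root)
    idx = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    tiprow = np.full(n, -1, dtype=np.int64)
    child_ptr = np.zeros(n + 1, dtype=np.int64)
    kids = []
    for i, nd in enumerate(nodes):
        tiprow[i] = nd.tip
        kids.extend(idx[id(c)] for c in nd.children)
        child_ptr[i + 1] = len(kids)
    return np.arange(n, dtype=np.int64), child_ptr, np.array(kids, dtype=np.int64), tiprow


class _Scorer:
    """Caches matrix arrays and evaluates search objectives."""

    def __init__(self, matrix: CharacterMatrix, criterion: str, k: float,
                 weights: np.ndarray | None):
        self.matrix = matrix
        self.criterion = criterion
        self.k = float(k)
        self.tipmasks = matrix.masks.astype(np.int64)
        self.kmax = int(matrix.n_states.max())
        self.w = np.ones(matrix.n_char) if weights is None else np.asarray(weights, float)
        self.m = char_min_steps(matrix).astype(float)
        self._buf = np.zeros(matrix.n_char, dtype=np.int64)

    def steps(self, root: _N) -> np.ndarray:
        order, cp, ci, tr = _arrays(root)
        _hartigan_steps(order, cp, ci, tr, self.tipmasks, self.kmax, self._buf)
        return self._buf

    def objective(self, root: _N) -> float:
        """Lower is better for both criteria."""
        s = self.steps(root)
        if self.criterion == "ew":
            return float(np.sum(s * self.w))
        h = s - self.m
        return float(np.sum(self.w * (1.0 - self.k / (self.k + h))))


def _splits_key(root: _N, n_taxa: int) -> frozenset[int]:
    """Canonical unrooted-topology key: taxon bitmasks of the side not
    containing taxon 0, over all internal edges."""
    out = set()
    full = (1 << n_taxa) - 1
    below: dict[int, int] = {}
    for v in _postorder(root):
        m = (1 << v.tip) if v.tip >= 0 else 0
        for c in v.children:
            m |= below[id(c)]
        below[id(v)] = m
        if v.parent is not None:
            s = m if not (m & 1) else (full & ~m)
            if s.bit_count() >= 2 and (full & ~s).bit_count() >= 2:
                out.add(s)
    return frozenset(out)


def _to_dendropy(root: _N, taxa: list[str],
                 tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    tns = tns or dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(v: _N, parent):
        nd = dendropy.Node()
        if v.tip >= 0:
            nd.taxon = tns.get_taxon(taxa[v.tip])
        parent.add_child(nd)
        for c in v.children:
            build(c, nd)

    for c in root.children:
        build(c, tree.seed_node)
    if root.tip >= 0:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(taxa[root.tip])
        tree.seed_node.add_child(nd)
    return tree


def _from_dendropy(tree: dendropy.Tree, taxa: list[str]) -> _N:
    index = {t: i for i, t in enumerate(taxa)}

    def build(nd) -> _N:
        if nd.is_leaf():
            return _N(index[nd.taxon.label])
        v = _N()
        for c in nd.child_nodes():
            _link(v, build(c))
        return v

    return build(tree.seed_node)


def _random_addition(scorer: _Scorer, rng: np.random.Generator) -> _N:
    """Stepwise addition in random taxon order, greedy best edge."""
    n = scorer.matrix.n_taxa
    order = list(rng.permutation(n))
    a, b, c = order[:3]
    root = _N()
    _link(root, _N(a))
    inner = _N()
    _link(inner, _N(b))
    _link(inner, _N(c))
    _link(root, inner)
    for t in order[3:]:
        best, best_obj = None, np.inf
        edges = [v for v in _postorder(root) if v.parent is not None]
        perm = rng.permutation(len(edges))
        for ei in perm:
            v = edges[ei]
            p = v.parent
            mid = _N()
            pos = p.children.index(v)
            p.children[pos] = mid
            mid.parent = p
            leaf = _N(t)
            _link(mid, v)
            _link(mid, leaf)
            obj = scorer.objective(root)
            if obj < best_obj - 1e-12:
                best_obj, best = obj, v
            # undo
            p.children[pos] = v
            v.parent = p
        # commit
        v = best
        p = v.parent
        mid = _N()
        pos = p.children.index(v)
        p.children[pos] = mid
        mid.parent = p
        _link(mid, v)
        _link(mid, _N(t))
    return root


def _detach(v: _N) -> tuple[_N, _N, _N, int]:
    """Remove subtree v, suppressing its (kept-aside) parent node.
    Returns (parent, sibling, grandparent, position) for undo."""
    p = v.parent
    g = p.parent
    sib = p.children[0] if p.children[1] is v else p.children[1]
    pos = g.children.index(p)
    g.children[pos] = sib
    sib.parent = g
    v.parent = None
    p.parent = None  # p floats until _undo_detach or garbage collection
    return p, sib, g, pos


def _undo_detach(v: _N, p: _N, sib: _N, g: _N, pos: int) -> None:
    g.children[pos] = p
    p.parent = g
    sib.parent = p
    v.parent = p  # p.children still [sib, v] in some order


def _attach(v: _N, edge_child: _N) -> _N:
    """Insert v on the edge above edge_child; returns the new mid node."""
    p = edge_child.parent
    mid = _N()
    pos = p.children.index(edge_child)
    p.children[pos] = mid
    mid.parent = p
    _link(mid, edge_child)
    _link(mid, v)
    return mid


def _remove_mid(mid: _N, v: _N) -> None:
    """Undo _attach."""
    p = mid.parent
    other = mid.children[0] if mid.children[1] is v else mid.children[1]
    pos = p.children.index(mid)
    p.children[pos] = other
    other.parent = p
    v.parent = None


def _reroots(v: _N):
    """All rootings of the unrooted version of subtree v, for TBR.

    Each edge of the subtree yields a fresh copy rooted on that edge; the
    old degree-2 root is suppressed during re-orientation.
    """
    yield _copy(v)
    if not v.children:
        return
    nodes = _postorder(v)
    adj: dict[int, list[_N]] = {id(x): [] for x in nodes}
    for x in nodes:
        if x.parent is not None:
            adj[id(x)].append(x.parent)
            adj[id(x.parent)].append(x)

    def orient(node: _N, came_from: _N) -> _N:
        kids = [nb for nb in adj[id(node)] if nb is not came_from]
        if not kids:
            return _N(node.tip)
        if len(kids) == 1:  # suppress the old degree-2 root
            return orient(kids[0], node)
        nn = _N(node.tip)
        for kb in kids:
            _link(nn, orient(kb, node))
        return nn

    for x in nodes:
        if x.parent is None or x.parent is v:
            continue  # skip rootings equivalent to the original
        r = _N()
        _link(r, orient(x, x.parent))
        _link(r, orient(x.parent, x))
        yield r


def _connected(v: _N, root: _N) -> bool:
    x = v
    while x.parent is not None:
        x = x.parent
    return x is root


def _swap_sweep(root: _N, scorer: _Scorer, obj: float, tbr: bool) -> tuple[float, bool]:
    """One first-improvement SPR (optionally TBR) pass over all subtrees.

    Improvements are accepted in place and the pass continues; nodes
    orphaned by an accepted rearrangement are detected by a cheap
    connectivity walk and skipped (the next pass revisits everything).
    Mutates the tree; returns (objective, improved any?).
    """
    improved_any = False
    nodes = [v for v in _postorder(root) if v.parent is not None and v.parent.parent is not None]
    for v in nodes:
        if (
            v.parent is None
            or v.parent.parent is None
            or v not in v.parent.children
            or not _connected(v, root)
        ):
            continue
        p, sib, g, pos = _detach(v)
        remaining = [x for x in _postorder(root) if x.parent is not None]
        variants = list(_reroots(v)) if (tbr and v.children) else [v]
        accepted = False
        for var in variants:
            for ec in remaining:
                mid = _attach(var, ec)
                new_obj = scorer.objective(root)
                if new_obj < obj - 1e-9:
                    obj = new_obj
                    improved_any = accepted = True
                    break
                _remove_mid(mid, var)
            if accepted:
                break
        if not accepted:
            _undo_detach(v, p, sib, g, pos)
    return obj, improved_any


def search(
    matrix: CharacterMatrix,
    criterion: str = "ew",
    k: float = 12.0,
    n_starts: int = 10,
    seed: int = 0,
    weights: np.ndarray | None = None,
    tbr: bool | str = "auto",
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> TreeSample:
    """Heuristic parsimony search.

    Random-addition starting trees, improved by SPR (and TBR rerooting of
    the pruned clade) to a local optimum; all distinct optimal unrooted
    topologies found across starts are returned.  Deterministic under a
    fixed seed.  ``tbr="auto"`` enables the cubic TBR neighborhood only on
    small trees (<= 24 taxa), where its cost is negligible; extra random
    starts are the cheaper route to the optimum on larger matrices.
    """
    if matrix.n_taxa < 4:
        raise ValueError("search needs at least 4 taxa")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if criterion not in ("ew", "iw"):
        raise ValueError("criterion must be 'ew' or 'iw'")
    if tbr == "auto":
        tbr = matrix.n_taxa <= 24
    rng = np.random.default_rng(seed)
    scorer = _Scorer(matrix, criterion, k, weights)
    best_obj = np.inf
    best: dict[frozenset, _N] = {}
    for _ in range(n_starts):
        root = _random_addition(scorer, rng)
        obj = scorer.objective(root)
        improved = True
        while improved:
            obj, improved = _swap_sweep(root, scorer, obj, tbr)
        if obj < best_obj - 1e-9:
            best_obj = obj
            best = {_splits_key(root, matrix.n_taxa): root}
        elif abs(obj - best_obj) <= 1e-9:
            key = _splits_key(root, matrix.n_taxa)
            if key not in best:
                best[key] = root
    trees = [_to_dendropy(r, matrix.taxa, taxon_namespace) for r in best.values()]
    tns = trees[0].taxon_namespace
    for t in trees[1:]:
        t.migrate_taxon_namespace(tns)
    scores = [tree_length(t, matrix, weights) for t in trees]
    import pandas as pd

    params = pd.DataFrame(
        {
            "length": [s.length for s in scores],
            "ci": [s.ci for s in scores],
            "ri": [s.ri for s in scores],
            "fit": [s.fit(k) for s in scores],
        }
    )
    return TreeSample(trees=trees, params=params)


def bootstrap_support(
    matrix: CharacterMatrix,
    B: int = 100,
    criterion: str = "ew",
    k: float = 12.0,
    seed: int = 0,
    n_starts: int = 2,
    tbr: bool = False,
) -> dict[frozenset, float]:
    """Nonparametric bootstrap over characters.

    Each replicate resamples characters with replacement (as integer
    weights), re-runs the search, and every split is credited with the
    fraction of that replicate's optimal trees containing it.  Returns
    split -> support in percent, splits keyed as frozensets of taxon
    labels (the side without the first taxon).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    acc: dict[frozenset, float] = {}
    for b in range(B):
        w = rng.multinomial(matrix.n_char, np.full(matrix.n_char, 1.0 / matrix.n_char))
        res = search(
            matrix, criterion=criterion, k=k, n_starts=n_starts,
            seed=int(rng.integers(2**31 - 1)), weights=w, tbr=tbr,
        )
        per_tree = 1.0 / len(res.trees)
        seen: dict[frozenset, float] = {}
        for t in res.trees:
            r = _from_dendropy(t, matrix.taxa)
            for s in _splits_key(r, matrix.n_taxa):
                labels = frozenset(
                    matrix.taxa[i] for i in range(matrix.n_taxa) if s >> i & 1
                )
                seen[labels] = seen.get(labels, 0.0) + per_tree
        for key, frac in seen.items():
            acc[key] = acc.get(key, 0.0) + frac
    return {key: 100.0 * v / B for key, v in acc.items()}
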