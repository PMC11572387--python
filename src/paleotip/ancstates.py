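"""Ancestral-state reconstruction and synapomorphy extraction.

Two routes, as is usual for discrete morphology:

* **Parsimony mapping** — Hartigan down/up passes give the set of states
  each node can take in at least one most-parsimonious reconstruction; a
  branch carries an *unambiguous* change when the parent and child final
  sets are disjoint, and an *ambiguous* one when the sets differ but
  overlap (polymorphic codings surface as ambiguous).  One concrete
  optimal resolution is also produced, whose change count equals the
  character's parsimony length on the tree.

* **Stochastic mapping** — for each character the k-state Markov model is
  fitted by maximum likelihood under equal (ER), symmetric (SYM) or
  all-rates-different (ARD) constraints, the best model chosen by AIC,
  and full character histories are then sampled conditional on the tip
  data (node states from their conditional distributions, branch paths by
  endpoint-conditioned simulation with a uniformization fallback).

Branches are keyed by the frozenset of leaf labels below them.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .matrixio import CharacterMatrix

__all__ = [
    "BranchChange",
    "ParsimonyMap",
    "StochasticMap",
    "parsimony_map",
    "fit_mk_variant",
    "select_model",
    "stochastic_map",
    "synapomorphies",
    "MkFit",
]


@dataclass(frozen=True)
class BranchChange:
    char: int
    clade: frozenset  # leaves below the branch
    from_states: tuple
    to_states: tuple
    ambiguous: bool


def _clade_sets(tree: dendropy.Tree) -> dict[int, frozenset]:
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            s = frozenset()
            for ch in node.child_nodes():
                s |= below[id(ch)]
            below[id(node)] = s
    return below


# ---------------------------------------------------------------------------
# parsimony mapping


@dataclass
class ParsimonyMap:
    changes: list[BranchChange]
    resolved: list[BranchChange]  # one concrete optimal resolution
    node_sets: dict[int, dict[frozenset, frozenset]]  # char -> clade -> MPR state set
    char_lengths: np.ndarray

    def changes_on(self, clade: frozenset, resolved: bool = False) -> list[BranchChange]:
        pool = self.resolved if resolved else self.changes
        return [c for c in pool if c.clade == clade]


def _bits(m: int) -> tuple:
    return tuple(s for s in range(16) if m >> s & 1)


def parsimony_map(tree: dendropy.Tree, matrix: CharacterMatrix) -> ParsimonyMap:
    """Hartigan most-parsimonious reconstruction on a (possibly
    multifurcating) tree, with per-branch change calls."""
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    below = _clade_sets(tree)
    nodes = list(tree.postorder_node_iter())
    changes: list[BranchChange] = []
    resolved: list[BranchChange] = []
    node_sets: dict[int, dict[frozenset, frozenset]] = {}
    lengths = np.zeros(matrix.n_char, dtype=np.int64)

    for j in range(matrix.n_char):
        k = int(matrix.n_states[j])
        VU: dict[int, int] = {}
        VL: dict[int, int] = {}
        # down-pass
        for node in nodes:
            if node.is_leaf():
                VU[id(node)] = int(matrix.masks[taxon_index[node.taxon.label], j])
                VL[id(node)] = 0
                continue
            counts = np.zeros(k, dtype=int)
            for ch in node.child_nodes():
                m = VU[id(ch)]
                for s in range(k):
                    counts[s] += m >> s & 1
            mx = counts.max()
            VU[id(node)] = int(sum(1 << s for s in range(k) if counts[s] == mx))
            VL[id(node)] = int(sum(1 << s for s in range(k) if counts[s] == mx - 1)) if mx > 1 else 0
            lengths[j] += len(node.child_nodes()) - mx
        # up-pass: final sets
        F: dict[int, int] = {}
        for node in reversed(nodes):
            if node.parent_node is None:
                F[id(node)] = VU[id(node)]
            else:
                K = F[id(node.parent_node)]
                vu, vl = VU[id(node)], VL[id(node)]
                if node.is_leaf():
                    F[id(node)] = (vu & K) or vu
                elif (K & vu) == K:
                    F[id(node)] = K
                else:
                    F[id(node)] = vu | (K & vl)
        node_sets[j] = {below[id(n)]: frozenset(_bits(F[id(n)])) for n in nodes}
        # change calls
        for node in nodes:
            p = node.parent_node
            if p is None:
                continue
            fp, fc = F[id(p)], F[id(node)]
            if fp & fc:
                if fp != fc:
                    changes.append(
                        BranchChange(j, below[id(node)], _bits(fp), _bits(fc), True)
                    )
            else:
                changes.append(
                    BranchChange(j, below[id(node)], _bits(fp), _bits(fc), False)
                )
        # one concrete optimal resolution (Hartigan's construction)
        assign: dict[int, int] = {}
        for node in reversed(nodes):
            if node.parent_node is None:
                assign[id(node)] = min(_bits(VU[id(node)]))
            else:
                sp = assign[id(node.parent_node)]
                pool = VU[id(node)]
                assign[id(node)] = sp if (pool >> sp & 1) else min(_bits(pool))
                if assign[id(node)] != sp:
                    resolved.append(
                        BranchChange(j, below[id(node)], (sp,), (assign[id(node)],), False)
                    )
    return ParsimonyMap(changes, resolved, node_sets, lengths)


# ---------------------------------------------------------------------------
# Mk variants on a dated tree


def _build_q(k: int, rates: np.ndarray, model: str) -> np.ndarray:
    Q = np.zeros((k, k))
    idx = 0
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        for a in range(k):
            for b in range(a + 1, k):
                Q[a, b] = Q[b, a] = rates[idx]
                idx += 1
    elif model == "ARD":
        for a in range(k):
            for b in range(k):
                if a != b:
                    Q[a, b] = rates[idx]
                    idx += 1
    else:
        raise ValueError("model must be ER, SYM or ARD")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _n_params(k: int, model: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model]


def _char_partials(tree, matrix, j, taxon_index):
    k = int(matrix.n_states[j])
    out = {}
    for leaf in tree.leaf_node_iter():
        m = int(matrix.masks[taxon_index[leaf.taxon.label], j])
        out[id(leaf)] = np.array([(m >> s) & 1 for s in range(k)], dtype=float)
    return out


def _propagator(Q):
    """P(t) factory: eigendecomposition when well-conditioned, expm otherwise."""
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            def P(t):
                M = (V * np.exp(w * t)) @ Vi
                return np.maximum(M.real, 0.0)
            return P
    except np.linalg.LinAlgError:
        pass
    return lambda t: expm(Q * t)


def _loglik_q(tree, tip_partials, Q, k):
    store = {}
    logscale = 0.0
    P = _propagator(Q)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            store[id(node)] = tip_partials[id(node)]
            continue
        L = np.ones(k)
        for ch in node.child_nodes():
            t = ch.edge.length or 0.0
            L = L * (P(t) @ store.pop(id(ch)))
        mx = L.max()
        if mx <= 0:
            return -np.inf
        L /= mx
        logscale += np.log(mx)
        store[id(node)] = L
    root = store[id(tree.seed_node)]
    return float(np.log(root.mean()) + logscale)


@dataclass
class MkFit:
    model: str
    k: int
    rates: np.ndarray
    loglik: float
    aic: float
    boundary: bool = False  # rate pinned at the lower optimization bound

    def q_matrix(self) -> np.ndarray:
        return _build_q(self.k, self.rates, self.model)


def fit_mk_variant(tree: dendropy.Tree, matrix: CharacterMatrix, char: int,
                   model: str = "ER") -> MkFit:
    """ML fit of one rate-constraint class for one character on a dated tree."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length or 0.0) < 0:
            raise ValueError("dated tree required: negative duration found")
    total_len = sum(nd.edge.length or 0.0 for nd in tree.preorder_node_iter()
                    if nd.parent_node is not None)
    if total_len <= 0:
        raise ValueError("dated tree required: zero total duration")
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    k = int(matrix.n_states[char])
    tips = _char_partials(tree, matrix, char, taxon_index)
    p = _n_params(k, model)
    lo, hi = np.log(1e-8), np.log(50.0)

    def nll(logr):
        Q = _build_q(k, np.exp(np.clip(logr, lo, hi)), model)
        return -_loglik_q(tree, tips, Q, k)

    x0 = np.full(p, np.log(max(1.0 / total_len, 1e-6)))
    res = minimize(nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * p,
                   options={"maxiter": 200, "maxfun": 2000})
    rates = np.exp(res.x)
    ll = -float(res.fun)
    # a vanishing rate means the data carry no changes for this class
    return MkFit(model, k, rates, ll, 2 * p - 2 * ll,
                 boundary=bool(np.any(rates < 1e-5)))


def select_model(tree: dendropy.Tree, matrix: CharacterMatrix, char: int,
                 models: tuple = ("ER", "SYM", "ARD")) -> MkFit:
    """Fit each rate class and return the best by AIC (ties -> simpler)."""
    fits = [fit_mk_variant(tree, matrix, char, m) for m in models]
    return min(fits, key=lambda f: (round(f.aic, 9), _n_params(f.k, f.model)))


# ---------------------------------------------------------------------------
# stochastic mapping


def _sample_path(rng, Q, a, b, t, max_tries=100):
    """Endpoint-conditioned CTMC path from a to b over duration t.

    Nielsen-style rejection (with the first event forced when a != b),
    then uniformization if rejection keeps failing or the branch is stiff.
    """
    k = Q.shape[0]
    mu0 = -Q.diagonal().min()
    if mu0 * t > 50:
        max_tries = 0  # rejection would simulate huge event counts
    for _ in range(max_tries):
        path = []
        s, tau = a, 0.0
        if a != b:
            rate = -Q[s, s]
            if rate <= 0:
                break
            # first event forced: truncated exponential on (0, t)
            u = rng.random()
            tau = -np.log(1 - u * (1 - np.exp(-rate * t))) / rate
            probs = Q[s].copy()
            probs[s] = 0
            probs = probs / probs.sum()
            s = rng.choice(k, p=probs)
            path.append((tau, s))
        while True:
            rate = -Q[s, s]
            dt = rng.exponential(1 / rate) if rate > 0 else np.inf
            if tau + dt >= t:
                break
            tau += dt
            probs = Q[s].copy()
            probs[s] = 0
            probs = probs / probs.sum()
            s = rng.choice(k, p=probs)
            path.append((tau, s))
        if s == b:
            return path
    # uniformization fallback
    mu = max(mu0, 1e-12)
    R = np.eye(k) + Q / mu
    Pt = expm(Q * t)
    if Pt[a, b] <= 0:
        raise RuntimeError("impossible endpoint pair")
    # sample the number of uniformized jumps
    from math import exp, lgamma, log, sqrt as math_sqrt

    Rpow = [np.eye(k)]
    n = 0
    cum = 0.0
    u = rng.random() * Pt[a, b]
    n_cap = int(mu * t + 12 * math_sqrt(mu * t) + 20)
    while True:
        w = exp(-mu * t + n * log(max(mu * t, 1e-300)) - lgamma(n + 1)) * Rpow[n][a, b]
        cum += w
        if cum >= u or n >= n_cap:
            break
        Rpow.append(Rpow[-1] @ R)
        n += 1
    # bridge the jump chain, reusing the cached powers of R
    while len(Rpow) <= n:
        Rpow.append(Rpow[-1] @ R)
    states = [a]
    for i in range(1, n):
        prev = states[-1]
        wts = R[prev, :] * Rpow[n - i][:, b]
        wts = np.maximum(wts, 0)
        states.append(rng.choice(k, p=wts / wts.sum()))
    states.append(b)
    times = np.sort(rng.random(n)) * t
    path = []
    cur = a
    for i in range(n):
        if states[i + 1] != cur:  # drop virtual jumps
            path.append((float(times[i]), int(states[i + 1])))
            cur = int(states[i + 1])
    return path


@dataclass
class StochasticMap:
    char: int
    fit: MkFit
    node_probs: dict[frozenset, np.ndarray]  # clade -> P(state) across maps
    expected_changes: dict[frozenset, float]  # branch -> mean #changes
    change_freq: dict[tuple, float]  # (clade, from, to) -> frequency across maps
    n_maps: int

    def dominant_change(self, clade: frozenset):
        cands = {kk: v for kk, v in self.change_freq.items() if kk[0] == clade}
        if not cands:
            return None
        (cl, a, b), f = max(cands.items(), key=lambda kv: kv[1])
        return (a, b, f)


def stochastic_map(tree: dendropy.Tree, matrix: CharacterMatrix, char: int,
                   fit: MkFit | None = None, n_maps: int = 1000,
                   seed: int = 0) -> StochasticMap:
    """Sample full character histories conditional on the tip data."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    if fit is None:
        fit = select_model(tree, matrix, char)
    rng = np.random.default_rng(seed)
    Q = fit.q_matrix()
    k = fit.k
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    tips = _char_partials(tree, matrix, char, taxon_index)
    below = _clade_sets(tree)
    nodes = list(tree.postorder_node_iter())
    # conditional likelihoods (downpass), kept per node
    L: dict[int, np.ndarray] = {}
    P_edge: dict[int, np.ndarray] = {}
    for node in nodes:
        if node.is_leaf():
            L[id(node)] = tips[id(node)].copy()
        else:
            v = np.ones(k)
            for ch in node.child_nodes():
                P_edge[id(ch)] = expm(Q * (ch.edge.length or 0.0))
                v = v * (P_edge[id(ch)] @ L[id(ch)])
            mx = v.max()
            L[id(node)] = v / (mx if mx > 0 else 1.0)

    node_counts = {below[id(n)]: np.zeros(k) for n in nodes}
    branch_changes = {below[id(n)]: 0.0 for n in nodes if n.parent_node is not None}
    change_counts: dict[tuple, int] = {}
    root = tree.seed_node
    for _ in range(n_maps):
        states: dict[int, int] = {}
        w = L[id(root)] / L[id(root)].sum()
        states[id(root)] = int(rng.choice(k, p=w))
        for node in reversed(nodes):
            if node.parent_node is None:
                continue
            sp = states[id(node.parent_node)]
            w = P_edge[id(node)][sp, :] * L[id(node)]
            w = w / w.sum()
            sc = int(rng.choice(k, p=w))
            states[id(node)] = sc
            path = _sample_path(rng, Q, sp, sc, node.edge.length or 0.0)
            clade = below[id(node)]
            branch_changes[clade] += len(path)
            cur = sp
            for _, s2 in path:
                change_counts[(clade, cur, s2)] = change_counts.get((clade, cur, s2), 0) + 1
                cur = s2
        for n in nodes:
            node_counts[below[id(n)]][states[id(n)]] += 1

    return StochasticMap(
        char=char,
        fit=fit,
        node_probs={c: v / n_maps for c, v in node_counts.items()},
        expected_changes={c: v / n_maps for c, v in branch_changes.items()},
        change_freq={kk: v / n_maps for kk, v in change_counts.items()},
        n_maps=n_maps,
    )


# ---------------------------------------------------------------------------
# synapomorphies


def synapomorphies(pmap: ParsimonyMap, clade: frozenset,
                   include_ambiguous: bool = False) -> list[dict]:
    """Character changes on the stem branch of ``clade``.

    A change is *exclusive* when its derived state is gained on no other
    branch of the tree (census over unambiguous changes plus the resolved
    map).  Raises if the clade is not a branch of the mapped tree.
    """
    all_clades = {c.clade for c in pmap.changes} | {c.clade for c in pmap.resolved}
    known = set()
    for ch_sets in pmap.node_sets.values():
        known |= set(ch_sets)
    if clade not in known:
        raise KeyError(f"clade {sorted(clade)} is not a node of the mapped tree")
    out = []
    stem = pmap.changes_on(clade)
    for ch in stem:
        if ch.ambiguous and not include_ambiguous:
            continue
        derived = set(ch.to_states)
        exclusive = True
        for other in pmap.changes + pmap.resolved:
            if other.char != ch.char or other.clade == clade:
                continue
            if not other.ambiguous and set(other.to_states) & derived:
                exclusive = False
                break
        out.append(
            {
                "char": ch.char,
                "from": ch.from_states,
                "to": ch.to_states,
                "ambiguous": ch.ambiguous,
                "exclusive": exclusive,
            }
        )
    return out
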