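"""Bayesian tip-dating under the fossilized birth-death (FBD) tree prior.

The model: a dated tree whose fossil tips carry uniform age priors, an
FBD prior on the tree (speciation λ, extinction μ, fossil sampling ψ per
lineage per My, extant sampling probability ρ), an offset-exponential
prior on the root age, a lognormal prior on the base clock rate, and the
Mkv(+gamma) likelihood of the morphological matrix with per-branch
effective lengths given by the clock model:

* strict — effective length = c·t;
* IGR    — effective lengths independent Gamma(mean c·t, variance v·t),
  a punctuated, uncorrelated relaxed clock;
* TK02   — nodal rates lognormal around the parent's rate with variance
  v·t (autocorrelated, gradual); branch rate = mean of its endpoint rates.

Two fossil-sampling strategies are supported: 'fossiltip' (fossils are
terminal tips only; sampled-ancestor configurations have prior mass
zero) and 'random' (fossils may also sit as sampled ancestors, i.e.
zero-length pendant attachments on a surviving lineage).  The sampler is
single-chain Metropolis-Hastings with node-age, tip-age, parameter,
relaxed-clock and constrained topology moves.  Marginal likelihoods come
from stepping-stone sampling over a power-posterior path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .matrixio import CharacterMatrix, TipAgeTable
from .mk import MkModel
from .treesample import TreeSample

__all__ = [
    "FBDParams",
    "Priors",
    "derive_clock_prior",
    "fbd_log_density",
    "run_mcmc",
    "McmcResult",
    "stepping_stone",
    "compare_models",
    "effective_sample_size",
    "hpd_interval",
    "mcc_tree",
    "SteppingStoneConfig",
]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# clock-rate prior arithmetic


def derive_clock_prior(median_tree_length: float, root_prior_median: float = 37.1):
    """Informative clock-rate prior from a preceding non-clock analysis.

    The median non-clock tree length (expected changes per character over
    the whole tree) divided by the median of the root-age prior gives a
    per-My base rate; the prior on the rate is lognormal with mean(log) =
    ln(rate) and sd(log) = exp(rate).

    Returns (rate, mean_log, sd_log).
    """
    if median_tree_length <= 0 or root_prior_median <= 0:
        raise ValueError("medians must be positive")
    rate = median_tree_length / root_prior_median
    return rate, math.log(rate), math.exp(rate)


def clock_prior_from_sample(tree_lengths, root_prior_median: float = 37.1):
    """derive_clock_prior from a posterior sample of tree lengths."""
    arr = np.asarray(list(tree_lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("empty non-clock sample")
    return derive_clock_prior(float(np.median(arr)), root_prior_median)


# ---------------------------------------------------------------------------
# FBD density


@dataclass
class FBDParams:
    lam: float = 0.2
    mu: float = 0.1
    psi: float = 0.1
    rho: float = 1.0
    strategy: str = "fossiltip"  # fossiltip | random

    def __post_init__(self) -> None:
        if self.strategy == "diversity":
            raise ValueError("the 'diversity' sampling strategy is not supported")
        if self.strategy not in ("fossiltip", "random"):
            raise ValueError("strategy must be 'fossiltip' or 'random'")
        if min(self.lam, self.mu, self.psi) < 0:
            raise ValueError("rates must be non-negative")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")


def _fbd_c1c2(lam, mu, psi, rho):
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
    if c1 == 0:
        return 0.0, 0.0
    c2 = -(lam - mu - 2 * lam * rho - psi) / c1
    return c1, c2


def _log_q(t, lam, mu, psi, rho):
    c1, c2 = _fbd_c1c2(lam, mu, psi, rho)
    if c1 == 0:
        return 0.0
    # q(t) = 4 e^{-c1 t} / ((1-c2) e^{-c1 t} + (1+c2))^2
    e = math.exp(-c1 * t)
    denom = (1 - c2) * e + (1 + c2)
    return math.log(4.0) - c1 * t - 2.0 * math.log(abs(denom))


def _p0(t, lam, mu, psi, rho):
    """P(lineage at age t leaves no sample at all)."""
    if lam == 0 and psi == 0:
        return 1.0 - rho * math.exp(-mu * t) if mu > 0 else 1.0 - rho
    c1, c2 = _fbd_c1c2(lam, mu, psi, rho)
    e = math.exp(-c1 * t)
    frac = (e * (1 - c2) - (1 + c2)) / (e * (1 - c2) + (1 + c2))
    return (lam + mu + psi + c1 * frac) / (2 * lam)


def fbd_log_density(tree: dendropy.Tree, params: FBDParams,
                    sa_tol: float = 1e-8) -> float:
    """Log FBD prior density of a dated tree, conditioned on the root age.

    Every node must carry an ``age`` attribute (Ma); extant tips have age
    0, fossil tips age > 0.  A fossil tip whose pendant branch has zero
    duration is treated as a sampled ancestor of its sibling lineage; under
    'fossiltip' such configurations return -inf.
    """
    lam, mu, psi, rho = params.lam, params.mu, params.psi, params.rho
    leaves = [nd for nd in tree.leaf_node_iter()]
    if len(leaves) <= 1:
        nd = leaves[0] if leaves else None
        if nd is not None and nd.age > _EPS:
            return math.log(psi) if psi > 0 else -np.inf
        return math.log(rho)
    logf = 0.0
    n_extant = 0
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        age = node.age
        if node.is_leaf():
            is_sa = (
                node.parent_node is not None
                and abs(node.parent_node.age - age) <= sa_tol
                and age > _EPS
            )
            if age <= _EPS:
                n_extant += 1
                logf += math.log(rho)
            elif is_sa:
                if params.strategy == "fossiltip":
                    return -np.inf
                logf += math.log(psi) if psi > 0 else -np.inf
            else:
                if psi <= 0:
                    return -np.inf
                p0 = _p0(age, lam, mu, psi, rho)
                logf += math.log(psi) + math.log(max(p0, 1e-300)) - _log_q(age, lam, mu, psi, rho)
        else:
            # a bifurcation whose child is a zero-length fossil tip is the
            # sampled-ancestor attachment, not a speciation event
            sa_node = any(
                ch.is_leaf() and ch.age > _EPS and abs(age - ch.age) <= sa_tol
                for ch in node.child_nodes()
            )
            if node is root:
                logf += 2.0 * _log_q(age, lam, mu, psi, rho)
            elif sa_node:
                pass  # psi term carried by the fossil leaf
            else:
                if lam <= 0:
                    return -np.inf
                logf += math.log(lam) + _log_q(age, lam, mu, psi, rho)
    return logf


# ---------------------------------------------------------------------------
# priors


@dataclass
class Priors:
    root_offset: float = 33.0
    root_mean: float = 41.2  # mean of the offset-exponential (offset + scale)
    clock_mean_log: float = -2.45367
    clock_sd_log: float = 1.08978
    rate_hyper: float = 10.0  # exponential rate on lambda, mu, psi
    alpha_rate: float = 1.0  # exponential rate on the gamma shape
    relaxed_var_rate: float = 10.0  # exponential rate on the clock variance v
    ingroup: frozenset | None = None  # monophyly constraint

    def log_root(self, age: float) -> float:
        scale = self.root_mean - self.root_offset
        if age < self.root_offset or scale <= 0:
            return -np.inf
        return -math.log(scale) - (age - self.root_offset) / scale

    def root_median(self) -> float:
        return self.root_offset + (self.root_mean - self.root_offset) * math.log(2.0)

    def log_clock(self, c: float) -> float:
        if c <= 0:
            return -np.inf
        z = (math.log(c) - self.clock_mean_log) / self.clock_sd_log
        return -math.log(c * self.clock_sd_log * math.sqrt(2 * math.pi)) - 0.5 * z * z

    def log_exp(self, x: float, rate: float) -> float:
        return math.log(rate) - rate * x if x >= 0 else -np.inf


# ---------------------------------------------------------------------------
# array tree state


class _State:
    """Array-encoded dated tree plus model parameters.

    Tips are nodes 0..n_tips-1 in matrix taxon order; internals follow.
    parent[root] = -1.  Fossil sampled-ancestor configurations are tips
    whose age equals their parent's age.
    """

    __slots__ = ("parent", "age", "n_tips", "params", "branch_len", "node_lograte")

    def __init__(self, parent, age, n_tips, params):
        self.parent = parent  # np.ndarray int
        self.age = age  # np.ndarray float
        self.n_tips = n_tips
        self.params = params  # dict: c, v, alpha, lam, mu, psi
        self.branch_len = None  # IGR latent effective lengths (per node != root)
        self.node_lograte = None  # TK02 latent log rates (per node)

    def copy(self) -> "_State":
        s = _State(self.parent.copy(), self.age.copy(), self.n_tips, dict(self.params))
        s.branch_len = None if self.branch_len is None else self.branch_len.copy()
        s.node_lograte = None if self.node_lograte is None else self.node_lograte.copy()
        return s

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(v)
        return ch

    def postorder(self) -> list[int]:
        ch = self.children()
        out, stack = [], [self.root()]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(ch[v])
        return out[::-1]

    def durations(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        d[mask] = self.age[self.parent[mask]] - self.age[mask]
        return d

    def clade_masks(self) -> np.ndarray:
        masks = np.zeros(self.n_nodes, dtype=object)
        ch = self.children()
        for v in self.postorder():
            m = 1 << v if v < self.n_tips else 0
            for c in ch[v]:
                m |= masks[c]
            masks[v] = m
        return masks

    def to_dendropy(self, taxa: list[str],
                    tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        tns = tns or dendropy.TaxonNamespace(taxa)
        tree = dendropy.Tree(taxon_namespace=tns)
        ch = self.children()
        nodes = {}
        for v in self.postorder():
            if v < self.n_tips:
                nd = dendropy.Node(taxon=tns.get_taxon(taxa[v]))
            else:
                nd = dendropy.Node()
            nd.age = float(self.age[v])
            nodes[v] = nd
            for c in ch[v]:
                nd.add_child(nodes[c])
                nodes[c].edge.length = float(self.age[v] - self.age[c])
        tree.seed_node = nodes[self.root()]
        return tree


def _fbd_log_density_arrays(state: _State, fbd: FBDParams) -> float:
    lam, mu, psi, rho = fbd.lam, fbd.mu, fbd.psi, fbd.rho
    ch = state.children()
    root = state.root()
    logf = 2.0 * _log_q(state.age[root], lam, mu, psi, rho)
    for v in range(state.n_nodes):
        age = float(state.age[v])
        if v < state.n_tips:
            p = state.parent[v]
            is_sa = p >= 0 and abs(state.age[p] - age) <= 1e-8 and age > _EPS
            if age <= _EPS:
                logf += math.log(rho)
            elif is_sa:
                if fbd.strategy == "fossiltip":
                    return -np.inf
                if psi <= 0:
                    return -np.inf
                logf += math.log(psi)
            else:
                if psi <= 0:
                    return -np.inf
                p0 = _p0(age, lam, mu, psi, rho)
                logf += math.log(psi) + math.log(max(p0, 1e-300)) - _log_q(age, lam, mu, psi, rho)
        elif v != root:
            sa_node = any(
                c < state.n_tips and state.age[c] > _EPS and abs(age - state.age[c]) <= 1e-8
                for c in ch[v]
            )
            if sa_node:
                continue
            if lam <= 0:
                return -np.inf
            logf += math.log(lam) + _log_q(age, lam, mu, psi, rho)
    return logf


# ---------------------------------------------------------------------------
# fast Mkv likelihood on array trees (augmented with constant patterns)


class _MkEngine:
    """Pruning likelihood over the array tree, with the Mkv ascertainment
    patterns appended as pseudo-characters so one pass yields both."""

    def __init__(self, matrix: CharacterMatrix, model: MkModel):
        self.model = model
        self.kvec_real = matrix.n_states.astype(float)
        kmax = int(matrix.n_states.max())
        self.kmax = kmax
        classes = sorted(set(int(x) for x in matrix.n_states))
        self.classes = classes
        n_real = matrix.n_char
        cols = []
        tip = np.zeros((matrix.n_taxa, n_real + sum(classes), kmax))
        for s in range(kmax):
            tip[:, :n_real, s] = (matrix.masks >> s) & 1
        kv = list(matrix.n_states.astype(float))
        j = n_real
        self.const_cols: dict[int, list[int]] = {}
        for k in classes:
            self.const_cols[k] = list(range(j, j + k))
            for s in range(k):
                tip[:, j, :] = 0.0
                tip[:, j, s] = 1.0  # constant pattern: every taxon in state s
                kv.append(float(k))
                j += 1
        self.tip = tip
        self.kvec = np.array(kv)
        self.n_real = n_real
        self.state_mask = (np.arange(kmax)[None, :] < self.kvec[:, None]).astype(float)

    def loglik(self, state: _State, eff_len: np.ndarray) -> float:
        """Total Mkv log-likelihood; eff_len indexed by child node."""
        model = self.model
        rates = model.rates()
        kvec, kmax = self.kvec, self.kmax
        order = state.postorder()
        ch = state.children()
        nchar = kvec.shape[0]
        logs = np.empty((len(rates), nchar))
        for ri, r in enumerate(rates):
            logscale = np.zeros(nchar)
            store: dict[int, np.ndarray] = {}
            for v in order:
                if v < state.n_tips:
                    store[v] = self.tip[v]
                    continue
                L = np.ones((nchar, kmax))
                for c in ch[v]:
                    t = max(eff_len[c], 0.0) * r
                    ek = np.exp(-kvec * t / (kvec - 1.0))
                    p_same = 1.0 / kvec + (1.0 - 1.0 / kvec) * ek
                    p_diff = (1.0 - ek) / kvec
                    Lc = store.pop(c)
                    tot = Lc.sum(axis=1)
                    L = L * (p_diff[:, None] * tot[:, None] + (p_same - p_diff)[:, None] * Lc)
                L = L * self.state_mask
                mx = L.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                L = L / mx[:, None]
                logscale += np.log(mx)
                store[v] = L
            site = (store[order[-1]] / kvec[:, None]).sum(axis=1)
            logs[ri] = np.log(np.maximum(site, 1e-300)) + logscale
        mx = logs.max(axis=0)
        ll = mx + np.log(np.mean(np.exp(logs - mx), axis=0))
        total = float(ll[: self.n_real].sum())
        if self.model.conditioning == "variable":
            for k in self.classes:
                p_const = float(np.exp(ll[self.const_cols[k]]).sum())
                p_var = max(1.0 - p_const, 1e-300)
                n_k = int(np.sum(self.kvec_real == k))
                total -= n_k * math.log(p_var)
        return total


# ---------------------------------------------------------------------------
# clock models: effective lengths and latent priors


def _effective_lengths(state: _State, clock: str) -> np.ndarray:
    t = state.durations()
    c = state.params["c"]
    if clock == "strict":
        return c * t
    if clock == "igr":
        return state.branch_len
    if clock == "tk02":
        r = np.exp(state.node_lograte)
        rp = r[state.parent.clip(min=0)]
        return t * 0.5 * (r + rp)
    raise ValueError("clock must be strict, igr or tk02")


def _log_latent_prior(state: _State, clock: str) -> float:
    from scipy.stats import gamma as gamma_dist, norm

    t = state.durations()
    c, v = state.params["c"], state.params.get("v", 0.0)
    if clock == "strict":
        return 0.0
    mask = state.parent >= 0
    if clock == "igr":
        tt = np.maximum(t[mask], 1e-12)
        shape = c * c * tt / v
        scale = v / c
        x = np.maximum(state.branch_len[mask], 1e-300)
        return float(np.sum(gamma_dist.logpdf(x, shape, scale=scale)))
    if clock == "tk02":
        lp = 0.0
        root = state.root()
        lr = state.node_lograte
        if abs(lr[root] - math.log(c)) > 1e-9:
            return -np.inf  # root rate pinned at the base rate
        for u in range(state.n_nodes):
            p = state.parent[u]
            if p < 0:
                continue
            tt = max(t[u], 1e-12)
            var = v * tt
            lp += norm.logpdf(lr[u], lr[p] - var / 2.0, math.sqrt(var))
        return float(lp)
    raise ValueError(clock)


# ---------------------------------------------------------------------------
# posterior and moves


@dataclass
class _Model:
    matrix: CharacterMatrix
    ages: TipAgeTable
    fbd_strategy: str
    clock: str
    priors: Priors
    mk: MkModel
    engine: _MkEngine
    ingroup_mask: int | None
    likelihood_on: bool = True
    beta: float = 1.0
    sample_alpha: bool = True
    sample_topology: bool = True
    sample_ages: bool = True
    tree_prior_on: bool = True

    def fbd(self, state: _State) -> FBDParams:
        return FBDParams(
            state.params["lam"], state.params["mu"], state.params["psi"],
            state.params["rho"], self.fbd_strategy,
        )

    def log_prior(self, state: _State) -> float:
        pr = self.priors
        lp = pr.log_root(float(state.age[state.root()]))
        if not np.isfinite(lp):
            return -np.inf
        # tip ages within their intervals (uniform)
        for i, tax in enumerate(self.matrix.taxa):
            lo, hi = self.ages.intervals[tax]
            a = float(state.age[i])
            if a < lo - 1e-9 or a > hi + 1e-9:
                return -np.inf
            if hi > lo:
                lp -= math.log(hi - lo)
        # parent older than child
        d = state.durations()
        if np.any(d[state.parent >= 0] < -1e-9):
            return -np.inf
        if self.ingroup_mask is not None:
            masks = state.clade_masks()
            if not any(int(m) == self.ingroup_mask for m in masks):
                return -np.inf
        p = state.params
        lp += pr.log_clock(p["c"])
        lp += pr.log_exp(p["lam"], pr.rate_hyper)
        lp += pr.log_exp(p["mu"], pr.rate_hyper)
        lp += pr.log_exp(p["psi"], pr.rate_hyper)
        if self.sample_alpha:
            lp += pr.log_exp(p["alpha"], pr.alpha_rate)
        if self.clock != "strict":
            lp += pr.log_exp(p["v"], pr.relaxed_var_rate)
        if not np.isfinite(lp):
            return -np.inf
        if self.tree_prior_on:
            lf = _fbd_log_density_arrays(state, self.fbd(state))
            if not np.isfinite(lf):
                return -np.inf
            lp += lf
        ll = _log_latent_prior(state, self.clock)
        return lp + ll

    def log_lik(self, state: _State) -> float:
        if not self.likelihood_on:
            return 0.0
        model = self.mk
        if self.sample_alpha:
            model = MkModel(state.params["alpha"], model.n_cat, model.conditioning)
        self.engine.model = model
        return self.engine.loglik(state, _effective_lengths(state, self.clock))

    def log_post(self, state: _State) -> tuple[float, float]:
        lp = self.log_prior(state)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        ll = self.log_lik(state) if (self.likelihood_on and self.beta > 0) else 0.0
        return lp + self.beta * ll, ll


def _scale_move(x: float, rng, tune: float = 0.3) -> tuple[float, float]:
    f = math.exp(tune * (rng.random() - 0.5))
    return x * f, math.log(f)


def _propose(model: _Model, state: _State, rng) -> tuple[_State, float]:
    """One random proposal; returns (new state, log Hastings ratio)."""
    s = state.copy()
    moves = ["param", "clockrate"]
    if model.sample_ages:
        moves += ["age", "root", "tip"]
        if model.fbd_strategy == "random":
            moves.append("sa")
    if model.clock == "igr":
        moves.append("igr")
    if model.clock == "tk02":
        moves.append("tk02")
    if model.sample_topology and s.n_tips >= 4:
        moves += ["topo", "topo"]
    if model.sample_alpha:
        moves.append("alpha")
    mv = moves[rng.integers(len(moves))]
    root = s.root()
    ch = s.children()

    def is_sa_parent(v: int) -> bool:
        return any(
            c < s.n_tips and s.age[c] > _EPS and abs(s.age[v] - s.age[c]) <= 1e-8
            for c in ch[v]
        )

    if mv == "age":
        internals = [v for v in range(s.n_nodes)
                     if v >= s.n_tips and v != root and ch[v] and not is_sa_parent(v)]
        if not internals:
            return s, -np.inf
        v = internals[rng.integers(len(internals))]
        lo = max(float(s.age[c]) for c in ch[v])
        hi = float(s.age[s.parent[v]])
        if hi <= lo:
            return s, -np.inf
        s.age[v] = lo + rng.random() * (hi - lo)
        return s, 0.0
    if mv == "root":
        lo = max(float(s.age[c]) for c in ch[root])
        x = float(s.age[root]) - lo
        f = math.exp(0.5 * (rng.random() - 0.5))
        s.age[root] = lo + max(x, 1e-6) * f
        return s, math.log(f)
    if mv == "tip":
        fossils = [i for i, t in enumerate(model.matrix.taxa)
                   if model.ages.intervals[t][1] > model.ages.intervals[t][0]
                   and abs(s.age[s.parent[i]] - s.age[i]) > 1e-8]
        if not fossils:
            return s, -np.inf
        i = fossils[rng.integers(len(fossils))]
        lo, hi = model.ages.intervals[model.matrix.taxa[i]]
        hi = min(hi, float(s.age[s.parent[i]]))
        if hi <= lo:
            return s, -np.inf
        s.age[i] = lo + rng.random() * (hi - lo)
        return s, 0.0
    if mv == "clockrate":
        s.params["c"], lh = _scale_move(s.params["c"], rng, tune=2.5)
        return s, lh
    if mv == "alpha":
        s.params["alpha"], lh = _scale_move(s.params["alpha"], rng, tune=1.5)
        return s, lh
    if mv == "param":
        key = ("lam", "mu", "psi", "v")[rng.integers(4 if model.clock != "strict" else 3)]
        s.params[key], lh = _scale_move(s.params[key], rng, tune=1.5)
        return s, lh
    if mv == "igr":
        mask = np.where(s.parent >= 0)[0]
        e = int(mask[rng.integers(mask.size)])
        s.branch_len[e], lh = _scale_move(float(s.branch_len[e]), rng, tune=0.6)
        return s, lh
    if mv == "tk02":
        cand = [v for v in range(s.n_nodes) if v != root]
        v = cand[rng.integers(len(cand))]
        s.node_lograte[v] += rng.normal(0.0, 0.3)
        return s, 0.0
    if mv == "sa":
        fossils = [i for i, t in enumerate(model.matrix.taxa)
                   if model.ages.intervals[t][1] > 0]
        if not fossils:
            return s, -np.inf
        i = fossils[rng.integers(len(fossils))]
        p = s.parent[i]
        if p < 0:
            return s, -np.inf
        g = s.parent[p]
        upper = float(s.age[g]) if g >= 0 else float(s.age[p]) + 5.0
        sib = [c for c in ch[p] if c != i]
        lo = max([float(s.age[i])] + [float(s.age[c]) for c in sib])
        if abs(s.age[p] - s.age[i]) <= 1e-8:
            # expand: parent age drawn uniformly above the attachment
            if upper <= lo:
                return s, -np.inf
            s.age[p] = lo + rng.random() * (upper - lo)
            return s, math.log(upper - lo)
        # collapse to sampled ancestor
        if float(s.age[i]) < lo - 1e-12 or upper <= lo:
            return s, -np.inf
        old_range = upper - lo
        s.age[p] = float(s.age[i])
        return s, -math.log(old_range)
    # topo: narrow exchange respecting ages
    def _exchange_cands(children):
        def sa_parent(v):
            return any(
                c < s.n_tips and s.age[c] > _EPS and abs(s.age[v] - s.age[c]) <= 1e-8
                for c in children[v]
            )

        out = []
        for gp in range(s.n_tips, s.n_nodes):
            if sa_parent(gp):
                continue
            for pnode in children[gp]:
                if pnode < s.n_tips or sa_parent(pnode):
                    continue
                for u in children[pnode]:
                    for w in children[gp]:
                        if w != pnode and s.age[pnode] > s.age[w] + 1e-12:
                            out.append((pnode, u, gp, w))
        return out

    cands = _exchange_cands(ch)
    if not cands:
        return s, -np.inf
    pnode, u, gp, w = cands[rng.integers(len(cands))]
    s.parent[u] = gp
    s.parent[w] = pnode
    n_back = len(_exchange_cands(s.children()))
    return s, math.log(len(cands)) - math.log(max(n_back, 1))


# ---------------------------------------------------------------------------
# starting state


def _state_from_tree(tree: dendropy.Tree, matrix: CharacterMatrix, clock: str,
                     priors: Priors, rho: float) -> _State:
    """Build an array state from a dated dendropy tree (node ``age`` set)."""
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    n = matrix.n_taxa
    n_nodes = n + len(internals)
    ids = {}
    nxt = n
    for nd in nodes:
        if nd.is_leaf():
            ids[id(nd)] = taxon_index[nd.taxon.label]
        else:
            ids[id(nd)] = nxt
            nxt += 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    for nd in nodes:
        age[ids[id(nd)]] = float(nd.age)
        if nd.parent_node is not None:
            parent[ids[id(nd)]] = ids[id(nd.parent_node)]
    params = {"c": math.exp(priors.clock_mean_log), "v": 0.1, "alpha": 1.0,
              "lam": 0.15, "mu": 0.1, "psi": 0.1, "rho": rho}
    st = _State(parent, age, n, params)
    if clock == "igr":
        st.branch_len = np.maximum(st.durations() * params["c"], 1e-8)
    if clock == "tk02":
        st.node_lograte = np.full(n_nodes, math.log(params["c"]))
    return st


def _starting_state(matrix: CharacterMatrix, ages: TipAgeTable, priors: Priors,
                    clock: str, rng, rho: float) -> _State:
    n = matrix.n_taxa
    tip_age = np.array([
        0.5 * (ages.intervals[t][0] + ages.intervals[t][1]) for t in matrix.taxa
    ])
    ingroup = priors.ingroup
    order = sorted(range(n), key=lambda i: tip_age[i])
    if ingroup is not None:
        ing = [i for i in order if matrix.taxa[i] in ingroup]
        out = [i for i in order if matrix.taxa[i] not in ingroup]
        order = ing  # pectinate ingroup first, outgroup(s) attach above
    else:
        ing, out = order, []
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    age[:n] = tip_age
    nxt = n
    cur = order[0]
    for i in order[1:]:
        p = nxt
        nxt += 1
        parent[cur] = p
        parent[i] = p
        age[p] = max(age[cur], age[i]) + 1.0 + rng.random()
        cur = p
    for i in out:
        p = nxt
        nxt += 1
        parent[cur] = p
        parent[i] = p
        age[p] = max(age[cur], age[i]) + 1.0 + rng.random()
        cur = p
    root = cur
    age[root] = max(age[root], priors.root_offset + 0.5)
    # push ancestors up if needed
    for v in range(n_nodes):
        p = parent[v]
        while p >= 0 and age[p] <= age[v]:
            age[p] = age[v] + 0.5
            v, p = p, parent[p]
    params = {"c": math.exp(priors.clock_mean_log), "v": 0.1, "alpha": 1.0,
              "lam": 0.15, "mu": 0.1, "psi": 0.1, "rho": rho}
    st = _State(parent, age, n, params)
    if clock == "igr":
        st.branch_len = np.maximum(st.durations() * params["c"], 1e-8)
    if clock == "tk02":
        st.node_lograte = np.full(n_nodes, math.log(params["c"]))
    return st


# ---------------------------------------------------------------------------
# the sampler


@dataclass
class McmcResult:
    sample: TreeSample
    trace: pd.DataFrame
    ess: dict[str, float]
    low_ess: list[str]
    acceptance: float


def run_mcmc(
    matrix: CharacterMatrix,
    ages: TipAgeTable,
    *,
    clock: str = "igr",
    strategy: str = "fossiltip",
    priors: Priors | None = None,
    mk_model: MkModel | None = None,
    rho: float = 1.0,
    generations: int = 20000,
    sample_every: int = 20,
    burnin: float = 0.30,
    seed: int = 0,
    likelihood_on: bool = True,
    sample_topology: bool = True,
    sample_ages: bool = True,
    sample_alpha: bool = True,
    tree_prior_on: bool = True,
    start_tree: dendropy.Tree | None = None,
    beta: float = 1.0,
    ess_threshold: float = 200.0,
) -> McmcResult:
    """Single-chain Metropolis-Hastings tip-dating run.

    Returns the post-burn-in posterior TreeSample (trees carry node
    ``age`` attributes), the parameter trace, and ESS diagnostics with
    parameters below ``ess_threshold`` flagged.
    """
    for t in matrix.taxa:
        if t not in ages:
            raise ValueError(f"no age interval for taxon {t}")
    priors = priors or Priors()
    mk_model = mk_model or MkModel(alpha=1.0, n_cat=4, conditioning="variable")
    rng = np.random.default_rng(seed)
    engine = _MkEngine(matrix, mk_model)
    ingroup_mask = None
    if priors.ingroup is not None:
        ingroup_mask = sum(
            1 << i for i, t in enumerate(matrix.taxa) if t in priors.ingroup
        )
    model = _Model(matrix, ages, strategy, clock, priors, mk_model, engine,
                   ingroup_mask, likelihood_on, beta, sample_alpha,
                   sample_topology, sample_ages, tree_prior_on)
    if start_tree is not None:
        state = _state_from_tree(start_tree, matrix, clock, priors, rho)
    else:
        state = _starting_state(matrix, ages, priors, clock, rng, rho)
    lp, ll = model.log_post(state)
    tries = 0
    while not np.isfinite(lp):
        state.age[state.root()] += 1.0
        lp, ll = model.log_post(state)
        tries += 1
        if tries > 200:
            raise RuntimeError("could not find a feasible starting state "
                               "(check constraints and tip-age intervals)")
    rows, trees = [], []
    n_acc = 0
    taxa = matrix.taxa
    tns = dendropy.TaxonNamespace(taxa)
    keep_from = int(burnin * generations)
    for g in range(1, generations + 1):
        prop, lh = _propose(model, state, rng)
        if np.isfinite(lh):
            lp2, ll2 = model.log_post(prop)
            if np.isfinite(lp2) and math.log(rng.random() + 1e-300) < lp2 - lp + lh:
                state, lp, ll = prop, lp2, ll2
                n_acc += 1
        if g % sample_every == 0 and g > keep_from:
            if likelihood_on and beta == 0.0:
                ll = model.log_lik(state)  # recorded for stepping-stone use
            row = {"gen": g, "log_posterior": lp, "log_likelihood": ll,
                   "root_age": float(state.age[state.root()]),
                   "tree_length_my": float(state.durations().sum()),
                   **{k: state.params[k] for k in ("c", "v", "alpha", "lam", "mu", "psi")}}
            for i, t in enumerate(taxa):
                if ages.intervals[t][1] > ages.intervals[t][0]:
                    row[f"age_{t}"] = float(state.age[i])
            rows.append(row)
            trees.append(state.to_dendropy(taxa, tns))
    trace = pd.DataFrame(rows)
    ess = {}
    for col in trace.columns:
        if col in ("gen",):
            continue
        x = trace[col].to_numpy(dtype=float)
        if np.std(x) > 0:
            ess[col] = effective_sample_size(x)
    low = sorted(k for k, v in ess.items() if v < ess_threshold)
    return McmcResult(TreeSample(trees, trace), trace, ess, low,
                      n_acc / max(generations, 1))


# ---------------------------------------------------------------------------
# non-clock Bayesian analysis (unconstrained branch lengths)


def _brlen_tree(state: _State, taxa, tns) -> dendropy.Tree:
    """Array state -> dendropy tree with edge lengths from branch_len."""
    tree = dendropy.Tree(taxon_namespace=tns)
    ch = state.children()
    nodes = {}
    for v in state.postorder():
        nd = dendropy.Node(taxon=tns.get_taxon(taxa[v])) if v < state.n_tips else dendropy.Node()
        nodes[v] = nd
        for c in ch[v]:
            nd.add_child(nodes[c])
            nodes[c].edge.length = float(state.branch_len[c])
    tree.seed_node = nodes[state.root()]
    return tree


def run_nonclock(
    matrix: CharacterMatrix,
    *,
    mk_model: MkModel | None = None,
    brlen_rate: float = 10.0,
    alpha_rate: float = 1.0,
    generations: int = 20000,
    sample_every: int = 20,
    burnin: float = 0.30,
    seed: int = 0,
    sample_topology: bool = True,
    sample_alpha: bool = True,
) -> McmcResult:
    """Non-clock Mkv MCMC: topology, branch lengths (iid exponential
    prior) and the gamma shape.  Its main product is the posterior tree
    length used to derive the clock-rate prior for tip dating."""
    mk_model = mk_model or MkModel(alpha=1.0, n_cat=4, conditioning="variable")
    rng = np.random.default_rng(seed)
    engine = _MkEngine(matrix, mk_model)
    n = matrix.n_taxa
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    cur = 0
    nxt = n
    for i in range(1, n):
        parent[cur] = nxt
        parent[i] = nxt
        cur = nxt
        nxt += 1
    state = _State(parent, np.zeros(n_nodes), n, {"alpha": 1.0})
    state.branch_len = np.full(n_nodes, 0.05)

    def log_prior(s):
        lp = float(np.sum(np.log(brlen_rate) - brlen_rate * s.branch_len[s.parent >= 0]))
        if np.any(s.branch_len[s.parent >= 0] <= 0):
            return -np.inf
        if sample_alpha:
            lp += math.log(alpha_rate) - alpha_rate * s.params["alpha"]
        return lp

    def log_lik(s):
        m = MkModel(s.params["alpha"], mk_model.n_cat, mk_model.conditioning) \
            if sample_alpha else mk_model
        engine.model = m
        return engine.loglik(s, s.branch_len)

    lp = log_prior(state) + log_lik(state)
    rows, trees = [], []
    taxa = matrix.taxa
    tns = dendropy.TaxonNamespace(taxa)
    keep_from = int(burnin * generations)
    n_acc = 0
    for g in range(1, generations + 1):
        s = state.copy()
        moves = ["brlen", "brlen"]
        if sample_alpha:
            moves.append("alpha")
        if sample_topology and n >= 4:
            moves.append("nni")
        mv = moves[rng.integers(len(moves))]
        lh = 0.0
        if mv == "brlen":
            mask = np.where(s.parent >= 0)[0]
            e = int(mask[rng.integers(mask.size)])
            s.branch_len[e], lh = _scale_move(float(s.branch_len[e]), rng, tune=1.8)
        elif mv == "alpha":
            s.params["alpha"], lh = _scale_move(s.params["alpha"], rng, tune=1.5)
        else:
            ch = s.children()
            cands = []
            for gp in range(n, n_nodes):
                for pn in ch[gp]:
                    if pn < n:
                        continue
                    for u in ch[pn]:
                        for w in ch[gp]:
                            if w != pn:
                                cands.append((pn, u, gp, w))
            if cands:
                pn, u, gp, w = cands[rng.integers(len(cands))]
                s.parent[u] = gp
                s.parent[w] = pn
        lp2 = log_prior(s)
        if np.isfinite(lp2):
            lp2 += log_lik(s)
        if np.isfinite(lp2) and math.log(rng.random() + 1e-300) < lp2 - lp + lh:
            state, lp = s, lp2
            n_acc += 1
        if g % sample_every == 0 and g > keep_from:
            tl = float(state.branch_len[state.parent >= 0].sum())
            rows.append({"gen": g, "log_posterior": lp, "tree_length": tl,
                         "alpha": state.params["alpha"]})
            trees.append(_brlen_tree(state, taxa, tns))
    trace = pd.DataFrame(rows)
    ess = {c: effective_sample_size(trace[c].to_numpy(float))
           for c in ("log_posterior", "tree_length", "alpha")
           if np.std(trace[c].to_numpy(float)) > 0}
    low = sorted(k for k, v in ess.items() if v < 200.0)
    return McmcResult(TreeSample(trees, trace), trace, ess, low, n_acc / generations)


# ---------------------------------------------------------------------------
# diagnostics & summaries


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS (Tracer-style)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, n // 2):
        if rho[k] < 0.0:
            break
        tau += 2.0 * rho[k]
    return float(n / max(tau, 1.0))


def hpd_interval(x, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sorted draws."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    k = max(int(math.ceil(mass * n)), 1)
    if k >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[k:] - xs[: n - k]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + k])


def _rooted_clades(tree: dendropy.Tree) -> dict[frozenset, float]:
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._cl = frozenset([node.taxon.label])
        else:
            s = frozenset()
            for c in node.child_nodes():
                s |= c._cl
            node._cl = s
        out[node._cl] = getattr(node, "age", None)
    return out


def mcc_tree(sample: TreeSample) -> dendropy.Tree:
    """Maximum clade credibility tree.

    The sampled tree maximizing the product of its clades' posterior
    frequencies; node ages are replaced by the median age of the matching
    clade across the sample, and nodes are annotated with posterior
    support and 95% HPD age intervals.
    """
    clade_ages: dict[frozenset, list[float]] = {}
    per_tree = []
    for t in sample:
        cl = _rooted_clades(t)
        per_tree.append(cl)
        for c, a in cl.items():
            clade_ages.setdefault(c, []).append(a)
    n = len(sample.trees)
    freq = {c: len(v) / n for c, v in clade_ages.items()}
    scores = [sum(math.log(freq[c]) for c in cl) for cl in per_tree]
    best_i = int(np.argmax(scores))
    best = sample.trees[best_i].clone(depth=1)
    for node in best.postorder_node_iter():
        if node.is_leaf():
            node._cl = frozenset([node.taxon.label])
        else:
            node._cl = frozenset().union(*[c._cl for c in node.child_nodes()])
        ages = [a for a in clade_ages[node._cl] if a is not None]
        node.posterior = freq[node._cl]
        if ages:
            node.age = float(np.median(ages))
            node.age_hpd = hpd_interval(ages)
    # rebuild durations from summarized ages, keeping parent >= child
    for node in best.preorder_node_iter():
        if node.parent_node is not None:
            node.age = min(node.age, node.parent_node.age)
            node.edge.length = node.parent_node.age - node.age
    return best


# ---------------------------------------------------------------------------
# stepping-stone sampling


@dataclass
class SteppingStoneConfig:
    n_steps: int = 8
    alpha: float = 0.3  # beta spacing: beta_k = (k/K)^(1/alpha)
    generations_per_step: int = 4000
    sample_every: int = 10
    burnin: float = 0.25
    seed: int = 0


def stepping_stone_generic(loglik_draws) -> float:
    """Stepping-stone estimator from per-step log-likelihood draws.

    ``loglik_draws`` is a list of (beta_low, beta_high, draws-at-beta_low);
    the marginal likelihood ratio of each step is estimated as
    mean exp((beta_high - beta_low) * loglik) under beta_low.
    """
    total = 0.0
    for b_lo, b_hi, draws in loglik_draws:
        d = np.asarray(draws, dtype=float)
        if d.size == 0:
            raise ValueError("empty stepping-stone step")
        w = (b_hi - b_lo) * d
        mx = w.max()
        total += mx + math.log(np.mean(np.exp(w - mx)))
    return total


def stepping_stone(
    matrix: CharacterMatrix,
    ages: TipAgeTable,
    config: SteppingStoneConfig | None = None,
    **mcmc_kwargs,
) -> float:
    """Log marginal likelihood of a tip-dating model by stepping stones.

    Powers descend 1 -> 0 along quantiles of Beta(alpha, 1); each power
    runs its own chain and the Xie et al. estimator stitches the ratios.
    """
    config = config or SteppingStoneConfig()
    if config.n_steps < 2:
        raise ValueError("need at least 2 power steps")
    K = config.n_steps
    betas = [(k / K) ** (1.0 / config.alpha) for k in range(K + 1)]  # 0 .. 1
    draws = []
    for k in range(K):
        b_lo, b_hi = betas[k], betas[k + 1]
        res = run_mcmc(
            matrix, ages, beta=b_lo,
            generations=config.generations_per_step,
            sample_every=config.sample_every,
            burnin=config.burnin,
            seed=config.seed + 1000 + k,
            **mcmc_kwargs,
        )
        draws.append((b_lo, b_hi, res.trace["log_likelihood"].to_numpy()))
    return stepping_stone_generic(draws)


def compare_models(log_ml_a: float, log_ml_b: float) -> tuple[float, str]:
    """2 ln Bayes factor of model A over model B with a verbal category."""
    two_ln_bf = 2.0 * (log_ml_a - log_ml_b)
    a = abs(two_ln_bf)
    if a == 0:
        cat = "none"
    elif a <= 2:
        cat = "barely worth mentioning"
    elif a <= 10:
        cat = "positive"
    else:
        cat = "strong"
    return two_ln_bf, cat
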