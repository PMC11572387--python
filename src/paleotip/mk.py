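"""Mk / Mkv likelihood for discrete morphological characters.

The Mk model is the k-state symmetric continuous-time Markov chain: all
off-diagonal rates equal, scaled so a branch length of 1 is one expected
substitution.  Transition probabilities have the closed form

    P(same)  = 1/k + (1 - 1/k) * exp(-k t / (k-1))
    P(diff)  = 1/k - (1/k)     * exp(-k t / (k-1))

Among-character rate heterogeneity uses a discrete gamma with ``n_cat``
equal-weight categories whose rates are the means of the quantile slices
(mean exactly 1).  The Mkv variant conditions each character's likelihood
on being variable — the ascertainment correction for morphological
matrices in which constant characters are never coded — computed per
observed state count k_c.

Polymorphic and missing cells enter as partial likelihoods of 1 for every
member state.  Underflow is handled by per-node rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .matrixio import CharacterMatrix

__all__ = ["MkModel", "char_loglik", "ascertainment_correction", "discrete_gamma_rates",
           "estimate_alpha"]


def discrete_gamma_rates(alpha: float, n_cat: int) -> np.ndarray:
    """Mean-of-slice discrete gamma rates (mean exactly 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_cat == 1 or not np.isfinite(alpha):
        return np.ones(max(1, n_cat))
    edges = gamma_dist.ppf(np.linspace(0, 1, n_cat + 1), alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    return n_cat * (upper - lower)


@dataclass
class MkModel:
    """Mk(+gamma) model specification shared by the non-clock and clock stages."""

    alpha: float = np.inf  # gamma shape; inf = rate-homogeneous
    n_cat: int = 4
    conditioning: str = "variable"  # "none" | "variable" (Mkv)

    def __post_init__(self) -> None:
        if self.conditioning not in ("none", "variable"):
            raise ValueError("conditioning must be 'none' or 'variable'")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def rates(self) -> np.ndarray:
        if not np.isfinite(self.alpha):
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_cat)


def _tip_partials(matrix: CharacterMatrix, kmax: int) -> np.ndarray:
    """(ntax, nchar, kmax) indicator partials from bitmasks."""
    out = np.zeros((matrix.n_taxa, matrix.n_char, kmax))
    for s in range(kmax):
        out[:, :, s] = (matrix.masks >> s) & 1
    return out


def _edge_probs(t: float, kvec: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-character (p_same, p_diff) for one branch of length t."""
    if t < 0:
        raise ValueError("negative branch length")
    ek = np.exp(-kvec * t / (kvec - 1.0))
    p_same = 1.0 / kvec + (1.0 - 1.0 / kvec) * ek
    p_diff = (1.0 - ek) / kvec
    return p_same, p_diff


def _prune(tree: dendropy.Tree, partials_at_tip, kvec: np.ndarray, kmax: int,
           rate: float, state_mask: np.ndarray):
    """One Felsenstein pass at a single rate; returns per-char site
    likelihoods and the accumulated log scaling factors."""
    n_char = kvec.shape[0]
    logscale = np.zeros(n_char)
    store: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            store[id(node)] = partials_at_tip(node)
            continue
        L = np.ones((n_char, kmax))
        for ch in node.child_nodes():
            t = ch.edge.length if ch.edge.length is not None else 0.0
            p_same, p_diff = _edge_probs(t * rate, kvec, kmax)
            Lc = store.pop(id(ch))
            tot = Lc.sum(axis=1)
            contrib = p_diff[:, None] * tot[:, None] + (p_same - p_diff)[:, None] * Lc
            L = L * contrib
        L = L * state_mask
        mx = L.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        L /= mx[:, None]
        logscale += np.log(mx)
        store[id(node)] = L
    root = store[id(tree.seed_node)]
    site = (root / kvec[:, None] * state_mask).sum(axis=1)
    return site, logscale


def _site_likelihoods(tree, matrix, model: MkModel, partials=None):
    kvec = matrix.n_states.astype(float)
    kmax = int(matrix.n_states.max())
    tips = partials if partials is not None else _tip_partials(matrix, kmax)
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    state_mask = (np.arange(kmax)[None, :] < matrix.n_states[:, None]).astype(float)

    def at_tip(node):
        return tips[taxon_index[node.taxon.label]]

    rates = model.rates()
    per_rate = []
    for r in rates:
        site, logscale = _prune(tree, at_tip, kvec, kmax, float(r), state_mask)
        per_rate.append((site, logscale))
    # combine categories in log space: L = mean_r site_r * exp(logscale_r)
    logs = np.stack([np.log(np.maximum(s, 1e-300)) + ls for s, ls in per_rate])
    mx = logs.max(axis=0)
    return mx + np.log(np.mean(np.exp(logs - mx), axis=0))


def ascertainment_correction(tree: dendropy.Tree, matrix: CharacterMatrix,
                             model: MkModel) -> dict[int, float]:
    """log P(character is variable) per observed state count k_c.

    P(variable) = 1 - sum over the k_c constant patterns of their
    likelihood on the tree under the same gamma mixture.
    """
    out: dict[int, float] = {}
    for k in sorted(set(int(x) for x in matrix.n_states)):
        # constant pattern s in column s
        masks = np.zeros((matrix.n_taxa, k), dtype=np.uint16)
        for s in range(k):
            masks[:, s] = 1 << s
        const = CharacterMatrix(list(matrix.taxa), masks, np.full(k, k))
        ll = _site_likelihoods(tree, const, model)
        p_const = float(np.exp(ll).sum())
        p_var = max(1.0 - p_const, 0.0)
        out[k] = np.log(p_var) if p_var > 0 else -np.inf
    return out


def char_loglik(tree: dendropy.Tree, matrix: CharacterMatrix, model: MkModel,
                return_per_char: bool = False):
    """Mk(+gamma, +Mkv conditioning) log-likelihood of a matrix on a tree.

    Branch lengths are expected substitutions per character.  Returns the
    total log-likelihood, or (total, per-character array).
    """
    ll = _site_likelihoods(tree, matrix, model)
    if model.conditioning == "variable":
        corr = ascertainment_correction(tree, matrix, model)
        cvec = np.array([corr[int(k)] for k in matrix.n_states])
        # P(variable)=0 (no possible change) makes conditioning degenerate
        ll = np.where(np.isfinite(cvec), ll - cvec, np.nan)
    total = float(ll.sum())
    return (total, ll) if return_per_char else total


def estimate_alpha(tree: dendropy.Tree, matrix: CharacterMatrix, n_cat: int = 4,
                   conditioning: str = "none") -> float:
    """ML estimate of the gamma shape on a fixed tree (1-D bounded search)."""
    from scipy.optimize import minimize_scalar

    def nll(log_a):
        return -char_loglik(tree, matrix, MkModel(np.exp(log_a), n_cat, conditioning))

    res = minimize_scalar(nll, bounds=(np.log(0.02), np.log(50.0)), method="bounded")
    return float(np.exp(res.x))
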