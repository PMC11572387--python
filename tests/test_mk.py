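import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from conftest import tree
from paleotip.matrixio import CharacterMatrix
from paleotip.mk import (MkModel, ascertainment_correction, char_loglik,
                         discrete_gamma_rates, estimate_alpha)


def enum_loglik(t, matrix, model):
    """Independent oracle: sum over all internal-state assignments with
    transition matrices from the matrix exponential."""
    nodes = list(t.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    tindex = {x: i for i, x in enumerate(matrix.taxa)}
    total = 0.0
    for j in range(matrix.n_char):
        k = int(matrix.n_states[j])
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, -1.0)
        site = 0.0
        for r in model.rates():
            s = 0.0
            for assign in itertools.product(range(k), repeat=len(internals)):
                amap = {id(n): st for n, st in zip(internals, assign)}
                p = 1.0 / k
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    P = expm(Q * (n.edge.length or 0.0) * r)
                    ps = amap[id(n.parent_node)]
                    if n.is_leaf():
                        mask = int(matrix.masks[tindex[n.taxon.label], j])
                        p *= sum(P[ps, x] for x in range(k) if mask >> x & 1)
                    else:
                        p *= P[ps, amap[id(n)]]
                s += p
            site += s / len(model.rates())
        total += np.log(site)
    return total


def test_two_state_closed_form():
    # P(different tip states) = (1 - exp(-2t)) / 2 for the 2-state chain
    for t_tot in (0.2, 1.0, 4.0):
        t = tree(f"(A:{t_tot / 2},B:{t_tot / 2});")
        m = CharacterMatrix.from_sets(["A", "B"], [[0], [1]])
        ll = char_loglik(t, m, MkModel(np.inf, 1, "none"))
        assert ll == pytest.approx(np.log(0.25 * (1 - np.exp(-2 * t_tot))))


def test_stationary_independence_limit():
    t = tree("(A:60,B:60);")
    m = CharacterMatrix.from_sets(["A", "B"], [[0], [1]])
    ll = char_loglik(t, m, MkModel(np.inf, 1, "none"))
    assert ll == pytest.approx(np.log(0.25), abs=1e-6)


def test_pruning_equals_enumeration_with_gamma(rng):
    t = tree("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);")
    m = CharacterMatrix.from_sets(
        ["A", "B", "C", "D"], [[{0}, {1}], [{1, 2}, {0}], [{2}, {0, 1}], [{0, 1, 2}, {1}]]
    )
    model = MkModel(alpha=0.7, n_cat=3, conditioning="none")
    assert char_loglik(t, m, model) == pytest.approx(enum_loglik(t, m, model), abs=1e-9)


def test_loglik_invariant_under_rerooting(rng):
    from conftest import random_matrix

    taxa = list("ABCDE")
    m = random_matrix(rng, taxa, 6, max_states=3, p_missing=0.1)
    tns = dendropy.TaxonNamespace(taxa)
    t = tree("((A:0.2,B:0.4):0.3,(C:0.5,(D:0.1,E:0.6):0.2):0.1);", tns)
    model = MkModel(alpha=1.2, n_cat=4, conditioning="none")
    base = char_loglik(t, m, model)
    t.reroot_at_edge(t.find_node_with_taxon_label("D").edge,
                     length1=0.04, length2=0.06, update_bipartitions=False)
    assert char_loglik(t, m, model) == pytest.approx(base, abs=1e-8)


def test_shrinking_tip_set_cannot_increase_likelihood():
    t = tree("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);")
    model = MkModel(np.inf, 1, "none")
    m_full = CharacterMatrix.from_sets(["A", "B", "C", "D"], [[{0, 1}], [{1}], [{0}], [{1}]])
    m_single = CharacterMatrix.from_sets(["A", "B", "C", "D"], [[{0}], [{1}], [{0}], [{1}]])
    assert char_loglik(t, m_single, model) < char_loglik(t, m_full, model)


def test_ascertainment_limits_and_simulation(rng):
    # stationary limit: P(variable) -> 1/2 for a long 2-tip binary tree
    t_inf = tree("(A:50,B:50);")
    m2 = CharacterMatrix.from_sets(["A", "B"], [[0], [1]])
    corr = ascertainment_correction(t_inf, m2, MkModel(np.inf, 1, "none"))
    assert np.exp(corr[2]) == pytest.approx(0.5, abs=1e-6)
    # degenerate: no branch length -> conditioning impossible
    t0 = tree("(A:0,B:0);")
    assert np.isnan(char_loglik(t0, m2, MkModel(np.inf, 1, "variable")))
    # Monte-Carlo check of P(variable) on a fixed 5-taxon tree
    t5 = tree("((A:0.4,B:0.7):0.3,(C:0.2,(D:0.5,E:0.3):0.4):0.2);")
    taxa = list("ABCDE")
    m5 = CharacterMatrix.from_sets(taxa, [[0], [1], [0], [1], [0]])
    model = MkModel(np.inf, 1, "none")
    p_var = np.exp(ascertainment_correction(t5, m5, model)[2])
    n_sim = 4000
    rngs = np.random.default_rng(7)
    nodes = list(t5.preorder_node_iter())
    var = 0
    for _ in range(n_sim):
        states = {id(t5.seed_node): rngs.integers(2)}
        tipstates = []
        for nd in nodes:
            if nd.parent_node is None:
                continue
            s = states[id(nd.parent_node)]
            p_same = 0.5 + 0.5 * np.exp(-2 * (nd.edge.length or 0))
            if rngs.random() >= p_same:
                s = 1 - s
            states[id(nd)] = s
            if nd.is_leaf():
                tipstates.append(s)
        var += len(set(tipstates)) > 1
    se = np.sqrt(p_var * (1 - p_var) / n_sim)
    assert abs(var / n_sim - p_var) < 3 * se + 1e-9


def test_mkv_conditioning_increases_loglik():
    t = tree("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);")
    m = CharacterMatrix.from_sets(["A", "B", "C", "D"], [[0], [1], [0], [1]])
    none = char_loglik(t, m, MkModel(np.inf, 1, "none"))
    mkv = char_loglik(t, m, MkModel(np.inf, 1, "variable"))
    assert mkv > none  # dividing by P(variable) < 1


def test_discrete_gamma_rates_mean_one():
    for a in (0.2, 0.5, 1.0, 5.0):
        r = discrete_gamma_rates(a, 4)
        assert r.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(r) > 0)
    with pytest.raises(ValueError):
        discrete_gamma_rates(-1.0, 4)
    with pytest.raises(ValueError):
        MkModel(alpha=0.0)


def test_alpha_recovery_on_simulated_characters():
    """ML alpha on 1,000 characters simulated with alpha = 0.5 lands near 0.5."""
    from paleotip.simulate import SimConfig, simulate_characters
    from paleotip.matrixio import set_node_ages

    t = tree("((A:2,B:3):2,(C:1,(D:2,E:4):1):2);")
    set_node_ages(t)
    cfg = SimConfig(clock="strict", clock_rate=0.25, alpha=0.5, n_cat=8,
                    n_char=1000, state_counts={2: 1.0}, missing_fraction=0.0,
                    polymorphic_fraction=0.0, mkv=False)
    m = simulate_characters(t, cfg, seed=99)
    scaled = t.clone(depth=1)
    for nd in scaled.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= cfg.clock_rate
    a_hat = estimate_alpha(scaled, m, n_cat=8, conditioning="none")
    assert 0.3 < a_hat < 0.8
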