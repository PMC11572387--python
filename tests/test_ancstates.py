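import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import brute_force_length, random_matrix, tree
from paleotip import parsimony as P
from paleotip.ancstates import (fit_mk_variant, parsimony_map, select_model,
                                stochastic_map, synapomorphies, _build_q,
                                _char_partials, _clade_sets, _loglik_q)
from paleotip.matrixio import CharacterMatrix, set_node_ages

TAXA6 = list("ABCDEF")
NWK6 = "((A:1,B:1):1,((C:0.5,D:0.5):1.5,(E:1,F:1):1):0.5);"


@pytest.fixture()
def dated6():
    t = tree(NWK6)
    set_node_ages(t)
    return t


def test_invariant_character_maps_no_changes(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[0]] * 6)
    pm = parsimony_map(dated6, m)
    assert pm.changes == [] and pm.resolved == []
    assert pm.char_lengths[0] == 0


def test_resolved_changes_equal_parsimony_length(rng, dated6):
    for trial in range(5):
        m = random_matrix(rng, TAXA6, 8, max_states=3, p_missing=0.15, p_poly=0.1)
        pm = parsimony_map(dated6, m)
        s = P.tree_length(dated6, m)
        assert np.array_equal(pm.char_lengths, s.steps)
        per_char = np.zeros(m.n_char, dtype=int)
        for c in pm.resolved:
            per_char[c.char] += 1
        assert np.array_equal(per_char, s.steps)
        assert brute_force_length(dated6, m) == int(s.steps.sum())


def test_unambiguous_change_with_majority_root_state(dated6):
    # 0 everywhere except the CD clade: a single unambiguous 0 -> 1 gain
    m = CharacterMatrix.from_sets(TAXA6, [[0], [0], [1], [1], [0], [0]])
    pm = parsimony_map(dated6, m)
    unamb = [c for c in pm.changes if not c.ambiguous]
    assert len(unamb) == 1
    assert unamb[0].clade == frozenset("CD")
    assert unamb[0].from_states == (0,) and unamb[0].to_states == (1,)


def test_balanced_split_maps_as_ambiguous(dated6):
    # a perfectly balanced 0/1 split leaves the root equivocal: the single
    # change can sit on either stem, so both calls are flagged ambiguous
    m = CharacterMatrix.from_sets(TAXA6, [[0], [0], [1], [1], [1], [1]])
    pm = parsimony_map(dated6, m)
    assert pm.changes and all(c.ambiguous for c in pm.changes)
    assert pm.char_lengths[0] == 1


def test_polymorphic_tips_map_as_ambiguous(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[{0, 1}], [{0}], [{1}], [{1}], [{1}], [{1}]])
    pm = parsimony_map(dated6, m)
    assert pm.changes and all(c.ambiguous for c in pm.changes)


def test_er_fit_matches_grid_search(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[0], [0], [1], [1], [0], [1]])
    fit = fit_mk_variant(dated6, m, 0, "ER")
    tindex = {t: i for i, t in enumerate(m.taxa)}
    tips = _char_partials(dated6, m, 0, tindex)
    grid = np.linspace(0.005, 5, 4000)
    lls = [_loglik_q(dated6, tips, _build_q(2, np.array([r]), "ER"), 2) for r in grid]
    assert fit.rates[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-2)
    assert fit.loglik == pytest.approx(max(lls), abs=1e-4)


def test_model_nesting_likelihood_order(rng, dated6):
    m = random_matrix(rng, TAXA6, 3, max_states=3)
    for j in range(m.n_char):
        f_er = fit_mk_variant(dated6, m, j, "ER")
        f_sym = fit_mk_variant(dated6, m, j, "SYM")
        f_ard = fit_mk_variant(dated6, m, j, "ARD")
        assert f_er.loglik <= f_sym.loglik + 1e-5 <= f_ard.loglik + 2e-5


def test_single_state_character_hits_rate_boundary(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[0]] * 6)
    best = select_model(dated6, m, 0)
    assert best.model == "ER"
    assert best.boundary
    assert best.rates[0] < 1e-6


def test_undated_tree_rejected():
    t = tree("((A,B),((C,D),(E,F)));")  # no branch lengths
    m = CharacterMatrix.from_sets(TAXA6, [[0], [0], [1], [1], [0], [1]])
    with pytest.raises(ValueError):
        fit_mk_variant(t, m, 0, "ER")


def test_stochastic_map_matches_exact_marginals(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[0], [0], [1], [1], [0], [1]])
    fit = fit_mk_variant(dated6, m, 0, "ER")
    n_maps = 3000
    sm = stochastic_map(dated6, m, 0, fit=fit, n_maps=n_maps, seed=11)
    # exact marginals by enumeration over internal states
    Q = fit.q_matrix()
    nodes = list(dated6.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    tindex = {t: i for i, t in enumerate(m.taxa)}
    marg = {id(n): np.zeros(2) for n in internals}
    tot = 0.0
    for assign in itertools.product(range(2), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        p = 0.5
        for n in nodes:
            if n.parent_node is None:
                continue
            Pm = expm(Q * (n.edge.length or 0.0))
            ps = amap[id(n.parent_node)]
            if n.is_leaf():
                mask = int(m.masks[tindex[n.taxon.label], 0])
                p *= sum(Pm[ps, x] for x in range(2) if mask >> x & 1)
            else:
                p *= Pm[ps, amap[id(n)]]
        for n in internals:
            marg[id(n)][amap[id(n)]] += p
        tot += p
    below = _clade_sets(dated6)
    for n in internals:
        exact = marg[id(n)] / tot
        mc = sm.node_probs[below[id(n)]]
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-4) / n_maps)
        assert np.all(np.abs(exact - mc) <= 3 * se + 0.01)


def test_stochastic_map_invariant_character_certain(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[1]] * 6)
    fit = fit_mk_variant(dated6, m, 0, "ER")
    sm = stochastic_map(dated6, m, 0, fit=fit, n_maps=200, seed=2)
    for clade, probs in sm.node_probs.items():
        assert probs[1] > 0.99
    with pytest.raises(ValueError):
        stochastic_map(dated6, m, 0, fit=fit, n_maps=0)


def test_stochastic_map_seed_convergence(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[0], [1], [1], [0], [1], [0]])
    fit = fit_mk_variant(dated6, m, 0, "ER")
    a = stochastic_map(dated6, m, 0, fit=fit, n_maps=2000, seed=1)
    b = stochastic_map(dated6, m, 0, fit=fit, n_maps=2000, seed=2)
    for clade in a.node_probs:
        tv = 0.5 * np.abs(a.node_probs[clade] - b.node_probs[clade]).sum()
        assert tv < 0.04


def test_synapomorphy_exclusivity_census(dated6):
    # clean apomorphy of CD: exclusive; convergent gains in AB and EF: not
    m = CharacterMatrix.from_sets(
        TAXA6,
        [
            [0, 1], [0, 1],      # A, B : char1 state 1 (gain #1)
            [1, 0], [1, 0],      # C, D : char0 gain, exclusive
            [0, 1], [0, 1],      # E, F : char1 state 1 (gain #2)
        ],
    )
    pm = parsimony_map(dated6, m)
    syn_cd = synapomorphies(pm, frozenset("CD"))
    assert [s for s in syn_cd if s["char"] == 0 and s["exclusive"]]
    syn_ab = synapomorphies(pm, frozenset("AB"))
    char1 = [s for s in syn_ab if s["char"] == 1]
    if char1:  # convergent: must not be exclusive
        assert not char1[0]["exclusive"]
    with pytest.raises(KeyError):
        synapomorphies(pm, frozenset(["A", "C"]))


def test_root_has_no_stem_synapomorphies(dated6):
    m = CharacterMatrix.from_sets(TAXA6, [[0], [0], [1], [1], [1], [1]])
    pm = parsimony_map(dated6, m)
    assert synapomorphies(pm, frozenset(TAXA6)) == []
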