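import dendropy
import numpy as np
import pytest

from paleotip.matrixio import CharacterMatrix


@pytest.fixture(scope="session")
def taxa5():
    return ["A", "B", "C", "D", "E"]


@pytest.fixture(scope="session")
def tns5(taxa5):
    return dendropy.TaxonNamespace(taxa5)


def tree(nwk, tns=None):
    return dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)


@pytest.fixture(scope="session")
def balanced5(tns5):
    return tree("((A,B),(C,(D,E)));", tns5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, taxa, n_char, max_states=3, p_missing=0.0, p_poly=0.0):
    """Random uncertainty-set matrix with self-consistent alphabets:
    each column's missing cells span exactly its observed states."""
    cols = []
    for _ in range(n_char):
        k = int(rng.integers(2, max_states + 1))
        col = []
        for _ in taxa:
            u = rng.random()
            if u < p_missing:
                col.append(None)
            elif u < p_missing + p_poly and k > 2:
                col.append(set(rng.choice(k, size=2, replace=False).tolist()))
            else:
                col.append({int(rng.integers(k))})
        observed = set()
        for c in col:
            if c is not None:
                observed |= c
        k_obs = max(max(observed) + 1, 2) if observed else 2
        cols.append([set(range(k_obs)) if c is None else c for c in col])
    cells = [[cols[j][i] for j in range(n_char)] for i in range(len(taxa))]
    return CharacterMatrix.from_sets(list(taxa), cells)


def brute_force_length(tree, matrix):
    """Minimum-cost internal-state assignment by exhaustive enumeration
    (independent of the package's Hartigan pass)."""
    import itertools

    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    tindex = {t: i for i, t in enumerate(matrix.taxa)}
    total = 0
    for j in range(matrix.n_char):
        k = int(matrix.n_states[j])
        best = 10 ** 9
        for assign in itertools.product(range(k), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            cost = 0
            for n in nodes:
                if n.parent_node is None:
                    continue
                ps = amap[id(n.parent_node)]
                if n.is_leaf():
                    m = int(matrix.masks[tindex[n.taxon.label], j])
                    if not (m >> ps) & 1:
                        cost += 1
                elif amap[id(n)] != ps:
                    cost += 1
            best = min(best, cost)
        total += best
    return total
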