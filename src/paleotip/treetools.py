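"""Consensus trees, rogue-taxon detection, and tree-set pruning.

Splits are bipartitions of the common taxon set, encoded as integer
bitmasks over the sorted taxon labels and normalized to the side that
excludes the first taxon.  Rogue detection greedily removes the taxon
whose deletion most increases the information content of the majority
consensus: the sum over retained splits of the phylogenetic information
content of the split (how many binary trees it excludes, in bits)
weighted by its support fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy

from .treesample import TreeSample

__all__ = [
    "split_frequencies",
    "majority_consensus",
    "detect_rogues",
    "prune_sample",
    "consensus_information",
]


def _tree_splits(tree: dendropy.Tree, index: dict[str, int], mask_all: int) -> set[int]:
    """Nontrivial splits of one tree, normalized to exclude taxon 0."""
    out: set[int] = set()
    below: dict[int, int] = {}
    n = bin(mask_all).count("1")
    for node in tree.postorder_node_iter():
        m = 0
        if node.is_leaf():
            m = 1 << index[node.taxon.label]
        for ch in node.child_nodes():
            m |= below[id(ch)]
        below[id(node)] = m
        if node.parent_node is not None:
            s = m if not (m & 1) else (mask_all & ~m)
            if 2 <= s.bit_count() <= n - 2:
                out.add(s)
    return out


def _restricted_splits(splits: set[int], keep_mask: int, full_index_n: int) -> set[int]:
    """Restrict a tree's splits to a taxon subset (bitmask keep_mask)."""
    nk = keep_mask.bit_count()
    low_bit = keep_mask & -keep_mask
    out = set()
    for s in splits:
        r = s & keep_mask
        if r & low_bit:
            r = keep_mask & ~r
        if 2 <= r.bit_count() <= nk - 2:
            out.add(r)
    return out


def _label_index(sample: TreeSample) -> tuple[list[str], dict[str, int]]:
    labels = sample.taxon_labels
    return labels, {t: i for i, t in enumerate(labels)}


def split_frequencies(sample: TreeSample) -> tuple[dict[int, float], list[str]]:
    """Split -> frequency over a tree sample; also returns the label order."""
    labels, index = _label_index(sample)
    mask_all = (1 << len(labels)) - 1
    counts: dict[int, int] = {}
    for t in sample:
        for s in _tree_splits(t, index, mask_all):
            counts[s] = counts.get(s, 0) + 1
    n = len(sample.trees)
    return {s: c / n for s, c in counts.items()}, labels


def _tree_from_clades(keep: dict[int, float], labels: list[str]) -> dendropy.Tree:
    n = len(labels)
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    full = (1 << n) - 1
    # clades = split sides excluding taxon 0; nest by size
    order = sorted(keep, key=lambda s: -s.bit_count())
    nodes: list[tuple[int, dendropy.Node]] = [(full, tree.seed_node)]
    for s in order:
        candidates = [(m, nd) for m, nd in nodes if (s & m) == s]
        parent = min(candidates, key=lambda x: x[0].bit_count())[1]
        nd = dendropy.Node()
        nd.support = keep[s]
        nd.label = f"{keep[s]:.3f}"
        parent.add_child(nd)
        nodes.append((s, nd))
    for i, lab in enumerate(labels):
        bit = 1 << i
        best = None
        for m, nd in nodes:
            if m & bit and (best is None or m.bit_count() < best[0].bit_count()):
                best = (m, nd)
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        best[1].add_child(leaf)
    return tree


def majority_consensus(sample: TreeSample, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: exactly the splits with frequency > threshold.

    Splits at exactly the threshold are excluded (strict ``>``), keeping
    the consensus a function of the sample alone.  Node labels and the
    ``support`` attribute carry the split frequencies.
    """
    if threshold < 0.5:
        raise ValueError("threshold must be >= 0.5 for a consistent consensus")
    freqs, labels = split_frequencies(sample)
    keep = {s: f for s, f in freqs.items() if f > threshold}
    return _tree_from_clades(keep, labels)


def _log2_num_unrooted(m: int) -> float:
    """log2 (2m-5)!! — the number of unrooted binary trees on m labels."""
    if m < 3:
        return 0.0
    return sum(math.log2(i) for i in range(3, 2 * m - 4, 2))


def split_information(clade_size: int, n_taxa: int) -> float:
    """Phylogenetic information content (bits) of one split on n taxa."""
    a = clade_size
    return (
        _log2_num_unrooted(n_taxa)
        - _log2_num_unrooted(a + 1)
        - _log2_num_unrooted(n_taxa - a + 1)
    )


def _info_of_subset(per_tree_splits: list[set[int]], keep_mask: int) -> float:
    nk = keep_mask.bit_count()
    counts: dict[int, int] = {}
    for splits in per_tree_splits:
        for s in _restricted_splits(splits, keep_mask, nk):
            counts[s] = counts.get(s, 0) + 1
    n = len(per_tree_splits)
    info = 0.0
    for s, c in counts.items():
        f = c / n
        if f > 0.5:
            info += f * split_information(s.bit_count(), nk)
    return info


@dataclass
class RogueReport:
    rogues: list[str]
    gains: list[float]
    info_trace: list[float]  # consensus information after each removal


def detect_rogues(sample: TreeSample, min_taxa: int = 4) -> RogueReport:
    """Greedy rogue-taxon removal maximizing consensus information.

    At each step the taxon whose deletion most increases the
    support-weighted information content of the majority consensus is
    dropped; stops when no single removal increases it.
    """
    if len(sample.trees) < 2:
        return RogueReport([], [], [])
    labels, index = _label_index(sample)
    mask_all = (1 << len(labels)) - 1
    per_tree = [_tree_splits(t, index, mask_all) for t in sample]
    keep = mask_all
    base = _info_of_subset(per_tree, keep)
    rogues, gains, trace = [], [], [base]
    while keep.bit_count() > min_taxa:
        best_gain, best_bit = 0.0, None
        for i in range(len(labels)):
            bit = 1 << i
            if not keep & bit:
                continue
            info = _info_of_subset(per_tree, keep & ~bit)
            if info - base > best_gain + 1e-12:
                best_gain, best_bit = info - base, bit
        if best_bit is None:
            break
        keep &= ~best_bit
        base += best_gain
        rogues.append(labels[best_bit.bit_length() - 1])
        gains.append(best_gain)
        trace.append(base)
        # invariant by construction: information never decreases
        assert all(trace[i + 1] >= trace[i] - 1e-9 for i in range(len(trace) - 1))
    return RogueReport(rogues, gains, trace)


def prune_sample(sample: TreeSample, drop: list[str]) -> TreeSample:
    """Remove taxa from every tree, suppressing degree-2 nodes.

    Branch lengths merge additively; node ``age`` attributes, when
    present, are preserved on surviving nodes.
    """
    drop = list(drop)
    if not drop:
        return TreeSample(list(sample.trees), sample.params)
    labels = sample.taxon_labels
    unknown = [d for d in drop if d not in labels]
    if unknown:
        raise ValueError(f"cannot drop taxa absent from sample: {unknown}")
    if len(labels) - len(drop) < 3:
        raise ValueError("pruning would leave fewer than 3 taxa")
    out = []
    for t in sample:
        c = t.clone(depth=1)
        c.prune_taxa_with_labels(drop, suppress_unifurcations=True)
        out.append(c)
    return TreeSample(out, sample.params)
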