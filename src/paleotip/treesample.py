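"""Ordered collections of (tree, parameter draw) records.

A :class:`TreeSample` is the common currency between stages: parsimony
search results, bootstrap replicates and MCMC posteriors all travel as a
list of dendropy trees on one taxon namespace plus an aligned parameter
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd


@dataclass
class TreeSample:
    trees: list[dendropy.Tree]
    params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.params is not None and len(self.params) != len(self.trees):
            raise ValueError("params rows must match number of trees")
        tns = {id(t.taxon_namespace) for t in self.trees}
        if len(tns) > 1:
            raise ValueError("trees must share one taxon namespace")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def taxon_labels(self) -> list[str]:
        labels = {
            frozenset(leaf.taxon.label for leaf in t.leaf_node_iter()) for t in self.trees
        }
        if len(labels) != 1:
            raise ValueError("trees carry mixed taxon sets")
        return sorted(next(iter(labels)))
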