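"""Readers, writers and the shared data model for discrete morphological data.

The central objects are:

* :class:`CharacterMatrix` — a taxa × characters table of *state sets*.
  Each cell is a non-empty set of integer states; a missing observation
  (``?`` or the gap symbol ``-``) is the full alphabet of its character,
  and a polymorphic/uncertain coding such as ``(01)`` or ``{01}`` is the
  set of listed states.  All downstream stages (parsimony, likelihood,
  mapping) treat these sets as uncertainty: any member state may be
  realized at no cost.
* :class:`TipAgeTable` — one stratigraphic age interval ``[age_min,
  age_max]`` in Ma per taxon; extant taxa carry ``[0, 0]``.
* dated trees — plain :class:`dendropy.Tree` objects on which every node
  carries an ``age`` attribute (Ma before present).

NEXUS/Newick parsing is delegated to dendropy; this module enforces the
data-model invariants on top of it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CharacterMatrix",
    "TipAgeTable",
    "MatrixParseError",
    "TipAgeError",
    "parse_nexus",
    "write_nexus",
    "parse_tip_ages",
    "write_tip_ages",
    "read_tree",
    "read_trees",
    "write_trees",
    "set_node_ages",
    "tree_from_ages",
]


class MatrixParseError(ValueError):
    """Raised when a NEXUS matrix violates the data model."""


class TipAgeError(ValueError):
    """Raised when a tip-age table is incomplete or inconsistent."""


def normalize_label(label: str) -> str:
    """Taxon-label normalization: spaces become underscores, case kept."""
    return label.strip().replace(" ", "_")


@dataclass
class CharacterMatrix:
    """Discrete morphological matrix with uncertainty sets as cells.

    ``masks[i, j]`` is a bitmask over states of character ``j`` for taxon
    ``i``: bit ``s`` set means state ``s`` is compatible with the
    observation.  ``n_states[j]`` is the alphabet size of character ``j``
    (``max observed state + 1``, at least 2 so that single-state
    characters still define a valid Mk alphabet).
    """

    taxa: list[str]
    masks: np.ndarray  # (ntax, nchar) uint16 bitmasks, never 0
    n_states: np.ndarray  # (nchar,) int

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=np.uint16)
        self.n_states = np.asarray(self.n_states, dtype=np.int64)
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixParseError(f"duplicate taxon labels: {dup}")
        if self.masks.shape != (len(self.taxa), len(self.n_states)):
            raise MatrixParseError("masks shape does not match taxa/characters")
        if np.any(self.masks == 0):
            raise MatrixParseError("empty state set in matrix cell")
        full = (np.uint16(1) << self.n_states.astype(np.uint16)) - 1
        if np.any(self.masks & ~full):
            raise MatrixParseError("cell state outside character alphabet")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return int(self.masks.shape[1])

    def cell(self, taxon: str | int, char: int) -> frozenset[int]:
        """State set of one cell."""
        i = taxon if isinstance(taxon, int) else self.taxa.index(taxon)
        m = int(self.masks[i, char])
        return frozenset(s for s in range(int(self.n_states[char])) if m >> s & 1)

    def is_missing(self, i: int, j: int) -> bool:
        return int(self.masks[i, j]) == (1 << int(self.n_states[j])) - 1

    @classmethod
    def from_sets(cls, taxa: list[str], cells: list[list[set[int] | int]]) -> "CharacterMatrix":
        """Build a matrix from per-taxon rows of ints or sets of ints."""
        taxa = [normalize_label(t) for t in taxa]
        nchar = len(cells[0])
        rows = []
        for r in cells:
            if len(r) != nchar:
                raise MatrixParseError("ragged rows")
            rows.append([{c} if isinstance(c, int) else set(c) for c in r])
        n_states = np.array(
            [max(2, 1 + max(max(row[j]) for row in rows)) for j in range(nchar)], dtype=np.int64
        )
        masks = np.zeros((len(taxa), nchar), dtype=np.uint16)
        for i, row in enumerate(rows):
            for j, s in enumerate(row):
                masks[i, j] = sum(1 << int(x) for x in s)
        return cls(taxa, masks, n_states)

    def subset_taxa(self, keep: list[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in keep]
        sub = self.masks[idx, :].copy()
        # clip alphabets to what the kept taxa can still realize
        n_states = self.n_states.copy()
        full = (np.uint16(1) << self.n_states.astype(np.uint16)) - 1
        for j in range(self.n_char):
            nonmiss = sub[:, j][sub[:, j] != full[j]]
            hi = 0
            for m in nonmiss:
                hi = max(hi, int(m).bit_length() - 1)
            k = max(2, hi + 1)
            if k < n_states[j]:
                n_states[j] = k
                sub[:, j] = np.where(sub[:, j] == full[j], (1 << k) - 1, sub[:, j] & ((1 << k) - 1))
        return CharacterMatrix([self.taxa[i] for i in idx], sub, n_states)

    def subset_chars(self, cols: list[int]) -> "CharacterMatrix":
        return CharacterMatrix(list(self.taxa), self.masks[:, cols].copy(), self.n_states[cols].copy())


_SYMBOLS = "0123456789"


def _cell_token(mask: int, k: int) -> str:
    full = (1 << k) - 1
    if mask == full:
        return "?"
    states = [s for s in range(k) if mask >> s & 1]
    if len(states) == 1:
        return _SYMBOLS[states[0]]
    return "(" + "".join(_SYMBOLS[s] for s in states) + ")"


def write_nexus(matrix: CharacterMatrix, path_or_buf) -> None:
    """Serialize to NEXUS (DATA block, datatype=standard)."""
    kmax = int(matrix.n_states.max())
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
        f"FORMAT DATATYPE=STANDARD SYMBOLS=\"{_SYMBOLS[:kmax]}\" MISSING=? GAP=-;",
        "MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, t in enumerate(matrix.taxa):
        row = "".join(
            _cell_token(int(matrix.masks[i, j]), int(matrix.n_states[j]))
            for j in range(matrix.n_char)
        )
        lines.append(t.ljust(width) + row)
    lines += [";", "END;", ""]
    text = "\n".join(lines)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def parse_nexus(path=None, *, data: str | None = None) -> CharacterMatrix:
    """Read a NEXUS standard-datatype matrix into a :class:`CharacterMatrix`.

    ``?`` and ``-`` map to the full per-character alphabet; ``(..)`` and
    ``{..}`` state sets map to the listed states.  The per-character
    alphabet is ``{0 .. max observed state}`` (minimum two states).
    """
    try:
        if data is not None:
            dm = dendropy.StandardCharacterMatrix.get(data=data, schema="nexus")
        else:
            dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as e:  # dendropy errors carry line numbers in str()
        raise MatrixParseError(f"NEXUS parse failure: {e}") from e

    taxa = [normalize_label(t.label) for t in dm.taxon_namespace]
    nchar = max(len(dm[t]) for t in dm.taxon_namespace)
    cells: list[list[set[int] | None]] = []
    for tax in dm.taxon_namespace:
        row = dm[tax]
        if len(row) != nchar:
            raise MatrixParseError(f"taxon {tax.label!r}: row length {len(row)} != NCHAR {nchar}")
        out_row: list[set[int] | None] = []
        for st in row:
            if st.is_gap_state:
                out_row.append(None)  # missing
                continue
            ms = st.member_states
            if ms is None:
                out_row.append({int(st.symbol)})
            else:
                syms = {s.symbol for s in ms} - {"-", "?"}
                if not syms or len(syms) == len(_SYMBOLS):
                    out_row.append(None)
                elif st.symbol == "?":
                    out_row.append(None)
                else:
                    out_row.append({int(s) for s in syms})
        cells.append(out_row)

    n_states = np.zeros(nchar, dtype=np.int64)
    for j in range(nchar):
        hi = 0
        for row in cells:
            if row[j] is not None:
                hi = max(hi, max(row[j]))
        n_states[j] = max(2, hi + 1)
    masks = np.zeros((len(taxa), nchar), dtype=np.uint16)
    for i, row in enumerate(cells):
        for j, s in enumerate(row):
            if s is None:
                masks[i, j] = (1 << int(n_states[j])) - 1
            else:
                masks[i, j] = sum(1 << x for x in s)
    return CharacterMatrix(taxa, masks, n_states)


@dataclass
class TipAgeTable:
    """Per-taxon stratigraphic age interval, Ma before present."""

    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [
            t
            for t, (lo, hi) in self.intervals.items()
            if lo < 0 or hi < 0 or lo > hi or not (np.isfinite(lo) and np.isfinite(hi))
        ]
        if bad:
            raise TipAgeError(f"invalid age intervals (need 0 <= min <= max) for: {sorted(bad)}")

    def __getitem__(self, taxon: str) -> tuple[float, float]:
        return self.intervals[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.intervals

    @property
    def taxa(self) -> list[str]:
        return list(self.intervals)

    def fad(self, taxon: str) -> float:
        """First-appearance datum: the old end of the interval."""
        return self.intervals[taxon][1]

    def is_extant(self, taxon: str) -> bool:
        lo, hi = self.intervals[taxon]
        return lo == 0.0 and hi == 0.0

    def restrict(self, taxa: list[str]) -> "TipAgeTable":
        return TipAgeTable({t: self.intervals[t] for t in taxa})


def parse_tip_ages(path_or_buf, matrix: CharacterMatrix | None = None) -> TipAgeTable:
    """Read a ``taxon,min_ma,max_ma`` CSV; validate against a matrix if given."""
    df = pd.read_csv(path_or_buf)
    need = {"taxon", "min_ma", "max_ma"}
    if not need.issubset(df.columns):
        raise TipAgeError(f"tip-age CSV must have columns {sorted(need)}, got {list(df.columns)}")
    intervals: dict[str, tuple[float, float]] = {}
    for _, r in df.iterrows():
        t = normalize_label(str(r["taxon"]))
        if t in intervals:
            raise TipAgeError(f"duplicate taxon in age table: {t}")
        intervals[t] = (float(r["min_ma"]), float(r["max_ma"]))
    table = TipAgeTable(intervals)
    if matrix is not None:
        missing = [t for t in matrix.taxa if t not in table]
        if missing:
            raise TipAgeError(f"age table lacks matrix taxa: {missing}")
    return table


def write_tip_ages(table: TipAgeTable, path_or_buf) -> None:
    df = pd.DataFrame(
        [(t, lo, hi) for t, (lo, hi) in table.intervals.items()],
        columns=["taxon", "min_ma", "max_ma"],
    )
    df.to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# trees


def read_tree(path=None, *, data: str | None = None, schema: str = "newick") -> dendropy.Tree:
    if data is not None:
        t = dendropy.Tree.get(data=data, schema=schema)
    else:
        t = dendropy.Tree.get(path=str(path), schema=schema)
    for leaf in t.leaf_node_iter():
        leaf.taxon.label = normalize_label(leaf.taxon.label)
    return t

def read_trees(path=None, *, data: str | None = None, schema: str = "nexus") -> list[dendropy.Tree]:
    if data is not None:
        tl = dendropy.TreeList.get(data=data, schema=schema)
    else:
        tl = dendropy.TreeList.get(path=str(path), schema=schema)
    for taxon in tl.taxon_namespace:
        taxon.label = normalize_label(taxon.label)
    return list(tl)

def write_trees(trees, path_or_buf, schema: str = "nexus") -> None:
    tl = dendropy.TreeList(taxon_namespace=trees[0].taxon_namespace)
    tl.extend(trees)
    text = tl.as_string(schema=schema)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def set_node_ages(tree: dendropy.Tree, tip_ages: dict[str, float] | None = None) -> dendropy.Tree:
    """Attach an ``age`` attribute (Ma) to every node from edge lengths.

    ``tip_ages`` gives the age of each leaf (default 0 = extant); internal
    node ages follow from ``child age + child edge length``.  Conflicting
    paths are reconciled by the maximum (tolerance 1e-6 asserted by callers
    that require exactness).
    """
    ages = tip_ages or {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.age = float(ages.get(node.taxon.label, 0.0))
        else:
            node.age = max(
                ch.age + (ch.edge.length if ch.edge.length is not None else 0.0)
                for ch in node.child_nodes()
            )
    return tree


def tree_from_ages(tree: dendropy.Tree) -> dendropy.Tree:
    """Set edge lengths (durations, My) from node ``age`` attributes."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
            if node.edge.length < -1e-9:
                raise ValueError("negative branch duration: child older than parent")
            node.edge.length = max(0.0, node.edge.length)
    return tree
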