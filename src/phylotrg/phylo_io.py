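"""Trees, species mapping and tabular formats.

This module owns every external format the pipeline touches:

* newick trees (species trees and gene trees), parsed through dendropy and
  held in a lightweight :class:`TreeNode` structure that the reconciliation
  algorithms traverse directly;
* 12-column tab-separated similarity-search hit tables (the classical
  ``outfmt 6`` dialect);
* TSV tables with headers for orthology calls, gene annotations, isoform
  lengths, expression matrices and site-level selection posteriors.

Gene-tree leaves are linked to species through a :class:`SpeciesMap`; by
default the species mnemonic is the suffix after the final underscore of the
sequence ID (the PhylomeDB-style convention), but an explicit lookup table
may be supplied instead.  An unmappable leaf is always an error, never a
silent drop.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import (
    DataError,
    FormatError,
    NewickParseError,
    SchemaError,
    SpeciesMapError,
)

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "GeneTree",
    "SpeciesMap",
    "HitTable",
    "HIT_COLUMNS",
    "DEFAULT_TOOLS",
    "read_newick",
    "write_newick",
    "read_hit_table",
    "write_hit_table",
    "read_table",
]


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted tree.

    Leaves carry a ``label`` (species mnemonic or sequence ID); internal
    nodes may carry an optional name and/or ``support``.  ``length`` is the
    length of the branch subtending this node (optional everywhere: the
    reconciliation operations are purely topological).
    """

    __slots__ = ("label", "length", "support", "children", "parent",
                 "species", "age_rank")

    def __init__(self, label: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.species: str | None = None     # set on gene-tree leaves
        self.age_rank: int | None = None    # set on species-tree nodes

    # -- construction -------------------------------------------------------

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def detach(self) -> "TreeNode":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    # -- queries -------------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.label, self.length, self.support)
        clone.species = self.species
        clone.age_rank = self.age_rank
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {write_newick_node(self)}>"


def _needs_quotes(label: str) -> bool:
    return bool(re.search(r"[\s()\[\]:;,']", label))


def _format_label(label: str | None) -> str:
    if label is None:
        return ""
    if _needs_quotes(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick_node(node: TreeNode, with_lengths: bool = True,
                      with_support: bool = True) -> str:
    """Serialize the subtree rooted at ``node`` (no trailing semicolon)."""
    if node.is_leaf:
        out = _format_label(node.label)
    else:
        inner = ",".join(write_newick_node(c, with_lengths, with_support)
                         for c in node.children)
        tag = ""
        if node.support is not None and with_support:
            tag = str(node.support)
        elif node.label:
            tag = _format_label(node.label)
        out = f"({inner}){tag}"
    if with_lengths and node.length is not None:
        out += ":" + str(node.length)
    return out


# ---------------------------------------------------------------------------
# Species map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesMap:
    """Rule linking gene-tree leaf labels to species mnemonics.

    ``kind`` is ``"regex"`` (the first capture group of ``pattern`` is the
    mnemonic) or ``"table"`` (explicit sequence-ID lookup).  The default rule
    takes the suffix after the final underscore, e.g. ``gene12_STRPU`` →
    ``STRPU``.
    """

    kind: str = "regex"
    pattern: str = r"_([^_]+)$"
    table: Mapping[str, str] = field(default_factory=dict)

    def species_of(self, label: str) -> str:
        if self.kind == "regex":
            m = re.search(self.pattern, label)
            if m is None or not m.group(1):
                raise SpeciesMapError(
                    f"leaf {label!r} does not match species pattern "
                    f"{self.pattern!r}")
            return m.group(1)
        if self.kind == "table":
            try:
                return self.table[label]
            except KeyError:
                raise SpeciesMapError(
                    f"leaf {label!r} is not in the species lookup table"
                ) from None
        raise SpeciesMapError(f"unknown species-map kind {self.kind!r}")


DEFAULT_SPECIES_MAP = SpeciesMap()


# ---------------------------------------------------------------------------
# Species tree and gene tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """Rooted tree over species mnemonics.

    The frame onto which duplication densities, gains and losses are mapped.
    Leaf labels must be unique; every internal node has at least two
    children; optional ``age_rank`` values must not decrease from the leaves
    toward the root.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()
        self._leafsets: dict[int, frozenset[str]] = {}
        for node in root.postorder():
            if node.is_leaf:
                self._leafsets[id(node)] = frozenset([node.label])
            else:
                self._leafsets[id(node)] = frozenset().union(
                    *(self._leafsets[id(c)] for c in node.children))

    def _validate(self) -> None:
        labels = self.root.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataError(f"duplicate species leaf labels: {dupes}")
        for node in self.root.postorder():
            if not node.is_leaf and len(node.children) < 2:
                raise DataError("species-tree internal node with a single "
                                "child (unresolved unary node)")
            if node.age_rank is not None and node.age_rank < 0:
                raise DataError("negative age_rank")
            for child in node.children:
                if (node.age_rank is not None and child.age_rank is not None
                        and node.age_rank < child.age_rank):
                    raise DataError("age_rank must be non-decreasing from "
                                    "leaves to root")

    # -- queries -------------------------------------------------------------

    @property
    def species(self) -> frozenset[str]:
        return self._leafsets[id(self.root)]

    def leafset(self, node: TreeNode) -> frozenset[str]:
        return self._leafsets[id(node)]

    def mrca(self, species: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of a set of species (smallest clade
        containing them all)."""
        wanted = frozenset(species)
        missing = wanted - self.species
        if missing:
            raise DataError(
                f"species absent from species tree: {sorted(missing)}")
        if not wanted:
            raise DataError("mrca of the empty species set is undefined")
        node = self.root
        while True:
            covering = [c for c in node.children
                        if wanted <= self._leafsets[id(c)]]
            if not covering:
                return node
            node = covering[0]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def newick(self, with_lengths: bool = True) -> str:
        return write_newick_node(self.root, with_lengths=with_lengths) + ";"

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(self.root.copy())


class GeneTree:
    """Rooted (or as-parsed) gene tree; each leaf carries a sequence ID and
    the species it resolves to under the declared :class:`SpeciesMap`."""

    def __init__(self, root: TreeNode, species_map: SpeciesMap = DEFAULT_SPECIES_MAP,
                 seed_sequence_id: str | None = None):
        self.root = root
        self.species_map = species_map
        self.seed_sequence_id = seed_sequence_id
        self.explicitly_rooted = False
        labels = root.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataError(f"duplicate gene-tree leaf labels: {dupes}")
        for leaf in root.leaves():
            if leaf.species is None:
                leaf.species = species_map.species_of(leaf.label)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(l.species for l in self.root.leaves())

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.root.postorder()
                   if not n.is_leaf)

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def newick(self, with_lengths: bool = True) -> str:
        return write_newick_node(self.root, with_lengths=with_lengths) + ";"

    def copy(self) -> "GeneTree":
        clone = GeneTree(self.root.copy(), self.species_map,
                         self.seed_sequence_id)
        clone.explicitly_rooted = self.explicitly_rooted
        return clone


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

def _to_treenode(dnode: dendropy.Node, internal_label_as_support: bool) -> TreeNode:
    if dnode.taxon is not None:
        label = dnode.taxon.label
    else:
        label = dnode.label
    node = TreeNode(length=dnode.edge.length)
    if dnode.is_leaf():
        node.label = label
    else:
        # internal label: a bare number is a support value by convention
        if label is not None and internal_label_as_support:
            try:
                node.support = float(label)
            except ValueError:
                node.label = label
        else:
            node.label = label
    for child in dnode.child_nodes():
        node.add_child(_to_treenode(child, internal_label_as_support))
    return node


def parse_newick(text: str, internal_label_as_support: bool = True) -> TreeNode:
    """Parse one newick string into a :class:`TreeNode`.

    Plain newick with optional support-as-internal-label; bracketed comment
    blocks (including NHX annotations) are tolerated and ignored.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "multiple" in str(exc).lower() or "duplicate" in str(exc).lower():
            raise DataError(f"duplicate leaf labels: {exc}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return _to_treenode(dtree.seed_node, internal_label_as_support)


def read_newick(text: str, kind: str = "species",
                species_map: SpeciesMap = DEFAULT_SPECIES_MAP,
                ) -> SpeciesTree | GeneTree:
    """Read a newick string into a :class:`SpeciesTree` or :class:`GeneTree`.

    For gene trees every leaf must resolve through ``species_map``; an
    unmappable leaf raises :class:`~phylotrg.errors.SpeciesMapError` naming
    the leaf.
    """
    root = parse_newick(text)
    if kind == "species":
        return SpeciesTree(root)
    if kind == "gene":
        return GeneTree(root, species_map)
    raise ValueError(f"kind must be 'species' or 'gene', got {kind!r}")


def write_newick(tree: SpeciesTree | GeneTree | TreeNode,
                 with_lengths: bool = True) -> str:
    if isinstance(tree, TreeNode):
        return write_newick_node(tree, with_lengths=with_lengths) + ";"
    return tree.newick(with_lengths=with_lengths)


# ---------------------------------------------------------------------------
# Hit tables (12-column tab-separated similarity-search dialect)
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
_HIT_FLOAT = {"pident", "evalue", "bitscore"}
_HIT_INT = {"length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"}


class HitTable:
    """Similarity-search hits plus an optional query-length registry.

    ``df`` keeps one row per hit in input order with the canonical 12
    columns; ``query_lengths`` maps query IDs to sequence lengths and is
    required by coverage-based filtering.
    """

    def __init__(self, df: pd.DataFrame,
                 query_lengths: Mapping[str, int] | None = None):
        if list(df.columns) != HIT_COLUMNS:
            raise SchemaError(
                f"hit table must have columns {HIT_COLUMNS}, got "
                f"{list(df.columns)}")
        if len(df) and (df["evalue"] < 0).any():
            raise DataError("negative e-value in hit table")
        if len(df) and (df["bitscore"] < 0).any():
            raise DataError("negative bit score in hit table")
        if len(df):
            bad = df[(df["qstart"] < 1) | (df["qstart"] > df["qend"])]
            if len(bad):
                raise DataError(
                    "hit with query start < 1 or start > end "
                    f"(first offender query {bad.iloc[0]['qseqid']!r})")
        self.df = df.reset_index(drop=True)
        self.query_lengths = dict(query_lengths or {})
        if self.query_lengths:
            known = df["qseqid"].isin(self.query_lengths)
            if len(df) and known.any():
                sub = df[known]
                qlen = sub["qseqid"].map(self.query_lengths)
                if (sub["qend"] > qlen).any():
                    raise DataError("hit extends past registered query length")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (isinstance(other, HitTable)
                and self.df.equals(other.df)
                and self.query_lengths == other.query_lengths)


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=(float if c in _HIT_FLOAT
                                             else int if c in _HIT_INT
                                             else object))
                         for c in HIT_COLUMNS})


def read_hit_table(source, query_lengths: Mapping[str, int] | None = None
                   ) -> HitTable:
    """Read a 12-column tab-separated hit file.

    Row order is preserved; a row with the wrong column count raises
    :class:`~phylotrg.errors.FormatError` with its line number.  Both
    ``1e-05`` and ``0.00001`` notations parse to the same e-value.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 12:
            raise FormatError(
                f"line {lineno}: expected 12 tab-separated columns, "
                f"got {len(parts)}")
        try:
            row = []
            for col, value in zip(HIT_COLUMNS, parts):
                if col in _HIT_FLOAT:
                    row.append(float(value))
                elif col in _HIT_INT:
                    row.append(int(value))
                else:
                    row.append(value)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        rows.append(row)
    if not rows:
        return HitTable(_empty_hits(), query_lengths)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HitTable(df, query_lengths)


def write_hit_table(hits: HitTable, path) -> None:
    hits.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Typed TSV tables
# ---------------------------------------------------------------------------

DEFAULT_TOOLS = frozenset({
    "InParanoid", "ProteinOrtho", "SwiftOrtho", "FastOrtho", "OMA",
    "OrthoFinder",
})

_ABSENT = {"", "n/a", "na", "none", "-", "nan"}


def _parse_term_set(cell) -> frozenset[str]:
    """``'GO:1; GO:2'`` → ``{'GO:1','GO:2'}``; N/A-like markers → empty set."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if text.lower() in _ABSENT:
        return frozenset()
    return frozenset(t.strip() for t in re.split(r"[;,]", text) if t.strip())


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     schema: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema} table is missing required column(s): {missing}")


def _read_tsv(source) -> tuple[pd.DataFrame, list[str]]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    header = text.splitlines()[0].rstrip("\n").split("\t") if text.strip() else []
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    return df, header


def read_table(source, schema: str, tools: Iterable[str] = DEFAULT_TOOLS):
    """Read a typed TSV table.

    ``schema`` is one of ``orthology``, ``annotation``, ``expression``,
    ``selection`` or ``isoform``.  Missing optional cells become explicit
    absent markers (empty frozensets, ``None``), never empty strings.
    """
    readers: dict[str, Callable] = {
        "orthology": _read_orthology,
        "annotation": _read_annotation,
        "expression": _read_expression,
        "selection": _read_selection,
        "isoform": _read_isoform,
    }
    if schema not in readers:
        raise ValueError(f"unknown schema {schema!r}; choose from "
                         f"{sorted(readers)}")
    if schema == "orthology":
        return readers[schema](source, frozenset(tools))
    return readers[schema](source)


def _read_orthology(source, tools: frozenset[str]) -> pd.DataFrame:
    df, _ = _read_tsv(source)
    _require_columns(df, ["gene", "tool", "target_species", "target_gene"],
                     "orthology")
    unknown = sorted(set(df["tool"]) - set(tools))
    if unknown:
        raise SchemaError(f"unknown orthology tool name(s): {unknown}; "
                          f"registered tools: {sorted(tools)}")
    if "one_to_one" in df.columns:
        df["one_to_one"] = df["one_to_one"].str.lower().isin(
            {"1", "true", "yes", "y"})
    else:
        df["one_to_one"] = True
    return df.reset_index(drop=True)


def _read_annotation(source) -> pd.DataFrame:
    df, _ = _read_tsv(source)
    _require_columns(df, ["gene"], "annotation")
    out = pd.DataFrame({"gene": df["gene"]})
    out["go_terms"] = (df["go_terms"].map(_parse_term_set)
                       if "go_terms" in df.columns
                       else [frozenset()] * len(df))
    out["domains"] = (df["domains"].map(_parse_term_set)
                      if "domains" in df.columns
                      else [frozenset()] * len(df))
    return out


def _read_expression(source) -> pd.DataFrame:
    df, header = _read_tsv(source)
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise SchemaError(f"duplicate expression column header(s): {dupes}")
    _require_columns(df, ["gene"], "expression")
    if df["gene"].duplicated().any():
        dupes = sorted(df.loc[df["gene"].duplicated(), "gene"])
        raise SchemaError(f"duplicate gene row(s) in expression table: {dupes}")
    out = df.set_index("gene").astype(float)
    if (out.values < 0).any():
        raise DataError("negative TPM value in expression table")
    out.columns = [float(c) for c in out.columns]
    return out


def _read_selection(source) -> pd.DataFrame:
    df, _ = _read_tsv(source)
    _require_columns(df, ["gene", "site", "pp_positive", "pp_negative"],
                     "selection")
    out = df.copy()
    out["site"] = out["site"].astype(int)
    for col in ("pp_positive", "pp_negative"):
        out[col] = out[col].astype(float)
        if len(out) and ((out[col] < 0) | (out[col] > 1)).any():
            raise DataError(f"posterior probability outside [0, 1] in {col}")
    return out.reset_index(drop=True)


def _read_isoform(source) -> pd.DataFrame:
    df, _ = _read_tsv(source)
    _require_columns(df, ["gene", "isoform", "length"], "isoform")
    out = df.copy()
    out["length"] = out["length"].astype(int)
    if len(out) and (out["length"] <= 0).any():
        raise DataError("non-positive isoform length")
    return out.reset_index(drop=True)
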