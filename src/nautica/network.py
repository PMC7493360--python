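"""Protein-protein interaction network construction and per-pair features.

The reference network is an undirected graph of physical protein-protein
interactions (BioGRID-style). Two file dialects are supported: a BioGRID
TAB-like TSV with header, and a headerless two/three-column edge list. The
network is filtered to physical evidence, optionally to one organism, and
transcription factors (TFs) are eligible for classification only when their
degree in the full network reaches a minimum (default 3) — TFs below that are
treated as artefacts of network incompleteness but are retained as potential
shared partners of other pairs.

The classifier's central network feature is ``N12``, the number of shared
interactors (common neighbours) of a TF pair, counting both TF and non-TF
partners and excluding the two pair members themselves. N12 values are
summarised into eleven bins, 0..9 and a collapsed "10+" tail bin.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ._util import canonical_pair, normalize_symbol
from .errors import EmptyResultError, FormatError, SymbolNotFoundError

logger = logging.getLogger(__name__)

N_BINS = 11  # bins 0..9 plus the collapsed 10+ tail
TAIL_BIN = 10

#: Default column names for the BioGRID TAB-like dialect.
BIOGRID_COLUMNS = {
    "symbol_a": "Official Symbol Interactor A",
    "symbol_b": "Official Symbol Interactor B",
    "system_type": "Experimental System Type",
    "taxon_a": "Organism Interactor A",
    "taxon_b": "Organism Interactor B",
}


@dataclass
class PPINetwork:
    """Undirected PPI graph with TF annotations.

    Edges are unordered, self-loop free, and carry an optional frozenset of
    provenance tags (e.g. ``{"physical", "multi-validated"}``) under the
    ``tags`` edge attribute.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    tf_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {canonical_pair(u, v) for u, v in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, symbol: str) -> int:
        self._require(symbol)
        return self.graph.degree[symbol]

    def neighbors(self, symbol: str) -> set[str]:
        self._require(symbol)
        return set(self.graph[symbol])

    def is_tf(self, symbol: str) -> bool:
        return self.tf_flags.get(symbol, False)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(normalize_symbol(a), normalize_symbol(b))

    def _require(self, symbol: str) -> None:
        if symbol not in self.graph:
            raise SymbolNotFoundError(symbol)

    def copy(self) -> "PPINetwork":
        return PPINetwork(self.graph.copy(), dict(self.tf_flags))


@dataclass(frozen=True)
class PairFeatures:
    """The three network-derived facts about a candidate TF pair."""

    tf_a: str
    tf_b: str
    direct_edge: bool
    n12: int
    bin: int

    def __post_init__(self):
        if self.tf_a >= self.tf_b:
            raise ValueError("pair must be in canonical order (tf_a < tf_b)")
        if self.n12 < 0:
            raise ValueError("n12 must be non-negative")
        if self.bin != min(self.n12, TAIL_BIN):
            raise ValueError("bin must equal min(n12, 10)")


def bin_index(n12: int) -> int:
    """Map a shared-interactor count onto the eleven-bin scale.

    Bins are N12 = 0, 1, ..., 9 and a final bin collapsing the distribution
    tail N12 >= 10.
    """
    if n12 < 0:
        raise ValueError(f"n12 must be non-negative, got {n12}")
    return min(int(n12), TAIL_BIN)


def _add_edge(g: nx.Graph, a: str, b: str, tags: frozenset[str]) -> None:
    if g.has_edge(a, b):
        g.edges[a, b]["tags"] = g.edges[a, b].get("tags", frozenset()) | tags
    else:
        g.add_edge(a, b, tags=tags)


def read_edge_list(
    path: str | Path,
    dialect: str = "simple_tsv",
    taxon_filter: int | None = None,
    require_tag: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> PPINetwork:
    """Read a PPI edge list into a :class:`PPINetwork`.

    Parameters
    ----------
    path
        TSV file to read.
    dialect
        ``"biogrid_tab"``: tab-separated with a header; rows are kept only if
        the experimental system type is ``physical`` (and, when
        ``taxon_filter`` is given, both organism taxon ids match it).
        ``"simple_tsv"``: headerless, two columns per edge, optional third
        column of comma-separated provenance tags.
    taxon_filter
        Organism taxon id (e.g. 9606 for human); biogrid_tab dialect only.
    require_tag
        Keep only edges carrying this provenance tag (e.g.
        ``"multi-validated"``). Readers accept pre-filtered files, so this is
        optional and applies only where a tag column is present.
    columns
        Overrides for the biogrid_tab column names (keys as in
        :data:`BIOGRID_COLUMNS`).

    Duplicate rows collapse to a single edge; self-interactions are dropped
    (counts of both are logged).
    """
    path = Path(path)
    if dialect == "biogrid_tab":
        rows = _read_biogrid_rows(path, taxon_filter, columns)
    elif dialect == "simple_tsv":
        rows = _read_simple_rows(path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    g = nx.Graph()
    n_self, n_dup = 0, 0
    for a, b, tags in rows:
        if require_tag is not None and require_tag not in tags:
            continue
        if a == b:
            n_self += 1
            continue
        a, b = canonical_pair(a, b)
        if g.has_edge(a, b):
            n_dup += 1
        _add_edge(g, a, b, tags)
    if n_self or n_dup:
        logger.info(
            "read_edge_list(%s): dropped %d self-interactions, collapsed %d duplicate rows",
            path.name, n_self, n_dup,
        )
    if g.number_of_edges() == 0:
        raise EmptyResultError(f"empty network after filtering: {path}")
    return PPINetwork(graph=g)


def _read_biogrid_rows(path, taxon_filter, columns):
    cols = dict(BIOGRID_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    for key in ("symbol_a", "symbol_b", "system_type"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column {cols[key]!r} in {path}")
    mask = df[cols["system_type"]].str.strip().str.lower() == "physical"
    if taxon_filter is not None:
        for key in ("taxon_a", "taxon_b"):
            if cols[key] not in df.columns:
                raise FormatError(f"missing required column {cols[key]!r} in {path}")
            mask &= pd.to_numeric(df[cols[key]], errors="coerce") == taxon_filter
    kept = df.loc[mask]
    for _, row in kept.iterrows():
        yield (
            normalize_symbol(row[cols["symbol_a"]]),
            normalize_symbol(row[cols["symbol_b"]]),
            frozenset({"physical"}),
        )


def _read_simple_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least two tab-separated columns"
                )
            tags = frozenset()
            if len(parts) >= 3 and parts[2].strip():
                tags = frozenset(t.strip() for t in parts[2].split(",") if t.strip())
            yield normalize_symbol(parts[0]), normalize_symbol(parts[1]), tags


def read_tf_list(path: str | Path) -> set[str]:
    """Read a TF symbol list: one symbol per line, ``#`` comments allowed."""
    tfs: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tfs.add(normalize_symbol(line))
    return tfs


def filter_network(
    net: PPINetwork, tf_list: Iterable[str], min_degree: int = 3
) -> tuple[PPINetwork, frozenset[str]]:
    """Flag TFs and determine which are eligible for classification.

    A TF is eligible when its degree in the FULL network (all nodes, not the
    TF-restricted subgraph) is at least ``min_degree``. Ineligible TFs and
    non-TF proteins stay in the network — they still serve as shared partners
    when counting N12 — but no candidate pair involving them is classified.

    Returns the network (with ``tf_flags`` set) and the eligible-TF set.
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    tfs = {normalize_symbol(t) for t in tf_list}
    out = net.copy()
    out.tf_flags = {t: True for t in tfs if t in out.graph}
    if not out.tf_flags:
        logger.warning("filter_network: no TF from the list is present in the network")
        return out, frozenset()
    eligible = frozenset(
        t for t in out.tf_flags if out.graph.degree[t] >= min_degree
    )
    return out, eligible


def shared_interactors(net: PPINetwork, a: str, b: str) -> int:
    """Number of common neighbours of ``a`` and ``b`` (the N12 feature).

    Counts both TF and non-TF shared partners; excludes ``a`` and ``b``
    themselves, so a direct edge between the two does not contribute.
    """
    a, b = normalize_symbol(a), normalize_symbol(b)
    if a == b:
        raise ValueError("shared_interactors requires two distinct symbols")
    net._require(a)
    net._require(b)
    common = set(net.graph[a]) & set(net.graph[b])
    common.discard(a)
    common.discard(b)
    return len(common)


def pair_features(net: PPINetwork, a: str, b: str) -> PairFeatures:
    """Assemble the (direct_edge, N12, bin) feature triple for one pair."""
    a, b = canonical_pair(a, b)
    n12 = shared_interactors(net, a, b)
    return PairFeatures(
        tf_a=a,
        tf_b=b,
        direct_edge=net.graph.has_edge(a, b),
        n12=n12,
        bin=bin_index(n12),
    )


def degree_distribution(
    net: PPINetwork, restrict_to_tf_edges: bool = False
) -> dict[int, int]:
    """Histogram of node degrees (degree -> node count).

    With ``restrict_to_tf_edges`` only edges whose both endpoints are flagged
    TFs are counted, and only TF nodes appear in the histogram; isolated TFs
    (degree 0 among TF-TF edges) are included.
    """
    if net.n_nodes() == 0:
        raise EmptyResultError("degree_distribution of an empty network")
    if restrict_to_tf_edges:
        tf_nodes = [n for n in net.graph if net.is_tf(n)]
        sub = net.graph.subgraph(tf_nodes)
        degrees = [sub.degree[n] for n in tf_nodes]
    else:
        degrees = [d for _, d in net.graph.degree()]
    return dict(Counter(degrees))
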