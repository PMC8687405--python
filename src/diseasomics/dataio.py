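"""Readers/writers for expression matrices, GMT gene-set libraries and
interaction networks.

All gene identifiers are treated as HGNC-style symbols and uppercased on
input; matching across files is exact string match after uppercasing.
Regulator, drug and condition node labels keep their original case (miRNA
names such as ``mir-335-5p`` are conventionally lowercase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("raw", "log2", "zscore")
GROUP_LABELS = ("case", "control")
NETWORK_KINDS = (
    "ppi_undirected",
    "regulator_bipartite",
    "drug_bipartite",
    "diseasome_bipartite",
)
# bipartite kinds: (source node class, target node class)
BIPARTITE_CLASSES = {
    "regulator_bipartite": ("regulator", "gene"),
    "drug_bipartite": ("drug", "gene"),
    "diseasome_bipartite": ("condition", "gene"),
}


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with case/control labels.

    Parameters
    ----------
    condition_id
        Label for the condition (disease or risk factor) the cohort measures.
    data
        DataFrame with one row per gene (or probe, before collapsing) and one
        column per sample.  Row index entries are uppercased symbols, or
        ``SYMBOL@k`` probe keys when the same symbol occurs on several rows.
    groups
        Map sample id -> ``"case"`` or ``"control"``.
    scale
        One of ``raw`` (intensities), ``log2`` or ``zscore``.
    probe_to_gene
        Optional map probe key -> symbol, present when duplicate symbols were
        kept as distinct probe rows and the matrix still needs collapsing.
    """

    condition_id: str
    data: pd.DataFrame
    groups: dict[str, str]
    scale: str = "raw"
    probe_to_gene: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in SCALES:
            raise DataError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise DataError(f"duplicate sample ids: {dupes}")
        idx = list(self.data.index)
        if len(set(idx)) != len(idx):
            dupes = sorted({g for g in idx if idx.count(g) > 1})
            raise DataError(f"duplicate gene/probe keys: {dupes}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise DataError(f"samples missing from group map: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in GROUP_LABELS}
        if bad:
            raise DataError(f"group labels must be case/control, got {bad}")
        if not np.issubdtype(self.data.to_numpy().dtype, np.number):
            raise DataError("expression values must be numeric")
        if self.data.isna().to_numpy().any():
            r, c = np.argwhere(self.data.isna().to_numpy())[0]
            raise DataError(
                f"missing value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}; NA cells are not permitted"
            )

    # -- convenience accessors ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def needs_collapse(self) -> bool:
        return self.probe_to_gene is not None

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == label]

    def case_values(self) -> pd.DataFrame:
        return self.data[self.samples_in_group("case")]

    def control_values(self) -> pd.DataFrame:
        return self.data[self.samples_in_group("control")]

    def replace_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        """Return a copy with new values (same samples) and a new scale flag."""
        return ExpressionMatrix(
            condition_id=self.condition_id,
            data=values,
            groups=dict(self.groups),
            scale=scale,
            probe_to_gene=None if self.probe_to_gene is None else dict(self.probe_to_gene),
            meta=dict(self.meta),
        )


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> case|control TSV (optional header)."""
    groups: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise DataError(f"{path}: line {i + 1}: expected 2 columns, got {len(fields)}")
        sample, label = fields[0].strip(), fields[1].strip().lower()
        if label not in GROUP_LABELS:
            if i == 0:  # tolerate a header row
                continue
            raise DataError(f"{path}: line {i + 1}: group must be case/control, got {label!r}")
        if sample in groups:
            raise DataError(f"{path}: duplicate sample {sample!r}")
        groups[sample] = label
    if not groups:
        raise DataError(f"{path}: empty group map")
    return groups


def read_expression(
    path: str | Path,
    groups_path: str | Path,
    condition_id: str | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = gene id).

    Symbols are uppercased.  Rows sharing a symbol are retained under distinct
    probe keys ``SYMBOL@1``, ``SYMBOL@2`` ... and the matrix is flagged for
    probe collapsing.  Every sample must appear in the group map; NA or
    non-numeric cells are rejected.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise DataError(f"{path}: empty file")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    if not cols:
        raise DataError(f"{path}: no sample columns in header")
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise DataError(f"{path}: duplicate sample ids in header: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = cols  # undo pandas' dedup mangling guard; verified unique above
    if df.empty:
        raise DataError(f"{path}: no data rows")

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise DataError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at row {gene!r}, column {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().argmax()]
            raise DataError(f"{path}: missing value at row {gene!r}, column {col!r}")
        numeric[col] = converted

    numeric.index = [str(g).strip().upper() for g in numeric.index]

    groups = read_groups(groups_path)
    missing = [s for s in cols if s not in groups]
    if missing:
        raise DataError(f"{path}: samples missing from group map: {missing}")
    groups = {s: groups[s] for s in cols}

    probe_to_gene = None
    if numeric.index.duplicated().any():
        counts: dict[str, int] = {}
        keys: list[str] = []
        dup_symbols = set(numeric.index[numeric.index.duplicated(keep=False)])
        probe_to_gene = {}
        for sym in numeric.index:
            if sym in dup_symbols:
                counts[sym] = counts.get(sym, 0) + 1
                key = f"{sym}@{counts[sym]}"
            else:
                key = sym
            keys.append(key)
            probe_to_gene[key] = sym
        numeric.index = keys
        logger.info(
            "%s: %d symbols occur on multiple rows; kept as probe keys, collapse required",
            path,
            len(dup_symbols),
        )

    return ExpressionMatrix(
        condition_id=condition_id if condition_id is not None else path.stem,
        data=numeric,
        groups=groups,
        scale="raw",
        probe_to_gene=probe_to_gene,
    )


def write_expression(M: ExpressionMatrix, path: str | Path, groups_path: str | Path | None = None) -> None:
    """Write the matrix as TSV (and optionally its group map)."""
    df = M.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            for s in M.sample_ids:
                fh.write(f"{s}\t{M.groups[s]}\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe -> symbol TSV."""
    pm: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2 or not fields[1].strip():
            raise DataError(f"{path}: line {i + 1}: expected 'probe<TAB>symbol'")
        pm[fields[0].strip()] = fields[1].strip().upper()
    return pm


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a one-symbol-per-line gene list (e.g. a disease gene list)."""
    genes = {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(genes)


# ---------------------------------------------------------------------------
# GeneSetLibrary (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetLibrary:
    """Named gene sets with a background universe (GMT semantics)."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]]  # term_id -> (description, genes)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise DataError(f"gene set {term!r} is empty")
            if self.universe and not genes <= self.universe:
                raise DataError(f"gene set {term!r} not a subset of the universe")

    @property
    def terms(self) -> list[str]:
        return list(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def description(self, term: str) -> str:
        return self.sets[term][0]


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...`` per line.

    The universe defaults to the union of all sets; genes are uppercased.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}: line {i + 1}: GMT needs >=3 tab-separated fields")
        term, desc = fields[0], fields[1]
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            raise DataError(f"{path}: line {i + 1}: term {term!r} has no genes")
        if term in sets:
            raise DataError(f"{path}: duplicate term {term!r}")
        sets[term] = (desc, genes)
    if not sets:
        raise DataError(f"{path}: no gene sets")
    universe = frozenset().union(*(g for _, g in sets.values()))
    return GeneSetLibrary(name=name or path.stem, sets=sets, universe=universe)


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in lib.sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# InteractionNetwork
# ---------------------------------------------------------------------------


@dataclass
class InteractionNetwork:
    """A graph wrapper: undirected weighted PPI or a bipartite lookup table.

    Bipartite kinds store edges in an undirected ``networkx`` graph with a
    ``node_class`` attribute on every node; edges may only join distinct
    classes.  PPI weights live in ``[0, 1]`` (STRING combined-score scale).
    """

    kind: str
    graph: nx.Graph
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise DataError(f"unknown network kind {self.kind!r}")
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise DataError(f"self-loops not allowed: {loops[:3]}")
        if self.kind in BIPARTITE_CLASSES:
            classes = set(BIPARTITE_CLASSES[self.kind])
            for n, d in g.nodes(data=True):
                if d.get("node_class") not in classes:
                    raise DataError(f"node {n!r} lacks a valid node_class for {self.kind}")
            for a, b in g.edges():
                if g.nodes[a]["node_class"] == g.nodes[b]["node_class"]:
                    raise DataError(f"edge {a!r}-{b!r} joins two {g.nodes[a]['node_class']} nodes")
        if self.kind == "ppi_undirected":
            for a, b, w in g.edges(data="weight", default=1.0):
                if not (0.0 <= w <= 1.0):
                    raise DataError(f"PPI weight {w} outside [0,1] on edge {a!r}-{b!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> frozenset[tuple[str, str]]:
        """Canonical (sorted-pair) edge set, order-insensitive."""
        return frozenset(tuple(sorted((str(a), str(b)))) for a, b in self.graph.edges())

    def nodes_of_class(self, node_class: str) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data=True) if d.get("node_class") == node_class
        )


def build_network(
    kind: str,
    edges: list[tuple[str, str, float]],
    extra_nodes: dict[str, str] | None = None,
) -> InteractionNetwork:
    """Assemble an InteractionNetwork from (a, b, weight) triples.

    For bipartite kinds the first endpoint is the source class (regulator,
    drug, condition) and the second the gene.  ``extra_nodes`` adds isolated
    nodes as a node -> node_class map.
    """
    g = nx.Graph()
    if kind in BIPARTITE_CLASSES:
        src_class, tgt_class = BIPARTITE_CLASSES[kind]
        for a, b, w in edges:
            b = b.upper() if tgt_class == "gene" else b
            g.add_node(a, node_class=src_class)
            g.add_node(b, node_class=tgt_class)
            g.add_edge(a, b, weight=float(w))
    else:
        for a, b, w in edges:
            g.add_edge(a.upper(), b.upper(), weight=float(w))
    if extra_nodes:
        for n, cls in extra_nodes.items():
            if n not in g:
                g.add_node(n, node_class=cls)
    return InteractionNetwork(kind=kind, graph=g)


def read_edge_list(
    path: str | Path,
    kind: str = "ppi_undirected",
    weight_threshold: float | None = None,
) -> InteractionNetwork:
    """Read a TSV edge list: columns a, b and optional weight.

    Self-loops are dropped (count logged and stored in ``meta``); duplicate
    undirected edges are deduplicated.  Weights above 1 are auto-detected as
    STRING combined scores on the 0-1000 scale and divided by 1000 for the
    PPI kind.  Edges with weight below ``weight_threshold`` are discarded.
    """
    path = Path(path)
    if weight_threshold is not None and not (0.0 <= weight_threshold <= 1.0):
        raise DataError(f"weight_threshold must be in [0,1], got {weight_threshold}")
    raw: list[tuple[str, str, float]] = []
    for i, line in enumerate(path.read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise DataError(f"{path}: line {i + 1}: expected at least 2 columns")
        a, b = fields[0].strip(), fields[1].strip()
        if len(fields) >= 3 and fields[2].strip():
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise DataError(f"{path}: line {i + 1}: bad weight {fields[2]!r}") from exc
        else:
            w = 1.0
        raw.append((a, b, w))
    if not raw:
        raise DataError(f"{path}: no edges")

    weights = [w for _, _, w in raw]
    if kind == "ppi_undirected" and max(weights) > 1.0:
        logger.info("%s: weights exceed 1; interpreting as combined score / 1000", path)
        raw = [(a, b, w / 1000.0) for a, b, w in raw]
    if kind == "ppi_undirected":
        bad = [w for _, _, w in raw if not (0.0 <= w <= 1.0)]
        if bad:
            raise DataError(f"{path}: PPI weights outside [0,1]: {bad[:3]}")

    n_loops = sum(1 for a, b, _ in raw if a == b)
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    edges = [(a, b, w) for a, b, w in raw if a != b]
    if weight_threshold is not None:
        edges = [(a, b, w) for a, b, w in edges if w >= weight_threshold]
    net = build_network(kind, edges)
    net.meta["self_loops_dropped"] = n_loops
    net.meta["source"] = str(path)
    return net


def write_network(net: InteractionNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write a network as ``tsv`` (a, b, weight), ``sif`` or ``graphml``.

    For bipartite kinds the source-class node is written first so that
    ``read_edge_list`` round-trips the node classes.  Edge order is sorted
    for deterministic output.
    """
    path = Path(path)
    g = net.graph
    if net.kind in BIPARTITE_CLASSES:
        src_class, _ = BIPARTITE_CLASSES[net.kind]

        def orient(a: str, b: str) -> tuple[str, str]:
            return (a, b) if g.nodes[a]["node_class"] == src_class else (b, a)

    else:

        def orient(a: str, b: str) -> tuple[str, str]:
            return tuple(sorted((a, b)))  # type: ignore[return-value]

    rows = sorted(
        (*orient(a, b), d.get("weight", 1.0)) for a, b, d in g.edges(data=True)
    )
    if format == "tsv":
        with open(path, "w") as fh:
            for a, b, w in rows:
                fh.write(f"{a}\t{b}\t{w:g}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b, _ in rows:
                fh.write(f"{a}\tinteracts\t{b}\n")
            for n in sorted(nx.isolates(g)):
                fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise DataError(f"unknown network format {format!r}; expected tsv, sif or graphml")
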