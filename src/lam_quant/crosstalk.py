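"""Cluster-to-cluster ligand-receptor crosstalk graphs.

A gene is "expressed" in a cluster when at least a threshold fraction
(default 30%) of the cluster's cells have a nonzero UMI count for it.  For
every ordered cluster pair (A, B) — self-loops included — the directed edge
A -> B is weighted by the number of ligand-receptor pairs whose ligand is
expressed in A and whose receptor is expressed in B.  Detection fraction is
the only criterion; expression magnitude is never used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.30


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Cluster-labelled UMI count matrix (cells x genes, dense)."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_of: pd.Series  # index: cell_id, value: cluster label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if (self.counts < 0).any():
            raise ValueError("UMI counts must be non-negative")
        self.gene_ids = [g.upper() for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene symbols must be unique after uppercasing")
        self.cluster_of = pd.Series(self.cluster_of)
        missing = [c for c in self.cell_ids if c not in self.cluster_of.index]
        if missing:
            raise ValueError(f"cells without cluster assignment: {missing[:5]}")

    @property
    def clusters(self) -> list:
        return sorted(pd.unique(self.cluster_of.loc[self.cell_ids]))


@dataclass
class LRPairTable:
    """Ordered (ligand, receptor) gene-symbol pairs, deduplicated."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        normalized = []
        for lig, rec in self.pairs:
            key = (str(lig).upper(), str(rec).upper())
            if key not in seen:
                seen.add(key)
                normalized.append(key)
        self.pairs = normalized

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LRPairTable":
        """Read a two-column (ligand, receptor) TSV, with or without header."""
        frame = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c.lower() for c in frame.columns]
        if "ligand" in cols and "receptor" in cols:
            lig = frame.iloc[:, cols.index("ligand")]
            rec = frame.iloc[:, cols.index("receptor")]
        else:
            # headerless file: the read header row is actually data
            frame = pd.read_csv(path, sep="\t", dtype=str, header=None)
            lig, rec = frame.iloc[:, 0], frame.iloc[:, 1]
        return cls(list(zip(lig, rec)))

    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DetectionProfile:
    """Per-(cluster, gene) fraction of cells with UMI > 0."""

    fraction: pd.DataFrame  # rows: clusters, columns: genes

    def __post_init__(self) -> None:
        vals = self.fraction.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("detection fractions must lie in [0, 1]")


@dataclass
class CrosstalkGraph:
    """Directed cluster graph; edge weight = number of contributing LR pairs."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        for _, _, data in self.graph.edges(data=True):
            if data["weight"] != len(data["pairs"]):
                raise ValueError("edge weight must equal the number of pairs")
            if data["weight"] < 1:
                raise ValueError("zero-weight edges must be absent")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def weight(self, source, target) -> int:
        if self.graph.has_edge(source, target):
            return int(self.graph[source][target]["weight"])
        return 0

    def edge_pairs(self, source, target) -> list[tuple[str, str]]:
        if self.graph.has_edge(source, target):
            return list(self.graph[source][target]["pairs"])
        return []

    def edges(self) -> list[tuple]:
        return [
            (u, v, int(d["weight"])) for u, v, d in self.graph.edges(data=True)
        ]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_id_file(path: str | Path) -> list[str]:
    """First column of a headerless TSV (10x-style genes/barcodes file)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return frame.iloc[:, 0].tolist()


def load_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    clusters_path: str | Path = "",
) -> ExpressionMatrix:
    """Load a cluster-labelled UMI matrix.

    Two layouts are supported:

    * MatrixMarket ``.mtx`` (genes x cells) with headerless row/column TSVs
      (``genes_path``, ``cells_path``), as written by 10x Cell Ranger;
    * dense CSV (genes x cells) with gene ids in the first column and cell
      ids in the header, in which case ``genes_path``/``cells_path`` are
      omitted.

    ``clusters_path`` is a CSV whose first two columns are (cell_id, cluster).
    Cells absent from the cluster table are dropped with a logged count.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires genes_path and cells_path")
        mat = mmread(matrix_path)
        genes = _read_id_file(genes_path)
        cells = _read_id_file(cells_path)
        if mat.shape != (len(genes), len(cells)):
            raise OSError(
                f"matrix is {mat.shape[0]} x {mat.shape[1]} but id files list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
        counts = np.asarray(mat.todense()).T  # -> cells x genes
    else:
        frame = pd.read_csv(matrix_path, index_col=0)
        genes = [str(g) for g in frame.index]
        cells = [str(c) for c in frame.columns]
        counts = frame.to_numpy().T
    cluster_frame = pd.read_csv(clusters_path, dtype={0: str})
    cluster_of = pd.Series(
        cluster_frame.iloc[:, 1].values,
        index=cluster_frame.iloc[:, 0].astype(str).values,
    )
    keep = [i for i, c in enumerate(cells) if c in cluster_of.index]
    dropped = len(cells) - len(keep)
    if dropped:
        logger.warning("dropping %d cells without a cluster assignment", dropped)
    if not keep:
        raise ValueError("no cells with cluster assignments remain")
    cells = [cells[i] for i in keep]
    counts = counts[keep]
    return ExpressionMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells,
        cluster_of=cluster_of.loc[cells],
    )


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def detection_fraction(expr: ExpressionMatrix) -> DetectionProfile:
    """Fraction of each cluster's cells with UMI > 0, per gene."""
    labels = expr.cluster_of.loc[expr.cell_ids].to_numpy()
    detected = pd.DataFrame(
        expr.counts > 0, index=expr.cell_ids, columns=expr.gene_ids
    )
    frac = detected.groupby(labels, sort=True).mean()
    if (frac.index.value_counts() == 0).any():  # pragma: no cover - defensive
        raise ValueError("empty cluster encountered")
    return DetectionProfile(fraction=frac)


def expressed_sets(
    profile: DetectionProfile, threshold: float = DEFAULT_THRESHOLD
) -> dict:
    """Genes whose detection fraction is >= threshold, per cluster.

    The boundary is inclusive: a gene detected in exactly ``threshold`` of a
    cluster's cells counts as expressed.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    frac = profile.fraction
    return {
        cluster: set(frac.columns[(frac.loc[cluster] >= threshold).to_numpy()])
        for cluster in frac.index
    }


def build_graph(
    sets: dict,
    pairs: LRPairTable,
    include_self_loops: bool = True,
) -> CrosstalkGraph:
    """Directed crosstalk graph over clusters.

    Edge A -> B carries every (ligand, receptor) pair with the ligand
    expressed in A and the receptor in B; its weight is the pair count.
    Zero-weight edges are omitted; clusters with no edges remain as isolated
    nodes.
    """
    if not sets:
        raise ValueError("expressed sets must not be empty")
    graph = nx.DiGraph()
    graph.add_nodes_from(sets.keys())
    matrix_genes = set().union(*sets.values()) if sets else set()
    if pairs.pairs and not (pairs.genes() & matrix_genes):
        logger.warning("no pair-table gene is expressed in any cluster")
    edge_pairs: dict[tuple, list[tuple[str, str]]] = {}
    for lig, rec in pairs.pairs:
        sources = [c for c, genes in sets.items() if lig in genes]
        targets = [c for c, genes in sets.items() if rec in genes]
        for a in sources:
            for b in targets:
                if not include_self_loops and a == b:
                    continue
                edge_pairs.setdefault((a, b), []).append((lig, rec))
    for (a, b), plist in edge_pairs.items():
        graph.add_edge(a, b, weight=len(plist), pairs=plist)
    return CrosstalkGraph(graph=graph)


def hub_scores(graph: CrosstalkGraph) -> pd.DataFrame:
    """Weighted in/out/total degree per cluster, descending by total.

    Self-loops contribute to both in- and out-degree.  Betweenness centrality
    is included for reference only.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    betweenness = nx.betweenness_centrality(g)
    rows = []
    for node in g.nodes:
        out_w = sum(d["weight"] for _, _, d in g.out_edges(node, data=True))
        in_w = sum(d["weight"] for _, _, d in g.in_edges(node, data=True))
        rows.append(
            {
                "cluster": node,
                "out_weight": out_w,
                "in_weight": in_w,
                "total_weight": out_w + in_w,
                "betweenness": betweenness[node],
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["total_weight", "cluster"], ascending=[False, True], kind="mergesort"
    )
    return frame.reset_index(drop=True)


def diff_graph(g1: CrosstalkGraph, g2: CrosstalkGraph) -> pd.DataFrame:
    """Edge-wise weight comparison of two graphs (union of edges, missing=0)."""
    edges = {(u, v) for u, v, _ in g1.edges()} | {(u, v) for u, v, _ in g2.edges()}
    rows = [
        {
            "source": u,
            "target": v,
            "weight_a": g1.weight(u, v),
            "weight_b": g2.weight(u, v),
            "difference": g1.weight(u, v) - g2.weight(u, v),
        }
        for u, v in sorted(edges, key=lambda e: (str(e[0]), str(e[1])))
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "weight_a", "weight_b", "difference"]
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

_PAIR_SEP = ";"
_GENE_SEP = "|"


def export_graph(
    graph: CrosstalkGraph, path: str | Path, format: str = "edgelist_tsv"
) -> Path:
    """Write the graph as GraphML or an edge-list TSV.

    Both formats carry the weight and the contributing pair list (encoded as
    ``LIG|REC;LIG|REC;...``) and round-trip losslessly via :func:`read_graph`.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(str(n) for n in graph.nodes)
        for u, v, w in graph.edges():
            pairs = _PAIR_SEP.join(
                _GENE_SEP.join(p) for p in graph.edge_pairs(u, v)
            )
            g.add_edge(str(u), str(v), weight=w, pairs=pairs)
        nx.write_graphml(g, path)
    elif format == "edgelist_tsv":
        rows = []
        for u, v, w in graph.edges():
            pairs = _PAIR_SEP.join(
                _GENE_SEP.join(p) for p in graph.edge_pairs(u, v)
            )
            rows.append({"source": u, "target": v, "weight": w, "pairs": pairs})
        frame = pd.DataFrame(rows, columns=["source", "target", "weight", "pairs"])
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_graph(path: str | Path, format: str = "edgelist_tsv") -> CrosstalkGraph:
    """Inverse of :func:`export_graph` (node labels come back as strings)."""
    path = Path(path)
    g = nx.DiGraph()
    if format == "graphml":
        raw = nx.read_graphml(path)
        g.add_nodes_from(raw.nodes)
        for u, v, data in raw.edges(data=True):
            pairs = _decode_pairs(data.get("pairs", ""))
            g.add_edge(u, v, weight=int(data["weight"]), pairs=pairs)
    elif format == "edgelist_tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        for _, row in frame.iterrows():
            pairs = _decode_pairs(row["pairs"] if pd.notna(row["pairs"]) else "")
            g.add_edge(row["source"], row["target"], weight=int(row["weight"]),
                       pairs=pairs)
    else:
        raise ValueError(f"unknown format {format!r}")
    return CrosstalkGraph(graph=g)


def _decode_pairs(encoded: str) -> list[tuple[str, str]]:
    if not encoded:
        return []
    return [tuple(tok.split(_GENE_SEP)) for tok in encoded.split(_PAIR_SEP)]


# ---------------------------------------------------------------------------
# synthetic expression
# ---------------------------------------------------------------------------


def generate_synthetic_expression(
    n_clusters: int,
    cells_per_cluster: int,
    genes: int | list[str],
    planted: list[tuple] = (),
    rng_seed: int = 0,
    background_rate: float = 0.05,
    mean_extra_count: float = 1.0,
) -> ExpressionMatrix:
    """Clustered UMI counts with controlled per-cluster detection rates.

    Each (cluster, gene) cell is detected with a Bernoulli draw at the
    planted rate (default ``background_rate``); detected cells get a count of
    1 plus a Poisson draw, so planted rate 1.0 yields detection fraction
    exactly 1.0.  ``planted`` entries are (cluster_label, gene, rate).
    """
    if n_clusters < 1 or cells_per_cluster < 1:
        raise ValueError("n_clusters and cells_per_cluster must be >= 1")
    if isinstance(genes, int):
        gene_ids = [f"G{i:04d}" for i in range(genes)]
    else:
        gene_ids = [str(g).upper() for g in genes]
    cluster_labels = [f"C{i}" for i in range(n_clusters)]
    rate = np.full((n_clusters, len(gene_ids)), float(background_rate))
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    cluster_index = {c: i for i, c in enumerate(cluster_labels)}
    for cluster, gene, r in planted:
        if not 0 <= r <= 1:
            raise ValueError(f"planted detection rate {r} outside [0, 1]")
        rate[cluster_index[str(cluster)], gene_index[str(gene).upper()]] = r
    rng = np.random.default_rng(rng_seed)
    n_cells = n_clusters * cells_per_cluster
    cell_rates = np.repeat(rate, cells_per_cluster, axis=0)
    detected = rng.random((n_cells, len(gene_ids))) < cell_rates
    counts = detected * (1 + rng.poisson(mean_extra_count, size=detected.shape))
    cell_ids = [
        f"{cluster_labels[i // cells_per_cluster]}_cell{i % cells_per_cluster:05d}"
        for i in range(n_cells)
    ]
    cluster_of = pd.Series(
        [cluster_labels[i // cells_per_cluster] for i in range(n_cells)],
        index=cell_ids,
    )
    return ExpressionMatrix(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cluster_of=cluster_of,
    )
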