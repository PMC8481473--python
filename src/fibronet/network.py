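"""Interactome interconnectivity statistics for gene sets.

The interactome is an undirected simple graph of physical protein-protein
interactions for one species, cleaned of genetic interactions, self-loops,
duplicate edges and cross-species pairs.  The central statistic is
*interconnectivity*: the percentage of a gene set's in-graph members that
lie in the largest connected component (LCC) of the subgraph induced by the
set alone — neighbours outside the set do not bridge components.  Its
significance is assessed against a resampling null built from random node
sets of equal size, summarised as a Z-score.  The module also computes the
subset-size vs interconnectivity curve and a GSEA-style running-sum
enrichment score for degree connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "InterconnectivityResult",
    "NullDistribution",
    "SizeCurve",
    "DegreeEnrichmentResult",
    "clean_interactome",
    "read_biogrid_tab",
    "read_edge_list",
    "interconnectivity",
    "null_distribution",
    "size_curve",
    "degree_enrichment",
    "mean_degree",
    "z_score",
]


class Interactome:
    """Cleaned undirected simple PPI graph with a fast sparse backend.

    Wraps a :class:`networkx.Graph`; node order for the sparse adjacency is
    the sorted node list, so results are independent of insertion order.
    """

    def __init__(self, graph: nx.Graph, provenance: str = ""):
        if any(u == v for u, v in graph.edges):
            raise ValueError("interactome must not contain self-loops")
        self.graph = graph
        self.provenance = provenance
        self._nodes = sorted(graph.nodes)
        self._index = {n: i for i, n in enumerate(self._nodes)}
        rows, cols = [], []
        for u, v in graph.edges:
            iu, iv = self._index[u], self._index[v]
            rows += [iu, iv]
            cols += [iv, iu]
        n = len(self._nodes)
        data = np.ones(len(rows), dtype=np.int8)
        self._adj = csr_matrix((data, (rows, cols)), shape=(n, n))

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def indices_of(self, genes) -> tuple[np.ndarray, list[str]]:
        """Matrix row indices of the genes present in the graph, plus the
        dropped (absent) ids."""
        present, dropped = [], []
        for g in dict.fromkeys(genes):
            if g in self._index:
                present.append(self._index[g])
            else:
                dropped.append(g)
        return np.asarray(sorted(present), dtype=np.intp), dropped

    def lcc_fraction_of_indices(self, idx: np.ndarray) -> tuple[int, float]:
        """Size of, and percent of ``idx`` in, the largest connected
        component of the induced subgraph."""
        if len(idx) == 0:
            raise ValueError("empty index set")
        sub = self._adj[idx][:, idx]
        _, labels = connected_components(sub, directed=False)
        lcc = int(np.bincount(labels).max())
        return lcc, 100.0 * lcc / len(idx)


@dataclass(frozen=True)
class InterconnectivityResult:
    n_set_in_graph: int
    lcc_size: int
    fraction: float  # percent, full precision; round only for display
    dropped: tuple[str, ...]


@dataclass
class NullDistribution:
    """Resampling null for interconnectivity at a fixed sample size."""

    sample_size: int
    fractions: np.ndarray  # percent per random sample
    seed: int
    ddof: int = 0  # population SD by default

    @property
    def n_samples(self) -> int:
        return len(self.fractions)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def sd(self) -> float:
        return float(np.std(self.fractions, ddof=self.ddof))

    def z_of(self, observed: float) -> float:
        return z_score(observed, self.mean, self.sd)


@dataclass(frozen=True)
class SizeCurve:
    points: pd.DataFrame  # columns: subset_size, mean_fraction, n_reps
    seed: int


@dataclass(frozen=True)
class DegreeEnrichmentResult:
    es: float
    set_mean_degree: float
    background_mean_degree: float
    weight_exponent: float
    running_sum: np.ndarray = field(repr=False, default=None)


def z_score(observed: float, mean: float, sd: float) -> float:
    if sd <= 0:
        raise ValueError("null SD must be positive to form a Z-score")
    return (observed - mean) / sd


# ---------------------------------------------------------------------------
# construction / cleaning


def read_biogrid_tab(path) -> pd.DataFrame:
    """Read a BioGRID TAB-style TSV into the raw edge-row frame expected by
    :func:`clean_interactome`.

    Recognised columns (case-insensitive, spaces/underscores equivalent):
    official symbol interactor A/B, experimental system type, organism
    interactor A/B.  Malformed rows (missing symbols) are skipped with a
    logged line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    canon = {c.lower().replace(" ", "_"): c for c in df.columns}

    def col(*names):
        for name in names:
            if name in canon:
                return canon[name]
        raise ValueError(f"missing column (any of {names}) in {sorted(canon)}")

    out = pd.DataFrame(
        {
            "symbol_a": df[col("official_symbol_interactor_a", "symbol_a", "interactor_a")],
            "symbol_b": df[col("official_symbol_interactor_b", "symbol_b", "interactor_b")],
            "interaction_type": df[
                col("experimental_system_type", "interaction_type", "type")
            ].str.lower(),
        }
    )
    for side in ("a", "b"):
        try:
            out[f"organism_{side}"] = df[
                col(f"organism_interactor_{side}", f"organism_{side}")
            ].astype(str)
        except ValueError:
            out[f"organism_{side}"] = ""
    bad = out["symbol_a"].isna() | out["symbol_b"].isna()
    for line in out.index[bad]:
        logger.warning("skipping malformed interaction row at line %d", line + 2)
    return out[~bad]


def clean_interactome(
    rows: pd.DataFrame, organism: str | None = None, provenance: str = ""
) -> Interactome:
    """Build a cleaned interactome from raw edge rows.

    Keeps only physical interactions; if ``organism`` is given, both
    interactors must belong to it.  Self-loops and duplicate edges
    (``(a, b)`` equivalent to ``(b, a)``) are removed.
    """
    if rows.empty:
        raise ValueError("no interaction rows supplied")
    keep = rows["interaction_type"].str.lower() == "physical"
    if organism is not None and "organism_a" in rows.columns:
        keep &= (rows["organism_a"].astype(str) == str(organism)) & (
            rows["organism_b"].astype(str) == str(organism)
        )
    edges = {
        frozenset((a, b))
        for a, b in zip(rows.loc[keep, "symbol_a"], rows.loc[keep, "symbol_b"])
        if a != b
    }
    if not edges:
        raise ValueError("zero edges remain after cleaning")
    g = nx.Graph()
    # sorted insertion keeps node/edge iteration order hash-seed independent
    g.add_edges_from(sorted(tuple(sorted(e)) for e in edges))
    return Interactome(g, provenance=provenance)


def read_edge_list(path, provenance: str = "") -> Interactome:
    """Read a plain two-column (tab-separated) edge list; header optional
    (detected by a first line starting with '#' or named columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if str(df.iloc[0, 0]).lower() in ("symbol_a", "node_a", "gene_a", "source"):
        df = df.iloc[1:]
    rows = pd.DataFrame(
        {"symbol_a": df[0], "symbol_b": df[1], "interaction_type": "physical"}
    )
    return clean_interactome(rows, provenance=provenance)


# ---------------------------------------------------------------------------
# statistics


def interconnectivity(graph: Interactome, gene_set) -> InterconnectivityResult:
    """Fraction of in-graph set genes inside the LCC of the set-induced
    subgraph (breadth-first component search on the induced adjacency)."""
    idx, dropped = graph.indices_of(gene_set)
    if len(idx) == 0:
        raise ValueError("no gene-set members present in the interactome")
    if dropped:
        logger.info("dropped %d gene(s) absent from interactome", len(dropped))
    lcc, fraction = graph.lcc_fraction_of_indices(idx)
    return InterconnectivityResult(
        n_set_in_graph=len(idx), lcc_size=lcc, fraction=fraction, dropped=tuple(dropped)
    )


def null_distribution(
    graph: Interactome, sample_size: int, n_samples: int = 1000, seed: int | None = None
) -> NullDistribution:
    """Interconnectivity null from uniform node samples without replacement."""
    if sample_size > graph.n_nodes:
        raise ValueError(
            f"sample_size {sample_size} exceeds interactome size {graph.n_nodes}"
        )
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_samples, dtype=float)
    for i in range(n_samples):
        idx = rng.choice(graph.n_nodes, size=sample_size, replace=False)
        idx.sort()
        _, fractions[i] = graph.lcc_fraction_of_indices(idx)
    return NullDistribution(sample_size=sample_size, fractions=fractions, seed=seed)


def size_curve(
    graph: Interactome,
    sizes=None,
    reps: int = 100,
    seed: int | None = None,
) -> SizeCurve:
    """Mean interconnectivity of random node subsets across subset sizes.

    Default sizes run from 50 in steps of 50 up to the interactome size
    (historically displayed on a log10 x-axis)."""
    if sizes is None:
        sizes = range(50, graph.n_nodes + 1, 50)
    sizes = list(sizes)
    if not sizes:
        raise ValueError("empty size list")
    if max(sizes) > graph.n_nodes:
        raise ValueError("largest subset size exceeds interactome size")
    rng = np.random.default_rng(seed)
    records = []
    for size in sizes:
        fractions = np.empty(reps, dtype=float)
        for r in range(reps):
            idx = rng.choice(graph.n_nodes, size=size, replace=False)
            idx.sort()
            _, fractions[r] = graph.lcc_fraction_of_indices(idx)
        records.append(
            {"subset_size": size, "mean_fraction": float(fractions.mean()), "n_reps": reps}
        )
    return SizeCurve(points=pd.DataFrame(records), seed=seed)


def mean_degree(graph: Interactome, gene_set=None) -> float:
    """Arithmetic mean interactome degree over a node set (default: all)."""
    degrees = dict(graph.graph.degree)
    if gene_set is None:
        queried = list(degrees)
    else:
        queried = [g for g in dict.fromkeys(gene_set) if g in degrees]
    if not queried:
        raise ValueError("no queried genes present in the interactome")
    return float(np.mean([degrees[g] for g in queried]))


def degree_enrichment(
    graph: Interactome, gene_set, weight_exponent: float = 1.0
) -> DegreeEnrichmentResult:
    """GSEA-style running-sum enrichment of a gene set for degree
    connectivity.

    All interactome nodes are ranked by degree, descending, ties broken
    lexicographically by id.  Walking down the ranking, set members ("hits")
    increment the running sum by degree**weight_exponent normalised over the
    set; non-members decrement it by 1/(N - n).  The enrichment score is the
    signed deviation of largest magnitude.
    """
    degrees = dict(graph.graph.degree)
    members = {g for g in gene_set if g in degrees}
    if not members:
        raise ValueError("no gene-set members present in the interactome")
    n_tot = graph.n_nodes
    if len(members) == n_tot:
        raise ValueError("gene set covers the whole interactome; no misses to rank")

    ranking = sorted(degrees, key=lambda g: (-degrees[g], g))
    is_hit = np.fromiter((g in members for g in ranking), dtype=bool, count=n_tot)
    weights = np.array(
        [float(degrees[g]) ** weight_exponent if hit else 0.0 for g, hit in zip(ranking, is_hit)]
    )
    hit_total = weights.sum()
    if hit_total == 0:  # all set members degree 0 with exponent > 0
        weights[is_hit] = 1.0
        hit_total = weights.sum()
    steps = np.where(is_hit, weights / hit_total, -1.0 / (n_tot - len(members)))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return DegreeEnrichmentResult(
        es=es,
        set_mean_degree=float(np.mean([degrees[g] for g in members])),
        background_mean_degree=float(np.mean(list(degrees.values()))),
        weight_exponent=weight_exponent,
        running_sum=running,
    )
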