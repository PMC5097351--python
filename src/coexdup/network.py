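"""Co-expression network construction, Markov clustering, and pair graph metrics.

Edges are scored per gene pair as the Fisher z-transform of the Pearson
correlation of the two genes' tissue profiles, f = atanh(R), standardized over
all defined (non-zero-variance) unordered pairs so the edge-score distribution
has mean 0 and sd 1. A pair is an edge when its standardized score z exceeds a
cutoff (2.5 by default, strict).

The all-pairs pass streams over row blocks so the full n x n matrix never has
to be held in memory; results are independent of the block size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .expression import ExpressionAtlas

_CLAMP = 1.0 - 1e-12


@dataclass
class CoexpressionNetwork:
    """Thresholded co-expression network.

    ``edges`` holds one row per unordered pair with z > cutoff. ``gene_ids``
    is the full node set (genes may have degree 0). ``undefined_genes`` are
    zero-variance profiles excluded from scoring.
    """

    gene_ids: List[str]
    cutoff: float
    edges: pd.DataFrame  # columns gene1, gene2, z
    fisher_mean: float
    fisher_sd: float
    n_scored_pairs: int
    undefined_genes: List[str] = field(default_factory=list)
    _graph: Optional[nx.Graph] = field(default=None, repr=False, compare=False)

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.gene_ids)
            g.add_weighted_edges_from(
                self.edges[["gene1", "gene2", "z"]].itertuples(index=False, name=None),
                weight="z",
            )
            self._graph = g
        return self._graph

    def neighbors(self, gene: str) -> set:
        if gene not in self.graph:
            raise KeyError(f"gene {gene!r} not in network")
        return set(self.graph.neighbors(gene))

    def write_edges(self, path: str) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_edge_file(cls, path: str, gene_ids: Sequence[str], cutoff: float = 2.5) -> "CoexpressionNetwork":
        edges = pd.read_csv(path, sep="\t")
        return cls(
            gene_ids=list(gene_ids),
            cutoff=cutoff,
            edges=edges,
            fisher_mean=float("nan"),
            fisher_sd=float("nan"),
            n_scored_pairs=len(edges),
        )


def correlation_matrix(atlas: ExpressionAtlas) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlation of gene tissue profiles.

    Returns (R, defined) where ``defined`` flags genes with non-zero variance;
    rows/columns of undefined genes are set to NaN (diagonal stays 1).
    """
    x = np.asarray(atlas.values.values, dtype=np.float64)
    if x.shape[1] < 3:
        raise ValueError("correlation requires at least 3 tissue columns")
    xn, defined = _normalized_rows(x)
    r = xn @ xn.T
    np.clip(r, -1.0, 1.0, out=r)
    r[~defined, :] = np.nan
    r[:, ~defined] = np.nan
    np.fill_diagonal(r, 1.0)
    return r, defined


def _normalized_rows(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    defined = norms > 0
    safe = np.where(defined, norms, 1.0)
    return centered / safe[:, None], defined


def fisher_transform(r: np.ndarray) -> np.ndarray:
    """f = atanh(R) with |R| clamped to 1 - 1e-12 to keep scores finite."""
    return np.arctanh(np.clip(r, -_CLAMP, _CLAMP))


def fisher_standardize(r: np.ndarray) -> Tuple[np.ndarray, float, float]:
    """Standardize Fisher scores over the defined upper-triangle pairs.

    Returns (z, mean, sd) where z is a full symmetric matrix with NaN for
    undefined pairs and NaN on the diagonal.
    """
    n = r.shape[0]
    f = fisher_transform(r)
    iu = np.triu_indices(n, k=1)
    vals = f[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined gene pairs to standardize")
    mean = float(vals.mean())
    sd = float(vals.std())
    if sd == 0:
        raise ValueError("Fisher score distribution is degenerate (sd = 0)")
    z = (f - mean) / sd
    np.fill_diagonal(z, np.nan)
    return z, mean, sd


def threshold_network(
    z: np.ndarray,
    gene_ids: Sequence[str],
    cutoff: float = 2.5,
    fisher_mean: float = float("nan"),
    fisher_sd: float = float("nan"),
) -> CoexpressionNetwork:
    """Edge list from a standardized score matrix: z > cutoff, strict."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    zvals = z[iu, ju]
    keep = np.isfinite(zvals) & (zvals > cutoff)
    ids = np.asarray(gene_ids)
    edges = pd.DataFrame(
        {"gene1": ids[iu[keep]], "gene2": ids[ju[keep]], "z": zvals[keep]}
    )
    offdiag_defined = np.isfinite(z).sum(axis=1)
    undefined = [gene_ids[i] for i in range(n) if n > 1 and offdiag_defined[i] == 0]
    return CoexpressionNetwork(
        gene_ids=list(gene_ids),
        cutoff=cutoff,
        edges=edges,
        fisher_mean=fisher_mean,
        fisher_sd=fisher_sd,
        n_scored_pairs=int(np.isfinite(zvals).sum()),
        undefined_genes=undefined,
    )


def build_network(
    atlas: ExpressionAtlas,
    cutoff: float = 2.5,
    block_size: int = 1024,
) -> CoexpressionNetwork:
    """Build the thresholded network, streaming the all-pairs matrix in row blocks.

    Two passes over row blocks: the first accumulates the mean and sd of the
    Fisher scores across all defined unordered pairs, the second emits edges
    with standardized score z > cutoff. Results do not depend on block_size.
    """
    x = np.asarray(atlas.values.values, dtype=np.float64)
    n, t = x.shape
    if t < 3:
        raise ValueError("correlation requires at least 3 tissue columns")
    if block_size < 1:
        raise ValueError("block_size must be positive")
    xn, defined = _normalized_rows(x)
    def_idx = np.where(defined)[0]
    if def_idx.size < 2:
        raise ValueError("no defined gene pairs to standardize")

    # pass 1: moments of the Fisher scores over defined upper-triangle pairs
    total = 0
    s1 = 0.0
    s2 = 0.0
    for start in range(0, n, block_size):
        rows = np.arange(start, min(start + block_size, n))
        rows = rows[defined[rows]]
        if rows.size == 0:
            continue
        r_blk = np.clip(xn[rows] @ xn[def_idx].T, -1.0, 1.0)
        f_blk = fisher_transform(r_blk)
        mask = def_idx[None, :] > rows[:, None]  # strict upper triangle, global indexing
        vals = f_blk[mask]
        total += vals.size
        s1 += float(vals.sum())
        s2 += float((vals * vals).sum())
    mean = s1 / total
    var = s2 / total - mean * mean
    sd = float(np.sqrt(max(var, 0.0)))
    if sd == 0:
        raise ValueError("Fisher score distribution is degenerate (sd = 0)")

    # pass 2: emit edges
    ids = np.asarray(atlas.values.index)
    g1: List[np.ndarray] = []
    g2: List[np.ndarray] = []
    zs: List[np.ndarray] = []
    for start in range(0, n, block_size):
        rows = np.arange(start, min(start + block_size, n))
        rows = rows[defined[rows]]
        if rows.size == 0:
            continue
        r_blk = np.clip(xn[rows] @ xn[def_idx].T, -1.0, 1.0)
        z_blk = (fisher_transform(r_blk) - mean) / sd
        mask = (def_idx[None, :] > rows[:, None]) & (z_blk > cutoff)
        ii, jj = np.nonzero(mask)
        g1.append(ids[rows[ii]])
        g2.append(ids[def_idx[jj]])
        zs.append(z_blk[ii, jj])
    edges = pd.DataFrame(
        {
            "gene1": np.concatenate(g1) if g1 else np.array([], dtype=object),
            "gene2": np.concatenate(g2) if g2 else np.array([], dtype=object),
            "z": np.concatenate(zs) if zs else np.array([], dtype=float),
        }
    )
    return CoexpressionNetwork(
        gene_ids=list(ids),
        cutoff=cutoff,
        edges=edges,
        fisher_mean=mean,
        fisher_sd=sd,
        n_scored_pairs=total,
        undefined_genes=[ids[i] for i in np.where(~defined)[0]],
    )


@dataclass
class ModuleAssignment:
    """Disjoint module membership from Markov clustering."""

    assignment: Dict[str, int]
    n_iterations: int

    @property
    def module_sizes(self) -> Dict[int, int]:
        sizes: Dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def modules(self, min_size: int = 1) -> Dict[int, List[str]]:
        out: Dict[int, List[str]] = {}
        for gene, m in self.assignment.items():
            out.setdefault(m, []).append(gene)
        return {m: genes for m, genes in out.items() if len(genes) >= min_size}

    def large_modules(self, min_size: int = 10) -> Dict[int, List[str]]:
        """Modules at or above the reporting size threshold."""
        return self.modules(min_size=min_size)


def detect_modules_mcl(
    network: CoexpressionNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loop: float = 1.0,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
    max_iterations: int = 200,
) -> ModuleAssignment:
    """Markov clustering on the binary adjacency of the thresholded network.

    Standard MCL: add self-loops, column-normalize, then alternate expansion
    (matrix power) and inflation (elementwise power + renormalization) with
    pruning of tiny entries, until the matrix is stable. Clusters are read off
    the attractor rows; overlaps are resolved by assigning a node to the
    cluster of its lowest-indexed attractor.
    """
    if len(network.edges) == 0:
        raise ValueError("cannot cluster an empty network")
    nodes = sorted(set(network.edges["gene1"]) | set(network.edges["gene2"]))
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rows = [index[g] for g in network.edges["gene1"]]
    cols = [index[g] for g in network.edges["gene2"]]
    data = np.ones(len(rows))
    a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    a = (a + a.T + self_loop * sp.identity(n)).tocsc()

    m = _col_normalize(a)
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        m2 = m
        for _ in range(expansion - 1):
            m2 = m2 @ m
        m2 = m2.tocsc()
        m2.data = np.power(m2.data, inflation)
        m2.data[m2.data < prune_threshold] = 0.0
        m2.eliminate_zeros()
        m2 = _col_normalize(m2)
        diff = abs(m2 - m)
        change = diff.max() if diff.nnz else 0.0
        m = m2
        if change < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"MCL did not converge after {max_iterations} iterations")

    return ModuleAssignment(assignment=_clusters_from_attractors(m.tocsr(), nodes), n_iterations=it)


def _col_normalize(m: sp.spmatrix) -> sp.csc_matrix:
    m = m.tocsc()
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    scale = sp.diags(1.0 / sums)
    return (m @ scale).tocsc()


def _clusters_from_attractors(m: sp.csr_matrix, nodes: List[str]) -> Dict[str, int]:
    n = len(nodes)
    diag = m.diagonal()
    attractors = np.where(diag > 0)[0]
    if attractors.size == 0:  # degenerate; fall back to max-mass rows
        attractors = np.unique(np.asarray(m.argmax(axis=0)).ravel())
    # union attractors whose support overlaps
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_owner: Dict[int, int] = {}
    for a in attractors:
        support = m.indices[m.indptr[a] : m.indptr[a + 1]]
        for jj in support:
            j = int(jj)
            if j in node_owner:
                ra, rb = find(int(a)), find(node_owner[j])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            else:
                node_owner[j] = int(a)
            node_owner[j] = min(node_owner[j], int(a))

    # assign each node to the cluster of its lowest-indexed supporting attractor
    assignment: Dict[str, int] = {}
    roots: Dict[int, int] = {}
    mc = m.tocsc()
    for j in range(n):
        col_rows = mc.indices[mc.indptr[j] : mc.indptr[j + 1]]
        cands = [int(i) for i in col_rows if int(i) in parent]
        if not cands:
            cands = [int(col_rows[np.argmax(mc.data[mc.indptr[j] : mc.indptr[j + 1]])])] if col_rows.size else [j]
            parent.setdefault(cands[0], cands[0])
        root = find(min(cands))
        label = roots.setdefault(root, len(roots))
        assignment[nodes[j]] = label
    return assignment


@dataclass
class PairGraphMetrics:
    """Graph-theoretic divergence metrics for one duplicate pair."""

    shortest_path_len: float  # inf when disconnected
    clustering_coeff_1: float
    clustering_coeff_2: float
    edge_connectivity: int


def pair_graph_metrics(network: CoexpressionNetwork, gene1: str, gene2: str) -> PairGraphMetrics:
    """Shortest path length, per-node clustering coefficients, pair edge connectivity."""
    g = network.graph
    for gene in (gene1, gene2):
        if gene not in g:
            raise KeyError(f"gene {gene!r} not in network")
    try:
        spl = float(nx.shortest_path_length(g, gene1, gene2))
    except nx.NetworkXNoPath:
        spl = float("inf")
    cc = nx.clustering(g, [gene1, gene2])
    if spl == float("inf"):
        ec = 0
    else:
        ec = int(nx.algorithms.connectivity.local_edge_connectivity(g, gene1, gene2))
    return PairGraphMetrics(
        shortest_path_len=spl,
        clustering_coeff_1=float(cc[gene1]),
        clustering_coeff_2=float(cc[gene2]),
        edge_connectivity=ec,
    )
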