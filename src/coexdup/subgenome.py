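"""Subgenome-level network statistics: edge fractionation, enrichment, hubs.

After the maize whole-genome duplication, co-expression edges can be
partitioned by the subgenome labels of their endpoints into maize1-intra,
maize2-intra and inter-subgenome edges. This module quantifies that
partition (as counts and as densities, i.e. observed edges over possible
pairs), tests pathway-level differences with paired t-tests, compares the
observed inter-edge load against a random-graph permutation null, tests
per-module subgenome enrichment (chi-square, Bonferroni), and flags hub genes
against a degree null from 1000 size-matched random graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .network import CoexpressionNetwork, ModuleAssignment


@dataclass
class EdgeFractionation:
    """Edge counts and densities partitioned by subgenome labels."""

    m1_intra: int
    m2_intra: int
    inter: int
    possible_m1: int
    possible_m2: int
    possible_inter: int
    n_maize1: int
    n_maize2: int
    dropped_edges: int  # edges touching an ambiguous/unlabeled endpoint

    @property
    def densities(self) -> Tuple[float, float, float]:
        return (
            self.m1_intra / self.possible_m1 if self.possible_m1 else 0.0,
            self.m2_intra / self.possible_m2 if self.possible_m2 else 0.0,
            self.inter / self.possible_inter if self.possible_inter else 0.0,
        )

    @property
    def intra_density(self) -> float:
        possible = self.possible_m1 + self.possible_m2
        return (self.m1_intra + self.m2_intra) / possible if possible else 0.0

    @property
    def total_edges(self) -> int:
        return self.m1_intra + self.m2_intra + self.inter


def _labels(subgenome_map: pd.DataFrame) -> Dict[str, str]:
    return dict(zip(subgenome_map["gene_id"], subgenome_map["subgenome"]))


def count_subgenome_edges(
    network: CoexpressionNetwork,
    subgenome_map: pd.DataFrame,
    gene_subset: Optional[Sequence[str]] = None,
) -> EdgeFractionation:
    """Partition the network's edges (within a gene subset) by subgenome label.

    Only genes anchored distinctly to maize1 or maize2 contribute; edges with
    an ambiguous or unlabeled endpoint are counted as dropped.
    """
    labels = _labels(subgenome_map)
    nodes = set(network.gene_ids) if gene_subset is None else set(gene_subset) & set(network.gene_ids)
    m1 = {g for g in nodes if labels.get(g) == "maize1"}
    m2 = {g for g in nodes if labels.get(g) == "maize2"}
    if not m1 and not m2:
        raise ValueError("no distinctly labeled maize1/maize2 genes in the subset")
    m1_intra = m2_intra = inter = dropped = 0
    for g1, g2 in zip(network.edges["gene1"], network.edges["gene2"]):
        if g1 not in nodes or g2 not in nodes:
            continue
        in1a, in1b = g1 in m1, g2 in m1
        in2a, in2b = g1 in m2, g2 in m2
        if in1a and in1b:
            m1_intra += 1
        elif in2a and in2b:
            m2_intra += 1
        elif (in1a and in2b) or (in2a and in1b):
            inter += 1
        else:
            dropped += 1
    n1, n2 = len(m1), len(m2)
    return EdgeFractionation(
        m1_intra=m1_intra,
        m2_intra=m2_intra,
        inter=inter,
        possible_m1=n1 * (n1 - 1) // 2,
        possible_m2=n2 * (n2 - 1) // 2,
        possible_inter=n1 * n2,
        n_maize1=n1,
        n_maize2=n2,
        dropped_edges=dropped,
    )


def _paired_t(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Paired two-sample t-test; all-zero differences give (0, 1) by contract."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(diff, 0.0) or np.isclose(diff.std(ddof=1), 0.0):
        return 0.0, 1.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def pathway_fractionation(
    network: CoexpressionNetwork,
    subgenome_map: pd.DataFrame,
    pathways: Mapping[str, Sequence[str]],
    pairs: Optional[pd.DataFrame] = None,
    min_edges: int = 7,
    min_wgd_pairs: int = 2,
) -> Tuple[pd.DataFrame, Dict[str, Tuple[float, float]]]:
    """Per-pathway edge fractionation plus paired t-tests across pathways.

    A pathway is retained when it has at least ``min_edges`` labeled edges
    and, if a pair table is given, at least ``min_wgd_pairs`` retained WGD
    pairs among its genes. The paired t-tests compare, across retained
    pathways: maize1 vs maize2 intra densities, pooled intra vs inter
    densities, and absolute intra vs inter edge counts.
    """
    wgd_pairs: List[Tuple[str, str]] = []
    if pairs is not None:
        wgd = pairs[pairs["dup_type"] == "WGD"]
        wgd_pairs = list(zip(wgd["gene1"], wgd["gene2"]))
    rows = []
    for name, genes in pathways.items():
        genes = set(genes) & set(network.gene_ids)
        if pairs is not None:
            n_wgd = sum(1 for a, b in wgd_pairs if a in genes and b in genes)
            if n_wgd < min_wgd_pairs:
                continue
        else:
            n_wgd = np.nan
        try:
            frac = count_subgenome_edges(network, subgenome_map, genes)
        except ValueError:
            continue
        if frac.total_edges < min_edges:
            continue
        d1, d2, di = frac.densities
        rows.append(
            (name, len(genes), n_wgd, frac.m1_intra, frac.m2_intra, frac.inter,
             d1, d2, di, frac.intra_density)
        )
    per_pathway = pd.DataFrame(
        rows,
        columns=["pathway", "n_genes", "n_wgd_pairs", "m1_intra", "m2_intra",
                 "inter", "density_m1", "density_m2", "density_inter", "density_intra"],
    )
    if len(per_pathway) < 2:
        raise ValueError(
            f"only {len(per_pathway)} pathways pass the filters; need at least 2"
        )
    tests = {
        "m1_vs_m2_density": _paired_t(per_pathway["density_m1"].values, per_pathway["density_m2"].values),
        "intra_vs_inter_density": _paired_t(per_pathway["density_intra"].values, per_pathway["density_inter"].values),
        "intra_vs_inter_count": _paired_t(
            (per_pathway["m1_intra"] + per_pathway["m2_intra"]).values, per_pathway["inter"].values
        ),
    }
    return per_pathway, tests


def _sample_edges(
    rng: np.random.Generator, n_nodes: int, n_edges: int
) -> Tuple[np.ndarray, np.ndarray]:
    """n_edges distinct unordered pairs drawn uniformly from n_nodes nodes."""
    max_pairs = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_pairs:
        raise ValueError(f"cannot place {n_edges} edges among {n_nodes} nodes")
    codes: np.ndarray = np.empty(0, dtype=np.int64)
    while codes.size < n_edges:
        need = int((n_edges - codes.size) * 1.1) + 8
        i = rng.integers(0, n_nodes, size=need)
        j = rng.integers(0, n_nodes, size=need)
        ok = i != j
        lo, hi = np.minimum(i[ok], j[ok]), np.maximum(i[ok], j[ok])
        new = lo.astype(np.int64) * n_nodes + hi
        codes = np.unique(np.concatenate([codes, new]))
    take = rng.permutation(codes.size)[:n_edges]
    chosen = codes[take]
    return (chosen // n_nodes).astype(np.int64), (chosen % n_nodes).astype(np.int64)


def permute_edge_null(
    n1: int,
    n2: int,
    n_edges: int,
    observed_inter: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> Dict[str, object]:
    """Permutation null for the inter-subgenome edge count.

    Each permutation rewires the same number of edges uniformly among the
    same labeled nodes (first ``n1`` node indices are maize1) and counts
    inter-subgenome edges. Two-sided p with add-one smoothing:
    p = (1 + #{|null - mean| >= |observed - mean|}) / (1 + n_perm).
    """
    n = n1 + n2
    if n_edges > n * (n - 1) // 2:
        raise ValueError("infeasible edge count for the labeled node set")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for k in range(n_perm):
        i, j = _sample_edges(rng, n, n_edges)
        null[k] = int(((i < n1) != (j < n1)).sum())
    center = null.mean()
    p = (1 + int((np.abs(null - center) >= abs(observed_inter - center)).sum())) / (1 + n_perm)
    return {
        "null": null,
        "null_mean": float(center),
        "observed": int(observed_inter),
        "p_value": float(p),
        "n_perm": n_perm,
    }


def contingency_edge_test(frac: EdgeFractionation) -> Tuple[float, float]:
    """Chi-square on the 2x2 table (observed, unrealized pairs) x (intra, inter)."""
    intra_obs = frac.m1_intra + frac.m2_intra
    intra_pos = frac.possible_m1 + frac.possible_m2
    table = np.array(
        [
            [intra_obs, intra_pos - intra_obs],
            [frac.inter, frac.possible_inter - frac.inter],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty row or column")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def module_subgenome_enrichment(
    modules: ModuleAssignment,
    subgenome_map: pd.DataFrame,
    min_labeled: int = 20,
    background: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Per-module chi-square test of subgenome composition vs the background.

    Modules with fewer than ``min_labeled`` maize1+maize2 genes are skipped;
    p-values are Bonferroni-adjusted by the number of tested modules.
    """
    labels = _labels(subgenome_map)
    if background is None:
        vals = subgenome_map["subgenome"].value_counts()
        background = (int(vals.get("maize1", 0)), int(vals.get("maize2", 0)))
    b1, b2 = background
    if b1 <= 0 or b2 <= 0:
        raise ValueError("background counts must be positive")
    p1 = b1 / (b1 + b2)
    rows = []
    for mid, genes in sorted(modules.modules().items()):
        o1 = sum(1 for g in genes if labels.get(g) == "maize1")
        o2 = sum(1 for g in genes if labels.get(g) == "maize2")
        n = o1 + o2
        if n < min_labeled:
            continue
        stat, p = stats.chisquare([o1, o2], f_exp=[n * p1, n * (1 - p1)])
        rows.append((mid, len(genes), o1, o2, float(stat), float(p)))
    out = pd.DataFrame(
        rows, columns=["module_id", "module_size", "n_maize1", "n_maize2", "chi2", "p_value"]
    )
    if len(out) == 0:
        warnings.warn("no modules reach the labeled-gene minimum; empty result")
        out["p_adjusted"] = pd.Series(dtype=float)
        return out
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    return out


@dataclass
class HubResult:
    """Hub calls against a permutation degree null."""

    degrees: pd.Series  # per-gene observed degree
    cutoff: int
    hub_flags: pd.Series
    n_permutations: int
    alpha: float
    null_stat: str

    @property
    def hubs(self) -> List[str]:
        return self.hub_flags.index[self.hub_flags].tolist()


def detect_hub_genes(
    network: CoexpressionNetwork,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    null_stat: str = "pooled",
) -> HubResult:
    """Hub genes by degree against random graphs with matched nodes and edges.

    Each permutation draws a uniform simple graph with the observed node and
    edge counts. With ``null_stat='pooled'`` the cutoff is the (1 - alpha)
    nearest-rank quantile of the pooled null degree distribution; with
    ``'max'`` it is that quantile of the per-permutation maximum degree.
    Hubs are genes with observed degree strictly above the cutoff.
    """
    if len(network.edges) == 0:
        raise ValueError("network has no edges")
    if null_stat not in ("pooled", "max"):
        raise ValueError("null_stat must be 'pooled' or 'max'")
    genes = list(network.gene_ids)
    n = len(genes)
    m = len(network.edges)
    idx = {g: i for i, g in enumerate(genes)}
    deg = np.zeros(n, dtype=np.int64)
    for g1, g2 in zip(network.edges["gene1"], network.edges["gene2"]):
        deg[idx[g1]] += 1
        deg[idx[g2]] += 1

    rng = np.random.default_rng(seed)
    if null_stat == "pooled":
        pooled = np.empty(n_perm * n, dtype=np.int64)
        for k in range(n_perm):
            i, j = _sample_edges(rng, n, m)
            d = np.bincount(np.concatenate([i, j]), minlength=n)
            pooled[k * n : (k + 1) * n] = d
        cutoff = int(_nearest_rank_quantile(pooled, 1 - alpha))
    else:
        maxima = np.empty(n_perm, dtype=np.int64)
        for k in range(n_perm):
            i, j = _sample_edges(rng, n, m)
            maxima[k] = int(np.bincount(np.concatenate([i, j]), minlength=n).max())
        cutoff = int(_nearest_rank_quantile(maxima, 1 - alpha))

    degrees = pd.Series(deg, index=genes, name="degree")
    return HubResult(
        degrees=degrees,
        cutoff=cutoff,
        hub_flags=degrees > cutoff,
        n_permutations=n_perm,
        alpha=alpha,
        null_stat=null_stat,
    )


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (ceiling) quantile of a sample."""
    s = np.sort(values)
    k = int(np.ceil(q * s.size))
    return s[max(k - 1, 0)]


def hub_subgenome_bias(
    hubs: HubResult,
    subgenome_map: pd.DataFrame,
    background: Optional[Tuple[int, int]] = None,
) -> Tuple[float, float]:
    """Chi-square of hub subgenome composition against the background counts."""
    labels = _labels(subgenome_map)
    if background is None:
        vals = subgenome_map["subgenome"].value_counts()
        background = (int(vals.get("maize1", 0)), int(vals.get("maize2", 0)))
    b1, b2 = background
    o1 = sum(1 for g in hubs.hubs if labels.get(g) == "maize1")
    o2 = sum(1 for g in hubs.hubs if labels.get(g) == "maize2")
    n = o1 + o2
    if n == 0:
        raise ValueError("no hub genes with a distinct subgenome label")
    p1 = b1 / (b1 + b2)
    stat, p = stats.chisquare([o1, o2], f_exp=[n * p1, n * (1 - p1)])
    return float(stat), float(p)
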