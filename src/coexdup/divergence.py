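"""Duplicate-pair co-expression divergence classification and its correlates.

For a duplicate pair (gene1, gene2), the statistics ``gene1common`` and
``gene2common`` are the shared-neighbor proportions: the number of network
neighbors shared by both duplicates divided by the total neighbor count of
each duplicate. Pairs with at least ten neighbors on both sides are assigned
to one of four geometric classes by Euclidean distance (radius 0.1) to the
target corners of the unit square:

* I  - (1, 1): completely shared neighborhoods,
* II - (0.5, 0.5): half-shared,
* III- (1, 0) or (0, 1): one duplicate's neighborhood nested in the other's,
* IV - (0, 0): disjoint neighborhoods,

with ``unclassified`` for everything else. Degenerate pairs: V when exactly
one duplicate has no neighbors and the other has at least ten, VI when both
have none; remaining pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .network import CoexpressionNetwork

TYPE_LABELS = ("I", "II", "III", "IV", "V", "VI", "unclassified", "excluded")
_CENTERS = {"I": [(1.0, 1.0)], "II": [(0.5, 0.5)], "III": [(1.0, 0.0), (0.0, 1.0)], "IV": [(0.0, 0.0)]}


def shared_neighbor_proportions(
    network: CoexpressionNetwork, gene1: str, gene2: str
) -> Tuple[float, float, int, int]:
    """(gene1common, gene2common, n1, n2), partner gene excluded from both sets."""
    n1set = network.neighbors(gene1) - {gene2}
    n2set = network.neighbors(gene2) - {gene1}
    shared = len(n1set & n2set)
    g1c = shared / len(n1set) if n1set else 0.0
    g2c = shared / len(n2set) if n2set else 0.0
    return g1c, g2c, len(n1set), len(n2set)


def classify_pair_type(
    gene1common: float,
    gene2common: float,
    n1: int,
    n2: int,
    radius: float = 0.1,
    min_neighbors: int = 10,
) -> str:
    """Divergence type label from shared-neighbor proportions and counts."""
    if n1 < 0 or n2 < 0:
        raise ValueError("neighbor counts must be non-negative")
    if not (0.0 <= gene1common <= 1.0 and 0.0 <= gene2common <= 1.0):
        raise ValueError("shared-neighbor proportions must lie in [0, 1]")
    if n1 == 0 and n2 == 0:
        return "VI"
    if (n1 == 0) != (n2 == 0):
        return "V" if max(n1, n2) >= min_neighbors else "excluded"
    if n1 < min_neighbors or n2 < min_neighbors:
        return "excluded"
    point = np.array([gene1common, gene2common])
    for label, centers in _CENTERS.items():
        for c in centers:
            if np.hypot(point[0] - c[0], point[1] - c[1]) <= radius:
                return label
    return "unclassified"


@dataclass
class DivergenceRecord:
    gene1: str
    gene2: str
    n_neighbors1: int
    n_neighbors2: int
    gene1common: float
    gene2common: float
    type_label: str


def classify_network_pairs(
    network: CoexpressionNetwork,
    pairs: pd.DataFrame,
    radius: float = 0.1,
    min_neighbors: int = 10,
    require_present: bool = False,
) -> pd.DataFrame:
    """Classify every pair; pairs with a member outside the network are dropped
    (or raise, with ``require_present``). Returns the pair table with columns
    n1, n2, g1common, g2common, type appended."""
    node_set = set(network.gene_ids)
    adjacency = _adjacency(network)
    rows = []
    for rec in pairs.itertuples(index=False):
        if rec.gene1 not in node_set or rec.gene2 not in node_set:
            if require_present:
                raise KeyError(f"pair ({rec.gene1}, {rec.gene2}) not fully in network")
            continue
        n1set = adjacency.get(rec.gene1, set()) - {rec.gene2}
        n2set = adjacency.get(rec.gene2, set()) - {rec.gene1}
        shared = len(n1set & n2set)
        g1c = shared / len(n1set) if n1set else 0.0
        g2c = shared / len(n2set) if n2set else 0.0
        label = classify_pair_type(g1c, g2c, len(n1set), len(n2set), radius, min_neighbors)
        rows.append((*tuple(rec), len(n1set), len(n2set), g1c, g2c, label))
    return pd.DataFrame(rows, columns=[*pairs.columns, "n1", "n2", "g1common", "g2common", "type"])


def _adjacency(network: CoexpressionNetwork) -> Dict[str, set]:
    adj: Dict[str, set] = {}
    for g1, g2 in zip(network.edges["gene1"], network.edges["gene2"]):
        adj.setdefault(g1, set()).add(g2)
        adj.setdefault(g2, set()).add(g1)
    return adj


def type_by_duptype_enrichment(records: pd.DataFrame) -> pd.DataFrame:
    """Observed vs expected duplication-type composition of each divergence type.

    The expected proportion of duplication type d within divergence type t is
    d's marginal proportion among all classified (non-excluded) pairs. Each
    cell gets a two-sided exact binomial p-value against that marginal and a
    log2(observed/expected proportion) ratio (-inf for empty cells).
    """
    classified = records[records["type"] != "excluded"]
    if len(classified) == 0:
        raise ValueError("no classified pairs")
    marginals = classified["dup_type"].value_counts(normalize=True)
    rows = []
    for t, grp in classified.groupby("type"):
        n_t = len(grp)
        for d, p_d in marginals.items():
            obs = int((grp["dup_type"] == d).sum())
            expected = n_t * p_d
            obs_prop = obs / n_t
            log2_ratio = np.log2(obs_prop / p_d) if obs > 0 else -np.inf
            pval = stats.binomtest(obs, n_t, p_d, alternative="two-sided").pvalue
            rows.append((t, d, obs, expected, obs_prop, float(p_d), log2_ratio, pval))
    return pd.DataFrame(
        rows,
        columns=[
            "type", "dup_type", "observed", "expected",
            "observed_prop", "expected_prop", "log2_ratio", "p_value",
        ],
    )


def ds_by_type_summary(
    records: pd.DataFrame,
    group_a: Sequence[str] = ("I", "II", "III"),
    group_b: Sequence[str] = ("IV", "V"),
) -> Dict[str, object]:
    """Duplication-age (dS) distributions per divergence type, on the WGD scale.

    dS is normalized by the sample sd of dS over WGD pairs, so WGD ages are on
    a unit scale; types are compared by a two-sided rank-sum test between the
    pooled ``group_a`` and ``group_b`` classes.
    """
    scored = records.dropna(subset=["dS"])
    wgd = scored[scored["dup_type"] == "WGD"]["dS"]
    if len(wgd) < 2:
        raise ValueError("need at least 2 WGD pairs with dS")
    sd = float(wgd.std(ddof=1))
    if np.isclose(sd, 0.0, atol=1e-12 * max(float(wgd.abs().max()), 1.0)):
        raise ValueError("sd of WGD dS is zero; cannot normalize")
    norm = scored.assign(ds_norm=scored["dS"] / sd)
    per_type = (
        norm.groupby("type")["ds_norm"]
        .agg(n="count", median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    a = norm[norm["type"].isin(group_a)]["ds_norm"]
    b = norm[norm["type"].isin(group_b)]["ds_norm"]
    if len(a) and len(b):
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        stat, p = np.nan, np.nan
    return {
        "sd_wgd": sd,
        "per_type": per_type,
        "rank_sum_statistic": float(stat),
        "rank_sum_p": float(p),
        "group_a": tuple(group_a),
        "group_b": tuple(group_b),
    }
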