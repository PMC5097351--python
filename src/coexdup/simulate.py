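"""Synthetic data generators with planted ground truth.

Three generators mirror the real inputs of the pipeline:

* a tissue expression atlas (gene x tissue-replicate TPM matrix) with planted
  co-expression modules,
* a duplicate-pair table with duplication types and simulated dS,
* a subgenome map (maize1/maize2 homeologous blocks with fractionation) plus
  pathway gene sets.

Expression is designed on the asinh scale, where co-expression is defined
downstream, and mapped through a per-gene affine + sinh to TPM. Because the
downstream asinh transform is the exact inverse of that mapping up to the
per-gene affine, planted correlations survive preprocessing exactly.

A fourth, composite generator (:func:`generate_divergence_benchmark`) plants
duplicate pairs whose shared-neighbor geometry lands on each of the divergence
classifier's target centers, by giving each pair designed common and private
partner genes in correlation space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import ExpressionAtlas

DUP_TYPES = ("WGD", "tandem", "inserted")

DEFAULT_DS_PARAMS: Dict[str, Tuple[float, float]] = {
    # mean/sd of dS per duplication type: WGD lowest mean and smallest spread
    # (single event), inserted older, tandem spread over a long period.
    "WGD": (0.15, 0.05),
    "tandem": (0.35, 0.25),
    "inserted": (0.50, 0.20),
}
DEFAULT_TYPE_PROPORTIONS: Dict[str, float] = {"WGD": 0.30, "tandem": 0.15, "inserted": 0.55}


# --------------------------------------------------------------------------
# expression atlas
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtlasSpec:
    """Design of a synthetic tissue atlas with planted co-expression modules."""

    n_genes: int
    n_tissues: int = 64
    replicates_per_tissue: int = 2
    n_modules: int = 0
    module_sizes: Tuple[int, ...] = ()
    within_module_corr: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_tissues < 3:
            raise ValueError("n_tissues must be at least 3")
        if self.replicates_per_tissue not in (2, 3):
            raise ValueError("replicates_per_tissue must be 2 or 3")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        if not 0.0 <= self.within_module_corr <= 1.0:
            raise ValueError("within_module_corr must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _profiles_to_tpm(
    profiles: np.ndarray, rng: np.random.Generator, margin: float = 0.05, scale_sigma: float = 0.15
) -> np.ndarray:
    """Map asinh-scale profiles to non-negative TPM via per-gene affine + sinh.

    asinh(TPM) = a_i * profile + b_i, so Pearson correlations on the asinh
    scale equal the designed profile correlations exactly.
    """
    n = profiles.shape[0]
    slope = np.exp(rng.normal(np.log(0.9), scale_sigma, size=n))
    vals = slope[:, None] * profiles
    shift = margin - vals.min(axis=1)
    return np.sinh(vals + shift[:, None])


def _replicate_columns(n_tissues: int, reps: int) -> Tuple[List[str], Dict[str, str], List[str]]:
    tissues = [f"T{t + 1:02d}" for t in range(n_tissues)]
    columns = [f"{t}:{r + 1}" for t in tissues for r in range(reps)]
    rep_map = {c: c.split(":")[0] for c in columns}
    return columns, rep_map, tissues


def _expand_replicates(
    profiles: np.ndarray, reps: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    mat = np.repeat(profiles, reps, axis=1)
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    return mat


def generate_expression_atlas(
    spec: AtlasSpec,
    gene_ids: Optional[Sequence[str]] = None,
    module_labels: Optional[Mapping[str, int]] = None,
) -> Tuple[ExpressionAtlas, pd.Series]:
    """Atlas with planted modules; returns (atlas, gene -> module label, -1 = none).

    Each module has one latent tissue profile; a member gene's profile mixes
    the latent with gene-private variation so that the expected within-module
    correlation is ``within_module_corr``. Replicate columns add Gaussian
    noise of sd ``noise_sd`` on the asinh scale.
    """
    rng = np.random.default_rng(spec.seed)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    elif len(gene_ids) != spec.n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    gene_ids = list(gene_ids)

    labels = np.full(spec.n_genes, -1, dtype=int)
    if module_labels is not None:
        for i, g in enumerate(gene_ids):
            labels[i] = module_labels.get(g, -1)
        n_modules = labels.max() + 1 if labels.max() >= 0 else 0
    else:
        pos = 0
        for m, size in enumerate(spec.module_sizes):
            labels[pos : pos + size] = m
            pos += size
        n_modules = spec.n_modules

    w = spec.within_module_corr
    latents = rng.normal(0.0, 1.0, size=(max(n_modules, 1), spec.n_tissues))
    profiles = np.empty((spec.n_genes, spec.n_tissues))
    for i in range(spec.n_genes):
        private = rng.normal(0.0, 1.0, size=spec.n_tissues)
        if labels[i] >= 0:
            profiles[i] = math.sqrt(w) * latents[labels[i]] + math.sqrt(1.0 - w) * private
        else:
            profiles[i] = private

    columns, rep_map, _ = _replicate_columns(spec.n_tissues, spec.replicates_per_tissue)
    mat = _expand_replicates(profiles, spec.replicates_per_tissue, spec.noise_sd, rng)
    tpm = _profiles_to_tpm(mat, rng)
    atlas = ExpressionAtlas(
        values=pd.DataFrame(tpm, index=gene_ids, columns=columns),
        replicate_map=rep_map,
    )
    return atlas, pd.Series(labels, index=gene_ids, name="module")


# --------------------------------------------------------------------------
# duplicate pairs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedPairSpec:
    """Design of a planted duplicate-pair table."""

    n_pairs: int
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    divergence_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.25, "IV": 0.35, "V": 0.20, "VI": 0.20}
    )
    ds_params: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DS_PARAMS)
    )

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if abs(sum(self.type_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")
        if abs(sum(self.divergence_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("divergence_proportions must sum to 1")
        for t, (mu, sd) in self.ds_params.items():
            if mu < 0 or sd < 0:
                raise ValueError(f"ds_params for {t} must be non-negative")
        bad = set(self.divergence_proportions) - {"I", "IV", "V", "VI"}
        if bad:
            raise ValueError(
                f"divergence types {sorted(bad)} cannot be planted by module "
                "co-membership; use generate_divergence_benchmark for II/III"
            )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws resampled until non-negative."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))
    return np.abs(out)  # pathological spec; fall back to reflection


def generate_duplicate_pairs(
    spec: PlantedPairSpec, module_labels: pd.Series, seed: int = 0
) -> pd.DataFrame:
    """Duplicate pairs planted through module co-membership.

    Planted divergence labels realizable from membership alone: I (both genes
    in the same module), IV (different modules), V (one module gene, one
    unnetworked gene), VI (two unnetworked genes). Genes are used at most once
    across pairs.
    """
    rng = np.random.default_rng(seed)
    by_module: Dict[int, List[str]] = {}
    singletons: List[str] = []
    for gene, m in module_labels.items():
        if m < 0:
            singletons.append(gene)
        else:
            by_module.setdefault(int(m), []).append(gene)
    for genes in by_module.values():
        rng.shuffle(genes)
    rng.shuffle(singletons)

    dup_types = list(spec.type_proportions)
    dup_probs = [spec.type_proportions[t] for t in dup_types]
    div_types = list(spec.divergence_proportions)
    div_probs = [spec.divergence_proportions[t] for t in div_types]

    rows = []
    module_order = sorted(by_module, key=lambda m: -len(by_module[m]))
    for _ in range(spec.n_pairs):
        div = div_types[rng.choice(len(div_types), p=div_probs)]
        try:
            if div == "I":
                m = next(m for m in module_order if len(by_module[m]) >= 2)
                g1, g2 = by_module[m].pop(), by_module[m].pop()
            elif div == "IV":
                ma, mb = [m for m in module_order if len(by_module[m]) >= 1][:2]
                g1, g2 = by_module[ma].pop(), by_module[mb].pop()
            elif div == "V":
                m = next(m for m in module_order if len(by_module[m]) >= 1)
                g1, g2 = by_module[m].pop(), singletons.pop()
            else:  # VI
                g1, g2 = singletons.pop(), singletons.pop()
        except (StopIteration, IndexError) as exc:
            raise ValueError("requested pairs exceed available genes") from exc
        module_order = sorted(by_module, key=lambda m: -len(by_module[m]))
        dup = dup_types[rng.choice(len(dup_types), p=dup_probs)]
        mu, sd = spec.ds_params.get(dup, (0.3, 0.1))
        ds = float(_truncated_normal(rng, mu, sd, 1)[0])
        g1, g2 = sorted((g1, g2))
        rows.append((g1, g2, dup, ds, div))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "dup_type", "dS", "planted_divergence"])


# --------------------------------------------------------------------------
# subgenome structure and pathways
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SubgenomeSpec:
    """Design of a fractionated two-subgenome gene complement."""

    n_maize1: int
    n_maize2: int
    fractionation_rate: float = 0.3
    n_pathways: int = 20
    pathway_size_range: Tuple[int, int] = (8, 20)
    n_ambiguous: int = 0
    nonsyntenic_fraction: float = 0.25  # share of maize1 genes at non-syntenic positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maize1 < 1 or self.n_maize2 < 1:
            raise ValueError("subgenome gene counts must be positive")
        if not 0.0 <= self.fractionation_rate <= 1.0:
            raise ValueError("fractionation_rate must lie in [0, 1]")
        lo, hi = self.pathway_size_range
        if lo > hi or lo < 4:
            raise ValueError(
                "pathway_size_range infeasible: need at least 4 genes "
                "(two retained WGD pairs) per pathway"
            )


BLOCK_GENES = 25  # genes per syntenic block
GENE_SPACING = 5000
GENE_LENGTH = 3000


def generate_subgenome_structure(
    spec: SubgenomeSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, List[str]]]:
    """Subgenome map, homeolog pair table, and pathway gene sets.

    maize1 genes sit on homeologous block pairs; for each maize1 gene the
    maize2 homeolog is retained unless fractionated (probability
    ``fractionation_rate``), with the retained count reconciled to exactly
    ``n_maize2``. Every emitted pathway contains at least two retained WGD
    pairs. Returns (map, homeolog pairs with retained/lost status, pathways).
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_maize1, spec.n_maize2

    # syntenic maize1 genes are homeolog candidates; the rest sit at
    # non-syntenic (transposed) positions
    n_syn1 = max(int(round(n1 * (1.0 - spec.nonsyntenic_fraction))), min(n1, 1))
    lost_flags = rng.random(n_syn1) < spec.fractionation_rate
    retained = int(n_syn1 - lost_flags.sum())
    if retained > n2:
        # reconcile: mark extra homeologs lost (lowest-priority positions)
        extra = retained - n2
        keep_idx = np.where(~lost_flags)[0]
        lost_flags[rng.choice(keep_idx, size=extra, replace=False)] = True
        retained = n2
    n_extra_m2 = n2 - retained  # maize2 genes without a maize1 homeolog

    m1_ids = [f"m1g{i + 1:05d}" for i in range(n1)]
    m2_hom_ids = [f"m2g{i + 1:05d}" if not lost_flags[i] else None for i in range(n_syn1)]
    extra_ids = [f"m2x{i + 1:05d}" for i in range(n_extra_m2)]
    amb_ids = [f"ambg{i + 1:05d}" for i in range(spec.n_ambiguous)]

    records = []
    pairs = []
    for i, g1 in enumerate(m1_ids[:n_syn1]):
        block = f"B{i // BLOCK_GENES + 1:04d}"
        pos = i % BLOCK_GENES
        chrom1 = f"chr{(i // BLOCK_GENES) % 5 + 1}"
        chrom2 = f"chr{(i // BLOCK_GENES) % 5 + 6}"
        start = 1 + pos * GENE_SPACING
        records.append((g1, "maize1", block, chrom1, start, start + GENE_LENGTH - 1))
        g2 = m2_hom_ids[i]
        if g2 is not None:
            records.append((g2, "maize2", block, chrom2, start, start + GENE_LENGTH - 1))
            pairs.append((g1, g2, "retained"))
        else:
            pairs.append((g1, "", "lost"))
    for j, g in enumerate(m1_ids[n_syn1:]):
        records.append((g, "maize1", ".", f"chr{j % 5 + 1}", 1 + j * GENE_SPACING, j * GENE_SPACING + GENE_LENGTH))
    for j, g in enumerate(extra_ids):
        # maize2 genes at non-syntenic positions (no block)
        records.append((g, "maize2", ".", f"chr{j % 5 + 6}", 1 + j * GENE_SPACING, j * GENE_SPACING + GENE_LENGTH))
    for j, g in enumerate(amb_ids):
        records.append((g, "ambiguous", ".", f"chr{j % 10 + 1}", 1 + j * GENE_SPACING, j * GENE_SPACING + GENE_LENGTH))

    map_df = pd.DataFrame(
        records, columns=["gene_id", "subgenome", "block_id", "chrom", "start", "end"]
    )
    pair_df = pd.DataFrame(pairs, columns=["gene1", "gene2", "status"])

    retained_pairs = pair_df[pair_df["status"] == "retained"].reset_index(drop=True)
    if spec.n_pathways > 0 and len(retained_pairs) < 2:
        raise ValueError("pathway_size_range infeasible: fewer than 2 retained WGD pairs exist")
    all_genes = map_df["gene_id"].tolist()
    lo, hi = spec.pathway_size_range
    pathways: Dict[str, List[str]] = {}
    for p in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_seed_pairs = min(2 + int(rng.integers(0, 2)), size // 2, len(retained_pairs))
        n_seed_pairs = max(n_seed_pairs, 2)
        chosen = rng.choice(len(retained_pairs), size=n_seed_pairs, replace=False)
        members: List[str] = []
        for c in chosen:
            members.extend([retained_pairs.loc[int(c), "gene1"], retained_pairs.loc[int(c), "gene2"]])
        pool = [g for g in all_genes if g not in set(members)]
        fill = size - len(members)
        if fill > 0:
            members.extend(rng.choice(pool, size=min(fill, len(pool)), replace=False).tolist())
        pathways[f"PWY{p + 1:03d}"] = members
    return map_df, pair_df, pathways


def sample_typed_pairs(
    map_df: pd.DataFrame,
    homeolog_pairs: pd.DataFrame,
    n_pairs: int,
    type_proportions: Mapping[str, float] = None,
    ds_params: Mapping[str, Tuple[float, float]] = None,
    tandem_window: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Duplicate pairs with duplication types consistent with the synteny map.

    WGD pairs are retained homeologs; tandem pairs are same-block neighbors
    within ``tandem_window`` intervening genes; inserted pairs have one
    non-syntenic member.
    """
    type_proportions = dict(type_proportions or DEFAULT_TYPE_PROPORTIONS)
    ds_params = dict(ds_params or DEFAULT_DS_PARAMS)
    rng = np.random.default_rng(seed)

    retained = homeolog_pairs[homeolog_pairs["status"] == "retained"]
    wgd_pool = list(retained.itertuples(index=False, name=None))
    rng.shuffle(wgd_pool)

    placed = map_df[map_df["block_id"] != "."]
    tandem_pool = []
    for (_, _), grp in placed.groupby(["block_id", "subgenome"], sort=True):
        genes = grp.sort_values("start")["gene_id"].tolist()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if j - i - 1 <= tandem_window:
                    tandem_pool.append((genes[i], genes[j]))
    rng.shuffle(tandem_pool)

    nonsyn = map_df[map_df["block_id"] == "."]["gene_id"].tolist()
    syn = placed["gene_id"].tolist()
    rng.shuffle(nonsyn)
    rng.shuffle(syn)

    types = list(type_proportions)
    probs = [type_proportions[t] for t in types]
    rows = []
    used: set = set()
    for _ in range(n_pairs):
        t = types[rng.choice(len(types), p=probs)]
        g1 = g2 = None
        if t == "WGD":
            while wgd_pool:
                a, b, _ = wgd_pool.pop()
                if a not in used and b not in used:
                    g1, g2 = a, b
                    break
        elif t == "tandem":
            while tandem_pool:
                a, b = tandem_pool.pop()
                if a not in used and b not in used:
                    g1, g2 = a, b
                    break
        else:
            while nonsyn and syn:
                a = nonsyn.pop()
                b = syn.pop()
                if a not in used and b not in used:
                    g1, g2 = a, b
                    break
        if g1 is None:
            raise ValueError(f"exhausted candidate pool for duplication type {t}")
        used.update((g1, g2))
        mu, sd = ds_params.get(t, (0.3, 0.1))
        ds = float(_truncated_normal(rng, mu, sd, 1)[0])
        rows.append((*sorted((g1, g2)), t, ds))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "dup_type", "dS"])


# --------------------------------------------------------------------------
# divergence benchmark: pairs planted on the classifier's target geometry
# --------------------------------------------------------------------------

BENCHMARK_PROPORTIONS: Dict[str, float] = {
    "I": 0.10,
    "II": 0.10,
    "III": 0.05,
    "IV": 0.40,
    "V": 0.10,
    "VI": 0.15,
    "unclassified": 0.10,
}

# designed correlation geometry (before scaling by within_module_corr)
_RHO_PAIR = 0.6          # designed correlation between the two pair members
_COMMON_MIX2 = 0.95      # squared weight of the bisector in a common partner
_PRIVATE_MIX2 = 0.90     # squared weight of the owner in a private partner
_MODULE_MIX2 = 0.998     # squared weight of the module latent in a member

_COMMON_CORR = math.sqrt(_COMMON_MIX2 * (1.0 + _RHO_PAIR) / 2.0)   # ~0.872 to each member
_PRIVATE_CORR = math.sqrt(_PRIVATE_MIX2)                           # ~0.949 to the owner
_PRIVATE_CROSS = _PRIVATE_CORR * _RHO_PAIR                         # ~0.569 to the other member


class _DirectionBuilder:
    """Accumulates designed unit directions in tissue space."""

    def __init__(self, n_tissues: int, rng: np.random.Generator):
        self.t = n_tissues
        self.rng = rng
        self.dirs: List[np.ndarray] = []
        self.ids: List[str] = []

    def _unit(self, v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    def rand_unit(self) -> np.ndarray:
        return self._unit(self.rng.normal(size=self.t))

    def jitter(self, basis: Sequence[np.ndarray]) -> np.ndarray:
        """Random unit vector orthogonal to the given orthonormal basis."""
        v = self.rng.normal(size=self.t)
        for b in basis:
            v = v - (v @ b) * b
        return self._unit(v)

    def add(self, gene_id: str, direction: np.ndarray) -> str:
        self.ids.append(gene_id)
        self.dirs.append(direction)
        return gene_id

    def add_module(self, prefix: str, size: int) -> List[str]:
        latent = self.rand_unit()
        out = []
        for k in range(size):
            jit = self.jitter([latent])
            d = math.sqrt(_MODULE_MIX2) * latent + math.sqrt(1 - _MODULE_MIX2) * jit
            out.append(self.add(f"{prefix}_{k + 1:03d}", d))
        return out

    def pair_frame(self) -> Tuple[np.ndarray, np.ndarray, List[np.ndarray]]:
        """(u1, u2, orthonormal basis of their span) with u1.u2 = _RHO_PAIR."""
        u1 = self.rand_unit()
        e2 = self.jitter([u1])
        u2 = _RHO_PAIR * u1 + math.sqrt(1 - _RHO_PAIR**2) * e2
        return u1, u2, [u1, e2]

    def add_partners(
        self, prefix: str, basis: List[np.ndarray], anchor: np.ndarray, mix2: float, count: int
    ) -> List[str]:
        out = []
        for k in range(count):
            jit = self.jitter(basis)
            d = math.sqrt(mix2) * anchor + math.sqrt(1 - mix2) * jit
            out.append(self.add(f"{prefix}_{k + 1:03d}", d))
        return out


def _allocate_counts(n: int, proportions: Mapping[str, float]) -> Dict[str, int]:
    """Largest-remainder allocation of n among the proportion keys."""
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return counts


def _fisher_census(profiles: np.ndarray, block_size: int = 2048) -> Tuple[int, float, float]:
    """(count, sum f, sum f^2) of Fisher scores over all unordered profile pairs."""
    x = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    xn = x / norms
    n = xn.shape[0]
    total, s1, s2 = 0, 0.0, 0.0
    for start in range(0, n, block_size):
        rows = np.arange(start, min(start + block_size, n))
        r = np.clip(xn[rows] @ xn.T, -(1 - 1e-12), 1 - 1e-12)
        f = np.arctanh(r)
        mask = np.arange(n)[None, :] > rows[:, None]
        vals = f[mask]
        total += vals.size
        s1 += float(vals.sum())
        s2 += float((vals * vals).sum())
    return total, s1, s2


def _solve_backbone_size(
    n0: int, census: Tuple[int, float, float], target_sd: float, n_tissues: int, k_max: int = 5000
) -> int:
    """Backbone (filler) module size whose Fisher-score spread hits target_sd.

    The backbone emulates the broad constitutive co-expression block a real
    atlas contains; its size fixes the spread of the standardized edge-score
    distribution and hence the correlation level the z cutoff corresponds to.
    """
    p0, s1_0, s2_0 = census
    f_fill = math.atanh(_MODULE_MIX2)
    bg2 = 1.0 / (n_tissues - 3)
    ks = np.arange(2, k_max, dtype=float)
    within = ks * (ks - 1) / 2
    p = p0 + within + ks * n0
    s1 = s1_0 + within * f_fill
    s2 = s2_0 + within * f_fill**2 + ks * n0 * bg2
    var = s2 / p - (s1 / p) ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    return int(ks[np.argmin(np.abs(sd - target_sd))])


def generate_divergence_benchmark(
    n_pairs: int = 500,
    n_tissues: int = 64,
    replicates_per_tissue: int = 2,
    within_module_corr: float = 1.0,
    noise_sd: float = 0.0,
    z_cutoff: float = 2.5,
    proportions: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> Tuple[ExpressionAtlas, pd.DataFrame]:
    """Atlas + pair table planting all six divergence types plus unclassified.

    Each pair's shared-neighbor geometry is realized with designed partner
    genes in correlation space:

    * I  - both members in one co-expression module (all neighbors shared),
    * II - a common partner block plus equal private blocks (overlap 1/2),
    * III- a small common block plus a large block private to one member,
    * IV - members in two unrelated modules (no shared neighbors),
    * V  - one member in a module, the other profile-isolated,
    * VI - both members profile-isolated,
    * unclassified - overlap proportions placed away from every target center.

    ``within_module_corr`` scales every designed correlation (1.0 = noise-free
    planting); a calibrated backbone module fixes the standardized-score
    spread so the z cutoff separates designed partner edges from 64-tissue
    sampling noise. Deterministic given seed.
    """
    props = dict(proportions or BENCHMARK_PROPORTIONS)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("benchmark proportions must sum to 1")
    counts = _allocate_counts(n_pairs, props)
    rng = np.random.default_rng(seed)
    b = _DirectionBuilder(n_tissues, rng)
    pair_rows: List[Tuple[str, str, str]] = []  # gene1, gene2, planted label

    # type I: shared modules, 5 pairs + 2 extras per 12-gene module
    i_left = counts.get("I", 0)
    mod_idx = 0
    while i_left > 0:
        take = min(5, i_left)
        genes = b.add_module(f"I_m{mod_idx:03d}", 2 * take + max(12 - 2 * take, 2))
        for p in range(take):
            pair_rows.append((genes[2 * p], genes[2 * p + 1], "I"))
        i_left -= take
        mod_idx += 1

    # type II: (0.5, 0.5) - equal common and private partner blocks
    for p in range(counts.get("II", 0)):
        u1, u2, basis = b.pair_frame()
        g1 = b.add(f"II_{p:03d}_g1", u1)
        g2 = b.add(f"II_{p:03d}_g2", u2)
        bis = (u1 + u2) / np.linalg.norm(u1 + u2)
        b.add_partners(f"II_{p:03d}_c", basis, bis, _COMMON_MIX2, 12)
        b.add_partners(f"II_{p:03d}_p1", basis, u1, _PRIVATE_MIX2, 12)
        b.add_partners(f"II_{p:03d}_p2", basis, u2, _PRIVATE_MIX2, 12)
        pair_rows.append((g1, g2, "II"))

    # type III: (1, ~0.08) - small common block, large block private to gene2
    for p in range(counts.get("III", 0)):
        u1, u2, basis = b.pair_frame()
        g1 = b.add(f"III_{p:03d}_g1", u1)
        g2 = b.add(f"III_{p:03d}_g2", u2)
        bis = (u1 + u2) / np.linalg.norm(u1 + u2)
        b.add_partners(f"III_{p:03d}_c", basis, bis, _COMMON_MIX2, 13)
        b.add_partners(f"III_{p:03d}_p2", basis, u2, _PRIVATE_MIX2, 150)
        pair_rows.append((g1, g2, "III"))

    # type IV: members in unrelated modules
    iv = counts.get("IV", 0)
    g1_slots: List[str] = []
    g2_slots: List[str] = []
    midx = 0
    while len(g1_slots) < iv:
        g1_slots.extend(b.add_module(f"IV_a{midx:03d}", 12))
        midx += 1
    midx = 0
    while len(g2_slots) < iv:
        g2_slots.extend(b.add_module(f"IV_b{midx:03d}", 12))
        midx += 1
    for p in range(iv):
        pair_rows.append((g1_slots[p], g2_slots[p], "IV"))

    # type V: gene1 in a module, gene2 isolated
    v = counts.get("V", 0)
    v_slots: List[str] = []
    midx = 0
    while len(v_slots) < v:
        v_slots.extend(b.add_module(f"V_m{midx:03d}", 12))
        midx += 1
    for p in range(v):
        g2 = b.add(f"V_{p:03d}_g2", b.rand_unit())
        pair_rows.append((v_slots[p], g2, "V"))

    # type VI: both isolated
    for p in range(counts.get("VI", 0)):
        g1 = b.add(f"VI_{p:03d}_g1", b.rand_unit())
        g2 = b.add(f"VI_{p:03d}_g2", b.rand_unit())
        pair_rows.append((g1, g2, "VI"))

    # unclassified: overlap (~0.30, ~0.69), away from every target center
    for p in range(counts.get("unclassified", 0)):
        u1, u2, basis = b.pair_frame()
        g1 = b.add(f"U_{p:03d}_g1", u1)
        g2 = b.add(f"U_{p:03d}_g2", u2)
        bis = (u1 + u2) / np.linalg.norm(u1 + u2)
        b.add_partners(f"U_{p:03d}_c", basis, bis, _COMMON_MIX2, 9)
        b.add_partners(f"U_{p:03d}_p1", basis, u1, _PRIVATE_MIX2, 21)
        b.add_partners(f"U_{p:03d}_p2", basis, u2, _PRIVATE_MIX2, 4)
        pair_rows.append((g1, g2, "unclassified"))

    # scale the planted geometry by within_module_corr
    w = within_module_corr
    designed = np.vstack(b.dirs)
    if w < 1.0:
        noise = rng.normal(size=designed.shape)
        noise /= np.linalg.norm(noise, axis=1, keepdims=True)
        designed = math.sqrt(w) * designed + math.sqrt(1.0 - w) * noise

    # calibrate the backbone so z_cutoff lands between designed edges and noise
    f_lo = math.atanh(w * _PRIVATE_CROSS)
    f_hi = math.atanh(w * _COMMON_CORR)
    target_sd = 0.5 * (f_lo + f_hi) / z_cutoff
    census = _fisher_census(designed)
    k = _solve_backbone_size(designed.shape[0], census, target_sd, n_tissues)
    b2 = _DirectionBuilder(n_tissues, rng)
    b2.add_module("backbone", k)
    profiles = np.vstack([designed, np.vstack(b2.dirs)])
    gene_ids = b.ids + b2.ids

    profiles = profiles * math.sqrt(n_tissues)  # unit entries, realistic asinh range
    columns, rep_map, _ = _replicate_columns(n_tissues, replicates_per_tissue)
    mat = _expand_replicates(profiles, replicates_per_tissue, noise_sd, rng)
    tpm = _profiles_to_tpm(mat, rng)
    atlas = ExpressionAtlas(
        values=pd.DataFrame(tpm, index=gene_ids, columns=columns), replicate_map=rep_map
    )

    dup_names = list(DEFAULT_TYPE_PROPORTIONS)
    dup_probs = [DEFAULT_TYPE_PROPORTIONS[t] for t in dup_names]
    rows = []
    for g1, g2, label in pair_rows:
        dup = dup_names[rng.choice(len(dup_names), p=dup_probs)]
        mu, sd = DEFAULT_DS_PARAMS[dup]
        ds = float(_truncated_normal(rng, mu, sd, 1)[0])
        a, bgene = sorted((g1, g2))
        rows.append((a, bgene, dup, ds, label))
    pairs = pd.DataFrame(
        rows, columns=["gene1", "gene2", "dup_type", "dS", "planted_divergence"]
    )
    return atlas, pairs


# --------------------------------------------------------------------------
# linked dataset: one gene universe shared by atlas, pairs and subgenome map
# --------------------------------------------------------------------------


def generate_linked_dataset(
    atlas_spec: AtlasSpec,
    pair_spec: PlantedPairSpec,
    subgenome_spec: SubgenomeSpec,
    tandem_window: int = 5,
) -> Dict[str, object]:
    """All pipeline inputs over one shared gene universe.

    The subgenome structure defines the gene universe; duplicate pairs are
    sampled consistently with the synteny map (so duplication types are
    recoverable from it); module membership is then constructed to realize
    the planted divergence labels; finally the atlas is generated from that
    membership. Returns a dict with keys atlas, module_labels, pairs, map,
    homeologs, pathways.
    """
    map_df, homeologs, pathways = generate_subgenome_structure(subgenome_spec)
    universe = map_df["gene_id"].tolist()
    if atlas_spec.n_genes != len(universe):
        raise ValueError(
            f"n_genes ({atlas_spec.n_genes}) must equal the subgenome universe "
            f"size ({len(universe)})"
        )
    rng = np.random.default_rng(atlas_spec.seed + 1)
    typed = sample_typed_pairs(
        map_df,
        homeologs,
        pair_spec.n_pairs,
        pair_spec.type_proportions,
        pair_spec.ds_params,
        tandem_window=tandem_window,
        seed=atlas_spec.seed + 2,
    )

    div_names = list(pair_spec.divergence_proportions)
    div_probs = [pair_spec.divergence_proportions[t] for t in div_names]
    planted = [div_names[rng.choice(len(div_names), p=div_probs)] for _ in range(len(typed))]
    typed = typed.assign(planted_divergence=planted)

    # build module membership realizing the planted labels
    module_of: Dict[str, int] = {}
    next_module = 0
    open_mods: Dict[str, Tuple[int, int]] = {}  # pool -> (module id, fill level)
    cap = 30  # planted module size; large enough for the module-level tests

    def place(pool: str, gene: str) -> None:
        nonlocal next_module
        mid, fill = open_mods.get(pool, (-1, cap))
        if fill >= cap:
            mid, fill = next_module, 0
            next_module += 1
        module_of[gene] = mid
        open_mods[pool] = (mid, fill + 1)

    for row in typed.itertuples(index=False):
        lab = row.planted_divergence
        if lab == "I":
            mid, fill = open_mods.get("I", (-1, cap))
            if fill + 2 > cap:
                mid, fill = next_module, 0
                next_module += 1
            module_of[row.gene1] = mid
            module_of[row.gene2] = mid
            open_mods["I"] = (mid, fill + 2)
        elif lab == "IV":
            place("IVa", row.gene1)
            place("IVb", row.gene2)
        elif lab == "V":
            place("V", row.gene1)
        # VI: both stay unlabeled

    # pad partially filled modules to capacity with unused genes
    used = set(module_of) | set(typed["gene1"]) | set(typed["gene2"])
    free = [g for g in universe if g not in used]
    rng.shuffle(free)
    fill_counts: Dict[int, int] = {}
    for mid in module_of.values():
        fill_counts[mid] = fill_counts.get(mid, 0) + 1
    for mid in sorted(fill_counts):
        while fill_counts[mid] < cap and free:
            module_of[free.pop()] = mid
            fill_counts[mid] += 1

    # rebuild pathways around modules so each pathway is co-expression-coherent
    # (real metabolic pathways are; module-less pathways would carry no edges)
    module_members: Dict[int, List[str]] = {}
    for g, mid in module_of.items():
        module_members.setdefault(mid, []).append(g)
    retained_pairs = homeologs[homeologs["status"] == "retained"].reset_index(drop=True)
    mod_ids = sorted(module_members)
    if mod_ids and len(retained_pairs) >= 2:
        lo, hi = subgenome_spec.pathway_size_range
        pathways = {}
        for p in range(subgenome_spec.n_pathways):
            members = list(module_members[mod_ids[p % len(mod_ids)]])
            chosen = rng.choice(len(retained_pairs), size=2, replace=False)
            for c in chosen:
                members.extend(
                    [retained_pairs.loc[int(c), "gene1"], retained_pairs.loc[int(c), "gene2"]]
                )
            members = list(dict.fromkeys(members))
            if len(members) < max(lo, 4):
                pool = [g for g in universe if g not in set(members)]
                members.extend(rng.choice(pool, size=max(lo, 4) - len(members), replace=False))
            pathways[f"PWY{p + 1:03d}"] = members

    atlas, labels = generate_expression_atlas(atlas_spec, gene_ids=universe, module_labels=module_of)
    return {
        "atlas": atlas,
        "module_labels": labels,
        "pairs": typed,
        "map": map_df,
        "homeologs": homeologs,
        "pathways": pathways,
    }
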