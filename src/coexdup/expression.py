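"""Expression-atlas preprocessing: replicate averaging, expression filter, asinh.

The atlas is a gene x sample TPM matrix. Samples are tissue/stage libraries with
2-3 biological replicates each; a replicate map ties each column to its tissue.
Preprocessing (in pipeline order) is: average replicates per tissue, drop genes
that are not expressed (TPM > 0 in at least three tissues, or TPM > 5 in at
least one), and compress the dynamic range with the inverse hyperbolic sine,
asinh(x) = ln(x + sqrt(x^2 + 1)), which behaves like ln(2x) for large x while
staying linear near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import io as cdio


@dataclass
class ExpressionAtlas:
    """A TPM matrix (genes x samples) plus the sample -> tissue replicate map.

    After :func:`average_replicates` the columns are tissues and the replicate
    map is the identity.
    """

    values: pd.DataFrame
    replicate_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs in atlas")
        if not self.replicate_map:
            self.replicate_map = {c: c for c in self.values.columns}
        unmapped = [c for c in self.values.columns if c not in self.replicate_map]
        if unmapped:
            raise ValueError(f"columns missing from replicate map: {unmapped}")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for c in self.values.columns:
            seen.setdefault(self.replicate_map[c], None)
        return list(seen)

    @classmethod
    def from_files(cls, expression_path: str, replicate_map_path: str | None = None) -> "ExpressionAtlas":
        values = cdio.read_expression_tsv(expression_path)
        if (values.values < 0).any():
            raise ValueError("negative TPM values in expression matrix")
        rep_map = cdio.read_replicate_map(replicate_map_path) if replicate_map_path else {}
        return cls(values=values, replicate_map=rep_map)

    def write(self, expression_path: str, replicate_map_path: str | None = None) -> None:
        cdio.write_expression_tsv(self.values, expression_path)
        if replicate_map_path:
            cdio.write_replicate_map(self.replicate_map, replicate_map_path)


def average_replicates(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Collapse replicate columns to one arithmetic-mean column per tissue."""
    groups: Dict[str, List[str]] = {}
    for col in atlas.values.columns:
        groups.setdefault(atlas.replicate_map[col], []).append(col)
    for tissue, cols in groups.items():
        if not cols:
            raise ValueError(f"tissue {tissue!r} has no replicate columns")
    averaged = pd.DataFrame(
        {tissue: atlas.values[cols].mean(axis=1) for tissue, cols in groups.items()},
        index=atlas.values.index,
    )
    return ExpressionAtlas(values=averaged, replicate_map={t: t for t in averaged.columns})


def filter_expressed(
    atlas: ExpressionAtlas,
    min_expressed_tissues: int = 3,
    high_tpm: float = 5.0,
) -> Tuple[ExpressionAtlas, List[str]]:
    """Keep genes expressed in the atlas; return (kept atlas, removed gene IDs).

    A gene counts as expressed iff TPM > 0 in at least ``min_expressed_tissues``
    tissues, or TPM > ``high_tpm`` in at least one tissue (both strict).
    Operates on replicate-averaged, per-tissue columns.
    """
    vals = atlas.values.values
    keep = ((vals > 0).sum(axis=1) >= min_expressed_tissues) | ((vals > high_tpm).any(axis=1))
    kept = atlas.values.loc[keep]
    removed = atlas.values.index[~keep].tolist()
    rep_map = {c: atlas.replicate_map[c] for c in atlas.values.columns}
    return ExpressionAtlas(values=kept, replicate_map=rep_map), removed


def asinh_transform(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Apply asinh elementwise. Rejects negative input."""
    if (atlas.values.values < 0).any():
        raise ValueError("asinh transform expects non-negative TPM values")
    out = pd.DataFrame(
        np.arcsinh(atlas.values.values),
        index=atlas.values.index,
        columns=atlas.values.columns,
    )
    return ExpressionAtlas(values=out, replicate_map=dict(atlas.replicate_map))


def preprocess(
    atlas: ExpressionAtlas,
    min_expressed_tissues: int = 3,
    high_tpm: float = 5.0,
) -> Tuple[ExpressionAtlas, List[str]]:
    """Full preprocessing: replicate-average, filter, asinh. Returns (atlas, removed)."""
    averaged = average_replicates(atlas)
    kept, removed = filter_expressed(averaged, min_expressed_tissues, high_tpm)
    return asinh_transform(kept), removed
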