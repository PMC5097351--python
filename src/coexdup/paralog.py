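"""Paralog detection from protein sequences and duplication-type assignment.

Candidate duplicate pairs come from all-vs-all global (Needleman-Wunsch)
protein alignment under BLOSUM62 with affine gaps; a pair is retained when the
aligned fraction of each protein exceeds a coverage threshold (40% for both
members) and the raw alignment score clears a floor. Duplication types are
then read off a subgenome/synteny map: WGD for homeologous-block pairs,
tandem for close same-block neighbors, inserted otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"


def _blosum62_with_neutral_x():
    mat = substitution_matrices.load("BLOSUM62")
    arr = np.array(mat)
    letters = mat.alphabet
    xi = letters.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    return substitution_matrices.Array(alphabet=letters, dims=2, data=arr)


_MATRIX = _blosum62_with_neutral_x()


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate_protein(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name} is empty")
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"{name} contains illegal characters: {sorted(bad)}")
    return seq


@dataclass
class AlignmentResult:
    score: float
    coverage1: float
    coverage2: float
    aligned_columns: int


def global_align(
    seq1: str, seq2: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> AlignmentResult:
    """Optimal global alignment score and mutual coverage under BLOSUM62.

    Coverage counts residue-residue aligned columns only (gap columns are
    excluded from the numerator); denominators are the full protein lengths.
    """
    seq1 = _validate_protein(seq1, "seq1")
    seq2 = _validate_protein(seq2, "seq2")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(seq1, seq2)[0]
    blocks1, _ = aln.aligned
    cols = int(sum(b - a for a, b in blocks1))
    return AlignmentResult(
        score=float(aln.score),
        coverage1=cols / len(seq1),
        coverage2=cols / len(seq2),
        aligned_columns=cols,
    )


def read_proteome(path: str) -> Dict[str, str]:
    seqs = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq)
    return seqs


def detect_paralog_pairs(
    proteome: Mapping[str, str],
    min_coverage: float = 0.4,
    min_score: float = 50.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> pd.DataFrame:
    """All-vs-all paralog candidates: coverage > min_coverage for both, score >= min_score.

    Returns one row per unordered pair (lexicographically canonical), columns
    gene1, gene2, score, coverage1, coverage2.
    """
    ids = list(proteome)
    if len(ids) < 2:
        raise ValueError("paralog detection needs at least 2 sequences")
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            res = global_align(proteome[a], proteome[b], gap_open, gap_extend)
            if res.coverage1 > min_coverage and res.coverage2 > min_coverage and res.score >= min_score:
                rows.append((a, b, res.score, res.coverage1, res.coverage2))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "score", "coverage1", "coverage2"])


def classify_duplication_type(
    pairs: pd.DataFrame,
    subgenome_map: pd.DataFrame,
    tandem_window: int = 5,
) -> pd.DataFrame:
    """Assign WGD / tandem / inserted to each pair from the synteny map.

    WGD: members on the homeologous maize1/maize2 copies of one block.
    Tandem: members in the same block and subgenome within ``tandem_window``
    intervening genes. Inserted: everything else, including pairs with a
    non-syntenic or unplaced member (flagged ``unplaced``).
    """
    info: Dict[str, Tuple[str, str, str, int]] = {}
    order: Dict[Tuple[str, str], Dict[str, int]] = {}
    placed = subgenome_map[subgenome_map["block_id"] != "."]
    for (block, sub), grp in placed.groupby(["block_id", "subgenome"], sort=True):
        ranks = {g: r for r, g in enumerate(grp.sort_values("start")["gene_id"])}
        order[(block, sub)] = ranks
    for rec in subgenome_map.itertuples(index=False):
        info[rec.gene_id] = (rec.subgenome, rec.block_id, rec.chrom, rec.start)

    types: List[str] = []
    unplaced_flags: List[bool] = []
    for rec in pairs.itertuples(index=False):
        i1, i2 = info.get(rec.gene1), info.get(rec.gene2)
        unplaced = i1 is None or i2 is None
        if unplaced or i1[1] == "." or i2[1] == ".":
            types.append("inserted")
            unplaced_flags.append(unplaced)
            continue
        sub1, blk1, _, _ = i1
        sub2, blk2, _, _ = i2
        if blk1 == blk2 and {sub1, sub2} == {"maize1", "maize2"}:
            types.append("WGD")
        elif blk1 == blk2 and sub1 == sub2:
            ranks = order[(blk1, sub1)]
            gap = abs(ranks[rec.gene1] - ranks[rec.gene2]) - 1
            types.append("tandem" if gap <= tandem_window else "inserted")
        else:
            types.append("inserted")
        unplaced_flags.append(False)
    out = pairs.copy()
    out["dup_type"] = types
    out["unplaced"] = unplaced_flags
    return out
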