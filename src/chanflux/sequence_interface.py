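"""Pairwise sequence comparison of channel paralogs.

Global (Needleman-Wunsch) alignment with affine gaps quantifies how
similar two channel sequences are — percent identity and percent
similarity over the full alignment length, EMBOSS-needle style — and
maps residue numbering between paralogs so that interface positions
(e.g. an Ile in one sequence opposite an Ala in the other) can be
compared across systems.

The dynamic programming is delegated to Biopython's PairwiseAligner; the
scoring conventions are fixed here: BLOSUM62, gap open 10.0 (first
gapped position), gap extend 0.5, end gaps penalised by default
(configurable), unknown residue X scored 0 against everything.
Identity% counts identical columns / alignment length (gaps included in
the denominator); similarity% additionally counts columns whose
substitution score is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InputError, ParameterError

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ScoredAlignment:
    """A global pairwise alignment with EMBOSS-style summary statistics."""

    aligned_seq1: str
    aligned_seq2: str
    score: float
    identity_pct: float
    similarity_pct: float
    matrix_name: str

    def __post_init__(self):
        if len(self.aligned_seq1) != len(self.aligned_seq2):
            raise InputError("gapped sequences must have equal length")

    @property
    def length(self) -> int:
        return len(self.aligned_seq1)

    def column_positions(self) -> List[Tuple[int | None, int | None]]:
        """1-based residue numbers (pos1, pos2) per column; None at gaps."""
        out, p1, p2 = [], 0, 0
        for a, b in zip(self.aligned_seq1, self.aligned_seq2):
            p1 += a != "-"
            p2 += b != "-"
            out.append((p1 if a != "-" else None, p2 if b != "-" else None))
        return out

    def position_map(self) -> Dict[int, int]:
        """seq1 residue number -> seq2 residue number for aligned columns."""
        return {
            p1: p2
            for p1, p2 in self.column_positions()
            if p1 is not None and p2 is not None
        }


def read_fasta(path) -> Dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def _validate(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = [i + 1 for i, c in enumerate(seq) if c not in VALID_RESIDUES]
    if not seq:
        raise InputError(f"{label} is empty")
    if bad:
        raise InputError(f"{label} has illegal characters at positions {bad}")
    return seq


def _load_matrix(name: str):
    m = substitution_matrices.load(name)
    # X is tolerated and scored 0 against everything
    m = m.copy()
    if "X" in m.alphabet:
        xi = m.alphabet.index("X")
        m[xi, :] = 0.0
        m[:, xi] = 0.0
    return m


def needleman_wunsch_align(
    seq1: str,
    seq2: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    penalize_end_gaps: bool = True,
) -> ScoredAlignment:
    """Optimal global alignment under affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  End
    gaps are penalised unless ``penalize_end_gaps=False`` (the EMBOSS
    ``-endweight false`` behaviour).
    """
    if gap_open < 0 or gap_extend < 0:
        raise ParameterError("gap penalties must be non-negative")
    s1 = _validate(seq1, "seq1")
    s2 = _validate(seq2, "seq2")
    sub = _load_matrix(matrix)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if not penalize_end_gaps:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aln = aligner.align(s1, s2)[0]
    g1, g2 = str(aln[0]), str(aln[1])

    ident = sim = 0
    for a, b in zip(g1, g2):
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
            sim += 1
        elif sub[a, b] > 0:
            sim += 1
    length = len(g1)
    return ScoredAlignment(
        aligned_seq1=g1,
        aligned_seq2=g2,
        score=float(aln.score),
        identity_pct=100.0 * ident / length,
        similarity_pct=100.0 * sim / length,
        matrix_name=matrix,
    )


@dataclass(frozen=True)
class DifferenceRecord:
    """One aligned column where the two sequences differ."""

    seq1_position: int | None  # 1-based; None when seq1 is gapped
    seq1_residue: str
    seq2_position: int | None
    seq2_residue: str


def interface_difference_positions(
    aln: ScoredAlignment, region: Tuple[int, int]
) -> List[DifferenceRecord]:
    """Columns within a seq1 position range where the residues differ.

    ``region`` is an inclusive 1-based (start, end) range on seq1 — e.g.
    a transmembrane segment.  Gapped columns inside the region count as
    differences.
    """
    start, end = region
    n1 = sum(c != "-" for c in aln.aligned_seq1)
    if not (1 <= start <= end <= n1):
        raise ParameterError(f"region {region} outside seq1 (length {n1})")
    records = []
    for (p1, p2), a, b in zip(
        aln.column_positions(), aln.aligned_seq1, aln.aligned_seq2
    ):
        if p1 is None or not (start <= p1 <= end):
            continue
        if a != b:
            records.append(
                DifferenceRecord(
                    seq1_position=p1, seq1_residue=a, seq2_position=p2, seq2_residue=b
                )
            )
    return records
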