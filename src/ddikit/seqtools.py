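"""Pairwise global alignment statistics and consensus-motif scanning.

Identity/similarity percentages follow the EMBOSS needle conventions:
BLOSUM62 with gap open 10 / extend 0.5 by default (a gap of length L
costs ``open + L*extend``), end gaps free, and percentages computed
over all aligned columns (gap columns included in the denominator;
configurable to gapless columns only). "Similar" means the
substitution score of the aligned pair is positive.

Motif scanning handles fixed-position/wildcard consensus patterns such
as the ubiquitin-interacting-motif signature L-x-x-A-x-x-x-S, reporting
every (possibly overlapping) match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from ddikit.io import SequenceRecord


@dataclass(frozen=True)
class MotifPattern:
    """Ordered position constraints: a fixed residue letter or None (wildcard)."""

    positions: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError("motif pattern must have length >= 2")
        if not any(p is not None for p in self.positions):
            raise ValueError("motif pattern needs at least one fixed position")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def parse(cls, text: str) -> "MotifPattern":
        """Parse ``"L,x,x,A,x,x,x,S"``, ``"L-x-x-A-x-x-x-S"`` or ``"LxxAxxxS"``
        (x/X/*/. = wildcard; in the compact form lower-case x is the wildcard)."""
        if "," in text or "-" in text:
            tokens = [t.strip() for t in text.replace("-", ",").split(",") if t.strip()]
            positions = tuple(
                None if t in ("x", "X", "*", ".") else t.upper() for t in tokens
            )
        else:
            positions = tuple(None if c in ("x", "*", ".") else c.upper() for c in text)
        return cls(positions)


@dataclass(frozen=True)
class MotifMatch:
    start: int  # 1-based
    substring: str


def scan_motif(seq: SequenceRecord | str, pattern: MotifPattern) -> list[MotifMatch]:
    """All (possibly overlapping) motif matches, ascending by position.

    A pattern longer than the sequence yields an empty result, not an error.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    n, m = len(residues), len(pattern)
    matches = []
    for i in range(n - m + 1):
        if all(p is None or residues[i + j] == p for j, p in enumerate(pattern.positions)):
            matches.append(MotifMatch(start=i + 1, substring=residues[i : i + m]))
    return matches


@dataclass
class PairwiseAlignment:
    """A global alignment with its score and derived percentages."""

    aligned_a: str
    aligned_b: str
    score: float
    matrix_name: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def ungapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    penalize_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment with affine gaps.

    A gap of length L costs ``gap_open + L * gap_extend`` (needle
    convention). With ``penalize_end_gaps=False`` (the needle default)
    terminal gaps are free. Ties among optimal alignments are broken
    deterministically (first optimal traceback reported).
    """
    seq_a = a.residues if isinstance(a, SequenceRecord) else a
    seq_b = b.residues if isinstance(b, SequenceRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    try:
        submat = substitution_matrices.load(matrix.upper())
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = submat
    # Biopython charges open on the first gap element; shift so a length-L
    # gap costs open + L*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if not penalize_end_gaps:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
        matrix_name=matrix.upper(),
    )


def identity_similarity(
    aln: PairwiseAlignment,
    matrix: str | None = None,
    include_gap_columns: bool = True,
) -> tuple[float, float]:
    """(percent identity, percent similarity) of a pairwise alignment.

    Identity = identical columns / denominator * 100; similarity adds
    columns whose substitution score is positive. The denominator is
    the full alignment length by default (needle convention) or only
    columns with residues on both sides when
    ``include_gap_columns=False``.
    """
    submat = substitution_matrices.load((matrix or aln.matrix_name).upper())
    identical = similar = gapless = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            continue
        gapless += 1
        if x == y:
            identical += 1
        if submat[x, y] > 0:
            similar += 1
    denom = aln.length if include_gap_columns else gapless
    if denom == 0:
        return 0.0, 0.0
    return 100.0 * identical / denom, 100.0 * similar / denom


def identity_between(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    include_gap_columns: bool = True,
) -> tuple[float, float]:
    """Convenience: align two sequences and return (identity %, similarity %)."""
    aln = global_align(a, b, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
    return identity_similarity(aln, include_gap_columns=include_gap_columns)
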