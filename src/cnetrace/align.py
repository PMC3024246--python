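"""Pairwise global alignment with affine gap penalties.

The pipeline compares each query species' region to the reference region
with a true global (end-gap-penalized) alignment, the classic affine-gap
dynamic programme.  A gap of length ``L`` costs ``gap_open + L * gap_extend``.
``N`` scores as a mismatch against everything, including another ``N``,
consistent with the identity rule used downstream.

The heavy lifting is done by Biopython's ``PairwiseAligner``; this module
wraps it with the package's scoring conventions and exposes the
reference-anchored coordinate projection the detection stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import RegionSequence

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "align_global",
    "project_to_reference",
    "alignment_fasta",
]

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class Scoring:
    """Match/mismatch/affine-gap scores (defaults: +2/-1, open -3, extend -1)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0

    def validate(self) -> None:
        if not (self.match > 0 >= self.mismatch):
            raise ValueError("scoring requires match > 0 >= mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap_open and gap_extend must be <= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Reference-anchored global alignment of two regions.

    ``ref_row`` and ``qry_row`` are equal-length gapped strings over
    ``{A,C,G,T,N,-}``; no column is a gap in both rows.
    """

    ref_species: str
    qry_species: str
    ref_row: str
    qry_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.qry_row):
            raise ValueError("alignment rows differ in length")
        for r, q in zip(self.ref_row, self.qry_row):
            if r == "-" and q == "-":
                raise ValueError("column gapped in both rows")

    @property
    def ref_seq(self) -> str:
        return self.ref_row.replace("-", "")

    @property
    def qry_seq(self) -> str:
        return self.qry_row.replace("-", "")

    @property
    def ref_length(self) -> int:
        return len(self.ref_row) - self.ref_row.count("-")

    def ref_coord_of_column(self) -> np.ndarray:
        """Per-column reference position; -1 for reference-gap columns."""
        cols = np.frombuffer(self.ref_row.encode(), dtype=np.uint8)
        is_base = cols != ord("-")
        coord = np.cumsum(is_base) - 1
        return np.where(is_base, coord, -1)

    def column_of_ref(self) -> np.ndarray:
        """Strictly increasing column index of each reference position."""
        cols = np.frombuffer(self.ref_row.encode(), dtype=np.uint8)
        return np.flatnonzero(cols != ord("-"))

    def match_columns(self) -> np.ndarray:
        """Boolean per column: both rows carry the same base in {A,C,G,T}."""
        r = np.frombuffer(self.ref_row.encode(), dtype=np.uint8)
        q = np.frombuffer(self.qry_row.encode(), dtype=np.uint8)
        acgt = np.isin(r, np.frombuffer(b"ACGT", dtype=np.uint8))
        return (r == q) & acgt


def _substitution_matrix(scoring: Scoring) -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            same_real = a == b and a != "N"
            m[a, b] = scoring.match if same_real else scoring.mismatch
    return m


def align_global(
    ref: RegionSequence | str,
    qry: RegionSequence | str,
    scoring: Scoring = Scoring(),
    ref_species: str | None = None,
    qry_species: str | None = None,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of query against reference.

    Accepts :class:`RegionSequence` objects or plain strings.  The
    traceback is deterministic (first alignment in the aligner's fixed
    enumeration order); ties in score do not affect the score itself,
    which is what downstream identity windows are computed from.
    """
    scoring.validate()
    if isinstance(ref, RegionSequence):
        ref_species = ref.species_id
        ref_seq = ref.seq
    else:
        ref_seq = ref.upper()
        ref_species = ref_species or "ref"
    if isinstance(qry, RegionSequence):
        qry_species = qry.species_id
        qry_seq = qry.seq
    else:
        qry_seq = qry.upper()
        qry_species = qry_species or "qry"
    if not ref_seq or not qry_seq:
        raise ValueError("cannot align an empty sequence")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(scoring)
    # length-L gap costs gap_open + L * gap_extend
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    result = aligner.align(ref_seq, qry_seq)
    best = result[0]
    return PairwiseAlignment(
        ref_species=ref_species,
        qry_species=qry_species,
        ref_row=str(best[0]),
        qry_row=str(best[1]),
        score=float(best.score),
    )


def project_to_reference(aln: PairwiseAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Map reference positions to alignment columns.

    Returns ``(column_of_ref, insertions_between)`` where
    ``column_of_ref[i]`` is the alignment column of reference position
    ``i`` (strictly increasing) and ``insertions_between[i]`` counts the
    query-only columns strictly between reference positions ``i`` and
    ``i + 1`` (length ``L - 1``).
    """
    col_of_ref = aln.column_of_ref()
    if col_of_ref.size == 0:
        return col_of_ref, np.zeros(0, dtype=int)
    gaps_between = np.diff(col_of_ref) - 1
    return col_of_ref, gaps_between


def alignment_fasta(aln: PairwiseAlignment) -> str:
    """Two-record gapped FASTA rendering of the alignment, for inspection."""
    return (
        f">{aln.ref_species}\n{aln.ref_row}\n"
        f">{aln.qry_species}\n{aln.qry_row}\n"
    )
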