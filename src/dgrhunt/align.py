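"""Local and global pairwise alignment with blast-like scoring.

The detection pipeline replaces external blastp/blastall calls with in-process
alignment.  Protein search uses Smith–Waterman with BLOSUM62 and affine gaps
(open 11, extend 1); DNA fragment comparison uses megablast-like weights
(match +2, mismatch -3, gap open 5, extend 2).  A gap of length k costs
``open + k * extend`` in both cases.  Significance of protein scores is
assessed with the Karlin–Altschul expectation E = K * m * n * exp(-lambda*S)
using the conventional gapped BLOSUM62 parameters (lambda = 0.267, K = 0.041);
the effective-length correction is omitted, which is adequate because only the
1e-10 decision boundary is consumed downstream.

Stop codons in translated frames are retained as ``*`` and scored so harshly
that an optimal local alignment never crosses one, mimicking a protein-level
search against stop-delimited ORFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

STOP_SCORE = -1000.0  # forbids local alignments from crossing a stop column

Interval = tuple[int, int]


@lru_cache(maxsize=None)
def protein_matrix() -> substitution_matrices.Array:
    """BLOSUM62 with X scored as the worst-case mismatch and '*' prohibitive.

    X arises from codons containing N; scoring it at the matrix minimum (-4)
    makes ambiguous positions maximally unfavourable without breaking an
    alignment outright.
    """
    m = substitution_matrices.load("BLOSUM62").copy()
    worst = float(np.min(np.array(m)))
    for ch in m.alphabet:
        m["X", ch] = worst
        m[ch, "X"] = worst
        m["*", ch] = STOP_SCORE
        m[ch, "*"] = STOP_SCORE
    return m


@lru_cache(maxsize=None)
def dna_matrix(match: float = 2.0, mismatch: float = -3.0) -> substitution_matrices.Array:
    """Megablast-like DNA matrix over ACGTN; N never matches anything."""
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


def _make_aligner(matrix, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = matrix
    # biopython charges open_gap_score on the first gapped position, so a gap
    # of length k costs open + k*extend under our convention.
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    al.mode = mode
    return al


@lru_cache(maxsize=None)
def _cached_aligner(kind: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    matrix = protein_matrix() if kind == "protein" else dna_matrix()
    return _make_aligner(matrix, gap_open, gap_extend, mode)


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment between two sequences.

    ``query_interval``/``target_interval`` delimit the aligned spans (0-based
    half-open); ``columns`` lists aligned positions as ``(qpos, tpos)`` with
    ``None`` marking a gap on that side.
    """

    score: float
    query_interval: Interval
    target_interval: Interval
    columns: tuple[tuple[int | None, int | None], ...]

    @property
    def aligned_columns(self) -> int:
        return len(self.columns)


def _columns_from_biopython(aln) -> tuple[tuple[int | None, int | None], ...]:
    cols: list[tuple[int | None, int | None]] = []
    blocks_q, blocks_t = aln.aligned
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if prev_q is not None:
            for q in range(prev_q, qs):
                cols.append((q, None))
            for t in range(prev_t, ts):
                cols.append((None, t))
        cols.extend((q, t) for q, t in zip(range(qs, qe), range(ts, te)))
        prev_q, prev_t = qe, te
    return tuple(cols)


def local_align(query: str, target: str, kind: str, gap_open: float, gap_extend: float,
                score_only: bool = False) -> LocalAlignment | float:
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    al = _cached_aligner(kind, gap_open, gap_extend, "local")
    if score_only:
        return float(al.score(query, target))
    alns = al.align(query, target)
    # alignments are lazily enumerated and co-optimal; take the first
    aln = alns[0] if alns.score > 0 else None
    if aln is None:
        return LocalAlignment(0.0, (0, 0), (0, 0), ())
    cols = _columns_from_biopython(aln)
    qpos = [q for q, _ in cols if q is not None]
    tpos = [t for _, t in cols if t is not None]
    return LocalAlignment(float(aln.score), (qpos[0], qpos[-1] + 1), (tpos[0], tpos[-1] + 1), cols)


def local_align_protein(query: str, target: str, gap_open: float = 11.0,
                        gap_extend: float = 1.0, score_only: bool = False):
    """Smith–Waterman on proteins under BLOSUM62; see module docstring."""
    return local_align(query, target, "protein", gap_open, gap_extend, score_only)


def local_align_dna(query: str, target: str, gap_open: float = 5.0,
                    gap_extend: float = 2.0, score_only: bool = False):
    return local_align(query, target, "dna", gap_open, gap_extend, score_only)


def global_align_dna(a: str, b: str, gap_open: float = 5.0, gap_extend: float = 2.0):
    """End-to-end alignment of two DNA strings; returns gapped row strings."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    al = _cached_aligner("dna", gap_open, gap_extend, "global")
    aln = al.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def evalue(score: float, query_len: int, target_len: int, db_size: int | None = None,
           lam: float = KA_LAMBDA, K: float = KA_K) -> float:
    """Karlin–Altschul expectation for a raw local-alignment score.

    ``db_size`` is the total residue count on the database side of the search;
    when omitted the single target's length is used.  E scales linearly with
    m*n and decreases monotonically in the score.
    """
    if query_len <= 0 or target_len <= 0 or (db_size is not None and db_size <= 0):
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("raw local alignment scores are non-negative")
    n = db_size if db_size is not None else target_len
    return K * query_len * n * math.exp(-lam * score)


def min_score_for_evalue(cutoff: float, query_len: int, db_size: int,
                         lam: float = KA_LAMBDA, K: float = KA_K) -> float:
    """Smallest raw score whose expectation is at or below *cutoff*."""
    return (math.log(K * query_len * db_size) - math.log(cutoff)) / lam
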