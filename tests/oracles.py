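"""Independent brute-force oracles for cross-checking the pipeline.

Everything here is written from first principles, separate from the package's
implementation paths: a plain three-matrix local-alignment DP, an
all-diagonals maximal-scoring-segment repeat scan (Ruzzo–Tompa), exhaustive
enumeration for codon repertoires, and a naive all-offsets motif matcher.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

_B62 = substitution_matrices.load("BLOSUM62")
_TABLE = unambiguous_dna_by_id[1]
_CODON_AA = dict(_TABLE.forward_table)
for _c in _TABLE.stop_codons:
    _CODON_AA[_c] = "*"

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------- alignment

def brute_local_affine(q: str, t: str, gap_open: float = 11.0,
                       gap_extend: float = 1.0, matrix=None) -> float:
    """Smith–Waterman score by direct DP; a gap of length k costs
    open + k*extend.  Written independently of the package's aligner."""
    matrix = matrix if matrix is not None else _B62
    n, m = len(q), len(t)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]   # best ending in a match/mismatch or fresh
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # best ending in a gap in q (t consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # best ending in a gap in t (q consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0.0, diag + float(matrix[q[i - 1], t[j - 1]]))
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


# -------------------------------------------------------------- repeat scan

def maximal_scoring_segments(scores: list[float]) -> list[tuple[int, int]]:
    """All maximal-scoring subsequences of a score vector (Ruzzo–Tompa)."""
    I: list[dict] = []
    cum = 0.0
    for i, s in enumerate(scores):
        left = cum
        cum += s
        if s <= 0:
            continue
        seg = {"s": i, "e": i + 1, "L": left, "R": cum}
        while True:
            j = None
            for idx in range(len(I) - 1, -1, -1):
                if I[idx]["L"] < seg["L"]:
                    j = idx
                    break
            if j is None or I[j]["R"] >= seg["R"]:
                I.append(seg)
                break
            seg = {"s": I[j]["s"], "e": seg["e"], "L": I[j]["L"], "R": seg["R"]}
            I = I[:j]
    return [(d["s"], d["e"]) for d in I]


def kadane_best_segment(scores: list[float]) -> float:
    """Maximum segment sum (0 if all segments are negative); used to vet the
    maximal-scoring-segment enumeration on random vectors."""
    best = cur = 0.0
    for s in scores:
        cur = max(0.0, cur + s)
        best = max(best, cur)
    return best


def _anchor_trim_bool(m: list[bool], anchor: int) -> tuple[int, int] | None:
    run = 0
    first = None
    for i, v in enumerate(m):
        run = run + 1 if v else 0
        if run >= anchor:
            first = i - anchor + 1
            break
    if first is None:
        return None
    run = 0
    for j in range(len(m) - 1, -1, -1):
        run = run + 1 if m[j] else 0
        if run >= anchor:
            return (first, j + anchor)
    return None


def brute_repeat_scan(seq: str, min_len: int, min_identity: float,
                      match: float = 2.0, mismatch: float = -3.0,
                      end_anchor: int = 8) -> set[tuple]:
    """All-diagonals gapless repeat-pair scan of one contig.

    For every alignment diagonal (direct) and anti-diagonal (inverted), all
    maximal-scoring segments are enumerated, trimmed to match-anchored ends,
    and kept when long and identical enough.  Pairs are canonicalised with
    copy A upstream; overlapping copies are excluded.  Returns a set of
    ``(a_start, a_end, b_start, b_end, orientation)`` tuples.
    """
    L = len(seq)
    x = np.frombuffer(seq.encode(), dtype="S1")
    y = np.frombuffer(rc(seq).encode(), dtype="S1")
    notn = x != b"N"
    pairs: set[tuple] = set()
    kern = np.ones(min(min_len, 200))
    # candidate prefilter: some window of length w with >= 0.6*w matches
    thresh = 0.6 * len(kern)

    def _segments(mvec: np.ndarray):
        if len(mvec) < min_len:
            return []
        if len(mvec) >= len(kern):
            if np.convolve(mvec.astype(float), kern, "valid").max() < thresh:
                return []
        scores = np.where(mvec, match, mismatch).tolist()
        out = []
        mlist = mvec.tolist()
        for s, e in maximal_scoring_segments(scores):
            kept = _anchor_trim_bool(mlist[s:e], end_anchor)
            if kept is None:
                continue
            ks, ke = s + kept[0], s + kept[1]
            if ke - ks < min_len:
                continue
            ident = sum(mlist[ks:ke]) / (ke - ks)
            if ident + 1e-9 >= min_identity:
                out.append((ks, ke))
        return out

    for d in range(1, L):
        if L - d < min_len:
            break
        mvec = (x[:-d] == x[d:]) & notn[:-d] & notn[d:]
        for s, e in _segments(mvec):
            a, b = (s, e), (s + d, e + d)
            if a[1] <= b[0]:
                pairs.add((a[0], a[1], b[0], b[1], "direct"))
    for c in range(-(L - 1), L):
        n = L - abs(c)
        if n < min_len:
            continue
        xo, yo = max(0, -c), max(0, c)
        # an anti-diagonal pairs position i with forward position L-1-(i+c);
        # truncate at the self-pairing centre so each inverted pair appears
        # once (upstream copy first) and mirrored blocks cannot merge
        n = min(n, (L - c) // 2 - xo)
        if n < min_len:
            continue
        mvec = (x[xo:xo + n] == y[yo:yo + n]) & notn[xo:xo + n]
        for s, e in _segments(mvec):
            a = (xo + s, xo + e)
            b = (L - (yo + e), L - (yo + s))
            if a == b or (a[0] < b[1] and b[0] < a[1]):
                continue
            if a[0] > b[0]:
                a, b = b, a
            pairs.add((a[0], a[1], b[0], b[1], "inverted"))
    return pairs


# ---------------------------------------------------------------- diversity

def brute_repertoire(codons: list[str]) -> int:
    """Number of distinct stop-free peptides reachable by substituting every
    adenine of the concatenated template independently, by full enumeration."""
    seq = "".join(codons)
    a_pos = [i for i, b in enumerate(seq) if b == "A"]
    peptides = set()
    for combo in itertools.product("ACGT", repeat=len(a_pos)):
        variant = list(seq)
        for p, b in zip(a_pos, combo):
            variant[p] = b
        v = "".join(variant)
        pep = "".join(_CODON_AA[v[i:i + 3]] for i in range(0, len(v), 3))
        if "*" not in pep:
            peptides.add(pep)
    return len(peptides)


# --------------------------------------------------------------- motif scan

def brute_motif_find(protein: str, pattern: str) -> list[int]:
    """All offsets where the pattern (X = wildcard) matches, by direct check."""
    hits = []
    for off in range(len(protein) - len(pattern) + 1):
        if all(pc == "X" or protein[off + k] == pc for k, pc in enumerate(pattern)):
            hits.append(off)
    return hits


# ------------------------------------------------------------ dinucleotides

def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts
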