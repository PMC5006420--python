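"""Stage 2: windowed near-repeat discovery around RT hits.

The region around each RT hit (10 kb on each side) is fragmented into 200 bp
windows stepped by 50 bp; windows are compared all-vs-all in both
orientations, and window-level matches lying on a consistent alignment
diagonal are chained and refined into maximal candidate repeat pairs
(putative TR/VR).  A shared-k-mer prefilter skips the vast majority of
unrelated window pairs; any pair of windows sharing a homologous stretch of
the lengths this pipeline cares about (>= 50 bp at >= 80 % identity of
substitution-dominated divergence) shares 10-mers with overwhelming
probability.

Boundary refinement follows the local-alignment (score-maximal) convention of
blast-style searches: a merged repeat pair's extent is the maximum-scoring
local alignment of its neighbourhood under the DNA scores (match +2,
mismatch -3, affine gaps), which extends through the substitution-dominated
interior of a TR/VR pair (expected column score +1.5 at 90 % identity) but
stops within a few bases of the homology boundary (expected column score
-1.75 in unrelated flanks).  The brute-force oracle used in tests recovers
the same segments independently as maximal-scoring runs along every
alignment diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

from dgrhunt import align
from dgrhunt.core import Contig, Interval, interval_jaccard, intervals_overlap, revcomp
from dgrhunt.rt_search import RTHit


@dataclass(frozen=True)
class WindowFragment:
    contig_id: str
    interval: Interval

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class FragmentMatch:
    """A local alignment between two window fragments (genomic subspans).

    ``identity`` counts matches over all alignment columns, gaps included.
    For inverted matches ``interval_b`` is still a forward-strand interval.
    """

    interval_a: Interval
    interval_b: Interval
    orientation: str  # "direct" | "inverted"
    identity: float
    aligned_columns: int
    score: float


@dataclass(frozen=True)
class RepeatPair:
    """A merged, maximal candidate repeat pair with a column alignment.

    ``alignment`` lists columns as ``(base_a, base_b)`` with ``-`` for gaps;
    for inverted pairs ``base_b`` is the reverse complement of copy B, so the
    columns read colinearly with copy A.  ``identity`` is computed over
    columns excluding gaps and Ns, matching the mismatch classifier.
    """

    contig_id: str
    interval_a: Interval
    interval_b: Interval
    orientation: str
    alignment: tuple[tuple[str, str], ...]
    identity: float

    @property
    def aligned_columns(self) -> int:
        return len(self.alignment)


def fragment_windows(region: Interval, window: int = 200, step: int = 50) -> list[Interval]:
    """Sliding windows covering *region*: starts every *step*, last window
    truncated at the region end; a region not longer than the window yields a
    single window equal to the region."""
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    rs, re_ = region
    if re_ - rs <= window:
        return [(rs, re_)]
    out = []
    s = rs
    while True:
        e = min(s + window, re_)
        out.append((s, e))
        if e == re_:
            break
        s += step
        if s >= re_:
            break
    return out


def make_fragments(contig: Contig, region: Interval, window: int = 200,
                   step: int = 50) -> list[WindowFragment]:
    return [WindowFragment(contig.id, iv) for iv in fragment_windows(region, window, step)]


def scan_flanks(contig: Contig, rt_hit: RTHit, flank: int = 10_000) -> Interval:
    """The RT interval padded by *flank* on both sides, clipped to the contig."""
    s, e = rt_hit.nt_interval
    return (max(0, s - flank), min(len(contig), e + flank))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i:i + k]}


def compare_fragments(
    fragments: list[WindowFragment],
    contig: Contig,
    min_identity: float = 0.8,
    min_score: float = 40.0,
    seed_k: int = 12,
) -> list[FragmentMatch]:
    """Compare every pair of non-overlapping fragments in both orientations.

    Pairs sharing no *seed_k*-mer (in the relevant orientation) are skipped
    without alignment.  Matches are returned with ``interval_a`` upstream of
    ``interval_b``.
    """
    if len(fragments) < 2:
        return []
    seqs = [contig.seq[f.interval[0]:f.interval[1]] for f in fragments]
    fwd = [_kmers(s, seed_k) for s in seqs]
    rc = [_kmers(revcomp(s), seed_k) for s in seqs]

    index: dict[str, list[int]] = {}
    for i, ks in enumerate(fwd):
        for km in ks:
            index.setdefault(km, []).append(i)

    cand: set[tuple[int, int, str]] = set()
    for i in range(len(fragments)):
        for km in fwd[i]:
            for j in index.get(km, ()):
                if j != i:
                    cand.add((min(i, j), max(i, j), "direct"))
        for km in rc[i]:
            for j in index.get(km, ()):
                if j != i:
                    cand.add((min(i, j), max(i, j), "inverted"))

    out: list[FragmentMatch] = []
    for i, j, orient in sorted(cand):
        fa, fb = fragments[i], fragments[j]
        if intervals_overlap(fa.interval, fb.interval):
            continue
        sa = seqs[i]
        sb = seqs[j] if orient == "direct" else revcomp(seqs[j])
        if align.local_align_dna(sa, sb, score_only=True) < min_score:
            continue
        la = align.local_align_dna(sa, sb)
        if la.score < min_score or not la.columns:
            continue
        matches = sum(
            1 for q, t in la.columns
            if q is not None and t is not None and sa[q] == sb[t] and sa[q] != "N"
        )
        ident = matches / len(la.columns)
        if ident < min_identity:
            continue
        a_iv = (fa.interval[0] + la.query_interval[0], fa.interval[0] + la.query_interval[1])
        if orient == "direct":
            b_iv = (fb.interval[0] + la.target_interval[0], fb.interval[0] + la.target_interval[1])
        else:
            n = len(sb)
            ts, te = la.target_interval
            b_iv = (fb.interval[0] + n - te, fb.interval[0] + n - ts)
        out.append(FragmentMatch(a_iv, b_iv, orient, ident, len(la.columns), la.score))
    return out


def _align_columns(sa: str, sb: str) -> list[tuple[int | None, int | None]]:
    """Global alignment columns of two DNA strings as (a_pos, b_pos) pairs."""
    ga, gb, _ = align.global_align_dna(sa, sb)
    cols = []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        pa = ia if ca != "-" else None
        pb = ib if cb != "-" else None
        cols.append((pa, pb))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return cols


def anchor_trim(match_vector: list[bool], end_anchor: int) -> Interval | None:
    """Trim a column match vector so both ends sit on a run of at least
    *end_anchor* consecutive matches; returns the retained column range.

    This is the canonical end rule for repeat pairs: score-maximal local
    alignments can pick up a few chance matches (possibly bracketing a chance
    mismatch) beyond the true homology boundary, and requiring an anchored
    end removes that boundary noise deterministically.  The brute-force
    oracle applies the same rule.
    """
    if end_anchor <= 1:
        return (0, len(match_vector)) if match_vector else None
    run = 0
    first = None
    for i, v in enumerate(match_vector):
        run = run + 1 if v else 0
        if run >= end_anchor:
            first = i - end_anchor + 1
            break
    if first is None:
        return None
    run = 0
    for j in range(len(match_vector) - 1, -1, -1):
        run = run + 1 if match_vector[j] else 0
        if run >= end_anchor:
            return (first, j + end_anchor)
    return None


def _best_gapless_segment(x: str, other: str, dd: int, i0: int, i1: int,
                          end_anchor: int, match: float = 2.0,
                          mismatch: float = -3.0):
    """Maximum-scoring gapless run along one diagonal, anchor-trimmed.

    Position i of *x* pairs with position i+dd of *other*; the scan covers
    i in [i0, i1).  Returns (score, start, end) in x coordinates, or None.
    """
    mvec = [
        x[i] == other[i + dd] and x[i] != "N" and other[i + dd] != "N"
        for i in range(i0, i1)
    ]
    best_sum = cur = 0.0
    cur_start = 0
    best_seg = None
    for k, v in enumerate(mvec):
        s = match if v else mismatch
        if cur <= 0:
            cur = 0.0
            cur_start = k
        cur += s
        if cur > best_sum:
            best_sum = cur
            best_seg = (cur_start, k + 1)
    if best_seg is None:
        return None
    s, e = best_seg
    kept = anchor_trim(mvec[s:e], end_anchor)
    if kept is None:
        return None
    ks, ke = s + kept[0], s + kept[1]
    score = sum(match if v else mismatch for v in mvec[ks:ke])
    return score, i0 + ks, i0 + ke


def _finalize_pair(contig: Contig, a_iv: Interval, b_iv: Interval,
                   orientation: str, end_anchor: int = 8) -> RepeatPair | None:
    """Align the two copies end-to-end, trim to anchored ends, and package.

    Returns None when no anchored extent exists.
    """
    sa = contig.seq[a_iv[0]:a_iv[1]]
    sb = contig.seq[b_iv[0]:b_iv[1]]
    if orientation == "inverted":
        sb = revcomp(sb)
    cols = _align_columns(sa, sb)
    mvec = [
        pa is not None and pb is not None and sa[pa] == sb[pb] and sa[pa] != "N"
        for pa, pb in cols
    ]
    kept = anchor_trim(mvec, end_anchor)
    if kept is None:
        return None
    cols = cols[kept[0]:kept[1]]
    apos = [pa for pa, _ in cols if pa is not None]
    bpos = [pb for _, pb in cols if pb is not None]
    if not apos or not bpos:
        return None
    new_a = (a_iv[0] + apos[0], a_iv[0] + apos[-1] + 1)
    if orientation == "direct":
        new_b = (b_iv[0] + bpos[0], b_iv[0] + bpos[-1] + 1)
    else:
        nb = b_iv[1] - b_iv[0]
        new_b = (b_iv[0] + nb - (bpos[-1] + 1), b_iv[0] + nb - bpos[0])
    pairs = tuple(
        (sa[pa] if pa is not None else "-", sb[pb] if pb is not None else "-")
        for pa, pb in cols
    )
    informative = [(a, b) for a, b in pairs if a != "-" and b != "-" and "N" not in (a, b)]
    ident = (sum(1 for a, b in informative if a == b) / len(informative)) if informative else 0.0
    return RepeatPair(contig.id, new_a, new_b, orientation, pairs, ident)


def chain_and_merge(
    matches: list[FragmentMatch],
    contig: Contig,
    min_identity: float = 0.8,
    min_length: int = 50,
    merge_tol: int = 10,
    window: int = 200,
    end_anchor: int = 8,
) -> list[RepeatPair]:
    """Consolidate window-level matches into maximal repeat pairs.

    Matches of one orientation whose alignment diagonals agree within
    ``merge_tol`` and whose footprints are near-contiguous are merged; each
    merged core is extended by up to one window on each side and re-aligned
    locally, so the reported pair is the score-maximal repeat segment (see
    module docstring).  Pairs shorter than ``min_length`` aligned columns or
    below ``min_identity`` are dropped.
    """
    L = len(contig)

    def diag(m: FragmentMatch) -> int:
        if m.orientation == "direct":
            return m.interval_b[0] - m.interval_a[0]
        return m.interval_a[0] + m.interval_b[1]

    clusters: list[dict] = []
    for m in sorted(matches, key=lambda m: (m.orientation, diag(m), m.interval_a)):
        placed = False
        for cl in clusters:
            if cl["orient"] != m.orientation:
                continue
            if abs(diag(m) - cl["diag"]) > merge_tol:
                continue
            if m.interval_a[0] > cl["a"][1] + window or m.interval_a[1] < cl["a"][0] - window:
                continue
            cl["a"] = (min(cl["a"][0], m.interval_a[0]), max(cl["a"][1], m.interval_a[1]))
            cl["b"] = (min(cl["b"][0], m.interval_b[0]), max(cl["b"][1], m.interval_b[1]))
            placed = True
            break
        if not placed:
            clusters.append({"orient": m.orientation, "diag": diag(m),
                             "a": m.interval_a, "b": m.interval_b})

    rcseq = revcomp(contig.seq)
    pairs: list[RepeatPair] = []
    for cl in clusters:
        (as_, ae), (bs, be) = cl["a"], cl["b"]
        lo = max(0, as_ - window)
        hi = min(L, ae + window)
        best = None  # (score, -length, diagonal, a_interval)
        if cl["orient"] == "direct":
            diags = range(cl["diag"] - merge_tol, cl["diag"] + merge_tol + 1)
        else:
            diags = range(L - cl["diag"] - merge_tol, L - cl["diag"] + merge_tol + 1)
        for dd in diags:
            i0 = max(lo, -dd)
            i1 = min(hi, L - dd)
            if cl["orient"] == "direct":
                if dd == 0:
                    continue
                other = contig.seq
            else:
                # stop at the anti-diagonal's self-pairing centre so a copy
                # never aligns past its own mirror image
                i1 = min(i1, (L - dd) // 2)
                other = rcseq
            if i1 - i0 < min_length:
                continue
            seg = _best_gapless_segment(contig.seq, other, dd, i0, i1, end_anchor)
            if seg is None:
                continue
            score, s, e = seg
            if best is None or (score, e - s) > (best[0], best[3] - best[2]):
                best = (score, dd, s, e)
        if best is None:
            continue
        _, dd, s, e = best
        orient = cl["orient"]
        a_iv = (s, e)
        if orient == "direct":
            b_iv = (s + dd, e + dd)
        else:
            b_iv = (L - (e + dd), L - (s + dd))
        if a_iv == b_iv or intervals_overlap(a_iv, b_iv):
            continue
        if a_iv[0] > b_iv[0]:
            a_iv, b_iv = b_iv, a_iv
        pair = _finalize_pair(contig, a_iv, b_iv, orient, end_anchor)
        if pair is not None and pair.identity >= min_identity \
                and pair.aligned_columns >= min_length:
            pairs.append(pair)

    # non-redundant: exact dedupe, then drop pairs contained in a longer pair
    seen = {}
    for p in pairs:
        key = (p.interval_a, p.interval_b, p.orientation)
        if key not in seen:
            seen[key] = p
    uniq = list(seen.values())
    kept: list[RepeatPair] = []
    for p in sorted(uniq, key=lambda p: -p.aligned_columns):
        redundant = any(
            q.orientation == p.orientation
            and (
                (q.interval_a[0] <= p.interval_a[0] and p.interval_a[1] <= q.interval_a[1]
                 and q.interval_b[0] <= p.interval_b[0] and p.interval_b[1] <= q.interval_b[1])
                or (interval_jaccard(q.interval_a, p.interval_a) >= 0.9
                    and interval_jaccard(q.interval_b, p.interval_b) >= 0.9)
            )
            for q in kept
        )
        if not redundant:
            kept.append(p)
    kept.sort(key=lambda p: (p.interval_a, p.interval_b))
    return kept


def find_repeat_pairs(
    contig: Contig,
    region: Interval | None = None,
    window: int = 200,
    step: int = 50,
    min_identity: float = 0.8,
    min_score: float = 40.0,
    min_length: int = 50,
    merge_tol: int = 10,
    end_anchor: int = 8,
) -> list[RepeatPair]:
    """Windowed repeat scan of *region* (whole contig by default)."""
    if region is None:
        region = (0, len(contig))
    frags = make_fragments(contig, region, window, step)
    matches = compare_fragments(frags, contig, min_identity=min_identity, min_score=min_score)
    return chain_and_merge(matches, contig, min_identity=min_identity,
                           min_length=min_length, merge_tol=merge_tol, window=window,
                           end_anchor=end_anchor)
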