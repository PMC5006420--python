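"""Synthetic contigs with planted, ground-truthed DGRs.

The generator emulates the canonical DGR architecture: a variable-protein ORF
whose variable region (VR) derives from a nearby invariant template region
(TR) by adenine-specific substitution, a shared invariant terminal segment
(IMH in the VR, IMH* in the TR, modelled here as an identical 3' segment), a
perfect-palindrome hairpin downstream of the VR, and a reverse-transcriptase
gene, all within a few kb of each other on one contig.  Matched null contigs
are dinucleotide-preserving shuffles.

Every planted feature is reported in a :class:`TruthRecord` with exact
coordinates, so downstream detection stages can be validated without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from dgrhunt.core import (
    AA_TO_CODONS,
    CODON_TO_AA,
    STOP_CODONS,
    Contig,
    Interval,
    revcomp,
    validate_protein,
)

_DEFAULT_RT = None  # loaded lazily from the bundled toy reference set


def _default_rt_protein() -> str:
    global _DEFAULT_RT
    if _DEFAULT_RT is None:
        from dgrhunt.rt_search import load_toy_rt_references

        _DEFAULT_RT = load_toy_rt_references()[0].protein
    return _DEFAULT_RT


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one planted DGR; defaults give a ~91 % identical TR/VR
    pair (8 substitutions over 90 bp), matching the typical ~90 % identity of
    natural TR/VR repeats."""

    contig_length: int = 50_000
    rt_protein: str | None = None
    tr_length: int = 90
    n_adenine_subs: int = 7
    n_non_adenine_subs: int = 1
    tr_vr_gap: int = 2000
    imh_length: int = 20
    start_margin: int = 8
    hairpin_stem: int = 12
    hairpin_loop: int = 6
    background_gc: float = 0.40
    seed: int = 0

    def resolved_rt_protein(self) -> str:
        return self.rt_protein if self.rt_protein is not None else _default_rt_protein()


@dataclass(frozen=True)
class TruthRecord:
    """Exact coordinates (0-based half-open) of every planted feature."""

    contig_id: str
    rt_interval: Interval
    rt_strand: str
    tr_interval: Interval
    vr_interval: Interval
    imh_interval: Interval
    hairpin_interval: Interval
    substituted_positions: tuple[tuple[int, str, str], ...]


def make_rt_gene(rt_protein: str, seed: int) -> str:
    """Reverse-translate a protein into a codon sequence (no stop appended).

    Codons are drawn uniformly over synonymous choices with a seeded RNG, so
    the result is deterministic and translates exactly back to *rt_protein*.
    """
    validate_protein(rt_protein)
    rng = np.random.default_rng(seed)
    return "".join(
        AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in rt_protein
    )


def _creates_stop(seq: list[str], pos: int, base: str, frame: int | None) -> bool:
    if frame is None:
        return False
    cstart = pos - ((pos - frame) % 3)
    if cstart < frame or cstart + 3 > len(seq):
        return False
    codon = seq[cstart:cstart + 3]
    codon[pos - cstart] = base
    return "".join(codon) in STOP_CODONS


def mutagenize_tr(
    tr: str,
    n_adenine_subs: int,
    n_non_adenine_subs: int,
    imh_length: int,
    seed: int,
    frame: int | None = None,
    start_margin: int = 0,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Derive a VR from a TR by adenine-specific (plus a few non-adenine)
    substitutions, keeping the terminal *imh_length* bases invariant.

    Adenine substitutions replace an A with C/G/T; non-adenine substitutions
    replace C/G/T with one of the other two non-A bases, so recounting column
    types from the two strings reproduces the requested counts exactly.  When
    *frame* is given, substitutions that would create an in-frame stop codon
    are re-drawn, so a stop-free TR yields a stop-free VR.  *start_margin*
    keeps the leading bases invariant as well, so the planted repeat's extent
    is sharply defined at both ends (the IMH plays that role at the 3' end).
    """
    rng = np.random.default_rng(seed)
    mutable_end = len(tr) - imh_length
    if mutable_end < 0:
        raise ValueError("imh_length exceeds TR length")
    a_pool = [i for i in range(start_margin, mutable_end) if tr[i] == "A"]
    b_pool = [i for i in range(start_margin, mutable_end) if tr[i] in "CGT"]
    if n_adenine_subs > len(a_pool):
        raise ValueError(
            f"requested {n_adenine_subs} adenine substitutions but only "
            f"{len(a_pool)} adenines lie outside the IMH segment"
        )
    if n_non_adenine_subs > len(b_pool):
        raise ValueError(
            f"requested {n_non_adenine_subs} non-adenine substitutions but only "
            f"{len(b_pool)} non-adenine bases lie outside the IMH segment"
        )
    vr = list(tr)
    subs: list[tuple[int, str, str]] = []

    def _apply(pool: list[int], count: int, targets_for) -> None:
        order = list(rng.permutation(len(pool)))
        placed = 0
        for idx in order:
            if placed == count:
                break
            pos = pool[idx]
            targets = targets_for(tr[pos])
            rng.shuffle(targets)
            for t in targets:
                if not _creates_stop(vr, pos, t, frame):
                    vr[pos] = t
                    subs.append((pos, tr[pos], t))
                    placed += 1
                    break
        if placed < count:
            raise ValueError("could not place all requested substitutions without creating stops")

    _apply(a_pool, n_adenine_subs, lambda b: [c for c in "CGT"])
    _apply(b_pool, n_non_adenine_subs, lambda b: [c for c in "CGT" if c != b])
    subs.sort()
    return "".join(vr), subs


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_stopfree_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    out = []
    while len(out) < n_codons:
        codon = _random_dna(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _draw_tr(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """A TR that is stop-free in frame 0 and has enough mutable positions."""
    for _ in range(500):
        tr = _random_stopfree_codons(rng, cfg.tr_length // 3, cfg.background_gc)
        tr += _random_dna(rng, cfg.tr_length % 3, cfg.background_gc)
        mutable = tr[cfg.start_margin: len(tr) - cfg.imh_length]
        if (mutable.count("A") >= cfg.n_adenine_subs
                and sum(mutable.count(b) for b in "CGT") >= cfg.n_non_adenine_subs):
            return tr
    raise ValueError("could not draw a TR satisfying the substitution budget")


def plant_dgr(config: GeneratorConfig) -> tuple[Contig, TruthRecord]:
    """Build one contig containing, in order: VR (inside a stop-free ORF),
    hairpin, TR, RT gene, embedded in i.i.d. background sequence.

    Raises ValueError if the features cannot be placed inside the contig.
    """
    cfg = config
    if cfg.tr_length % 3:
        raise ValueError("tr_length must be a multiple of 3 so the VR sits in frame")
    rng = np.random.default_rng(cfg.seed)
    protein = cfg.resolved_rt_protein()

    tr = _draw_tr(rng, cfg)
    vr, subs = mutagenize_tr(
        tr, cfg.n_adenine_subs, cfg.n_non_adenine_subs, cfg.imh_length,
        seed=int(rng.integers(2**31)), frame=0, start_margin=cfg.start_margin,
    )

    lead = _random_stopfree_codons(rng, 6, cfg.background_gc)
    tail = _random_stopfree_codons(rng, 6, cfg.background_gc)
    orf = "ATG" + lead + vr + tail + "TAA"
    vr_off_in_orf = 3 + len(lead)

    stem = _random_dna(rng, cfg.hairpin_stem, cfg.background_gc)
    loop = _random_dna(rng, cfg.hairpin_loop, cfg.background_gc)
    hairpin = stem + loop + revcomp(stem)

    hairpin_offset = 30  # bp between VR ORF end and hairpin start
    rt_spacer = 300      # bp between TR end and RT gene start
    gap_after_hairpin = cfg.tr_vr_gap - hairpin_offset - len(hairpin)
    if gap_after_hairpin < 0:
        raise ValueError("tr_vr_gap too small to hold the hairpin element")

    rt_gene = make_rt_gene(protein, seed=int(rng.integers(2**31))) + "TAA"

    block_parts = [
        orf,
        _random_dna(rng, hairpin_offset, cfg.background_gc),
        hairpin,
        _random_dna(rng, gap_after_hairpin, cfg.background_gc),
        tr,
        _random_dna(rng, rt_spacer, cfg.background_gc),
        rt_gene,
    ]
    block = "".join(block_parts)
    if len(block) > cfg.contig_length:
        raise ValueError(
            f"planted features ({len(block)} bp) exceed contig_length {cfg.contig_length}"
        )
    # every feature must stay within 10 kb of the RT gene
    rt_off_in_block = len(block) - len(rt_gene)
    if rt_off_in_block > 10_000:
        raise ValueError("VR/TR would fall more than 10 kb from the RT gene")

    start = int(rng.integers(cfg.contig_length - len(block) + 1))
    pre = _random_dna(rng, start, cfg.background_gc)
    post = _random_dna(rng, cfg.contig_length - start - len(block), cfg.background_gc)
    seq = pre + block + post

    contig_id = f"synthetic_dgr_seed{cfg.seed}"
    vr_start = start + vr_off_in_orf
    hp_start = start + len(orf) + hairpin_offset
    tr_start = hp_start + len(hairpin) + gap_after_hairpin
    rt_start = start + rt_off_in_block
    truth = TruthRecord(
        contig_id=contig_id,
        rt_interval=(rt_start, rt_start + len(rt_gene)),
        rt_strand="+",
        tr_interval=(tr_start, tr_start + len(tr)),
        vr_interval=(vr_start, vr_start + len(vr)),
        imh_interval=(vr_start + len(vr) - cfg.imh_length, vr_start + len(vr)),
        hairpin_interval=(hp_start, hp_start + len(hairpin)),
        substituted_positions=tuple(subs),
    )
    return Contig(contig_id, seq, source="synthetic"), truth


def swap_repeat_copies(contig: Contig, truth: TruthRecord) -> tuple[Contig, TruthRecord]:
    """Exchange the sequences at the TR and VR intervals (equal length), used
    to test that detection and TR/VR labelling are order-agnostic."""
    (ts, te), (vs, ve) = truth.tr_interval, truth.vr_interval
    s = contig.seq
    tr_seq, vr_seq = s[ts:te], s[vs:ve]
    lo, hi = sorted([(ts, te, vr_seq), (vs, ve, tr_seq)])
    new = s[: lo[0]] + lo[2] + s[lo[1]: hi[0]] + hi[2] + s[hi[1]:]
    swapped = replace(truth, tr_interval=truth.vr_interval, vr_interval=truth.tr_interval)
    return Contig(contig.id + "_swapped", new, source="synthetic"), swapped


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle: a uniform random sequence with exactly the
    same dinucleotide (and hence mononucleotide) counts, same first and last
    base.  Uses rejection sampling of the last-edge arborescence."""
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(10_000):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for DNA
        raise RuntimeError("dinucleotide shuffle failed to find an arborescence")
    pools: dict[str, list[str]] = {}
    for v, succs in edges.items():
        pool = list(succs)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        pools[v] = pool
    out = [seq[0]]
    idx = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_null_contig(length: int, source_contig: Contig, seed: int) -> Contig:
    """Negative-control contig matched in composition to *source_contig*.

    When *length* equals the source length this is an exact
    dinucleotide-preserving shuffle; otherwise the sequence is sampled from
    the source's first-order Markov (dinucleotide transition) model.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    if length == len(source_contig.seq):
        seq = _dinucleotide_shuffle(source_contig.seq, rng)
    else:
        src = source_contig.seq
        bases = "ACGTN"
        counts = {a: np.array([1e-9] * 5) for a in bases}
        for a, b in zip(src, src[1:]):
            counts[a][bases.index(b)] += 1
        cur = src[0]
        out = [cur]
        for _ in range(length - 1):
            p = counts[cur] / counts[cur].sum()
            cur = bases[rng.choice(5, p=p)]
            out.append(cur)
        seq = "".join(out)
    return Contig(f"null_{source_contig.id}_seed{seed}", seq, source="synthetic")
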