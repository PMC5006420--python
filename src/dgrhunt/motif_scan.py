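"""Conserved-motif classifier for AvpA-like DGR variable proteins.

Three short consensus motifs distinguish the AvpA-like family of C-type
lectin fold variable proteins: GXXVVVYAH (beta3 strand), HPXXXPFXG (a short
helix in the large insert packing against beta3) and RFXGV (the beta5 strand,
encoded by the IMH element).  X is a single-residue wildcard; the motifs must
occur in this order along the chain for a protein to be called AvpA-like.
Their reference positions in AvpA are residues 67-75, 139-147 and 205-209.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


@dataclass(frozen=True)
class MotifPattern:
    id: str
    pattern: str  # residues plus X as single-residue wildcard
    expected_order_rank: int

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError("motif patterns must be at least 3 residues")

    def regex(self) -> re.Pattern:
        body = "".join("[A-Z]" if c == "X" else re.escape(c) for c in self.pattern)
        # lookahead so overlapping occurrences are all reported
        return re.compile(f"(?=({body}))")


AVPA_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("GXXVVVYAH", "GXXVVVYAH", 1),
    MotifPattern("HPXXXPFXG", "HPXXXPFXG", 2),
    MotifPattern("RFXGV", "RFXGV", 3),
)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_id: str
    start: int  # 0-based offset in the protein
    matched: str


@dataclass(frozen=True)
class AvpaClassification:
    protein_id: str
    is_avpa_like: bool
    found_motifs: tuple[str, ...]
    missing_motifs: tuple[str, ...]
    order_violation: bool
    hits: tuple[MotifHit, ...]
    c_terminal_rfxgv: MotifHit | None  # candidate IMH-encoded beta5 strand


def scan_motifs(protein: str, patterns: tuple[MotifPattern, ...] = AVPA_MOTIFS,
                protein_id: str = "") -> list[MotifHit]:
    """All occurrences of each pattern (overlaps allowed), sorted by start.

    An X in the protein is an unknown residue and matches only a pattern X
    (wildcard positions); it never satisfies a literal pattern residue.
    """
    hits = []
    for pat in patterns:
        for m in pat.regex().finditer(protein):
            hits.append(MotifHit(protein_id, pat.id, m.start(), m.group(1)))
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def _ordered_chain(hits_by_rank: list[list[MotifHit]], pattern_lengths: list[int]) -> bool:
    """True if one hit per motif can be chosen with each motif starting after
    the previous one ends (greedy earliest choice is optimal here)."""
    prev_end = -1
    for hits, plen in zip(hits_by_rank, pattern_lengths):
        starts = [h.start for h in hits if h.start > prev_end]
        if not starts:
            return False
        prev_end = min(starts) + plen - 1
    return True


def classify_avpa_like(protein: str, protein_id: str = "",
                       patterns: tuple[MotifPattern, ...] = AVPA_MOTIFS) -> AvpaClassification:
    """AvpA-like iff all three motifs occur in rank order without overlap."""
    ranked = sorted(patterns, key=lambda p: p.expected_order_rank)
    hits = scan_motifs(protein, patterns, protein_id)
    by_id: dict[str, list[MotifHit]] = {p.id: [] for p in ranked}
    for h in hits:
        by_id[h.motif_id].append(h)
    found = tuple(p.id for p in ranked if by_id[p.id])
    missing = tuple(p.id for p in ranked if not by_id[p.id])
    order_ok = not missing and _ordered_chain(
        [by_id[p.id] for p in ranked], [len(p.pattern) for p in ranked]
    )
    rfxgv = [h for h in hits if h.motif_id == ranked[-1].id]
    return AvpaClassification(
        protein_id=protein_id,
        is_avpa_like=order_ok,
        found_motifs=found,
        missing_motifs=missing,
        order_violation=bool(not missing and not order_ok),
        hits=tuple(hits),
        c_terminal_rfxgv=max(rfxgv, key=lambda h: h.start) if rfxgv else None,
    )
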