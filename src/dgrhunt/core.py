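"""Shared sequence primitives: contigs, intervals, the genetic code.

All genomic coordinates in this package are 0-based half-open tuples
``(start, end)`` on the forward strand; conversion to 1-based inclusive
happens only when writing GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"

_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _c in _TABLE.stop_codons:
    CODON_TO_AA[_c] = STOP
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _a in sorted(CODON_TO_AA.items()):
    if _a != STOP:
        AA_TO_CODONS.setdefault(_a, ())
        AA_TO_CODONS[_a] = AA_TO_CODONS[_a] + (_c,)
STOP_CODONS = frozenset(_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Interval = tuple[int, int]


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_dna(seq: str) -> str:
    """Translate an in-frame DNA string; codons with N become X, stops '*'.

    Trailing bases short of a codon are ignored.
    """
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def interval_length(iv: Interval) -> int:
    return iv[1] - iv[0]


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def interval_jaccard(a: Interval, b: Interval) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence with provenance (input file or synthetic)."""

    id: str
    seq: str
    source: str = "input"

    def __post_init__(self) -> None:
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"contig {self.id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "Contig":
        return Contig(self.id, revcomp(self.seq), self.source)


def validate_protein(protein: str) -> None:
    """Raise ValueError naming the first offending position if *protein*
    contains a character outside the 20 standard amino acids."""
    for i, ch in enumerate(protein):
        if ch not in AA_ALPHABET:
            raise ValueError(f"non-standard amino acid {ch!r} at position {i}")
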