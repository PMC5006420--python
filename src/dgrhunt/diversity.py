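"""Theoretical variant repertoire of a VR under adenine mutagenesis.

The mutagenesis model: every adenine of the template (TR) codon independently
becomes any of A, C, G or T in the VR (retention allowed, since TR and VR are
only *typically* different); non-adenine positions are invariant.  Per codon
this yields 4^(#adenines) nucleotide variants; the repertoire of a VR is the
product over its codons of the number of distinct non-stop residues reachable.
Stop-producing variants are excluded from the product and flagged, since the
repertoire of interest is protein variants.

AAY codons (A A pyrimidine) are the sweet spot of this system: they reach 15
distinct amino acids (the NNY half of the code) and can never produce a stop,
because every stop codon requires an A or G at the third position.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from dgrhunt.core import CODON_TO_AA, STOP


@dataclass(frozen=True)
class CodonVariantSet:
    """All outcomes of adenine mutagenesis of one template codon."""

    template_codon: str
    adenine_positions: tuple[int, ...]
    amino_acids: frozenset[str]
    n_stop_variants: int
    n_nt_variants: int


@dataclass(frozen=True)
class DiversityReport:
    """Codon-level repertoire of a VR mutagenised from its template.

    ``variable_codon_indices`` lists codons whose mutagenesis can change the
    encoded residue; ``adenine_codon_indices`` lists all codons containing at
    least one template adenine (a superset: some adenine substitutions are
    synonymous).  ``repertoire_size`` is exact; ``log10_repertoire`` is
    provided for comparison at large sizes.
    """

    n_codons: int
    adenine_codon_indices: tuple[int, ...]
    variable_codon_indices: tuple[int, ...]
    per_codon: tuple[CodonVariantSet, ...]
    repertoire_size: int
    log10_repertoire: float
    any_stop_reachable: bool

    def to_dict(self) -> dict:
        return {
            "n_codons": self.n_codons,
            "adenine_codon_indices": list(self.adenine_codon_indices),
            "variable_codon_indices": list(self.variable_codon_indices),
            "repertoire_size": str(self.repertoire_size),
            "log10_repertoire": self.log10_repertoire,
            "any_stop_reachable": self.any_stop_reachable,
            "per_codon": [
                {
                    "template_codon": c.template_codon,
                    "adenine_positions": list(c.adenine_positions),
                    "amino_acids": sorted(c.amino_acids),
                    "n_stop_variants": c.n_stop_variants,
                    "n_nt_variants": c.n_nt_variants,
                }
                for c in self.per_codon
            ],
        }


def codon_variants(template_codon: str) -> CodonVariantSet:
    """Enumerate every adenine-substituted variant of one codon."""
    codon = template_codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"invalid codon {template_codon!r}")
    a_pos = tuple(i for i in range(3) if codon[i] == "A")
    residues = set()
    n_stop = 0
    for combo in itertools.product("ACGT", repeat=len(a_pos)):
        variant = list(codon)
        for p, b in zip(a_pos, combo):
            variant[p] = b
        aa = CODON_TO_AA["".join(variant)]
        if aa == STOP:
            n_stop += 1
        else:
            residues.add(aa)
    return CodonVariantSet(codon, a_pos, frozenset(residues), n_stop, 4 ** len(a_pos))


def repertoire_size(vr_codons: list[str]) -> DiversityReport:
    """Repertoire of a codon list: product of per-codon distinct residues."""
    if not vr_codons:
        raise ValueError("empty codon list")
    per = tuple(codon_variants(c) for c in vr_codons)
    size = 1
    for c in per:
        size *= len(c.amino_acids)
    return DiversityReport(
        n_codons=len(per),
        adenine_codon_indices=tuple(i for i, c in enumerate(per) if c.adenine_positions),
        variable_codon_indices=tuple(i for i, c in enumerate(per) if len(c.amino_acids) > 1),
        per_codon=per,
        repertoire_size=size,
        log10_repertoire=math.log10(size) if size else float("-inf"),
        any_stop_reachable=any(c.n_stop_variants for c in per),
    )


def variable_positions_from_pair(tr: str, vr_frame_offset: int) -> DiversityReport:
    """Repertoire of a VR given its template sequence and reading-frame offset.

    The TR is decomposed into codons in the VR's frame (the leading
    *vr_frame_offset* bases and any trailing partial codon are dropped); the
    per-codon variant sets are computed on the TR, the invariant source.
    """
    if vr_frame_offset not in (0, 1, 2):
        raise ValueError("frame offset must be 0, 1 or 2")
    trimmed = tr.upper()[vr_frame_offset:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    if len(trimmed) < 3:
        raise ValueError("TR too short after frame trimming")
    codons = [trimmed[i:i + 3] for i in range(0, len(trimmed), 3)]
    return repertoire_size(codons)
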