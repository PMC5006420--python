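"""Stage 1: find reverse-transcriptase-like genes in contigs.

Contigs are translated in all six frames (no external gene caller needed) and
each frame is searched against a reference set of DGR reverse-transcriptase
proteins by local alignment; hits are retained at a Karlin–Altschul
expectation of 1e-10 or better, the conventional cutoff for this search.
Stops are kept in the frame strings and scored so that alignments never cross
them, which makes the frame search equivalent to searching stop-delimited
ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

from dgrhunt import align
from dgrhunt.core import AA_ALPHABET, Contig, Interval, revcomp, translate_dna


@dataclass(frozen=True)
class RTReference:
    id: str
    protein: str

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        bad = set(self.protein) - AA_ALPHABET - {"X"}
        if bad:
            raise ValueError(f"reference {self.id!r}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class RTHit:
    """A local-alignment hit of a reference RT protein in a translated frame.

    ``nt_interval`` is 0-based half-open on the forward strand;
    ``aa_interval`` indexes the translated frame string.
    """

    contig_id: str
    strand: str
    frame: int
    nt_interval: Interval
    aa_interval: Interval
    reference_id: str
    score: float
    evalue: float


@dataclass(frozen=True)
class TranslatedFrame:
    """One of the six translation frames of a contig, with exact nt<->aa maps."""

    contig_id: str
    strand: str
    frame: int
    aa: str
    contig_length: int

    def aa_to_nt(self, aa_interval: Interval) -> Interval:
        """Forward-strand nucleotide interval spanned by an aa interval."""
        s, e = aa_interval
        if self.strand == "+":
            return (self.frame + 3 * s, self.frame + 3 * e)
        L = self.contig_length
        return (L - self.frame - 3 * e, L - self.frame - 3 * s)

    def nt_to_aa(self, pos: int) -> int:
        """Index of the codon containing forward-strand position *pos*."""
        if self.strand == "+":
            return (pos - self.frame) // 3
        return (self.contig_length - self.frame - 1 - pos) // 3


def six_frame_translate(contig: Contig) -> list[TranslatedFrame]:
    """Translate a contig in all six frames; codons with N give X, stops '*'."""
    frames = []
    rc = revcomp(contig.seq)
    for strand, seq in (("+", contig.seq), ("-", rc)):
        for f in range(3):
            frames.append(
                TranslatedFrame(contig.id, strand, f, translate_dna(seq[f:]), len(contig))
            )
    return frames


def load_toy_rt_references() -> list[RTReference]:
    """Bundled synthetic toy RT set used for tests and the simulator default.

    These are generated sequences with RT-motif flavour, not natural proteins;
    real analyses should supply their own reference set of known DGR RTs.
    """
    path = resources.files("dgrhunt.data") / "toy_rt_refs.synthetic.faa"
    with path.open() as fh:
        return [RTReference(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]


def read_rt_references(path) -> list[RTReference]:
    refs = [RTReference(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not refs:
        raise ValueError(f"no reference sequences in {path}")
    return refs


def find_rt_hits(
    contig: Contig,
    refs: list[RTReference],
    evalue_cutoff: float = 1e-10,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[RTHit]:
    """Search a contig's six frames against the RT reference set.

    Returns hits with E <= cutoff, sorted by E-value ascending; overlapping
    hits to the same reference keep only the best-scoring one.  The search
    space for the expectation is reference length x total translated residues
    of the contig.
    """
    if not refs:
        raise ValueError("reference set is empty")
    if evalue_cutoff <= 0:
        return []
    frames = six_frame_translate(contig)
    searched = sum(len(f.aa) for f in frames)
    if searched == 0:
        return []
    # Alignments may not cross a stop column, so each frame is searched as its
    # stop-delimited segments (the ORF-level view of the frame).  Segments too
    # short to ever reach a significant score are skipped outright: even at
    # the best BLOSUM62 diagonal score (11 per column) a segment shorter than
    # min_segment residues cannot clear the cutoff for any realistic search
    # space here.
    min_segment = 12
    hits: list[RTHit] = []
    for ref in refs:
        smin = align.min_score_for_evalue(evalue_cutoff, len(ref.protein), searched)
        for fr in frames:
            offset = 0
            for seg in fr.aa.split("*"):
                if len(seg) >= max(min_segment, int(smin / 11.0)):
                    score = align.local_align_protein(seg, ref.protein, gap_open,
                                                      gap_extend, score_only=True)
                    if score >= smin:
                        la = align.local_align_protein(seg, ref.protein, gap_open, gap_extend)
                        e = align.evalue(la.score, len(ref.protein), len(fr.aa),
                                         db_size=searched)
                        if e <= evalue_cutoff:
                            qs, qe = la.query_interval
                            aa_iv = (offset + qs, offset + qe)
                            hits.append(
                                RTHit(
                                    contig_id=contig.id,
                                    strand=fr.strand,
                                    frame=fr.frame,
                                    nt_interval=fr.aa_to_nt(aa_iv),
                                    aa_interval=aa_iv,
                                    reference_id=ref.id,
                                    score=la.score,
                                    evalue=e,
                                )
                            )
                offset += len(seg) + 1
    # Merge overlapping hits to the same reference: keep the best-scoring one.
    hits.sort(key=lambda h: (-h.score, h.nt_interval))
    kept: list[RTHit] = []
    for h in hits:
        clash = any(
            k.reference_id == h.reference_id
            and k.nt_interval[0] < h.nt_interval[1]
            and h.nt_interval[0] < k.nt_interval[1]
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.evalue, h.nt_interval))
    return kept
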