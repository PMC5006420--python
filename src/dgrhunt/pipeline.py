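"""End-to-end orchestration: rtsearch -> scan -> call -> diversity -> motifs.

Contigs are processed independently and results aggregated, so any execution
order yields identical output.  Stage defaults are the conventional detection
parameters: 1e-10 RT E-value cutoff, 10 kb flank, 200/50 bp windows, and the
>=5 adenine-variable / <=1 non-adenine acceptance rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from dgrhunt import io as dio
from dgrhunt.core import Contig, Interval, intervals_overlap, revcomp, translate_dna
from dgrhunt.diversity import variable_positions_from_pair
from dgrhunt.mismatch_classify import DGRCall, call_dgrs
from dgrhunt.motif_scan import classify_avpa_like
from dgrhunt.repeat_scan import RepeatPair, find_repeat_pairs, scan_flanks
from dgrhunt.rt_search import RTHit, find_rt_hits, read_rt_references

logger = logging.getLogger("dgrhunt")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds; defaults are the standard detection parameters."""

    window: int = 200
    step: int = 50
    flank: int = 10_000
    evalue: float = 1e-10
    min_identity: float = 0.8
    min_score: float = 40.0
    min_length: int = 50
    merge_tol: int = 10
    min_adenine: int = 5
    max_non_adenine: int = 1
    strict: bool = False
    max_ambiguous_frac: float = 0.05
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), default_flow_style=True, width=2**20).strip()

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def header_comments(self) -> list[str]:
        return [f"dgrhunt config hash={self.hash()}", f"config: {self.to_yaml()}"]


@dataclass
class OrfAnnotation:
    """Longest stop-free reading-frame run overlapping an interval."""

    strand: str
    frame: int
    nt_interval: Interval
    protein: str
    vr_frame_offset: int


@dataclass
class PipelineResult:
    hits: list[RTHit] = field(default_factory=list)
    pairs: list[RepeatPair] = field(default_factory=list)
    calls: list[DGRCall] = field(default_factory=list)
    diversity: dict = field(default_factory=dict)
    motifs: list[dict] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)


def annotate_vr_orf(contig: Contig, vr_interval: Interval) -> OrfAnnotation | None:
    """Find the longest stop-free codon run among the six frames that fully
    contains the VR; reported as an annotation, never used as a filter."""
    L = len(contig)
    best: OrfAnnotation | None = None
    for strand in "+-":
        seq = contig.seq if strand == "+" else revcomp(contig.seq)
        for f in range(3):
            aa = translate_dna(seq[f:])
            run_start = 0
            for i, ch in enumerate(aa + "*"):
                if ch == "*":
                    if i > run_start:
                        nt_s, nt_e = f + 3 * run_start, f + 3 * i
                        iv = (nt_s, nt_e) if strand == "+" else (L - nt_e, L - nt_s)
                        if iv[0] <= vr_interval[0] and vr_interval[1] <= iv[1]:
                            if best is None or (i - run_start) > len(best.protein):
                                # phase of the VR's first base in reading order
                                if strand == "+":
                                    phase = (vr_interval[0] - nt_s) % 3
                                else:
                                    phase = ((L - vr_interval[1]) - nt_s) % 3
                                best = OrfAnnotation(
                                    strand, f, iv, aa[run_start:i], (3 - phase) % 3
                                )
                    run_start = i + 1
    return best


def process_contig(contig: Contig, refs, config: PipelineConfig) -> PipelineResult:
    res = PipelineResult()
    res.hits = find_rt_hits(contig, refs, evalue_cutoff=config.evalue)
    regions: list[Interval] = []
    for hit in res.hits:
        region = scan_flanks(contig, hit, config.flank)
        if not any(region == r for r in regions):
            regions.append(region)
    pairs: list[RepeatPair] = []
    for region in regions:
        for p in find_repeat_pairs(
            contig, region, window=config.window, step=config.step,
            min_identity=config.min_identity, min_score=config.min_score,
            min_length=config.min_length, merge_tol=config.merge_tol,
        ):
            if p not in pairs:
                pairs.append(p)
    res.pairs = pairs
    res.calls = call_dgrs(
        res.hits, pairs,
        min_adenine=config.min_adenine, max_non_adenine=config.max_non_adenine,
        strict_polarity=config.strict, max_ambiguous_frac=config.max_ambiguous_frac,
        flank=config.flank,
    )
    for k, call in enumerate(res.calls):
        call_id = f"{contig.id}:dgr{k}"
        tr_seq = contig.seq[call.tr_interval[0]:call.tr_interval[1]]
        orf = annotate_vr_orf(contig, call.vr_interval)
        tr_oriented = tr_seq
        if call.orientation == "inverted":
            tr_oriented = revcomp(tr_oriented)
        offset = 0
        if orf is not None:
            offset = orf.vr_frame_offset
            if orf.strand == "-":
                tr_oriented = revcomp(tr_oriented)
        try:
            report = variable_positions_from_pair(tr_oriented, offset)
            res.diversity[call_id] = report.to_dict()
        except ValueError:
            pass
        if orf is not None:
            cls = classify_avpa_like(orf.protein, protein_id=call_id)
            res.motifs.append({
                "call_id": call_id,
                "orf_strand": orf.strand,
                "orf_start": orf.nt_interval[0],
                "orf_end": orf.nt_interval[1],
                "is_avpa_like": cls.is_avpa_like,
                "found_motifs": ",".join(cls.found_motifs) or ".",
                "missing_motifs": ",".join(cls.missing_motifs) or ".",
            })
    return res


def _hits_frame(hits: list[RTHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": h.contig_id, "strand": h.strand, "frame": h.frame,
                "nt_start": h.nt_interval[0], "nt_end": h.nt_interval[1],
                "ref": h.reference_id, "score": h.score, "evalue": h.evalue,
            }
            for h in hits
        ],
        columns=["contig", "strand", "frame", "nt_start", "nt_end", "ref", "score", "evalue"],
    )


def _pairs_frame(pairs: list[RepeatPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": p.contig_id,
                "a_start": p.interval_a[0], "a_end": p.interval_a[1],
                "b_start": p.interval_b[0], "b_end": p.interval_b[1],
                "orientation": p.orientation, "identity": round(p.identity, 6),
                "aligned_columns": p.aligned_columns,
            }
            for p in pairs
        ],
        columns=["contig", "a_start", "a_end", "b_start", "b_end",
                 "orientation", "identity", "aligned_columns"],
    )


def _calls_frame(calls: list[DGRCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig_id,
                "rt_start": c.rt_hit.nt_interval[0], "rt_end": c.rt_hit.nt_interval[1],
                "tr_start": c.tr_interval[0], "tr_end": c.tr_interval[1],
                "vr_start": c.vr_interval[0], "vr_end": c.vr_interval[1],
                "orientation": c.orientation,
                "sense": c.sense,
                "identity": round(c.identity, 6),
                "n_adenine_variable": c.profile.n_adenine_variable,
                "n_non_adenine": c.profile.n_non_adenine,
                "polarity_consistent": c.polarity_consistent,
                "ambiguous_polarity": c.ambiguous_polarity,
                "filter_trace": "|".join(c.filter_trace),
            }
            for c in calls
        ],
        columns=["contig", "rt_start", "rt_end", "tr_start", "tr_end", "vr_start",
                 "vr_end", "orientation", "sense", "identity", "n_adenine_variable",
                 "n_non_adenine", "polarity_consistent", "ambiguous_polarity",
                 "filter_trace"],
    )


def calls_gff3_lines(calls: list[DGRCall]) -> list[str]:
    lines = []
    for k, c in enumerate(calls):
        span = (
            min(c.rt_hit.nt_interval[0], c.tr_interval[0], c.vr_interval[0]),
            max(c.rt_hit.nt_interval[1], c.tr_interval[1], c.vr_interval[1]),
        )
        pid = f"dgr{k}"
        attrs = {
            "ID": pid,
            "identity": f"{c.identity:.4f}",
            "n_adenine_variable": c.profile.n_adenine_variable,
            "n_non_adenine": c.profile.n_non_adenine,
            "n_ambiguous": c.profile.n_ambiguous,
            "sense": c.sense,
            "polarity_consistent": c.polarity_consistent,
        }
        lines.append(dio.gff3_line(c.contig_id, "dgrhunt",
                                   "diversity_generating_retroelement", span, "+", attrs))
        lines.append(dio.gff3_line(c.contig_id, "dgrhunt", "reverse_transcriptase",
                                   c.rt_hit.nt_interval, c.rt_hit.strand,
                                   {"ID": f"{pid}.rt", "Parent": pid,
                                    "ref": c.rt_hit.reference_id,
                                    "evalue": f"{c.rt_hit.evalue:.3g}"}))
        lines.append(dio.gff3_line(c.contig_id, "dgrhunt", "template_region",
                                   c.tr_interval, "+",
                                   {"ID": f"{pid}.tr", "Parent": pid}))
        lines.append(dio.gff3_line(c.contig_id, "dgrhunt", "variable_region",
                                   c.vr_interval, "+",
                                   {"ID": f"{pid}.vr", "Parent": pid}))
    return lines


def run_pipeline(contigs_path, rt_db_path, outdir, config: PipelineConfig | None = None) -> PipelineResult:
    """Run all stages over a contig FASTA and write the result bundle.

    Produces hits.tsv, pairs.tsv, calls.tsv, calls.gff3, diversity.json,
    motifs.tsv and run.log under *outdir*.  Zero calls is a normal outcome,
    not an error.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        contigs = dio.read_fasta(contigs_path)
        refs = read_rt_references(rt_db_path)
        logger.info("loaded %d contigs, %d RT references", len(contigs), len(refs))
        total = PipelineResult()
        for contig in contigs:
            res = process_contig(contig, refs, config)
            logger.info(
                "contig %s: %d RT hits, %d repeat pairs, %d calls",
                contig.id, len(res.hits), len(res.pairs), len(res.calls),
            )
            total.hits.extend(res.hits)
            total.pairs.extend(res.pairs)
            total.calls.extend(res.calls)
            total.diversity.update(res.diversity)
            total.motifs.extend(res.motifs)
        total.stage_counts = {
            "contigs": len(contigs),
            "rt_hits": len(total.hits),
            "repeat_pairs": len(total.pairs),
            "calls": len(total.calls),
        }
        hdr = config.header_comments()
        dio.write_tsv(_hits_frame(total.hits), outdir / "hits.tsv", hdr)
        dio.write_tsv(_pairs_frame(total.pairs), outdir / "pairs.tsv", hdr)
        dio.write_tsv(_calls_frame(total.calls), outdir / "calls.tsv", hdr)
        dio.write_gff3(calls_gff3_lines(total.calls), outdir / "calls.gff3", hdr)
        with open(outdir / "diversity.json", "w") as fh:
            json.dump(total.diversity, fh, indent=1, sort_keys=True)
        dio.write_tsv(
            pd.DataFrame(total.motifs, columns=["call_id", "orf_strand", "orf_start",
                                                "orf_end", "is_avpa_like",
                                                "found_motifs", "missing_motifs"]),
            outdir / "motifs.tsv", hdr,
        )
        logger.info("stage counts: %s", total.stage_counts)
        return total
    finally:
        logger.removeHandler(handler)
        handler.close()
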