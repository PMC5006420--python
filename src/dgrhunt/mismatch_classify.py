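"""Stage 3: adenine-specific mismatch typing and DGR calling.

Every column of a candidate repeat-pair alignment is typed as match,
adenine-variable (exactly one copy has an A), non-adenine mismatch, or
ambiguous (gap or N).  A pair is accepted as a putative TR/VR pair when it
shows at least five adenine-variable columns and at most one non-adenine
mismatch — the operational signature of DGR adenine mutagenesis.  A strict
mode additionally demands zero non-adenine mismatches and unanimous polarity,
honouring the stricter recording wording of the rule.

The template copy (TR) is the one carrying the majority of the adenines at
adenine-variable columns: the TR is the invariant donor, so its adenines are
the positions that appear substituted in the VR.

Adenine-specificity is defined in the sense of the element's own strand.  A
DGR lying on the reverse strand of a contig shows thymine-specific mismatches
in forward-strand coordinates, so every pair is typed in both senses (forward
and complemented) and the better-supported sense is used; this makes calling
invariant to reverse-complementing the contig.
"""

from __future__ import annotations

from dataclasses import dataclass

from dgrhunt.core import Interval, intervals_overlap
from dgrhunt.repeat_scan import RepeatPair
from dgrhunt.rt_search import RTHit

_VALID = set("ACGTN-")
_COMP = str.maketrans("ACGTN-", "TGCAN-")


@dataclass(frozen=True)
class MismatchProfile:
    """Per-column typing of a repeat-pair alignment.

    ``polarity_a``/``polarity_b`` count adenine-variable columns whose A lies
    on copy A / copy B; they sum to ``n_adenine_variable``.
    """

    n_match: int
    n_adenine_variable: int
    n_non_adenine: int
    n_ambiguous: int
    polarity_a: int
    polarity_b: int

    @property
    def n_columns(self) -> int:
        return self.n_match + self.n_adenine_variable + self.n_non_adenine + self.n_ambiguous

    @property
    def identity(self) -> float:
        informative = self.n_columns - self.n_ambiguous
        return self.n_match / informative if informative else 0.0


@dataclass(frozen=True)
class Decision:
    accepted: bool
    reasons: tuple[str, ...]  # every failed rule, empty when accepted


@dataclass(frozen=True)
class DGRCall:
    contig_id: str
    rt_hit: RTHit
    tr_interval: Interval
    vr_interval: Interval
    orientation: str
    sense: str  # strand sense in which adenine-specificity holds
    profile: MismatchProfile
    identity: float
    polarity_consistent: bool
    ambiguous_polarity: bool
    filter_trace: tuple[str, ...]


def classify_mismatches(pair: RepeatPair, sense: str = "+") -> MismatchProfile:
    """Type every alignment column of a repeat pair.

    For inverted pairs the stored alignment already holds the reverse
    complement of copy B, so adenine typing needs no special casing here.
    With ``sense='-'`` both bases are complemented first, typing the pair as
    an element on the reverse strand (adenine there reads as thymine here).
    """
    if not pair.alignment:
        raise ValueError("empty alignment")
    n_match = n_av = n_non = n_amb = pol_a = pol_b = 0
    for idx, (a, b) in enumerate(pair.alignment):
        if a not in _VALID or b not in _VALID:
            raise ValueError(f"invalid characters {(a, b)!r} at alignment column {idx}")
        if sense == "-":
            a, b = a.translate(_COMP), b.translate(_COMP)
        if a in "N-" or b in "N-":
            n_amb += 1
        elif a == b:
            n_match += 1
        elif a == "A":
            n_av += 1
            pol_a += 1
        elif b == "A":
            n_av += 1
            pol_b += 1
        else:
            n_non += 1
    return MismatchProfile(n_match, n_av, n_non, n_amb, pol_a, pol_b)


def accept_pair(
    profile: MismatchProfile,
    min_adenine: int = 5,
    max_non_adenine: int = 1,
    strict_polarity: bool = False,
    max_ambiguous_frac: float = 0.05,
) -> Decision:
    """Apply the acceptance rule; reasons list every failed criterion."""
    reasons = []
    if profile.n_adenine_variable < min_adenine:
        reasons.append(
            f"adenine_variable<{min_adenine} ({profile.n_adenine_variable})"
        )
    if profile.n_non_adenine > max_non_adenine:
        reasons.append(f"non_adenine>{max_non_adenine} ({profile.n_non_adenine})")
    if strict_polarity and profile.n_adenine_variable and \
            min(profile.polarity_a, profile.polarity_b) > 0:
        reasons.append("polarity_not_unanimous")
    if profile.n_columns and profile.n_ambiguous > max_ambiguous_frac * profile.n_columns:
        reasons.append(f"ambiguous_frac>{max_ambiguous_frac}")
    return Decision(accepted=not reasons, reasons=tuple(reasons))


def assign_tr_vr(pair: RepeatPair, profile: MismatchProfile):
    """Decide which copy is the template.

    Returns a list of ``(tr_interval, vr_interval, polarity_consistent,
    ambiguous)`` tuples — one entry normally, two flagged entries on an exact
    polarity tie.
    """
    if profile.n_adenine_variable == 0:
        raise ValueError("cannot assign TR/VR with zero adenine-variable columns")
    consistent = min(profile.polarity_a, profile.polarity_b) == 0
    if profile.polarity_a > profile.polarity_b:
        return [(pair.interval_a, pair.interval_b, consistent, False)]
    if profile.polarity_b > profile.polarity_a:
        return [(pair.interval_b, pair.interval_a, consistent, False)]
    return [
        (pair.interval_a, pair.interval_b, False, True),
        (pair.interval_b, pair.interval_a, False, True),
    ]


def call_dgrs(
    rt_hits: list[RTHit],
    pairs: list[RepeatPair],
    min_adenine: int = 5,
    max_non_adenine: int = 1,
    strict_polarity: bool = False,
    max_ambiguous_frac: float = 0.05,
    flank: int = 10_000,
) -> list[DGRCall]:
    """Combine RT hits and repeat pairs into accepted DGR calls.

    One call per accepted (hit, pair) combination (two on a polarity tie,
    flagged ambiguous); each call's filter trace records the flank check, the
    pair identity, and the acceptance-rule outcome.  Hits of different
    references to one RT locus (overlapping intervals) are collapsed to the
    best-scoring hit first, so one RT gene yields one call per pair.
    """
    loci: list[RTHit] = []
    for h in sorted(rt_hits, key=lambda h: (-h.score, h.evalue)):
        if not any(
            k.contig_id == h.contig_id
            and k.nt_interval[0] < h.nt_interval[1]
            and h.nt_interval[0] < k.nt_interval[1]
            for k in loci
        ):
            loci.append(h)
    calls: list[DGRCall] = []
    for hit in loci:
        for pair in pairs:
            if pair.contig_id != hit.contig_id:
                continue
            flank_iv = (hit.nt_interval[0] - flank, hit.nt_interval[1] + flank)
            in_flank = (
                intervals_overlap(pair.interval_a, flank_iv)
                and intervals_overlap(pair.interval_b, flank_iv)
            )
            trace = [f"flank<= {flank}bp of RT: {'pass' if in_flank else 'fail'}"]
            if not in_flank:
                continue
            # type in both strand senses; keep the better-supported one
            candidates = [(classify_mismatches(pair, s), s) for s in "+-"]
            profile, sense = max(
                candidates,
                key=lambda ps: (ps[0].n_adenine_variable, -ps[0].n_non_adenine,
                                ps[1] == "+"),
            )
            trace.append(f"identity={pair.identity:.4f}")
            trace.append(f"sense={sense}")
            decision = accept_pair(profile, min_adenine, max_non_adenine,
                                   strict_polarity, max_ambiguous_frac)
            trace.append(
                "accept" if decision.accepted else "reject:" + ";".join(decision.reasons)
            )
            if not decision.accepted:
                continue
            for tr_iv, vr_iv, consistent, ambiguous in assign_tr_vr(pair, profile):
                if strict_polarity and not consistent:
                    continue
                calls.append(
                    DGRCall(
                        contig_id=pair.contig_id,
                        rt_hit=hit,
                        tr_interval=tr_iv,
                        vr_interval=vr_iv,
                        orientation=pair.orientation,
                        sense=sense,
                        profile=profile,
                        identity=pair.identity,
                        polarity_consistent=consistent,
                        ambiguous_polarity=ambiguous,
                        filter_trace=tuple(trace),
                    )
                )
    calls.sort(key=lambda c: (c.contig_id, min(c.tr_interval[0], c.vr_interval[0]),
                              c.tr_interval, c.vr_interval))
    return calls
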