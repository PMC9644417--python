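"""Deterministic breakpoint verification.

Encodes the manual-review confirmation rules for structural
rearrangements as a total, deterministic classifier. A rearrangement is
*confirmed* when at least two non-duplicate reads carry the same
misaligned (soft-clipped) sequence at each of the two partner loci; a
single concordant read per partner suffices when a paired sample
(targeted or WGS) shows the same clipped sequences and itself has at
least five non-duplicate misaligned reads at a partner. Any remaining
clip evidence is *equivocal* — a single soft-clipped read is suggestive
but not definitive on its own — and no evidence at all is *absent*.

Clip sequences are compared junction-anchored: clips on the left of an
alignment are reversed so that position 0 is always the base adjacent
to the junction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .clump import ClipEvidence, TranslocationCall

__all__ = [
    "PartnerEvidence",
    "VerificationInput",
    "VerificationResult",
    "seqs_concordant",
    "verify_event",
    "verify_batch",
    "partner_evidence_from_clips",
]

STATUS_ORDER = {"absent": 0, "equivocal": 1, "confirmed": 2}


@dataclass
class PartnerEvidence:
    """Clip evidence at one rearrangement partner, junction-anchored."""

    n_nondup_clips: int
    clip_seqs: list[str] = field(default_factory=list)
    coverage_drop: bool = False  # reported, not used in status logic


@dataclass
class VerificationInput:
    partner_a: PartnerEvidence
    partner_b: PartnerEvidence
    paired_sample: Optional[tuple[PartnerEvidence, PartnerEvidence]] = None


@dataclass(frozen=True)
class VerificationResult:
    status: str  # confirmed, equivocal or absent
    rule_fired: str


def seqs_concordant(a: str, b: str, min_overlap: int = 10) -> bool:
    """True iff two junction-anchored clip sequences agree exactly over
    their overlapping prefix of length >= min_overlap."""
    n = min(len(a), len(b))
    return n >= min_overlap and a[:n] == b[:n]


def _has_concordant_pair(seqs: Sequence[str], min_overlap: int) -> bool:
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if seqs_concordant(seqs[i], seqs[j], min_overlap):
                return True
    return False


def _cross_concordant(own: Sequence[str], paired: Sequence[str], min_overlap: int) -> bool:
    return any(seqs_concordant(a, b, min_overlap) for a in own for b in paired)


def verify_event(ev: VerificationInput, min_overlap: int = 10) -> VerificationResult:
    """Classify one rearrangement as confirmed / equivocal / absent."""
    a, b = ev.partner_a, ev.partner_b
    # Rule 1: >=2 mutually concordant non-duplicate clips at both partners.
    if (
        a.n_nondup_clips >= 2
        and b.n_nondup_clips >= 2
        and _has_concordant_pair(a.clip_seqs, min_overlap)
        and _has_concordant_pair(b.clip_seqs, min_overlap)
    ):
        return VerificationResult("confirmed", "two_nondup_reads_both_partners")
    # Rule 2: one concordant read per partner suffices when a paired
    # sample agrees and has >=5 non-duplicate misaligned reads.
    if ev.paired_sample is not None:
        pa, pb = ev.paired_sample
        if (
            a.n_nondup_clips >= 1
            and b.n_nondup_clips >= 1
            and max(pa.n_nondup_clips, pb.n_nondup_clips) >= 5
            and _cross_concordant(a.clip_seqs, pa.clip_seqs, min_overlap)
            and _cross_concordant(b.clip_seqs, pb.clip_seqs, min_overlap)
        ):
            return VerificationResult("confirmed", "paired_sample_concordance")
    if a.n_nondup_clips + b.n_nondup_clips >= 1:
        return VerificationResult("equivocal", "single_evidence_not_definitive")
    return VerificationResult("absent", "no_evidence")


def partner_evidence_from_clips(clips: Sequence[ClipEvidence]) -> PartnerEvidence:
    """Collapse clip evidence to non-duplicate reads, junction-anchored.

    Duplicate-flagged reads never reach the evidence stage; on top of
    that, clips sharing an identical (coordinate, side, sequence) stack
    from the *same* read name are collapsed — PCR duplicates of one
    molecule produce identical stacks, whereas independent molecules
    have staggered ends.
    """
    seen: dict[tuple[str, int, str, str], ClipEvidence] = {}
    for c in clips:
        seen.setdefault((c.qname, c.clip_coord, c.side, c.clipped_seq), c)
    unique = list(seen.values())
    return PartnerEvidence(
        n_nondup_clips=len({c.qname for c in unique}),
        clip_seqs=[c.junction_anchored_seq for c in unique],
    )


def _evidence_for_call(call: TranslocationCall) -> tuple[PartnerEvidence, PartnerEvidence]:
    return (
        partner_evidence_from_clips(call.clips_a),
        partner_evidence_from_clips(call.clips_b),
    )


def _match_paired_call(
    call: TranslocationCall, paired: Sequence[TranslocationCall], tol: int = 10
) -> Optional[TranslocationCall]:
    for other in paired:
        if (
            other.chrom_a == call.chrom_a
            and other.chrom_b == call.chrom_b
            and abs(other.pos_a - call.pos_a) <= tol
            and abs(other.pos_b - call.pos_b) <= tol
        ):
            return other
    return None


def verify_batch(
    calls: Sequence[TranslocationCall],
    paired: Optional[Sequence[TranslocationCall]] = None,
    min_overlap: int = 10,
    tol: int = 10,
) -> dict[str, int]:
    """Annotate calls in place with verification status; return summary counts.

    Calls already filtered (blacklist etc.) are left untouched. A call
    classified *absent* keeps its candidate status (no clip evidence at
    all — window-resolution pair-only clusters).
    """
    summary: Counter = Counter()
    for call in calls:
        if call.status == "filtered":
            continue
        ev_a, ev_b = _evidence_for_call(call)
        paired_ev = None
        if paired:
            match = _match_paired_call(call, paired, tol)
            if match is not None:
                paired_ev = _evidence_for_call(match)
        result = verify_event(
            VerificationInput(ev_a, ev_b, paired_ev), min_overlap=min_overlap
        )
        summary[result.status] += 1
        call.rule_fired = result.rule_fired
        if result.status in ("confirmed", "equivocal"):
            call.status = result.status
    return dict(summary)
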