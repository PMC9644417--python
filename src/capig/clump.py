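"""CluMP — clustering of mate pairs — translocation calling.

The caller works in four stages over coordinate-sorted aligned
paired-end reads:

1. extract discordant pairs: both mates well mapped, not duplicates,
   and either inter-chromosomal or with a large insert size;
2. cluster pairs supporting the same rearrangement (single linkage
   within a chromosome-pair and mate-orientation class);
3. collect soft-clip evidence: high base-quality, high mapping-quality
   reads inside the cluster windows whose soft-clipped plus mismatching
   bases make up a significant fraction of the read — at a true
   breakpoint the clipped bases continue on the partner locus;
4. refine each cluster to a base-pair breakpoint (modal clip
   coordinate, per-position majority consensus of the clipped
   sequences) and filter calls against blacklist/Ig-locus intervals.

Default thresholds: MAPQ >= 30, mean base quality >= 20, mismatch
fraction >= 0.33, minimum insert 5,000 bp, cluster window 1,000 bp.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .io import GenomicIntervals

__all__ = [
    "AlignedReadView",
    "ClumpConfig",
    "DiscordantPair",
    "BreakpointCluster",
    "ClipEvidence",
    "TranslocationCall",
    "ReadIndex",
    "load_reads",
    "extract_discordant",
    "cluster_pairs",
    "collect_clip_support",
    "refine_breakpoint",
    "filter_events",
    "call_translocations",
    "calls_to_rows",
    "call_to_dict",
    "call_from_dict",
]

_CIGAR_REF_OPS = set("MDN=X")


def _cigar_ref_len(cigar: str) -> int:
    n, total = 0, 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            if ch in _CIGAR_REF_OPS:
                total += n
            n = 0
    return total


@dataclass(slots=True)
class AlignedReadView:
    """Caller-facing view of one aligned read (1-based coordinates)."""

    qname: str
    chrom: str
    pos: int  # 1-based leftmost mapped base
    mapq: int
    cigar: str
    mean_baseq: float
    mate_chrom: Optional[str]
    mate_pos: int
    insert_size: int  # absolute template length
    is_duplicate: bool
    nm: int
    clipped_prefix: str
    clipped_suffix: str
    is_reverse: bool
    read_len: int
    ref_len: int
    seq: Optional[str] = None

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def end(self) -> int:
        """1-based inclusive rightmost mapped base."""
        return self.pos + self.ref_len - 1

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedReadView":
        quals = aln.query_qualities
        mean_q = float(sum(quals)) / len(quals) if quals else 0.0
        seq = aln.query_sequence or ""
        prefix = suffix = ""
        ct = aln.cigartuples or []
        if ct and ct[0][0] == 4:
            prefix = seq[: ct[0][1]]
        if ct and ct[-1][0] == 4:
            suffix = seq[len(seq) - ct[-1][1] :]
        mate_chrom = aln.next_reference_name
        if mate_chrom == "=":
            mate_chrom = aln.reference_name
        return cls(
            qname=aln.query_name,
            chrom=aln.reference_name,
            pos=aln.reference_start + 1,
            mapq=aln.mapping_quality,
            cigar=aln.cigarstring or "",
            mean_baseq=mean_q,
            mate_chrom=mate_chrom,
            mate_pos=(aln.next_reference_start + 1) if aln.next_reference_start >= 0 else 0,
            insert_size=abs(aln.template_length),
            is_duplicate=aln.is_duplicate,
            nm=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
            clipped_prefix=prefix,
            clipped_suffix=suffix,
            is_reverse=aln.is_reverse,
            read_len=aln.query_length or len(seq),
            ref_len=aln.reference_length or _cigar_ref_len(aln.cigarstring or ""),
            seq=seq or None,
        )


@dataclass
class ClumpConfig:
    min_insert: int = 5000
    min_mapq: int = 30
    min_baseq: float = 20.0
    min_mismatch_frac: float = 0.33
    cluster_window: int = 1000
    min_pairs: int = 2
    breakpoint_pad: int = 500

    def __post_init__(self) -> None:
        for name in ("min_insert", "min_mapq", "cluster_window", "min_pairs", "breakpoint_pad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.min_mismatch_frac <= 1):
            raise ValueError("min_mismatch_frac must be in (0, 1]")


@dataclass(frozen=True)
class DiscordantPair:
    """Canonicalised pair evidence: anchorA <= anchorB by (chrom, pos)."""

    qname: str
    anchor_a: tuple[str, int, str]  # (chrom, pos, strand)
    anchor_b: tuple[str, int, str]
    min_pair_mapq: int
    inter_chromosomal: bool

    @property
    def orientation_class(self) -> str:
        code = {"+": "F", "-": "R"}
        return code[self.anchor_a[2]] + code[self.anchor_b[2]]


@dataclass
class BreakpointCluster:
    window_a: tuple[str, int, int]  # (chrom, start1, end1) inclusive anchor extents
    window_b: tuple[str, int, int]
    pairs: list[DiscordantPair]
    orientation_class: str


@dataclass(frozen=True)
class ClipEvidence:
    qname: str
    clip_coord: int  # 1-based reference coordinate of the junction-side aligned base
    side: str  # left (clip precedes alignment) or right (clip follows)
    clipped_seq: str
    mean_baseq: float
    mapq: int

    @property
    def junction_anchored_seq(self) -> str:
        """Clip read outward from the junction (left clips reversed)."""
        return self.clipped_seq[::-1] if self.side == "left" else self.clipped_seq


@dataclass
class TranslocationCall:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    n_pairs: int
    n_clip_reads_a: int
    n_clip_reads_b: int
    consensus_clip_a: str
    consensus_clip_b: str
    resolution: str  # base_pair or window
    status: str = "candidate"
    filter_reason: str = ""
    rule_fired: str = ""
    clips_a: list[ClipEvidence] = field(default_factory=list)
    clips_b: list[ClipEvidence] = field(default_factory=list)

    @property
    def sort_key(self):
        return (self.chrom_a, self.pos_a, self.chrom_b, self.pos_b)


# ---------------------------------------------------------------------------
# stage 1: discordant pair extraction


def is_discordant_pair(r1: AlignedReadView, r2: AlignedReadView, cfg: ClumpConfig) -> bool:
    """Literal predicate on a mate pair; kept separate so tests can brute-force it."""
    if r1.mapq < cfg.min_mapq or r2.mapq < cfg.min_mapq:
        return False
    if r1.is_duplicate or r2.is_duplicate:
        return False
    return r1.chrom != r2.chrom or r1.insert_size >= cfg.min_insert


def _canonical_pair(r1: AlignedReadView, r2: AlignedReadView) -> DiscordantPair:
    a = (r1.chrom, r1.pos, r1.strand)
    b = (r2.chrom, r2.pos, r2.strand)
    if (b[0], b[1]) < (a[0], a[1]):
        a, b = b, a
    return DiscordantPair(
        qname=r1.qname,
        anchor_a=a,
        anchor_b=b,
        min_pair_mapq=min(r1.mapq, r2.mapq),
        inter_chromosomal=r1.chrom != r2.chrom,
    )


@dataclass
class ExtractReport:
    n_reads: int = 0
    n_pairs_seen: int = 0
    n_missing_mate: int = 0


def extract_discordant(
    reads: Iterable[AlignedReadView], cfg: ClumpConfig
) -> tuple[list[DiscordantPair], ExtractReport]:
    """Extract discordant mate pairs from a coordinate-sorted read stream.

    A pair is emitted iff both mates pass the mapping-quality gate,
    neither is a duplicate, and the pair is inter-chromosomal or has
    insert size >= ``min_insert`` (inclusive). Each template is emitted
    at most once. Unsorted input is a hard error; reads whose mate never
    appears are counted as skipped.
    """
    report = ExtractReport()
    pending: dict[str, AlignedReadView] = {}
    pairs: list[DiscordantPair] = []
    last: tuple[str, int] | None = None
    finished_chroms: set[str] = set()
    for read in reads:
        report.n_reads += 1
        if last is not None:
            if read.chrom == last[0]:
                if read.pos < last[1]:
                    raise ValueError(
                        f"input not coordinate-sorted at {read.chrom}:{read.pos} (qname {read.qname})"
                    )
            else:
                if read.chrom in finished_chroms:
                    raise ValueError(f"input not coordinate-sorted: chromosome {read.chrom} revisited")
                finished_chroms.add(last[0])
        last = (read.chrom, read.pos)
        if read.mate_chrom is None or not read.mate_chrom:
            report.n_missing_mate += 1
            continue
        mate = pending.pop(read.qname, None)
        if mate is None:
            pending[read.qname] = read
            continue
        report.n_pairs_seen += 1
        if is_discordant_pair(mate, read, cfg):
            pairs.append(_canonical_pair(mate, read))
    report.n_missing_mate += len(pending)
    pairs.sort(key=lambda p: (p.anchor_a, p.anchor_b, p.qname))
    return pairs, report


# ---------------------------------------------------------------------------
# stage 2: single-linkage clustering


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_pairs(pairs: Sequence[DiscordantPair], cfg: ClumpConfig) -> list[BreakpointCluster]:
    """Single-linkage clustering within (chromA, chromB, orientation class).

    Two pairs join a cluster iff their A anchors are within
    ``cluster_window`` AND their B anchors are within ``cluster_window``.
    Deterministic: pairs are pre-sorted by anchors, clusters emitted in
    window order.
    """
    groups: dict[tuple[str, str, str], list[DiscordantPair]] = defaultdict(list)
    for p in pairs:
        groups[(p.anchor_a[0], p.anchor_b[0], p.orientation_class)].append(p)
    clusters: list[BreakpointCluster] = []
    w = cfg.cluster_window
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda p: (p.anchor_a[1], p.anchor_b[1], p.qname))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            pa_i, pb_i = members[i].anchor_a[1], members[i].anchor_b[1]
            for j in range(i + 1, len(members)):
                if members[j].anchor_a[1] - pa_i > w:
                    break  # sorted on A anchor: no later j can link to i
                if abs(members[j].anchor_b[1] - pb_i) <= w:
                    uf.union(i, j)
        comp: dict[int, list[DiscordantPair]] = defaultdict(list)
        for i, p in enumerate(members):
            comp[uf.find(i)].append(p)
        for root in sorted(comp):
            mem = comp[root]
            pas = [p.anchor_a[1] for p in mem]
            pbs = [p.anchor_b[1] for p in mem]
            clusters.append(
                BreakpointCluster(
                    window_a=(key[0], min(pas), max(pas)),
                    window_b=(key[1], min(pbs), max(pbs)),
                    pairs=mem,
                    orientation_class=key[2],
                )
            )
    clusters.sort(key=lambda c: (c.window_a, c.window_b, c.orientation_class))
    return clusters


# ---------------------------------------------------------------------------
# stage 3: soft-clip evidence


class ReadIndex:
    """In-memory region-query index over aligned reads."""

    def __init__(self, reads: Iterable[AlignedReadView]) -> None:
        self._by_chrom: dict[str, list[AlignedReadView]] = defaultdict(list)
        for r in reads:
            self._by_chrom[r.chrom].append(r)
        self._starts: dict[str, list[int]] = {}
        self._max_ref_len: dict[str, int] = {}
        for chrom, rs in self._by_chrom.items():
            rs.sort(key=lambda r: r.pos)
            self._starts[chrom] = [r.pos for r in rs]
            self._max_ref_len[chrom] = max((r.ref_len for r in rs), default=0)

    def fetch(self, chrom: str, start1: int, end1: int) -> list[AlignedReadView]:
        """Reads whose aligned span overlaps [start1, end1] (1-based inclusive)."""
        rs = self._by_chrom.get(chrom)
        if not rs:
            return []
        starts = self._starts[chrom]
        lo = bisect.bisect_left(starts, start1 - self._max_ref_len[chrom])
        hi = bisect.bisect_right(starts, end1)
        return [r for r in rs[lo:hi] if r.end >= start1]


def mismatch_fraction(read: AlignedReadView) -> float:
    """Soft-clipped bases plus aligned-base edit distance over read length."""
    if read.read_len <= 0:
        return 0.0
    return (len(read.clipped_prefix) + len(read.clipped_suffix) + read.nm) / read.read_len


def clip_evidence_from_read(read: AlignedReadView) -> list[ClipEvidence]:
    out = []
    if read.clipped_prefix:
        out.append(
            ClipEvidence(read.qname, read.pos, "left", read.clipped_prefix, read.mean_baseq, read.mapq)
        )
    if read.clipped_suffix:
        out.append(
            ClipEvidence(read.qname, read.end, "right", read.clipped_suffix, read.mean_baseq, read.mapq)
        )
    return out


def collect_clip_support(
    reads: ReadIndex, cluster: BreakpointCluster, cfg: ClumpConfig
) -> tuple[list[ClipEvidence], list[ClipEvidence]]:
    """Collect qualifying soft-clip evidence for both cluster windows.

    A read contributes iff MAPQ >= min_mapq, mean base quality >=
    min_baseq, not a duplicate, and its mismatch fraction (clipped bases
    + NM over read length) >= min_mismatch_frac.
    """
    sides = []
    for chrom, start, end in (cluster.window_a, cluster.window_b):
        evidence: list[ClipEvidence] = []
        for read in reads.fetch(chrom, start - cfg.breakpoint_pad, end + cfg.breakpoint_pad):
            if read.is_duplicate or read.mapq < cfg.min_mapq or read.mean_baseq < cfg.min_baseq:
                continue
            if mismatch_fraction(read) < cfg.min_mismatch_frac:
                continue
            evidence.extend(clip_evidence_from_read(read))
        evidence.sort(key=lambda e: (e.clip_coord, e.side, e.qname))
        sides.append(evidence)
    return sides[0], sides[1]


# ---------------------------------------------------------------------------
# stage 4: refinement and filtering


def _consensus(seqs: list[str]) -> str:
    """Per-position majority base over junction-anchored sequences.

    Ties break to the lexicographically smallest base; length is the
    longest contributing sequence.
    """
    if not seqs:
        return ""
    out = []
    for i in range(max(len(s) for s in seqs)):
        counts = Counter(s[i] for s in seqs if len(s) > i)
        best = min(counts, key=lambda b: (-counts[b], b))
        out.append(best)
    return "".join(out)


def _refine_side(
    window: tuple[str, int, int], clips: list[ClipEvidence]
) -> tuple[int, str, int, str]:
    """Return (position, consensus clip, n non-duplicate clip reads, resolution)."""
    chrom, start, end = window
    if not clips:
        return (start + end) // 2, "", 0, "window"
    coord_counts = Counter(c.clip_coord for c in clips)
    modal = min(coord_counts, key=lambda c: (-coord_counts[c], c))
    at_modal = [c for c in clips if c.clip_coord == modal]
    side_counts = Counter(c.side for c in at_modal)
    modal_side = min(side_counts, key=lambda s: (-side_counts[s], s))
    seqs = [c.junction_anchored_seq for c in at_modal if c.side == modal_side]
    cons = _consensus(seqs)
    if modal_side == "left":
        cons = cons[::-1]  # back to reference orientation
    n_reads = len({c.qname for c in clips})
    return modal, cons, n_reads, "base_pair"


def refine_breakpoint(
    cluster: BreakpointCluster,
    clips_a: list[ClipEvidence],
    clips_b: list[ClipEvidence],
) -> TranslocationCall:
    """Refine a cluster to a call: modal clip coordinate per side, with a
    per-position majority consensus of the clipped sequences aligned at
    the junction. Sides without clip evidence fall back to the window
    midpoint (window resolution)."""
    pos_a, cons_a, n_a, res_a = _refine_side(cluster.window_a, clips_a)
    pos_b, cons_b, n_b, res_b = _refine_side(cluster.window_b, clips_b)
    resolution = "base_pair" if (res_a == "base_pair" or res_b == "base_pair") else "window"
    return TranslocationCall(
        chrom_a=cluster.window_a[0],
        pos_a=pos_a,
        chrom_b=cluster.window_b[0],
        pos_b=pos_b,
        n_pairs=len(cluster.pairs),
        n_clip_reads_a=n_a,
        n_clip_reads_b=n_b,
        consensus_clip_a=cons_a,
        consensus_clip_b=cons_b,
        resolution=resolution,
        clips_a=clips_a,
        clips_b=clips_b,
    )


def filter_events(
    calls: list[TranslocationCall],
    blacklist: GenomicIntervals | None,
    ig_loci: GenomicIntervals | None,
    cfg: ClumpConfig,
) -> list[TranslocationCall]:
    """Mark calls as filtered (status + reason); nothing is deleted.

    Reasons, checked in order: ``blacklist`` (either breakpoint inside a
    blacklist interval), ``ig_internal`` (both breakpoints inside Ig
    loci — those rearrangements are the clonotype pipeline's job),
    ``low_support`` (fewer than ``min_pairs`` pairs and no clip
    evidence). Idempotent.
    """
    blacklist = blacklist or GenomicIntervals.empty()
    ig_loci = ig_loci or GenomicIntervals.empty()
    for call in calls:
        reason = ""
        if blacklist.contains(call.chrom_a, call.pos_a) or blacklist.contains(call.chrom_b, call.pos_b):
            reason = "blacklist"
        elif ig_loci.contains(call.chrom_a, call.pos_a) and ig_loci.contains(call.chrom_b, call.pos_b):
            reason = "ig_internal"
        elif call.n_pairs < cfg.min_pairs and call.n_clip_reads_a + call.n_clip_reads_b == 0:
            reason = "low_support"
        if reason:
            call.status = "filtered"
            call.filter_reason = reason
        elif call.status == "filtered":
            call.status = "candidate"
            call.filter_reason = ""
    return calls


def call_translocations(
    reads: Iterable[AlignedReadView] | str | Path,
    cfg: ClumpConfig | None = None,
    blacklist: GenomicIntervals | None = None,
    ig_loci: GenomicIntervals | None = None,
) -> list[TranslocationCall]:
    """Full pipeline: extract -> cluster -> clip support -> refine -> filter.

    ``reads`` may be a SAM/BAM path or an in-memory read list.
    Output is stable-ordered by (chromA, posA, chromB, posB).
    """
    cfg = cfg or ClumpConfig()
    if isinstance(reads, (str, Path)):
        reads = load_reads(reads)
    else:
        reads = list(reads)
    pairs, _ = extract_discordant(reads, cfg)
    clusters = cluster_pairs(pairs, cfg)
    index = ReadIndex(reads)
    calls = []
    for cluster in clusters:
        clips_a, clips_b = collect_clip_support(index, cluster, cfg)
        calls.append(refine_breakpoint(cluster, clips_a, clips_b))
    filter_events(calls, blacklist, ig_loci, cfg)
    calls.sort(key=lambda c: c.sort_key)
    return calls


# ---------------------------------------------------------------------------
# I/O


def load_reads(path: str | Path) -> list[AlignedReadView]:
    """Load mapped, primary, non-supplementary reads from SAM/BAM."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            out.append(AlignedReadView.from_pysam(aln))
    return out


CALL_COLUMNS = [
    "chrom_a",
    "pos_a",
    "chrom_b",
    "pos_b",
    "n_pairs",
    "n_clip_reads_a",
    "n_clip_reads_b",
    "consensus_clip_a",
    "consensus_clip_b",
    "resolution",
    "status",
    "filter_reason",
    "rule_fired",
]


def calls_to_rows(calls: list[TranslocationCall]) -> list[dict]:
    return [{c: getattr(call, c) for c in CALL_COLUMNS} for call in calls]


def call_to_dict(call: TranslocationCall) -> dict:
    d = {c: getattr(call, c) for c in CALL_COLUMNS}
    for side in ("a", "b"):
        d[f"clips_{side}"] = [
            {
                "qname": e.qname,
                "clip_coord": e.clip_coord,
                "side": e.side,
                "clipped_seq": e.clipped_seq,
                "mean_baseq": e.mean_baseq,
                "mapq": e.mapq,
            }
            for e in getattr(call, f"clips_{side}")
        ]
    return d


def call_from_dict(d: dict) -> TranslocationCall:
    clips = {}
    for side in ("a", "b"):
        clips[side] = [ClipEvidence(**e) for e in d.get(f"clips_{side}", [])]
    return TranslocationCall(
        **{c: d[c] for c in CALL_COLUMNS},
        clips_a=clips["a"],
        clips_b=clips["b"],
    )
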