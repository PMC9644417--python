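"""Immunoglobulin segment references and capture-probe design.

Hybrid-capture panels for V(D)J rearrangement detection bait the 3'
ends of V genes and the 5' ends of J genes, so that captured fragments
are likely to span the rearrangement junction (the CDR3). Constant (C)
region exons are baited whole, because class-switch recombination
errors in those regions are a known source of illegitimate
rearrangement. This module parses an IMGT-style germline segment
reference and derives the probe panel from it: fixed-length (default
120 nt) single-stranded probes anchored at the relevant segment end,
deduplicated on sequence, and screened for promiscuity (probes sharing
exact k-mers with many other probes pull down off-target fragments).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "SegmentRecord",
    "Probe",
    "ProbeConfig",
    "ParseReport",
    "parse_segment_fasta",
    "design_probes",
    "screen_promiscuity",
    "write_probe_fasta",
    "parse_probe_fasta",
    "probe_bed",
    "design_report",
]

_NT_RE = re.compile(r"^[ACGTN]+$")
_LOCI = ("IGH", "IGK", "IGL")
_FUNCTIONALITY = {
    "F": "functional",
    "functional": "functional",
    "P": "pseudogene",
    "pseudogene": "pseudogene",
    "ORF": "ORF",
}


@dataclass(frozen=True)
class SegmentRecord:
    """One germline V/J/C gene segment in coding orientation."""

    gene_name: str
    allele: str
    segment_class: str  # V, J or C
    locus: str  # IGH, IGK or IGL
    functionality: str  # functional, pseudogene or ORF
    sequence: str
    genomic_interval: Optional[tuple[str, int, int, str]] = None  # (chrom, start0, end0, strand)

    @property
    def full_name(self) -> str:
        return f"{self.gene_name}*{self.allele}" if self.allele else self.gene_name


@dataclass(frozen=True)
class Probe:
    probe_id: str
    source: SegmentRecord
    anchored_end: str  # three_prime, five_prime or exon
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProbeConfig:
    probe_len: int = 120
    min_segment_len: int = 40
    promiscuity_k: int = 25
    promiscuity_max_hits: int = 5

    def __post_init__(self) -> None:
        if not (self.probe_len >= self.min_segment_len >= self.promiscuity_k >= 1):
            raise ValueError(
                "require probe_len >= min_segment_len >= promiscuity_k >= 1, got "
                f"{self.probe_len} >= {self.min_segment_len} >= {self.promiscuity_k}"
            )


@dataclass
class ParseReport:
    n_parsed: int = 0
    n_skipped: int = 0
    skipped_headers: list[str] = field(default_factory=list)


def _locus_from_gene(gene: str) -> Optional[str]:
    prefix = gene[:3].upper()
    return prefix if prefix in _LOCI else None


def _parse_simple_header(header: str) -> Optional[dict]:
    # >gene|class|locus|functionality  (gene may carry an *allele suffix)
    parts = header.split("|")
    if len(parts) != 4:
        return None
    name, seg_class, locus, func = (p.strip() for p in parts)
    seg_class = seg_class.upper()
    locus = locus.upper()
    func = _FUNCTIONALITY.get(func)
    if seg_class not in ("V", "J", "C") or locus not in _LOCI or func is None:
        return None
    gene, _, allele = name.partition("*")
    if _locus_from_gene(gene) != locus:
        return None
    return dict(gene_name=gene, allele=allele, segment_class=seg_class, locus=locus, functionality=func)


def _parse_imgt_header(header: str) -> Optional[dict]:
    # IMGT flat headers are pipe-delimited:
    # accession|IGHV1-2*02|Homo sapiens|F|V-REGION|...
    parts = header.split("|")
    if len(parts) < 5:
        return None
    allele_name = parts[1].strip()
    func_raw = parts[3].strip().strip("()[]")
    label = parts[4].strip().upper()
    gene, _, allele = allele_name.partition("*")
    locus = _locus_from_gene(gene)
    func = _FUNCTIONALITY.get(func_raw)
    if locus is None or func is None:
        return None
    if label.startswith("V"):
        seg_class = "V"
    elif label.startswith("J"):
        seg_class = "J"
    elif label.startswith(("C", "EX")):
        seg_class = "C"
    else:
        return None
    return dict(gene_name=gene, allele=allele, segment_class=seg_class, locus=locus, functionality=func)


def parse_segment_fasta(
    path: str | Path, dialect: str = "simple"
) -> tuple[list[SegmentRecord], ParseReport]:
    """Parse a germline segment FASTA under the given header dialect.

    Unparseable headers are skipped and counted in the report;
    non-nucleotide sequence characters are a hard error naming the record.
    """
    if dialect not in ("simple", "imgt_header"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parse_header = _parse_simple_header if dialect == "simple" else _parse_imgt_header
    records: list[SegmentRecord] = []
    report = ParseReport()
    n_entries = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        header = rec.description
        seq = str(rec.seq).upper().replace(".", "")  # IMGT gap dots
        fields = parse_header(header)
        if fields is None:
            report.n_skipped += 1
            report.skipped_headers.append(header)
            continue
        if not seq or not _NT_RE.match(seq):
            raise ValueError(f"non-nucleotide characters in record {header!r}")
        records.append(SegmentRecord(sequence=seq, **fields))
    if n_entries == 0:
        raise ValueError(f"empty segment FASTA: {path}")
    report.n_parsed = len(records)
    return records, report


def _probes_for_segment(seg: SegmentRecord, cfg: ProbeConfig) -> list[Probe]:
    L = cfg.probe_len
    seq = seg.sequence
    if seg.segment_class == "V":
        return [Probe(f"{seg.full_name}|3p", seg, "three_prime", seq[-L:])]
    if seg.segment_class == "J":
        return [Probe(f"{seg.full_name}|5p", seg, "five_prime", seq[:L])]
    # C segments: whole exon if short enough, otherwise full-length tiles
    # stepped from the 5' end; the final tile is anchored to the 3' end so
    # every probe is exactly probe_len.
    if len(seq) <= L:
        return [Probe(f"{seg.full_name}|exon", seg, "exon", seq)]
    starts = list(range(0, len(seq) - L, L)) + [len(seq) - L]
    return [Probe(f"{seg.full_name}|exon{i}", seg, "exon", seq[s : s + L]) for i, s in enumerate(starts)]


def design_probes(segments: Iterable[SegmentRecord], cfg: ProbeConfig | None = None) -> list[Probe]:
    """Derive the capture probe panel from parsed segments.

    V segments yield 3'-anchored probes, J segments 5'-anchored probes,
    C segments exon probes/tiles. Segments shorter than
    ``min_segment_len`` are skipped; probes are deduplicated on exact
    sequence identity keeping the lexicographically smallest probe_id.
    """
    cfg = cfg or ProbeConfig()
    by_seq: dict[str, Probe] = {}
    for seg in segments:
        if len(seg.sequence) < cfg.min_segment_len:
            continue
        for probe in _probes_for_segment(seg, cfg):
            prev = by_seq.get(probe.sequence)
            if prev is None or probe.probe_id < prev.probe_id:
                by_seq[probe.sequence] = probe
    return sorted(by_seq.values(), key=lambda p: p.probe_id)


def screen_promiscuity(
    probes: list[Probe], cfg: ProbeConfig | None = None
) -> tuple[list[Probe], list[Probe]]:
    """Flag probes sharing exact k-mers with too many other probes.

    A probe is flagged when more than ``promiscuity_max_hits`` *other*
    probes share at least one exact ``promiscuity_k``-mer with it.
    Returns (kept, flagged); the union is the input, order preserved.
    """
    cfg = cfg or ProbeConfig()
    k = cfg.promiscuity_k
    kmer_index: dict[str, set[int]] = defaultdict(set)
    for idx, probe in enumerate(probes):
        seq = probe.sequence
        for i in range(max(0, len(seq) - k + 1)):
            kmer_index[seq[i : i + k]].add(idx)
    kept, flagged = [], []
    for idx, probe in enumerate(probes):
        seq = probe.sequence
        hits: set[int] = set()
        for i in range(max(0, len(seq) - k + 1)):
            hits |= kmer_index[seq[i : i + k]]
        hits.discard(idx)
        if cfg.promiscuity_max_hits is not None and len(hits) > cfg.promiscuity_max_hits:
            flagged.append(probe)
        else:
            kept.append(probe)
    return kept, flagged


def write_probe_fasta(probes: Iterable[Probe], path: str | Path) -> None:
    """Write probes as ``>probe_id|source|anchored_end`` FASTA."""
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}|{p.source.full_name}|{p.anchored_end}\n{p.sequence}\n")


def parse_probe_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read back a probe FASTA as (probe_id, anchored_end, sequence)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        out.append(("|".join(parts[:-2]), parts[-1], str(rec.seq).upper()))
    return out


def probe_bed(probes: Iterable[Probe]) -> list[tuple[str, int, int, str]]:
    """0-based half-open genomic intervals for probes whose source has one.

    Probe coordinates are taken from the anchored end of the source
    segment's genomic interval; the segment strand rides along in the name.
    """
    rows = []
    for p in probes:
        gi = p.source.genomic_interval
        if gi is None:
            continue
        chrom, start0, end0, strand = gi
        L = p.length
        at_three_prime = p.anchored_end == "three_prime"
        # on the minus strand the segment 3' end is the interval start
        if at_three_prime != (strand == "-"):
            rows.append((chrom, max(start0, end0 - L), end0, f"{p.probe_id}|{strand}"))
        else:
            rows.append((chrom, start0, min(end0, start0 + L), f"{p.probe_id}|{strand}"))
    return rows


def design_report(
    segments: list[SegmentRecord], probes: list[Probe], flagged: list[Probe], cfg: ProbeConfig
) -> list[dict]:
    """Per-class summary rows for the design report TSV."""
    rows = []
    for seg_class in ("V", "J", "C"):
        segs = [s for s in segments if s.segment_class == seg_class]
        prbs = [p for p in probes if p.source.segment_class == seg_class]
        flg = [p for p in flagged if p.source.segment_class == seg_class]
        rows.append(
            {
                "segment_class": seg_class,
                "n_segments": len(segs),
                "n_too_short": sum(len(s.sequence) < cfg.min_segment_len for s in segs),
                "n_probes": len(prbs),
                "n_flagged_promiscuous": len(flg),
            }
        )
    return rows
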