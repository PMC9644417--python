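"""Seeded synthetic data: capture-like reads with planted translocations,
dilution series, and clone-table cohorts with planted dominant clones.

The read simulator emulates a hybrid-capture experiment around planted
inter-chromosomal junctions. A derivative chromosome joins the A-side
partner (the baited locus) to the B side; each fragment is
tumor-derived with probability ``tumor_fraction``. Tumor fragments are
drawn around the junction on the derivative, normal fragments around
the baited locus on the unrearranged chromosome. Reads overlapping the
junction are emitted already aligned, soft-clipped at the junction on
the side carrying the minority of their bases, with correct CIGAR,
mate fields and flags — no external aligner is in the loop, so the
caller under test is isolated from aligner behaviour. Fragment lengths
are Normal(300, 30) by default (or 150 to mimic cell-free DNA), reads
150 bp, PCR duplicates injected at a 2% rate.

The clone-cohort simulator emulates the statistical structure of
assembler output on monoclonal samples: one dominant clone per locus
(clonal fraction drawn well above 0.15) plus low-fraction artifact
clones (fractions log-uniform over [0.005, 0.5], hence heavily skewed
low), a configurable subset of which recur across many samples to
exercise the cohort-specificity filter.

Every output byte is a deterministic function of the config; each
output stream draws from its own RNG namespace derived from the master
seed, so adding a stream never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .clump import AlignedReadView
from .io import write_bed
from .vdj_filter import CloneRecord, write_clone_table

__all__ = [
    "SimConfig",
    "PlantedBreakpoint",
    "PlantedClone",
    "TruthSet",
    "Reference",
    "SimResult",
    "PlantedCloneSpec",
    "ArtifactCloneSpec",
    "make_reference",
    "simulate_translocation_reads",
    "simulate_dilution_series",
    "simulate_clone_cohort",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    seed: int = 0
    # (chrom, length, optional Ig-locus (start0, end0))
    ref_spec: Sequence[tuple] = (("chr14", 50_000, (20_000, 30_000)), ("chr4", 50_000, None))
    # ((chromA, posA), (chromB, posB)), 1-based; A is the baited side
    breakpoints: Sequence[tuple[tuple[str, int], tuple[str, int]]] = (
        (("chr14", 25_000), ("chr4", 25_000)),
    )
    tumor_fraction: float = 0.1
    n_fragments: int = 20_000
    frag_len_mean: int = 300
    frag_len_sd: int = 30
    read_len: int = 150
    dup_rate: float = 0.02
    baseq_mean: float = 35.0
    baseq_sd: float = 3.0
    capture_span: int = 1000  # fragments drawn within +/- span of the bait

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.read_len > self.frag_len_mean:
            raise ValueError("read_len must not exceed frag_len_mean")
        lengths = {c: l for c, l, *_ in self.ref_spec}
        for (ca, pa), (cb, pb) in self.breakpoints:
            for chrom, pos in ((ca, pa), (cb, pb)):
                if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
                    raise ValueError(f"breakpoint {chrom}:{pos} outside reference")


@dataclass(frozen=True)
class PlantedBreakpoint:
    chrom_a: str
    pos_a: int  # last A-side base before the junction (1-based)
    chrom_b: str
    pos_b: int  # first B-side base after the junction (1-based)
    junction_seq_a: str  # partner bases appearing in clips at side A
    junction_seq_b: str  # partner bases appearing in clips at side B


@dataclass(frozen=True)
class PlantedClone:
    sample_id: str
    locus: str
    cdr3_nt: str
    clone_count: int
    clone_fraction: float


@dataclass
class TruthSet:
    breakpoints: list[PlantedBreakpoint] = field(default_factory=list)
    clones: list[PlantedClone] = field(default_factory=list)
    fragment_origins: list[int] = field(default_factory=list)  # 1 = tumor
    tumor_fraction: Optional[float] = None
    shared_artifacts: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_tumor_fragments(self) -> int:
        return int(sum(self.fragment_origins))


@dataclass
class Reference:
    seqs: dict[str, str]
    ig_intervals: list[tuple[str, int, int, str]]

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "reference.fa"
        with open(fasta, "w") as fh:
            for chrom, seq in self.seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        bed = out_dir / "ig_loci.bed"
        write_bed(self.ig_intervals, bed)
        return fasta, bed


@dataclass
class SimResult:
    reads: list[AlignedReadView]
    truth: TruthSet
    reference: Reference
    sam_path: Optional[Path] = None


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *stream]))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def make_reference(cfg: SimConfig) -> Reference:
    """Seeded random reference sequences plus Ig-locus BED intervals."""
    rng = _rng(cfg.seed, 0)
    seqs: dict[str, str] = {}
    ig: list[tuple[str, int, int, str]] = []
    for entry in cfg.ref_spec:
        chrom, length = entry[0], entry[1]
        seqs[chrom] = _random_seq(rng, length)
        interval = entry[2] if len(entry) > 2 else None
        if interval is not None:
            ig.append((chrom, interval[0], interval[1], f"{chrom}_ig"))
    return Reference(seqs=seqs, ig_intervals=ig)


# ---------------------------------------------------------------------------
# aligned-read simulation


def _map_derivative_interval(
    s: int, e: int, seq_a: str, seq_b: str, bp: tuple, read_len: int
) -> tuple[str, int, str, str, str, int, str]:
    """Map a derivative-coordinate interval [s, e] to an alignment.

    The derivative is chromA[1..posA] ++ chromB[posB..]; the junction
    sits after derivative position D = posA. Junction-spanning reads are
    aligned to the side holding the majority of their bases (ties to A)
    and soft-clipped on the other side.
    Returns (chrom, pos, cigar, clipped_prefix, clipped_suffix, ref_len, seq).
    """
    (chrom_a, pos_a), (chrom_b, pos_b) = bp
    D = pos_a
    a_lo, a_hi = s, min(e, D)
    b_lo, b_hi = max(s, D + 1), e
    a_seq = seq_a[a_lo - 1 : a_hi] if a_hi >= a_lo else ""
    b_seq = seq_b[pos_b - 1 + (b_lo - D - 1) : pos_b - 1 + (b_hi - D)] if b_hi >= b_lo else ""
    a, b = len(a_seq), len(b_seq)
    seq = a_seq + b_seq
    if b == 0:
        return chrom_a, a_lo, f"{a}M", "", "", a, seq
    if a == 0:
        return chrom_b, pos_b + (b_lo - D - 1), f"{b}M", "", "", b, seq
    if a >= b:
        return chrom_a, pos_a - a + 1, f"{a}M{b}S", "", b_seq, a, seq
    return chrom_b, pos_b, f"{a}S{b}M", a_seq, "", b, seq


def simulate_translocation_reads(
    cfg: SimConfig,
    reference: Optional[Reference] = None,
    out_sam: Optional[str | Path] = None,
) -> SimResult:
    """Generate coordinate-sorted aligned paired-end reads around the
    planted junctions, with soft-clipped junction reads,
    inter-chromosomal mate pairs, injected duplicates, and a truth set
    recording every planted junction sequence."""
    ref = reference or make_reference(cfg)
    lengths = {c: len(s) for c, s in ref.seqs.items()}
    rl = cfg.read_len
    for (ca, pa), (cb, pb) in cfg.breakpoints:
        if pa <= rl or pa + rl > lengths[ca] or pb <= rl or pb + rl > lengths[cb]:
            raise ValueError(f"junction ({ca}:{pa})-({cb}:{pb}) within read_len of a chromosome end")

    rng = _rng(cfg.seed, 1)
    n = cfg.n_fragments
    is_tumor = rng.random(n) < cfg.tumor_fraction
    flens = np.clip(
        np.rint(rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, size=n)).astype(int), rl, None
    )
    bp_idx = rng.integers(0, len(cfg.breakpoints), size=n)
    start_u = rng.random(n)
    quals = np.clip(rng.normal(cfg.baseq_mean, cfg.baseq_sd, size=(n, 2)), 2.0, 40.0)
    dup = rng.random(n) < cfg.dup_rate

    span = cfg.capture_span
    records: list[AlignedReadView] = []
    origins: list[int] = []
    for i in range(n):
        flen = int(flens[i])
        (chrom_a, pos_a), (chrom_b, pos_b) = bp = cfg.breakpoints[int(bp_idx[i])]
        seq_a, seq_b = ref.seqs[chrom_a], ref.seqs[chrom_b]
        if is_tumor[i]:
            D = pos_a
            lo = max(1, D - span)
            hi = min(D + span, D + (lengths[chrom_b] - pos_b + 1)) - flen
            if hi < lo:
                hi = lo
            s = lo + int(start_u[i] * (hi - lo + 1))
            maps = [
                _map_derivative_interval(s, s + rl - 1, seq_a, seq_b, bp, rl),
                _map_derivative_interval(s + flen - rl, s + flen - 1, seq_a, seq_b, bp, rl),
            ]
            qname = f"t{i:06d}"
            origins.append(1)
        else:
            lo = max(1, pos_a - span)
            hi = min(lengths[chrom_a] - flen + 1, pos_a + span - flen)
            if hi < lo:
                hi = lo
            s = lo + int(start_u[i] * (hi - lo + 1))
            maps = [
                (chrom_a, s, f"{rl}M", "", "", rl, seq_a[s - 1 : s + rl - 1]),
                (
                    chrom_a,
                    s + flen - rl,
                    f"{rl}M",
                    "",
                    "",
                    rl,
                    seq_a[s + flen - rl - 1 : s + flen - 1],
                ),
            ]
            qname = f"n{i:06d}"
            origins.append(0)

        pair = []
        for r in range(2):
            chrom, pos, cigar, cpre, csuf, ref_len, seq = maps[r]
            m_chrom, m_pos = maps[1 - r][0], maps[1 - r][1]
            if chrom == m_chrom:
                left = min(pos, m_pos)
                right = max(pos + ref_len - 1, maps[1 - r][1] + maps[1 - r][5] - 1)
                isize = right - left + 1
            else:
                isize = 0
            pair.append(
                AlignedReadView(
                    qname=qname,
                    chrom=chrom,
                    pos=pos,
                    mapq=60,
                    cigar=cigar,
                    mean_baseq=float(quals[i, r]),
                    mate_chrom=m_chrom,
                    mate_pos=m_pos,
                    insert_size=isize,
                    is_duplicate=False,
                    nm=0,
                    clipped_prefix=cpre,
                    clipped_suffix=csuf,
                    is_reverse=bool(r),
                    read_len=rl,
                    ref_len=ref_len,
                    seq=seq,
                )
            )
        records.extend(pair)
        if dup[i]:
            for r in pair:
                records.append(dataclasses.replace(r, qname=r.qname + ".d1", is_duplicate=True))

    chrom_order = {entry[0]: k for k, entry in enumerate(cfg.ref_spec)}
    records.sort(key=lambda r: (chrom_order[r.chrom], r.pos, r.qname, r.is_reverse))

    truth = TruthSet(tumor_fraction=cfg.tumor_fraction, fragment_origins=origins)
    for (ca, pa), (cb, pb) in cfg.breakpoints:
        truth.breakpoints.append(
            PlantedBreakpoint(
                chrom_a=ca,
                pos_a=pa,
                chrom_b=cb,
                pos_b=pb,
                junction_seq_a=ref.seqs[cb][pb - 1 : pb - 1 + rl],
                junction_seq_b=ref.seqs[ca][pa - rl : pa],
            )
        )
    sam_path = None
    if out_sam is not None:
        sam_path = Path(out_sam)
        write_sam(records, cfg, sam_path)
    return SimResult(reads=records, truth=truth, reference=ref, sam_path=sam_path)


def write_sam(records: Sequence[AlignedReadView], cfg: SimConfig, path: str | Path) -> None:
    """Write simulated records as coordinate-sorted SAM text."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": entry[0], "LN": entry[1]} for entry in cfg.ref_spec],
    }
    tid = {entry[0]: k for k, entry in enumerate(cfg.ref_spec)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.qname
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos - 1
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar
            a.query_sequence = r.seq or "N" * r.read_len
            a.query_qualities = pysam.qualitystring_to_array(
                chr(int(round(r.mean_baseq)) + 33) * r.read_len
            )
            flag = 0x1 | (0x80 if r.is_reverse else 0x40)
            if r.is_reverse:
                flag |= 0x10
            else:
                flag |= 0x20
            if r.chrom == r.mate_chrom:
                flag |= 0x2
            if r.is_duplicate:
                flag |= 0x400
            a.flag = flag
            a.next_reference_id = tid[r.mate_chrom]
            a.next_reference_start = r.mate_pos - 1
            a.template_length = r.insert_size if not r.is_reverse else -r.insert_size
            a.set_tag("NM", r.nm)
            fh.write(a)


def simulate_dilution_series(
    cfg: SimConfig,
    dilutions: Sequence[float],
    out_dir: Optional[str | Path] = None,
) -> tuple[dict[str, SimResult], dict]:
    """One simulated run per dilution, sharing reference and breakpoints.

    Per-dilution seeds are derived from the master seed and the dilution
    index, so runs are independent but fully reproducible. Returns
    (results keyed by dilution label, manifest).
    """
    ref = make_reference(cfg)
    results: dict[str, SimResult] = {}
    manifest: dict = {"seed": cfg.seed, "dilutions": []}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for idx, dil in enumerate(dilutions):
        child_seed = int(np.random.SeedSequence([cfg.seed, 7, idx]).generate_state(1)[0] % 2**31)
        sub = dataclasses.replace(cfg, tumor_fraction=float(dil), seed=child_seed)
        label = f"{dil:g}"
        sam = out_path / f"dilution_{label}.sam" if out_path is not None else None
        results[label] = simulate_translocation_reads(sub, reference=ref, out_sam=sam)
        manifest["dilutions"].append(
            {
                "label": label,
                "tumor_fraction": float(dil),
                "seed": child_seed,
                "n_fragments": cfg.n_fragments,
                "sam": str(sam) if sam is not None else None,
            }
        )
    if out_path is not None:
        with open(out_path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
    return results, manifest


# ---------------------------------------------------------------------------
# clone cohorts

_GENES = {
    "IGH": (
        ["IGHV1-2", "IGHV3-30", "IGHV3-9", "IGHV4-39", "IGHV4-4"],
        ["IGHD2-2", "IGHD3-10", "IGHD3-22"],
        ["IGHJ3", "IGHJ4", "IGHJ6"],
    ),
    "IGK": (["IGKV3-15", "IGKV1-37", "IGKV4-1"], [], ["IGKJ2", "IGKJ4", "IGKJ5"]),
    "IGL": (["IGLV2-14", "IGLV1-44"], [], ["IGLJ2", "IGLJ3"]),
}


@dataclass
class PlantedCloneSpec:
    n_per_locus: int = 1
    loci: Sequence[str] = ("IGH",)
    fraction_range: tuple[float, float] = (0.3, 0.9)  # raw weight, pre-normalisation


@dataclass
class ArtifactCloneSpec:
    n_per_sample: int = 20
    fraction_range: tuple[float, float] = (0.005, 0.5)  # log-uniform, skewed low
    n_shared: int = 1
    shared_in: int = 8  # samples carrying each shared artifact
    # recurrent polymorphism-like artifacts can be prominent; None = fraction_range
    shared_fraction_range: Optional[tuple[float, float]] = None


def simulate_clone_cohort(
    n_samples: int = 10,
    planted: PlantedCloneSpec | None = None,
    artifacts: ArtifactCloneSpec | None = None,
    seed: int = 0,
    depth_range: tuple[int, int] = (1000, 3000),
    out_dir: Optional[str | Path] = None,
) -> tuple[dict[str, list[CloneRecord]], TruthSet]:
    """Generate per-sample clone tables with planted dominant clones,
    low-fraction artifacts and cross-sample shared artifacts. Fractions
    are normalised per (sample, locus); counts derive from a per-locus
    sequencing depth."""
    planted = planted or PlantedCloneSpec()
    artifacts = artifacts or ArtifactCloneSpec()
    shared_in = min(artifacts.shared_in, n_samples)  # capped at cohort size
    rng = _rng(seed, 2)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    truth = TruthSet()

    shared: list[tuple[str, str, set[str]]] = []  # (locus, cdr3, members)
    for _ in range(artifacts.n_shared):
        locus = planted.loci[int(rng.integers(0, len(planted.loci)))]
        cdr3 = _random_seq(rng, int(rng.integers(30, 61)))
        members = set(rng.choice(samples, size=shared_in, replace=False).tolist())
        shared.append((locus, cdr3, members))
        truth.shared_artifacts[cdr3] = sorted(members)

    def gene_triplet(locus: str) -> tuple[str, str, str]:
        vs, ds, js = _GENES[locus]
        v = vs[int(rng.integers(0, len(vs)))]
        d = ds[int(rng.integers(0, len(ds)))] if ds else ""
        j = js[int(rng.integers(0, len(js)))]
        return v, d, j

    lo_f, hi_f = artifacts.fraction_range
    cohort: dict[str, list[CloneRecord]] = {}
    for sample in samples:
        rows: list[tuple[str, str, str, str, str, float, bool]] = []
        for locus in planted.loci:
            for _ in range(planted.n_per_locus):
                v, d, j = gene_triplet(locus)
                cdr3 = _random_seq(rng, int(rng.integers(30, 61)))
                w = float(rng.uniform(*planted.fraction_range))
                rows.append((locus, v, d, j, cdr3, w, True))
            for _ in range(artifacts.n_per_sample):
                v, d, j = gene_triplet(locus)
                cdr3 = _random_seq(rng, int(rng.integers(30, 61)))
                w = float(np.exp(rng.uniform(np.log(lo_f), np.log(hi_f))))
                rows.append((locus, v, d, j, cdr3, w, False))
        s_lo, s_hi = artifacts.shared_fraction_range or artifacts.fraction_range
        for locus, cdr3, members in shared:
            if sample in members:
                v, d, j = gene_triplet(locus)
                w = float(np.exp(rng.uniform(np.log(s_lo), np.log(s_hi))))
                rows.append((locus, v, d, j, cdr3, w, False))

        records: list[CloneRecord] = []
        for locus in {r[0] for r in rows}:
            locus_rows = [r for r in rows if r[0] == locus]
            depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
            total_w = sum(r[5] for r in locus_rows)
            counts = [max(1, int(round(r[5] / total_w * depth))) for r in locus_rows]
            total_c = sum(counts)
            for r, count in zip(locus_rows, counts):
                _, v, d, j, cdr3, _, is_planted = r
                fraction = count / total_c
                records.append(
                    CloneRecord(
                        sample_id=sample,
                        locus=locus,
                        v_gene=v,
                        d_gene=d,
                        j_gene=j,
                        cdr3_nt=cdr3,
                        cdr3_aa="",
                        clone_count=count,
                        clone_fraction=fraction,
                    )
                )
                if is_planted:
                    truth.clones.append(
                        PlantedClone(
                            sample_id=sample,
                            locus=locus,
                            cdr3_nt=cdr3,
                            clone_count=count,
                            clone_fraction=fraction,
                        )
                    )
        records.sort(key=lambda c: (-c.clone_count, c.cdr3_nt))
        cohort[sample] = records

    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for sample, records in cohort.items():
            write_clone_table(records, out_path / f"{sample}.tsv")
    return cohort, truth
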