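from pathlib import Path

import numpy as np
import pytest

from capig.clump import AlignedReadView

DATA_DIR = Path(__file__).parent / "data"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def make_read(
    qname="r1",
    chrom="chr1",
    pos=1000,
    mapq=60,
    cigar="150M",
    mean_baseq=35.0,
    mate_chrom="chr1",
    mate_pos=1200,
    insert_size=300,
    is_duplicate=False,
    nm=0,
    clipped_prefix="",
    clipped_suffix="",
    is_reverse=False,
    read_len=150,
    ref_len=None,
) -> AlignedReadView:
    if ref_len is None:
        ref_len = read_len - len(clipped_prefix) - len(clipped_suffix)
    return AlignedReadView(
        qname=qname,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        cigar=cigar,
        mean_baseq=mean_baseq,
        mate_chrom=mate_chrom,
        mate_pos=mate_pos,
        insert_size=insert_size,
        is_duplicate=is_duplicate,
        nm=nm,
        clipped_prefix=clipped_prefix,
        clipped_suffix=clipped_suffix,
        is_reverse=is_reverse,
        read_len=read_len,
        ref_len=ref_len,
    )


def make_pair(qname, chrom1, pos1, chrom2, pos2, mapq=(60, 60), insert=None, dup=False):
    """A mutually-consistent mate pair for extraction tests."""
    if insert is None:
        insert = abs(pos2 - pos1) + 150 if chrom1 == chrom2 else 0
    r1 = make_read(
        qname=qname, chrom=chrom1, pos=pos1, mapq=mapq[0], mate_chrom=chrom2,
        mate_pos=pos2, insert_size=insert, is_duplicate=dup,
    )
    r2 = make_read(
        qname=qname, chrom=chrom2, pos=pos2, mapq=mapq[1], mate_chrom=chrom1,
        mate_pos=pos1, insert_size=insert, is_duplicate=dup, is_reverse=True,
    )
    return r1, r2


def sort_reads(reads, chrom_order=None):
    """Coordinate-sort with a stable chromosome block order."""
    if chrom_order is None:
        chrom_order = sorted({r.chrom for r in reads})
    rank = {c: i for i, c in enumerate(chrom_order)}
    return sorted(reads, key=lambda r: (rank[r.chrom], r.pos, r.qname))


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def toy_segment_fasta(tmp_path):
    """Toy germline segment reference: 12 V, 2 J, 1 C, one malformed header."""
    rng = np.random.default_rng(42)
    path = tmp_path / "segments.fa"
    with open(path, "w") as fh:
        for i in range(12):
            fh.write(f">IGHV{i + 1}-1*01|V|IGH|functional\n{random_seq(rng, 300)}\n")
        fh.write(f">IGHJ4*01|J|IGH|functional\n{random_seq(rng, 60)}\n")
        fh.write(f">IGKJ1*01|J|IGK|functional\n{random_seq(rng, 55)}\n")
        fh.write(f">IGHM*01|C|IGH|functional\n{random_seq(rng, 310)}\n")
        fh.write(f">not_a_segment_header\n{random_seq(rng, 80)}\n")
    return path
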