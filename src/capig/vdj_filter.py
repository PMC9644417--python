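"""V(D)J clonotype candidate filtering over MiXCR-style clone tables.

Clone assemblers emit many candidate clonotypes per sample; in a
monoclonal plasma-cell disorder only a handful are real. The filtering
cascade encoded here keeps a candidate iff it

1. does not hit a pseudogene,
2. has a clonal fraction > 0.10 of reads at its immunoglobulin locus
   (fractions are recomputed per (sample, locus) from raw counts),
3. its exact CDR3 nucleotide sequence occurs in at most 5 samples of
   the cohort (recurrent sequences are polymorphisms or capture
   artifacts, not clones), and
4. has an absolute clone count > 50 (cell lines) or > 10 (patient
   samples, where sensitivity is preferred).

All inequalities are strict where stated. The specificity filter counts
occurrences among post-fraction-filter candidates.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "CloneRecord",
    "FilterConfig",
    "CohortIndex",
    "DEFAULT_COLUMN_MAP",
    "load_clone_table",
    "remove_pseudogenes",
    "recompute_locus_fractions",
    "filter_by_fraction",
    "build_cohort_index",
    "filter_by_specificity",
    "filter_by_count",
    "call_candidates",
    "write_clone_table",
]

_LOCI = ("IGH", "IGK", "IGL")


@dataclass(frozen=True, slots=True)
class CloneRecord:
    sample_id: str
    locus: str
    v_gene: str
    d_gene: str  # empty when absent
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    clone_count: int
    clone_fraction: float
    is_pseudogene_hit: bool = False


@dataclass
class FilterConfig:
    min_fraction: float = 0.10  # strict >
    max_cohort_occurrences: int = 5  # inclusive <=
    min_count_cell_line: int = 50  # strict >
    min_count_patient: int = 10  # strict >
    mode: str = "cell_line"

    def __post_init__(self) -> None:
        if self.mode not in ("cell_line", "patient"):
            raise ValueError(f"mode must be cell_line or patient, got {self.mode!r}")
        if min(self.min_fraction, self.max_cohort_occurrences, self.min_count_cell_line, self.min_count_patient) <= 0:
            raise ValueError("filter thresholds must be positive")

    @property
    def min_count(self) -> int:
        return self.min_count_cell_line if self.mode == "cell_line" else self.min_count_patient


@dataclass
class CohortIndex:
    """cdr3_nt -> set of sample_ids containing it among candidates."""

    samples_by_cdr3: dict[str, set[str]] = field(default_factory=dict)

    def occurrence(self, cdr3_nt: str) -> int:
        return len(self.samples_by_cdr3.get(cdr3_nt, ()))


# MiXCR exportClones-style column names
DEFAULT_COLUMN_MAP = {
    "count": "cloneCount",
    "fraction": "cloneFraction",
    "v": "allVHitsWithScore",
    "d": "allDHitsWithScore",
    "j": "allJHitsWithScore",
    "cdr3_nt": "nSeqCDR3",
    "cdr3_aa": "aaSeqCDR3",
}

_SCORE_RE = re.compile(r"\(.*?\)")


def _clean_gene(raw: object) -> str:
    """First hit of a MiXCR hit list, score and allele stripped."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ""
    first = str(raw).split(",")[0].strip()
    first = _SCORE_RE.sub("", first)
    return first.split("*")[0].strip()


def load_clone_table(
    path: str | Path,
    sample_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[CloneRecord], list[int]]:
    """Load a MiXCR-export-like TSV into CloneRecords.

    Locus is inferred from the V-gene prefix. Returns (records, rejected
    row numbers); rows with unparsable counts/fractions or an
    unrecognisable locus are rejected. A missing mandatory column is a
    hard error naming it.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("count", "fraction", "v", "j", "cdr3_nt"):
        if cmap[key] not in df.columns:
            raise ValueError(f"missing mandatory column {cmap[key]!r} in {path}")
    sample = sample_id if sample_id is not None else Path(path).stem
    records: list[CloneRecord] = []
    rejected: list[int] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rd = dict(zip(df.columns, row))
        v_gene = _clean_gene(rd[cmap["v"]])
        locus = v_gene[:3].upper()
        cdr3 = str(rd[cmap["cdr3_nt"]] or "").strip().upper()
        try:
            count = int(float(rd[cmap["count"]]))
            fraction = float(rd[cmap["fraction"]])
        except (TypeError, ValueError):
            rejected.append(idx)
            continue
        if locus not in _LOCI or count < 1 or not cdr3:
            rejected.append(idx)
            continue
        records.append(
            CloneRecord(
                sample_id=sample,
                locus=locus,
                v_gene=v_gene,
                d_gene=_clean_gene(rd.get(cmap["d"])) if cmap["d"] in df.columns else "",
                j_gene=_clean_gene(rd[cmap["j"]]),
                cdr3_nt=cdr3,
                cdr3_aa=str(rd.get(cmap["cdr3_aa"], "") or "") if cmap["cdr3_aa"] in df.columns else "",
                clone_count=count,
                clone_fraction=fraction,
            )
        )
    return records, rejected


def remove_pseudogenes(clones: Iterable[CloneRecord], pseudogene_names: set[str]) -> list[CloneRecord]:
    """Drop clones whose V or J gene is in the pseudogene set."""
    kept = []
    for c in clones:
        if c.v_gene in pseudogene_names or c.j_gene in pseudogene_names:
            continue
        kept.append(c)
    return kept


def recompute_locus_fractions(clones: Iterable[CloneRecord]) -> list[CloneRecord]:
    """clone_fraction := clone_count / total count at the same (sample, locus)."""
    clones = list(clones)
    totals: dict[tuple[str, str], int] = defaultdict(int)
    for c in clones:
        totals[(c.sample_id, c.locus)] += c.clone_count
    return [
        replace(c, clone_fraction=c.clone_count / totals[(c.sample_id, c.locus)]) for c in clones
    ]


def filter_by_fraction(clones: Iterable[CloneRecord], cfg: FilterConfig) -> list[CloneRecord]:
    """Keep iff clone_fraction > min_fraction (strict)."""
    return [c for c in clones if c.clone_fraction > cfg.min_fraction]


def build_cohort_index(candidate_lists: Mapping[str, Iterable[CloneRecord]]) -> CohortIndex:
    """Index exact CDR3 sequences to the distinct samples containing them.

    Samples from the same donor are not collapsed.
    """
    index = CohortIndex()
    for sample, clones in candidate_lists.items():
        for c in clones:
            index.samples_by_cdr3.setdefault(c.cdr3_nt, set()).add(sample)
    return index


def filter_by_specificity(
    clones: Iterable[CloneRecord], index: CohortIndex, cfg: FilterConfig
) -> list[CloneRecord]:
    """Keep iff the CDR3 occurs in <= max_cohort_occurrences samples."""
    return [c for c in clones if index.occurrence(c.cdr3_nt) <= cfg.max_cohort_occurrences]


def filter_by_count(clones: Iterable[CloneRecord], cfg: FilterConfig) -> list[CloneRecord]:
    """Keep iff clone_count > mode-dependent threshold (strict)."""
    return [c for c in clones if c.clone_count > cfg.min_count]


def _sorted_out(clones: list[CloneRecord]) -> list[CloneRecord]:
    return sorted(clones, key=lambda c: (-c.clone_count, c.cdr3_nt))


def call_candidates(
    cohort: Mapping[str, Iterable[CloneRecord]],
    cfg: FilterConfig | None = None,
    pseudogenes: Optional[set[str]] = None,
) -> tuple[dict[str, list[CloneRecord]], dict]:
    """Run the full cascade over a cohort of per-sample clone tables.

    Stage order: pseudogene removal -> per-locus fraction recompute ->
    fraction filter -> cohort specificity filter (occurrences counted
    among post-fraction candidates) -> count filter. Returns per-sample
    candidate lists (sorted by (-count, cdr3)) and an audit report with
    per-stage drop counts per sample.
    """
    cfg = cfg or FilterConfig()
    pseudogenes = pseudogenes or set()
    audit: dict = {"per_sample": {}, "config": vars(cfg).copy()}
    staged: dict[str, list[CloneRecord]] = {}
    for sample, clones in cohort.items():
        clones = list(clones)
        n0 = len(clones)
        no_pseudo = remove_pseudogenes(clones, pseudogenes)
        refr = recompute_locus_fractions(no_pseudo)
        frac = filter_by_fraction(refr, cfg)
        staged[sample] = frac
        audit["per_sample"][sample] = {
            "input": n0,
            "dropped_pseudogene": n0 - len(no_pseudo),
            "dropped_fraction": len(no_pseudo) - len(frac),
        }
    index = build_cohort_index(staged)
    out: dict[str, list[CloneRecord]] = {}
    for sample, frac in staged.items():
        spec = filter_by_specificity(frac, index, cfg)
        final = filter_by_count(spec, cfg)
        rec = audit["per_sample"][sample]
        rec["dropped_specificity"] = len(frac) - len(spec)
        rec["dropped_count"] = len(spec) - len(final)
        rec["candidates"] = len(final)
        out[sample] = _sorted_out(final)
    return out, audit


CLONE_COLUMNS = ["cloneCount", "cloneFraction", "allVHitsWithScore", "allDHitsWithScore", "allJHitsWithScore", "nSeqCDR3", "aaSeqCDR3"]


def write_clone_table(clones: Iterable[CloneRecord], path: str | Path) -> None:
    """Write clones back out in MiXCR-export-like TSV form."""
    rows = [
        {
            "cloneCount": c.clone_count,
            "cloneFraction": f"{c.clone_fraction:.6g}",
            "allVHitsWithScore": c.v_gene,
            "allDHitsWithScore": c.d_gene,
            "allJHitsWithScore": c.j_gene,
            "nSeqCDR3": c.cdr3_nt,
            "aaSeqCDR3": c.cdr3_aa,
        }
        for c in clones
    ]
    pd.DataFrame(rows, columns=CLONE_COLUMNS).to_csv(path, sep="\t", index=False)
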