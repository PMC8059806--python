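"""Genomic context for mapped variants: QTL interval overlap and conservation.

QTL intervals come from an Animal QTLdb-style TSV (1-based inclusive
coordinates, trait name and category).  Conservation is a phyloP-style
per-base track in bedGraph (0-based half-open): positive scores mark
slower-than-neutral evolution (conserved, "slow"), negative scores faster
("fast"), zero "neutral".  Positions not covered by the track are reported
as missing and excluded from class fractions, mirroring the fact that only
a subset of loci can be aligned to the scored genome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from intervaltree import IntervalTree

from mirsnp.mapping import MappedVariant

NEUTRAL_TOL = 1e-9


@dataclass(frozen=True)
class QtlInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    trait_name: str
    trait_category: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"QTL {self.trait_name}: end < start")


@dataclass(frozen=True)
class ConservationScore:
    chrom: str
    pos: int  # 1-based
    score: Optional[float]  # None when the track does not cover the position

    @property
    def missing(self) -> bool:
        return self.score is None

    @property
    def conservation_class(self) -> Optional[str]:
        """slow (score > 0), fast (< 0) or neutral (|score| <= 1e-9)."""
        if self.score is None:
            return None
        if self.score > NEUTRAL_TOL:
            return "slow"
        if self.score < -NEUTRAL_TOL:
            return "fast"
        return "neutral"


def load_qtl_table(path: Union[str, Path]) -> List[QtlInterval]:
    """Read a QTL TSV with columns chrom, start, end, trait_name, trait_category."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                QtlInterval(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    trait_name=row["trait_name"],
                    trait_category=row["trait_category"],
                )
            )
    return out


def load_bedgraph(path: Union[str, Path]) -> List[Tuple[str, int, int, float]]:
    """Read bedGraph rows (chrom, 0-based start, end, score)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, score = line.split("\t")
            rows.append((chrom, int(start), int(end), float(score)))
    return rows


def overlap_snps_qtl(
    mapped: Sequence[MappedVariant], qtls: Sequence[QtlInterval]
) -> List[Tuple[str, str, str, str]]:
    """All (snp_id, mirna_id, trait_name, trait_category) containment pairs.

    A pair is reported when the SNP position falls inside the QTL interval
    (1-based inclusive on both ends, same chromosome).  Output is sorted by
    (chrom, pos, trait_name, snp_id, mirna_id) and deduplicated: a SNP
    mapped to several matures of one precursor yields one row per QTL.
    """
    trees: Dict[str, IntervalTree] = {}
    for q in qtls:
        trees.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end + 1, q)
    seen = set()
    rows = []
    for mv in mapped:
        tree = trees.get(mv.chrom)
        if tree is None:
            continue
        for iv in tree.at(mv.pos):
            q: QtlInterval = iv.data
            key = (mv.snp_id, mv.precursor_id, q.trait_name, q.trait_category)
            if key in seen:
                continue
            seen.add(key)
            rows.append((mv.chrom, mv.pos, key))
    rows.sort(key=lambda r: (r[0], r[1], r[2][2], r[2][0], r[2][1]))
    return [key for _, _, key in rows]


def overlap_precursors_qtl(
    annotations: Iterable, qtls: Sequence[QtlInterval]
) -> List[Tuple[str, str, str]]:
    """(precursor_id, trait_name, trait_category) pairs by interval intersection.

    Alternative overlap rule judging the whole precursor interval rather
    than the SNP position (``--by-precursor``).
    """
    trees: Dict[str, IntervalTree] = {}
    for q in qtls:
        trees.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end + 1, q)
    rows = set()
    for ann in annotations:
        tree = trees.get(ann.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(ann.start, ann.end + 1):
            q = iv.data
            rows.add((ann.precursor_id, q.trait_name, q.trait_category))
    return sorted(rows)


def lookup_conservation(
    positions: Sequence[Tuple[str, int]],
    track: Sequence[Tuple[str, int, int, float]],
    mapping: Optional[Dict[Tuple[str, int], Tuple[str, int]]] = None,
) -> List[ConservationScore]:
    """Attach track scores to 1-based (chrom, pos) queries.

    ``track`` holds non-overlapping bedGraph intervals (0-based half-open);
    overlap raises a validation error.  ``mapping`` optionally translates
    source coordinates to track coordinates (e.g. a cross-species homology
    map); identity by default.  Uncovered positions get a missing score.
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end, score in track:
        if end <= start:
            raise ValueError(f"bedGraph interval with end <= start at {chrom}:{start}")
        tree = trees.setdefault(chrom, IntervalTree())
        if tree.overlap(start, end):
            raise ValueError(f"overlapping bedGraph intervals at {chrom}:{start}-{end}")
        tree.addi(start, end, score)
    out = []
    for chrom, pos in positions:
        t_chrom, t_pos = (mapping or {}).get((chrom, pos), (chrom, pos))
        hits = trees.get(t_chrom, IntervalTree()).at(t_pos - 1)  # 1-based -> 0-based
        score = next(iter(hits)).data if hits else None
        out.append(ConservationScore(chrom=chrom, pos=pos, score=score))
    return out


@dataclass(frozen=True)
class ConservationSummary:
    n_scored: int
    n_missing: int
    frac_slow: Optional[float]
    frac_neutral: Optional[float]
    frac_fast: Optional[float]

    @property
    def undefined(self) -> bool:
        return self.n_scored == 0


def conservation_summary(scores: Iterable[ConservationScore]) -> ConservationSummary:
    """Class fractions over scored loci; missing loci never enter denominators."""
    scores = list(scores)
    scored = [s for s in scores if not s.missing]
    n = len(scored)
    if n == 0:
        return ConservationSummary(0, len(scores), None, None, None)
    slow = sum(1 for s in scored if s.conservation_class == "slow")
    fast = sum(1 for s in scored if s.conservation_class == "fast")
    neutral = n - slow - fast
    return ConservationSummary(
        n_scored=n,
        n_missing=len(scores) - n,
        frac_slow=slow / n,
        frac_neutral=neutral / n,
        frac_fast=fast / n,
    )
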