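"""Canonical seed-match target prediction and reference-vs-variant target diffs.

A mature miRNA recognizes a 3'UTR mainly through Watson-Crick pairing of its
seed (nucleotides 2-8).  The canonical site-type hierarchy on the mRNA sense
strand is, for a mature sequence ``m``:

* ``8mer``     — reverse complement of m2-m8 followed by an A
* ``7mer-m8``  — reverse complement of m2-m8, not followed by an A
* ``7mer-A1``  — reverse complement of m2-m7 followed by an A, with the base
  aligned opposite m8 not pairing
* ``6mer``     — reverse complement of m2-m7 alone, with neither extension

The engine scans UTRs for these sites, decides targethood by a configurable
policy (which site types count, minimum sites per transcript) and diffs the
target sets obtained with the reference and the variant mature sequence into
gained / lost / maintained transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set

from mirsnp._seq import rna_complement, rna_revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: Site types that confer targethood by default.  6mer sites are marginal in
#: the canonical scheme: they are reported by :func:`seed_sites` but do not
#: count toward target calls unless the policy says so.
DEFAULT_COUNTED_TYPES = frozenset({"8mer", "7mer-m8", "7mer-A1"})

_UTR_ALPHABET = frozenset("ACGUN")


@dataclass(frozen=True)
class SitePolicy:
    """Which site types make a transcript a target, and how many are needed."""

    counted_site_types: FrozenSet[str] = DEFAULT_COUNTED_TYPES
    min_sites_per_transcript: int = 1

    def __post_init__(self) -> None:
        counted = frozenset(self.counted_site_types)
        if not counted:
            raise ValueError("counted_site_types must be non-empty")
        unknown = counted - set(SITE_TYPES)
        if unknown:
            raise ValueError(f"unknown site types: {sorted(unknown)}")
        if self.min_sites_per_transcript < 1:
            raise ValueError("min_sites_per_transcript must be >= 1")
        object.__setattr__(self, "counted_site_types", counted)


DEFAULT_POLICY = SitePolicy()


@dataclass(frozen=True)
class TargetSite:
    """One seed-match site: transcript, 0-based start of the site, type."""

    transcript_id: str
    utr_position: int
    site_type: str


@dataclass(frozen=True)
class TargetDiff:
    """Set difference between reference and variant target predictions."""

    gained: FrozenSet[str]
    lost: FrozenSet[str]
    maintained: FrozenSet[str]
    prop_gained: float
    prop_lost: float
    prop_maintained: float

    @property
    def union_size(self) -> int:
        return len(self.gained) + len(self.lost) + len(self.maintained)


def seed_strings(mature_seq: str) -> tuple[str, str, str]:
    """Return (S, S6, m8_complement) for a mature sequence.

    S is the reverse complement of mature positions 2-8 (7 nt), S6 of
    positions 2-7 (6 nt); the complement of position 8 is the first base of S.
    """
    if len(mature_seq) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature_seq!r}")
    seed28 = mature_seq[1:8]  # positions 2..8, 1-based
    s = rna_revcomp(seed28)
    s6 = rna_revcomp(mature_seq[1:7])
    return s, s6, rna_complement(mature_seq[7])


def seed_sites(mature_seq: str, utr_seq: str, policy: SitePolicy = DEFAULT_POLICY) -> List[TargetSite]:
    """Scan one UTR for canonical seed-match sites of one mature miRNA.

    Every reported site is maximal for its offset: an offset where the full
    7-nt seed match S begins yields an 8mer or 7mer-m8, never additionally the
    nested 7mer-A1/6mer (those start one base downstream and are excluded
    there because the m8-aligned base pairs).  Windows containing N never
    match.  ``policy`` is accepted for interface symmetry; all four site
    types are always reported, counting happens in :func:`predict_targets`.
    """
    mature_seq = mature_seq.upper()
    utr = utr_seq.upper()
    bad = set(utr) - _UTR_ALPHABET
    if bad:
        raise ValueError(f"UTR contains non-ACGUN characters: {sorted(bad)}")
    s, s6, m8c = seed_strings(mature_seq)
    n = len(utr)
    sites: List[TargetSite] = []
    for p in range(n - 5):
        window6 = utr[p : p + 6]
        if "N" in window6 or window6 != s6:
            continue
        # does the m8-aligned base (immediately 5' of the 6mer core) pair?
        m8_pairs = p >= 1 and utr[p - 1] == m8c and m8c != "N"
        if m8_pairs:
            # the full 7-nt match S begins at p-1; classify there, once
            q = p - 1
            if q + 7 < n and utr[q + 7] == "A":
                sites.append(TargetSite("", q, "8mer"))
            else:
                sites.append(TargetSite("", q, "7mer-m8"))
        else:
            if p + 6 < n and utr[p + 6] == "A":
                sites.append(TargetSite("", p, "7mer-A1"))
            else:
                sites.append(TargetSite("", p, "6mer"))
    return sites


def count_sites(sites: Iterable[TargetSite], counted_types: FrozenSet[str]) -> int:
    return sum(1 for s in sites if s.site_type in counted_types)


def predict_targets(
    mature_seq: str,
    utr_db: Dict[str, str],
    policy: SitePolicy = DEFAULT_POLICY,
) -> Set[str]:
    """Return the transcript IDs targeted by ``mature_seq`` under ``policy``.

    A transcript is a target iff its number of counted-type sites reaches
    ``policy.min_sites_per_transcript``.  Deterministic and independent of
    the iteration order of ``utr_db``.
    """
    targets: Set[str] = set()
    for transcript_id in sorted(utr_db):
        sites = seed_sites(mature_seq, utr_db[transcript_id], policy)
        if count_sites(sites, policy.counted_site_types) >= policy.min_sites_per_transcript:
            targets.add(transcript_id)
    return targets


def sites_in_db(
    mature_seq: str, utr_db: Dict[str, str], policy: SitePolicy = DEFAULT_POLICY
) -> List[TargetSite]:
    """All sites across a UTR database, with transcript IDs filled in."""
    out: List[TargetSite] = []
    for transcript_id in sorted(utr_db):
        for s in seed_sites(mature_seq, utr_db[transcript_id], policy):
            out.append(TargetSite(transcript_id, s.utr_position, s.site_type))
    return out


def diff_targets(ref_set: Set[str], alt_set: Set[str]) -> TargetDiff:
    """Partition the union of two target sets into gained / lost / maintained."""
    ref = frozenset(ref_set)
    alt = frozenset(alt_set)
    gained = alt - ref
    lost = ref - alt
    maintained = ref & alt
    total = len(gained) + len(lost) + len(maintained)
    if total:
        pg, pl, pm = len(gained) / total, len(lost) / total, len(maintained) / total
    else:
        pg = pl = pm = 0.0
    return TargetDiff(gained, lost, maintained, pg, pl, pm)


def classify_mirna_alteration(diff: TargetDiff) -> str:
    """'altered' iff the variant gained or lost at least one target."""
    return "altered" if (diff.gained or diff.lost) else "unaltered"
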