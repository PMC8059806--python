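"""Cohort statistics: Welch's t-test, Ts/Tv comparisons, headline summaries.

Welch's two-sample t-test (unequal variances) is implemented from the
textbook formulas — t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny) with
Welch-Satterthwaite degrees of freedom — and the two-sided p-value comes
from scipy's t distribution.  It is used to compare transitions against
transversions with respect to per-variant quantities such as the induced
MFE change or the number of altered targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from mirsnp.folding import DdgResult
from mirsnp.mapping import MappedVariant
from mirsnp.targets import TargetDiff


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_value: float
    mean_x: float
    mean_y: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test, two-sided.

    Both samples need n >= 2.  The degenerate case of two zero-variance
    samples with equal means returns t = 0, p = 1; zero variance with
    different means returns an infinite statistic and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"welch_t needs n >= 2 per group (got {nx}, {ny})")
    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return WelchResult(0.0, float(nx + ny - 2), 1.0, mx, my)
        t = math.inf if mx > my else -math.inf
        return WelchResult(t, float(nx + ny - 2), 0.0, mx, my)
    t = (mx - my) / math.sqrt(se2)
    denom = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    # denom can underflow to 0 for near-constant samples; fall back to pooled df
    df = se2**2 / denom if denom > 0 else float(nx + ny - 2)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t, df, min(p, 1.0), mx, my)


@dataclass(frozen=True)
class TsTvComparison:
    n_transition: int
    n_transversion: int
    mean_transition: Optional[float]
    mean_transversion: Optional[float]
    welch: Optional[WelchResult]  # None when a group has < 2 members

    @property
    def testable(self) -> bool:
        return self.welch is not None


def ts_tv_compare(
    mapped: Sequence[MappedVariant], per_variant_values: Mapping[str, float]
) -> TsTvComparison:
    """Split per-variant values by substitution type and Welch-test the groups.

    ``per_variant_values`` maps snp_id to a real quantity (e.g. ddG or the
    altered-target count).  Group means are reported even when one group is
    too small to test.
    """
    subst_by_snp: Dict[str, str] = {}
    for mv in mapped:
        prev = subst_by_snp.setdefault(mv.snp_id, mv.substitution_type)
        if prev != mv.substitution_type:
            raise ValueError(f"inconsistent substitution type for SNP {mv.snp_id}")
    ts, tv = [], []
    for snp_id, value in sorted(per_variant_values.items()):
        try:
            kind = subst_by_snp[snp_id]
        except KeyError:
            raise ValueError(f"SNP {snp_id} has a value but no mapped substitution type")
        (ts if kind == "transition" else tv).append(float(value))
    welch = welch_t(ts, tv) if len(ts) >= 2 and len(tv) >= 2 else None
    return TsTvComparison(
        n_transition=len(ts),
        n_transversion=len(tv),
        mean_transition=float(np.mean(ts)) if ts else None,
        mean_transversion=float(np.mean(tv)) if tv else None,
        welch=welch,
    )


@dataclass(frozen=True)
class CohortSummary:
    n_mirna_total: int
    n_with_snp: int
    n_mature_snp: int
    n_seed_snp: int
    n_altered_target: int
    fraction_altered: Optional[float]
    prop_gained: Optional[float]
    prop_lost: Optional[float]
    prop_unaltered: Optional[float]
    ts_count: int
    tv_count: int


def build_cohort_summary(
    n_mirna_total: int,
    mapped: Sequence[MappedVariant],
    diffs: Mapping[str, TargetDiff],
) -> CohortSummary:
    """Nested miRNA counts and pooled target proportions for the cohort.

    Counts are at the miRNA (precursor) level — a precursor with any SNP, a
    precursor with any mature-region SNP, any seed SNP — mirroring the
    nested with-SNP >= mature >= seed chain.  ``diffs`` is keyed by the
    seed-level (snp_id, mature_id) pair serialized as "snp_id|mature_id";
    pooled proportions aggregate gained/lost/maintained target counts over
    all diffs.  Ts/Tv counts are per unique SNP.
    """
    with_snp = {mv.precursor_id for mv in mapped}
    mature_snp = {mv.precursor_id for mv in mapped if mv.region_class != "precursor_only"}
    seed_snp = {mv.precursor_id for mv in mapped if mv.region_class == "seed"}
    if not with_snp >= mature_snp >= seed_snp:
        raise ValueError("inconsistent region nesting in mapped variants")
    if n_mirna_total < len(with_snp):
        raise ValueError("n_mirna_total smaller than the number of precursors with SNPs")

    seed_keys = {f"{mv.snp_id}|{mv.mature_id}" for mv in mapped if mv.region_class == "seed"}
    unknown = set(diffs) - seed_keys
    if unknown:
        raise ValueError(f"diff keys not among seed-mapped variants: {sorted(unknown)[:3]}")

    altered_precursors = set()
    key_to_precursor = {
        f"{mv.snp_id}|{mv.mature_id}": mv.precursor_id
        for mv in mapped
        if mv.region_class == "seed"
    }
    g = l = m = 0
    for key, diff in diffs.items():
        g += len(diff.gained)
        l += len(diff.lost)
        m += len(diff.maintained)
        if diff.gained or diff.lost:
            altered_precursors.add(key_to_precursor[key])
    total = g + l + m

    subst = {mv.snp_id: mv.substitution_type for mv in mapped}
    ts = sum(1 for v in subst.values() if v == "transition")
    return CohortSummary(
        n_mirna_total=n_mirna_total,
        n_with_snp=len(with_snp),
        n_mature_snp=len(mature_snp),
        n_seed_snp=len(seed_snp),
        n_altered_target=len(altered_precursors),
        fraction_altered=(len(altered_precursors) / len(seed_snp)) if seed_snp else None,
        prop_gained=g / total if total else None,
        prop_lost=l / total if total else None,
        prop_unaltered=m / total if total else None,
        ts_count=ts,
        tv_count=len(subst) - ts,
    )
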