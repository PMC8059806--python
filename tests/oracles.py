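"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — exhaustive enumeration, all-pairs
scans, textbook formulas — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Set, Tuple

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}

PAIR_E = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "U"): -2.0, ("U", "A"): -2.0,
          ("G", "U"): -1.0, ("U", "G"): -1.0}


def enumerate_mfe(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over every pseudoknot-free structure, fully enumerated.

    Lists every legal pair set via :func:`enumerate_structures` and rescores
    each one; feasible only for short sequences.
    """
    best = 0.0
    for pairs in enumerate_structures(seq, min_loop):
        e = sum(PAIR_E[(seq[i], seq[j])] for i, j in pairs)
        best = min(best, e)
    return best


def enumerate_structures(seq: str, min_loop: int = 3) -> List[List[Tuple[int, int]]]:
    """Every pseudoknot-free pair set (for tiny sequences only)."""
    n = len(seq)

    def rec(i: int, j: int) -> List[List[Tuple[int, int]]]:
        if j - i < min_loop + 1:
            return [[]]
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) not in PAIR_E:
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    out.append([(i, k)] + inner + outer)
        return out

    return rec(0, n - 1)


def brute_force_sites(mature: str, utr: str) -> List[Tuple[int, str]]:
    """(position, site_type) pairs by direct per-window application of the
    canonical definitions, scanning every UTR offset independently."""
    rc = lambda s: "".join(_COMP[b] for b in reversed(s))
    s = rc(mature[1:8])
    s6 = rc(mature[1:7])
    m8c = _COMP[mature[7]]
    n = len(utr)
    hits = []
    for p in range(n):
        if utr[p : p + 7] == s and "N" not in s:
            if p + 7 < n and utr[p + 7] == "A":
                hits.append((p, "8mer"))
            else:
                hits.append((p, "7mer-m8"))
        elif utr[p : p + 6] == s6 and "N" not in s6:
            m8_pairs = p >= 1 and utr[p - 1] == m8c
            if m8_pairs:
                continue  # belongs to the 7/8mer reported at p-1
            if p + 6 < n and utr[p + 6] == "A":
                hits.append((p, "7mer-A1"))
            else:
                hits.append((p, "6mer"))
    return hits


def brute_force_targets(mature: str, utr_db: Dict[str, str],
                        counted: Set[str], min_sites: int = 1) -> Set[str]:
    out = set()
    for tx, utr in utr_db.items():
        k = sum(1 for _, t in brute_force_sites(mature, utr) if t in counted)
        if k >= min_sites:
            out.add(tx)
    return out


def all_pairs_qtl(snps: Sequence[Tuple[str, str, int]],
                  qtls: Sequence[Tuple[str, int, int, str, str]]) -> Set[tuple]:
    """All-pairs SNP-in-QTL containment: (snp_id, trait_name) pairs."""
    out = set()
    for snp_id, chrom, pos in snps:
        for qchrom, start, end, trait, cat in qtls:
            if chrom == qchrom and start <= pos <= end:
                out.add((snp_id, trait, cat))
    return out


def welch_formula(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """(t, df) straight from the textbook formulas, with explicit loops."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = sx2 / nx + sy2 / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((sx2 / nx) ** 2 / (nx - 1) + (sy2 / ny) ** 2 / (ny - 1))
    return t, df
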