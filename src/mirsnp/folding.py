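"""Hairpin minimum-free-energy folding and variant ddG classification.

Secondary structure is predicted with an additive per-pair energy model
solved by a Nussinov-style O(n^3) dynamic program: each Watson-Crick or
wobble pair contributes a fixed negative energy (GC -3, AU -2, GU -1
kcal/mol by default) and hairpin loops must span at least ``min_loop``
unpaired bases.  This is deliberately simpler than a full nearest-neighbor
thermodynamic model: the quantity of interest downstream is the energy
*difference* ddG = MFE(variant) - MFE(reference) between two sequences
differing at a single base, which is dominated by the pairing gained or
lost at that base.  The ``FoldingBackend`` protocol lets callers plug an
external thermodynamic folder for absolute energies; the ddG classification
is backend-agnostic.

A |ddG| at or above the threshold (default 2.0 kcal/mol) is called
maturation-altering: positive ddG destabilizes the hairpin (reduced mature
miRNA production), negative ddG stabilizes it (increased production).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Protocol, Tuple

DEFAULT_PAIR_ENERGIES: Dict[frozenset, float] = {
    frozenset(("G", "C")): -3.0,
    frozenset(("A", "U")): -2.0,
    frozenset(("G", "U")): -1.0,
}

DEFAULT_THRESHOLD = 2.0

_RNA_ALPHABET = frozenset("ACGUN")


@dataclass(frozen=True)
class EnergyModel:
    """Additive pair energies (kcal/mol) and minimum hairpin-loop length."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.gc > 0 or self.au > 0 or self.gu > 0:
            raise ValueError("pair energies must be <= 0")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")

    def pair_energy(self, a: str, b: str) -> Optional[float]:
        """Energy of pairing bases a and b, or None if they cannot pair."""
        pair = frozenset((a, b))
        if pair == frozenset(("G", "C")):
            return self.gc
        if pair == frozenset(("A", "U")):
            return self.au
        if pair == frozenset(("G", "U")):
            return self.gu
        return None


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class FoldResult:
    """MFE (kcal/mol), dot-bracket structure and number of pairs."""

    mfe: float
    structure: str
    n_pairs: int


@dataclass(frozen=True)
class DdgResult:
    """ddG = MFE(variant) - MFE(reference) and its maturation call."""

    ddg: float
    category: str  # reduced_production | increased_production | below_threshold
    threshold: float
    mfe_ref: float
    mfe_alt: float


class FoldingBackend(Protocol):
    def __call__(self, seq: str) -> FoldResult: ...


def _validate_rna(seq: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - _RNA_ALPHABET)
    if bad:
        raise ValueError(f"invalid RNA characters: {bad}")
    return seq


def fold_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> FoldResult:
    """Globally optimal pseudoknot-free structure under the pair-energy model.

    The DP minimizes the sum of pair energies over all nested structures
    whose hairpin loops hold at least ``model.min_loop`` unpaired bases;
    N bases never pair.  Ties in the traceback are broken deterministically:
    leave position i unpaired if co-optimal, otherwise pair i with the
    smallest co-optimal partner j.
    """
    seq = _validate_rna(seq)
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    min_span = model.min_loop + 1  # j - i >= min_span for a legal pair (i, j)
    # E[i][j] = optimal energy of subsequence i..j inclusive
    E = [[0.0] * n for _ in range(n)]
    for span in range(min_span, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1][j]  # i unpaired
            for k in range(i + min_span, j + 1):
                e = model.pair_energy(seq[i], seq[k])
                if e is None:
                    continue
                inner = E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
                outer = E[k + 1][j] if k + 1 <= j else 0.0
                cand = e + inner + outer
                if cand < best:
                    best = cand
            E[i][j] = best
    structure = ["."] * n
    n_pairs = 0
    stack: List[Tuple[int, int]] = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_span:
            continue
        if E[i][j] == E[i + 1][j]:  # prefer i unpaired on ties
            stack.append((i + 1, j))
            continue
        for k in range(i + min_span, j + 1):  # then smallest partner k
            e = model.pair_energy(seq[i], seq[k])
            if e is None:
                continue
            inner = E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
            outer = E[k + 1][j] if k + 1 <= j else 0.0
            if E[i][j] == e + inner + outer:
                structure[i], structure[k] = "(", ")"
                n_pairs += 1
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    return FoldResult(mfe=E[0][n - 1], structure="".join(structure), n_pairs=n_pairs)


def ddg(
    ref_seq: str,
    alt_seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    threshold: float = DEFAULT_THRESHOLD,
    backend: Optional[FoldingBackend] = None,
) -> DdgResult:
    """Energy change of a single-base variant and its maturation call.

    Category rule: ddG >= threshold -> reduced_production, ddG <= -threshold
    -> increased_production, else below_threshold (the boundary value itself
    counts as altering).
    """
    if len(ref_seq) != len(alt_seq):
        raise ValueError(
            f"length mismatch: ref {len(ref_seq)} vs alt {len(alt_seq)}"
        )
    n_diff = sum(a != b for a, b in zip(ref_seq.upper(), alt_seq.upper()))
    if n_diff > 1:
        raise ValueError(f"sequences differ at {n_diff} positions (max 1)")
    fold = backend if backend is not None else (lambda s: fold_mfe(s, model))
    ref_fold = fold(ref_seq)
    alt_fold = fold(alt_seq)
    value = alt_fold.mfe - ref_fold.mfe
    if value >= threshold:
        category = "reduced_production"
    elif value <= -threshold:
        category = "increased_production"
    else:
        category = "below_threshold"
    return DdgResult(
        ddg=value,
        category=category,
        threshold=threshold,
        mfe_ref=ref_fold.mfe,
        mfe_alt=alt_fold.mfe,
    )


@dataclass(frozen=True)
class DdgCohortSummary:
    n_total: int
    n_reduced: int
    n_increased: int
    n_below: int
    fraction_altering: Optional[float]  # |ddG| >= threshold
    fraction_positive_above: Optional[float]  # ddG >= threshold only

    @property
    def undefined(self) -> bool:
        return self.n_total == 0


def cohort_ddg_summary(results: Iterable[DdgResult]) -> DdgCohortSummary:
    """Counts and fractions per ddG category over a cohort.

    Both the two-sided tally (|ddG| >= threshold) and the one-sided tally
    (ddG >= threshold) are reported, since either reading of "altering" is
    defensible.
    """
    results = list(results)
    n = len(results)
    reduced = sum(1 for r in results if r.category == "reduced_production")
    increased = sum(1 for r in results if r.category == "increased_production")
    below = n - reduced - increased
    return DdgCohortSummary(
        n_total=n,
        n_reduced=reduced,
        n_increased=increased,
        n_below=below,
        fraction_altering=((reduced + increased) / n) if n else None,
        fraction_positive_above=(reduced / n) if n else None,
    )


def rescore_structure(seq: str, structure: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Re-derive the energy of a dot-bracket structure; validates it too."""
    seq = _validate_rna(seq)
    if len(structure) != len(seq):
        raise ValueError("structure/sequence length mismatch")
    stack: List[int] = []
    total = 0.0
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at {idx}")
            i = stack.pop()
            if idx - i < model.min_loop + 1:
                raise ValueError(f"pair ({i},{idx}) violates min_loop")
            e = model.pair_energy(seq[i], seq[idx])
            if e is None:
                raise ValueError(f"illegal pair {seq[i]}-{seq[idx]} at ({i},{idx})")
            total += e
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' remaining")
    return total
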