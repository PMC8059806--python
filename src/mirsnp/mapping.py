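"""Place SNPs inside miRNA annotations and build strand-correct variant sequences.

Annotations follow the miRBase GFF3 dialect: ``miRNA_primary_transcript``
features (precursor hairpins) with child ``miRNA`` features (mature products)
linked by ``Derives_from``.  Precursor sequences are supplied in sense (5'->3')
orientation in a companion FASTA keyed by the GFF3 ``Name``.  Variants come
from a VCF; only single-nucleotide substitutions are used, multi-allelic
records are expanded and indels skipped with a logged count.

All internal coordinates are 0-based half-open; GFF3/VCF 1-based inclusive
coordinates are converted at the I/O boundary only.  A SNP inside a precursor
is classified as ``seed`` (mature positions 2-8), ``mature_non_seed`` or
``precursor_only``, and its alleles are complemented onto the sense strand
(T->U) before sequence substitution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import gffutils
import pysam
from Bio import SeqIO

from mirsnp._seq import dna_complement, dna_to_rna

logger = logging.getLogger(__name__)

SEED_START, SEED_END = 2, 8  # 1-based inclusive positions within the mature

_DNA = frozenset("ACGT")


class AnnotationError(ValueError):
    """Inconsistent annotation bundle (dangling references, bad coordinates)."""


class ReferenceMismatchError(ValueError):
    """VCF reference allele disagrees with the annotated precursor base."""

    def __init__(self, snp_id: str, expected: str, observed: str):
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"SNP {snp_id}: annotated base {expected!r} != VCF reference {observed!r}"
            " (assembly mix-up?)"
        )


@dataclass(frozen=True)
class MatureRecord:
    """One mature product: genomic interval plus the fixed 2-8 seed range."""

    mature_id: str
    start: int  # 1-based inclusive genomic
    end: int
    seed_range: Tuple[int, int] = (SEED_START, SEED_END)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AnnotationError(f"mature {self.mature_id}: end < start")
        if self.end - self.start + 1 < 8:
            raise AnnotationError(f"mature {self.mature_id}: shorter than 8 nt")


@dataclass(frozen=True)
class MirnaAnnotation:
    """One precursor hairpin with its mature sub-intervals."""

    precursor_id: str
    chrom: str
    start: int  # 1-based inclusive genomic
    end: int
    strand: str
    precursor_seq: str  # RNA, sense orientation
    matures: Tuple[MatureRecord, ...]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AnnotationError(f"precursor {self.precursor_id}: end < start")
        if self.strand not in "+-":
            raise AnnotationError(f"precursor {self.precursor_id}: bad strand {self.strand!r}")
        expected = self.end - self.start + 1
        if len(self.precursor_seq) != expected:
            raise AnnotationError(
                f"precursor {self.precursor_id}: sequence length {len(self.precursor_seq)}"
                f" != interval length {expected}"
            )
        for m in self.matures:
            if m.start < self.start or m.end > self.end:
                raise AnnotationError(
                    f"mature {m.mature_id} exceeds precursor {self.precursor_id} interval"
                )

    def sense_offset(self, pos: int) -> int:
        """1-based offset of genomic position ``pos`` within the sense precursor."""
        if self.strand == "+":
            return pos - self.start + 1
        return self.end - pos + 1

    def mature_seq(self, mature: MatureRecord) -> str:
        """Sense-orientation sequence of one mature product."""
        if self.strand == "+":
            lo = mature.start - self.start
            hi = mature.end - self.start + 1
        else:
            lo = self.end - mature.end
            hi = self.end - mature.start + 1
        return self.precursor_seq[lo:hi]


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int  # 1-based
    snp_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref == alt")
        if self.ref_allele not in _DNA or self.alt_allele not in _DNA:
            raise ValueError(f"{self.snp_id}: alleles must be single A/C/G/T bases")


@dataclass(frozen=True)
class MappedVariant:
    """A SNP placed inside one miRNA precursor (and at most one mature)."""

    snp_id: str
    precursor_id: str
    chrom: str
    pos: int
    mature_id: Optional[str]
    region_class: str  # precursor_only | mature_non_seed | seed
    precursor_offset: int  # 1-based within sense precursor
    mature_offset: Optional[int]
    sense_ref: str  # RNA base on the miRNA sense strand
    sense_alt: str
    substitution_type: str  # transition | transversion
    ref_precursor_seq: str
    alt_precursor_seq: str
    ref_mature_seq: Optional[str]
    alt_mature_seq: Optional[str]


def substitution_type(ref: str, alt: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if ref not in _DNA or alt not in _DNA:
        raise ValueError(f"alleles must be A/C/G/T, got {ref!r}, {alt!r}")
    if {ref, alt} in ({"A", "G"}, {"C", "T"}):
        return "transition"
    return "transversion"


def apply_variant(seq: str, offset: int, alt: str) -> str:
    """Substitute ``alt`` at 1-based ``offset``; involution with the old base."""
    if not 1 <= offset <= len(seq):
        raise IndexError(f"offset {offset} out of range for length {len(seq)}")
    return seq[: offset - 1] + alt + seq[offset:]


def load_mirna_annotations(
    gff3_path: Union[str, Path], fasta_path: Union[str, Path]
) -> List[MirnaAnnotation]:
    """Parse a miRBase-dialect GFF3 plus precursor FASTA into annotations.

    Every ``miRNA`` feature must carry a ``Derives_from`` resolving to a
    loaded ``miRNA_primary_transcript``; FASTA record IDs match the
    precursors' ``Name`` attributes.  Precursor sequence lengths are
    validated against their genomic intervals.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    precursors: Dict[str, dict] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", feat.attributes["ID"])[0]
        feat_id = feat.attributes["ID"][0]
        if name not in seqs:
            raise AnnotationError(f"precursor {name}: no FASTA record")
        precursors[feat_id] = dict(
            name=name,
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
            seq=dna_to_rna(seqs[name]),
            matures=[],
        )

    for feat in db.features_of_type("miRNA"):
        derives = feat.attributes.get("Derives_from")
        if not derives or derives[0] not in precursors:
            raise AnnotationError(
                f"mature {feat.attributes.get('ID', ['?'])[0]}: Derives_from does not"
                " resolve to a loaded precursor"
            )
        name = feat.attributes.get("Name", feat.attributes["ID"])[0]
        precursors[derives[0]]["matures"].append(
            MatureRecord(mature_id=name, start=feat.start, end=feat.end)
        )

    out = []
    for rec in precursors.values():
        out.append(
            MirnaAnnotation(
                precursor_id=rec["name"],
                chrom=rec["chrom"],
                start=rec["start"],
                end=rec["end"],
                strand=rec["strand"],
                precursor_seq=rec["seq"],
                matures=tuple(sorted(rec["matures"], key=lambda m: (m.start, m.mature_id))),
            )
        )
    out.sort(key=lambda a: (a.chrom, a.start, a.precursor_id))
    return out


def load_snps(vcf_path: Union[str, Path]) -> List[SnpRecord]:
    """Read SNVs from a VCF; expand multi-allelics, dedupe, skip indels."""
    n_indel = 0
    seen = set()
    out: List[SnpRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for i, rec in enumerate(vcf):
            try:
                ref = rec.ref.upper()
                alts = [a.upper() for a in (rec.alts or ())]
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"malformed VCF record #{i + 1}: {exc}") from exc
            for alt in alts:
                if len(ref) != 1 or len(alt) != 1 or ref not in _DNA or alt not in _DNA:
                    n_indel += 1
                    continue
                key = (rec.chrom, rec.pos, ref, alt)
                if key in seen:
                    continue
                seen.add(key)
                snp_id = rec.id or f"{rec.chrom}:{rec.pos}:{ref}>{alt}"
                out.append(SnpRecord(rec.chrom, rec.pos, snp_id, ref, alt))
    if n_indel:
        logger.info("skipped %d non-SNV alleles (indels/symbolic)", n_indel)
    return out


def map_variant(
    snp: SnpRecord, ann: MirnaAnnotation, skip_mismatch: bool = False
) -> List[MappedVariant]:
    """Map one SNP against one precursor.

    Returns an empty list when the SNP lies outside the precursor interval;
    otherwise one ``MappedVariant`` per overlapped mature product (a SNP in
    the 5p/3p overlap affects both matures), or a single ``precursor_only``
    record when no mature is hit.  The strand-adjusted reference allele must
    equal the annotated precursor base; a mismatch raises
    :class:`ReferenceMismatchError` unless ``skip_mismatch`` is set, in which
    case the SNP is dropped with a log line.
    """
    if snp.chrom != ann.chrom or not ann.start <= snp.pos <= ann.end:
        return []
    offset = ann.sense_offset(snp.pos)
    if ann.strand == "+":
        sense_ref = dna_to_rna(snp.ref_allele)
        sense_alt = dna_to_rna(snp.alt_allele)
    else:
        sense_ref = dna_to_rna(dna_complement(snp.ref_allele))
        sense_alt = dna_to_rna(dna_complement(snp.alt_allele))
    annotated = ann.precursor_seq[offset - 1]
    if annotated != sense_ref:
        if skip_mismatch:
            logger.warning(
                "SNP %s: reference mismatch (%s vs %s), skipped", snp.snp_id, annotated, sense_ref
            )
            return []
        raise ReferenceMismatchError(snp.snp_id, annotated, sense_ref)
    subst = substitution_type(snp.ref_allele, snp.alt_allele)
    alt_precursor = apply_variant(ann.precursor_seq, offset, sense_alt)

    hits: List[MappedVariant] = []
    for mature in ann.matures:
        if not mature.start <= snp.pos <= mature.end:
            continue
        if ann.strand == "+":
            m_off = snp.pos - mature.start + 1
        else:
            m_off = mature.end - snp.pos + 1
        region = "seed" if SEED_START <= m_off <= SEED_END else "mature_non_seed"
        ref_mat = ann.mature_seq(mature)
        hits.append(
            MappedVariant(
                snp_id=snp.snp_id,
                precursor_id=ann.precursor_id,
                chrom=snp.chrom,
                pos=snp.pos,
                mature_id=mature.mature_id,
                region_class=region,
                precursor_offset=offset,
                mature_offset=m_off,
                sense_ref=sense_ref,
                sense_alt=sense_alt,
                substitution_type=subst,
                ref_precursor_seq=ann.precursor_seq,
                alt_precursor_seq=alt_precursor,
                ref_mature_seq=ref_mat,
                alt_mature_seq=apply_variant(ref_mat, m_off, sense_alt),
            )
        )
    if not hits:
        hits.append(
            MappedVariant(
                snp_id=snp.snp_id,
                precursor_id=ann.precursor_id,
                chrom=snp.chrom,
                pos=snp.pos,
                mature_id=None,
                region_class="precursor_only",
                precursor_offset=offset,
                mature_offset=None,
                sense_ref=sense_ref,
                sense_alt=sense_alt,
                substitution_type=subst,
                ref_precursor_seq=ann.precursor_seq,
                alt_precursor_seq=alt_precursor,
                ref_mature_seq=None,
                alt_mature_seq=None,
            )
        )
    return hits


def map_all(
    snps: Sequence[SnpRecord],
    annotations: Sequence[MirnaAnnotation],
    skip_mismatch: bool = False,
) -> List[MappedVariant]:
    """Map every SNP against every overlapping precursor, deterministically."""
    by_chrom: Dict[str, List[MirnaAnnotation]] = {}
    for ann in annotations:
        by_chrom.setdefault(ann.chrom, []).append(ann)
    out: List[MappedVariant] = []
    for snp in sorted(snps, key=lambda s: (s.chrom, s.pos, s.snp_id, s.alt_allele)):
        for ann in by_chrom.get(snp.chrom, ()):
            out.extend(map_variant(snp, ann, skip_mismatch=skip_mismatch))
    return out
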