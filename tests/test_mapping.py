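"""SNP placement inside miRNA coordinate space, strand handling, I/O parsing."""

import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirsnp.mapping import (
    AnnotationError,
    MatureRecord,
    MirnaAnnotation,
    ReferenceMismatchError,
    SnpRecord,
    apply_variant,
    load_mirna_annotations,
    load_snps,
    map_variant,
    substitution_type,
)


def _ann(strand="+", seq=None, matures=()):
    seq = seq if seq is not None else "ACGU" * 20  # 80 nt
    return MirnaAnnotation(
        precursor_id="mir-1",
        chrom="chr1",
        start=1001,
        end=1080,
        strand=strand,
        precursor_seq=seq,
        matures=tuple(matures),
    )


class TestSubstitutionType:
    def test_all_twelve_ordered_pairs(self):
        """Exactly 4 ordered transitions and 8 transversions exist."""
        purines, pyrimidines = set("AG"), set("CT")
        outcomes = {}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                outcomes[(ref, alt)] = substitution_type(ref, alt)
                same_family = ({ref, alt} <= purines) or ({ref, alt} <= pyrimidines)
                assert outcomes[(ref, alt)] == ("transition" if same_family else "transversion")
        counts = list(outcomes.values())
        assert counts.count("transition") == 4 and counts.count("transversion") == 8

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            substitution_type("A", "A")


class TestApplyVariant:
    def test_basic_substitution(self):
        assert apply_variant("UAGC", 2, "G") == "UGGC"

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            apply_variant("UAGC", 5, "G")
        with pytest.raises(IndexError):
            apply_variant("UAGC", 0, "G")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGU", min_size=1, max_size=40),
        data=st.data(),
    )
    def test_involution(self, seq, data):
        i = data.draw(st.integers(1, len(seq)))
        b = data.draw(st.sampled_from("ACGU"))
        assert apply_variant(apply_variant(seq, i, b), i, seq[i - 1]) == seq


class TestMapVariant:
    def test_plus_strand_offset(self):
        ann = _ann("+")
        snp = SnpRecord("chr1", 1005, "s1", ann.precursor_seq[4].replace("U", "T"), "G")
        [mv] = map_variant(snp, ann)
        assert mv.precursor_offset == 5
        assert mv.region_class == "precursor_only"
        assert mv.alt_precursor_seq[4] == "G"

    def test_minus_strand_complement_and_offset(self):
        seq = "U" + "ACGU" * 19 + "GGG"  # sense base 1 is U
        ann = _ann("-", seq=seq)
        # genomic end maps to sense offset 1; sense U corresponds to genomic A
        snp = SnpRecord("chr1", 1080, "s1", "A", "C")
        [mv] = map_variant(snp, ann)
        assert mv.precursor_offset == 1
        assert mv.sense_ref == "U" and mv.sense_alt == "G"

    def test_outside_interval_returns_empty(self):
        ann = _ann("+")
        assert map_variant(SnpRecord("chr1", 999, "s1", "A", "C"), ann) == []
        assert map_variant(SnpRecord("chr2", 1005, "s1", "A", "C"), ann) == []

    def test_seed_boundaries(self):
        """Mature positions 2-8 are seed; 1 and 9 are not."""
        mature = MatureRecord("miR-1", start=1011, end=1032)
        ann = _ann("+", matures=[mature])
        for pos, expected in [
            (1011, "mature_non_seed"),  # mature position 1
            (1012, "seed"),  # position 2
            (1018, "seed"),  # position 8
            (1019, "mature_non_seed"),  # position 9
        ]:
            ref = ann.precursor_seq[pos - 1001].replace("U", "T")
            alt = "G" if ref != "G" else "A"
            [mv] = map_variant(SnpRecord("chr1", pos, "s", ref, alt), ann)
            assert mv.region_class == expected, pos
            assert mv.mature_offset == pos - 1011 + 1

    def test_reference_mismatch_raises_and_skips(self):
        ann = _ann("+")
        wrong_ref = "G" if ann.precursor_seq[4] != "G" else "A"
        snp = SnpRecord("chr1", 1005, "s1", wrong_ref, "C" if wrong_ref != "C" else "T")
        with pytest.raises(ReferenceMismatchError):
            map_variant(snp, ann)
        assert map_variant(snp, ann, skip_mismatch=True) == []

    def test_overlapping_matures_produce_two_records(self):
        m5p = MatureRecord("miR-1-5p", start=1005, end=1030)
        m3p = MatureRecord("miR-1-3p", start=1028, end=1060)
        ann = _ann("+", matures=[m5p, m3p])
        ref = ann.precursor_seq[1028 - 1001].replace("U", "T")
        hits = map_variant(SnpRecord("chr1", 1028, "s", ref, "G" if ref != "G" else "C"), ann)
        assert sorted(mv.mature_id for mv in hits) == ["miR-1-3p", "miR-1-5p"]

    def test_region_classification_matches_naive_scan(self):
        """Every precursor offset classified identically by a per-base scan."""
        mature = MatureRecord("miR-1", start=1020, end=1045)
        for strand in "+-":
            ann = _ann(strand, matures=[mature])
            for pos in range(1001, 1081):
                sense_off = ann.sense_offset(pos)
                base = ann.precursor_seq[sense_off - 1].replace("U", "T")
                genomic_ref = base if strand == "+" else {"A": "T", "T": "A", "G": "C", "C": "G"}[base]
                alt = "A" if genomic_ref != "A" else "G"
                hits = map_variant(SnpRecord("chr1", pos, "s", genomic_ref, alt), ann)
                # naive truth from genomic coordinates alone
                if 1020 <= pos <= 1045:
                    m_off = (pos - 1020 + 1) if strand == "+" else (1045 - pos + 1)
                    want = "seed" if 2 <= m_off <= 8 else "mature_non_seed"
                else:
                    want = "precursor_only"
                assert [mv.region_class for mv in hits] == [want], (strand, pos)

    def test_nested_partition_seed_within_mature_within_precursor(self):
        mature = MatureRecord("miR-1", start=1020, end=1045)
        ann = _ann("+", matures=[mature])
        classes = []
        for pos in range(1001, 1081):
            ref = ann.precursor_seq[pos - 1001].replace("U", "T")
            [mv] = map_variant(SnpRecord("chr1", pos, "s", ref, "G" if ref != "G" else "A"), ann)
            classes.append(mv.region_class)
        n_seed = classes.count("seed")
        n_mature = n_seed + classes.count("mature_non_seed")
        assert n_seed == 7
        assert n_mature == 26
        assert len(classes) == 80


class TestAnnotationValidation:
    def test_mature_exceeding_precursor_rejected(self):
        with pytest.raises(AnnotationError, match="exceeds"):
            _ann("+", matures=[MatureRecord("bad", start=990, end=1020)])

    def test_sequence_length_mismatch_rejected(self):
        with pytest.raises(AnnotationError, match="length"):
            MirnaAnnotation("mir-1", "chr1", 1001, 1080, "+", "ACGU", ())

    def test_short_mature_rejected(self):
        with pytest.raises(AnnotationError, match="shorter"):
            MatureRecord("tiny", start=1001, end=1005)


GFF = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\t.\tmiRNA_primary_transcript\t1001\t1080\t.\t+\t.\tID=MI001;Name=mir-test
    chr1\t.\tmiRNA\t1010\t1031\t.\t+\t.\tID=MIMAT001;Name=miR-test;Derives_from=MI001
    """
)


class TestLoaders:
    def test_gff3_fasta_crosslink(self, tmp_path):
        (tmp_path / "a.gff3").write_text(GFF)
        (tmp_path / "a.fa").write_text(">mir-test\n" + "ACGU" * 20 + "\n")
        [ann] = load_mirna_annotations(tmp_path / "a.gff3", tmp_path / "a.fa")
        assert ann.precursor_id == "mir-test"
        [mature] = ann.matures
        # mature chr1:1010-1031 occupies sense offsets 10..31 on the plus strand
        assert ann.sense_offset(mature.start) == 10
        assert ann.sense_offset(mature.end) == 31
        assert len(ann.mature_seq(mature)) == 22

    def test_minus_strand_offsets_counted_from_genomic_end(self, tmp_path):
        gff = GFF.replace("\t+\t", "\t-\t").replace("1010\t1031", "1050\t1071")
        (tmp_path / "a.gff3").write_text(gff)
        (tmp_path / "a.fa").write_text(">mir-test\n" + "ACGU" * 20 + "\n")
        [ann] = load_mirna_annotations(tmp_path / "a.gff3", tmp_path / "a.fa")
        [mature] = ann.matures
        assert ann.sense_offset(mature.end) == 10
        assert ann.sense_offset(mature.start) == 31

    def test_dangling_derives_from_rejected(self, tmp_path):
        bad = GFF.replace("Derives_from=MI001", "Derives_from=MI999")
        (tmp_path / "a.gff3").write_text(bad)
        (tmp_path / "a.fa").write_text(">mir-test\n" + "ACGU" * 20 + "\n")
        with pytest.raises(AnnotationError, match="Derives_from"):
            load_mirna_annotations(tmp_path / "a.gff3", tmp_path / "a.fa")

    def test_fasta_length_mismatch_rejected(self, tmp_path):
        (tmp_path / "a.gff3").write_text(GFF)
        (tmp_path / "a.fa").write_text(">mir-test\nACGUACGU\n")
        with pytest.raises(AnnotationError, match="mir-test"):
            load_mirna_annotations(tmp_path / "a.gff3", tmp_path / "a.fa")

    def _vcf(self, tmp_path, body):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        path = tmp_path / "x.vcf"
        path.write_text(header + body)
        return path

    def test_multiallelic_expansion(self, tmp_path):
        path = self._vcf(tmp_path, "chr1\t1005\trs1\tA\tG,T\t.\t.\t.\n")
        snps = load_snps(path)
        assert [(s.pos, s.ref_allele, s.alt_allele) for s in snps] == [(1005, "A", "G"), (1005, "A", "T")]

    def test_indels_skipped(self, tmp_path):
        path = self._vcf(tmp_path, "chr1\t1005\trs1\tAT\tA\t.\t.\t.\nchr1\t1010\trs2\tC\tG\t.\t.\t.\n")
        snps = load_snps(path)
        assert [s.snp_id for s in snps] == ["rs2"]

    def test_exact_duplicates_removed(self, tmp_path):
        body = "chr1\t1005\trs1\tA\tG\t.\t.\t.\nchr1\t1005\trs1b\tA\tG\t.\t.\t.\n"
        assert len(load_snps(self._vcf(tmp_path, body))) == 1

    def test_empty_vcf_body(self, tmp_path):
        assert load_snps(self._vcf(tmp_path, "")) == []
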