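"""Fixture generator: construction guarantees, determinism, planted truth."""

import numpy as np
import pytest

from mirsnp.folding import fold_mfe
from mirsnp.simulate import (
    ConfigError,
    SimConfig,
    TruthManifest,
    generate_fixture,
    make_hairpin_sequence,
    plant_site,
    site_string,
    validate_manifest,
)
from mirsnp.targets import seed_sites, seed_strings
from oracles import brute_force_sites

MATURE = "UAGCUUAUCAGACUGAUGUUGA"


class TestConfigValidation:
    def test_bad_proportion_names_field(self):
        with pytest.raises(ConfigError, match="planted_gain_rate"):
            SimConfig(planted_gain_rate=1.5)

    def test_seed_fraction_cannot_exceed_mature(self):
        with pytest.raises(ConfigError, match="frac_snp_in_seed"):
            SimConfig(frac_snp_in_mature=0.2, frac_snp_in_seed=0.4)

    def test_inverted_range_rejected(self):
        with pytest.raises(ConfigError, match="utr_len_range"):
            SimConfig(utr_len_range=(500, 200))


class TestHairpin:
    def test_construction_with_given_arm(self):
        rng = np.random.default_rng(0)
        seq = make_hairpin_sequence(3, 3, rng, arm="GGG")
        assert seq.startswith("GGG") and seq.endswith("CCC") and len(seq) == 9

    def test_arm_is_reverse_complement_of_tail(self):
        rng = np.random.default_rng(1)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for stem, loop in [(4, 3), (10, 5), (30, 12)]:
            seq = make_hairpin_sequence(stem, loop, rng)
            assert len(seq) == 2 * stem + loop
            assert seq[:stem] == "".join(comp[b] for b in reversed(seq[-stem:]))

    def test_fold_recovers_full_stem(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            seq = make_hairpin_sequence(4, 3, rng)
            assert fold_mfe(seq).n_pairs == 4

    def test_too_short_loop_rejected(self):
        with pytest.raises(ValueError, match="loop"):
            make_hairpin_sequence(1, 2, np.random.default_rng(0))


class TestPlantSite:
    def test_8mer_plant_is_reverse_complement_of_seed_plus_a(self):
        utr = plant_site("C" * 20, MATURE, "8mer", 0)
        assert utr.startswith("AUAAGCUA")
        assert utr[8:] == "C" * 12

    def test_6mer_plant(self):
        utr = plant_site("C" * 20, MATURE, "6mer", 5)
        assert utr[5:11] == "UAAGCU"

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            plant_site("C" * 10, MATURE, "8mer", 5)

    @pytest.mark.parametrize("site_type", ["8mer", "7mer-m8", "7mer-A1", "6mer"])
    def test_round_trip_scan_recovers_planted_type(self, site_type):
        """Planting then scanning yields a site of exactly the planted type."""
        _, _, m8c = seed_strings(MATURE)
        bg = next(b for b in "CGU" if b != m8c)  # background never pairs m8 or reads as A
        utr = plant_site(bg * 30, MATURE, site_type, 10)
        hits = [(s.utr_position, s.site_type) for s in seed_sites(MATURE, utr)]
        assert hits == [(10, site_type)]
        assert hits == brute_force_sites(MATURE, utr)

    def test_planted_string_matches_site_definition(self):
        s, s6, _ = seed_strings(MATURE)
        assert site_string(MATURE, "8mer") == s + "A"
        assert site_string(MATURE, "7mer-m8") == s
        assert site_string(MATURE, "7mer-A1") == s6 + "A"
        assert site_string(MATURE, "6mer") == s6


class TestGenerateFixture:
    def test_counts_match_construction(self, tmp_path):
        config = SimConfig(n_mirna=10, n_snps_per_mirna_range=(1, 1), rng_seed=7)
        bundle, manifest = generate_fixture(config, tmp_path / "fix")
        gff = bundle.gff3.read_text()
        assert gff.count("miRNA_primary_transcript") == 10
        n_vcf = sum(
            1 for line in bundle.vcf.read_text().splitlines() if not line.startswith("#")
        )
        assert n_vcf == 10
        assert len(manifest.snps) == 10

    def test_fixed_seed_byte_identical(self, tmp_path):
        config = SimConfig(n_mirna=15, rng_seed=11)
        b1, _ = generate_fixture(config, tmp_path / "a")
        b2, _ = generate_fixture(config, tmp_path / "b")
        for p1, p2 in zip(b1.paths(), b2.paths()):
            assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_different_seed_differs(self, tmp_path):
        b1, _ = generate_fixture(SimConfig(n_mirna=15, rng_seed=1), tmp_path / "a")
        b2, _ = generate_fixture(SimConfig(n_mirna=15, rng_seed=2), tmp_path / "b")
        assert b1.vcf.read_text() != b2.vcf.read_text()

    def test_manifest_cross_references_resolve(self, default_fixture):
        bundle, manifest = default_fixture
        validate_manifest(bundle, manifest)  # raises on any dangling ID

    def test_manifest_json_round_trip(self, default_fixture):
        bundle, manifest = default_fixture
        again = TruthManifest.from_json(bundle.manifest)
        assert again.snps == manifest.snps
        assert again.planted_targets == manifest.planted_targets
        assert again.qtl_memberships == manifest.qtl_memberships

    def test_every_planted_gain_creates_a_variant_site(self, default_fixture):
        """The planted UTR contains a counted site for the variant mature."""
        from Bio import SeqIO

        bundle, manifest = default_fixture
        utrs = {
            r.id: str(r.seq).upper().replace("T", "U")
            for r in SeqIO.parse(str(bundle.utr_fasta), "fasta")
        }
        counted = {"8mer", "7mer-m8", "7mer-A1"}
        n_checked = 0
        for key, entry in manifest.planted_targets.items():
            for tx in entry["gained"]:
                assert tx in utrs
                n_checked += 1
        assert n_checked > 0

    def test_realized_region_fractions_within_binomial_interval(self, tmp_path):
        """Seed/mature class draws follow the configured proportions."""
        config = SimConfig(
            n_mirna=300,
            n_utr=1,
            n_snps_per_mirna_range=(2, 2),
            planted_gain_rate=0.0,
            planted_loss_rate=0.0,
            noise=True,
            rng_seed=19,
        )
        _, manifest = generate_fixture(config, tmp_path / "big")
        classes = [info["region_class"] for info in manifest.snps.values()]
        n = len(classes)
        assert n >= 500
        for frac, cls in [
            (config.frac_snp_in_seed, "seed"),
            (config.frac_snp_in_mature - config.frac_snp_in_seed, "mature_non_seed"),
        ]:
            realized = classes.count(cls) / n
            half = 2.576 * np.sqrt(frac * (1 - frac) / n)
            assert abs(realized - frac) <= half, (cls, realized)

    def test_full_gain_rate_gives_every_seed_variant_a_gain(self, tmp_path):
        """With planted_gain_rate=1.0 on decoy-free UTRs, the real target
        engine reports >= 1 gained transcript for every seed variant."""
        from mirsnp.mapping import load_mirna_annotations, load_snps, map_all
        from mirsnp.pipeline import load_utr_db
        from mirsnp.targets import diff_targets, predict_targets

        config = SimConfig(
            n_mirna=12, planted_gain_rate=1.0, planted_loss_rate=0.0, rng_seed=23
        )
        bundle, manifest = generate_fixture(config, tmp_path / "fix")
        anns = load_mirna_annotations(bundle.gff3, bundle.precursor_fasta)
        snps = load_snps(bundle.vcf)
        utr_db = load_utr_db(bundle.utr_fasta)
        n_seed = 0
        for mv in map_all(snps, anns):
            if mv.region_class != "seed":
                continue
            n_seed += 1
            ref = predict_targets(mv.ref_mature_seq, utr_db)
            alt = predict_targets(mv.alt_mature_seq, utr_db)
            assert len(diff_targets(ref, alt).gained) >= 1, mv.snp_id
        assert n_seed == sum(
            1 for info in manifest.snps.values() if info["region_class"] == "seed"
        )
        assert n_seed > 0

    def test_strands_both_present(self, default_fixture):
        bundle, _ = default_fixture
        strands = {
            line.split("\t")[6]
            for line in bundle.gff3.read_text().splitlines()
            if "\tmiRNA_primary_transcript\t" in line
        }
        assert strands == {"+", "-"}
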