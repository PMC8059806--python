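"""Synthetic fixture generator with planted, recoverable ground truth.

Emulates the five inputs of the SNP-in-miRNA analysis — miRBase-dialect GFF3
annotations with precursor FASTA, a VCF of SNVs, a 3'UTR FASTA, an Animal
QTLdb-style trait-interval TSV and a phyloP-style bedGraph — as one
internally consistent bundle plus a JSON truth manifest.

Construction principles:

* Precursors are built hairpin-first (5' arm + loop + reverse-complement
  arm) so the folded structure is known; the mature miRNA is a substring of
  the 5' arm.  Each precursor is placed on a random strand to force
  strand-handling coverage.
* SNP region classes (seed / mature-non-seed / precursor-only) are drawn
  i.i.d. from configured proportions; alternate alleles are uniform over the
  three non-reference bases, giving the neutral 1:2 transition:transversion
  expectation.
* Decoy-free UTRs: background sequences are scrubbed of every active seed
  6mer core (reference and variant) so that the only seed-match sites in the
  database are the planted ones, making planted-truth recovery exact.  The
  ``noise`` flag disables scrubbing for realism-oriented statistics.
* Target gains are planted by writing the *variant* miRNA's site into a UTR
  the reference does not hit; losses by writing the *reference* site.  A
  seed SNP at mature positions 2-7 gets an 8mer plant; a position-8 SNP gets
  a 7mer-m8 plant (an 8mer there would leave the other allele a counted
  7mer-A1 site).
* QTL intervals are placed around randomly chosen precursors; the manifest
  records every actual (SNP, QTL) containment, including incidental ones.
* Conservation scores are positive (slow) with probability
  ``conserved_frac``, negative (fast) otherwise, one bedGraph interval per
  SNP locus.

Everything is driven by one ``numpy`` Generator seeded from
``SimConfig.rng_seed``; a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from mirsnp._seq import rna_revcomp, rna_to_dna, dna_complement
from mirsnp.targets import seed_strings

RNA_BASES = ("A", "C", "G", "U")
DNA_BASES = ("A", "C", "G", "T")

# (trait_category, trait_name) vocabulary in the style of cattle QTL databases
TRAIT_VOCABULARY: Tuple[Tuple[str, str], ...] = (
    ("Reproduction", "Calving ease"),
    ("Reproduction", "Stillbirth"),
    ("Reproduction", "Age at puberty"),
    ("Reproduction", "Calving index"),
    ("Reproduction", "Scrotal circumference"),
    ("Milk production", "Milk yield"),
    ("Milk production", "305-day milk yield"),
    ("Milk production", "Milk caproic acid content"),
    ("Milk production", "Milk beta-casein percentage"),
    ("Conformational", "Body weight (weaning)"),
    ("Conformational", "Residual feed intake"),
    ("Conformational", "Somatic cell score"),
    ("Meat characteristics", "Shear force"),
    ("Meat characteristics", "Intramuscular fat"),
    ("Meat characteristics", "Subcutaneous fat"),
    ("Environmental adaptation", "Cold tolerance"),
    ("Environmental adaptation", "Heat tolerance"),
    ("Disease tolerance", "Tick resistance"),
    ("Disease tolerance", "Bovine tuberculosis susceptibility"),
)

_CHROMS = ("chr1", "chr2", "chr3", "chr4", "chr5")
MATURE_LEN = 22


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    The defaults emulate the structure of a desk-scale cohort: a few dozen
    hairpins each carrying 1-3 SNVs, with roughly 45% of SNPs in mature
    sequences and half of those in seeds, gain/loss planting rates chosen so
    that ~three quarters of seed SNPs alter at least one target, and 86% of
    SNP loci conserved.
    """

    n_mirna: int = 50
    n_utr: int = 60
    utr_len_range: Tuple[int, int] = (200, 500)
    frac_snp_in_mature: float = 0.45
    frac_snp_in_seed: float = 0.22
    n_snps_per_mirna_range: Tuple[int, int] = (1, 3)
    planted_gain_rate: float = 0.55
    planted_loss_rate: float = 0.5
    n_qtl: int = 12
    qtl_len_range: Tuple[int, int] = (5_000, 50_000)
    conserved_frac: float = 0.86
    rng_seed: int = 7
    noise: bool = False  # disable decoy scrubbing (realism over exactness)

    def __post_init__(self) -> None:
        for name in (
            "frac_snp_in_mature",
            "frac_snp_in_seed",
            "planted_gain_rate",
            "planted_loss_rate",
            "conserved_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_snp_in_seed > self.frac_snp_in_mature:
            raise ConfigError("frac_snp_in_seed must be <= frac_snp_in_mature")
        if self.n_mirna < 1:
            raise ConfigError("n_mirna must be >= 1")
        if self.n_utr < 1:
            raise ConfigError("n_utr must be >= 1")
        for name in ("utr_len_range", "n_snps_per_mirna_range", "qtl_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must have low <= high, got ({lo}, {hi})")
        if self.utr_len_range[0] < 30:
            raise ConfigError("utr_len_range low bound must be >= 30")
        if self.n_qtl < 0:
            raise ConfigError("n_qtl must be >= 0")


@dataclass
class TruthManifest:
    """Planted ground truth keyed the same way the pipeline keys its outputs."""

    # snp_id -> {region_class, substitution_type, conservation_class,
    #            precursor_id, mature_id, chrom, pos}
    snps: Dict[str, dict]
    # "snp_id|mature_id" -> {"gained": [...], "lost": [...]}
    planted_targets: Dict[str, Dict[str, List[str]]]
    # every true (snp_id, precursor_id, trait_name, trait_category) containment
    qtl_memberships: List[Tuple[str, str, str, str]]
    # precursor_id -> sorted trait names of QTLs containing it entirely
    mirna_traits: Dict[str, List[str]]
    config: dict

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "snps": self.snps,
            "planted_targets": self.planted_targets,
            "qtl_memberships": [list(t) for t in self.qtl_memberships],
            "mirna_traits": self.mirna_traits,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            snps=d["snps"],
            planted_targets=d["planted_targets"],
            qtl_memberships=[tuple(t) for t in d["qtl_memberships"]],
            mirna_traits=d["mirna_traits"],
            config=d["config"],
        )


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of one generated fixture."""

    gff3: Path
    precursor_fasta: Path
    vcf: Path
    utr_fasta: Path
    qtl_tsv: Path
    bedgraph: Path
    manifest: Path

    def paths(self) -> Tuple[Path, ...]:
        return (
            self.gff3,
            self.precursor_fasta,
            self.vcf,
            self.utr_fasta,
            self.qtl_tsv,
            self.bedgraph,
            self.manifest,
        )


def _rand_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=n))


def make_hairpin_sequence(
    stem_len: int,
    loop_len: int,
    rng: np.random.Generator,
    arm: Optional[str] = None,
) -> str:
    """A perfect hairpin: 5' arm + loop + reverse complement of the arm.

    The 5' arm is drawn from ``rng`` unless given; loop bases are always
    drawn from ``rng``.  Loops shorter than 3 nt cannot close a hairpin.
    """
    if stem_len < 1:
        raise ValueError(f"stem_len must be >= 1, got {stem_len}")
    if loop_len < 3:
        raise ValueError(f"loop_len must be >= 3 (minimum hairpin loop), got {loop_len}")
    if arm is None:
        arm = _rand_rna(rng, stem_len)
    elif len(arm) != stem_len:
        raise ValueError("arm length != stem_len")
    loop = _rand_rna(rng, loop_len)
    return arm + loop + rna_revcomp(arm)


def plant_site(utr_seq: str, mature_seq: str, site_type: str, position: int) -> str:
    """Write the exact seed-match site of ``site_type`` into a UTR at ``position``.

    Inverse of the site scanner: the returned UTR contains, starting at the
    0-based ``position``, the site string implied by the type for
    ``mature_seq``; all other bases are unchanged.
    """
    site = site_string(mature_seq, site_type)
    if position < 0 or position + len(site) > len(utr_seq):
        raise IndexError(
            f"site of length {len(site)} at {position} exceeds UTR length {len(utr_seq)}"
        )
    return utr_seq[:position] + site + utr_seq[position + len(site) :]


def site_string(mature_seq: str, site_type: str) -> str:
    """The exact UTR substring a site type implies for a mature sequence."""
    s, s6, _ = seed_strings(mature_seq)
    if site_type == "8mer":
        return s + "A"
    if site_type == "7mer-m8":
        return s
    if site_type == "7mer-A1":
        return s6 + "A"
    if site_type == "6mer":
        return s6
    raise ValueError(f"unknown site type {site_type!r}")


def _scrub_utr(
    utr: List[str], forbidden: Set[str], rng: np.random.Generator, frozen: Sequence[Tuple[int, int]] = ()
) -> None:
    """Mutate bases until no forbidden 6mer occurs outside frozen intervals."""
    if not forbidden:
        return
    for _ in range(2000):
        hit = None
        for p in range(len(utr) - 5):
            if "".join(utr[p : p + 6]) in forbidden:
                if any(p < hi and p + 6 > lo for lo, hi in frozen):
                    continue
                hit = p
                break
        if hit is None:
            return
        # mutate a base of the occurrence that lies outside every frozen interval
        for q in range(hit + 2, hit + 6):  # middle-out, deterministic
            if not any(lo <= q < hi for lo, hi in frozen):
                choices = [b for b in RNA_BASES if b != utr[q]]
                utr[q] = choices[int(rng.integers(len(choices)))]
                break
    raise RuntimeError("UTR scrubbing did not converge")


def _find_forbidden(utr: str, forbidden: Set[str], lo: int, hi: int) -> List[int]:
    """Start positions of forbidden 6mers intersecting [lo, hi) of the UTR."""
    out = []
    for p in range(max(0, lo - 5), min(len(utr) - 5, hi)):
        if utr[p : p + 6] in forbidden:
            out.append(p)
    return out


def generate_fixture(
    config: SimConfig, outdir: Union[str, Path]
) -> Tuple[FixtureBundle, TruthManifest]:
    """Write the six-file fixture bundle and its truth manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)

    # ---- precursors -------------------------------------------------------
    mirnas = []  # dicts with name, chrom, start, end, strand, seq, mature offsets
    cursors = {c: 1000 for c in _CHROMS}
    used_s6: Set[str] = set()  # seed 6mer cores in play; kept unique so one
    # miRNA's planted site can never be a genuine site of another miRNA
    for i in range(config.n_mirna):
        for _try in range(200):
            stem = int(rng.integers(28, 35))
            loop = int(rng.integers(8, 15))
            seq = make_hairpin_sequence(stem, loop, rng)
            mature_off = int(rng.integers(1, stem - MATURE_LEN + 2))  # 1-based sense offset
            s6 = seed_strings(seq[mature_off - 1 : mature_off - 1 + MATURE_LEN])[1]
            if s6 not in used_s6:
                used_s6.add(s6)
                break
        else:  # pragma: no cover - 4^6 cores cannot be exhausted at sane sizes
            raise RuntimeError("could not draw a unique seed core")
        length = len(seq)
        chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + int(rng.integers(2000, 8001))
        cursors[chrom] = start + length
        name = f"sim-mir-{i + 1}"
        mirnas.append(
            dict(
                idx=i,
                name=name,
                mature_name=f"sim-miR-{i + 1}",
                chrom=chrom,
                start=start,
                end=start + length - 1,
                strand=strand,
                seq=seq,
                mature_off=mature_off,  # sense offset of mature start (1-based)
                mature_seq=seq[mature_off - 1 : mature_off - 1 + MATURE_LEN],
            )
        )

    # ---- SNPs -------------------------------------------------------------
    snps = []  # dicts: id, chrom, pos, ref, alt (DNA), region, mirna, mature_off
    snp_counter = 0
    p_seed = config.frac_snp_in_seed
    p_mat = config.frac_snp_in_mature
    for m in mirnas:
        n_snp = int(
            rng.integers(config.n_snps_per_mirna_range[0], config.n_snps_per_mirna_range[1] + 1)
        )
        used_offsets: Set[int] = set()
        length = len(m["seq"])
        mat_lo, mat_hi = m["mature_off"], m["mature_off"] + MATURE_LEN - 1
        for _ in range(n_snp):
            u = rng.random()
            for _try in range(100):
                if u < p_seed:
                    m_off = int(rng.integers(2, 9))  # seed positions 2..8
                    off = mat_lo + m_off - 1
                    region = "seed"
                elif u < p_mat:
                    m_off = int(rng.integers(1, MATURE_LEN + 1))
                    if 2 <= m_off <= 8:
                        continue
                    off = mat_lo + m_off - 1
                    region = "mature_non_seed"
                else:
                    off = int(rng.integers(1, length + 1))
                    if mat_lo <= off <= mat_hi:
                        continue
                    region = "precursor_only"
                if off in used_offsets:
                    continue
                break
            else:
                continue  # could not place this SNP; skip it
            used_offsets.add(off)
            sense_ref = m["seq"][off - 1]
            ref_dna = rna_to_dna(sense_ref)
            if m["strand"] == "-":
                ref_dna = dna_complement(ref_dna)
                pos = m["end"] - off + 1
            else:
                pos = m["start"] + off - 1
            alts = [b for b in DNA_BASES if b != ref_dna]
            alt_dna = alts[int(rng.integers(3))]
            sense_alt = alt_dna if m["strand"] == "+" else dna_complement(alt_dna)
            sense_alt = sense_alt.replace("T", "U")
            if region == "seed" and 2 <= (off - mat_lo + 1) <= 7:
                # the variant seed core must stay unique across the cohort,
                # otherwise a site planted for this variant would be a real
                # site of another miRNA and planted truth would drift
                m_off_1 = off - mat_lo + 1
                mat = m["mature_seq"]
                chosen = None
                for alt_cand in alts[int(rng.integers(3)) :] + alts:  # rng-offset order
                    sa = alt_cand if m["strand"] == "+" else dna_complement(alt_cand)
                    sa = sa.replace("T", "U")
                    vm = mat[: m_off_1 - 1] + sa + mat[m_off_1:]
                    s6v = seed_strings(vm)[1]
                    if s6v not in used_s6:
                        chosen = (alt_cand, sa, s6v)
                        break
                if chosen is None:
                    used_offsets.discard(off)
                    continue  # cannot give this locus a collision-free allele
                alt_dna, sense_alt, s6v = chosen
                used_s6.add(s6v)
            snp_counter += 1
            snps.append(
                dict(
                    snp_id=f"snp{snp_counter:05d}",
                    chrom=m["chrom"],
                    pos=pos,
                    ref=ref_dna,
                    alt=alt_dna,
                    region=region,
                    mirna=m,
                    sense_off=off,
                    mature_off=(off - mat_lo + 1) if region != "precursor_only" else None,
                    sense_alt=sense_alt,
                )
            )

    # ---- UTR database with planted sites ---------------------------------
    seed_snps = [s for s in snps if s["region"] == "seed"]
    forbidden: Set[str] = set()
    for m in mirnas:
        forbidden.add(seed_strings(m["mature_seq"])[1])
    variant_matures: Dict[str, str] = {}
    for s in seed_snps:
        mat = s["mirna"]["mature_seq"]
        vm = mat[: s["mature_off"] - 1] + s["sense_alt"] + mat[s["mature_off"] :]
        variant_matures[s["snp_id"]] = vm
        forbidden.add(seed_strings(vm)[1])

    utr_ids = [f"tx{j + 1:04d}" for j in range(config.n_utr)]
    utrs: Dict[str, List[str]] = {}
    frozen: Dict[str, List[Tuple[int, int]]] = {t: [] for t in utr_ids}
    for t in utr_ids:
        n = int(rng.integers(config.utr_len_range[0], config.utr_len_range[1] + 1))
        seq = list(_rand_rna(rng, n))
        if not config.noise:
            _scrub_utr(seq, forbidden, rng)
        utrs[t] = seq

    planted: Dict[str, Dict[str, List[str]]] = {}

    def _plant(mature_for_site: str, site_type: str, exclude: Set[str]) -> Optional[str]:
        """Plant a site for one allele into a UTR nobody else hits; return tx id."""
        site = site_string(mature_for_site, site_type)
        need = len(site) + (1 if site_type == "7mer-m8" else 0)  # room for non-A tail
        order = rng.permutation(len(utr_ids))
        for ui in order:
            t = utr_ids[int(ui)]
            if t in exclude:
                # the other allele of this SNP already hits this transcript;
                # reusing it would turn a gain+loss pair into "maintained"
                continue
            utr = utrs[t]
            if len(utr) < need + 2:
                continue
            for _try in range(60):
                pos = int(rng.integers(1, len(utr) - need))
                span = (pos, pos + need)
                if any(pos < hi and pos + need > lo for lo, hi in frozen[t]):
                    continue
                candidate = utr[:]
                candidate[pos : pos + len(site)] = list(site)
                if site_type == "7mer-m8" and candidate[pos + len(site)] == "A":
                    candidate[pos + len(site)] = "C"
                # the designed 6mer core starts one base into the site
                designed = {pos + 1}
                extra = [
                    p
                    for p in _find_forbidden("".join(candidate), forbidden, span[0], span[1])
                    if p not in designed
                ]
                if extra and not config.noise:
                    continue  # collision with another active seed; try elsewhere
                utrs[t] = candidate
                frozen[t].append(span)
                return t
        return None

    # Seed SNPs sharing a mature also share its reference sites: a loss site
    # planted for one sibling is lost by every sibling whose variant seed no
    # longer matches, so losses are planted and recorded per mature.  When
    # any sibling sits at seed position 8 (its variant keeps the 6mer core),
    # every plant in that mature uses 7mer-m8 with a non-A tail — an 8mer
    # would leave the other allele a counted 7mer-A1 site.
    by_mature: Dict[str, List[dict]] = {}
    for s in seed_snps:
        by_mature.setdefault(s["mirna"]["mature_name"], []).append(s)
    for mature_name, group in by_mature.items():
        has_pos8 = any(s["mature_off"] == 8 for s in group)
        want_gain = {s["snp_id"]: rng.random() < config.planted_gain_rate for s in group}
        want_loss = {s["snp_id"]: rng.random() < config.planted_loss_rate for s in group}

        def _site_type(snp: dict) -> str:
            return "7mer-m8" if (has_pos8 or snp["mature_off"] == 8) else "8mer"

        shared_lost: List[str] = []
        ref_mature = group[0]["mirna"]["mature_seq"]
        for s in group:
            if want_loss[s["snp_id"]]:
                tx = _plant(ref_mature, _site_type(s), exclude=set())
                if tx:
                    shared_lost.append(tx)
        shared_lost = sorted(set(shared_lost))
        for s in group:
            entry = {"gained": [], "lost": list(shared_lost)}
            if want_gain[s["snp_id"]]:
                tx = _plant(
                    variant_matures[s["snp_id"]], _site_type(s), exclude=set(shared_lost)
                )
                if tx:
                    entry["gained"].append(tx)
            planted[f"{s['snp_id']}|{mature_name}"] = entry

    # ---- QTL intervals ----------------------------------------------------
    qtls = []
    trait_order = rng.permutation(len(TRAIT_VOCABULARY))
    for q in range(config.n_qtl):
        m = mirnas[int(rng.integers(len(mirnas)))]
        qlen = int(rng.integers(config.qtl_len_range[0], config.qtl_len_range[1] + 1))
        prec_len = m["end"] - m["start"] + 1
        slack = max(qlen - prec_len, 0)
        start = max(1, m["start"] - int(rng.integers(0, slack + 1)))
        cat, trait = TRAIT_VOCABULARY[int(trait_order[q % len(TRAIT_VOCABULARY)])]
        qtls.append(dict(chrom=m["chrom"], start=start, end=start + qlen - 1, trait=trait, cat=cat))

    # actual containments, by direct arithmetic over all (SNP, QTL) pairs
    memberships = set()
    for s in snps:
        for q in qtls:
            if s["chrom"] == q["chrom"] and q["start"] <= s["pos"] <= q["end"]:
                memberships.add((s["snp_id"], s["mirna"]["name"], q["trait"], q["cat"]))
    mirna_traits: Dict[str, Set[str]] = {}
    for m in mirnas:
        for q in qtls:
            if m["chrom"] == q["chrom"] and q["start"] <= m["start"] and m["end"] <= q["end"]:
                mirna_traits.setdefault(m["name"], set()).add(q["trait"])

    # ---- conservation track ----------------------------------------------
    cons_class: Dict[str, str] = {}
    loci: Dict[Tuple[str, int], float] = {}
    for s in snps:
        locus = (s["chrom"], s["pos"])
        if locus not in loci:
            if rng.random() < config.conserved_frac:
                score = round(float(rng.uniform(0.5, 5.0)), 3)
            else:
                score = round(float(rng.uniform(-5.0, -0.5)), 3)
            loci[locus] = score
        cons_class[s["snp_id"]] = "slow" if loci[locus] > 0 else "fast"

    # ---- write files ------------------------------------------------------
    bundle = FixtureBundle(
        gff3=outdir / "mirna.gff3",
        precursor_fasta=outdir / "precursors.fa",
        vcf=outdir / "snps.vcf",
        utr_fasta=outdir / "utrs.fa",
        qtl_tsv=outdir / "qtl.tsv",
        bedgraph=outdir / "conservation.bedgraph",
        manifest=outdir / "truth.json",
    )

    with open(bundle.gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(mirnas, key=lambda d: (d["chrom"], d["start"])):
            mi = f"MI{m['idx'] + 1:07d}"
            fh.write(
                f"{m['chrom']}\t.\tmiRNA_primary_transcript\t{m['start']}\t{m['end']}\t.\t"
                f"{m['strand']}\t.\tID={mi};Name={m['name']}\n"
            )
            if m["strand"] == "+":
                ms = m["start"] + m["mature_off"] - 1
                me = ms + MATURE_LEN - 1
            else:
                me = m["end"] - m["mature_off"] + 1
                ms = me - MATURE_LEN + 1
            fh.write(
                f"{m['chrom']}\t.\tmiRNA\t{ms}\t{me}\t.\t{m['strand']}\t.\t"
                f"ID=MIMAT{m['idx'] + 1:07d};Name={m['mature_name']};Derives_from={mi}\n"
            )

    with open(bundle.precursor_fasta, "w") as fh:
        for m in mirnas:
            fh.write(f">{m['name']}\n{m['seq']}\n")

    chrom_lens = {c: cursors[c] + 100_000 for c in _CHROMS}
    with open(bundle.vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=mirsnp-simulate\n")
        for c in _CHROMS:
            fh.write(f"##contig=<ID={c},length={chrom_lens[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda d: (d["chrom"], d["pos"], d["snp_id"])):
            fh.write(f"{s['chrom']}\t{s['pos']}\t{s['snp_id']}\t{s['ref']}\t{s['alt']}\t.\t.\t.\n")

    with open(bundle.utr_fasta, "w") as fh:
        for t in utr_ids:
            fh.write(f">{t}\n{rna_to_dna(''.join(utrs[t]))}\n")

    with open(bundle.qtl_tsv, "w") as fh:
        fh.write("chrom\tstart\tend\ttrait_name\ttrait_category\n")
        for q in sorted(qtls, key=lambda d: (d["chrom"], d["start"], d["trait"])):
            fh.write(f"{q['chrom']}\t{q['start']}\t{q['end']}\t{q['trait']}\t{q['cat']}\n")

    with open(bundle.bedgraph, "w") as fh:
        for (chrom, pos), score in sorted(loci.items()):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{score}\n")

    manifest = TruthManifest(
        snps={
            s["snp_id"]: dict(
                region_class=s["region"],
                substitution_type=(
                    "transition" if {s["ref"], s["alt"]} in ({"A", "G"}, {"C", "T"}) else "transversion"
                ),
                conservation_class=cons_class[s["snp_id"]],
                precursor_id=s["mirna"]["name"],
                mature_id=s["mirna"]["mature_name"] if s["region"] != "precursor_only" else None,
                chrom=s["chrom"],
                pos=s["pos"],
            )
            for s in snps
        },
        planted_targets=planted,
        qtl_memberships=sorted(memberships),
        mirna_traits={k: sorted(v) for k, v in sorted(mirna_traits.items())},
        config=asdict(config),
    )
    manifest.to_json(bundle.manifest)
    return bundle, manifest


def validate_manifest(bundle: FixtureBundle, manifest: TruthManifest) -> None:
    """Check every cross-reference in the manifest against the written files."""
    from Bio import SeqIO

    utr_ids = {rec.id for rec in SeqIO.parse(str(bundle.utr_fasta), "fasta")}
    vcf_ids = set()
    with open(bundle.vcf) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            vcf_ids.add(line.split("\t")[2])
    for snp_id in manifest.snps:
        if snp_id not in vcf_ids:
            raise ValueError(f"manifest SNP {snp_id} missing from VCF")
    for key, entry in manifest.planted_targets.items():
        snp_id = key.split("|")[0]
        if snp_id not in vcf_ids:
            raise ValueError(f"planted-target SNP {snp_id} missing from VCF")
        for tx in entry["gained"] + entry["lost"]:
            if tx not in utr_ids:
                raise ValueError(f"planted transcript {tx} missing from UTR FASTA")
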