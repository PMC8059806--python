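"""End-to-end orchestration: map -> targets -> fold -> overlap -> report.

Each stage consumes the previous stage's in-memory objects (and writes its
table as TSV), so the stages form a DAG and rerunning on identical inputs is
byte-identical.  Numeric columns are printed with six significant digits for
reproducible diffs.  Per-stage record counts are logged to stderr as
machine-parsable ``stage=<name> n_in=... n_out=...`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml
from Bio import SeqIO

from mirsnp import context, folding, mapping, stats, targets
from mirsnp._seq import dna_to_rna

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    gff3: Path
    precursor_fasta: Path
    vcf: Path
    utr_fasta: Path
    qtl_tsv: Path
    bedgraph: Path
    outdir: Path
    mapping_tsv: Optional[Path] = None
    site_types: Tuple[str, ...] = tuple(sorted(targets.DEFAULT_COUNTED_TYPES))
    min_sites: int = 1
    threshold: float = folding.DEFAULT_THRESHOLD
    energy_model: folding.EnergyModel = field(default_factory=folding.EnergyModel)
    skip_mismatch: bool = False
    by_precursor: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        model = folding.EnergyModel(**raw.pop("energy_model", {}))
        paths = {
            k: Path(raw.pop(k))
            for k in ("gff3", "precursor_fasta", "vcf", "utr_fasta", "qtl_tsv", "bedgraph", "outdir")
        }
        if "mapping_tsv" in raw and raw["mapping_tsv"]:
            raw["mapping_tsv"] = Path(raw.pop("mapping_tsv"))
        if "site_types" in raw:
            raw["site_types"] = tuple(raw.pop("site_types"))
        return cls(energy_model=model, **paths, **raw)

    @property
    def policy(self) -> targets.SitePolicy:
        return targets.SitePolicy(frozenset(self.site_types), self.min_sites)


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _ids(s) -> str:
    return ",".join(sorted(s)) if s else "."


def stage_map(config: PipelineConfig) -> Tuple[List[mapping.MirnaAnnotation], List[mapping.MappedVariant]]:
    anns = mapping.load_mirna_annotations(config.gff3, config.precursor_fasta)
    snps = mapping.load_snps(config.vcf)
    mapped = mapping.map_all(snps, anns, skip_mismatch=config.skip_mismatch)
    logger.info("stage=map n_mirna=%d n_snps=%d n_mapped=%d", len(anns), len(snps), len(mapped))
    rows = [
        (
            mv.snp_id,
            mv.precursor_id,
            mv.chrom,
            mv.pos,
            mv.mature_id,
            mv.region_class,
            mv.precursor_offset,
            mv.mature_offset,
            mv.sense_ref,
            mv.sense_alt,
            mv.substitution_type,
            mv.ref_mature_seq,
            mv.alt_mature_seq,
        )
        for mv in mapped
    ]
    _write_tsv(
        config.outdir / "mapped_variants.tsv",
        [
            "snp_id",
            "precursor_id",
            "chrom",
            "pos",
            "mature_id",
            "region_class",
            "precursor_offset",
            "mature_offset",
            "sense_ref",
            "sense_alt",
            "substitution_type",
            "ref_mature_seq",
            "alt_mature_seq",
        ],
        rows,
    )
    return anns, mapped


def load_utr_db(path: Union[str, Path]) -> Dict[str, str]:
    return {rec.id: dna_to_rna(str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")}


def stage_targets(
    config: PipelineConfig, mapped: Sequence[mapping.MappedVariant]
) -> Dict[str, targets.TargetDiff]:
    """Predict ref/variant targets for every mature-region SNP and diff them.

    Diffs are keyed by "snp_id|mature_id".  Non-seed mature SNPs are diffed
    too (their diff is provably empty under seed-match semantics) so the
    output table documents that neutrality.
    """
    utr_db = load_utr_db(config.utr_fasta)
    policy = config.policy
    diffs: Dict[str, targets.TargetDiff] = {}
    rows = []
    ref_cache: Dict[str, frozenset] = {}
    for mv in mapped:
        if mv.mature_id is None:
            continue
        key = f"{mv.snp_id}|{mv.mature_id}"
        if mv.ref_mature_seq not in ref_cache:
            ref_cache[mv.ref_mature_seq] = frozenset(
                targets.predict_targets(mv.ref_mature_seq, utr_db, policy)
            )
        ref_set = ref_cache[mv.ref_mature_seq]
        alt_set = targets.predict_targets(mv.alt_mature_seq, utr_db, policy)
        diff = targets.diff_targets(set(ref_set), alt_set)
        diffs[key] = diff
        rows.append(
            (
                mv.snp_id,
                mv.mature_id,
                mv.precursor_id,
                mv.region_class,
                len(ref_set),
                len(alt_set),
                len(diff.gained),
                len(diff.lost),
                len(diff.maintained),
                diff.prop_gained,
                diff.prop_lost,
                diff.prop_maintained,
                targets.classify_mirna_alteration(diff),
                _ids(diff.gained),
                _ids(diff.lost),
                _ids(diff.maintained),
            )
        )
    logger.info("stage=targets n_in=%d n_diffs=%d", len(mapped), len(diffs))
    _write_tsv(
        config.outdir / "target_diff.tsv",
        [
            "snp_id",
            "mature_id",
            "precursor_id",
            "region_class",
            "n_ref_targets",
            "n_alt_targets",
            "n_gained",
            "n_lost",
            "n_maintained",
            "prop_gained",
            "prop_lost",
            "prop_maintained",
            "alteration",
            "gained_ids",
            "lost_ids",
            "maintained_ids",
        ],
        rows,
    )
    return diffs


def stage_fold(
    config: PipelineConfig, mapped: Sequence[mapping.MappedVariant]
) -> Dict[str, folding.DdgResult]:
    """Fold reference and variant precursors and classify ddG per SNP."""
    results: Dict[str, folding.DdgResult] = {}
    rows = []
    mfe_cache: Dict[str, folding.FoldResult] = {}

    def fold(seq: str) -> folding.FoldResult:
        if seq not in mfe_cache:
            mfe_cache[seq] = folding.fold_mfe(seq, config.energy_model)
        return mfe_cache[seq]

    seen = set()
    for mv in mapped:
        key = (mv.snp_id, mv.precursor_id)
        if key in seen:
            continue  # one fold per SNP x precursor even if two matures are hit
        seen.add(key)
        res = folding.ddg(
            mv.ref_precursor_seq,
            mv.alt_precursor_seq,
            config.energy_model,
            config.threshold,
            backend=fold,
        )
        results[mv.snp_id] = res
        rows.append((mv.snp_id, mv.precursor_id, res.mfe_ref, res.mfe_alt, res.ddg, res.category))
    logger.info("stage=fold n_in=%d n_folded=%d", len(mapped), len(rows))
    _write_tsv(
        config.outdir / "ddg.tsv",
        ["snp_id", "precursor_id", "mfe_ref", "mfe_alt", "ddg", "category"],
        rows,
    )
    return results


def stage_overlap(
    config: PipelineConfig,
    anns: Sequence[mapping.MirnaAnnotation],
    mapped: Sequence[mapping.MappedVariant],
    diffs: Mapping[str, targets.TargetDiff],
) -> List[Tuple[str, str, str, str]]:
    """Intersect SNP loci with QTL intervals; tabulate traits per altered miRNA."""
    qtls = context.load_qtl_table(config.qtl_tsv)
    rows = context.overlap_snps_qtl(mapped, qtls)
    altered_snps = {
        key.split("|")[0] for key, d in diffs.items() if d.gained or d.lost
    }
    _write_tsv(
        config.outdir / "qtl_overlap.tsv",
        ["snp_id", "mirna_id", "trait_name", "trait_category", "altered_targets"],
        [(s, m, t, c, "yes" if s in altered_snps else "no") for s, m, t, c in rows],
    )
    if config.by_precursor:
        prec_rows = context.overlap_precursors_qtl(anns, qtls)
        trait_map: Dict[Tuple[str, str], set] = {}
        for mirna_id, trait, cat in prec_rows:
            trait_map.setdefault((cat, trait), set()).add(mirna_id)
    else:
        trait_map = {}
        for snp_id, mirna_id, trait, cat in rows:
            if snp_id in altered_snps:
                trait_map.setdefault((cat, trait), set()).add(mirna_id)
    _write_tsv(
        config.outdir / "trait_mirna.tsv",
        ["trait_category", "trait_name", "mirnas"],
        [(cat, trait, _ids(m)) for (cat, trait), m in sorted(trait_map.items())],
    )
    logger.info("stage=overlap n_pairs=%d n_traits=%d", len(rows), len(trait_map))
    return rows


def stage_conservation(
    config: PipelineConfig, mapped: Sequence[mapping.MappedVariant]
) -> List[context.ConservationScore]:
    track = context.load_bedgraph(config.bedgraph)
    coord_map = None
    if config.mapping_tsv:
        coord_map = {}
        with open(config.mapping_tsv) as fh:
            next(fh)
            for line in fh:
                c1, p1, c2, p2 = line.rstrip("\n").split("\t")
                coord_map[(c1, int(p1))] = (c2, int(p2))
    loci = sorted({(mv.chrom, mv.pos) for mv in mapped})
    scores = context.lookup_conservation(loci, track, coord_map)
    by_locus = {(s.chrom, s.pos): s for s in scores}
    rows = []
    for mv in sorted(mapped, key=lambda m: (m.chrom, m.pos, m.snp_id)):
        s = by_locus[(mv.chrom, mv.pos)]
        rows.append((mv.snp_id, mv.chrom, mv.pos, s.score, s.conservation_class))
    seen = set()
    rows = [r for r in rows if not (r[0] in seen or seen.add(r[0]))]
    _write_tsv(
        config.outdir / "conservation.tsv",
        ["snp_id", "chrom", "pos", "phylop_score", "conservation_class"],
        rows,
    )
    logger.info("stage=conservation n_loci=%d", len(loci))
    return scores


def stage_report(
    config: PipelineConfig,
    anns: Sequence[mapping.MirnaAnnotation],
    mapped: Sequence[mapping.MappedVariant],
    diffs: Mapping[str, targets.TargetDiff],
    ddgs: Mapping[str, folding.DdgResult],
    cons: Sequence[context.ConservationScore],
) -> stats.CohortSummary:
    seed_diffs = {
        key: d
        for key, d in diffs.items()
        if any(
            f"{mv.snp_id}|{mv.mature_id}" == key and mv.region_class == "seed" for mv in mapped
        )
    }
    summary = stats.build_cohort_summary(len(anns), mapped, seed_diffs)
    ddg_summary = folding.cohort_ddg_summary(ddgs.values())
    cons_summary = context.conservation_summary(cons)

    welch_rows = []
    ddg_cmp = stats.ts_tv_compare(mapped, {k: v.ddg for k, v in ddgs.items()})
    alteration_by_snp: Dict[str, float] = {}
    for key, d in seed_diffs.items():
        snp_id = key.split("|")[0]
        alteration_by_snp[snp_id] = alteration_by_snp.get(snp_id, 0) + len(d.gained) + len(d.lost)
    alt_cmp = stats.ts_tv_compare(
        [mv for mv in mapped if mv.snp_id in alteration_by_snp], alteration_by_snp
    )
    for name, cmp in (("ddg", ddg_cmp), ("target_alteration", alt_cmp)):
        w = cmp.welch
        welch_rows.append(
            (
                name,
                cmp.n_transition,
                cmp.n_transversion,
                cmp.mean_transition,
                cmp.mean_transversion,
                w.t_statistic if w else None,
                w.df if w else None,
                w.p_value if w else None,
                "yes" if w else "no",
            )
        )
    _write_tsv(
        config.outdir / "welch_tests.tsv",
        ["comparison", "n_ts", "n_tv", "mean_ts", "mean_tv", "t", "df", "p_value", "testable"],
        welch_rows,
    )

    kv = [
        ("n_mirna_total", summary.n_mirna_total),
        ("n_with_snp", summary.n_with_snp),
        ("n_mature_snp", summary.n_mature_snp),
        ("n_seed_snp", summary.n_seed_snp),
        ("n_altered_target", summary.n_altered_target),
        ("fraction_altered", summary.fraction_altered),
        ("prop_gained", summary.prop_gained),
        ("prop_lost", summary.prop_lost),
        ("prop_unaltered", summary.prop_unaltered),
        ("ts_count", summary.ts_count),
        ("tv_count", summary.tv_count),
        ("ddg_n", ddg_summary.n_total),
        ("ddg_fraction_altering", ddg_summary.fraction_altering),
        ("ddg_fraction_positive_above", ddg_summary.fraction_positive_above),
        ("conservation_n_scored", cons_summary.n_scored),
        ("conservation_n_missing", cons_summary.n_missing),
        ("conservation_frac_slow", cons_summary.frac_slow),
        ("conservation_frac_neutral", cons_summary.frac_neutral),
        ("conservation_frac_fast", cons_summary.frac_fast),
    ]
    _write_tsv(config.outdir / "summary.tsv", ["key", "value"], kv)
    logger.info("stage=report n_seed_diffs=%d", len(seed_diffs))
    return summary


REPORT_FILES = (
    "mapped_variants.tsv",
    "target_diff.tsv",
    "ddg.tsv",
    "qtl_overlap.tsv",
    "trait_mirna.tsv",
    "conservation.tsv",
    "welch_tests.tsv",
    "summary.tsv",
)


def run_all(config: PipelineConfig) -> stats.CohortSummary:
    """Run every stage in order; raise :class:`StageError` naming the stage."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    try:
        anns, mapped = stage_map(config)
    except Exception as exc:
        raise StageError("map", exc) from exc
    try:
        diffs = stage_targets(config, mapped)
    except Exception as exc:
        raise StageError("targets", exc) from exc
    try:
        ddgs = stage_fold(config, mapped)
    except Exception as exc:
        raise StageError("fold", exc) from exc
    try:
        stage_overlap(config, anns, mapped, diffs)
    except Exception as exc:
        raise StageError("overlap", exc) from exc
    try:
        cons = stage_conservation(config, mapped)
    except Exception as exc:
        raise StageError("conservation", exc) from exc
    try:
        return stage_report(config, anns, mapped, diffs, ddgs, cons)
    except Exception as exc:
        raise StageError("report", exc) from exc
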