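"""Shared wiring for the numbered analysis drivers."""

from pathlib import Path

from mirsnp import pipeline


def fixture_config(root: Path) -> pipeline.PipelineConfig:
    fix = root / "results" / "fixture"
    if not fix.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cfg = pipeline.PipelineConfig(
        gff3=fix / "mirna.gff3",
        precursor_fasta=fix / "precursors.fa",
        vcf=fix / "snps.vcf",
        utr_fasta=fix / "utrs.fa",
        qtl_tsv=fix / "qtl.tsv",
        bedgraph=fix / "conservation.bedgraph",
        outdir=root / "results" / "pipeline",
    )
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    return cfg
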