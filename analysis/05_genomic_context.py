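#!/usr/bin/env python
"""Intersect SNPs with QTL intervals and attach conservation classes.

Reports which trait-associated intervals contain miRNA SNPs (flagging the
miRNAs whose target prediction the SNP altered) and the slow / neutral /
fast breakdown of phyloP-style scores at SNP loci.  Writes
results/pipeline/qtl_overlap.tsv, trait_mirna.tsv and conservation.tsv.
"""

from pathlib import Path

from helpers import fixture_config
from mirsnp import context, pipeline

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cfg = fixture_config(ROOT)
    anns, mapped = pipeline.stage_map(cfg)
    diffs = pipeline.stage_targets(cfg, mapped)
    rows = pipeline.stage_overlap(cfg, anns, mapped, diffs)
    cons = pipeline.stage_conservation(cfg, mapped)
    s = context.conservation_summary(cons)
    snps = {r[0] for r in rows}
    mirnas = {r[1] for r in rows}
    traits = {r[2] for r in rows}
    print(f"QTL overlap: {len(snps)} SNPs in {len(mirnas)} miRNAs across {len(traits)} traits")
    print(f"conservation over {s.n_scored} scored loci: "
          f"slow {100 * s.frac_slow:.1f}%, neutral {100 * s.frac_neutral:.1f}%, "
          f"fast {100 * s.frac_fast:.1f}% ({s.n_missing} unscored)")
    print(f"  tables: {cfg.outdir / 'qtl_overlap.tsv'}, {cfg.outdir / 'trait_mirna.tsv'}, "
          f"{cfg.outdir / 'conservation.tsv'}")


if __name__ == "__main__":
    main()
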