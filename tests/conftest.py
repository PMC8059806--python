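import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirsnp import pipeline, simulate


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The standard 50-miRNA decoy-free cohort (seed 7) plus its manifest."""
    outdir = tmp_path_factory.mktemp("fixture")
    bundle, manifest = simulate.generate_fixture(simulate.SimConfig(), outdir)
    return bundle, manifest


@pytest.fixture(scope="session")
def pipeline_run(default_fixture, tmp_path_factory):
    """Full pipeline outputs on the standard cohort."""
    bundle, manifest = default_fixture
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = pipeline.PipelineConfig(
        gff3=bundle.gff3,
        precursor_fasta=bundle.precursor_fasta,
        vcf=bundle.vcf,
        utr_fasta=bundle.utr_fasta,
        qtl_tsv=bundle.qtl_tsv,
        bedgraph=bundle.bedgraph,
        outdir=outdir,
    )
    summary = pipeline.run_all(cfg)
    return cfg, summary, bundle, manifest
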