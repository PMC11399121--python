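from pathlib import Path

import numpy as np
import pytest

from lnctarget import GeneAnnotation, PipelineConfig, run_pipeline
from lnctarget.synthetic import load_truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full synthetic pipeline run on generator defaults, shared
    across tests that only need to inspect its persisted outputs."""
    run_dir = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(random_seed=11, simulate={}, output_dir=str(run_dir))
    report = run_pipeline(cfg)
    truth = load_truth(Path(run_dir) / "sim")
    return Path(run_dir), report, truth


@pytest.fixture
def ten_genes():
    """Hand-built 10-gene annotation on one chromosome, alternating strands,
    three exons per gene (so introns exist between them)."""
    genes = []
    pos = 5000
    for i in range(10):
        strand = "+" if i % 2 == 0 else "-"
        start, end = pos, pos + 2000
        exons = [(start, start + 300), (start + 900, start + 1200), (end - 300, end)]
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i:02d}",
                gene_name=f"G{i}",
                chrom="chr1",
                strand=strand,
                tx_start=start,
                tx_end=end,
                exons=exons,
            )
        )
        pos = end + 9000
    return genes
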