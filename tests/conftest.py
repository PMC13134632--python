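import os

import pytest

from crypticsplice import synthetic_data as sd
from crypticsplice.pipeline import PipelineConfig, run_pipeline


SMALL_SIM = dict(
    seed=11,
    n_genes=120,
    n_r_preferred=15,
    n_k_preferred=15,
    n_shared=6,
    n_null=12,
    genes_per_chrom=60,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated dataset plus a full pipeline run over it."""
    root = tmp_path_factory.mktemp("smallsim")
    cfg = sd.SimulationConfig(**SMALL_SIM)
    sim = sd.simulate_all(cfg, os.path.join(root, "sim"))
    pcfg = PipelineConfig(
        sj_dir=os.path.join(root, "sim", "sj"),
        gtf=os.path.join(root, "sim", "annotation.gtf"),
        fasta=os.path.join(root, "sim", "genome.fa"),
        counts=os.path.join(root, "sim", "counts.tsv"),
        groups=os.path.join(root, "sim", "groups.tsv"),
        out_dir=os.path.join(root, "out"),
        n_controls=60,
        seed=11,
    )
    results = run_pipeline(pcfg)
    return {"config": cfg, "sim": sim, "pipeline_config": pcfg,
            "results": results, "root": str(root)}
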