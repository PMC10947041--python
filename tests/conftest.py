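import numpy as np
import pandas as pd
import pytest

from mbsvkit import pipeline
from mbsvkit.synthetic import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def dataset():
    """Small full synthetic study with a high decoy fraction."""
    config = SimulationConfig(n_variants=800, seed=7, frac_mbsv=0.05, frac_decoy=0.2)
    return simulate_all(config)


@pytest.fixture(scope="session")
def pipeline_inputs(dataset):
    d = dataset
    return pipeline.PipelineInputs(
        gwas=d.gwas, sites=d.sites,
        gene_expression=d.gene_rpkm, gene_units="RPKM",
        mirna_counts=d.mirna_counts, library_sizes=d.library_sizes,
        mirna_tiers=d.tiers, family_map=d.family_map,
        gtex_eqtls=d.gtex_eqtls, psychencode_eqtls=d.psychencode_eqtls,
        panel=d.panel)


@pytest.fixture(scope="session")
def pipeline_result(pipeline_inputs):
    return pipeline.run(pipeline_inputs, seed=1)


def make_sites(rows):
    """Site-score frame from (chrom, pos, ref, alt, allele, mirna, gene,
    transcript, targetscan, miranda, rnahybrid) tuples."""
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "allele", "mirna", "gene", "transcript",
        "targetscan", "miranda", "rnahybrid"])
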