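import json

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from breaksig import (SimConfig, generate, RunConfig, run_all, GenomeRef,
                      random_genome)
from breaksig.filtering import FilterThresholds


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeRef:
    """Deterministic 10 kb, 2-chromosome genome with an N run."""
    rng = np.random.default_rng(42)
    g = random_genome(10_000, n_chromosomes=2, gc_content=0.41, rng=rng,
                      n_run_length=200, n_runs_per_chrom=1)
    return g


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One default-configuration synthetic data set shared by the suite."""
    outdir = tmp_path_factory.mktemp("default_sim")
    manifest = generate(SimConfig(seed=101), outdir)
    truth = json.loads(open(manifest["paths"]["truth_json"]).read())
    return manifest, truth


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """Full pipeline run over the default synthetic data set."""
    manifest, truth = default_sim
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(
        off_vcf=manifest["paths"]["off_vcf"],
        esc_vcf=manifest["paths"]["esc_vcf"],
        genome_fasta=manifest["paths"]["genome_fasta"],
        breakpoints_bed=manifest["paths"]["breakpoints_bed"],
        outdir=str(outdir),
        thresholds=FilterThresholds(depth_policy="GE_MEAN"),
        mean_coverage=truth["mean_coverage"], seed=101)
    summary = run_all(cfg)
    return cfg, summary


@pytest.fixture(scope="session")
def sparse_sim(tmp_path_factory):
    """Sparse-background data set for cluster-detection recovery: the
    default genome and kataegis plan over a 100-per-Mb background."""
    outdir = tmp_path_factory.mktemp("sparse_sim")
    cfg = SimConfig(seed=55, n_shared_mutations=2_000, n_case_specific=500,
                    n_shared_indels=200, n_case_specific_indels=100)
    manifest = generate(cfg, outdir)
    truth = json.loads(open(manifest["paths"]["truth_json"]).read())
    return manifest, truth
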