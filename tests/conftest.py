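"""Shared fixtures: a scaled-down synthetic cohort and its pipeline result.

The small cohort keeps unit tests fast; the full-scale default configuration
is exercised by the acceptance tests.
"""

from __future__ import annotations

import dataclasses

import pytest

from cnvland.intervals import ChromosomeTable
from cnvland.pipeline import run_pipeline
from cnvland.synthetic_cohort import GenomeConfig, SyntheticConfig, generate


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    base = dict(
        seed=seed,
        n_patients=110,
        male_fraction=0.65,
        known_consanguinity_fraction=0.5,
        consanguineous_fraction=0.3,
        n_controls=100,
        pathogenic_carrier_count=12,
        pathogenic_call_count=13,
        vous_carrier_count=40,
        loh_rate_consanguineous=5.0,
        loh_rate_outbred=1.0,
        common_calls_rate=2.0,
        rare_benign_rate=0.5,
        control_background_rate=1.0,
        genome=GenomeConfig(n_genes=150),
        n_syndrome_regions=6,
        n_common_loci=15,
        n_common_roh=12,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate(small_cfg)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    ds = small_dataset
    return run_pipeline(
        ds.case_calls,
        ds.patients,
        ds.control_cohort,
        ds.gene_models,
        ds.syndrome_regions,
        ds.chrom_table,
    )


@pytest.fixture(scope="session")
def hg38() -> ChromosomeTable:
    return ChromosomeTable.hg38()


@pytest.fixture(scope="session")
def toy_chroms() -> ChromosomeTable:
    return ChromosomeTable(
        assembly="toy", lengths={"chr1": 10_000_000, "chr2": 5_000_000}
    )
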