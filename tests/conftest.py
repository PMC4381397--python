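import numpy as np
import pandas as pd
import pytest

from shoredmr.genome import Contig, GenomeLayout
from shoredmr.methylome_io import MUTANT, WILDTYPE, CpGCallTable
from shoredmr.synthetic_data import (
    SimulationConfig,
    simulate_layout_and_annotation,
    simulate_methylomes,
)


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout(
        [
            Contig("chr1", 1_000_000),
            Contig("chr2", 500_000),
            Contig("lambda", 48_502, is_spike_in=True),
        ]
    )


def make_table(records, sample_id="s1", group=WILDTYPE, layout=None):
    """records: list of (chrom, pos, meth, unmeth)."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "meth", "unmeth"])
    return CpGCallTable(sample_id=sample_id, group=group, df=df, layout=layout)


@pytest.fixture(scope="session")
def sim_config():
    # desk-scale slice of the study design: 2 chroms x 3 Mb, 2v2, 30x
    return SimulationConfig(seed=20_210, n_chroms=2, chrom_length=3_000_000)


@pytest.fixture(scope="session")
def sim_annotation(sim_config):
    return simulate_layout_and_annotation(sim_config)


@pytest.fixture(scope="session")
def sim_methylomes(sim_config, sim_annotation):
    tables, truth = simulate_methylomes(sim_config, sim_annotation)
    return tables, truth
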