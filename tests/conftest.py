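import pytest

from mirmeta.simulate import (SimConfig, simulate_contaminants,
                              simulate_precursors, simulate_reads)
from mirmeta.table1 import load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_by_name(table1):
    return {p.name: p for p in table1}


@pytest.fixture(scope="session")
def clean_library():
    """Zero-noise synthetic library with generous mature/star sampling."""
    cfg = SimConfig(seed=3, n_reads=40_000, error_rate=0.0,
                    mature_fraction=0.4, star_fraction=0.3,
                    contaminant_fraction=0.1, junk_fraction=0.05)
    precursors, pre_truth, _ = simulate_precursors(cfg)
    contaminants = simulate_contaminants(cfg)
    fastq, read_truth = simulate_reads(cfg, precursors, contaminants)
    return {"config": cfg, "precursors": precursors, "pre_truth": pre_truth,
            "contaminants": contaminants, "fastq": fastq,
            "read_truth": read_truth}
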