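import numpy as np
import pandas as pd
import pytest

import clonedyn as cd


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated experiment, shared across tests."""
    return cd.simulate_experiment(seed=1)


@pytest.fixture(scope="session")
def default_freqs(default_sim):
    return cd.counts_to_frequencies(default_sim.counts, min_reads=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_fastq(records):
    """Build FASTQ text from (name, sequence) pairs with dummy qualities."""
    lines = []
    for name, seq in records:
        lines += [f"@{name}", seq, "+", "I" * len(seq)]
    return "\n".join(lines) + "\n" if lines else ""


@pytest.fixture()
def fastq_factory(tmp_path):
    def _write(records, fname="reads.fastq"):
        path = tmp_path / fname
        path.write_text(make_fastq(records))
        return path

    return _write


def toy_freq_table():
    """Three samples over four barcodes, frequencies summing to one."""
    return pd.DataFrame(
        {
            "s1": [0.5, 0.25, 0.25, 0.0],
            "s2": [0.5, 0.25, 0.25, 0.0],
            "s3": [0.1, 0.2, 0.3, 0.4],
        },
        index=["AC", "AG", "TC", "TG"],
    )
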