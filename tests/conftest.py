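import numpy as np
import pandas as pd
import pytest

from pearpop.matrix import GenotypeMatrix
from pearpop.cohort import default_config, simulate_cohort

EXCLUDE_ADMIXED = ("sinkiangensis",)


def make_matrix(dosages, positions=None, chrom="chr1", groups=None, chrom_length=None):
    """Build a small GenotypeMatrix from a dosage array.

    ``groups`` is a list of "<region>_<status>" labels, one per sample
    (default: everyone Asian_wild).
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    groups = groups or ["Asian_wild"] * n_samples
    rows = []
    for i, g in enumerate(groups):
        region, status = g.split("_", 1)
        rows.append({"sample_id": f"s{i:02d}", "region": region, "status": status,
                     "species": "test"})
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "ref": "A", "alt": "G",
    })
    lengths = {chrom: chrom_length or int(max(positions))}
    return GenotypeMatrix(sites=sites, dosages=dosages, samples=pd.DataFrame(rows),
                          chrom_lengths=lengths)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort (seed 1) with its truth set."""
    return simulate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def default_truth(default_cohort):
    return default_cohort[1]
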