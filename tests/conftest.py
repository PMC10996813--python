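import numpy as np
import pandas as pd
import pytest

from alclomics import io_formats as io
from alclomics import synthetic_data as syn


SMALL_SPEC = dict(
    n_diagnosis=24, n_relapse=4, n_genes=800, n_probes=1200,
    n_immune_genes=60, n_proliferation_genes=60, n_relapse_genes=20,
    n_hyper_probes=80, n_marker_tracking_probes=20, n_eventual_relapsers=4,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by fast tests."""
    return syn.simulate_cohort(syn.CohortSpec(seed=42, **SMALL_SPEC))


@pytest.fixture
def beta_matrix():
    rng = np.random.default_rng(0)
    b = rng.uniform(0.02, 0.98, size=(10, 6))
    return io.OmicsMatrix(
        pd.DataFrame(b, index=[f"cp{i}" for i in range(10)],
                     columns=[f"S{i}" for i in range(6)]), "beta")


@pytest.fixture
def toy_manifest():
    rows = []
    for i in range(10):
        chrom = "chrX" if i < 2 else "chr1"
        vaf = 0.2 if i in (2, 3) else (0.01 if i == 4 else 0.0)
        rows.append((f"cp{i}", chrom, 1000 + i, f"G{i}", "gene_body", vaf))
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "position", "gene",
                                     "region_class", "snp_vaf"]).set_index("probe_id")
    return io.ProbeManifest(df)
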