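import numpy as np
import pandas as pd
import pytest

from condfdr.sumstats import AlignedPanel, from_frame
from condfdr.simulate import SimConfig, simulate_panel


@pytest.fixture
def toy_panel():
    """Four-SNP panel with hand-countable conditional ECDFs."""
    snps = pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3", "rs4"],
            "chrom": ["1", "1", "2", "2"],
            "pos": [100, 200, 100, 200],
        }
    )
    return AlignedPanel(
        snps=snps,
        p_primary=np.array([0.01, 0.2, 0.5, 0.9]),
        p_cond={"t2": np.array([0.001, 0.5, 0.02, 0.9])},
        primary_name="t1",
    )


@pytest.fixture(scope="session")
def sim_panel_tables():
    """One seeded mid-size two-trait simulation shared across tests."""
    cfg = SimConfig(n_snps=50_000, seed=11)
    t1, t2, ld, truth = simulate_panel(cfg)
    return from_frame(t1), from_frame(t2), ld, truth


def write_sumstats(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path
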