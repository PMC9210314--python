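import numpy as np
import pytest

from tritigs import qc
from tritigs.simulate import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=42, n_accessions=150, n_markers=800, n_subpops=5,
        n_envs=2, field_rows=20, field_cols=15, n_reps=2,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    """Desk-scale panel: genotypes, map, truth, trials."""
    return simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def qc_panel(small_panel):
    """QC'd and imputed panel with its restricted marker map."""
    geno, mm, truth, trials = small_panel
    g2, report = qc.run_qc(geno)
    mm2 = mm[mm["marker_id"].isin(set(g2.marker_ids))].reset_index(drop=True)
    return g2, mm2, truth, trials
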