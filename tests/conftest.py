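"""Shared fixtures: one full-scale synthetic study processed end to end.

The heavy pipeline run (20,000 probes, three PDX models, four
generations, treatment and in-vitro arms) is computed once per session
and reused by the tests that interrogate different stages of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pdxmeth.pipeline import run_simulated_pipeline
from pdxmeth.synthetic import SimulationDesign, simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

PIPELINE_SEED = 11  # fixed study seed for the shared end-to-end run


@pytest.fixture(scope="session")
def study_run() -> dict:
    """Full-scale pipeline run under the default study conditions."""
    sim, result = run_simulated_pipeline(SimulationDesign(n_probes=20_000, seed=PIPELINE_SEED))
    return {
        "sim": sim,
        "design": sim.design,
        "result": result,
        "report": result.report,
        "beta_raw": result.beta_raw,
        "beta_norm": result.beta_norm,
        "m_adj": result.m_adj,
        "universe": result.universe,
        "gen_results": result.gen_results,
        "res_dac": result.res_dac,
        "res_cis": result.res_cisplatin,
        "res_invitro": result.res_invitro,
        "stable": result.stable,
        "invivo": result.invivo_dac,
        "invitro": result.invitro_dac,
    }


@pytest.fixture(scope="session")
def small_sim():
    """Small simulation for cheap structural tests."""
    return simulate_dataset(SimulationDesign(n_probes=2_000, seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_manifest_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": ["cg01", "cg02", "cg03"],
            "chromosome": ["1", "2", "X"],
            "position": [100, 250, 50],
            "design_type": ["I", "II", "II"],
            "compartment": ["TSS200", "Body", "Intergenic"],
            "cgi_relation": ["Island", "OpenSea", "Shore"],
            "hil_class": ["HC", "LC", "IC"],
            "genes": ["CSK;ULK3", "TP53", ""],
            "snp_flag": [False, True, False],
            "crosshyb_flag": [False, False, True],
        }
    )
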