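import numpy as np
import pandas as pd
import pytest

import lipidcbm as L


@pytest.fixture(scope="session")
def design():
    return L.default_design()


@pytest.fixture(scope="session")
def pregnancy_design(design):
    """Only the six groups of the virgin-vs-pregnant replicate set."""
    gids = {1, 2, 3, 5, 6, 8}
    return L.StudyDesign(
        groups=[g for g in design.groups if g.group_id in gids],
        comparisons=[c for c in design.comparisons
                     if c.replicate_set_id == "pregnancy"])


@pytest.fixture(scope="session")
def fixture_cohort(design):
    """Small 60-variable cohort (12 decoys) with its truth ledger."""
    cfg = L.fixture_config(seed=0)
    lib = L.build_library(cfg)
    truth = L.make_truth(lib, cfg)
    tables, peaks, truth = L.simulate_cohort(design, truth, cfg)
    return {"config": cfg, "library": lib, "truth": truth,
            "tables": tables, "peaks": peaks}


@pytest.fixture(scope="session")
def fixture_qc(fixture_cohort):
    """QC stage run on the fixture cohort, per mode."""
    out = {}
    for mode, table in fixture_cohort["tables"].items():
        retained, report = L.run_qc_pipeline(
            fixture_cohort["peaks"][mode], table.library, table.samples,
            table.noise_level, mode)
        out[mode] = {"retained": retained, "report": report}
    return out


@pytest.fixture(scope="session")
def fixture_bundle():
    """Full pipeline bundle on the fixture preset."""
    return L.make_fixtures(seed=0)


def tiny_library(entries, mode="positive"):
    """entries: list of (class, carbons, double_bonds, mz)."""
    return [
        L.LipidVariable(f"{mode[:3]}_{cls}_{c}_{db}", cls, c, db, mode, mz)
        for cls, c, db, mz in entries
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
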