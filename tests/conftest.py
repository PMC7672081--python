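import numpy as np
import pandas as pd
import pytest

import scscreen as s


@pytest.fixture(scope="session")
def planted_panel():
    """Small panel with one planted (drug, pair) effect and forced group sizes."""
    cfg = s.PanelConfig(
        seed=11, n_genes=12, n_cell_lines=80, mutation_rate=0.12,
        planted_pairs=(s.PlantedPair("drug01", "G0001", "G0002", -2.0,
                                     n_mm=10, n_mw=15, n_wm=15),),
        drugs=(s.DrugSpec("drug01", baseline_sd=0.5),
               s.DrugSpec("drug02", baseline_sd=0.5)),
        missing_fraction=0.0,
    )
    return s.generate_panel(cfg)


@pytest.fixture(scope="session")
def planted_matrix(planted_panel):
    return s.build_damaging_matrix(
        planted_panel.variants, planted_panel.copy_number,
        s.FilterConfig(min_mutated_lines=5),
        planted_panel.cell_line_meta["cell_line"])


@pytest.fixture(scope="session")
def planted_dose(planted_panel):
    return s.average_replicates(planted_panel.dose_response)


@pytest.fixture
def toy_variants():
    return pd.DataFrame({
        "gene": ["TP53", "TP53", "KRAS"],
        "cell_line": ["L1", "L2", "L1"],
        "classification": ["nonsense", "missense", "missense"],
        "sift": [np.nan, 0.01, 0.2],
        "polyphen": [np.nan, 0.95, 0.99],
    })


@pytest.fixture
def toy_cohort():
    """Deterministic 8-patient cohort table for survival-invariant checks."""
    return pd.DataFrame({
        "patient": [f"P{i}" for i in range(8)],
        "group": ["MMC"] * 4 + ["WWC"] * 4,
        "age": [60] * 8,
        "sex": ["male", "female"] * 4,
        "cancer_type": ["SKCM"] * 8,
        "cancer_type_flag": [1] * 8,
        "os_months": [2.0, 4.0, 6.0, 8.0, 2.0, 4.0, 6.0, 8.0],
        "event": [True] * 8,
    })
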