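import numpy as np
import pandas as pd
import pytest

import scscreen as s
from scscreen.simulate import DEFAULT_PARTNERS, _apportion


def test_same_seed_identical_outputs():
    cfg = dict(seed=9, n_genes=8, n_cell_lines=40,
               planted_pairs=(s.PlantedPair("drug01", "G0001", "G0002", -1.0),))
    a = s.generate_panel(s.PanelConfig(**cfg))
    b = s.generate_panel(s.PanelConfig(**cfg))
    for x, y in zip(a[:5], b[:5]):
        pd.testing.assert_frame_equal(x, y)
    pd.testing.assert_frame_equal(a.truth["status"], b.truth["status"])


def test_different_seed_differs():
    a = s.generate_panel(s.PanelConfig(seed=1, n_genes=8, n_cell_lines=40))
    b = s.generate_panel(s.PanelConfig(seed=2, n_genes=8, n_cell_lines=40))
    assert not a.truth["status"].equals(b.truth["status"])


def test_generated_files_pass_validation_roundtrip(tmp_path, planted_panel):
    paths = s.write_panel(planted_panel, tmp_path)
    tables = s.read_tables({
        "coding_variants": paths["coding_variants"],
        "copy_number": paths["copy_number"],
        "dose_response": paths["dose_response"],
        "drug_meta": paths["drug_meta"],
        "cell_line_meta": paths["cell_line_meta"],
    })
    assert len(tables["cell_line_meta"]) == 80
    assert tables["drug_meta"]["commercial"].all()


def test_filter_reproduces_truth_matrix(planted_panel):
    """Damaging calls recovered from raw files equal the planted truth."""
    m = s.build_damaging_matrix(planted_panel.variants, planted_panel.copy_number,
                                s.FilterConfig(min_mutated_lines=1),
                                planted_panel.cell_line_meta["cell_line"])
    truth = planted_panel.truth["status"]
    recovered = m.status.reindex(index=truth.index, columns=truth.columns,
                                 fill_value=0)
    np.testing.assert_array_equal(recovered.to_numpy(), truth.to_numpy())


def test_forced_group_sizes_exact(planted_panel):
    truth = planted_panel.truth["status"]
    a = truth.loc["G0001"].astype(bool)
    b = truth.loc["G0002"].astype(bool)
    assert int((a & b).sum()) == 10
    assert int((a & ~b).sum()) == 15
    assert int((~a & b).sum()) == 15


def test_planted_delta_applied_to_mm_lines_only(planted_panel):
    manifest = planted_panel.truth["planted_pairs"].iloc[0]
    assert manifest["delta"] == -2.0
    mm_lines = set(manifest["mm_lines"].split(";"))
    dose = s.average_replicates(planted_panel.dose_response)
    d1 = dose[dose["drug"] == "drug01"].set_index("cell_line")["ln_ic50"]
    mm = d1.reindex([l for l in mm_lines if l in d1.index]).dropna()
    rest = d1.drop(index=mm.index)
    assert mm.mean() < rest.mean() - 1.0


def test_replicates_average_to_single_site_value(planted_panel):
    dose = planted_panel.dose_response
    reps = dose.groupby(["drug", "cell_line"]).filter(lambda g: len(g) == 2)
    assert len(reps) > 0  # replicate_fraction > 0 produced two-site rows
    merged = s.average_replicates(dose)
    assert merged.groupby(["drug", "cell_line"]).size().max() == 1


def test_unknown_planted_gene_rejected():
    with pytest.raises(ValueError, match="unknown gene"):
        s.PanelConfig(seed=1, n_genes=5,
                      planted_pairs=(s.PlantedPair("drug01", "G0001", "NOPE", -1.0),))
    with pytest.raises(ValueError, match="unknown drug"):
        s.PanelConfig(seed=1, n_genes=5,
                      planted_pairs=(s.PlantedPair("nope", "G0001", "G0002", -1.0),))


def test_null_panel_yields_no_candidates():
    cfg = s.PanelConfig(seed=21, n_genes=15, n_cell_lines=150, mutation_rate=0.3)
    panel = s.generate_panel(cfg)
    m = s.build_damaging_matrix(panel.variants, panel.copy_number,
                                s.FilterConfig(min_mutated_lines=10),
                                panel.cell_line_meta["cell_line"])
    dose = s.average_replicates(panel.dose_response)
    rec = s.screen_drug("drug01", m, dose)
    assert rec["candidate"].sum() == 0


def test_co_occurrence_knob_inflates_mm_fraction():
    base = s.PanelConfig(seed=5, n_genes=4, n_cell_lines=3000, mutation_rate=0.2)
    linked = s.PanelConfig(seed=5, n_genes=4, n_cell_lines=3000, mutation_rate=0.2,
                           co_occurring=(("G0001", "G0002", 8.0),))
    t0 = s.generate_panel(base).truth["status"]
    t1 = s.generate_panel(linked).truth["status"]
    mm0 = (t0.loc["G0001"] & t0.loc["G0002"]).mean()
    mm1 = (t1.loc["G0001"] & t1.loc["G0002"]).mean()
    assert mm1 > mm0 * 1.5
    # marginals approximately preserved
    assert abs(t1.loc["G0001"].mean() - 0.2) < 0.03


def test_apportionment_is_exact():
    assert _apportion(65, (30 / 65, 22 / 65, 2 / 65, 11 / 65)) == [30, 22, 2, 11]
    assert sum(_apportion(100, (1 / 3, 1 / 3, 1 / 3, 0))) == 100


def test_cohort_determinism_and_censoring_rate():
    cfg = s.CohortConfig(seed=4, n_patients=4000)
    a = s.generate_cohort(cfg)
    b = s.generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.clinical, b.clinical)
    observed = a.clinical["event"].mean()
    assert observed == pytest.approx(0.8, abs=0.03)  # 20% censoring in expectation


def test_cohort_null_hazard_logrank_uniformity():
    """With all hazard ratios 1 the MMC-vs-WWC log-rank P is not small."""
    pvals = []
    for seed in range(20):
        cfg = s.CohortConfig(seed=seed, n_patients=200,
                             proportions=(0.5, 0.0, 0.0, 0.5),
                             group_hrs={"WWC": 1.0, "WMC": 1.0,
                                        "MWC": 1.0, "MMC": 1.0})
        data = s.generate_cohort(cfg)
        cohort = s.classify_patients(data.maf, data.clinical, "BRAF",
                                     DEFAULT_PARTNERS)
        pvals.append(s.km_logrank(cohort, "MMC", "WWC").logrank_p)
    # under the null roughly uniform: not concentrated near zero
    assert np.mean(np.asarray(pvals) < 0.05) <= 0.25
    assert np.median(pvals) > 0.15
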