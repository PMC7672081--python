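import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import scscreen as s


# ---------------------------------------------------------------- oracles

def bh_stepup_oracle(p):
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) m/j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pooled_t_p(a, b):
    """Closed-form pooled-variance two-sample t, two-sided tail."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


def brute_force_screen(truth_status, dose, drug, cfg):
    """Straightforward re-screen from the truth mutation matrix."""
    vals = dose[dose["drug"] == drug].set_index("cell_line")["ln_ic50"]
    lines = [l for l in vals.index if l in truth_status.columns]
    rows = []
    for ga, gb in itertools.combinations(sorted(truth_status.index), 2):
        a = truth_status.loc[ga, lines].astype(bool)
        b = truth_status.loc[gb, lines].astype(bool)
        groups = {"WW": vals[lines][(~a & ~b).to_numpy()],
                  "WM": vals[lines][(~a & b).to_numpy()],
                  "MW": vals[lines][(a & ~b).to_numpy()],
                  "MM": vals[lines][(a & b).to_numpy()]}
        ok = all(len(v) >= cfg.min_group_size for v in groups.values())
        nonmm = np.concatenate([groups["WW"], groups["WM"], groups["MW"]])
        row = dict(gene_a=ga, gene_b=gb, passed_size=ok, model_p=np.nan,
                   direction=False, mm_ww=False)
        if ok:
            row["model_p"] = pooled_t_p(groups["MM"], nonmm)
            row["direction"] = groups["MM"].mean() < nonmm.mean()
            row["mm_ww"] = groups["MM"].max() < np.median(groups["WW"])
        rows.append(row)
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    tested = df["passed_size"]
    df.loc[tested, "q"] = bh_stepup_oracle(df.loc[tested, "model_p"].to_numpy())
    df["candidate"] = (tested & df["direction"] & df["mm_ww"]
                       & (df["q"] < cfg.q_threshold))
    return df


# ------------------------------------------------------------- replicates

def test_average_replicates_arithmetic_mean():
    rec = pd.DataFrame({
        "drug": ["d", "d", "d"], "cell_line": ["L1", "L2", "L2"],
        "ln_ic50": [2.3, 1.0, 3.0], "source": ["s1", "s1", "s2"],
    })
    out = s.average_replicates(rec).set_index("cell_line")["ln_ic50"]
    assert out["L1"] == 2.3
    assert out["L2"] == 2.0


def test_three_replicates_averaged_with_warning(caplog):
    rec = pd.DataFrame({
        "drug": ["d"] * 3, "cell_line": ["L1"] * 3,
        "ln_ic50": [1.0, 2.0, 3.0], "source": ["a", "b", "c"],
    })
    with caplog.at_level("WARNING", logger="scscreen"):
        out = s.average_replicates(rec)
    assert out["ln_ic50"].iloc[0] == 2.0
    assert any("replicates" in r.message for r in caplog.records)


# ---------------------------------------------------------------- groups

def test_assign_groups_labels_and_exclusion(planted_panel, planted_matrix, planted_dose):
    grouping = s.assign_groups(("G0001", "G0002"), planted_matrix,
                               planted_dose, "drug01")
    truth = planted_panel.truth["status"]
    measured = set(planted_dose.loc[planted_dose["drug"] == "drug01", "cell_line"])
    # only measured lines are labelled
    assert set(grouping.labels.index) <= measured
    for line, label in grouping.labels.items():
        a, b = truth.loc["G0001", line], truth.loc["G0002", line]
        assert label == "WM"[a] + "WM"[b]


# --------------------------------------------------------------- model P

def test_model_p_identical_samples_is_one(planted_matrix, planted_dose):
    vals = pd.DataFrame({
        "drug": "d", "cell_line": [f"L{i}" for i in range(6)],
        "ln_ic50": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
    })
    labels = pd.Series(["MM"] * 3 + ["WW"] * 3, index=vals["cell_line"])
    g = s.PairGrouping("d", "A", "B", labels)
    p, m_mm, m_non = s.model_p(g, vals)
    assert p == pytest.approx(1.0)
    assert m_mm == m_non == 2.0


def test_model_p_matches_hand_computed_pooled_t():
    vals = pd.DataFrame({
        "drug": "d", "cell_line": [f"L{i}" for i in range(8)],
        "ln_ic50": [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
    })
    labels = pd.Series(["MM"] * 4 + ["WW", "WM", "MW", "WW"],
                       index=vals["cell_line"])
    p, _, _ = s.model_p(s.PairGrouping("d", "A", "B", labels), vals)
    # frozen closed-form pooled-variance value: t = -4.898979, df = 6
    assert p == pytest.approx(0.0027136820350938, rel=1e-10)
    assert p == pytest.approx(pooled_t_p([0, 0, 1, 1], [2, 2, 3, 3]), rel=1e-12)


def test_model_p_degenerate_when_all_values_identical():
    vals = pd.DataFrame({"drug": "d", "cell_line": [f"L{i}" for i in range(6)],
                         "ln_ic50": [5.0] * 6})
    labels = pd.Series(["MM"] * 3 + ["WW"] * 3, index=vals["cell_line"])
    with pytest.raises(s.DegenerateTestError):
        s.model_p(s.PairGrouping("d", "A", "B", labels), vals)


# --------------------------------------------------------------------- BH

def test_bh_known_stepup():
    np.testing.assert_allclose(s.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(s.bh_adjust([0.2]), [0.2])


@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=1, max_size=6))
@settings(max_examples=200, deadline=None)
def test_bh_equals_stepup_oracle(p):
    np.testing.assert_allclose(s.bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)


def test_bh_all_permutations_of_six():
    base = [0.001, 0.02, 0.04, 0.2, 0.6, 0.9]
    for perm in itertools.permutations(base):
        np.testing.assert_allclose(s.bh_adjust(list(perm)),
                                   bh_stepup_oracle(list(perm)), atol=1e-12)


# ------------------------------------------------------------ full screen

def test_screen_recovers_unique_planted_pair(planted_matrix, planted_dose):
    rec = s.screen_drug("drug01", planted_matrix, planted_dose)
    cand = rec[rec["candidate"]]
    assert len(cand) == 1
    assert tuple(cand.iloc[0][["gene_a", "gene_b"]]) == ("G0001", "G0002")
    assert cand.iloc[0]["n_mm"] == 10
    assert cand.iloc[0]["mean_mm"] < cand.iloc[0]["mean_nonmm"]


def test_small_mm_group_excluded_from_bh_batch(planted_matrix, planted_dose):
    cfg = s.ScreenConfig(min_group_size=11)  # planted MM group has 10 lines
    rec = s.screen_drug("drug01", planted_matrix, planted_dose, cfg)
    row = rec[(rec["gene_a"] == "G0001") & (rec["gene_b"] == "G0002")].iloc[0]
    assert not row["passed_size"] and np.isnan(row["q"]) and not row["candidate"]


def test_screen_matches_brute_force_oracle(planted_panel):
    """Pair-for-pair equivalence with an independent recomputation."""
    cfg = s.ScreenConfig()
    panel = planted_panel
    matrix = s.build_damaging_matrix(panel.variants, panel.copy_number,
                                     s.FilterConfig(min_mutated_lines=1),
                                     panel.cell_line_meta["cell_line"])
    dose = s.average_replicates(panel.dose_response)
    for drug in ("drug01", "drug02"):
        mine = s.screen_drug(drug, matrix, dose, cfg).set_index(["gene_a", "gene_b"])
        # oracle recomputes from the truth matrix, which the generator
        # guarantees the damaging filter reproduces
        ref = brute_force_screen(panel.truth["status"], dose, drug, cfg)
        ref = ref.set_index(["gene_a", "gene_b"])
        assert set(mine.index) == set(ref.index)
        ref = ref.reindex(mine.index)
        pd.testing.assert_series_equal(mine["candidate"], ref["candidate"],
                                       check_names=False)
        np.testing.assert_allclose(mine["model_p"], ref["model_p"], atol=1e-12)
        np.testing.assert_allclose(mine["q"], ref["q"], atol=1e-12)


def test_screen_invariant_to_cell_line_order(planted_panel, planted_matrix):
    dose = s.average_replicates(planted_panel.dose_response)
    shuffled = dose.sample(frac=1, random_state=3).reset_index(drop=True)
    a = s.screen_drug("drug01", planted_matrix, dose)
    b = s.screen_drug("drug01", planted_matrix, shuffled)
    pd.testing.assert_frame_equal(a, b)


def test_screen_all_commercial_filter_and_summary(planted_matrix, planted_dose):
    drugs = pd.DataFrame({
        "drug": ["drug01", "drug02"], "name": ["a", "b"],
        "target_class": ["kinase inhibitor"] * 2, "commercial": [False, True],
    })
    rec = s.screen_all(planted_matrix, planted_dose, drugs,
                       s.ScreenConfig(commercial_only=True))
    assert set(rec["drug"]) == {"drug02"}  # planted drug01 dropped as non-commercial
    rec_all = s.screen_all(planted_matrix, planted_dose, drugs,
                           s.ScreenConfig(commercial_only=False))
    assert set(rec_all["drug"]) == {"drug01", "drug02"}
    assert rec_all[rec_all["candidate"]]["drug"].tolist() == ["drug01"]


def test_unknown_drug_raises(planted_matrix, planted_dose):
    with pytest.raises(KeyError):
        s.screen_drug("no-such-drug", planted_matrix, planted_dose)
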