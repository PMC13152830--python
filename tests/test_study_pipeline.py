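"""Pipeline-stage tests: descriptives, composition, attrition, reliability,
the LCSM stage, report serialization and the I/O layer."""

import math

import numpy as np
import pandas as pd
import pytest
import yaml
from scipy import stats

from lcskit import io as lio
from lcskit.sem_core import RawDataset, SampleMoments, SpecError
from lcskit.study_pipeline import (
    StudyConfig,
    StudyReport,
    attrition_analysis,
    cronbach_alpha,
    descriptive_table,
    fit_lcsm,
    load_config,
    run_study,
    sample_composition,
)
from lcskit.synthetic_data import (
    apgar_config,
    generate_from_moments,
    generate_item_responses,
    inject_missingness,
    recovery_parameters,
    simulate_lcs,
    table1_fixture,
)

FF = [f"FF_T{t}" for t in range(1, 5)]
EP = [f"EP_T{t}" for t in range(1, 5)]


# ---------------------------------------------------------------------------
# descriptives

def test_exact_mode_descriptives_reproduce_published_table(table1):
    data = generate_from_moments(table1, 468, seed=13, mode="exact")
    table = descriptive_table(data).round(2)
    sds = np.sqrt(np.diag(table1.covariance_matrix))
    R_target = table1.covariance_matrix / np.outer(sds, sds)
    assert table.means == [round(m, 2) for m in table1.mean_vector]
    assert table.sds == [round(s, 2) for s in sds]
    R = np.array(table.correlations)
    assert np.array_equal(np.round(R, 2), np.round(R_target, 2))


def test_descriptive_stars_match_published_levels(table1):
    data = generate_from_moments(table1, 468, seed=13, mode="exact")
    table = descriptive_table(data)
    idx = {v: i for i, v in enumerate(table.variable_names)}
    # r(FF_T4, EP_T1) = -0.15 is the table's single ** entry; the rest ***
    assert table.stars[idx["FF_T4"]][idx["EP_T1"]] == "**"
    assert table.stars[idx["FF_T1"]][idx["EP_T1"]] == "***"


def test_self_correlation_is_one_with_no_star(table1):
    data = generate_from_moments(table1, 100, seed=1)
    table = descriptive_table(data)
    assert table.correlations[0][0] == 1.0
    assert table.stars[0][0] == ""


def test_correlation_p_values_match_reference_implementation():
    rng = np.random.default_rng(5)
    x = rng.normal(size=80)
    y = 0.4 * x + rng.normal(size=80)
    data = RawDataset(frame=pd.DataFrame({"x": x, "y": y}), variable_names=["x", "y"])
    table = descriptive_table(data)
    r_ref, p_ref = stats.pearsonr(x, y)
    assert table.correlations[0][1] == pytest.approx(r_ref, abs=1e-12)
    assert table.p_values[0][1] == pytest.approx(p_ref, rel=1e-9)


def test_zero_variance_column_reported_undefined():
    frame = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
    table = descriptive_table(RawDataset(frame=frame, variable_names=["a", "b"]))
    assert math.isnan(table.correlations[0][1])


def test_too_few_complete_pairs_errors():
    frame = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan],
                          "b": [np.nan, 1.0, 2.0, 3.0]})
    with pytest.raises(SpecError):
        descriptive_table(RawDataset(frame=frame, variable_names=["a", "b"]))


# ---------------------------------------------------------------------------
# composition / attrition

def test_sample_composition_published_arithmetic():
    frame = pd.DataFrame({
        "completer": [True] * 468 + [False] * 130,
        "gender": (["m"] * 174 + ["f"] * 294) + ["m"] * 130,
        "age": [12.0] * 598,
    })
    out = sample_composition(frame)
    assert out["enrolled"] == 598 and out["completers"] == 468
    assert out["retention_pct"] == 78.3
    assert out["gender"]["m"]["pct"] == 37.2
    assert out["gender"]["f"]["pct"] == 62.8


def test_sample_composition_all_completers():
    frame = pd.DataFrame({"completer": [True] * 10, "age": range(10)})
    assert sample_composition(frame)["retention_pct"] == 100.0


def test_attrition_identical_groups_not_flagged():
    base = pd.DataFrame({"score": np.tile([3.0, 4.0, 5.0, 6.0], 10),
                         "cat": np.tile(["a", "b"], 20)})
    frame = pd.concat([base.assign(completer=True), base.assign(completer=False)])
    out = attrition_analysis(frame, "completer", ["score"], ["cat"])
    assert (out["statistic"] == 0).all()
    assert not out["flagged"].any()


def test_attrition_power_for_half_sd_shift():
    flagged = 0
    for r in range(20):
        rng = np.random.default_rng(900 + r)
        frame = pd.DataFrame({
            "score": np.r_[rng.normal(0, 1, 200), rng.normal(0.5, 1, 200)],
            "completer": [True] * 200 + [False] * 200,
        })
        out = attrition_analysis(frame, "completer", ["score"])
        flagged += bool(out["flagged"].iloc[0])
    assert flagged >= 19


def test_attrition_empty_categorical_cell_never_crashes():
    frame = pd.DataFrame({
        "cat": ["a"] * 30 + ["b"] * 5 + ["a"] * 20,
        "completer": [True] * 35 + [False] * 20,
    })
    out = attrition_analysis(frame, "completer", [], ["cat"])
    assert out["p"].between(0, 1).all()


def test_attrition_single_group_errors():
    frame = pd.DataFrame({"x": [1.0, 2.0], "completer": [True, True]})
    with pytest.raises(SpecError):
        attrition_analysis(frame, "completer", ["x"])


# ---------------------------------------------------------------------------
# reliability

def test_cronbach_alpha_closed_form_exchangeable():
    k, rho, n = 6, 0.35, 20_000
    rng = np.random.default_rng(3)
    f = rng.normal(size=n)
    items = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * rng.normal(size=(n, k))
    expected = k * rho / (1 + (k - 1) * rho)
    assert cronbach_alpha(items) == pytest.approx(expected, abs=0.02)


def test_cronbach_alpha_uncorrelated_items_not_clamped():
    rng = np.random.default_rng(4)
    items = rng.normal(size=(400, 2))
    items[:, 1] = -0.3 * items[:, 0] + rng.normal(size=400)  # negative correlation
    assert cronbach_alpha(items) < 0.0


def test_cronbach_alpha_errors():
    with pytest.raises(SpecError):
        cronbach_alpha(np.ones((10, 1)))
    with pytest.raises(SpecError):
        cronbach_alpha(np.ones((10, 3)))


# ---------------------------------------------------------------------------
# LCSM stage and the full study

def test_fit_lcsm_requires_exactly_one_input(table1):
    with pytest.raises(SpecError):
        fit_lcsm()
    with pytest.raises(SpecError):
        fit_lcsm(data=generate_from_moments(table1, 50, seed=0), moments=table1)


def test_run_study_recovers_couplings_from_generative_data(tmp_path):
    params = recovery_parameters()
    data = simulate_lcs(params, 100_000, seed=17)
    lio.write_wide_csv(data, tmp_path / "raw.csv")
    config = StudyConfig(raw_path=str(tmp_path / "raw.csv"), run_invariance=False)
    report = run_study(config)
    assert "lcsm" in report.stages and report.errors == {}
    est = {e["label"]: e["value"] for e in report.stages["lcsm"]["estimates"]}
    true = params.label_values()
    for label in ("gamma_xy", "gamma_yx", "xi_xy", "xi_yx"):
        assert abs(est[label] - true[label]) < 0.02, label


def test_run_study_missing_input_is_config_error(tmp_path):
    config = StudyConfig(raw_path=str(tmp_path / "absent.csv"))
    with pytest.raises(SpecError):
        run_study(config)
    with pytest.raises(SpecError):
        StudyConfig().validate()  # neither input given


def test_report_completeness_and_roundtrip(tmp_path, table1):
    lio.write_moments_csv(table1, tmp_path / "moments.csv")
    config = StudyConfig(moments_path=str(tmp_path / "moments.csv"))
    report = run_study(config)
    lcsm = report.stages["lcsm"]
    assert lcsm["converged"] and lcsm["df"] > 0
    assert len(lcsm["structural_labels_present"]) == 14
    for key in ("cfi", "tli", "rmsea", "srmr"):
        assert key in lcsm
    values = [e["value"] for e in lcsm["estimates"]]
    std = [e["standardized_value"] for e in lcsm["estimates"]]
    assert len(values) == len(std) == 24
    assert set(lcsm["coupling_signs"]) == {"xi_xy", "xi_yx"}
    # serialize / re-parse losslessly
    again = StudyReport.from_json(report.to_json())
    assert again.stages["lcsm"]["df"] == lcsm["df"]
    assert again.warnings == report.warnings


def test_pipeline_determinism(tmp_path):
    data = simulate_lcs(recovery_parameters(), 600, seed=2)
    miss = inject_missingness(data, "MCAR", 0.1, seed=3)
    lio.write_wide_csv(miss, tmp_path / "raw.csv")
    config = StudyConfig(raw_path=str(tmp_path / "raw.csv"),
                         completer_col="completer", run_invariance=False)
    r1 = run_study(config)
    r2 = run_study(config)
    assert r1.to_json() == r2.to_json()


def test_run_study_with_items_reports_alpha_and_invariance(tmp_path):
    data = simulate_lcs(recovery_parameters(), 400, seed=30)
    items = generate_item_responses(apgar_config(), 400, seed=31)
    frame = pd.concat([data.frame, items.frame], axis=1)
    lio.write_wide_csv(RawDataset(frame=frame, variable_names=list(frame.columns)),
                       tmp_path / "raw.csv")
    waves = [[f"ff_w{w}_i{i}" for i in range(1, 6)] for w in range(1, 5)]
    config = StudyConfig(raw_path=str(tmp_path / "raw.csv"),
                         item_constructs={"ff": waves})
    report = run_study(config)
    assert len(report.stages["alpha"]["ff"]) == 4
    inv = report.stages["invariance"]["ff"]
    assert set(inv["decisions"]) == {"metric", "scalar"}
    assert inv["fits"]["configural"]["df"] < inv["fits"]["scalar"]["df"]


# ---------------------------------------------------------------------------
# I/O

def test_moments_csv_roundtrip(tmp_path, table1):
    lio.write_moments_csv(table1, tmp_path / "m.csv")
    back = lio.read_moments_csv(tmp_path / "m.csv")
    assert back.variable_names == table1.variable_names
    assert np.abs(back.mean_vector - table1.mean_vector).max() < 1e-12
    assert np.abs(back.covariance_matrix - table1.covariance_matrix).max() < 1e-10
    assert back.n == table1.n


def test_wide_csv_missing_sentinel(tmp_path):
    (tmp_path / "d.csv").write_text("a,b\n1.0,\n-999,2.0\n3.0,4.0\n")
    data = lio.read_wide_csv(tmp_path / "d.csv", ["a", "b"], missing_sentinel=-999)
    X = data.values()
    assert math.isnan(X[0, 1]) and math.isnan(X[1, 0])
    assert X[2, 0] == 3.0


def test_config_yaml_loading(tmp_path):
    payload = {"moments_path": "m.csv", "seed": 7, "run_invariance": False}
    (tmp_path / "c.yaml").write_text(yaml.safe_dump(payload))
    config = load_config(tmp_path / "c.yaml")
    assert config.seed == 7 and config.run_invariance is False
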