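"""Study driver: grid construction, run records, and the evaluation tables."""

import numpy as np
import pandas as pd
import pytest

from wienerfit import (StudyDesign, bias_rmse, build_grid,
                       cross_method_correlations, descriptive_correlations,
                       export_report, negative_ter_tabulation,
                       problematic_fraction, recovery_correlations,
                       rmse_anova, run_study)


@pytest.fixture(scope="module")
def tiny_design():
    return StudyDesign(a_levels=(1.0, 2.0), z_levels=(0.2, 0.8),
                       ter_levels=(0.1,), v_levels=(0.0, 0.5),
                       n_levels=(50,), datasets_per_cell=2,
                       replications=2, root_seed=3)


@pytest.fixture(scope="module")
def tiny_records(tiny_design):
    return run_study(tiny_design, methods=("ez", "ml-nm"))


def _synthetic_records(estimates_offset=0.0, seed=0):
    """Handmade records with known estimate-truth structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for true_a in (0.5, 1.0, 2.0):
        for true_v in (-1.0, 0.0, 1.0):
            for ds in range(4):
                rows.append({
                    "true_a": true_a, "true_z": 0.5, "true_ter": 0.3,
                    "true_v": true_v, "n": 100, "dataset": ds, "rep": 0,
                    "method": "toy", "seed": 0, "problematic": False,
                    "p_up": 0.5, "m_rt": 0.6, "m_up": 0.6, "m_lo": 0.6,
                    "v_rt": 0.02, "v_up": 0.02, "v_lo": 0.02, "min_rt": 0.35,
                    "est_a": true_a + estimates_offset,
                    "est_z": 0.5, "est_ter": 0.3,
                    "est_v": true_v + estimates_offset,
                    "converged": True, "objective": 0.0, "iterations": 1,
                })
    return pd.DataFrame(rows)


class TestDesignAndRecords:
    def test_default_grid_has_540_cells_and_8100_runs(self):
        design = StudyDesign()
        assert design.n_cells == 540
        assert len(build_grid(design)) == 540
        assert design.runs_per_method == 8100

    def test_singleton_levels_give_one_cell(self):
        d = StudyDesign(a_levels=(1,), z_levels=(0.5,), ter_levels=(0.3,),
                        v_levels=(0.5,), n_levels=(50,))
        assert len(build_grid(d)) == 1

    def test_reduced_design_gives_540_records(self):
        assert StudyDesign().reduced().runs_per_method == 540

    def test_record_count(self, tiny_design, tiny_records):
        per_method = tiny_design.runs_per_method
        assert (tiny_records["method"] == "ez").sum() == per_method
        assert (tiny_records["method"] == "ml-nm").sum() == per_method

    def test_ez_identical_across_replications(self, tiny_records):
        ez = tiny_records[tiny_records["method"] == "ez"]
        spread = (ez.groupby(["true_a", "true_z", "true_v", "dataset"])
                  ["est_a"].nunique())
        assert (spread == 1).all()

    def test_study_reproducible(self, tiny_design, tiny_records):
        again = run_study(tiny_design, methods=("ez", "ml-nm"))
        pd.testing.assert_frame_equal(tiny_records, again)


class TestBiasRmse:
    def test_perfect_estimates_zero_bias_rmse(self):
        table = bias_rmse(_synthetic_records(0.0))
        assert np.allclose(table["bias"], 0.0)
        assert np.allclose(table["rmse"], 0.0)

    def test_constant_offset(self):
        table = bias_rmse(_synthetic_records(0.1),
                          group_by=("parameter", "method", "n"))
        sub = table[table["parameter"] == "a"]
        assert sub["bias"].iloc[0] == pytest.approx(0.1)
        assert sub["rmse"].iloc[0] == pytest.approx(0.1)

    def test_hand_computed_four_records(self):
        rec = _synthetic_records(0.0).iloc[:4].copy()
        rec["est_a"] = [0.6, 0.4, 0.7, 0.3]  # truth 0.5
        t = bias_rmse(rec, group_by=("parameter", "method"))
        row = t[t["parameter"] == "a"].iloc[0]
        assert row["bias"] == pytest.approx(0.0)
        assert row["rmse"] == pytest.approx(np.sqrt(np.mean([0.01, 0.01, 0.04, 0.04])))

    def test_rmse_at_least_abs_bias(self, tiny_records):
        table = bias_rmse(tiny_records)
        assert (table["rmse"] >= table["bias"].abs() - 1e-12).all()


class TestCorrelations:
    def test_perfect_estimation_r_one(self):
        t = recovery_correlations(_synthetic_records(0.0))
        sub = t[(t["parameter"] == "a") & (t["n"] == "all")]
        assert sub["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_estimates_r_near_zero(self):
        rec = _synthetic_records(0.0, seed=1)
        rng = np.random.default_rng(2)
        rec["est_a"] = rng.normal(1, 0.3, len(rec))
        t = recovery_correlations(rec)
        r = t[(t["parameter"] == "a") & (t["n"] == "all")]["r"].iloc[0]
        assert abs(r) < 0.4

    def test_cross_method_diagonal_and_ez_z_unavailable(self, tiny_records):
        cm = cross_method_correlations(tiny_records)
        assert cm.loc["ez:a", "ez:a"] == pytest.approx(1.0)
        # EZ fixes z, so its column is flagged unavailable (all NaN)
        assert "ez:z" in cm.columns
        assert cm["ez:z"].isna().all()
        assert np.isfinite(cm.loc["ml-nm:z", "ml-nm:z"])

    def test_identical_methods_correlate_perfectly(self):
        rec = pd.concat([_synthetic_records(0.0), _synthetic_records(0.0)])
        rec = rec.reset_index(drop=True)
        rec.loc[rec.index >= len(rec) // 2, "method"] = "toy2"
        cm = cross_method_correlations(rec)
        assert cm.loc["toy:a", "toy2:a"] == pytest.approx(1.0)

    def test_descriptive_z_truth_tracks_p_up(self, tiny_records):
        t = descriptive_correlations(tiny_records)
        row = t[(t["parameter"] == "z_rel") & (t["source"] == "true")
                & (t["stat"] == "p_up")]
        assert row["r"].iloc[0] > 0.5


class TestNegativeTer:
    def test_no_negatives_gives_zero_table(self):
        t = negative_ter_tabulation(_synthetic_records(0.0).assign(method="ez"))
        assert (t["freq"] == 0).all()
        assert t.attrs["total_negative"] == 0

    def test_percentages_sum_to_hundred_per_block(self):
        rec = _synthetic_records(0.0).assign(method="ez")
        rec.loc[rec.index[:5], "est_ter"] = -0.1
        t = negative_ter_tabulation(rec)
        sums = t.groupby("parameter")["pct"].sum()
        assert np.allclose(sums, 100.0)


class TestProblematicFraction:
    def test_deterministic_under_seed(self):
        f1 = problematic_fraction(n_rep=3, seed=5)
        f2 = problematic_fraction(n_rep=3, seed=5)
        assert f1 == f2

    def test_grows_with_extreme_drift_levels(self):
        base = problematic_fraction(n_rep=10, seed=1)
        ext2 = problematic_fraction(
            n_rep=10, drift_levels=(-2, -1, -0.5, 0, 0.5, 1, 2), seed=1)
        ext3 = problematic_fraction(
            n_rep=10, drift_levels=(-3, -2, -1, -0.5, 0, 0.5, 1, 2, 3), seed=1)
        assert base < ext2 < ext3


class TestRmseAnova:
    def test_pure_method_effect_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for method, shift in (("m1", 0.0), ("m2", 0.5)):
            for truth in (0.5, 1.0, 1.5, 2.0):
                for n in (50, 100, 400):
                    for _ in range(3):
                        rows.append({"parameter": "a", "method": method,
                                     "truth": truth, "n": n,
                                     "rmse": 0.2 + shift + rng.normal(0, 0.01)})
        table = rmse_anova(pd.DataFrame(rows), "a")
        pvals = table["PR(>F)"]
        assert pvals["C(method)"] < 0.001
        assert pvals["truth"] > 0.05

    def test_constant_rmse_gives_zero_effect_ss(self):
        rows = [{"parameter": "v", "method": m, "truth": t, "n": n, "rmse": 0.3}
                for m in ("m1", "m2") for t in (0.5, 1.0, 2.0)
                for n in (50, 100, 400)]
        table = rmse_anova(pd.DataFrame(rows), "v")
        effects = [ix for ix in table.index
                   if ix not in ("Intercept", "Residual")]
        assert np.allclose(table.loc[effects, "sum_sq"], 0.0, atol=1e-12)


class TestExport:
    def test_round_trip_and_manifest(self, tmp_path, tiny_records):
        tables = {"records": tiny_records,
                  "bias_rmse": bias_rmse(tiny_records)}
        export_report(tables, tmp_path, manifest={"root_seed": 3})
        back = pd.read_csv(tmp_path / "records.csv")
        assert len(back) == len(tiny_records)
        import json
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["root_seed"] == 3
        assert (tmp_path / "bias_rmse.csv").exists()
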