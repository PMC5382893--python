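import numpy as np
import pytest

from ecofilter.evaluation import auc
from ecofilter.experiments import (
    ExperimentReport,
    catalogue_summary,
    fn_recovery_experiment,
    forbidden_links_experiment,
    imputation_experiment,
    robustness_sweep,
)
from ecofilter.linear_filter import FilterParams, loo_impute_oracle
from ecofilter.matrix_io import ForbiddenMask
from ecofilter.synthetic import SyntheticConfig, generate, make_forbidden_mask

from conftest import make_matrix, random_matrix


def naive_fn_recovery(matrix, params=None):
    """Brute-force recovery AUCs: explicit variants, per-cell fixed-point oracle."""
    p = params or FilterParams()
    values = matrix.values
    neg_mask = values == 0
    per_flip = []
    for i, j in np.argwhere(values > 0):
        variant = matrix.with_values(
            np.where(
                (np.arange(values.shape[0])[:, None] == i)
                & (np.arange(values.shape[1])[None, :] == j),
                0.0,
                values,
            )
        )
        scores = np.array(
            [
                [
                    loo_impute_oracle(variant, r, c, p)
                    for c in range(values.shape[1])
                ]
                for r in range(values.shape[0])
            ]
        )
        per_flip.append(auc([scores[i, j]], scores[neg_mask]))
    return per_flip


class TestImputationExperiment:
    def test_nested_staircase_beats_chance(self, staircase10):
        rep = imputation_experiment(staircase10)
        assert rep.results["auc"] > 0.5
        assert rep.experiment == "imputation" and rep.variant == "raw"
        assert set(rep.results["precision_at_k"]) == {"10", "20", "50", "100"}

    def test_single_positive_cell_is_legal(self):
        m = make_matrix([[1.0, 0.0], [0.0, 0.0]])
        rep = imputation_experiment(m)
        assert 0.0 <= rep.results["auc"] <= 1.0

    def test_all_positive_matrix_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            imputation_experiment(make_matrix(np.ones((3, 3))))

    def test_binarized_variant_recorded(self, rng):
        m = random_matrix(rng, 6, 6, density=0.4, weighted=True)
        rep = imputation_experiment(m, binarize_first=True)
        assert rep.variant == "binarized"
        assert rep.results["auc"] == imputation_experiment(
            m, binarize_first=True
        ).results["auc"]


class TestFnRecovery:
    def test_flip_count_equals_positive_count(self):
        m = make_matrix([[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 0]])
        rep = fn_recovery_experiment(m)
        assert rep.results["n_flips"] == 4
        assert len(rep.results["per_flip_auc"]) == 4

    def test_per_flip_aucs_in_unit_interval(self, rng):
        m = random_matrix(rng, 5, 6, density=0.4, weighted=False)
        rep = fn_recovery_experiment(m)
        assert all(0.0 <= a <= 1.0 for a in rep.results["per_flip_auc"])

    def test_nested_staircase_recovers_above_chance(self, staircase10):
        rep = fn_recovery_experiment(staircase10)
        assert rep.results["recovery_auc"] > 0.5

    def test_matches_naive_oracle_on_small_matrices(self, small_fixture_suite):
        for m in small_fixture_suite:
            if not (m.values > 0).any() or not (m.values == 0).any():
                continue
            rep = fn_recovery_experiment(m)
            naive = naive_fn_recovery(m)
            assert rep.results["per_flip_auc"] == pytest.approx(naive, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            fn_recovery_experiment(make_matrix(np.zeros((3, 3))))


class TestRobustnessSweep:
    def test_same_seed_reproduces_identical_tables(self, staircase10):
        kw = dict(fractions=(0.2, 0.5), n_repeats=3, seed=11)
        a = robustness_sweep(staircase10, **kw)
        b = robustness_sweep(staircase10, **kw)
        assert a.results["table"] == b.results["table"]

    def test_single_removal_reduces_to_flip_definition(self):
        m = generate(SyntheticConfig(10, 10, "nested", 0.1, seed=0))  # 10 positives
        rep = robustness_sweep(m, fractions=(0.1,), n_repeats=1, seed=3)
        rows = [r for r in rep.results["table"] if r["method"] == "filter"]
        assert len(rows) == 1
        assert 0.0 <= rows[0]["auc"] <= 1.0

    def test_fraction_removing_all_positives_rejected(self):
        m = generate(SyntheticConfig(6, 6, "random", 0.1, seed=0))
        with pytest.raises(ValueError):
            robustness_sweep(m, fractions=(0.99,), n_repeats=1, seed=0)

    def test_filter_auc_stays_high_under_heavy_degradation(self):
        m = generate(SyntheticConfig(15, 15, "nested", 0.25, seed=2))
        rep = robustness_sweep(m, fractions=(0.1, 0.5, 0.9), n_repeats=20, seed=7)
        means = {
            (r["fraction"], r["method"]): r["mean"]
            for r in rep.results["summary"]
        }
        assert means[(0.9, "filter")] > 0.5


class TestForbiddenLinks:
    def test_mask_covering_all_negatives(self, staircase10):
        mask = ForbiddenMask(staircase10.values == 0)
        rep = forbidden_links_experiment(staircase10, mask)
        r = rep.results
        assert r["auc_pos_vs_forbidden"] == r["auc_pos_vs_all_neg"]
        assert r["auc_pos_vs_potential_fn"] is None

    def test_empty_mask_warns_and_reports_absent(self, staircase10):
        mask = ForbiddenMask(np.zeros(staircase10.shape, dtype=bool))
        with pytest.warns(UserWarning, match="empty forbidden"):
            rep = forbidden_links_experiment(staircase10, mask)
        r = rep.results
        assert r["auc_pos_vs_forbidden"] is None
        assert r["auc_pos_vs_potential_fn"] == r["auc_pos_vs_all_neg"]

    def test_low_degree_forbidden_cells_are_easier_to_separate(self):
        m = generate(SyntheticConfig(12, 12, "nested", 0.25, seed=1))
        mask = make_forbidden_mask(m, 0.4, placement="lowest_degree")
        rep = forbidden_links_experiment(m, mask)
        r = rep.results
        assert r["auc_pos_vs_forbidden"] >= r["auc_pos_vs_potential_fn"]

    def test_histograms_count_every_cell(self, staircase10):
        mask = make_forbidden_mask(staircase10, 0.5, placement="lowest_degree")
        rep = forbidden_links_experiment(staircase10, mask)
        h = rep.results["histograms"]
        total = sum(np.sum(counts) for counts in h.values())
        assert total == staircase10.values.size


class TestCatalogueSummary:
    def _report(self, auc_value, dens, n_pos):
        return ExperimentReport(
            experiment="imputation",
            dataset="x",
            params={},
            variant="raw",
            seed=None,
            results={"auc": auc_value, "density": dens, "n_pos": n_pos},
        )

    def test_single_report_single_stratum(self):
        df = catalogue_summary([self._report(0.8, 0.05, 30)])
        assert df.iloc[0, 0] == 0.8
        assert df.notna().sum().sum() == 1

    def test_same_stratum_averages(self):
        df = catalogue_summary(
            [self._report(0.8, 0.05, 30), self._report(0.6, 0.09, 40)]
        )
        assert df.iloc[0, 0] == pytest.approx(0.7)

    def test_half_open_bin_edges(self):
        # density exactly 0.1 belongs to [0.1, 0.25); count 50 to [50, 100)
        df = catalogue_summary([self._report(0.9, 0.1, 50)])
        assert df.loc["[0.1, 0.25)", "[50, 100)"] == 0.9

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            catalogue_summary([])


class TestReportSerialization:
    def test_json_round_trip_and_tsv(self, tmp_path, staircase10):
        import json

        rep = imputation_experiment(staircase10)
        path = tmp_path / "rep.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["results"]["auc"] == rep.results["auc"]
        assert "timestamp" in loaded["provenance"]
        rep.to_tsv(tmp_path / "rep.tsv")
        assert (tmp_path / "rep.tsv").read_text().startswith("key\tvalue")
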