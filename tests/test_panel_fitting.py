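"""Gene screening, single-factor fitting and greedy panel construction."""

import numpy as np
import pytest

import maxlogit as ml
from maxlogit.errors import FitError, ValidationError
from maxlogit.panel_fitting import best_threshold_accuracy


def two_class_matrix(case_values, control_values, gene_ids=None, scale="log2"):
    """Build a matrix + labels from per-gene lists of case/control values."""
    case_values = np.atleast_2d(np.asarray(case_values, dtype=float))
    control_values = np.atleast_2d(np.asarray(control_values, dtype=float))
    n_case, n_ctrl = case_values.shape[1], control_values.shape[1]
    gene_ids = tuple(gene_ids or (f"G{i}" for i in range(case_values.shape[0])))
    sample_ids = tuple(
        [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)]
    )
    matrix = ml.ExpressionMatrix(
        gene_ids, sample_ids, np.hstack([case_values, control_values]), scale
    )
    labels = ml.SampleLabels(
        sample_ids, tuple(["case"] * n_case + ["control"] * n_ctrl), "case", "control"
    )
    return matrix, labels


class TestBestThresholdOracle:
    def test_separable_scores_one(self):
        x = np.array([1.0, 2.0, 10.0, 12.0])
        y = np.array([False, False, True, True])
        assert best_threshold_accuracy(x, y) == 1.0

    def test_reversed_direction_found(self):
        x = np.array([10.0, 12.0, 1.0, 2.0])
        y = np.array([False, False, True, True])
        assert best_threshold_accuracy(x, y) == 1.0

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            x = np.round(rng.normal(size=n), 1)  # ties on purpose
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            # exhaustive oracle over every candidate threshold and direction
            cands = np.concatenate([x - 1e-9, x + 1e-9])
            brute = max(
                max(((x > t) == y).mean(), ((x < t) == y).mean()) for t in cands
            )
            assert best_threshold_accuracy(x, y) == pytest.approx(brute)


class TestScreenGenes:
    def test_signal_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        spec = ml.SyntheticCohortSpec(
            n_case=40, n_control=40, n_genes=21,
            signal_genes={"SIGNAL": 4.0}, noise_sd=1.0, seed=0,
        )
        matrix, labels, _ = ml.generate_cohort(spec)
        ranked = ml.screen_genes(matrix, labels, top_m=21)
        assert ranked[0][0] == "SIGNAL"
        # brute force: no other gene has a higher single-gene accuracy
        y = labels.is_positive()
        best = max(
            best_threshold_accuracy(matrix.gene_row(g), y) for g in matrix.gene_ids
        )
        assert ranked[0][1] == pytest.approx(best)

    def test_constant_gene_scores_chance(self):
        matrix, labels = two_class_matrix(
            [[5.0, 5.0], [1.0, 2.0]], [[5.0, 5.0], [9.0, 8.0]], ["FLAT", "VAR"]
        )
        scores = dict(ml.screen_genes(matrix, labels, top_m=2))
        assert scores["FLAT"] == 0.5

    def test_top_m_equal_to_gene_count_returns_all(self):
        matrix, labels = two_class_matrix(
            [[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]
        )
        assert len(ml.screen_genes(matrix, labels, top_m=2)) == 2

    def test_top_m_too_large_rejected(self):
        matrix, labels = two_class_matrix(
            [[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]
        )
        with pytest.raises(ValidationError):
            ml.screen_genes(matrix, labels, top_m=3)


class TestFitCompetingFactor:
    def test_separable_one_gene_recovers_positive_direction(self):
        matrix, labels = two_class_matrix([[10.0, 12.0]], [[1.0, 2.0]], ["G"])
        cf = ml.fit_competing_factor(matrix, labels, ["G"], ml.FitConfig())
        assert cf.coefficients["G"] > 0
        rep = ml.score_panel(
            ml.MaxLogisticPanel([cf], "case", "control"), matrix, labels
        )
        assert rep.accuracy == 1.0

    def test_specificity_first_forces_perfect_specificity(self):
        # overlapping classes: specificity must still be exactly 1.0
        matrix, labels = two_class_matrix(
            [[3.0, 5.0, 9.0, 11.0]], [[1.0, 2.0, 4.0, 6.0]], ["G"]
        )
        config = ml.FitConfig(mode="specificity_first")
        cf = ml.fit_competing_factor(matrix, labels, ["G"], config)
        rep = ml.score_panel(
            ml.MaxLogisticPanel([cf], "case", "control"), matrix, labels
        )
        assert rep.specificity == 1.0
        assert rep.sensitivity < 1.0

    def test_fitted_signs_match_generating_signs(self):
        spec = ml.SyntheticCohortSpec(
            n_case=60, n_control=60, n_genes=3,
            signal_genes={"UP1": 2.5, "UP2": 2.5, "DOWN": -2.5},
            noise_sd=1.0, seed=11,
        )
        matrix, labels, truth = ml.generate_cohort(spec)
        cf = ml.fit_competing_factor(
            matrix, labels, ["UP1", "UP2", "DOWN"], ml.FitConfig()
        )
        for gene, sign in truth.signal_signs.items():
            assert np.sign(cf.coefficients[gene]) == sign

    def test_oracle_equivalence_on_one_gene_problems(self):
        # accuracy_first on a single gene == brute-force best threshold
        rng = np.random.default_rng(123)
        config = ml.FitConfig(mode="accuracy_first")
        for _ in range(20):
            n_case = int(rng.integers(2, 10))
            n_ctrl = int(rng.integers(2, 10))
            case = rng.normal(1.0, 1.5, n_case)
            ctrl = rng.normal(0.0, 1.5, n_ctrl)
            matrix, labels = two_class_matrix([case], [ctrl], ["G"])
            cf = ml.fit_competing_factor(matrix, labels, ["G"], config)
            rep = ml.score_panel(
                ml.MaxLogisticPanel([cf], "case", "control"), matrix, labels
            )
            x = np.concatenate([case, ctrl])
            y = np.array([True] * n_case + [False] * n_ctrl)
            assert rep.accuracy == pytest.approx(best_threshold_accuracy(x, y))

    def test_all_constant_subset_is_fit_error(self):
        matrix, labels = two_class_matrix([[5.0, 5.0]], [[5.0, 5.0]], ["FLAT"])
        with pytest.raises(FitError):
            ml.fit_competing_factor(matrix, labels, ["FLAT"], ml.FitConfig())

    def test_subset_larger_than_cap_rejected(self):
        matrix, labels = two_class_matrix(
            [[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]
        )
        with pytest.raises(ValidationError):
            ml.fit_competing_factor(
                matrix, labels, ["G0", "G1"], ml.FitConfig(max_genes_per_factor=1)
            )


class TestFitPanel:
    def test_two_disjoint_subgroups_need_two_factors(self):
        spec = ml.SyntheticCohortSpec(
            n_case=30, n_control=30, n_genes=8,
            signal_genes={"SIGA": 0.0, "SIGB": 0.0},
            subgroups=(
                (0.6, {"SIGA": 4.0, "SIGB": -4.0}),
                (0.4, {"SIGA": -4.0, "SIGB": 4.0}),
            ),
            noise_sd=0.5, seed=7,
        )
        matrix, labels, _ = ml.generate_cohort(spec)
        single = ml.fit_panel(
            matrix, labels,
            ml.FitConfig(max_genes_per_factor=2, max_factors=1, screen_top_m=4),
        )
        multi = ml.fit_panel(
            matrix, labels,
            ml.FitConfig(max_genes_per_factor=2, max_factors=3, screen_top_m=4),
        )
        assert single.training_report.sensitivity < 1.0
        assert multi.training_report.accuracy == 1.0
        assert len(multi.panel.factors) == 2

    def test_homogeneous_cases_need_one_factor(self):
        spec = ml.SyntheticCohortSpec(
            n_case=30, n_control=30, n_genes=6,
            signal_genes={"SIG": 5.0}, noise_sd=0.5, seed=3,
        )
        matrix, labels, _ = ml.generate_cohort(spec)
        res = ml.fit_panel(
            matrix, labels,
            ml.FitConfig(max_genes_per_factor=2, max_factors=3, screen_top_m=4),
        )
        assert len(res.panel.factors) == 1
        assert res.training_report.accuracy == 1.0

    def test_shock_refit_matches_published_accuracy(self, table2_patients):
        matrix, labels = table2_patients
        res = ml.fit_panel(
            matrix, labels,
            ml.FitConfig(max_genes_per_factor=4, max_factors=3),
            genes=["NONO", "CKAP4", "FCAR", "PLEKHO1", "BMP6"],
        )
        assert res.training_report.accuracy >= 0.9375

    def test_sepsis_vs_healthy_pool_reaches_printed_optimum(self, table2):
        res = ml.fit_panel(
            table2.matrix, table2.sepsis_vs_healthy,
            ml.FitConfig(max_genes_per_factor=3, max_factors=3),
            genes=["RNF4", "NONO", "PLEKHO1"],
        )
        assert res.training_report.accuracy == 1.0

    def test_specificity_floor_holds_per_factor(self, table2_patients):
        matrix, labels = table2_patients
        res = ml.fit_panel(
            matrix, labels, ml.FitConfig(max_genes_per_factor=2, max_factors=3),
            genes=["NONO", "CKAP4", "FCAR", "PLEKHO1", "BMP6"],
        )
        ctrl_ids = [
            s for s, l in zip(labels.sample_ids, labels.labels)
            if l == labels.control_class
        ]
        for factor in res.panel.factors:
            wrapped = ml.MaxLogisticPanel(
                [factor], labels.positive_class, labels.control_class
            )
            rep = ml.score_panel(
                wrapped, matrix.subset_samples(ctrl_ids + ["P03"]),
                labels.subset(ctrl_ids + ["P03"]),
            )
            assert rep.specificity == 1.0

    def test_adding_factors_never_lowers_sensitivity(self, table2_patients):
        matrix, labels = table2_patients
        res = ml.fit_panel(
            matrix, labels, ml.FitConfig(max_genes_per_factor=2, max_factors=3),
            genes=["NONO", "CKAP4", "FCAR", "PLEKHO1", "BMP6"],
        )
        prev = 0.0
        for k in range(1, len(res.panel.factors) + 1):
            sub = ml.MaxLogisticPanel(
                res.panel.factors[:k], labels.positive_class, labels.control_class
            )
            sens = ml.score_panel(sub, matrix, labels).sensitivity
            assert sens >= prev
            prev = sens

    def test_deterministic_given_identical_inputs(self, table2_patients):
        matrix, labels = table2_patients
        cfg = ml.FitConfig(max_genes_per_factor=2, max_factors=2, seed=5)
        r1 = ml.fit_panel(matrix, labels, cfg, genes=["NONO", "CKAP4", "FCAR"])
        r2 = ml.fit_panel(matrix, labels, cfg, genes=["NONO", "CKAP4", "FCAR"])
        assert len(r1.panel.factors) == len(r2.panel.factors)
        for f1, f2 in zip(r1.panel.factors, r2.panel.factors):
            assert f1.intercept == f2.intercept
            assert f1.coefficients == f2.coefficients

    def test_empty_pool_is_fit_error(self, table2):
        with pytest.raises(FitError):
            ml.fit_panel(
                table2.matrix, table2.sepsis_vs_healthy, ml.FitConfig(), genes=[]
            )
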