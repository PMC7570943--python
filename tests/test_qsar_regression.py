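"""Correlation screening, exhaustive MLR enumeration, and validation.

Printed reference statistics are asserted at |diff| <= 1e-4 ("4 decimals"):
the published tables truncate rather than round a few final digits, so
exact 4-dp rounding equality would be stricter than the source itself.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coxqsar import (
    build_correlation_report,
    build_leaderboard,
    enumerate_subsets,
    external_validation,
    fit_mlr,
    flag_outliers,
    pearson,
    predict,
    residual_table,
    select_descriptors,
)
from coxqsar.compound_table import CompoundRecord, CompoundTable, load_predictions_reference
from coxqsar.errors import (
    CollinearityError,
    DataError,
    DegenerateInputError,
    DomainError,
    EmptySelectionError,
    MissingDescriptorError,
)
from coxqsar.synthetic_data import LinearGeneratorSpec, generate_training_table

# Published single-model and leaderboard statistics: subset -> (R, R2, R2_adj, SEE, F).
REFERENCE_STATS = {
    ("ATM",): (0.7651, 0.5854, 0.5623, 0.4804, 25.4183),
    ("ARO",): (0.7358, 0.5414, 0.5159, 0.5053, 21.2522),
    ("ACC",): (0.6399, 0.4095, 0.3767, 0.5733, 12.4871),
    ("DONN",): (0.4743, 0.2249, 0.1819, 0.6569, 5.2251),
    ("ATM", "ACC"): (0.9022, 0.8140, 0.7921, 0.3311, 37.2030),
    ("ARO", "ATM"): (0.8487, 0.7203, 0.6874, 0.4060, 21.8906),
    ("ATM", "DONN"): (0.8316, 0.6916, 0.6554, 0.4263, 19.0684),
    ("ACC", "DONN"): (0.7809, 0.6099, 0.5640, 0.4795, 13.2914),
    ("ARO", "DONN"): (0.7701, 0.5930, 0.5452, 0.4898, 12.3893),
    ("ARO", "ACC"): (0.7661, 0.5869, 0.5383, 0.4934, 12.0789),
    ("ATM", "ACC", "DONN"): (0.9599, 0.9215, 0.9068, 0.2217, 62.6376),
    ("ARO", "ATM", "ACC"): (0.9053, 0.8197, 0.7859, 0.3360, 24.2481),
    ("ARO", "ACC", "DONN"): (0.8207, 0.6736, 0.6125, 0.4521, 11.0113),
    ("ATM", "ACC", "DONN", "ARO"): (0.9617, 0.9250, 0.9050, 0.2238, 46.2719),
}


def oracle_ols(X, y):
    """Independent normal-equations solver: beta = (A'A)^-1 A'y."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def small_table(X, y, names):
    records = [
        CompoundRecord(
            f"c{i}",
            {n: int(v) for n, v in zip(names, row)},
            pic50=float(yi),
        )
        for i, (row, yi) in enumerate(zip(X, y))
    ]
    return CompoundTable(records, list(names))


class TestPearson:
    def test_reference_descriptor_activity_correlations(self, training_table):
        X = training_table.descriptor_matrix()
        y = training_table.pic50_vector()
        expected = {"ATM": 0.7651, "ARO": 0.7358, "DONN": 0.4743, "ACC": -0.6399}
        for i, name in enumerate(training_table.descriptor_names):
            assert pearson(X[:, i], y) == pytest.approx(expected[name], abs=1e-4)

    def test_self_correlation_is_one(self):
        v = [1.0, 2.0, 5.0, 3.0]
        assert pearson(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_raises_not_nan(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(DomainError):
            pearson([1.0, 2.0], [3.0, 4.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30).filter(
            lambda v: len(set(v)) > 1
        ),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance_and_bounds(self, v, scale, shift):
        x = np.array(v)
        y = scale * x + shift
        rho = pearson(x, y)
        assert rho == pytest.approx(1.0, abs=1e-8)
        assert -1.0 <= rho <= 1.0


class TestCorrelationReport:
    def test_reference_report(self, training_table):
        report = build_correlation_report(training_table, 0.4)
        assert report.descriptor_names == ["ATM", "ARO", "DONN", "ACC"]
        np.testing.assert_allclose(report.pairwise, report.pairwise.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(report.pairwise), 1.0)
        # lower-block pairwise values as published
        published = {
            ("ATM", "ARO"): 0.5659, ("ATM", "DONN"): 0.2027, ("ATM", "ACC"): -0.2280,
            ("ARO", "DONN"): 0.3559, ("ARO", "ACC"): -0.6492, ("DONN", "ACC"): -0.0423,
        }
        index = {n: i for i, n in enumerate(report.descriptor_names)}
        for (a, b), rho in published.items():
            assert report.pairwise[index[a], index[b]] == pytest.approx(rho, abs=1e-4)

    def test_single_descriptor_table(self):
        table = small_table([[1], [2], [3], [5]], [1.0, 2.1, 2.9, 5.2], ["ATM"])
        report = build_correlation_report(table, 0.0)
        assert report.pairwise.shape == (1, 1)
        assert report.pairwise[0, 0] == 1.0

    def test_constant_descriptor_names_offender(self):
        table = small_table([[1, 7], [2, 7], [3, 7]], [1.0, 2.0, 3.0], ["ATM", "SF"])
        with pytest.raises(DegenerateInputError, match="SF"):
            build_correlation_report(table, 0.4)


class TestSelection:
    def test_default_cutoff_keeps_all_four(self, training_table):
        report = build_correlation_report(training_table, 0.4)
        assert select_descriptors(report) == ["ATM", "ARO", "DONN", "ACC"]

    def test_cutoff_is_sign_blind(self, training_table):
        # ACC correlates at -0.6399 and must survive cutoffs below 0.64
        report = build_correlation_report(training_table, 0.6)
        assert "ACC" in select_descriptors(report)

    def test_higher_cutoff_drops_weak_descriptors(self, training_table):
        report = build_correlation_report(training_table, 0.7)
        assert select_descriptors(report) == ["ATM", "ARO"]

    def test_zero_cutoff_keeps_everything(self, training_table):
        report = build_correlation_report(training_table, 0.0)
        assert select_descriptors(report) == training_table.descriptor_names

    def test_impossible_cutoff_raises(self, training_table):
        report = build_correlation_report(training_table, 0.999)
        with pytest.raises(EmptySelectionError):
            select_descriptors(report)


class TestEnumeration:
    @pytest.mark.parametrize("n, p", [(4, 1), (4, 2), (4, 3), (4, 4), (6, 3)])
    def test_counts_match_binomial(self, n, p):
        descriptors = [f"D{i}" for i in range(n)]
        subsets = enumerate_subsets(descriptors, p)
        assert len(subsets) == math.comb(n, p)
        assert len(set(subsets)) == len(subsets)

    def test_power_set_total(self):
        descriptors = ["ATM", "ARO", "DONN", "ACC"]
        total = sum(len(enumerate_subsets(descriptors, p)) for p in range(1, 5))
        brute = [
            s
            for r in range(1, 5)
            for s in itertools.combinations(descriptors, r)
        ]
        assert total == len(brute) == 15

    def test_lexicographic_index_order(self):
        assert enumerate_subsets(["a", "b", "c"], 2) == [
            ("a", "b"), ("a", "c"), ("b", "c"),
        ]

    @pytest.mark.parametrize("p", [0, 5])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(DomainError):
            enumerate_subsets(["a", "b", "c", "d"], p)


class TestFit:
    @pytest.mark.parametrize("subset, expected", REFERENCE_STATS.items(),
                             ids=["+".join(s) for s in REFERENCE_STATS])
    def test_refit_reproduces_published_statistics(self, training_table, subset, expected):
        model = fit_mlr(training_table, list(subset))
        R, R2, R2_adj, SEE, F = expected
        assert model.stats["R"] == pytest.approx(R, abs=1e-4)
        assert model.stats["R2"] == pytest.approx(R2, abs=1e-4)
        assert model.stats["R2_adj"] == pytest.approx(R2_adj, abs=1e-4)
        assert model.stats["SEE"] == pytest.approx(SEE, abs=1e-4)
        assert model.stats["F"] == pytest.approx(F, abs=1e-3)

    def test_refit_reproduces_published_tetra_coefficients(self, training_table):
        model = fit_mlr(training_table, ["ATM", "ACC", "DONN", "ARO"])
        printed = {"ATM": 0.0907, "ACC": -0.3721, "DONN": 0.3766, "ARO": -0.0674}
        assert model.intercept == pytest.approx(6.1250, abs=1e-4)
        for name, coef in printed.items():
            assert model.coefficients[name] == pytest.approx(coef, abs=1e-4)

    def test_perfect_linear_fit(self):
        X = [[1], [2], [3], [4], [5]]
        y = [2.0 + 0.5 * x[0] for x in X]
        model = fit_mlr(small_table(X, y, ["ATM"]), ["ATM"])
        assert model.stats["R2"] == pytest.approx(1.0, abs=1e-12)
        assert model.stats["SEE"] == pytest.approx(0.0, abs=1e-8)

    def test_oracle_equivalence_on_small_tables(self):
        """statsmodels-backed fit agrees with an independent normal-equations
        solve to 1e-8 on small two-descriptor tables."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            X = rng.integers(0, 30, size=(n, 2)).astype(float)
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < 3:
                continue
            y = rng.normal(8.0, 1.0, size=n)
            model = fit_mlr(small_table(X, y, ["D1", "D2"]), ["D1", "D2"])
            beta = oracle_ols(X, y)
            assert model.intercept == pytest.approx(beta[0], abs=1e-8)
            assert model.coefficients["D1"] == pytest.approx(beta[1], abs=1e-8)
            assert model.coefficients["D2"] == pytest.approx(beta[2], abs=1e-8)

    def test_training_residuals_sum_to_zero(self, training_table):
        for subset in [["ATM"], ["ATM", "ACC"], ["ATM", "ACC", "DONN", "ARO"]]:
            model = fit_mlr(training_table, subset)
            residuals = [
                r.residual for r in residual_table(training_table, [model])
            ]
            assert sum(residuals) == pytest.approx(0.0, abs=1e-8)

    def test_statistic_internal_consistency(self, training_table):
        n = len(training_table)
        for subset in REFERENCE_STATS:
            model = fit_mlr(training_table, list(subset))
            p = len(subset)
            r2 = model.stats["R2"]
            assert model.stats["R"] == pytest.approx(math.sqrt(r2), abs=1e-10)
            assert model.stats["F"] == pytest.approx(
                (r2 / p) / ((1 - r2) / (n - p - 1)), abs=1e-10
            )
            assert model.stats["R2_adj"] == pytest.approx(
                1 - (1 - r2) * (n - 1) / (n - p - 1), abs=1e-10
            )

    def test_mono_model_R_equals_abs_pearson(self, training_table):
        X = training_table.descriptor_matrix()
        y = training_table.pic50_vector()
        for i, name in enumerate(training_table.descriptor_names):
            model = fit_mlr(training_table, [name])
            assert model.stats["R"] == pytest.approx(
                abs(pearson(X[:, i], y)), abs=1e-10
            )

    def test_collinear_design_rejected(self):
        X = [[i, 2 * i] for i in range(1, 8)]
        y = [float(i) for i in range(1, 8)]
        with pytest.raises(CollinearityError):
            fit_mlr(small_table(X, y, ["D1", "D2"]), ["D1", "D2"])

    def test_insufficient_degrees_of_freedom(self):
        X = [[1, 2], [2, 3], [3, 5]]
        y = [1.0, 2.0, 3.0]
        with pytest.raises(DataError, match="degrees of freedom"):
            fit_mlr(small_table(X, y, ["D1", "D2"]), ["D1", "D2"])


class TestPredict:
    @pytest.mark.parametrize(
        "compound, expected",
        [
            ({"ATM": 36, "ARO": 2, "DONN": 0, "ACC": 4}, 7.7670),  # pivot
            ({"ATM": 43, "ARO": 2, "DONN": 2, "ACC": 3}, 9.5272),  # Z-964
            ({"ATM": 38, "ARO": 2, "DONN": 0, "ACC": 4}, 7.9484),  # Z-814
            ({"ATM": 41, "ARO": 2, "DONN": 2, "ACC": 3}, 9.3458),  # Z-627
        ],
    )
    def test_printed_tetra_equation_values(self, reference_models, compound, expected):
        assert predict(reference_models["tetra"], compound) == pytest.approx(
            expected, abs=5e-5
        )

    def test_all_zero_descriptors_give_intercept(self, reference_models):
        model = reference_models["tetra"]
        zeros = {name: 0 for name in model.descriptor_subset}
        assert predict(model, zeros) == model.intercept

    def test_missing_descriptor_names_it(self, reference_models):
        with pytest.raises(MissingDescriptorError, match="ACC"):
            predict(reference_models["tetra"], {"ATM": 36, "ARO": 2, "DONN": 0})

    def test_as_printed_rounding(self, training_table):
        model = fit_mlr(training_table, ["ATM"]).as_printed()
        assert model.intercept == pytest.approx(4.2567, abs=1e-9)
        assert model.coefficients["ATM"] == pytest.approx(0.1112, abs=1e-9)


class TestResidualsAndValidation:
    def test_published_residual_tables_reproduce(self, training_table, internal_table,
                                                 external_table, reference_models):
        """Every printed predicted pIC50 and residual across all four models
        and all three compound sets reproduces at 4 decimals."""
        reference = load_predictions_reference().set_index("id")
        tables = {
            "training": training_table,
            "internal_validation": internal_table,
            "external_validation": external_table,
        }
        for model_name in ("mono", "bi", "tri", "tetra"):
            model = reference_models[model_name]
            for set_name, table in tables.items():
                for record in residual_table(table, [model]):
                    row = reference.loc[record.compound_id]
                    assert record.predicted_pic50 == pytest.approx(
                        row[model_name], abs=5e-5
                    ), (model_name, record.compound_id)
                    assert record.residual == pytest.approx(
                        row[f"d_{model_name}"], abs=5e-5
                    ), (model_name, record.compound_id)

    def test_molecule_12_tetra_residual(self, training_table, reference_models):
        records = residual_table(training_table, [reference_models["tetra"]])
        by_id = {r.compound_id: r for r in records}
        assert by_id["12"].residual == pytest.approx(0.0020, abs=5e-5)

    def test_pivot_mono_residual(self, training_table, reference_models):
        records = residual_table(training_table, [reference_models["mono"]])
        pivot = next(r for r in records if r.compound_id == "1")
        assert pivot.predicted_pic50 == pytest.approx(8.2562, abs=5e-5)
        assert pivot.residual == pytest.approx(-0.3354, abs=5e-5)

    def test_internal_set_all_flagged_at_default_threshold(
        self, internal_table, reference_models
    ):
        records = residual_table(internal_table, [reference_models["tetra"]])
        retained, flagged = flag_outliers(records, 0.4)
        assert retained == []
        published = [0.5944, -0.4464, -0.5269, -0.5120, -0.5972]
        assert [r.residual for r in flagged] == pytest.approx(published, abs=5e-5)

    def test_outlier_threshold_edge_cases(self, internal_table, reference_models):
        records = residual_table(internal_table, [reference_models["tetra"]])
        retained, flagged = flag_outliers(records, math.inf)
        assert flagged == []
        retained, flagged = flag_outliers(records, 0.0)
        assert retained == []

    def test_external_validation_celecoxib(self, external_table, reference_models):
        summary = external_validation(reference_models["tetra"], external_table)
        celecoxib = next(
            r for r in summary.records if r.compound_id == "Celecoxib"
        )
        assert celecoxib.residual == pytest.approx(0.8449, abs=5e-5)
        assert summary.max_abs_residual == pytest.approx(0.8449, abs=5e-5)

    def test_external_validation_molecule_27(self, external_table, reference_models):
        summary = external_validation(reference_models["tetra"], external_table)
        mol27 = next(r for r in summary.records if r.compound_id == "27")
        assert mol27.predicted_pic50 == pytest.approx(9.2110, abs=5e-5)
        assert mol27.residual == pytest.approx(0.0566, abs=5e-5)

    def test_external_validation_requires_external_rows(self, training_table,
                                                        reference_models):
        with pytest.raises(DataError):
            external_validation(reference_models["tetra"], training_table)


class TestLeaderboard:
    def test_completeness_and_ranking(self, training_table):
        leaderboard = build_leaderboard(
            training_table, ["ATM", "ARO", "DONN", "ACC"], 4
        )
        assert len(leaderboard.models) == 2**4 - 1
        for p in range(1, 5):
            assert len(leaderboard.by_size(p)) == math.comb(4, p)
        ranked = leaderboard.ranked()
        assert all(
            a.stats["R2"] >= b.stats["R2"] for a, b in zip(ranked, ranked[1:])
        )
        assert leaderboard.best.model_id == "ATM+ARO+DONN+ACC"

    def test_synthetic_noiseless_full_model_is_exact(self):
        table = generate_training_table(LinearGeneratorSpec(noise_sd=0.0, seed=7))
        leaderboard = build_leaderboard(table, table.descriptor_names, 4)
        full = leaderboard.by_size(4)[0]
        assert full.stats["R2"] == pytest.approx(1.0, abs=1e-10)
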