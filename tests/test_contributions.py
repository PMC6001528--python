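"""Contribution matrices, Riley study weights, aggregation, method contrast."""

import numpy as np
import pandas as pd
import pytest

from netmetareg import (
    BinSpec,
    ModelSpec,
    PriorSpec,
    ResultSpec,
    SimConfig,
    aggregate_contributions,
    augment_with_priors,
    build_design,
    center_covariate,
    compare_methods,
    contribution_new,
    contribution_table,
    default_results,
    result_contrast_vector,
    riley_functional,
    riley_table,
    riley_weights,
    simulate_dataset,
)
from netmetareg.data_io import ContrastDataset, StudyContrasts
from netmetareg.exceptions import UnsupportedConfigurationError, ValidationError

PARAMS = ["d(B)", "d(C)", "beta(B)", "beta(C)"]


def _pairwise(effects_covs, variances=None):
    variances = variances or [0.04] * len(effects_covs)
    return ContrastDataset(
        [
            StudyContrasts(f"s{i}", "A", ["B"], np.array([y]), np.array([[v]]), c)
            for i, ((y, c), v) in enumerate(zip(effects_covs, variances))
        ]
    )


class TestResultContrastVector:
    @pytest.mark.parametrize(
        "rspec, expected",
        [
            (ResultSpec(("B", "A")), [1, 0, 0, 0]),
            (ResultSpec(("C", "B")), [-1, 1, 0, 0]),
            (ResultSpec(("C", "B"), "coefficient"), [0, 0, -1, 1]),
            (ResultSpec(("B", "A"), "effect_at_value", 3.0), [1, 0, 3, 0]),
            (ResultSpec(("A", "C")), [0, -1, 0, 0]),
        ],
    )
    def test_consistency_combinations(self, rspec, expected):
        c = result_contrast_vector(rspec, PARAMS, "A", "independent", center=0.0)
        np.testing.assert_allclose(c, expected)

    def test_centre_honoured_for_effect_at_value(self):
        c = result_contrast_vector(
            ResultSpec(("B", "A"), "effect_at_value", 10.0), PARAMS, "A",
            "independent", center=4.0,
        )
        np.testing.assert_allclose(c, [1, 0, 6, 0])

    def test_common_functional_coefficient_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="fixed to zero"):
            c = result_contrast_vector(
                ResultSpec(("C", "B"), "coefficient"), ["d(B)", "d(C)", "beta"],
                "A", "common",
            )
        np.testing.assert_allclose(c, 0.0)

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValidationError):
            result_contrast_vector(ResultSpec(("Z", "A")), PARAMS, "A")


class TestContributionNew:
    def test_single_study_contributes_everything(self):
        ds = _pairwise([(0.5, 2.0), (0.7, 9.0)])
        dsys = build_design(ds, ModelSpec())
        for kind in ("effect_at_center", "coefficient"):
            row = contribution_new(dsys, ResultSpec(("B", "A"), kind))
            assert row.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_bruteforce_hat_matrix(self, fe_design):
        """Entry-by-entry dense reconstruction of c'(X'V^-1X)^-1X'V^-1."""
        X, y, V = fe_design.X, fe_design.y, fe_design.V()
        Vinv = np.linalg.inv(V)
        A = X.T @ Vinv @ X
        for rspec in default_results(["A", "B", "C"]):
            c = result_contrast_vector(
                rspec, fe_design.param_names, "A", "independent",
                fe_design.data.covariate_center,
            )
            w = c @ np.linalg.inv(A) @ X.T @ Vinv
            expected = 100 * np.abs(w) / np.abs(w).sum()
            got = contribution_new(fe_design, rspec).to_numpy()
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_bruteforce_with_prior_rows(self, fe_design):
        aug = augment_with_priors(fe_design, PriorSpec(variance=10.0))
        X, V = aug.X, aug.V()
        Vinv = np.linalg.inv(V)
        A = X.T @ Vinv @ X
        rspec = ResultSpec(("C", "B"), "coefficient")
        c = result_contrast_vector(
            rspec, aug.param_names, "A", "independent", aug.data.covariate_center
        )
        w = c @ np.linalg.inv(A) @ X.T @ Vinv
        expected = 100 * np.abs(w) / np.abs(w).sum()
        got = contribution_new(aug, rspec)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-10)
        # prior pseudo-rows are labelled apart from data rows
        assert sum(lab.startswith("prior:") for lab in got.index) == 4

    def test_rows_sum_to_100_across_configurations(self, rng):
        ds, _ = simulate_dataset(SimConfig(N=25, prop_three_arm=0.4), rng=rng)
        dsc = center_covariate(ds, "mean")
        for spec in (
            ModelSpec(),
            ModelSpec(effects="random", heterogeneity=0.05),
            ModelSpec(interactions="common"),
            ModelSpec(interactions="exchangeable", exchange_sd=0.05),
        ):
            dsys = build_design(dsc, spec)
            table = contribution_table(dsys)
            np.testing.assert_allclose(table.row_sums(), 100.0, atol=1e-6)

    def test_triangle_all_contributions_positive(self, fe_design):
        """With a trial on every edge, indirect evidence flows everywhere."""
        table = contribution_table(fe_design)
        study = aggregate_contributions(table, "study")
        assert (study.values.to_numpy() > 0).all()

    def test_effect_and_coefficient_contributions_differ(self, fe_design):
        eff = contribution_new(fe_design, ResultSpec(("B", "A")))
        coe = contribution_new(fe_design, ResultSpec(("B", "A"), "coefficient"))
        assert np.abs(eff.to_numpy() - coe.to_numpy()).max() > 0.5


class TestAggregation:
    def test_single_bin_spans_everything(self, fe_design):
        study = aggregate_contributions(contribution_table(fe_design), "study")
        binned = aggregate_contributions(study, "bin", BinSpec((0.0, 40.0)))
        np.testing.assert_allclose(binned.values.to_numpy(), 100.0, atol=1e-9)

    def test_study_level_sums_datapoint_entries(self, fe_design):
        table = contribution_table(fe_design)
        study = aggregate_contributions(table, "study")
        t06_cols = [c for c in table.values.columns if c.startswith("t06|")]
        np.testing.assert_allclose(
            study.values["t06"], table.values[t06_cols].sum(axis=1), atol=1e-12
        )

    def test_triangle_bins_match_hand_summed_values(self, fe_design, triangle):
        """Bin totals equal manual addition of the per-study percentages."""
        study = aggregate_contributions(contribution_table(fe_design), "study")
        binned = aggregate_contributions(study, "bin", BinSpec((0.0, 10.0, 20.0, 35.0)))
        covs = triangle.covariates(original_scale=True)
        low = [s for s, c in covs.items() if c < 10]
        label = "d:B_vs_A@center"
        np.testing.assert_allclose(
            binned.values.loc[label, "0–10"],
            study.values.loc[label, low].sum(),
            atol=1e-12,
        )
        # nothing sits in the covariate gap
        assert binned.values["10–20"].eq(0).all()

    def test_covariate_outside_bins_names_studies(self, fe_design):
        study = aggregate_contributions(contribution_table(fe_design), "study")
        with pytest.raises(ValidationError, match="t0"):
            aggregate_contributions(study, "bin", BinSpec((0.0, 10.0)))

    def test_final_bin_closed_on_the_right(self):
        b = BinSpec((0.0, 10.0, 20.0))
        assert b.assign(20.0) == 1 and b.assign(10.0) == 1 and b.assign(9.999) == 0
        assert b.assign(20.0001) is None


def pairwise_ma_design(effects, variances):
    """Intercept-only pairwise meta-analysis as a bare design system."""
    from netmetareg.model import DesignBlock, DesignSystem

    ds = _pairwise([(y, 0.0) for y in effects], list(variances))
    blocks = [
        DesignBlock(
            kind="data", label=f"s{i}", rows=slice(i, i + 1),
            within_cov=np.array([[v]]), covariate=0.0, contrasts=["B vs A"],
        )
        for i, v in enumerate(variances)
    ]
    return DesignSystem(
        y=np.asarray(effects, dtype=float),
        X=np.ones((len(effects), 1)),
        blocks=blocks,
        param_names=["d(B)"],
        reference="A",
        spec=ModelSpec(),
        data=ds,
    )


class TestRileyWeights:
    def test_pairwise_fe_meta_analysis_inverse_variance(self):
        """Classical reduction: in pairwise fixed-effect meta-analysis the
        variance-decomposition weights are the inverse-variance percentages."""
        variances = [0.04, 0.08, 0.02]
        dsys = pairwise_ma_design([0.5, 0.7, 0.3], variances)
        w = riley_weights(dsys, "d(B)")
        inv = np.array([1 / v for v in variances])
        np.testing.assert_allclose(w.to_numpy(), 100 * inv / inv.sum(), atol=1e-10)

    def test_single_study_gets_everything(self):
        ds = _pairwise([(0.5, 1.0), (0.7, 3.0)])
        dsys = build_design(ds, ModelSpec())
        w = riley_weights(dsys, "d(B)")
        assert w.sum() == pytest.approx(100.0, abs=1e-9)

    def test_equal_variance_symmetric_split(self):
        ds = _pairwise([(0.5, -1.0), (0.7, 1.0)])
        w = riley_weights(build_design(ds, ModelSpec()), "d(B)")
        np.testing.assert_allclose(w.to_numpy(), [50.0, 50.0], atol=1e-9)

    def test_weights_sum_to_100(self, fe_design):
        for p in fe_design.param_names:
            assert riley_weights(fe_design, p).sum() == pytest.approx(100.0, abs=1e-9)

    def test_prior_rows_unsupported(self, fe_design):
        aug = augment_with_priors(fe_design, PriorSpec())
        with pytest.raises(UnsupportedConfigurationError):
            riley_weights(aug, "d(B)")


class TestRileyFunctional:
    def test_basic_comparison_is_plain_weights(self, fe_design):
        direct = riley_weights(fe_design, "d(B)")
        via = riley_functional(fe_design, ResultSpec(("B", "A")))
        np.testing.assert_allclose(via[direct.index], direct, atol=1e-12)

    def test_functional_weights_sum_to_100(self, fe_design):
        w = riley_functional(fe_design, ResultSpec(("C", "B"), "coefficient"))
        assert w.sum() == pytest.approx(100.0, abs=1e-9)

    def test_invariant_to_original_reference(self, triangle):
        """Weights for C vs B do not depend on which reference built the design."""
        results = []
        for ref in ("A", "B"):
            dsys = build_design(triangle, ModelSpec(reference=ref))
            results.append(riley_functional(dsys, ResultSpec(("C", "B"))))
        np.testing.assert_allclose(
            results[0].sort_index(), results[1].sort_index(), atol=1e-9
        )

    def test_exchangeable_unsupported(self, triangle):
        spec = ModelSpec(interactions="exchangeable", exchange_sd=0.1)
        dsys = build_design(triangle, spec)
        with pytest.raises(UnsupportedConfigurationError):
            riley_functional(dsys, ResultSpec(("C", "B")))


class TestCompareMethods:
    def test_identical_tables_zero_difference(self, fe_design):
        t = aggregate_contributions(contribution_table(fe_design), "study")
        diff, summary = compare_methods(t, t)
        assert summary["max_abs_diff"] == 0.0

    def test_pairwise_meta_analysis_methods_agree(self):
        """Both methods reduce to inverse-variance weights in pairwise FE MA."""
        variances = [0.04, 0.08, 0.02]
        dsys = pairwise_ma_design([0.5, 0.7, 0.3], variances)
        inv = np.array([1 / v for v in variances])
        expected = 100 * inv / inv.sum()
        new = contribution_new(dsys, ResultSpec(("B", "A")))
        np.testing.assert_allclose(new.to_numpy(), expected, atol=1e-9)
        w = riley_weights(dsys, "d(B)")
        np.testing.assert_allclose(w.to_numpy(), expected, atol=1e-9)

    def test_methods_differ_on_triangle(self, fe_design):
        new = aggregate_contributions(contribution_table(fe_design), "study")
        riley = riley_table(fe_design)
        diff, summary = compare_methods(new, riley)
        assert summary["max_abs_diff"] > 0.0
        assert diff.shape == (6, 6)

    def test_label_mismatch_rejected(self, fe_design):
        t = aggregate_contributions(contribution_table(fe_design), "study")
        other = riley_table(fe_design, [ResultSpec(("B", "A"))])
        with pytest.raises(ValidationError):
            compare_methods(t, other)


def rescale_study_rows(dsys, label, k):
    """Rescale one study's rows (y -> k*y, V -> k^2*V, design row -> k*row).

    This transformation leaves the study's information content — and hence
    the model fit — unchanged, so it is the canonical probe for scale
    invariance of contribution methods.
    """
    import dataclasses

    y = dsys.y.copy()
    X = dsys.X.copy()
    blocks = []
    for b in dsys.blocks:
        if b.label == label and b.kind == "data":
            y[b.rows] *= k
            X[b.rows] *= k
            b = dataclasses.replace(b, within_cov=k**2 * b.within_cov)
        blocks.append(b)
    return dataclasses.replace(dsys, y=y, X=X, blocks=blocks)


class TestRescalingInvariance:
    def test_new_method_changes_riley_does_not(self, fe_design):
        """Documented contrast: hat-matrix contributions are not invariant to
        rescaling the data; variance-decomposition weights are."""
        d2 = rescale_study_rows(fe_design, "t01", 3.0)
        # the fit itself is unaffected by the rescaling
        from netmetareg import fit_gls

        np.testing.assert_allclose(
            fit_gls(fe_design).params, fit_gls(d2).params, atol=1e-10
        )
        rspec = ResultSpec(("B", "A"))
        new1 = contribution_new(fe_design, rspec)
        new2 = contribution_new(d2, rspec)
        assert np.abs(new1.to_numpy() - new2.to_numpy()).max() > 0.5
        r1 = riley_weights(fe_design, "d(B)")
        r2 = riley_weights(d2, "d(B)")
        np.testing.assert_allclose(r1, r2, atol=1e-9)


def test_serialised_table_round_trips(tmp_path, fe_design):
    table = aggregate_contributions(contribution_table(fe_design), "study")
    path = tmp_path / "contrib.csv"
    table.to_csv(path)
    back = pd.read_csv(path, index_col="result")
    np.testing.assert_allclose(back.to_numpy(), table.values.to_numpy(), atol=1e-12)
    assert "d:B_vs_A@center" in back.index
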