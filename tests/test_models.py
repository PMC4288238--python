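"""Model selection, quality filtering and the full model-fitting pass."""
import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import psea
from psea.models import QualityThresholds, apply_quality_filters, select_model_aic


def brute_force_select(y, refs, types=None):
    """Independent enumeration oracle: statsmodels OLS over all subsets,
    minimum AIC, ties to fewer regressors then canonical order."""
    types = list(types or refs.cell_types)
    best = None
    for size in range(1, len(types) + 1):
        for subset in itertools.combinations(types, size):
            X = sm.add_constant(refs.signals[list(subset)].to_numpy())
            aic = sm.OLS(y, X).fit().aic
            if best is None or aic < best[0] - 1e-9:
                best = (aic, subset)
    return best[1]


def test_exact_single_regressor_fit(zero_noise_refs):
    y = 2.0 * zero_noise_refs.signals["neuron"].to_numpy()
    model = select_model_aic(y, zero_noise_refs)
    assert model.regressors == ("neuron",)
    assert model.coefficients[0] == pytest.approx(2.0, rel=1e-10)
    assert model.intercept == pytest.approx(0.0, abs=1e-8)
    assert model.adj_r2 == pytest.approx(1.0, abs=1e-10)


def test_exact_two_regressor_fit(zero_noise_refs):
    y = (
        zero_noise_refs.signals["astrocyte"].to_numpy()
        + zero_noise_refs.signals["microglia"].to_numpy()
    )
    model = select_model_aic(y, zero_noise_refs)
    assert set(model.regressors) == {"astrocyte", "microglia"}


def test_constant_response_not_significant(noisy_refs):
    rng = np.random.default_rng(0)
    y = 100.0 + rng.normal(0, 1e-6, size=noisy_refs.signals.shape[0])
    model = select_model_aic(y, noisy_refs)
    assert model.f_pvalue > 0.05
    assert abs(model.coefficients).max() < 1e-6


def test_noisy_coefficients_near_truth_and_match_oracle(noisy_refs):
    """Simulated two-regressor response: closed-form fit equals statsmodels
    and recovers the truth within 3 standard errors."""
    rng = np.random.default_rng(7)
    xa = noisy_refs.signals["astrocyte"].to_numpy()
    xo = noisy_refs.signals["oligodendrocyte"].to_numpy()
    y = 1.5 * xa + 0.5 * xo + rng.normal(0, 5.0, size=xa.size)
    from psea._ols import fit_ols

    fit = fit_ols(y, np.column_stack([xa, xo]))
    ref = sm.OLS(y, sm.add_constant(np.column_stack([xa, xo]))).fit()
    np.testing.assert_allclose(fit.coefficients, ref.params[1:], rtol=1e-10)
    for est, se, truth in zip(fit.coefficients, fit.stderr[1:], (1.5, 0.5)):
        assert abs(est - truth) < 3 * se


@pytest.mark.parametrize("seed", [0, 1])
def test_selection_matches_brute_force_enumeration(seed):
    cfg = psea.SimulationConfig(seed=seed, n_genes=50, noise_sd_fraction=0.1)
    dataset, truth = psea.simulate_dataset(cfg)
    refs = psea.build_reference_signals(dataset, truth.markers)
    markers = set(truth.markers.all_probesets())
    for probeset in dataset.values.index:
        if probeset in markers:
            continue
        y = dataset.values.loc[probeset].to_numpy()
        model = select_model_aic(y, refs)
        assert model.regressors == brute_force_select(y, refs), probeset


def test_zero_noise_true_support_always_selected(zero_noise_sim, zero_noise_refs):
    cfg, dataset, truth = zero_noise_sim
    types = list(cfg.cell_types)
    models = psea.run_psea_models(dataset, zero_noise_refs, truth.markers)
    amean = truth.abundances.mean()
    for probeset, model in models.models.items():
        x = truth.base_expression.loc[dataset.gene_of(probeset)]
        expected = tuple(ct for ct in types if x[ct] > 0)
        assert tuple(sorted(model.regressors, key=types.index)) == expected
        # coefficients recover per-cell expression up to the known
        # abundance-to-reference proportionality constant
        for ct in model.regressors:
            np.testing.assert_allclose(
                model.coefficient(ct), x[ct] * amean[ct] / 100.0, rtol=1e-8
            )


@pytest.mark.parametrize(
    "field, value, flag",
    [
        ("adj_r2", 0.59, "adj_r2"),
        ("f_pvalue", 0.06, "f_test"),
        ("shapiro_pvalue", 0.009, "shapiro"),
    ],
)
def test_threshold_flags(field, value, flag):
    model = psea.PseaModel(
        probeset_id="p", gene="G", regressors=("neuron",), intercept=0.0,
        coefficients=np.array([1.0]), aic=0.0, f_pvalue=1e-6, adj_r2=0.9,
        shapiro_pvalue=0.5, mean_expression=100.0,
    )
    setattr(model, field, value)
    out = apply_quality_filters(model)
    assert not out.pass_flags[flag]
    assert not out.overall_pass


def test_intercept_rule_half_of_mean_expression():
    """Mean expression 100: intercept 60 rejected, 50 tolerated."""
    def with_intercept(b0):
        m = psea.PseaModel(
            probeset_id="p", gene="G", regressors=("neuron",), intercept=b0,
            coefficients=np.array([1.0]), aic=0.0, f_pvalue=1e-6, adj_r2=0.9,
            shapiro_pvalue=0.5, mean_expression=100.0,
        )
        return apply_quality_filters(m).pass_flags["intercept"]

    assert not with_intercept(60.0)
    assert not with_intercept(-60.0)
    assert with_intercept(50.0)


def test_negative_coefficient_rejected():
    m = psea.PseaModel(
        probeset_id="p", gene="G", regressors=("neuron", "microglia"),
        intercept=0.0, coefficients=np.array([1.0, -0.01]), aic=0.0,
        f_pvalue=1e-6, adj_r2=0.9, shapiro_pvalue=0.5, mean_expression=100.0,
    )
    out = apply_quality_filters(m)
    assert not out.pass_flags["coefficient_sign"]


def test_pass_is_monotone_in_thresholds(noisy_sim, noisy_refs):
    """Relaxing every threshold never removes a passing model."""
    _, dataset, truth = noisy_sim
    strict = QualityThresholds()
    loose = QualityThresholds(
        f_alpha=0.2, min_adj_r2=0.3, shapiro_alpha=0.001, intercept_fraction=1.0
    )
    m_strict = psea.run_psea_models(dataset, noisy_refs, truth.markers, strict)
    m_loose = psea.run_psea_models(dataset, noisy_refs, truth.markers, loose)
    assert set(m_strict.passing()) <= set(m_loose.passing())


def test_marker_probesets_removed(zero_noise_sim, zero_noise_refs):
    _, dataset, truth = zero_noise_sim
    marker_only = psea.ExpressionDataset(
        values=dataset.values.loc[truth.markers.all_probesets()],
        groups=dataset.groups,
        gene_map=dataset.gene_map,
    )
    models = psea.run_psea_models(marker_only, zero_noise_refs, truth.markers)
    assert models.models == {}
    assert models.stage_counts["probesets_in"] == 0


def test_zero_variance_probeset_skipped(zero_noise_sim, zero_noise_refs):
    _, dataset, truth = zero_noise_sim
    values = dataset.values.copy()
    values.iloc[-1] = 7.0  # constant row
    flat = psea.ExpressionDataset(
        values=values, groups=dataset.groups, gene_map=dataset.gene_map
    )
    models = psea.run_psea_models(flat, zero_noise_refs, truth.markers)
    pid = values.index[-1]
    assert models.skipped[pid] == "zero variance"
    assert pid not in models.models


def test_sample_misalignment_rejected(zero_noise_sim, zero_noise_refs):
    _, dataset, _ = zero_noise_sim
    shuffled = psea.ExpressionDataset(
        values=dataset.values.iloc[:, ::-1],
        groups=dataset.groups.iloc[::-1],
        gene_map=dataset.gene_map,
    )
    with pytest.raises(ValueError, match="aligned"):
        psea.run_psea_models(shuffled, zero_noise_refs)
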