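"""Per-probeset deconvolution models: subset regression, AIC selection, QC.

Each probeset's bulk expression is regressed on subsets of the cell-type
reference signals (with intercept). All non-empty subsets of the usable cell
types are enumerated — at most 15 candidates with four populations — and the
minimum-AIC model is kept, with ties broken toward fewer regressors and then
the canonical cell-type order. Selected models must then clear quality
filters: overall F-test p < 0.05, adjusted R^2 > 0.6, Shapiro-Wilk residual
normality p > 0.01, |intercept| at most half the probeset's mean expression,
and no negative cell-type coefficients. Marker probesets themselves are
removed from the final tables.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import OlsFit, RankDeficientError, fit_ols
from .expression_io import ExpressionDataset, MarkerSet
from .reference import ReferenceSignals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualityThresholds:
    """Model quality gates with their standard defaults."""

    f_alpha: float = 0.05
    min_adj_r2: float = 0.6
    shapiro_alpha: float = 0.01
    #: |intercept| must not exceed this fraction of the mean expression
    intercept_fraction: float = 0.5
    require_nonnegative_coefficients: bool = True


@dataclass
class PseaModel:
    """A selected per-probeset expression model and its diagnostics."""

    probeset_id: str
    gene: str | None
    regressors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    aic: float
    f_pvalue: float
    adj_r2: float
    shapiro_pvalue: float
    mean_expression: float
    fit: OlsFit | None = None
    pass_flags: dict[str, bool] = field(default_factory=dict)
    overall_pass: bool = False

    def coefficient(self, cell_type: str) -> float:
        return float(self.coefficients[self.regressors.index(cell_type)])


def shapiro_pvalue(residuals: np.ndarray, scale: float = 1.0) -> float:
    """Shapiro-Wilk normality p-value, treating an exact fit as passing.

    Residuals that are zero to machine precision (relative to ``scale``)
    carry no evidence against normality; the test itself would reject its
    own numerical noise there.
    """
    resid = np.asarray(residuals, dtype=float)
    if np.ptp(resid) <= 1e-9 * max(abs(scale), 1.0):
        return 1.0
    return float(stats.shapiro(resid).pvalue)


def select_model_aic(
    y: np.ndarray,
    refs: ReferenceSignals,
    candidate_types: list[str] | None = None,
) -> PseaModel:
    """Select the minimum-AIC regressor subset for one probeset.

    Candidates are all non-empty subsets of ``candidate_types`` (default: all
    reference columns), enumerated by increasing size and canonical order so
    that exact AIC ties resolve to the smaller, earlier subset.
    """
    y = np.asarray(y, dtype=float)
    types = list(candidate_types) if candidate_types is not None else refs.cell_types
    if not types:
        raise ValueError("no usable reference signals to select from")
    best: tuple[float, tuple[str, ...], OlsFit] | None = None
    for size in range(1, len(types) + 1):
        for subset in itertools.combinations(types, size):
            X = refs.signals[list(subset)].to_numpy()
            try:
                fit = fit_ols(y, X)
            except RankDeficientError:
                continue
            if best is None or fit.aic < best[0]:
                best = (fit.aic, subset, fit)
    if best is None:
        raise RankDeficientError("no candidate model could be fitted")
    aic, subset, fit = best
    mean_expr = float(np.mean(y))
    return PseaModel(
        probeset_id="",
        gene=None,
        regressors=subset,
        intercept=fit.intercept,
        coefficients=fit.coefficients,
        aic=aic,
        f_pvalue=fit.f_pvalue,
        adj_r2=fit.adj_r2,
        shapiro_pvalue=shapiro_pvalue(fit.residuals, scale=mean_expr),
        mean_expression=mean_expr,
        fit=fit,
    )


def apply_quality_filters(
    model: PseaModel, thresholds: QualityThresholds = QualityThresholds()
) -> PseaModel:
    """Attach per-criterion pass flags and the overall verdict to a model."""
    flags = {
        "f_test": model.f_pvalue < thresholds.f_alpha,
        "adj_r2": model.adj_r2 > thresholds.min_adj_r2,
        "shapiro": model.shapiro_pvalue > thresholds.shapiro_alpha,
        "intercept": abs(model.intercept)
        <= thresholds.intercept_fraction * model.mean_expression,
        "coefficient_sign": (
            bool(np.min(model.coefficients) >= 0)
            if thresholds.require_nonnegative_coefficients
            else True
        ),
    }
    return replace(model, pass_flags=flags, overall_pass=all(flags.values()))


@dataclass
class PseaModelCollection:
    """All fitted models plus per-stage bookkeeping counts."""

    models: dict[str, PseaModel]
    skipped: dict[str, str]
    stage_counts: dict[str, int]
    thresholds: QualityThresholds

    def passing(self) -> dict[str, PseaModel]:
        return {p: m for p, m in self.models.items() if m.overall_pass}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models.values():
            row = {
                "probeset_id": m.probeset_id,
                "gene": m.gene,
                "regressors": "+".join(m.regressors),
                "intercept": m.intercept,
                "aic": m.aic,
                "f_pvalue": m.f_pvalue,
                "adj_r2": m.adj_r2,
                "shapiro_pvalue": m.shapiro_pvalue,
                "mean_expression": m.mean_expression,
                "overall_pass": m.overall_pass,
            }
            for ct in m.regressors:
                row[f"coef_{ct}"] = m.coefficient(ct)
            for name, ok in m.pass_flags.items():
                row[f"pass_{name}"] = ok
            rows.append(row)
        return pd.DataFrame(rows)


def run_psea_models(
    dataset: ExpressionDataset,
    refs: ReferenceSignals,
    markers: MarkerSet | None = None,
    thresholds: QualityThresholds = QualityThresholds(),
    candidate_types: list[str] | None = None,
) -> PseaModelCollection:
    """Fit, select and quality-filter models for every non-marker probeset.

    Marker probesets (the ingredients of the reference signals) are removed
    from the output. Zero-variance probesets are skipped with a recorded
    reason. Per-stage counts (input, fitted, passing) are logged.
    """
    if list(dataset.values.columns) != list(refs.signals.index):
        raise ValueError("dataset and reference signals are not sample-aligned")
    marker_probesets = set(markers.all_probesets()) if markers is not None else set()

    models: dict[str, PseaModel] = {}
    skipped: dict[str, str] = {}
    n_input = 0
    values = dataset.values
    for probeset in values.index:
        if probeset in marker_probesets:
            continue
        n_input += 1
        y = values.loc[probeset].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            skipped[probeset] = "zero variance"
            continue
        try:
            model = select_model_aic(y, refs, candidate_types=candidate_types)
        except RankDeficientError as exc:
            skipped[probeset] = f"unfittable: {exc}"
            continue
        model.probeset_id = probeset
        model.gene = dataset.gene_of(probeset)
        models[probeset] = apply_quality_filters(model, thresholds)

    n_pass = sum(m.overall_pass for m in models.values())
    stage_counts = {
        "probesets_in": n_input,
        "models_fitted": len(models),
        "models_passing": n_pass,
        "skipped": len(skipped),
    }
    logger.info(
        "PSEA models: %d probesets in, %d fitted, %d passing, %d skipped",
        n_input, len(models), n_pass, len(skipped),
    )
    return PseaModelCollection(
        models=models, skipped=skipped, stage_counts=stage_counts,
        thresholds=thresholds,
    )
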