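"""Single-cell-type analysis for tissues with degenerate reference signals.

When some reference signals are unreliable (e.g. astrocyte and
oligodendrocyte markers decorrelated, as happens in basal-ganglia tissue),
fitting four-population models risks misassigning expression. This mode
restricts the analysis to probesets whose expression tracks exactly one cell
population — Pearson correlation above a high threshold with one reference
signal and below a low threshold with the other three — and fits
single-regressor models (intercept + reference + auxiliary term) for the
cell types that do have trustworthy signals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ols import RankDeficientError, fit_ols
from .de import DeTable, run_psea_de
from .expression_io import ExpressionDataset, MarkerSet
from .models import (
    PseaModel,
    QualityThresholds,
    apply_quality_filters,
    shapiro_pvalue,
)
from .reference import ReferenceSignals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenThresholds:
    """Correlation gates for exclusive single-cell-type expression."""

    high: float = 0.8
    low: float = 0.2
    #: apply the low rule to |r| instead of signed r
    use_abs_low: bool = False


def screen_single_type(
    dataset: ExpressionDataset,
    refs: ReferenceSignals,
    thresholds: ScreenThresholds = ScreenThresholds(),
    exclude: MarkerSet | None = None,
) -> pd.DataFrame:
    """Correlate every probeset with all reference signals and assign types.

    A probeset is assigned to a cell type iff its correlation with that
    type's signal exceeds ``high`` while its correlations with every other
    signal stay below ``low`` (signed by default). Screening uses all
    available signals, including ones not trusted for modeling: exclusivity
    must hold against every population. Returns one row per probeset with the
    correlations, the assigned type (or None) and a reason when unassigned.
    """
    marker_probesets = set(exclude.all_probesets()) if exclude is not None else set()
    types = refs.cell_types
    ref_mat = refs.signals.to_numpy()  # samples x types
    rows = []
    for probeset in dataset.values.index:
        if probeset in marker_probesets:
            continue
        y = dataset.values.loc[probeset].to_numpy(dtype=float)
        row: dict[str, object] = {"probeset_id": probeset}
        if np.std(y) == 0:
            for ct in types:
                row[f"r_{ct}"] = np.nan
            row["assigned_type"] = None
            row["reason"] = "zero variance"
            rows.append(row)
            continue
        rs = {}
        for j, ct in enumerate(types):
            rs[ct] = float(np.corrcoef(y, ref_mat[:, j])[0, 1])
            row[f"r_{ct}"] = rs[ct]
        low_r = (lambda r: abs(r)) if thresholds.use_abs_low else (lambda r: r)
        candidates = [
            ct
            for ct in types
            if rs[ct] > thresholds.high
            and all(low_r(rs[o]) < thresholds.low for o in types if o != ct)
        ]
        if len(candidates) == 1:
            row["assigned_type"] = candidates[0]
            row["reason"] = ""
        else:
            row["assigned_type"] = None
            row["reason"] = (
                "no exclusive correlation" if not candidates else "ambiguous"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_single_type_psea(
    dataset: ExpressionDataset,
    refs: ReferenceSignals,
    groups: pd.Series | None = None,
    target_types: list[str] | None = None,
    markers: MarkerSet | None = None,
    screen_thresholds: ScreenThresholds = ScreenThresholds(),
    quality: QualityThresholds = QualityThresholds(),
    alpha: float = 0.05,
    screen: pd.DataFrame | None = None,
) -> DeTable:
    """Screen, fit single-regressor models, and test differential expression.

    ``target_types`` restricts modeling to cell types with trustworthy
    reference signals (e.g. neurons and microglia); screened probesets
    assigned to other types are left out. Quality filters and the auxiliary
    test are identical to the full analysis.
    """
    if groups is None:
        groups = dataset.groups
    if target_types is None:
        target_types = refs.cell_types
    unknown = set(target_types) - set(refs.cell_types)
    if unknown:
        raise ValueError(f"target types without reference signals: {sorted(unknown)}")
    if screen is None:
        screen = screen_single_type(
            dataset, refs, thresholds=screen_thresholds, exclude=markers
        )

    models: dict[str, PseaModel] = {}
    assigned = screen[screen["assigned_type"].notna()]
    for _, row in assigned.iterrows():
        ct = row["assigned_type"]
        if ct not in target_types:
            continue
        probeset = row["probeset_id"]
        y = dataset.values.loc[probeset].to_numpy(dtype=float)
        try:
            fit = fit_ols(y, refs.signals[[ct]].to_numpy())
        except RankDeficientError:
            continue
        mean_expr = float(np.mean(y))
        model = PseaModel(
            probeset_id=probeset,
            gene=dataset.gene_of(probeset),
            regressors=(ct,),
            intercept=fit.intercept,
            coefficients=fit.coefficients,
            aic=fit.aic,
            f_pvalue=fit.f_pvalue,
            adj_r2=fit.adj_r2,
            shapiro_pvalue=shapiro_pvalue(fit.residuals, scale=mean_expr),
            mean_expression=mean_expr,
            fit=fit,
        )
        # Quality flags are recorded but, as in the full analysis, the DE
        # gate is the re-assessed augmented model: an interaction-free base
        # fit cannot be good for genes with a real disease slope change.
        models[probeset] = apply_quality_filters(model, quality)

    n_pass = sum(m.overall_pass for m in models.values())
    logger.info(
        "single-cell-type mode: %d probesets assigned, %d base models passing",
        len(assigned), n_pass,
    )
    return run_psea_de(models, dataset, refs, groups, alpha=alpha, thresholds=quality)


def concordance_with_standard(
    std_results: pd.DataFrame, alt_results: pd.DataFrame
) -> dict[str, float]:
    """Fraction of standard-mode DE probesets also found by the alternative.

    Computed on probeset ids: ``|std ∩ alt| / |std|``, pooled and per cell
    type (a probeset counts as shared per cell type when both tables call it
    in that type). An empty standard table gives NaN (undefined).
    """
    out: dict[str, float] = {}
    std_ids = set(std_results["probeset_id"]) if len(std_results) else set()
    alt_ids = set(alt_results["probeset_id"]) if len(alt_results) else set()
    out["pooled"] = len(std_ids & alt_ids) / len(std_ids) if std_ids else np.nan
    if len(std_results) and "cell_type" in std_results.columns:
        for ct, sub in std_results.groupby("cell_type"):
            s = set(sub["probeset_id"])
            if len(alt_results) and "cell_type" in alt_results.columns:
                a = set(alt_results.loc[alt_results["cell_type"] == ct, "probeset_id"])
            else:
                a = set()
            out[ct] = len(s & a) / len(s) if s else np.nan
    return out
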