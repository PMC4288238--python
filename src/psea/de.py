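"""Cell-type-specific differential expression via auxiliary regressors.

For each selected model and each cell type in it, an interaction column is
added: the cell type's reference signal on disease samples and zero on
controls. In the augmented fit the original coefficient is the cell-type-
specific expression in controls, the auxiliary coefficient is the disease-
associated change, and their sum is the specific expression in disease. The
auxiliary terms are added one at a time, the augmented model's quality is
re-assessed, and results are ranked by the auxiliary coefficient's t-test
p-value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._ols import RankDeficientError, fit_ols
from .expression_io import DISEASE, ExpressionDataset
from .models import (
    PseaModel,
    PseaModelCollection,
    QualityThresholds,
    shapiro_pvalue,
)
from .reference import ReferenceSignals

logger = logging.getLogger(__name__)


@dataclass
class DeResult:
    """Differential expression of one probeset in one cell type."""

    probeset_id: str
    gene: str | None
    cell_type: str
    control_coef: float
    aux_coef: float
    aux_pvalue: float
    log2_fold_change: float      # NaN when either slope is non-positive
    fold_change_defined: bool
    model_requality_pass: bool
    requality_flags: dict[str, bool] = field(default_factory=dict)
    fdr: float = np.nan
    untestable: bool = False
    reason: str = ""

    @property
    def disease_coef(self) -> float:
        """Specific expression in disease: control slope plus the change."""
        return self.control_coef + self.aux_coef

    @property
    def direction(self) -> str:
        if not np.isfinite(self.aux_coef) or self.aux_coef == 0:
            return "none"
        return "up" if self.aux_coef > 0 else "down"


def build_aux_regressor(ref_column: np.ndarray, groups: pd.Series | np.ndarray) -> np.ndarray:
    """Interaction column: reference signal on disease samples, zero elsewhere.

    The nonzero entries carry the reference-signal values (not 1s): the
    auxiliary coefficient is then a slope change, so control slope plus
    auxiliary coefficient equals the disease slope.
    """
    ref = np.asarray(ref_column, dtype=float)
    grp = np.asarray(groups)
    if ref.shape != grp.shape:
        raise ValueError("reference column and groups are not aligned")
    return np.where(grp == DISEASE, ref, 0.0)


def test_differential(
    model: PseaModel,
    cell_type: str,
    y: np.ndarray,
    refs: ReferenceSignals,
    groups: pd.Series,
    thresholds: QualityThresholds = QualityThresholds(),
) -> DeResult:
    """Add one auxiliary regressor to a selected model and test its coefficient.

    The p-value is the two-sided t-test on the auxiliary coefficient. Quality
    filters are re-applied to the augmented model, with the non-negativity
    rule on the interrogated cell type's control coefficient and on its
    implied disease slope (control + auxiliary); the auxiliary coefficient
    itself may be negative (down-regulation requires it).
    """
    if cell_type not in model.regressors:
        raise ValueError(f"{cell_type} is not a regressor of {model.probeset_id}")
    y = np.asarray(y, dtype=float)
    X = refs.signals[list(model.regressors)].to_numpy()
    aux = build_aux_regressor(refs.column(cell_type), groups.to_numpy())
    blank = dict(
        probeset_id=model.probeset_id, gene=model.gene, cell_type=cell_type,
        control_coef=np.nan, aux_coef=np.nan, aux_pvalue=np.nan,
        log2_fold_change=np.nan, fold_change_defined=False,
        model_requality_pass=False,
    )
    if np.ptp(aux) == 0:
        return DeResult(**blank, untestable=True, reason="degenerate auxiliary "
                        "regressor (no disease samples or zero reference)")
    try:
        fit = fit_ols(y, np.column_stack([X, aux]))
    except RankDeficientError as exc:
        return DeResult(**blank, untestable=True, reason=f"collinear: {exc}")

    idx = model.regressors.index(cell_type)
    control_coef = float(fit.coefficients[idx])
    aux_coef = float(fit.coefficients[-1])
    aux_pvalue = float(fit.t_pvalues[-1])
    if fit.rss <= 1e-12 * max(fit.tss, 1.0):
        # Numerically exact fit: the t-test would be comparing float rounding
        # noise against a ~zero residual variance. The auxiliary effect is
        # then either exactly present or exactly absent.
        if abs(aux_coef) > 1e-8 * abs(control_coef) + 1e-12:
            aux_pvalue = 0.0
        else:
            aux_pvalue = 1.0
            aux_coef = 0.0

    disease_coef = control_coef + aux_coef
    defined = control_coef > 0 and disease_coef > 0
    log2fc = float(np.log2(disease_coef / control_coef)) if defined else np.nan

    # Sign rule in re-assessment: the interrogated cell type's control slope
    # and implied disease slope (control + aux) must be non-negative. The
    # auxiliary coefficient itself may be negative (down-regulation requires
    # it), and the other regressors' signs are not re-gated here — they were
    # checked at the base-model stage; after the interaction is added, tiny
    # sign flips of incidental regressors are fit noise, not evidence.
    flags = {
        "f_test": fit.f_pvalue < thresholds.f_alpha,
        "adj_r2": fit.adj_r2 > thresholds.min_adj_r2,
        "shapiro": shapiro_pvalue(fit.residuals, scale=model.mean_expression)
        > thresholds.shapiro_alpha,
        "intercept": abs(fit.intercept)
        <= thresholds.intercept_fraction * model.mean_expression,
        "coefficient_sign": (
            control_coef >= 0 and disease_coef >= 0
            if thresholds.require_nonnegative_coefficients
            else True
        ),
    }
    return DeResult(
        probeset_id=model.probeset_id,
        gene=model.gene,
        cell_type=cell_type,
        control_coef=control_coef,
        aux_coef=aux_coef,
        aux_pvalue=aux_pvalue,
        log2_fold_change=log2fc,
        fold_change_defined=defined,
        model_requality_pass=all(flags.values()),
        requality_flags=flags,
    )


@dataclass
class DeTable:
    """All auxiliary-regressor tests, plus the significant subset."""

    results: list[DeResult]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "probeset_id": r.probeset_id,
                "gene": r.gene,
                "cell_type": r.cell_type,
                "control_coef": r.control_coef,
                "aux_coef": r.aux_coef,
                "disease_coef": r.disease_coef,
                "aux_pvalue": r.aux_pvalue,
                "fdr": r.fdr,
                "log2_fold_change": r.log2_fold_change,
                "direction": r.direction,
                "requality_pass": r.model_requality_pass,
                "untestable": r.untestable,
            }
            for r in self.results
        ]
        columns = [
            "probeset_id", "gene", "cell_type", "control_coef", "aux_coef",
            "disease_coef", "aux_pvalue", "fdr", "log2_fold_change",
            "direction", "requality_pass", "untestable",
        ]
        df = pd.DataFrame(rows, columns=columns)
        if len(df):
            df = df.sort_values("aux_pvalue", kind="mergesort").reset_index(drop=True)
        return df

    def significant(self) -> pd.DataFrame:
        """Tests with p < alpha whose augmented model re-passed quality."""
        df = self.to_frame()
        if not len(df):
            return df
        keep = (df["aux_pvalue"] < self.alpha) & df["requality_pass"] & ~df["untestable"]
        return df[keep].reset_index(drop=True)

    def gene_summary(self) -> pd.DataFrame:
        """Unique differentially expressed gene symbols per cell type."""
        sig = self.significant()
        rows = []
        for ct, sub in sig.groupby("cell_type"):
            genes = sub["gene"].dropna().unique()
            rows.append(
                {"cell_type": ct, "n_probesets": len(sub), "n_genes": len(genes)}
            )
        return pd.DataFrame(rows)


def run_psea_de(
    models: PseaModelCollection | dict[str, PseaModel],
    dataset: ExpressionDataset,
    refs: ReferenceSignals,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
    thresholds: QualityThresholds | None = None,
    only_passing_models: bool = False,
) -> DeTable:
    """Test every (model, member cell type) pair for disease effects.

    Given a :class:`PseaModelCollection`, all AIC-selected models are tested
    by default: the quality gate for the DE table is the *re-assessed
    augmented* model (``requality_pass``), since a gene with a genuine
    disease slope change cannot fit the interaction-free base model well —
    gating on the base fit would exclude precisely the strongest effects.
    (The base-model quality flags still define which probesets count as
    reliable expression assignments.) Set ``only_passing_models`` to restrict
    testing to base-passing models.

    The headline filter is the unadjusted p < alpha, as is conventional for
    this analysis; Benjamini-Hochberg FDR over all testable pairs is reported
    alongside for transparency but not applied by default.
    """
    if isinstance(models, PseaModelCollection):
        if thresholds is None:
            thresholds = models.thresholds
        model_map = models.passing() if only_passing_models else models.models
    else:
        model_map = models
    if thresholds is None:
        thresholds = QualityThresholds()
    if groups is None:
        groups = dataset.groups

    results: list[DeResult] = []
    for probeset, model in model_map.items():
        y = dataset.values.loc[probeset].to_numpy(dtype=float)
        for ct in model.regressors:
            results.append(
                test_differential(model, ct, y, refs, groups, thresholds)
            )

    testable = [r for r in results if not r.untestable and np.isfinite(r.aux_pvalue)]
    if testable:
        fdrs = multipletests([r.aux_pvalue for r in testable], method="fdr_bh")[1]
        for r, q in zip(testable, fdrs):
            r.fdr = float(q)
    logger.info(
        "PSEA DE: %d tests, %d significant at p<%g",
        len(results), sum(r.aux_pvalue < alpha for r in testable), alpha,
    )
    return DeTable(results=results, alpha=alpha)
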