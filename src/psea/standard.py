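"""Standard two-group differential expression and the paired comparison.

This is the composition-naive baseline: per-probeset two-group tests on
log2-transformed bulk expression, with optional empirical-Bayes variance
moderation (the moderated t of the limma lineage) and Benjamini-Hochberg
FDR. Because bulk expression confounds per-cell expression with cell-type
abundance, genes of a shrinking population look "differentially expressed"
here even when their per-cell expression is stable — the contrast the paired
report is designed to expose.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .expression_io import CONTROL, DISEASE, ExpressionDataset
from .reference import ReferenceSignals

logger = logging.getLogger(__name__)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < 1e-10 * x:
            x = x_new
            break
        x = x_new
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a common prior.

    Fits a scaled inverse-chi-square prior to the observed sample variances
    by matching the moments of log s^2 and returns the posterior variances
    ``(d0*s0^2 + df*s2)/(d0 + df)`` together with the prior df ``d0`` and
    prior variance ``s0^2``. Zero variances are excluded from the moment fit.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


def run_standard_de(
    dataset: ExpressionDataset,
    groups: pd.Series | None = None,
    moderated: bool = True,
) -> pd.DataFrame:
    """Per-probeset two-group DE on log2(x+1) expression.

    With ``moderated`` (default), per-gene variances are shrunk by empirical
    Bayes and the t statistic uses the augmented degrees of freedom;
    otherwise this is the ordinary equal-variance two-sample t-test. Returns
    a frame with log2 fold change, t, p and BH FDR, sorted by p.
    """
    if groups is None:
        groups = dataset.groups
    ctrl = groups.index[groups == CONTROL]
    dis = groups.index[groups == DISEASE]
    if len(ctrl) < 2 or len(dis) < 2:
        raise ValueError("need at least 2 samples per group")

    logx = np.log2(dataset.values + 1.0)
    xc = logx[ctrl].to_numpy()
    xd = logx[dis].to_numpy()
    n1, n2 = xc.shape[1], xd.shape[1]
    df = n1 + n2 - 2

    logfc = xd.mean(axis=1) - xc.mean(axis=1)
    s2 = (
        (n1 - 1) * xc.var(axis=1, ddof=1) + (n2 - 1) * xd.var(axis=1, ddof=1)
    ) / df

    if moderated:
        s2_post, d0, _s02 = _squeeze_var(s2, df)
        df_total = df + d0
    else:
        s2_post = s2
        df_total = df

    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / denom
    # zero variance, zero difference: no evidence either way
    degenerate = (denom == 0) & (logfc == 0)
    t[degenerate] = 0.0
    df_eff = min(df_total, 1e6)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_eff)
    pvals[degenerate] = 1.0
    pvals[(denom == 0) & (logfc != 0)] = 0.0

    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "probeset_id": dataset.values.index,
            "gene": [dataset.gene_of(p) for p in dataset.values.index],
            "log2_fold_change": logfc,
            "t_statistic": t,
            "pvalue": pvals,
            "fdr": fdr,
            "zero_variance": denom == 0,
        }
    )
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


@dataclass
class PairedRecord:
    """One probeset's side-by-side deconvolved vs bulk DE verdict."""

    probeset_id: str
    gene: str | None
    cell_type: str | None
    psea_significant: bool
    psea_log2fc: float
    standard_significant: bool
    standard_log2fc: float
    classification: str


def paired_report(
    psea_results: pd.DataFrame,
    standard_results: pd.DataFrame,
    probesets: list[str] | None = None,
    alpha: float = 0.05,
    standard_use_fdr: bool = True,
) -> pd.DataFrame:
    """Classify probesets by agreement between deconvolved and bulk DE.

    ``psea_results`` is a significant DE table (one row per probeset/cell
    type); ``standard_results`` comes from :func:`run_standard_de`.
    Classes: ``concordant`` (both call it, same direction), ``psea_only``,
    ``standard_only``, ``sign_discordant`` (both call it, opposite
    directions), ``neither``.
    """
    std = standard_results.set_index("probeset_id")
    psea_by_probeset: dict[str, pd.Series] = {}
    if len(psea_results):
        for pid, sub in psea_results.groupby("probeset_id"):
            psea_by_probeset[pid] = sub.loc[sub["aux_pvalue"].idxmin()]
    if probesets is None:
        probesets = sorted(set(std.index) | set(psea_by_probeset))

    rows = []
    for pid in probesets:
        p_hit = pid in psea_by_probeset
        p_fc = float(psea_by_probeset[pid]["log2_fold_change"]) if p_hit else np.nan
        p_ct = psea_by_probeset[pid]["cell_type"] if p_hit else None
        gene = psea_by_probeset[pid]["gene"] if p_hit else None
        s_hit = False
        s_fc = np.nan
        if pid in std.index:
            row = std.loc[pid]
            gene = gene if gene is not None else row["gene"]
            s_fc = float(row["log2_fold_change"])
            crit = row["fdr"] if standard_use_fdr else row["pvalue"]
            s_hit = bool(crit < alpha)
        if p_hit and s_hit:
            same = np.sign(p_fc) == np.sign(s_fc) or not np.isfinite(p_fc)
            cls = "concordant" if same else "sign_discordant"
        elif p_hit:
            cls = "psea_only"
        elif s_hit:
            cls = "standard_only"
        else:
            cls = "neither"
        rows.append(
            PairedRecord(
                probeset_id=pid, gene=gene, cell_type=p_ct,
                psea_significant=p_hit, psea_log2fc=p_fc,
                standard_significant=s_hit, standard_log2fc=s_fc,
                classification=cls,
            ).__dict__
        )
    return pd.DataFrame(rows)


def plot_pair(
    probeset: str,
    cell_type: str,
    dataset: ExpressionDataset,
    refs: ReferenceSignals,
    path,
) -> None:
    """Regression plot (expression vs reference signal, per-group slopes)
    next to group box plots, for one probeset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = dataset.values.loc[probeset]
    x = refs.signals[cell_type]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    for grp, color in ((CONTROL, "black"), (DISEASE, "red")):
        mask = dataset.groups == grp
        xs, ys = x[mask.values], y[mask.values]
        ax1.scatter(xs, ys, s=18, color=color, label=grp)
        if xs.std() > 0:
            b, a = np.polyfit(xs, ys, 1)
            grid = np.linspace(xs.min(), xs.max(), 2)
            ax1.plot(grid, a + b * grid, color=color)
    ax1.set_xlabel(f"{cell_type} reference signal")
    ax1.set_ylabel("expression")
    ax1.set_title(probeset)
    ax1.legend(frameon=False, fontsize=8)
    ax2.boxplot(
        [y[(dataset.groups == g).values] for g in (CONTROL, DISEASE)],
        tick_labels=[CONTROL, DISEASE],
    )
    ax2.set_ylabel("expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
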