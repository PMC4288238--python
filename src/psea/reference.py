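"""Marker QC and construction of per-cell-type reference expression signals.

A reference signal is a per-sample proxy for a cell population's abundance:
each marker probeset is scaled to an across-sample mean of 100 (equal
weight), probesets of the same gene are averaged into a gene measure, and
gene measures are averaged into the cell-type signal. Marker quality control
checks that probesets of one type co-vary (mean pairwise Pearson r above a
threshold) while probesets of different types do not.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset, MarkerSet

logger = logging.getLogger(__name__)

TARGET_MEAN = 100.0


@dataclass
class MarkerQC:
    """Within- and between-type marker correlation report.

    ``within`` maps cell type -> mean pairwise Pearson correlation among its
    marker probesets; ``between`` is a cell type x cell type matrix of mean
    cross-type probeset correlations; ``usable`` flags types whose within
    score clears the threshold. ``excluded`` lists zero-variance probesets
    that were dropped from the means; ``failing_pairs`` lists between-type
    pairs exceeding the advisory threshold.
    """

    within: pd.Series
    between: pd.DataFrame
    usable: dict[str, bool]
    within_min: float
    between_max: float
    excluded: list[str] = field(default_factory=list)
    failing_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def usable_types(self) -> list[str]:
        return [ct for ct, ok in self.usable.items() if ok]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_type": ct,
                "within_mean_r": self.within.get(ct, np.nan),
                "usable": self.usable[ct],
            }
            for ct in self.usable
        ]
        return pd.DataFrame(rows)


@dataclass
class ReferenceSignals:
    """Sample x cell-type matrix of reference expression signals.

    Each column has an across-sample mean of 100 by construction (arbitrary
    normalized units). ``gene_measures`` maps cell type -> sample x gene
    matrix of the intermediate per-gene measures.
    """

    signals: pd.DataFrame
    gene_measures: dict[str, pd.DataFrame] = field(default_factory=dict)
    qc: MarkerQC | None = None

    @property
    def cell_types(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.index)

    def column(self, cell_type: str) -> np.ndarray:
        return self.signals[cell_type].to_numpy()


def _marker_matrix(dataset: ExpressionDataset, probesets: list[str]) -> pd.DataFrame:
    """Probeset x sample values for the given markers, dropping zero variance."""
    sub = dataset.values.loc[probesets]
    return sub


def qc_marker_correlations(
    dataset: ExpressionDataset,
    markers: MarkerSet,
    within_min: float = 0.5,
    between_max: float = 0.05,
    use_abs_between: bool = False,
) -> MarkerQC:
    """Score marker coherence within and across cell types.

    Within-type score: mean of pairwise Pearson correlations (across samples)
    among the type's marker probesets; a type is usable if this exceeds
    ``within_min``. Between-type score: mean pairwise correlation between the
    probesets of the two types, signed by default, compared against the
    advisory ``between_max`` (pairs above it are reported, not gated).
    Zero-variance probesets have undefined correlations and are excluded.
    """
    markers.check_against(dataset)
    excluded: list[str] = []
    warnings: list[str] = []
    series: dict[str, dict[str, np.ndarray]] = {}
    for ct in markers.cell_types:
        series[ct] = {}
        for probeset in markers.probesets(ct):
            v = dataset.values.loc[probeset].to_numpy(dtype=float)
            if np.std(v) == 0:
                excluded.append(probeset)
                warnings.append(f"{probeset} ({ct}): zero variance, excluded from QC")
                continue
            series[ct][probeset] = v

    within: dict[str, float] = {}
    usable: dict[str, bool] = {}
    for ct in markers.cell_types:
        vs = list(series[ct].values())
        if len(vs) < 2:
            within[ct] = np.nan
            usable[ct] = True  # vacuous pass: nothing to correlate
            warnings.append(
                f"{ct}: fewer than 2 usable marker probesets; within-type QC vacuous"
            )
            continue
        rs = [
            np.corrcoef(a, b)[0, 1] for a, b in itertools.combinations(vs, 2)
        ]
        within[ct] = float(np.mean(rs))
        usable[ct] = within[ct] > within_min

    types = markers.cell_types
    between = pd.DataFrame(np.nan, index=types, columns=types)
    failing: list[tuple[str, str, float]] = []
    for ct_a, ct_b in itertools.combinations(types, 2):
        rs = [
            np.corrcoef(a, b)[0, 1]
            for a in series[ct_a].values()
            for b in series[ct_b].values()
        ]
        if not rs:
            continue
        score = float(np.mean(np.abs(rs) if use_abs_between else rs))
        between.loc[ct_a, ct_b] = between.loc[ct_b, ct_a] = score
        if score >= between_max:
            failing.append((ct_a, ct_b, score))
            warnings.append(
                f"between-type correlation {ct_a}/{ct_b} = {score:.3f} "
                f">= {between_max} (advisory)"
            )
    for msg in warnings:
        logger.warning(msg)
    return MarkerQC(
        within=pd.Series(within),
        between=between,
        usable=usable,
        within_min=within_min,
        between_max=between_max,
        excluded=excluded,
        failing_pairs=failing,
        warnings=warnings,
    )


def build_reference_signals(
    dataset: ExpressionDataset,
    markers: MarkerSet,
    usable_only: bool = False,
    qc: MarkerQC | None = None,
) -> ReferenceSignals:
    """Build the sample x cell-type reference signal matrix.

    For each marker probeset, values are scaled so their across-sample mean
    is exactly 100; probesets sharing a gene symbol are averaged into a gene
    measure, and gene measures are averaged into the cell-type signal. With
    ``usable_only`` (requires ``qc``), cell types flagged unusable are
    omitted. All-zero probesets cannot be normalized and are dropped with a
    warning; a type whose probesets all drop has no column.
    """
    markers.check_against(dataset)
    if usable_only and qc is None:
        qc = qc_marker_correlations(dataset, markers)
    keep_types = markers.cell_types
    if usable_only:
        keep_types = [ct for ct in keep_types if qc.usable.get(ct, False)]

    columns: dict[str, pd.Series] = {}
    gene_measures: dict[str, pd.DataFrame] = {}
    for ct in keep_types:
        per_gene: dict[str, pd.Series] = {}
        for gene, probesets in markers.genes(ct).items():
            scaled = []
            for probeset in probesets:
                v = dataset.values.loc[probeset]
                m = v.mean()
                if m == 0:
                    logger.warning(
                        "marker %s (%s/%s) is all zero; cannot normalize, dropped",
                        probeset, ct, gene,
                    )
                    continue
                scaled.append(v * (TARGET_MEAN / m))
            if scaled:
                per_gene[gene] = pd.concat(scaled, axis=1).mean(axis=1)
        if not per_gene:
            logger.warning("cell type %s has no usable marker probesets; omitted", ct)
            continue
        gm = pd.DataFrame(per_gene)
        gene_measures[ct] = gm
        columns[ct] = gm.mean(axis=1)

    signals = pd.DataFrame(columns, index=dataset.values.columns)
    return ReferenceSignals(signals=signals, gene_measures=gene_measures, qc=qc)
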