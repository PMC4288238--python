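"""External corroboration of cell-type assignments and DE calls.

Two independent checks: (1) cell-type-resolved expression tables (e.g. from
sorted or affinity-purified cell populations, mapped across species by a
static ortholog table) are used to tally whether genes a model assigns to a
cell type are actually detected there; (2) independent DE tables (e.g. from
laser-microdissected neurons) are used to count genes called in the same
direction at significance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Expression threshold (arbitrary normalized units) above which a gene is
#: considered detected in a cell type.
DETECTION_THRESHOLD = 100.0


@dataclass
class CellTypeExpressionTable:
    """Gene symbol x cell type matrix of normalized expression units."""

    values: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("gene symbols must be unique (collapse duplicates first)")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression units must be non-negative")


@dataclass
class ExternalDeTable:
    """Independent per-gene DE statistics used for direction concordance."""

    table: pd.DataFrame  # columns: gene, pvalue, log_fold_change
    source: str = ""

    def __post_init__(self) -> None:
        req = {"gene", "pvalue", "log_fold_change"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"external DE table missing columns {sorted(missing)}")
        p = self.table["pvalue"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")


def map_orthologs(
    foreign_table: pd.DataFrame, ortholog_map: pd.Series, source: str = ""
) -> CellTypeExpressionTable:
    """Replace foreign (e.g. mouse probeset) row ids by gene symbols.

    Rows without a mapping are dropped (count logged); several foreign ids
    mapping to one symbol are collapsed by the maximum expression value.
    """
    if ortholog_map.empty:
        raise ValueError("ortholog map is empty")
    mapped = foreign_table.loc[foreign_table.index.isin(ortholog_map.index)].copy()
    n_dropped = len(foreign_table) - len(mapped)
    if n_dropped:
        logger.info("ortholog mapping dropped %d unmapped rows", n_dropped)
    mapped.index = ortholog_map.loc[mapped.index]
    collapsed = mapped.groupby(level=0).max()
    return CellTypeExpressionTable(values=collapsed, source=source)


def format_support(n_hit: int, n_total: int) -> str:
    """Render a support fraction as e.g. ``81% (210/259)``."""
    if n_total == 0:
        return "NA (0/0)"
    return f"{round(100 * n_hit / n_total)}% ({n_hit}/{n_total})"


def expression_assignments(models) -> pd.DataFrame:
    """(gene, cell type) pairs implied by passing expression models.

    A gene is taken as expressed in every cell type that appears among the
    regressors of any of its passing probeset models; probesets without a
    gene symbol are skipped (tallies are gene-level).
    """
    pairs = set()
    model_iter = models.passing().values() if hasattr(models, "passing") else models
    for m in model_iter:
        if m.gene is None:
            continue
        for ct in m.regressors:
            pairs.add((m.gene, ct))
    return pd.DataFrame(sorted(pairs), columns=["gene", "cell_type"])


def tally_expression_support(
    assignments: pd.DataFrame,
    table: CellTypeExpressionTable,
    threshold: float = DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Tally how often assigned genes are detected in their assigned type.

    For each cell type present in both the assignments and the expression
    table: the denominator is the number of assigned genes present in the
    table, the numerator the subset whose expression there exceeds
    ``threshold``. Empty overlap yields NaN.
    """
    rows = []
    for ct, sub in assignments.groupby("cell_type"):
        genes = sub["gene"].unique()
        if ct not in table.values.columns:
            continue
        present = [g for g in genes if g in table.values.index]
        hits = [g for g in present if table.values.loc[g, ct] > threshold]
        frac = len(hits) / len(present) if present else np.nan
        rows.append(
            {
                "cell_type": ct,
                "n_assigned": len(genes),
                "n_in_table": len(present),
                "n_supported": len(hits),
                "fraction": frac,
                "display": format_support(len(hits), len(present)),
                "source": table.source,
            }
        )
    return pd.DataFrame(rows)


def direction_concordance(
    psea_de: pd.DataFrame,
    externals: list[ExternalDeTable],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Check DE genes against independent studies for same-direction calls.

    A gene is validated by a source iff that source reports p < alpha and a
    fold change of the same sign as the deconvolved call; sources lacking a
    fold change for the gene cannot validate it. Returns the per-gene
    validation matrix and summary counts of genes validated in >= 1 and
    >= 2 sources.
    """
    genes = psea_de.dropna(subset=["gene"]).drop_duplicates("gene")
    rows = []
    for _, rec in genes.iterrows():
        gene = rec["gene"]
        sign = np.sign(rec["log2_fold_change"])
        row: dict[str, object] = {
            "gene": gene,
            "psea_pvalue": rec["aux_pvalue"],
            "psea_log2fc": rec["log2_fold_change"],
        }
        n_valid = 0
        for ext in externals:
            sub = ext.table[ext.table["gene"] == gene]
            ok = False
            if len(sub):
                hit = sub[
                    (sub["pvalue"] < alpha)
                    & sub["log_fold_change"].notna()
                    & (np.sign(sub["log_fold_change"]) == sign)
                ]
                ok = bool(len(hit))
            row[f"validated_{ext.source or 'source'}"] = ok
            n_valid += ok
        row["n_sources_validating"] = n_valid
        rows.append(row)
    matrix = pd.DataFrame(rows)
    summary = {
        "n_genes": len(matrix),
        "validated_ge1": int((matrix["n_sources_validating"] >= 1).sum()) if len(matrix) else 0,
        "validated_ge2": int((matrix["n_sources_validating"] >= 2).sum()) if len(matrix) else 0,
    }
    return matrix, summary
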