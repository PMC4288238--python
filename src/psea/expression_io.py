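"""Reading and writing expression matrices, sample metadata and marker sets.

Expression is handled on a *linear* scale throughout the deconvolution:
the mixing model is linear in cell abundance, so log-encoded input (common in
series-matrix exports) is detected and undone on load. Matrices are TSV with
probesets in rows and samples in columns; sample metadata is a two-column TSV
(``sample_id``, ``group``); marker sets are YAML keyed by cell type.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Canonical cell-type order used for model enumeration and tie-breaking.
DEFAULT_CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte", "microglia")

CONTROL = "control"
DISEASE = "disease"

#: Maximum value at or below which a matrix is assumed to be log2-encoded.
#: Linear microarray intensities are in the hundreds to tens of thousands,
#: while log2 intensities rarely exceed ~16.
LOG_SCALE_MAX = 30.0

#: Marker lists bundled with the package (curated brain cell-type markers
#: for Affymetrix U133 arrays, as used for cortical and basal-ganglia data).
BUNDLED_MARKER_SETS = ("hd_ba4", "pd_cortex", "pd_nigra_putamen")


class ExpressionIOError(ValueError):
    """Malformed or inconsistent expression input files."""


@dataclass
class ExpressionDataset:
    """A probeset x sample expression matrix with group labels.

    Attributes
    ----------
    values : DataFrame, probesets in rows, samples in columns, linear scale.
    groups : Series indexed by sample id with values ``control``/``disease``.
    gene_map : Series mapping probeset id -> gene symbol (may be incomplete).
    log_detected : True if the input looked log2-encoded and was exponentiated.
    """

    values: pd.DataFrame
    groups: pd.Series
    gene_map: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    log_detected: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicated probeset ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicated sample ids: {dups}")
        missing = self.values.columns.difference(self.groups.index)
        extra = self.groups.index.difference(self.values.columns)
        if len(missing) or len(extra):
            raise ExpressionIOError(
                "sample ids of matrix and metadata disagree: "
                f"missing from metadata {sorted(missing)}, "
                f"missing from matrix {sorted(extra)}"
            )
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - {CONTROL, DISEASE}
        if bad:
            raise ExpressionIOError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ExpressionIOError("expression matrix contains non-finite values")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionIOError("expression matrix contains negative values")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_of(self, probeset: str) -> str | None:
        g = self.gene_map.get(probeset)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            return None
        return str(g)


@dataclass
class MarkerSet:
    """Curated marker probesets per cell type, the seed of reference signals.

    ``markers`` maps cell type -> list of ``(probeset_id, gene_symbol)``.
    A probeset may appear under at most one cell type.
    """

    markers: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ct, entries in self.markers.items():
            for probeset, _gene in entries:
                if probeset in seen:
                    raise ExpressionIOError(
                        f"probeset {probeset} listed under both "
                        f"{seen[probeset]} and {ct}"
                    )
                seen[probeset] = ct

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    def probesets(self, cell_type: str) -> list[str]:
        return [p for p, _ in self.markers[cell_type]]

    def all_probesets(self) -> list[str]:
        return [p for entries in self.markers.values() for p, _ in entries]

    def genes(self, cell_type: str) -> dict[str, list[str]]:
        """Gene symbol -> probesets of that gene, within one cell type."""
        out: dict[str, list[str]] = {}
        for probeset, gene in self.markers[cell_type]:
            out.setdefault(gene, []).append(probeset)
        return out

    def check_against(self, dataset: ExpressionDataset) -> None:
        missing = [p for p in self.all_probesets() if p not in dataset.values.index]
        if missing:
            raise ExpressionIOError(
                f"marker probesets absent from dataset: {missing}"
            )


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read an expression matrix TSV plus sample metadata (and annotations).

    If every matrix value is below :data:`LOG_SCALE_MAX` the matrix is taken
    to be log2-encoded and is exponentiated; ``log_detected`` records this.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = None
    matrix.columns.name = None
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise ExpressionIOError(f"non-numeric cells in {matrix_path}: {exc}") from exc

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ExpressionIOError(
            f"{metadata_path} must have columns sample_id and group"
        )
    groups = meta.set_index("sample_id")["group"]

    log_detected = False
    if matrix.size and float(np.nanmax(matrix.to_numpy())) < LOG_SCALE_MAX:
        matrix = np.power(2.0, matrix)
        log_detected = True

    gene_map = pd.Series(dtype=object)
    if annotation_path is not None:
        gene_map = read_annotation(annotation_path)

    return ExpressionDataset(
        values=matrix, groups=groups, gene_map=gene_map, log_detected=log_detected
    )


def read_annotation(path: str | Path) -> pd.Series:
    """Read a static probeset -> gene symbol table (TSV, two columns)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(ann.columns)
    if len(cols) < 2:
        raise ExpressionIOError(f"{path}: annotation needs two columns")
    return ann.set_index(cols[0])[cols[1]]


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path,
                     metadata_path: str | Path,
                     annotation_path: str | Path | None = None) -> None:
    """Write a dataset back to TSV; round-trips through :func:`read_expression`."""
    dataset.values.to_csv(matrix_path, sep="\t", index_label="probeset_id")
    pd.DataFrame(
        {"sample_id": dataset.groups.index, "group": dataset.groups.values}
    ).to_csv(metadata_path, sep="\t", index=False)
    if annotation_path is not None and len(dataset.gene_map):
        pd.DataFrame(
            {
                "probeset_id": dataset.gene_map.index,
                "hgnc_symbol": dataset.gene_map.values,
            }
        ).to_csv(annotation_path, sep="\t", index=False)


def _marker_set_from_mapping(raw: dict) -> MarkerSet:
    markers: dict[str, list[tuple[str, str]]] = {}
    for cell_type, entries in raw.items():
        if isinstance(entries, dict):
            markers[cell_type] = [(str(p), str(g)) for p, g in entries.items()]
        else:
            markers[cell_type] = [(str(p), str(g)) for p, g in entries]
    return MarkerSet(markers)


def load_marker_set(source: str | Path) -> MarkerSet:
    """Load a marker set from a YAML file or by bundled name.

    Bundled names (:data:`BUNDLED_MARKER_SETS`) refer to curated marker lists
    for human brain tissue shipped with the package.
    """
    if isinstance(source, str) and source in BUNDLED_MARKER_SETS:
        ref = importlib.resources.files("psea") / "data" / f"{source}.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ExpressionIOError(f"marker file {source} is not a mapping")
    return _marker_set_from_mapping(raw)


def read_ortholog_map(path: str | Path) -> pd.Series:
    """Read a static foreign-id -> gene-symbol ortholog table (TSV)."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(tab.columns)
    if len(cols) < 2:
        raise ExpressionIOError(f"{path}: ortholog map needs two columns")
    return tab.set_index(cols[0])[cols[1]]
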