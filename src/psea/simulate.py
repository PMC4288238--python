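"""Synthetic heterogeneous-tissue expression with known ground truth.

The generator emulates bulk brain microarray data: each sample is a mixture
of four cell populations (neurons, astrocytes, oligodendrocytes, microglia)
whose latent abundances vary across samples and shift with disease — neuronal
loss accompanied by gliosis, the histopathological pattern of
neurodegeneration. Bulk expression of gene g in sample s is

    y_gs = sum_k a_sk * x_gk * e_gks + noise,

where ``a`` are per-sample abundances, ``x`` is cell-type-specific expression
per cell, and ``e`` is a disease fold change applied to chosen (gene, cell
type) pairs in disease samples only. Marker genes are expressed in exactly
one cell type, so reference signals built from them track abundance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression_io import (
    CONTROL,
    DEFAULT_CELL_TYPES,
    DISEASE,
    ExpressionDataset,
    MarkerSet,
    write_expression,
)


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


#: Disease composition shift typical of neurodegeneration: neuronal loss
#: (here a 40% abundance decrease) accompanied by gliosis. Multiplies the
#: control abundance means in disease samples.
NEURODEGENERATION_SHIFTS = {
    "neuron": 0.6,
    "astrocyte": 1.5,
    "oligodendrocyte": 1.2,
    "microglia": 1.4,
}


@dataclass
class SimulationConfig:
    """Study design and generative parameters for a synthetic mixture.

    Defaults describe a cortical case/control cohort: 16 control and 18
    disease samples, four cell populations with stable composition across
    groups, per-sample abundance variability of CV 0.3, and 2000 genes of
    which 16 (4 per cell type) are single-cell-type markers. Disease-related
    composition change (neuronal loss, gliosis) is opted into via
    ``abundance_shift_disease`` (see :data:`NEURODEGENERATION_SHIFTS`).
    """

    n_control: int = 16
    n_disease: int = 18
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    abundance_means_control: dict[str, float] = field(
        default_factory=lambda: {
            "neuron": 1.0,
            "astrocyte": 0.5,
            "oligodendrocyte": 0.6,
            "microglia": 0.3,
        }
    )
    #: multiplicative disease shift of the abundance means; 1.0 = stable
    #: composition. Use :data:`NEURODEGENERATION_SHIFTS` for the
    #: neuronal-loss-with-gliosis pattern.
    abundance_shift_disease: dict[str, float] = field(
        default_factory=lambda: {
            "neuron": 1.0,
            "astrocyte": 1.0,
            "oligodendrocyte": 1.0,
            "microglia": 1.0,
        }
    )
    abundance_cv: float = 0.3
    n_genes: int = 2000
    n_markers_per_type: int = 4
    expression_level_range: tuple[float, float] = (50.0, 500.0)
    #: probability that a non-marker gene is expressed in 1, 2, 3, 4 types
    support_size_probs: tuple[float, ...] = (0.55, 0.25, 0.12, 0.08)
    #: disease effects: (gene_symbol, cell_type, fold_change)
    effect_table: tuple[tuple[str, str, float], ...] = ()
    noise_sd_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_control <= 0 or self.n_disease <= 0:
            raise SimulationConfigError("sample counts must be positive")
        if not 1 <= len(self.cell_types) <= 4:
            raise SimulationConfigError("between 1 and 4 cell types supported")
        if self.n_genes <= 0:
            raise SimulationConfigError("n_genes must be positive")
        if self.n_markers_per_type <= 0:
            raise SimulationConfigError("n_markers_per_type must be positive")
        if self.n_markers_per_type * len(self.cell_types) > self.n_genes:
            raise SimulationConfigError("more markers requested than genes")
        lo, hi = self.expression_level_range
        if not (0 < lo <= hi):
            raise SimulationConfigError("expression_level_range must be positive")
        if self.abundance_cv <= 0:
            raise SimulationConfigError("abundance_cv must be positive")
        if self.noise_sd_fraction < 0:
            raise SimulationConfigError("noise_sd_fraction must be >= 0")
        for ct in self.cell_types:
            m = self.abundance_means_control.get(ct)
            if m is None or m <= 0:
                raise SimulationConfigError(f"abundance mean for {ct} must be > 0")
            if self.abundance_shift_disease.get(ct, 1.0) <= 0:
                raise SimulationConfigError(f"abundance shift for {ct} must be > 0")
        for gene, ct, fold in self.effect_table:
            if fold <= 0:
                raise SimulationConfigError(f"fold change for {gene} must be > 0")
            if ct not in self.cell_types:
                raise SimulationConfigError(f"effect cell type {ct} unknown")
            if gene.startswith("MK_"):
                raise SimulationConfigError(
                    f"effect on marker gene {gene}: markers must stay stable"
                )


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated dataset.

    ``abundances`` is sample x cell type; ``base_expression`` is gene x cell
    type (per-cell expression, zero outside a gene's support set);
    ``applied_effects`` lists the realized (gene, cell type, fold) disease
    effects; ``markers`` names the designated single-cell-type marker genes.
    """

    abundances: pd.DataFrame
    base_expression: pd.DataFrame
    applied_effects: tuple[tuple[str, str, float], ...]
    markers: MarkerSet
    probeset_of_gene: pd.Series

    def expected_signal(self, groups: pd.Series) -> pd.DataFrame:
        """Noise-free bulk expression implied by the latent quantities."""
        a = self.abundances.to_numpy()          # samples x types
        x = self.base_expression.to_numpy()     # genes x types
        signal = np.repeat(x[None, :, :], a.shape[0], axis=0)  # s x g x k
        diseased = (groups.loc[self.abundances.index] == DISEASE).to_numpy()
        types = list(self.base_expression.columns)
        genes = self.base_expression.index
        for gene, ct, fold in self.applied_effects:
            gi = genes.get_loc(gene)
            ki = types.index(ct)
            signal[diseased, gi, ki] *= fold
        bulk = np.einsum("sk,sgk->gs", a, signal)
        return pd.DataFrame(
            bulk, index=self.probeset_of_gene.loc[genes].values,
            columns=self.abundances.index,
        )


def _marker_gene_name(cell_type: str, i: int) -> str:
    return f"MK_{cell_type[:5].upper()}_{i + 1}"


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a synthetic mixed-tissue dataset; deterministic given the seed.

    Abundances are Gamma-distributed per sample (mean from the config, CV
    ``abundance_cv``; the disease shift multiplies the mean), guaranteeing
    positivity with realistic right skew. Additive Gaussian noise has sd
    ``noise_sd_fraction`` times the expected signal, and bulk values are
    truncated at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = list(config.cell_types)
    k = len(types)

    sample_ids = [f"C{i + 1:02d}" for i in range(config.n_control)] + [
        f"D{i + 1:02d}" for i in range(config.n_disease)
    ]
    groups = pd.Series(
        [CONTROL] * config.n_control + [DISEASE] * config.n_disease,
        index=sample_ids, name="group",
    )

    # Per-sample latent abundances: Gamma(shape=1/cv^2, scale=mean*cv^2).
    shape = 1.0 / config.abundance_cv**2
    abund = np.empty((len(sample_ids), k))
    for j, ct in enumerate(types):
        mean = np.full(len(sample_ids), config.abundance_means_control[ct])
        mean[config.n_control:] *= config.abundance_shift_disease.get(ct, 1.0)
        abund[:, j] = rng.gamma(shape, mean * config.abundance_cv**2)
    abundances = pd.DataFrame(abund, index=sample_ids, columns=types)

    # Gene roster: markers first (one probeset per marker gene), then bulk genes.
    marker_entries: dict[str, list[tuple[str, str]]] = {ct: [] for ct in types}
    gene_symbols: list[str] = []
    probeset_ids: list[str] = []
    for ct in types:
        for i in range(config.n_markers_per_type):
            gene = _marker_gene_name(ct, i)
            probeset = f"{gene}_at"
            marker_entries[ct].append((probeset, gene))
            gene_symbols.append(gene)
            probeset_ids.append(probeset)
    n_other = config.n_genes - len(gene_symbols)
    for i in range(n_other):
        gene_symbols.append(f"G{i + 1:05d}")
        probeset_ids.append(f"G{i + 1:05d}_at")

    lo, hi = config.expression_level_range
    base = np.zeros((config.n_genes, k))
    n_markers = config.n_markers_per_type * k
    for idx in range(n_markers):
        base[idx, idx // config.n_markers_per_type] = rng.uniform(lo, hi)

    # Non-marker genes: support set of 1-4 cell types, uniform levels within.
    probs = np.asarray(config.support_size_probs[:k], dtype=float)
    probs = probs / probs.sum()
    forced = {}
    for gene, ct, _fold in config.effect_table:
        forced.setdefault(gene, set()).add(types.index(ct))
    for idx in range(n_markers, config.n_genes):
        size = rng.choice(np.arange(1, k + 1), p=probs)
        support = set(rng.choice(k, size=size, replace=False).tolist())
        support |= forced.get(gene_symbols[idx], set())
        for j in support:
            base[idx, j] = rng.uniform(lo, hi)

    base_expression = pd.DataFrame(base, index=gene_symbols, columns=types)
    probeset_of_gene = pd.Series(probeset_ids, index=gene_symbols)

    truth = GroundTruth(
        abundances=abundances,
        base_expression=base_expression,
        applied_effects=tuple(config.effect_table),
        markers=MarkerSet(marker_entries),
        probeset_of_gene=probeset_of_gene,
    )

    signal = truth.expected_signal(groups).to_numpy()
    if config.noise_sd_fraction > 0:
        # Homoskedastic per gene: sd is a fraction of the gene's expected
        # signal level, constant across samples. This matches the Gaussian
        # iid-residual model the downstream regressions assume (and gate on
        # via the Shapiro test).
        sd = config.noise_sd_fraction * signal.mean(axis=1, keepdims=True)
        noise = rng.normal(0.0, 1.0, size=signal.shape) * sd
        values = np.clip(signal + noise, 0.0, None)
    else:
        values = np.clip(signal, 0.0, None)

    dataset = ExpressionDataset(
        values=pd.DataFrame(values, index=probeset_ids, columns=sample_ids),
        groups=groups,
        gene_map=pd.Series(gene_symbols, index=probeset_ids),
    )
    return dataset, truth


def write_fixture(dataset: ExpressionDataset, truth: GroundTruth,
                  outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset and its ground truth as plain TSV/YAML files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression.tsv",
        "metadata": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "markers": outdir / "markers.yaml",
        "abundances": outdir / "truth_abundances.tsv",
        "base_expression": outdir / "truth_base_expression.tsv",
        "effects": outdir / "truth_effects.tsv",
    }
    write_expression(dataset, paths["matrix"], paths["metadata"], paths["annotation"])
    with open(paths["markers"], "w") as fh:
        yaml.safe_dump(
            {ct: {p: g for p, g in entries} for ct, entries in truth.markers.markers.items()},
            fh, sort_keys=False,
        )
    truth.abundances.to_csv(paths["abundances"], sep="\t", index_label="sample_id")
    truth.base_expression.to_csv(
        paths["base_expression"], sep="\t", index_label="gene"
    )
    pd.DataFrame(
        truth.applied_effects, columns=["gene", "cell_type", "fold_change"]
    ).to_csv(paths["effects"], sep="\t", index=False)
    return paths
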