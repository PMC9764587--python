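"""Synthetic cohort generator with planted effects.

Emulates a nine-donor lung cohort stratified by disease (COPD vs control),
age (old vs young) and smoking (active smoker vs never-smoker): three COPD
patients (all old), three old controls and three young controls, with four
active smokers and five never-smokers overall. UMI counts are negative
binomial per gene with a lognormal per-cell library-size factor.

Three kinds of effects can be planted, each recorded in a ground-truth
ledger so downstream recovery can be scored:

* condition-specific DEGs — a multiplicative ``2**log2fc`` shift of the NB
  mean of one gene, in one cell type, in the cells of individuals carrying
  the condition;
* ligand--receptor up-regulation — the ligand shifted in the sender cell
  type and the receptor in the receiver cell type, again restricted to the
  condition's individuals;
* latent cross-individual modules — a scalar ``u_i ~ Normal(0, 1)`` per
  individual scales focal genes in a sender cell type and target genes in a
  receiver cell type by ``2**(gamma * u_i)``, inducing the cross-individual
  pseudobulk correlation the crosstalk procedure looks for.

A configurable fraction of cells is drawn to fail QC (fewer than 301
expressed genes, or mitochondrial fraction above 30%) to exercise the
filter boundaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "PlantedDEG",
    "PlantedLRPair",
    "LatentModule",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_CELL_TYPES",
]

DEFAULT_CELL_TYPES = (
    "macrophage",
    "dendritic_cell",
    "monocyte",
    "mast_cell",
    "neutrophil",
    "NK_cell",
    "T_cell",
    "B_cell",
    "AT1",
    "AT2",
    "club_cell",
    "ciliated_cell",
    "stromal_cell",
    "endothelial_cell",
    "proliferating_cell",
)

CONDITIONS = ("disease", "aging", "smoking")


@dataclass(frozen=True)
class PlantedDEG:
    gene: str
    cell_type: str
    condition: str  # disease | aging | smoking
    log2fc: float


@dataclass(frozen=True)
class PlantedLRPair:
    ligand: str
    receptor: str
    sender_ct: str
    receiver_ct: str
    condition: str
    log2fc: float


@dataclass(frozen=True)
class LatentModule:
    sender_ct: str
    focal_genes: tuple
    receiver_ct: str
    target_genes: tuple
    gamma: float


def _default_individuals() -> pd.DataFrame:
    # 3 COPD (2 AS / 1 NS, all old), 3 old controls (2 AS / 1 NS),
    # 3 young controls (all NS): 4 active smokers, 5 never-smokers.
    rows = [
        ("COPD_1", "COPD", "old", "AS"),
        ("COPD_2", "COPD", "old", "AS"),
        ("COPD_3", "COPD", "old", "NS"),
        ("CO_1", "control", "old", "AS"),
        ("CO_2", "control", "old", "AS"),
        ("CO_3", "control", "old", "NS"),
        ("CY_1", "control", "young", "NS"),
        ("CY_2", "control", "young", "NS"),
        ("CY_3", "control", "young", "NS"),
    ]
    return pd.DataFrame(rows, columns=["individual", "disease", "age_group", "smoking"])


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study design: nine individuals in three groups,
    15 lung cell types, ~1,200 genes of which 12 are mitochondrial.
    """

    individuals: pd.DataFrame = field(default_factory=_default_individuals)
    cell_types: tuple = DEFAULT_CELL_TYPES
    cells_per_type_per_individual: tuple = (40, 60)  # inclusive range
    n_genes: int = 1200
    n_mito: int = 12
    mito_prefix: str = "MT-"
    baseline_log_mean: float = np.log(0.8)
    baseline_log_sd: float = 1.0
    mito_mean_scale: float = 8.0
    dispersion: float = 2.0  # NB size parameter theta; var = m + m^2/theta
    libsize_log_sd: float = 0.3
    planted_degs: list = field(default_factory=list)
    planted_lr_pairs: list = field(default_factory=list)
    latent_modules: list = field(default_factory=list)
    qc_failure_fraction: float = 0.0
    seed: int = 0

    def gene_names(self) -> list:
        mito = [f"{self.mito_prefix}G{i + 1}" for i in range(self.n_mito)]
        rest = [f"G{i + 1:05d}" for i in range(self.n_genes - self.n_mito)]
        return mito + rest

    def validate(self) -> None:
        genes = set(self.gene_names())
        cts = set(self.cell_types)
        if not 0 <= self.qc_failure_fraction < 1:
            raise ValueError("qc_failure_fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_mito < 0 or self.n_mito > self.n_genes:
            raise ValueError("n_mito must be within [0, n_genes]")
        lo, hi = self.cells_per_type_per_individual
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_type_per_individual must be a valid range")
        for p in self.planted_degs:
            if p.gene not in genes:
                raise ValueError(f"planted DEG gene {p.gene!r} not in gene universe")
            if p.cell_type not in cts:
                raise ValueError(f"planted DEG cell type {p.cell_type!r} unknown")
            if p.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {p.condition!r}")
            if not np.isfinite(p.log2fc):
                raise ValueError("planted log2fc must be finite")
        for p in self.planted_lr_pairs:
            for g in (p.ligand, p.receptor):
                if g not in genes:
                    raise ValueError(f"planted LR gene {g!r} not in gene universe")
            if p.sender_ct not in cts or p.receiver_ct not in cts:
                raise ValueError("planted LR cell type unknown")
            if p.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {p.condition!r}")
            if not np.isfinite(p.log2fc):
                raise ValueError("planted log2fc must be finite")
        for m in self.latent_modules:
            for g in list(m.focal_genes) + list(m.target_genes):
                if g not in genes:
                    raise ValueError(f"latent-module gene {g!r} not in gene universe")
            if m.sender_ct not in cts or m.receiver_ct not in cts:
                raise ValueError("latent-module cell type unknown")


@dataclass
class SyntheticTruth:
    """Ledger of every planted effect, for recovery scoring."""

    deg_ledger: list = field(default_factory=list)  # (gene, cell_type, condition, sign)
    lr_ledger: list = field(default_factory=list)
    module_ledger: list = field(default_factory=list)  # dicts with per-individual u_i

    def deg_set(self, cell_type=None, condition=None) -> set:
        out = set()
        for g, ct, cond, sign in self.deg_ledger:
            if cell_type is not None and ct != cell_type:
                continue
            if condition is not None and cond != condition:
                continue
            out.add(g)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "deg_ledger": self.deg_ledger,
                "lr_ledger": self.lr_ledger,
                "module_ledger": self.module_ledger,
            },
            indent=1,
        )


def _condition_mask(ind_table: pd.DataFrame, condition: str) -> pd.Series:
    if condition == "disease":
        return ind_table["disease"] == "COPD"
    if condition == "aging":
        return ind_table["age_group"] == "old"
    if condition == "smoking":
        return ind_table["smoking"] == "AS"
    raise ValueError(f"unknown condition {condition!r}")


def generate_cohort(spec: CohortSpec) -> tuple:
    """Draw a cohort; returns ``(AnnData, SyntheticTruth)``.

    The AnnData is cells x genes (sparse integer counts) with per-cell
    annotations ``individual``, ``cell_type``, ``disease``, ``age_group``,
    ``smoking`` in ``.obs`` and a boolean ``mito`` flag in ``.var``.
    Regeneration with the same spec (including seed) is bit-identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = spec.n_genes
    theta = spec.dispersion

    base_mean = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n_genes)
    )
    base_mean[: spec.n_mito] *= spec.mito_mean_scale

    # planted effects must land on genes the analyses can see: floor the
    # baseline mean of every planted gene at twice the median baseline
    planted_genes = {p.gene for p in spec.planted_degs}
    planted_genes |= {g for p in spec.planted_lr_pairs for g in (p.ligand, p.receptor)}
    for m in spec.latent_modules:
        planted_genes |= set(m.focal_genes) | set(m.target_genes)
    floor = 2.0 * np.exp(spec.baseline_log_mean)
    for g in planted_genes:
        base_mean[gene_idx[g]] = max(base_mean[gene_idx[g]], floor)

    inds = spec.individuals.reset_index(drop=True)
    cond_masks = {c: _condition_mask(inds, c).to_numpy() for c in CONDITIONS}

    # per-module latent values, one scalar per individual
    module_u = []
    for m in spec.latent_modules:
        module_u.append(rng.normal(0.0, 1.0, size=len(inds)))

    obs_rows = []
    blocks = []
    qc_planned = []  # (cell global index, mode)
    lo, hi = spec.cells_per_type_per_individual
    cell_counter = 0
    for i, ind in inds.iterrows():
        for ct in spec.cell_types:
            n_cells = int(rng.integers(lo, hi + 1))
            # log2 effect per gene for this (individual, cell type) block
            lfc = np.zeros(n_genes)
            for p in spec.planted_degs:
                if p.cell_type == ct and cond_masks[p.condition][i]:
                    lfc[gene_idx[p.gene]] += p.log2fc
            for p in spec.planted_lr_pairs:
                if cond_masks[p.condition][i]:
                    if p.sender_ct == ct:
                        lfc[gene_idx[p.ligand]] += p.log2fc
                    if p.receiver_ct == ct:
                        lfc[gene_idx[p.receptor]] += p.log2fc
            for m, u in zip(spec.latent_modules, module_u):
                if m.sender_ct == ct:
                    for g in m.focal_genes:
                        lfc[gene_idx[g]] += m.gamma * u[i]
                if m.receiver_ct == ct:
                    for g in m.target_genes:
                        lfc[gene_idx[g]] += m.gamma * u[i]
            mean = base_mean * np.exp2(lfc)
            lib = np.exp(rng.normal(0.0, spec.libsize_log_sd, size=n_cells))
            # NB via Poisson-Gamma mixture: exact and vectorizes over cells
            lam = rng.gamma(theta, 1.0 / theta, size=(n_cells, n_genes)) * (
                lib[:, None] * mean[None, :]
            )
            counts = rng.poisson(lam)
            blocks.append(counts)
            for k in range(n_cells):
                obs_rows.append(
                    (
                        f"cell_{cell_counter + k:06d}",
                        ind["individual"],
                        ct,
                        ind["disease"],
                        ind["age_group"],
                        ind["smoking"],
                    )
                )
            cell_counter += n_cells

    X = np.concatenate(blocks, axis=0)
    n_cells_total = X.shape[0]

    # plant QC failures: truncate to few expressed genes, or inflate mito
    if spec.qc_failure_fraction > 0:
        n_fail = int(round(spec.qc_failure_fraction * n_cells_total))
        fail_idx = rng.choice(n_cells_total, size=n_fail, replace=False)
        modes = rng.integers(0, 2, size=n_fail)
        for c, mode in zip(fail_idx, modes):
            if mode == 0 or spec.n_mito == 0:  # low-gene failure
                expressed = np.flatnonzero(X[c])
                if expressed.size > 150:
                    drop = rng.choice(expressed, size=expressed.size - 150, replace=False)
                    X[c, drop] = 0
            else:  # mito inflation above the 30% boundary
                non_mito_total = int(X[c, spec.n_mito :].sum())
                target = max(non_mito_total, 50)  # ~50% mito fraction
                extra = rng.multinomial(target, np.ones(spec.n_mito) / spec.n_mito)
                X[c, : spec.n_mito] = extra
            qc_planned.append((int(c), "low_gene" if mode == 0 else "high_mito"))

    obs = pd.DataFrame(
        obs_rows,
        columns=["barcode", "individual", "cell_type", "disease", "age_group", "smoking"],
    ).set_index("barcode")
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = [g.startswith(spec.mito_prefix) for g in genes]

    adata = ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
    adata.uns["qc_planned_failures"] = qc_planned

    truth = SyntheticTruth(
        deg_ledger=[
            (p.gene, p.cell_type, p.condition, "up" if p.log2fc > 0 else "down")
            for p in spec.planted_degs
        ],
        lr_ledger=[dataclasses.astuple(p) for p in spec.planted_lr_pairs],
        module_ledger=[
            {
                "sender_ct": m.sender_ct,
                "focal_genes": list(m.focal_genes),
                "receiver_ct": m.receiver_ct,
                "target_genes": list(m.target_genes),
                "gamma": m.gamma,
                "u": {ind: float(u[i]) for i, ind in enumerate(inds["individual"])},
            }
            for m, u in zip(spec.latent_modules, module_u)
        ],
    )
    return adata, truth


def write_cohort(adata: ad.AnnData, truth: SyntheticTruth, outdir) -> None:
    """Write matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv + cells.tsv
    + truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from scipy.io import mmwrite

    mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(adata.X.T))
    pd.DataFrame(
        {"gene": adata.var_names, "mito": adata.var["mito"].astype(int)}
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    (outdir / "truth.json").write_text(truth.to_json())


def read_cohort(indir) -> ad.AnnData:
    """Read a cohort written by :func:`write_cohort` (or the same dialect)."""
    indir = Path(indir)
    from scipy.io import mmread

    X = sparse.csr_matrix(mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.DataFrame(index=pd.Index(genes["gene"], name="gene"))
    var["mito"] = genes["mito"].astype(bool).to_numpy()
    return ad.AnnData(X=X, obs=obs, var=var)
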