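import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from condcomm.preprocess import QCThresholds, normalize, qc_filter
from condcomm.simulate import (
    CohortSpec,
    LatentModule,
    PlantedDEG,
    PlantedLRPair,
    generate_cohort,
)

# smaller-than-default cohorts keep the suite fast; the generator's
# nine-donor design (3 COPD / 3 old / 3 young, 4 AS / 5 NS) is unchanged
SMALL_CTS = ("monocyte", "AT2", "macrophage", "endothelial_cell", "club_cell")


def make_adata(counts, cell_types=None, individuals=None, mito_flags=None, **obs_extra):
    """Build a minimal annotated count matrix from a dense array (cells x genes)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    obs["cell_type"] = cell_types if cell_types is not None else "typeA"
    obs["individual"] = individuals if individuals is not None else "ind1"
    obs["disease"] = obs_extra.get("disease", "control")
    obs["age_group"] = obs_extra.get("age_group", "young")
    obs["smoking"] = obs_extra.get("smoking", "NS")
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    var["mito"] = mito_flags if mito_flags is not None else [False] * n_genes
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture(scope="session")
def null_cohort():
    spec = CohortSpec(
        cell_types=SMALL_CTS,
        cells_per_type_per_individual=(35, 50),
        n_genes=700,
        n_mito=8,
        seed=11,
    )
    adata, truth = generate_cohort(spec)
    return adata, truth


@pytest.fixture(scope="session")
def null_norm(null_cohort):
    adata, _ = null_cohort
    filtered, _ = qc_filter(adata, QCThresholds())
    return normalize(filtered)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one planted effect of every kind."""
    # balanced directions keep per-cell totals comparable across groups
    degs = [
        PlantedDEG(f"G{50 + i:05d}", "monocyte", "disease", 2.0 if i % 2 else -2.0)
        for i in range(40)
    ]
    degs += [PlantedDEG(f"G{150 + i:05d}", "club_cell", "aging", 2.0) for i in range(5)]
    spec = CohortSpec(
        cell_types=SMALL_CTS,
        cells_per_type_per_individual=(40, 60),
        n_genes=700,
        n_mito=8,
        planted_degs=degs,
        planted_lr_pairs=[
            PlantedLRPair("G00300", "G00301", "monocyte", "AT2", "disease", 2.5)
        ],
        latent_modules=[
            LatentModule(
                "macrophage",
                ("G00400", "G00401"),
                "endothelial_cell",
                ("G00410", "G00411", "G00412"),
                2.0,
            )
        ],
        seed=12,
    )
    adata, truth = generate_cohort(spec)
    return adata, truth


@pytest.fixture(scope="session")
def planted_norm(planted_cohort):
    adata, _ = planted_cohort
    filtered, _ = qc_filter(adata, QCThresholds())
    return normalize(filtered)
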