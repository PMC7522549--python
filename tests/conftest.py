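import numpy as np
import pandas as pd
import pytest

from pashub import differential, integration
from pashub.models import CASE, CONTROL, LAYER_MRNA, LAYER_PROTEIN, ExpressionMatrix, SampleDesign
from pashub.simulate import SimulationConfig, generate_paired_omics


@pytest.fixture
def design10() -> SampleDesign:
    ids = tuple(f"PAS{i}" for i in range(1, 6)) + tuple(f"NPAS{i}" for i in range(1, 6))
    return SampleDesign(ids, (CASE,) * 5 + (CONTROL,) * 5)


@pytest.fixture
def small_config() -> SimulationConfig:
    """Scaled-down study design for fast unit tests (structure preserved)."""
    return SimulationConfig(
        n_mrna=500,
        n_protein=200,
        n_de_mrna=40,
        n_de_protein=25,
        n_hub_consistent=6,
        n_hub_inconsistent=2,
        seed=11,
    )


def _make_matrix(values, design, layer=LAYER_MRNA, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=list(design.sample_ids))
    return ExpressionMatrix(df, layer, design)


@pytest.fixture
def make_matrix():
    return _make_matrix


@pytest.fixture(scope="session")
def full_runs():
    """Three full-size simulated datasets pushed through both DE layers.

    Shared by the recovery and calibration checks so the expensive runs
    happen once per session.
    """
    runs = []
    for seed in (1, 2, 3):
        cfg = SimulationConfig(seed=seed)
        mrna, protein, truth = generate_paired_omics(cfg)
        de_mrna = differential.run_differential(mrna)
        de_protein = differential.run_differential(protein)
        consistent, inconsistent = integration.select_hub_genes(de_mrna, de_protein)
        runs.append(
            {
                "config": cfg,
                "mrna": mrna,
                "protein": protein,
                "truth": truth,
                "de_mrna": de_mrna,
                "de_protein": de_protein,
                "consistent": consistent,
                "inconsistent": inconsistent,
            }
        )
    return runs
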