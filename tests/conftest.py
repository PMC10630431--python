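import numpy as np
import pandas as pd
import pytest

from nichescape import (
    CellTable,
    PlantedMarker,
    default_niche_bank,
    init_field,
    simulate_tissue,
    synth_cells_from_field,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def bank():
    return default_niche_bank()


@pytest.fixture(scope="session")
def field25():
    """One converged 4-niche tissue field with symmetric initial prevalences."""
    field = simulate_tissue(init_field(4, 0.25, seed=42))
    assert field.converged
    return field


@pytest.fixture(scope="session")
def dense_bank(bank):
    """Niche bank with the same structure at 8x density, for cell-level
    synthesis where kernel compositions must be well determined."""
    from nichescape import NicheBank

    return NicheBank(bank.B * 8, bank.cell_types, bank.niche_names)


@pytest.fixture(scope="session")
def synth_table(field25, dense_bank):
    """Synthetic cell table with planted marker-context associations.

    Markers: 'm_tls' rises with the TLS niche weight in CD4-T cells,
    'm_iface' with the cancer×inflammatory interface weight in
    macrophages, and 'm_null' is pure noise everywhere.
    """
    planted = [
        PlantedMarker("CD4-T", "m_tls", ("niche", 3), slope=1.0, noise_sd=0.1),
        PlantedMarker("Macrophage", "m_iface", ("interface", 0, 2), slope=4.0, noise_sd=0.1),
    ]
    table, truth = synth_cells_from_field(
        field25, dense_bank, planted=planted, extra_markers=["m_null"], seed=7
    )
    return table, truth


@pytest.fixture
def toy_cells():
    """Tiny two-sample cell table with two marker columns."""
    df = pd.DataFrame(
        {
            "sample_id": ["s1"] * 4 + ["s2"] * 3,
            "x": [10.0, 20.0, 30.0, 40.0, 15.0, 25.0, 35.0],
            "y": [10.0, 20.0, 30.0, 40.0, 15.0, 25.0, 35.0],
            "cell_type": ["A", "B", "A", "B", "A", "A", "B"],
            "CD45": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
            "PDL1": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7],
        }
    )
    return CellTable(
        df,
        marker_roles={"lineage": ["CD45"], "phenotypic": ["PDL1"]},
        extents={"s1": (100.0, 100.0), "s2": (100.0, 100.0)},
    )
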