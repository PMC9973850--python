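import pandas as pd
import pytest

from phyletic import (UniverseConfig, end_to_end_recovery, generate_universe,
                      load_taxonomy_index, plant_transfer_series)

DIVERGENCES = (0, 5, 10, 15, 20, 25, 30)


def taxonomy_frame(n_species=5, n_genus_other=8, n_family_other=20):
    """Taxonomy table: query + species-mates + genus-others + family-others."""
    rows = [{"accession": "QRY", "species_id": "s0", "genus_id": "g0",
             "family_id": "f0"}]
    rows += [{"accession": f"S{i}", "species_id": "s0", "genus_id": "g0",
              "family_id": "f0"} for i in range(n_species)]
    rows += [{"accession": f"G{i}", "species_id": f"s{i + 1}", "genus_id": "g0",
              "family_id": "f0"} for i in range(n_genus_other)]
    rows += [{"accession": f"F{i}", "species_id": f"sx{i}",
              "genus_id": f"g{i + 1}", "family_id": "f0"}
             for i in range(n_family_other)]
    return pd.DataFrame(rows)


@pytest.fixture
def small_index():
    return load_taxonomy_index(taxonomy_frame())


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale universe for fast pipeline tests."""
    return UniverseConfig(n_species_mates=4, n_genus_other=4, n_family_other=5,
                          genes_per_genome=8, gene_length=60, seed=7)


@pytest.fixture(scope="session")
def planted_recovery():
    """Default-condition universe with transfers planted at 0–30 % divergence,
    run once through the full mock pipeline (shared: the run is the expensive
    part)."""
    universe = generate_universe(UniverseConfig(seed=11))
    universe, events = plant_transfer_series(universe, divergences=DIVERGENCES,
                                             genes_per_divergence=3)
    cm, results = end_to_end_recovery(universe)
    return universe, events, cm, results
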