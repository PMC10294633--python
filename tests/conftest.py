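import pandas as pd
import pytest

from bdellosim import GeneratorConfig, load_prey_params


@pytest.fixture(scope="session")
def pm_params():
    return load_prey_params("P_mirabilis")


@pytest.fixture(scope="session")
def all_params():
    return {sp: load_prey_params(sp)
            for sp in ("P_mirabilis", "S_enterica", "S_flexneri", "E_coli")}


@pytest.fixture(scope="session")
def pm_event_table(pm_params):
    """Default synthetic P. mirabilis event table, n=100, fixed seed."""
    from bdellosim import gen_event_table
    cfg = GeneratorConfig(species=["P_mirabilis"], n_cells=100, seed=1)
    return gen_event_table(cfg, pm_params)


@pytest.fixture
def hand_event_table():
    """Three cells with manually chosen values for spreadsheet-style oracles."""
    return pd.DataFrame({
        "cell_id": ["c1", "c2", "c3"],
        "species": ["P_mirabilis"] * 3,
        "t_dnaN1": [40.0, 46.0, 52.0],
        "t_parB2": [60.0, 70.0, 80.0],
        "t_release": [240.0, 252.0, 264.0],
        "progeny_count": [2, 2, 2],
        "progeny_lengths": [[1.2, 1.3], [1.25, 1.25], [1.1, 1.4]],
    })
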