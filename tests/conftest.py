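import numpy as np
import pandas as pd
import pytest

from occutrends.dataprep import standardize_covariates
from occutrends.occupancy import fit_species, occupancy_trajectory
from occutrends.synth import SimConfig, generate_covariates, simulate_detection_history


@pytest.fixture(scope="session")
def study():
    """A small simulated museum study shared across test modules."""
    cfg = SimConfig(n_species=10, n_regions=3, n_years=80, start_year=1940,
                    seed=11)
    cov = generate_covariates(cfg)
    data, truth = simulate_detection_history(cfg, cov)
    std = standardize_covariates(cov, data.effort)
    return {"cfg": cfg, "cov": cov, "data": data, "truth": truth, "std": std}


@pytest.fixture(scope="session")
def fitted_study(study):
    """The same study with per-species selected fits and trajectories."""
    data, cov, std = study["data"], study["cov"], study["std"]
    fits, trajs = {}, {}
    for i, sp in enumerate(data.species):
        best, _ = fit_species(data, cov, std, sp, n_restarts=2, seed=100 + i)
        fits[sp] = best
        trajs[sp] = occupancy_trajectory(best, burn_in_years=4)
    return {**study, "fits": fits, "trajectories": trajs}


@pytest.fixture
def tiny_records():
    """Hand-built record table: two regions, three years, two species."""
    rows = [
        ("A", 1, 1900, "Tax"),
        ("A", 1, 1900, "Tax"),  # two records of A in (1, 1900)
        ("A", 2, 1901, "Tax"),
        ("B", 1, 1901, "Tax"),
        ("B", 1, 1902, "Tax"),
    ]
    return pd.DataFrame(rows, columns=["species", "region", "year", "taxon"])


@pytest.fixture(scope="session")
def traits_frame(study):
    truth = study["truth"]
    return pd.DataFrame({
        "species": [sp.name for sp in truth.species_params],
        "endemism": [sp.endemism for sp in truth.species_params],
        "habitat": [sp.habitat for sp in truth.species_params],
        "host_plant": [sp.host_plant for sp in truth.species_params],
    }).set_index("species")
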