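"""Generate a synthetic museum-record study and inspect its structure.

Builds the three input CSVs (records, covariates, traits) plus latent truth
from a known dynamic occupancy process, then shows how sparse and bursty the
resulting record table is — the situation a museum-collection analysis faces.
"""

import numpy as np
import pandas as pd

from occutrends import SimConfig, generate_study

cfg = SimConfig(n_species=15, n_regions=3, n_years=170, start_year=1853,
                seed=42)
paths = generate_study(cfg, "scratch/example_study")

records = pd.read_csv(paths["records"])
print(f"records written: {len(records)} rows, "
      f"{records['species'].nunique()} species names, "
      f"{records['year'].nunique()} distinct years of {cfg.n_years}")

per_cell = records.groupby(["region", "year"]).size()
print(f"surveyed region-years: {len(per_cell)} of {cfg.n_regions * cfg.n_years} "
      f"({100 * len(per_cell) / (cfg.n_regions * cfg.n_years):.0f}%)")
print(f"records per surveyed region-year: median {per_cell.median():.0f}, "
      f"max {per_cell.max()} (expedition bursts)")

truth = pd.read_csv(paths["truth_richness"])
first = truth[truth["year"] == cfg.start_year]["expected_richness"].mean()
last = truth[truth["year"] == cfg.start_year + cfg.n_years - 1][
    "expected_richness"].mean()
print(f"true expected richness: {first:.1f} (first year) -> {last:.1f} "
      f"(last year), out of {cfg.n_species} species")
# Most region-years carry no records at all, yet the latent richness the
# estimators must recover is defined in every year - that gap is the problem
# the occupancy model solves.
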