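"""Reference catalog of the global pollination-network survey.

Bundled descriptive records of the survey this pipeline operationalizes:
the per-location exotic plant records (species, location where exotic, number
of networks observed in) and the survey's composition counts.  Summaries are
computed from the bundled table at call time, never hard-coded.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_exotic_records",
    "invaded_network_distribution",
    "survey_network_counts",
    "total_exotic_occurrences",
    "n_invaded_networks",
    "n_unique_exotic_species",
    "total_record_networks",
]

#: number of invaded networks by how many exotic plant species each contains
INVADED_NETWORK_DISTRIBUTION: dict[int, int] = {1: 13, 2: 7, 3: 1, 4: 3, 6: 1}

#: survey composition: networks with presence/absence vs visit-count data
SURVEY_NETWORK_COUNTS: dict[str, int] = {"qualitative": 39, "quantitative": 20}


def load_exotic_records() -> pd.DataFrame:
    """The bundled exotic plant records table (species, location, n_networks)."""
    with resources.files("pollinet.data").joinpath(
        "exotic_plant_records.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def invaded_network_distribution() -> dict[int, int]:
    return dict(INVADED_NETWORK_DISTRIBUTION)


def survey_network_counts() -> dict[str, int]:
    return dict(SURVEY_NETWORK_COUNTS)


def total_exotic_occurrences(distribution: dict[int, int] | None = None) -> int:
    """Exotic species occurrences summed over the invaded-network distribution."""
    dist = distribution or invaded_network_distribution()
    return sum(k * n for k, n in dist.items())


def n_invaded_networks(distribution: dict[int, int] | None = None) -> int:
    dist = distribution or invaded_network_distribution()
    return sum(dist.values())


def n_unique_exotic_species(records: pd.DataFrame | None = None) -> int:
    """Distinct species names among the exotic records."""
    table = records if records is not None else load_exotic_records()
    return int(table["species"].nunique())


def total_record_networks(records: pd.DataFrame | None = None) -> int:
    """Sum of the per-record network counts."""
    table = records if records is not None else load_exotic_records()
    return int(table["n_networks"].sum())
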