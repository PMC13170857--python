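"""Packaged reference data.

``load_fjord_overview`` returns the published per-site overview of a
17-assemblage faunal dataset from a former fjord on Lolland, Denmark
(Late Mesolithic to Bronze Age): per site the MNI excluding fish, the
total NISP, and NISP per taxonomic class. The table is class-level only
— species-level counts live in that study's supplementary files, which
are not redistributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assemblage import AssemblageTable, table_from_records
from .feri import TraitMap

__all__ = ["load_fjord_overview", "fjord_overview_to_assemblage", "default_trait_map"]

_CLASS_COLUMNS = {
    "nisp_amphibians": "amphibian",
    "nisp_birds": "bird",
    "nisp_crustaceans": "crustacean",
    "nisp_fish": "fish",
    "nisp_mammals": "mammal",
    "nisp_marine_mammals": "marine mammal",
    "nisp_reptiles": "reptile",
}


def _data_path(name: str):
    return resources.files("zooarch.data").joinpath(name)


def load_fjord_overview() -> pd.DataFrame:
    """Per-site overview: mni_excl_fish, nisp_total, and NISP per class."""
    with resources.as_file(_data_path("fjord_site_overview.csv")) as p:
        return pd.read_csv(p)


def fjord_overview_to_assemblage(overview: pd.DataFrame | None = None) -> AssemblageTable:
    """Re-encode the class-level overview as a long assemblage table.

    Each (site, class) cell with a positive NISP becomes one record whose
    taxon/family/group labels all carry the class name — the overview has
    no finer resolution, so per-record MNI is left at 0 (unknown) and the
    per-site MNI total stays in the overview frame.
    """
    df = load_fjord_overview() if overview is None else overview
    records = []
    for row in df.itertuples():
        for col, cls in _CLASS_COLUMNS.items():
            count = int(getattr(row, col))
            if count <= 0:
                continue
            records.append(
                dict(
                    site_id=row.site_id,
                    site_name=row.site_name,
                    taxon=f"{cls} (class-level)",
                    tax_class=cls,
                    tax_family=f"{cls} (class-level)",
                    tax_group=f"{cls} (class-level)",
                    nisp=count,
                    mni=0,
                    biome="unknown",
                )
            )
    return table_from_records(records, provenance="packaged fjord overview")


def default_trait_map() -> TraitMap:
    """The shipped default fish salinity/sediment trait map."""
    with resources.as_file(_data_path("default_fish_traits.yaml")) as p:
        return TraitMap.from_yaml(p)
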