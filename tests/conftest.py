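import numpy as np
import pandas as pd
import pytest

from zooarch.assemblage import BIOME_VOCABULARY, AssemblageTable, table_from_records
from zooarch.chronology import CalibrationCurve


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_assemblage(rng, n_sites=4, n_taxa=8, max_count=200) -> AssemblageTable:
    """Random but schema-valid long-format table."""
    classes = ["fish", "mammal", "bird"]
    biomes = sorted(BIOME_VOCABULARY)
    records = []
    for s in range(n_sites):
        for t in range(n_taxa):
            nisp = int(rng.integers(0, max_count))
            if nisp == 0:
                continue
            records.append(
                dict(
                    site_id=f"S{s:02d}",
                    site_name=f"Site {s}",
                    taxon=f"taxon_{t}",
                    tax_class=classes[t % 3],
                    tax_family=f"family_{t % 4}",
                    tax_group=f"group_{t % 5}",
                    nisp=nisp,
                    mni=int(rng.integers(1, nisp + 1)),
                    biome=biomes[t % len(biomes)],
                )
            )
    return table_from_records(records)


@pytest.fixture
def small_table(rng):
    return random_assemblage(rng)


@pytest.fixture
def identity_curve():
    """Calibration curve where 14C age equals calendar age, zero curve error.

    curve_sigma must stay positive for the normal density; use a value
    that is negligible against any realistic lab error.
    """
    cal = np.arange(3000.0, 7001.0, 1.0)
    return CalibrationCurve(cal, cal.copy(), np.full_like(cal, 1e-6))


@pytest.fixture
def wiggly_curve():
    cal = np.arange(2000.0, 8001.0, 5.0)
    c14 = cal + 40 * np.sin(cal / 150.0) + 15 * np.cos(cal / 57.0)
    sig = 8.0 + 3.0 * np.sin(cal / 90.0) ** 2
    return CalibrationCurve(cal, c14, sig)
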